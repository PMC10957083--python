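"""Synthetic acute-toxicity data with the reference study's structure.

The generator emulates the bench design end to end: a 5-level
single-toxicant series and 12-level fixed-ratio mixture series, 10
animals per group and 3 replicates per level, with deaths drawn
binomially from a known true concentration-response curve (single
toxicants) or from a CA/IA truth model (mixtures).  The default true
curves are the bundled reference fits, so synthetic datasets look like
the study out of the box.

All randomness flows through numpy's SeedSequence: a dataset is fully
determined by (config, seed, component/ray, time).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import datasets
from .design import MixtureRay
from .families import get_family
from .records import DoseResponseRecord

__all__ = ["TrueCRC", "SyntheticStudyConfig", "simulate_single", "simulate_mixture"]


@dataclass(frozen=True)
class TrueCRC:
    """A known concentration-response curve used as simulation truth.

    Exposes ``predict``/``inverse`` so the mixture reference models accept
    a truth curve anywhere they accept a fitted one.
    """

    family: str
    alpha: float
    beta: float
    gamma: float | None = None

    def _params(self) -> np.ndarray:
        fam = get_family(self.family)
        if fam.n_params == 3:
            return np.array([self.alpha, self.beta, self.gamma], dtype=float)
        return np.array([self.alpha, self.beta], dtype=float)

    def predict(self, x) -> np.ndarray:
        return get_family(self.family).evaluate(x, self._params())

    def inverse(self, Y):
        return get_family(self.family).inverse(Y, self._params())


def _default_truth() -> dict[tuple[str, int], TrueCRC]:
    return {
        key: TrueCRC(ref["family"], ref["alpha"], ref["beta"], ref["gamma"])
        for key, ref in datasets.REFERENCE_FITS.items()
    }


@dataclass
class SyntheticStudyConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the reference bench design: 10 animals per exposure
    group, 3 replicates, 5 single-toxicant levels (the published design
    concentrations) and 12 mixture dilution levels.
    """

    truth: dict[tuple[str, int], TrueCRC] = field(default_factory=_default_truth)
    truth_model: str = "ca"
    single_concentrations: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(datasets.SINGLE_CONCENTRATIONS))
    n_exposed: int = 10
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exposed < 1:
            raise ValueError("n_exposed must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.truth_model not in ("ca", "ia"):
            raise ValueError("truth_model must be 'ca' or 'ia'")
        for concs in self.single_concentrations.values():
            if any(c <= 0 for c in concs):
                raise ValueError("single-series concentrations must be positive")

    def true_crc(self, component: str, time_h: float) -> TrueCRC:
        try:
            return self.truth[(component, int(time_h))]
        except KeyError:
            raise ValueError(
                f"no true curve configured for {component!r} at {time_h} h"
            ) from None


def _rng(config: SyntheticStudyConfig, tag: str, time_h: float) -> np.random.Generator:
    # stable child stream per (seed, tag, time); crc32 keeps tags text-stable
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(tag.encode()), int(time_h)]))


def _draw(rng, config, ids, concs, effect, time_h) -> list[DoseResponseRecord]:
    effect = min(max(float(effect), 0.0), 1.0)
    return [
        DoseResponseRecord(
            component_ids=ids, concentrations=concs, time_h=float(time_h),
            n_exposed=config.n_exposed,
            n_dead=int(rng.binomial(config.n_exposed, effect)),
            replicate=rep,
        )
        for rep in range(1, config.replicates + 1)
    ]


def simulate_single(config: SyntheticStudyConfig, component: str,
                    time_h: float = 96) -> list[DoseResponseRecord]:
    """Binomial mortality for one toxicant's concentration series."""
    crc = config.true_crc(component, time_h)
    concs = config.single_concentrations[component]
    rng = _rng(config, f"single:{component}", time_h)
    records: list[DoseResponseRecord] = []
    for x in concs:
        effect = float(crc.predict(np.array([x]))[0])
        records.extend(_draw(rng, config, (component,), (x,), effect, time_h))
    return records


def _mixture_truth_effect(config: SyntheticStudyConfig, ray: MixtureRay,
                          concs: Sequence[float], time_h: float) -> float:
    from .mixture import ca_effect, ia_effect  # local import avoids a cycle
    crcs = [config.true_crc(c, time_h) for c in ray.component_ids]
    fn = ca_effect if config.truth_model == "ca" else ia_effect
    return fn(list(concs), crcs)


def simulate_mixture(config: SyntheticStudyConfig, ray: MixtureRay,
                     time_h: float = 96) -> list[DoseResponseRecord]:
    """Binomial mortality along a fixed-ratio mixture dilution series.

    The per-level true effect comes from the configured truth model (CA
    or IA) applied to the components' true curves at the level's
    component concentrations.
    """
    if not ray.series:
        raise ValueError("ray has an empty dilution series; run frrd_series first")
    rng = _rng(config, f"mixture:{ray.design}", time_h)
    records: list[DoseResponseRecord] = []
    for total, concs in zip(ray.series, ray.component_concentrations()):
        effect = _mixture_truth_effect(config, ray, concs, time_h)
        records.extend(_draw(rng, config, ray.component_ids, tuple(concs),
                             effect, time_h))
    return records
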