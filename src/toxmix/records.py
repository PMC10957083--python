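"""Domain records shared across the package.

A bioassay exposes groups of animals to one or two toxicants at known
concentrations and counts deaths after a fixed exposure time.  Everything
downstream — curve fitting, effect-concentration estimation, mixture
modelling — consumes lists of :class:`DoseResponseRecord` or the pooled
(concentration, mortality-fraction) arrays derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseRecord",
    "FitQuality",
    "EffectConcentration",
    "InteractionResult",
    "records_to_frame",
    "frame_to_records",
    "pool_records",
]


@dataclass(frozen=True)
class DoseResponseRecord:
    """One exposure group: who was dosed with what, and how many died.

    Parameters
    ----------
    component_ids : list of str
        Toxicant names; length 1 for a single-toxicant group, 2 for a
        binary mixture.
    concentrations : list of float
        As-dosed concentration of each component, mg/L (same order as
        ``component_ids``).
    time_h : float
        Exposure time in hours.  Census times of 24/48/72/96 h are the
        convention for acute assays but any positive time is accepted.
    n_exposed, n_dead : int
        Animals at risk and deaths observed in this group.
    replicate : int
        Replicate index (1-based by convention).
    """

    component_ids: tuple[str, ...]
    concentrations: tuple[float, ...]
    time_h: float
    n_exposed: int
    n_dead: int
    replicate: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "component_ids", tuple(self.component_ids))
        object.__setattr__(self, "concentrations", tuple(float(c) for c in self.concentrations))
        if len(self.component_ids) != len(self.concentrations):
            raise ValueError("component_ids and concentrations must have equal length")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        if self.time_h <= 0:
            raise ValueError("time_h must be positive")
        if not (0 <= self.n_dead <= self.n_exposed):
            raise ValueError(f"need 0 <= n_dead <= n_exposed, got {self.n_dead}/{self.n_exposed}")
        if self.n_exposed < 1:
            raise ValueError("n_exposed must be >= 1")

    @property
    def total_concentration(self) -> float:
        return float(sum(self.concentrations))

    @property
    def mortality(self) -> float:
        """Observed mortality fraction in this group."""
        return self.n_dead / self.n_exposed


class FitQuality(NamedTuple):
    """Goodness-of-fit triple on the mortality-fraction scale.

    ``r2`` is the coefficient of determination, ``mse`` the mean of squared
    errors and ``mae`` the mean absolute error.
    """

    r2: float
    mse: float
    mae: float


@dataclass(frozen=True)
class EffectConcentration:
    """An LCx estimate with its confidence interval.

    ``ci_low <= ci_high`` always holds; the point estimate is not forced
    inside the interval because band-inversion intervals are asymmetric
    and, for reported/rounded values, may not bracket the point exactly.
    """

    level_p: float
    value: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.level_p < 1:
            raise ValueError("level_p must lie in (0, 1)")
        if self.value <= 0:
            raise ValueError("effect concentration must be positive")
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")

    @property
    def name(self) -> str:
        return f"LC{round(self.level_p * 100):d}"


@dataclass(frozen=True)
class InteractionResult:
    """Synergistic-ratio classification for one mixture component.

    ``sr = single_lc50 / mixture_lc50``; values above 1 mean the mixture is
    more lethal than the component alone (synergism), below 1 antagonism.
    """

    component_id: str
    single_lc50: float
    mixture_lc50: float
    sr: float
    label: str

    def __post_init__(self) -> None:
        if self.sr <= 0:
            raise ValueError("sr must be positive")
        if self.label not in ("antagonistic", "additive", "synergistic"):
            raise ValueError(f"unknown interaction label {self.label!r}")


_FRAME_COLUMNS = [
    "component_a", "conc_a_mg_L", "component_b", "conc_b_mg_L",
    "time_h", "n_exposed", "n_dead", "replicate",
]


def records_to_frame(records: Sequence[DoseResponseRecord]) -> pd.DataFrame:
    """Flatten records into the package's single CSV schema.

    Mixture rows fill both component columns; single-toxicant rows leave
    the second pair empty.
    """
    rows = []
    for r in records:
        comp_b = r.component_ids[1] if len(r.component_ids) > 1 else ""
        conc_b = r.concentrations[1] if len(r.concentrations) > 1 else np.nan
        rows.append({
            "component_a": r.component_ids[0],
            "conc_a_mg_L": r.concentrations[0],
            "component_b": comp_b,
            "conc_b_mg_L": conc_b,
            "time_h": r.time_h,
            "n_exposed": r.n_exposed,
            "n_dead": r.n_dead,
            "replicate": r.replicate,
        })
    return pd.DataFrame(rows, columns=_FRAME_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[DoseResponseRecord]:
    """Inverse of :func:`records_to_frame`, with per-row validation."""
    missing = [c for c in _FRAME_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing schema columns: {missing}")
    records: list[DoseResponseRecord] = []
    errors: list[str] = []
    for i, row in frame.iterrows():
        comp_b = row["component_b"]
        has_b = isinstance(comp_b, str) and comp_b != "" and not pd.isna(row["conc_b_mg_L"])
        ids = (str(row["component_a"]),) + ((str(comp_b),) if has_b else ())
        concs = (float(row["conc_a_mg_L"]),) + ((float(row["conc_b_mg_L"]),) if has_b else ())
        try:
            records.append(DoseResponseRecord(
                component_ids=ids,
                concentrations=concs,
                time_h=float(row["time_h"]),
                n_exposed=int(row["n_exposed"]),
                n_dead=int(row["n_dead"]),
                replicate=int(row["replicate"]),
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError("malformed mortality rows:\n" + "\n".join(errors))
    return records


def pool_records(
    records: Sequence[DoseResponseRecord], use_total: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Pool replicates: mean mortality fraction per distinct concentration.

    Returns sorted arrays ``(x, y)`` where ``x`` is the (total)
    concentration in mg/L and ``y`` the replicate-mean mortality fraction.
    """
    if not records:
        raise ValueError("no records to pool")
    by_conc: dict[float, list[float]] = {}
    for r in records:
        key = r.total_concentration if use_total else r.concentrations[0]
        by_conc.setdefault(round(key, 12), []).append(r.mortality)
    xs = np.array(sorted(by_conc))
    ys = np.array([float(np.mean(by_conc[x])) for x in xs])
    return xs, ys
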