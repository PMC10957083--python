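"""Binary-mixture experimental designs.

Two standard ways of choosing the mass ratio of a two-component mixture:

* EECR (equi-effect concentration ratio): components are mixed in
  proportion to a common effect concentration, e.g. their LC50s, so each
  contributes the same nominal effect at the top concentration.
* EquRay (direct equipartition ray): the segment joining the two
  components' LC50 intercepts on the concentration axes is divided into
  equidistant points; each point defines one fixed-ratio ray.

A ray is then turned into an exposure series by fixed-ratio serial
dilution (FRRD): the total concentration is diluted geometrically while
the component ratio is held constant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["MixtureRay", "eecr_ray", "equray_rays", "frrd_series"]


@dataclass(frozen=True)
class MixtureRay:
    """A fixed mass-fraction ratio of two components plus its dilutions.

    ``fractions`` are mass fractions of total concentration and sum to 1;
    ``series`` holds total concentrations (mg/L), strictly decreasing.
    """

    component_ids: tuple[str, str]
    fractions: tuple[float, float]
    design: str
    series: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "fractions", fr)
        object.__setattr__(self, "component_ids", tuple(self.component_ids))
        object.__setattr__(self, "series", tuple(float(s) for s in self.series))
        if len(fr) != 2 or not all(0 < f < 1 for f in fr):
            raise ValueError("fractions must be two values strictly inside (0, 1)")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if any(s2 >= s1 for s1, s2 in zip(self.series, self.series[1:])):
            raise ValueError("series must be strictly decreasing")

    def component_concentrations(self) -> np.ndarray:
        """Per-level (n_levels, 2) component concentrations in mg/L."""
        return np.outer(np.asarray(self.series), np.asarray(self.fractions))


def eecr_ray(
    lcp_a: float,
    lcp_b: float,
    label: str = "EECR 50",
    components: tuple[str, str] = ("A", "B"),
) -> MixtureRay:
    """Equi-effect ratio ray: mix in proportion to a shared LCp.

    The fractions are lcp_a/(lcp_a+lcp_b) and lcp_b/(lcp_a+lcp_b); the
    defining top concentration of the series is their sum.
    """
    if lcp_a <= 0 or lcp_b <= 0:
        raise ValueError("effect concentrations must be positive")
    total = lcp_a + lcp_b
    return MixtureRay(components, (lcp_a / total, lcp_b / total), label, (total,))


def equray_rays(
    lc50_a: float,
    lc50_b: float,
    n_rays: int = 5,
    components: tuple[str, str] = ("A", "B"),
    text_indexing: bool = False,
) -> list[MixtureRay]:
    """Equipartition rays between the two single-agent LC50 intercepts.

    Ray i (1-based) mixes (n+1−i)/(n+1) of component a's LC50 with
    i/(n+1) of component b's LC50, so component a's share falls as the
    index rises.  ``text_indexing=True`` flips the direction (ray i gets
    i/(n+1) of component a), the alternative convention seen in prose
    descriptions of the design.
    """
    if lc50_a <= 0 or lc50_b <= 0:
        raise ValueError("LC50 values must be positive")
    if n_rays < 1:
        raise ValueError("n_rays must be >= 1")
    rays = []
    for i in range(1, n_rays + 1):
        w = i if text_indexing else n_rays + 1 - i
        amount_a = w / (n_rays + 1) * lc50_a
        amount_b = (n_rays + 1 - w) / (n_rays + 1) * lc50_b
        total = amount_a + amount_b
        rays.append(MixtureRay(
            components, (amount_a / total, amount_b / total),
            f"EquRay {i}", (total,),
        ))
    return rays


def frrd_series(ray: MixtureRay, n_levels: int = 12, dilution_factor: float = 2.0,
                top: float | None = None) -> MixtureRay:
    """Fill a ray's dilution series: top / factor^k for k = 0..n_levels−1.

    ``top`` defaults to the ray's defining total concentration (its first
    series entry).  Component ratios are preserved exactly at every level.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    if top is None:
        if not ray.series:
            raise ValueError("ray has no defining top concentration; pass top=")
        top = ray.series[0]
    if top <= 0:
        raise ValueError("top concentration must be positive")
    series = tuple(top / dilution_factor**k for k in range(n_levels))
    return replace(ray, series=series)
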