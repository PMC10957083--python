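"""Mixture-toxicity reference models and interaction classification.

Two classical null models predict a mixture's effect from its components'
single-agent concentration-response curves:

* Concentration addition (CA, Loewe additivity): components act as
  dilutions of one another.  A mixture at mass fractions f_i has
  LCp_mix = 1 / Σ_i (f_i / LCp_i), the fraction-weighted harmonic mean of
  the component LCps.  Equivalently, the mixture effect at component
  concentrations c_i is the level p at which the toxic units
  Σ_i c_i / LCp_i(p) sum to one.
* Independent action (IA, response addition): components act through
  unrelated mechanisms and effects combine as E = 1 − Π_i (1 − f_i(c_i)).

Departure from additivity is quantified by the synergistic ratio
SR = C_i / E_i (single-agent LC50 over mixture LC50): SR > 1 synergism,
SR < 1 antagonism, SR = 1 additivity (up to a configurable tolerance).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .crc import CRCRegressor, fit_metrics
from .design import MixtureRay
from .records import FitQuality, InteractionResult

__all__ = [
    "ca_effect_concentration",
    "ca_effect",
    "ia_effect",
    "ia_effect_concentration",
    "synergistic_ratio",
    "compare_models",
    "predict_ray_effects",
]

_P_EPS = 1e-9


def ca_effect_concentration(fractions: Sequence[float], component_lcps: Sequence[float],
                            p: float = 0.5) -> float:
    """Mixture LCp under concentration addition.

    ``component_lcps`` are the single-agent LCp values at the same effect
    level ``p``; the result is their fraction-weighted harmonic mean,
    1 / Σ (f_i / LCp_i).
    """
    fr = np.asarray(fractions, dtype=float)
    lcps = np.asarray(component_lcps, dtype=float)
    if fr.shape != lcps.shape:
        raise ValueError("fractions and component_lcps must have equal length")
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if np.any(lcps <= 0):
        raise ValueError("component LCp values must be positive")
    if not 0 < p < 1:
        raise ValueError("effect level p must lie in (0, 1)")
    return float(1.0 / np.sum(fr / lcps))


def _single_effect(fit: CRCRegressor, c: float) -> float:
    return float(fit.predict(np.array([c]))[0]) if c > 0 else 0.0


def ca_effect(component_concs: Sequence[float], fits: Sequence[CRCRegressor]) -> float:
    """Mixture effect fraction under CA at given component concentrations.

    Solves Σ_i c_i / LCp_i(p) = 1 for the effect level p; the toxic-unit
    sum is monotone decreasing in p, so the root is unique.
    """
    concs = np.asarray(component_concs, dtype=float)
    if len(concs) != len(fits):
        raise ValueError("one fitted curve per component is required")
    if np.any(concs < 0):
        raise ValueError("concentrations must be non-negative")
    active = [(c, f) for c, f in zip(concs, fits) if c > 0]
    if not active:
        return 0.0

    def toxic_units(p):
        return sum(c / float(f.inverse(p)) for c, f in active) - 1.0

    # restrict to effect levels every component can attain: curves with a
    # positive zero-dose baseline (BCW, gamma > 0) or a ceiling below 1
    # (BCW, gamma < 0) have no inverse outside [f(0+), f(inf)]
    with np.errstate(over="ignore", under="ignore"):
        p_lo = max([_P_EPS] + [float(f.predict(np.array([1e-12]))[0]) + 1e-9
                               for _, f in active])
        p_hi = min([1 - _P_EPS] + [float(f.predict(np.array([1e12]))[0]) - 1e-9
                                   for _, f in active])
    if p_lo >= p_hi:
        raise ValueError("component curves have no common attainable effect range")
    if toxic_units(p_lo) < 0:   # below one toxic unit even at the lowest level
        return 0.0 if p_lo <= 2 * _P_EPS else p_lo
    if toxic_units(p_hi) > 0:   # above one toxic unit at the highest level
        return 1.0 if p_hi >= 1 - 2 * _P_EPS else p_hi
    return float(brentq(toxic_units, p_lo, p_hi, xtol=1e-12))


def ia_effect(component_concs: Sequence[float], fits: Sequence[CRCRegressor]) -> float:
    """Mixture effect under independent action: 1 − Π (1 − f_i(c_i))."""
    concs = np.asarray(component_concs, dtype=float)
    if len(concs) != len(fits):
        raise ValueError("one fitted curve per component is required")
    if np.any(concs < 0):
        raise ValueError("concentrations must be non-negative")
    survive = 1.0
    for c, fit in zip(concs, fits):
        survive *= 1.0 - _single_effect(fit, float(c))
    return 1.0 - survive


def ia_effect_concentration(ray: MixtureRay, fits: Sequence[CRCRegressor],
                            p: float) -> float:
    """Total concentration along a ray at which the IA effect equals p."""
    if not 0 < p < 1:
        raise ValueError("effect level p must lie in (0, 1)")
    fr = np.asarray(ray.fractions)

    def g(T):
        return ia_effect(fr * T, fits) - p

    lo, hi = 1e-9, 1.0
    for _ in range(64):
        if g(hi) > 0:
            break
        hi *= 4.0
    else:
        raise ValueError("IA effect never reaches p on the searched range")
    if g(lo) > 0:
        raise ValueError("IA effect already exceeds p at a vanishing concentration")
    return float(brentq(g, lo, hi, rtol=1e-9))


def synergistic_ratio(single_lc50: float, mixture_lc50: float,
                      component_id: str = "", tolerance: float = 0.05) -> InteractionResult:
    """Classify an interaction from the SR = single LC50 / mixture LC50.

    ``tolerance`` is the half-width of the additive band around SR = 1;
    0 reproduces the strict rule (additive only at exact equality).
    """
    if single_lc50 <= 0 or mixture_lc50 <= 0:
        raise ValueError("LC50 values must be positive")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    sr = single_lc50 / mixture_lc50
    if abs(sr - 1.0) <= tolerance:
        label = "additive"
    elif sr < 1.0:
        label = "antagonistic"
    else:
        label = "synergistic"
    return InteractionResult(component_id, single_lc50, mixture_lc50, sr, label)


def predict_ray_effects(ray: MixtureRay, fits: Sequence[CRCRegressor],
                        model: str, totals: Sequence[float]) -> np.ndarray:
    """Predicted effect fractions along a ray at given total concentrations."""
    fr = np.asarray(ray.fractions)
    totals = np.asarray(totals, dtype=float)
    if model == "ca":
        return np.array([ca_effect(fr * T, fits) for T in totals])
    if model == "ia":
        return np.array([ia_effect(fr * T, fits) for T in totals])
    raise ValueError("model must be 'ca' or 'ia'")


def compare_models(observed: Sequence[tuple[float, float]],
                   predictions: Mapping[str, Sequence[float]]) -> dict[str, FitQuality]:
    """Goodness of fit of each model's predicted effects to observations.

    ``observed`` is a list of (concentration, effect) pairs; each entry of
    ``predictions`` must supply one predicted effect per observation.
    """
    obs = np.asarray([e for _, e in observed], dtype=float)
    if obs.size < 3:
        raise ValueError("need at least three observation points")
    return {name: fit_metrics(obs, np.asarray(pred, dtype=float))
            for name, pred in predictions.items()}
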