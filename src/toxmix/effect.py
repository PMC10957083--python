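"""Effect-concentration (LCx) estimation and acute-hazard summaries.

The LCx point estimate inverts the fitted sigmoid in closed form.  Its
confidence interval inverts the observation confidence band: the
concentration where the *upper* band first reaches the effect level is the
lower concentration bound, and where the *lower* band reaches it is the
upper bound.  Both crossings are located by bisection on a wide bracket
around the point estimate.  A delta-method interval (variance of the
inverse propagated from the parameter covariance) is available as an
alternative.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .crc import CRCRegressor
from .records import EffectConcentration

__all__ = ["effect_concentration", "ghs_acute_class", "toxicity_factor"]

_BRACKET_FACTOR = 1e3
_XTOL_REL = 1e-6


def _band_crossing(fit: CRCRegressor, p: float, level: float, side: str,
                   lo: float, hi: float) -> float | None:
    """Concentration where the chosen band edge equals p, or None."""
    idx = 1 if side == "upper" else 0

    def g(x):
        return fit.observation_band(x, level)[idx][0] - p

    glo, ghi = g(lo), g(hi)
    if glo * ghi > 0:
        return None
    return brentq(g, lo, hi, rtol=_XTOL_REL)


def effect_concentration(
    fit: CRCRegressor,
    p: float,
    level: float = 0.95,
    method: str = "band",
) -> EffectConcentration:
    """LCp with a confidence interval from the fitted curve.

    Parameters
    ----------
    fit : CRCRegressor
        A fitted concentration-response curve.
    p : float
        Effect fraction in (0, 1); 0.5 gives the LC50.
    level : float, default 0.95
        Confidence level of the interval.
    method : {"band", "delta"}
        ``"band"`` inverts the observation confidence band (default);
        ``"delta"`` propagates parameter covariance through the closed-form
        inverse.
    """
    if not 0 < p < 1:
        raise ValueError("effect level p must lie in (0, 1)")
    value = float(fit.inverse(p))
    lo, hi = value / _BRACKET_FACTOR, value * _BRACKET_FACTOR

    if method == "delta":
        # d(inverse)/d(params) by central differences on the closed form
        fam = fit._fam()
        eps = 1e-6
        grad = np.empty(fit.n_params_)
        for j in range(fit.n_params_):
            pp, pm = fit.params_.copy(), fit.params_.copy()
            pp[j] += eps
            pm[j] -= eps
            grad[j] = (float(fam.inverse(p, pp)) - float(fam.inverse(p, pm))) / (2 * eps)
        se = float(np.sqrt(grad @ fit.param_cov_ @ grad))
        t = stats.t.ppf(1 - (1 - level) / 2, fit.n_points_ - fit.n_params_)
        ci_low, ci_high = max(value - t * se, 0.0), value + t * se
        return EffectConcentration(p, value, ci_low, ci_high, level)
    if method != "band":
        raise ValueError("method must be 'band' or 'delta'")

    ci_low = _band_crossing(fit, p, level, "upper", lo, hi)
    ci_high = _band_crossing(fit, p, level, "lower", lo, hi)
    if ci_low is None:
        warnings.warn(
            f"upper band never crosses p={p} in [{lo:g}, {hi:g}]; "
            "reporting an open lower bound", stacklevel=2)
        ci_low = 0.0
    if ci_high is None:
        warnings.warn(
            f"lower band never crosses p={p} in [{lo:g}, {hi:g}]; "
            "reporting an open upper bound", stacklevel=2)
        ci_high = np.inf
    return EffectConcentration(p, value, float(ci_low), float(ci_high), level)


def ghs_acute_class(lc50: float) -> str:
    """Acute aquatic hazard band from the 96-h LC50 (mg/L).

    The 1-10 mg/L band is "highly toxic" (strict inequalities); at or
    below 1 mg/L "very highly toxic"; at or above 10 mg/L "moderately to
    slightly toxic".
    """
    if lc50 <= 0:
        raise ValueError("LC50 must be positive")
    if lc50 <= 1:
        return "very highly toxic"
    if lc50 < 10:
        return "highly toxic"
    return "moderately to slightly toxic"


def toxicity_factor(lc50_less_toxic: float, lc50_more_toxic: float) -> float:
    """Ratio of LC50s: how many times more toxic the second agent is.

    Convention: pass the less toxic agent's (larger) LC50 first, so the
    factor is >= 1.  Round for reporting ("about N times more toxic").
    """
    if lc50_less_toxic <= 0 or lc50_more_toxic <= 0:
        raise ValueError("LC50 values must be positive")
    return lc50_less_toxic / lc50_more_toxic
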