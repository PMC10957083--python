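"""Concentration-response curve fitting.

The central object is :class:`CRCRegressor`, a scikit-learn style estimator
that fits one of the three sigmoid families (or picks the best of all
three) to pooled mortality fractions by unweighted nonlinear least
squares.  Replicates are pooled to the mean mortality per concentration
before fitting; the response scale is the proportion dead, not counts.

The fit supplies everything the downstream effect-level machinery needs:
point parameters, the Gauss-Newton parameter covariance (JᵀJ)⁻¹·s², the
residual variance s² = SSR/(n−m), and an observation confidence band

    ŷ ± t_{n−m, (1−level)/2} · sqrt(s² + v C vᵀ)

where v is the gradient of the curve with respect to the parameters.  The
band combines residual scatter and parameter uncertainty, so it is a
prediction-style band: inverting it yields conservative LCx intervals.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .families import FAMILIES, CRCFamily, get_family
from .records import DoseResponseRecord, FitQuality, pool_records

__all__ = [
    "CRCRegressor",
    "CRCFitError",
    "DegenerateDataError",
    "fit_crc",
    "select_best_family",
    "fit_metrics",
    "observation_band",
]


class CRCFitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best candidate found."""

    def __init__(self, message: str, best_params=None, best_ssr=None):
        super().__init__(message)
        self.best_params = best_params
        self.best_ssr = best_ssr


class DegenerateDataError(ValueError):
    """Response data carry no dose-response signal (all dead or all alive)."""


def fit_metrics(observed, predicted) -> FitQuality:
    """R², MSE and MAE between observed and predicted effect fractions.

    MSE is the mean of squared errors; R² is 1 − SSR/SStot.  Raises if the
    observed values are constant (total sum of squares is zero).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    if y.size < 2:
        raise ValueError("need at least two points for fit metrics")
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        raise DegenerateDataError("R² undefined: observed values are constant")
    err = y - yhat
    return FitQuality(
        r2=1.0 - float(np.sum(err**2)) / sstot,
        mse=float(np.mean(err**2)),
        mae=float(np.mean(np.abs(err))),
    )


# Optimizer box constraints.  The three-parameter families have
# degenerate ridges (e.g. GL with gamma -> 0 and |alpha|, |beta| -> inf
# approaches a limiting curve with absurd tail behaviour), so parameters
# are kept inside a generous but finite region around the start grid.
_PARAM_BOUNDS = {
    "weibull": ([-30.0, 1e-3], [10.0, 30.0]),
    "bcw": ([-30.0, 1e-3, -2.0], [10.0, 30.0, 2.0]),
    "gl": ([-30.0, 1e-3, 0.01], [10.0, 30.0, 5.0]),
}


def _refine(family: CRCFamily, x, y, start, max_nfev=200):
    """One local least-squares polish from a given start."""
    lo, hi = _PARAM_BOUNDS[family.name]
    start = np.clip(np.asarray(start, float), np.asarray(lo) + 1e-9,
                    np.asarray(hi) - 1e-9)

    def resid(p):
        with np.errstate(over="ignore", invalid="ignore"):
            return np.nan_to_num(family._f(x, p) - y, nan=1e3)

    def jac(p):
        with np.errstate(over="ignore", invalid="ignore"):
            return np.nan_to_num(family._grad(x, p))

    return least_squares(resid, start, jac=jac, bounds=(lo, hi), max_nfev=max_nfev)


class CRCRegressor(RegressorMixin, BaseEstimator):
    """Sigmoid concentration-response fit as a scikit-learn estimator.

    Parameters
    ----------
    family : {"weibull", "bcw", "gl", "auto"}, default "auto"
        Sigmoid family to fit.  ``"auto"`` fits all three and keeps the
        one with the highest R² (ties: fewer parameters, then lower MSE).
    n_refine : int, default 8
        How many of the best coarse-grid starts are polished by local
        least squares.  The three-parameter families are ill-conditioned,
        so a single start is not reliable.
    confidence : float, default 0.95
        Default level for the observation confidence band.

    Attributes
    ----------
    family_ : str
        Chosen family after fitting.
    params_ : ndarray
        Fitted parameter vector (alpha, beta[, gamma]).
    alpha_, beta_, gamma_ : float
        Named parameters; ``gamma_`` is None for the Weibull family.
    param_cov_ : ndarray, shape (m, m)
        Gauss-Newton covariance of the parameter estimates.
    resid_var_ : float
        Residual variance s² = SSR/(n−m).
    quality_ : FitQuality
        R², MSE, MAE of the fit on the pooled points.
    n_points_, n_params_ : int
        Pooled point count n and parameter count m.
    """

    def __init__(self, family: str = "auto", n_refine: int = 8, confidence: float = 0.95):
        self.family = family
        self.n_refine = n_refine
        self.confidence = confidence

    # -- fitting ------------------------------------------------------------

    def _validate_xy(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("CRCRegressor expects a single concentration column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape:
            raise ValueError("X and y length mismatch")
        if np.any(X <= 0):
            raise ValueError("all concentrations must be strictly positive")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("effect fractions must lie in [0, 1]")
        if np.all(y == 0) or np.all(y == 1):
            raise DegenerateDataError(
                "no dose-response signal: mortality is identically "
                f"{int(y[0]) if y.size else 0}"
            )
        return X, y

    def _fit_one(self, fam: CRCFamily, x, y):
        if np.unique(x).size < fam.n_params + 1:
            raise CRCFitError(
                f"{fam.name}: need at least {fam.n_params + 1} distinct concentrations"
            )
        starts = fam.starts()
        with np.errstate(over="ignore", invalid="ignore"):
            ssrs = np.array([
                float(np.nansum((np.nan_to_num(fam._f(x, p), nan=1e3) - y) ** 2))
                for p in starts
            ])
        order = np.argsort(ssrs)[: self.n_refine]
        lo, hi = (np.asarray(b) for b in _PARAM_BOUNDS[fam.name])
        best, best_ssr = None, np.inf
        pinned, pinned_ssr = None, np.inf
        for idx in order:
            try:
                sol = _refine(fam, x, y, starts[idx])
            except Exception:
                continue
            try:
                fam.evaluate(x, sol.x)  # enforces family parameter constraints
            except ValueError:
                continue
            ssr = float(2 * sol.cost)
            # an optimum pinned to the parameter box is the family's
            # degenerate limit for these data, not a usable fit
            at_bound = np.any((sol.x - lo < 1e-6) | (hi - sol.x < 1e-6))
            if at_bound:
                if ssr < pinned_ssr:
                    pinned, pinned_ssr = sol, ssr
                continue
            if ssr < best_ssr:
                best, best_ssr = sol, ssr
        if best is None:
            if pinned is not None:
                raise CRCFitError(
                    f"{fam.name}: fit degenerates (parameters at the search "
                    "boundary)", best_params=pinned.x, best_ssr=pinned_ssr)
            raise CRCFitError(f"{fam.name}: no start converged to a valid optimum")
        return best, best_ssr

    def fit(self, X, y):
        """Fit to concentrations ``X`` (mg/L) and mortality fractions ``y``."""
        x, y = self._validate_xy(X, y)
        names = list(FAMILIES) if self.family == "auto" else [get_family(self.family).name]

        candidates = []
        failures = []
        for name in names:
            fam = FAMILIES[name]
            try:
                sol, ssr = self._fit_one(fam, x, y)
            except (CRCFitError, ValueError) as exc:
                failures.append(str(exc))
                continue
            quality = fit_metrics(y, fam.evaluate(x, sol.x))
            candidates.append((fam, sol, ssr, quality))
        if not candidates:
            raise CRCFitError("all families failed to fit: " + "; ".join(failures))

        # highest R2; ties broken by fewer parameters, then lower MSE
        fam, sol, ssr, quality = min(
            candidates,
            key=lambda c: (-round(c[3].r2, 9), c[0].n_params, c[3].mse),
        )
        n, m = x.size, fam.n_params
        if n <= m:
            raise CRCFitError(f"{fam.name}: n={n} points cannot support m={m} parameters")
        self.family_ = fam.name
        self.params_ = sol.x.copy()
        self.alpha_, self.beta_ = float(sol.x[0]), float(sol.x[1])
        self.gamma_ = float(sol.x[2]) if m == 3 else None
        self.n_points_, self.n_params_ = n, m
        self.resid_var_ = ssr / (n - m)
        J = fam.gradient(x, sol.x)
        JtJ = J.T @ J
        self.param_cov_ = np.linalg.pinv(JtJ) * self.resid_var_
        self.quality_ = quality
        self.x_, self.y_ = x, y
        return self

    # -- prediction and inversion -------------------------------------------

    def _fam(self) -> CRCFamily:
        check_is_fitted(self, "params_")
        return FAMILIES[self.family_]

    def predict(self, X):
        """Expected effect fraction at concentrations ``X`` (mg/L)."""
        X = np.asarray(X, dtype=float)
        shape_in = X.shape
        x = X[:, 0] if X.ndim == 2 else X
        out = self._fam().evaluate(x, self.params_)
        return out.reshape(shape_in[:1]) if len(shape_in) else out

    def inverse(self, Y):
        """Concentration (mg/L) at effect level ``Y``; closed form."""
        return self._fam().inverse(Y, self.params_)

    def observation_band(self, xs, level: float | None = None):
        """Observation confidence band (lower, upper) at each concentration.

        Half-width is t_{n−m, (1−level)/2} · sqrt(s² + v C vᵀ) with v the
        parameter gradient of the curve at each x.
        """
        fam = self._fam()
        level = self.confidence if level is None else level
        if not 0 < level < 1:
            raise ValueError("confidence level must lie in (0, 1)")
        df = self.n_points_ - self.n_params_
        if df <= 0:
            raise ValueError("no residual degrees of freedom for a band")
        xs = np.atleast_1d(np.asarray(xs, dtype=float))
        yhat = fam.evaluate(xs, self.params_)
        V = fam.gradient(xs, self.params_)
        var_fit = np.einsum("ij,jk,ik->i", V, self.param_cov_, V)
        half = stats.t.ppf(1 - (1 - level) / 2, df) * np.sqrt(self.resid_var_ + var_fit)
        return yhat - half, yhat + half


# -- record-level wrappers ---------------------------------------------------

def fit_crc(records: list[DoseResponseRecord], family: str) -> CRCRegressor:
    """Fit one named family to pooled dose-response records."""
    x, y = pool_records(records)
    return CRCRegressor(family=family).fit(x, y)


def select_best_family(records: list[DoseResponseRecord]) -> CRCRegressor:
    """Fit all three families and return the best by R² (ties: fewer
    parameters, then lower MSE)."""
    x, y = pool_records(records)
    return CRCRegressor(family="auto").fit(x, y)


def observation_band(fit: CRCRegressor, xs, level: float = 0.95):
    """Functional alias for :meth:`CRCRegressor.observation_band`."""
    return fit.observation_band(xs, level)
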