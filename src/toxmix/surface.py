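"""Regression surrogates for mixture mortality ("QSAR" surface).

Observed binary-mixture mortality is regressed on composition variables —
each component's concentration, the total, and the first component's mass
fraction — since a fixed-ratio design varies exactly these.  Four model
families are compared on a train/test split: ridge regression (penalty by
internal cross-validation), gradient-boosted trees, a one-hidden-layer
perceptron, and ordinary multilinear regression.  The family with the
highest test R² is selected and can be inverted along a ray to read off
surrogate effect concentrations (LCx).

Tree ensembles produce piecewise-constant, occasionally non-monotone
dose-response slices; before inversion the predicted curve along a ray is
monotonized by a running maximum over total concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression, RidgeCV
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import FunctionTransformer, StandardScaler
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBRegressor

from .crc import DegenerateDataError, fit_metrics
from .records import DoseResponseRecord, FitQuality

__all__ = [
    "FEATURE_COLUMNS",
    "SurfaceModelReport",
    "MixtureSurface",
    "build_feature_table",
    "fit_surface",
    "surrogate_effect_concentration",
]

FEATURE_COLUMNS = ["conc_a", "conc_b", "total", "fraction_a"]
DEFAULT_FAMILIES = ("ridge", "xgboost", "mlp", "mlr")


@dataclass(frozen=True)
class SurfaceModelReport:
    """Train/test quality of one model family on the mixture surface."""

    model_family: str
    split_seed: int
    train_quality: FitQuality | None
    test_quality: FitQuality | None
    selected: bool
    failed: bool = False


def build_feature_table(records: list[DoseResponseRecord]) -> tuple[pd.DataFrame, np.ndarray]:
    """Composition features and mortality response from mixture records.

    Features per row: conc_a, conc_b (mg/L), their total, and component
    a's mass fraction.  Row order follows the input records.
    """
    rows = []
    y = []
    for i, r in enumerate(records):
        if len(r.concentrations) != 2:
            raise ValueError(
                f"record {i}: mixture feature table requires two component "
                f"concentrations, got {len(r.concentrations)}"
            )
        ca, cb = r.concentrations
        total = ca + cb
        if total <= 0:
            raise ValueError(f"record {i}: zero total concentration")
        rows.append((ca, cb, total, ca / total))
        y.append(r.mortality)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS), np.asarray(y)


def _log_concentrations(X):
    """Log10-transform the three concentration columns; mortality responds
    to log dose, which is also the axis every CRC here is defined on."""
    X = np.asarray(X, dtype=float).copy()
    X[:, :3] = np.log10(X[:, :3])
    return X


def _make_model(family: str, seed: int):
    log = FunctionTransformer(_log_concentrations)
    if family == "ridge":
        return make_pipeline(log, StandardScaler(),
                             RidgeCV(alphas=np.logspace(-4, 3, 15)))
    if family == "xgboost":
        # trees are invariant to the monotone log transform; kept for a
        # uniform feature pipeline across families
        return make_pipeline(log, XGBRegressor(
            n_estimators=200, max_depth=3, learning_rate=0.1,
            random_state=seed, n_jobs=1, verbosity=0,
        ))
    if family == "mlp":
        # lbfgs: sklearn's recommended solver for small datasets
        return make_pipeline(log, StandardScaler(), MLPRegressor(
            hidden_layer_sizes=(32,), solver="lbfgs", max_iter=5000,
            random_state=seed,
        ))
    if family == "mlr":
        return make_pipeline(log, LinearRegression())
    raise ValueError(f"unknown surface model family {family!r}")


class MixtureSurface(RegressorMixin, BaseEstimator):
    """Best-of-four regression surrogate of mixture mortality.

    Parameters
    ----------
    families : tuple of str
        Model families to compare; subset of {"ridge", "xgboost", "mlp",
        "mlr"}.
    split_ratio : float, default 0.8
        Training fraction of the 80:20-style split.
    random_state : int, default 0
        Seed for the split and for every stochastic model family.
    stratify_rays : bool, default False
        If True, split within each distinct mass-fraction ray instead of
        fully at random.

    Attributes
    ----------
    reports_ : list of SurfaceModelReport
        One per family, exactly one marked ``selected``.
    best_family_ : str
        Family with the highest test R² among those that converged.
    best_model_ : fitted sklearn-compatible regressor
    """

    def __init__(self, families=DEFAULT_FAMILIES, split_ratio: float = 0.8,
                 random_state: int = 0, stratify_rays: bool = False):
        self.families = families
        self.split_ratio = split_ratio
        self.random_state = random_state
        self.stratify_rays = stratify_rays

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        if len(X) < 10:
            raise ValueError("need at least 10 rows to fit and validate a surface")
        if np.allclose(y, y[0]):
            raise DegenerateDataError("constant response: no surface to learn")

        strat = None
        if self.stratify_rays:
            # stratify on the mass-fraction column (last feature)
            strat = np.unique(X[:, -1], return_inverse=True)[1]
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=self.split_ratio,
            random_state=self.random_state, stratify=strat,
        )
        if len(y_te) < 2:
            raise ValueError("split leaves fewer than 2 test rows")

        reports: list[SurfaceModelReport] = []
        fitted: dict[str, object] = {}
        for family in self.families:
            try:
                model = _make_model(family, self.random_state)
                model.fit(X_tr, y_tr)
                train_q = fit_metrics(y_tr, model.predict(X_tr))
                test_q = fit_metrics(y_te, model.predict(X_te))
            except Exception:
                reports.append(SurfaceModelReport(
                    family, self.random_state, None, None, False, failed=True))
                continue
            fitted[family] = model
            reports.append(SurfaceModelReport(
                family, self.random_state, train_q, test_q, False))
        if not fitted:
            raise RuntimeError("every surface model family failed to fit")

        best = max((r for r in reports if not r.failed), key=lambda r: r.test_quality.r2)
        self.reports_ = [
            SurfaceModelReport(r.model_family, r.split_seed, r.train_quality,
                               r.test_quality, r is best, r.failed)
            for r in reports
        ]
        self.best_family_ = best.model_family
        self.best_model_ = fitted[best.model_family]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "best_model_")
        return np.asarray(self.best_model_.predict(np.asarray(X, dtype=float)))

    def effect_concentration(self, fractions, p: float,
                             t_max: float = 1e3, n_grid: int = 4096) -> float:
        """Total concentration along a ray where the surrogate effect is p.

        The surrogate is evaluated on a log-spaced grid of totals,
        monotonized by a running maximum, and inverted by interpolation.
        """
        check_is_fitted(self, "best_model_")
        if not 0 < p < 1:
            raise ValueError("effect level p must lie in (0, 1)")
        fa, fb = float(fractions[0]), float(fractions[1])
        if abs(fa + fb - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        T = np.logspace(-4, np.log10(t_max), n_grid)
        feats = np.column_stack([fa * T, fb * T, T, np.full_like(T, fa)])
        # mortality is a fraction: clip regressor over/undershoot
        pred = np.maximum.accumulate(np.clip(self.predict(feats), 0.0, 1.0))
        if p > pred[-1] or p < pred[0]:
            raise ValueError(
                f"surrogate prediction never crosses effect level {p} "
                f"(range {pred[0]:.3f}..{pred[-1]:.3f})"
            )
        k = int(np.searchsorted(pred, p))
        if k == 0:
            return float(T[0])
        # linear interpolation on the monotonized step
        p0, p1 = pred[k - 1], pred[k]
        if p1 == p0:
            return float(T[k])
        w = (p - p0) / (p1 - p0)
        return float(T[k - 1] + w * (T[k] - T[k - 1]))


def fit_surface(features, response, families=DEFAULT_FAMILIES,
                split_ratio: float = 0.8, seed: int = 0,
                stratify_rays: bool = False) -> list[SurfaceModelReport]:
    """Fit all families and return their train/test reports."""
    est = MixtureSurface(families=families, split_ratio=split_ratio,
                         random_state=seed, stratify_rays=stratify_rays)
    est.fit(np.asarray(features, dtype=float), response)
    return est.reports_


def surrogate_effect_concentration(model: MixtureSurface, fractions, p: float) -> float:
    """Functional alias for :meth:`MixtureSurface.effect_concentration`."""
    return model.effect_concentration(fractions, p)
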