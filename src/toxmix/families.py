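"""Sigmoidal concentration-response families.

Three two- or three-parameter sigmoids map a positive concentration ``x``
(mg/L) to an expected effect fraction in (0, 1):

* ``weibull``:  f(x) = 1 − exp(−exp(α + β·lg x))
* ``bcw`` (Box–Cox–Weibull):  f(x) = 1 − exp(−exp(α + β·(x^γ − 1)/γ))
* ``gl`` (generalised logit):  f(x) = (1 + exp(−α − β·lg x))^(−γ)

``lg`` is log base 10.  Each family carries a closed-form inverse
(concentration at a stated effect level) derived algebraically from the
forward form, and the analytic parameter gradient used for covariance and
observation-band computation.  The Weibull family uses lg while the γ→0
limit of BCW uses the natural log of x: they are deliberately distinct
members, and ``bcw`` with γ = 0 is rejected rather than silently mapped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["CRCFamily", "FAMILIES", "get_family", "evaluate_crc", "invert_crc"]

_LG_E = np.log10(np.e)


def _check_x(x):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("concentration must be strictly positive")
    return x


def _check_params(name: str, params: np.ndarray) -> None:
    if name == "weibull":
        if params[1] == 0:
            raise ValueError("weibull requires beta != 0")
    elif name == "bcw":
        if params[1] == 0:
            raise ValueError("bcw requires beta != 0")
        if params[2] == 0:
            raise ValueError(
                "bcw with gamma = 0 is rejected; its gamma->0 limit is a "
                "natural-log Weibull, a distinct model from the lg-based "
                "'weibull' family"
            )
    elif name == "gl":
        if params[1] == 0:
            raise ValueError("gl requires beta != 0")
        if params[2] <= 0:
            raise ValueError("gl requires gamma > 0")
    else:  # pragma: no cover - registry guards this
        raise ValueError(f"unknown family {name!r}")


# --- forward forms ---------------------------------------------------------

def _weibull_f(x, p):
    return 1.0 - np.exp(-np.exp(p[0] + p[1] * np.log10(x)))


def _bcw_f(x, p):
    a, b, g = p
    return 1.0 - np.exp(-np.exp(a + b * (np.power(x, g) - 1.0) / g))


def _gl_f(x, p):
    a, b, g = p
    return np.power(1.0 + np.exp(-a - b * np.log10(x)), -g)


# --- closed-form inverses --------------------------------------------------

def _weibull_inv(Y, p):
    a, b = p
    return np.power(10.0, (np.log(-np.log1p(-Y)) - a) / b)


def _bcw_inv(Y, p):
    a, b, g = p
    u = (np.log(-np.log1p(-Y)) - a) / b
    base = 1.0 + g * u
    if np.any(base <= 0):
        raise ValueError("bcw inverse has no real solution at this effect level")
    return np.power(base, 1.0 / g)


def _gl_inv(Y, p):
    a, b, g = p
    return np.power(10.0, (-a - np.log(np.power(Y, -1.0 / g) - 1.0)) / b)


# --- parameter gradients (rows: observations, cols: alpha, beta[, gamma]) --

def _weibull_grad(x, p):
    eta = p[0] + p[1] * np.log10(x)
    e = np.exp(-np.exp(eta)) * np.exp(eta)   # d f / d eta
    return np.column_stack([e, e * np.log10(x)])


def _bcw_grad(x, p):
    a, b, g = p
    bc = (np.power(x, g) - 1.0) / g
    eta = a + b * bc
    e = np.exp(-np.exp(eta)) * np.exp(eta)
    dbc_dg = (g * np.power(x, g) * np.log(x) - (np.power(x, g) - 1.0)) / g**2
    return np.column_stack([e, e * bc, e * b * dbc_dg])


def _gl_grad(x, p):
    a, b, g = p
    z = np.exp(-a - b * np.log10(x))
    core = g * np.power(1.0 + z, -g - 1.0) * z
    return np.column_stack([core, core * np.log10(x), -np.power(1.0 + z, -g) * np.log1p(z)])


@dataclass(frozen=True)
class CRCFamily:
    """One sigmoid family: forward form, inverse, gradient, start grid."""

    name: str
    n_params: int
    param_names: tuple[str, ...]
    _f: Callable
    _inv: Callable
    _grad: Callable
    start_grid: tuple[tuple[float, ...], ...]

    def __call__(self, x, params) -> np.ndarray:
        return self.evaluate(x, params)

    def evaluate(self, x, params) -> np.ndarray:
        """Effect fraction at concentration ``x`` (mg/L)."""
        x = _check_x(x)
        params = np.asarray(params, dtype=float)
        _check_params(self.name, params)
        return self._f(x, params)

    def inverse(self, Y, params) -> np.ndarray:
        """Concentration (mg/L) at effect level ``Y`` ∈ (0, 1)."""
        Y = np.asarray(Y, dtype=float)
        if np.any((Y <= 0) | (Y >= 1)):
            raise ValueError("effect level must lie strictly in (0, 1)")
        params = np.asarray(params, dtype=float)
        _check_params(self.name, params)
        return self._inv(Y, params)

    def gradient(self, x, params) -> np.ndarray:
        """Jacobian of f w.r.t. parameters, shape (len(x), n_params)."""
        x = _check_x(x)
        params = np.asarray(params, dtype=float)
        _check_params(self.name, params)
        return self._grad(x, params)

    def starts(self) -> np.ndarray:
        """Multi-start initial parameter vectors (the coarse grid)."""
        return np.array(list(itertools.product(*self.start_grid)))


# Coarse multi-start grids: alpha in [-12, 2], beta in [0.5, 12]; gamma
# grids as appropriate per family (BCW near 0 excluded, GL positive).
_ALPHAS = (-12.0, -8.0, -5.0, -3.0, -1.5, -0.5, 0.5, 2.0)
_BETAS = (0.5, 1.0, 2.0, 4.0, 8.0, 12.0)

FAMILIES: dict[str, CRCFamily] = {
    "weibull": CRCFamily(
        "weibull", 2, ("alpha", "beta"), _weibull_f, _weibull_inv, _weibull_grad,
        (_ALPHAS, _BETAS),
    ),
    "bcw": CRCFamily(
        "bcw", 3, ("alpha", "beta", "gamma"), _bcw_f, _bcw_inv, _bcw_grad,
        (_ALPHAS, _BETAS, (-0.5, -0.25, -0.1, 0.1, 0.25, 0.5)),
    ),
    "gl": CRCFamily(
        "gl", 3, ("alpha", "beta", "gamma"), _gl_f, _gl_inv, _gl_grad,
        (_ALPHAS, _BETAS, (0.05, 0.2, 0.5, 1.0, 2.0)),
    ),
}

_ALIASES = {"weibull": "weibull", "bcw": "bcw", "box-cox-weibull": "bcw",
            "gl": "gl", "generalised logit": "gl", "generalized logit": "gl"}


def get_family(name: str) -> CRCFamily:
    try:
        return FAMILIES[_ALIASES[name.lower()]]
    except KeyError:
        raise ValueError(
            f"unknown CRC family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None


def _pack(family: str, alpha: float, beta: float, gamma: float | None) -> np.ndarray:
    fam = get_family(family)
    if fam.n_params == 3:
        if gamma is None:
            raise ValueError(f"{fam.name} requires gamma")
        return np.array([alpha, beta, gamma], dtype=float)
    return np.array([alpha, beta], dtype=float)


def evaluate_crc(family: str, alpha: float, beta: float, gamma: float | None = None, *, x):
    """Evaluate a named CRC family at concentration ``x`` (mg/L)."""
    return get_family(family).evaluate(x, _pack(family, alpha, beta, gamma))


def invert_crc(family: str, alpha: float, beta: float, gamma: float | None = None, *, Y):
    """Concentration (mg/L) producing effect fraction ``Y`` under the named family."""
    return get_family(family).inverse(Y, _pack(family, alpha, beta, gamma))
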