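"""Minimal plotting helper for fitted concentration-response curves."""

from __future__ import annotations

import numpy as np

from .crc import CRCRegressor


def plot_crc(fit: CRCRegressor, ax=None, band: bool = True, n: int = 200):
    """Plot a fitted curve, its data and (optionally) the observation band.

    Returns the matplotlib axes.  Concentration is drawn on a log axis.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs = np.logspace(np.log10(fit.x_.min() / 3), np.log10(fit.x_.max() * 3), n)
    ax.semilogx(xs, fit.predict(xs), label=f"{fit.family_} fit")
    ax.plot(fit.x_, fit.y_, "o", label="observed")
    if band:
        lo, hi = fit.observation_band(xs)
        ax.fill_between(xs, lo, hi, alpha=0.2, label=f"{fit.confidence:.0%} OCI")
    ax.set_xlabel("concentration (mg/L)")
    ax.set_ylabel("effect fraction")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    return ax
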