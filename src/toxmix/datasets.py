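"""Bundled reference data from a Cr/Ni acute-toxicity assay on ostracods.

A published 96-hour static-exposure study of potassium dichromate (Cr) and
nickel nitrate (Ni) on the freshwater ostracod *Heterocypris* sp. provides
the package's worked reference: five concentration levels per metal, ten
animals per group, three replicates, mortality recorded at 24/48/72/96 h.
These printed tables are small enough to ship in source and serve as
fixtures, oracles and realistic defaults for the synthetic generator.

Concentrations are as-dosed salt concentrations (mg/L of K2Cr2O7 and
Ni(NO3)2); conversion to elemental metal is left to the user.
"""

from __future__ import annotations

import numpy as np

from .records import DoseResponseRecord

__all__ = [
    "SINGLE_CONCENTRATIONS",
    "SINGLE_MORTALITY_PCT",
    "REFERENCE_FITS",
    "MIXTURE_DESIGN_FRACTIONS",
    "MIXTURE_LC50",
    "MIXTURE_LC30",
    "load_single_records",
    "reference_fit_params",
]

# Design concentrations, mg/L (5 levels per metal)
SINGLE_CONCENTRATIONS: dict[str, tuple[float, ...]] = {
    "Cr": (0.2, 0.59, 1.73, 5.1, 15.0),
    "Ni": (3.0, 5.87, 11.49, 22.48, 44.0),
}

# Observed mortality (%) per level at each census time
SINGLE_MORTALITY_PCT: dict[str, dict[int, tuple[int, ...]]] = {
    "Cr": {
        24: (3, 10, 20, 37, 67),
        48: (13, 23, 33, 50, 83),
        72: (20, 37, 43, 63, 100),
        96: (23, 47, 53, 77, 100),
    },
    "Ni": {
        24: (7, 23, 30, 43, 67),
        48: (13, 30, 43, 67, 83),
        72: (23, 40, 67, 87, 100),
        96: (37, 57, 90, 93, 100),
    },
}

# Reported best-fit curves per metal and census time:
# (family, alpha, beta, gamma, R2, MAE, LC10, LC30, LC50)
REFERENCE_FITS: dict[tuple[str, int], dict] = {
    ("Cr", 24): dict(family="gl", alpha=-5.91, beta=4.31, gamma=0.34,
                     r2=0.99, mae=0.01, lc10=0.63, lc30=3.59, lc50=8.5),
    ("Cr", 48): dict(family="weibull", alpha=-1.18, beta=1.38, gamma=None,
                     r2=0.98, mae=0.03, lc10=0.17, lc30=1.29, lc50=3.92),
    ("Cr", 72): dict(family="weibull", alpha=-0.72, beta=1.3, gamma=None,
                     r2=0.94, mae=0.06, lc10=0.07, lc30=0.58, lc50=1.86),
    ("Cr", 96): dict(family="weibull", alpha=-0.4, beta=1.21, gamma=None,
                     r2=0.96, mae=0.05, lc10=0.03, lc30=0.3, lc50=1.07),
    ("Ni", 24): dict(family="bcw", alpha=-3.13, beta=0.88, gamma=-0.03,
                     r2=0.98, mae=0.03, lc10=2.74, lc30=11.57, lc50=25.94),
    ("Ni", 48): dict(family="bcw", alpha=-3.17, beta=1.31, gamma=-0.16,
                     r2=0.99, mae=0.01, lc10=2.1, lc30=6.54, lc50=13.37),
    ("Ni", 72): dict(family="weibull", alpha=-2.48, beta=2.39, gamma=None,
                     r2=0.99, mae=0.01, lc10=1.25, lc30=4.03, lc50=7.65),
    ("Ni", 96): dict(family="gl", alpha=-9.44, beta=8.94, gamma=0.2,
                     r2=0.98, mae=0.023, lc10=0.59, lc30=2.42, lc50=4.7),
}

# Published mixture-design mass fractions (Cr fraction, Ni fraction)
MIXTURE_DESIGN_FRACTIONS: dict[str, tuple[float, float]] = {
    "EECR 10": (0.05, 0.95),
    "EECR 30": (0.08, 0.92),
    "EECR 50": (0.11, 0.89),
    "EquRay 1": (0.53, 0.47),
    "EquRay 2": (0.31, 0.69),
    "EquRay 3": (0.19, 0.81),
    "EquRay 4": (0.10, 0.90),
    "EquRay 5": (0.04, 0.96),
}

# Measured 96-h mixture effect concentrations (mg/L total)
MIXTURE_LC50: dict[str, float] = {
    "EECR 10": 1.07, "EECR 30": 0.66, "EECR 50": 0.56,
    "EquRay 1": 1.48, "EquRay 2": 1.25, "EquRay 3": 1.03,
    "EquRay 4": 0.97, "EquRay 5": 0.74,
}
MIXTURE_LC30: dict[str, float] = {
    "EECR 10": 0.46, "EECR 30": 0.24, "EECR 50": 0.16,
    "EquRay 1": 0.46, "EquRay 2": 0.36, "EquRay 3": 0.24,
    "EquRay 4": 0.24, "EquRay 5": 0.22,
}

_N_EXPOSED = 10
_REPLICATES = 3


def load_single_records(component: str, time_h: int) -> list[DoseResponseRecord]:
    """Single-toxicant dose-response records for one metal and census time.

    The published tables report the replicate-mean mortality percentage
    per level; the three replicates here carry death counts whose mean
    reproduces that percentage (30 animals per level in total).
    """
    concs = SINGLE_CONCENTRATIONS[component]
    pcts = SINGLE_MORTALITY_PCT[component][time_h]
    records = []
    for conc, pct in zip(concs, pcts):
        total_dead = round(pct / 100 * _N_EXPOSED * _REPLICATES)
        base, extra = divmod(total_dead, _REPLICATES)
        for rep in range(1, _REPLICATES + 1):
            records.append(DoseResponseRecord(
                component_ids=(component,),
                concentrations=(conc,),
                time_h=float(time_h),
                n_exposed=_N_EXPOSED,
                n_dead=base + (1 if rep <= extra else 0),
                replicate=rep,
            ))
    return records


def reference_fit_params(component: str, time_h: int) -> dict:
    """Published best-fit family and parameters for one metal/time."""
    return dict(REFERENCE_FITS[(component, time_h)])
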