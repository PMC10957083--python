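import numpy as np
import pytest

from toxmix import CRCRegressor, datasets
from toxmix.design import eecr_ray, equray_rays, frrd_series
from toxmix.simulate import TrueCRC


@pytest.fixture(scope="session")
def cr96_data():
    """Reference chromium 96-h series: concentrations and pooled mortality."""
    x = np.array(datasets.SINGLE_CONCENTRATIONS["Cr"])
    y = np.array(datasets.SINGLE_MORTALITY_PCT["Cr"][96]) / 100
    return x, y


@pytest.fixture(scope="session")
def cr96_weibull_fit(cr96_data):
    x, y = cr96_data
    return CRCRegressor(family="weibull").fit(x, y)


@pytest.fixture(scope="session")
def true_curves():
    """Reported 96-h curves used as simulation truth: (Cr Weibull, Ni GL)."""
    return (TrueCRC("weibull", -0.4, 1.21), TrueCRC("gl", -9.44, 8.94, 0.2))


@pytest.fixture(scope="session")
def reference_rays(true_curves):
    """The eight-ray mixture design built from the reported 96-h curves."""
    cr, ni = true_curves
    rays = []
    for p, label in ((0.1, "EECR 10"), (0.3, "EECR 30"), (0.5, "EECR 50")):
        ray = eecr_ray(float(cr.inverse(p)), float(ni.inverse(p)), label, ("Cr", "Ni"))
        rays.append(frrd_series(ray))
    for ray in equray_rays(float(cr.inverse(0.5)), float(ni.inverse(0.5)),
                           5, ("Cr", "Ni")):
        rays.append(frrd_series(ray))
    return rays
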