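"""Concentration-addition / independent-action predictions and SR classing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxmix import (
    ca_effect,
    ca_effect_concentration,
    compare_models,
    datasets,
    ia_effect,
    ia_effect_concentration,
    predict_ray_effects,
    synergistic_ratio,
)
from toxmix.design import frrd_series
from toxmix.records import pool_records
from toxmix.simulate import SyntheticStudyConfig, TrueCRC, simulate_mixture


class TestConcentrationAddition:
    def test_hand_evaluated_harmonic_mean(self):
        # 1 / (0.53/1.07 + 0.47/4.7) = 1.68 by direct arithmetic
        assert ca_effect_concentration((0.53, 0.47), (1.07, 4.7)) == pytest.approx(
            1.6797, abs=5e-4)

    def test_single_component_is_identity(self):
        assert ca_effect_concentration((1.0 - 1e-12, 1e-12), (2.5, 2.5)) == pytest.approx(2.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        f=st.floats(0.01, 0.99),
        lcp_a=st.floats(0.01, 50),
        lcp_b=st.floats(0.01, 50),
    )
    def test_between_component_lcps(self, f, lcp_a, lcp_b):
        mix = ca_effect_concentration((f, 1 - f), (lcp_a, lcp_b))
        assert min(lcp_a, lcp_b) - 1e-12 <= mix <= max(lcp_a, lcp_b) + 1e-12

    def test_zero_lcp_rejected(self):
        with pytest.raises(ValueError):
            ca_effect_concentration((0.5, 0.5), (0.0, 1.0))

    def test_ca_effect_consistent_with_harmonic_lcp(self, true_curves):
        # at the CA mixture LC50, the CA effect must be 0.5
        cr, ni = true_curves
        f = (0.53, 0.47)
        lc50s = (float(cr.inverse(0.5)), float(ni.inverse(0.5)))
        mix_lc50 = ca_effect_concentration(f, lc50s)
        concs = (f[0] * mix_lc50, f[1] * mix_lc50)
        assert ca_effect(concs, (cr, ni)) == pytest.approx(0.5, abs=1e-9)


class TestIndependentAction:
    def test_half_and_half(self):
        class Flat:
            def __init__(self, e):
                self.e = e

            def predict(self, x):
                return np.full(np.shape(x), self.e)

        assert ia_effect((1.0, 1.0), (Flat(0.5), Flat(0.5))) == pytest.approx(0.75)

    def test_zero_concentration_is_neutral(self, true_curves):
        cr, ni = true_curves
        alone = float(cr.predict(np.array([1.0]))[0])
        assert ia_effect((1.0, 0.0), (cr, ni)) == pytest.approx(alone)

    def test_direct_evaluation_of_reported_curves(self, true_curves):
        # independent check: evaluate both reported sigmoids by hand and
        # combine with 1 - (1-f1)(1-f2)
        cr, ni = true_curves
        f_cr = 1 - np.exp(-np.exp(-0.4 + 1.21 * np.log10(0.535)))
        f_ni = (1 + np.exp(9.44 - 8.94 * np.log10(2.35))) ** -0.2
        expected = 1 - (1 - f_cr) * (1 - f_ni)
        assert ia_effect((0.535, 2.35), (cr, ni)) == pytest.approx(expected, rel=1e-12)

    def test_at_least_max_single_effect(self, true_curves):
        cr, ni = true_curves
        concs = (0.8, 3.0)
        singles = [float(c.predict(np.array([x]))[0]) for c, x in zip((cr, ni), concs)]
        assert ia_effect(concs, (cr, ni)) >= max(singles)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        c1=st.floats(0.01, 20),
        c2=st.floats(0.01, 20),
        bump=st.floats(0.01, 5),
    )
    def test_monotone_in_each_concentration(self, true_curves, c1, c2, bump):
        cr, ni = true_curves
        base = ia_effect((c1, c2), (cr, ni))
        assert ia_effect((c1 + bump, c2), (cr, ni)) >= base
        assert ia_effect((c1, c2 + bump), (cr, ni)) >= base


class TestIAEffectConcentration:
    def test_single_component_ray_reduces_to_inverse(self, true_curves):
        cr, ni = true_curves
        from toxmix import MixtureRay

        ray = MixtureRay(("Cr", "Ni"), (1 - 1e-9, 1e-9), "almost pure")
        expected = float(cr.inverse(0.5))
        assert ia_effect_concentration(ray, (cr, ni), 0.5) == pytest.approx(
            expected, rel=1e-4)

    def test_equray1_converges_to_finite_lc50(self, reference_rays, true_curves):
        ray = next(r for r in reference_rays if r.design == "EquRay 1")
        lc50 = ia_effect_concentration(ray, true_curves, 0.5)
        assert 0 < lc50 < 10
        # consistency: the IA effect at that total is 0.5
        concs = np.asarray(ray.fractions) * lc50
        assert ia_effect(concs, true_curves) == pytest.approx(0.5, abs=1e-6)

    def test_ia_lcp_bounded_by_scaled_component_lcps(self, reference_rays, true_curves):
        # IA effect >= each component's own effect at its share, so the IA
        # LCp cannot exceed min_i(LCp_i / fraction_i) along any ray
        cr, ni = true_curves
        for ray in reference_rays:
            ia_lc50 = ia_effect_concentration(ray, (cr, ni), 0.5)
            bound = min(float(c.inverse(0.5)) / f
                        for c, f in zip((cr, ni), ray.fractions))
            assert ia_lc50 <= bound + 1e-9


class TestSynergisticRatio:
    def test_published_synergistic_case(self):
        # strict rule (no additive band) reproduces the published class
        res = synergistic_ratio(1.07, 1.03, "Cr", tolerance=0.0)
        assert round(res.sr, 2) == 1.04
        assert res.label == "synergistic"

    def test_published_antagonistic_case(self):
        res = synergistic_ratio(1.07, 1.48, "Cr")
        assert res.sr == pytest.approx(0.723, abs=0.005)
        assert res.label == "antagonistic"

    def test_equality_is_additive(self):
        res = synergistic_ratio(2.2, 2.2)
        assert res.sr == 1.0
        assert res.label == "additive"

    def test_default_tolerance_widens_additive_band(self):
        # |SR - 1| = 0.039 falls inside the default 0.05 additive band
        assert synergistic_ratio(1.07, 1.03).label == "additive"
        assert synergistic_ratio(1.0, 1.0, tolerance=0.0).label == "additive"

    def test_published_table_reconstructs_within_tolerance(self):
        # reported SR(Cr) and SR(Ni) values derive from unrounded mixture
        # LC50s; printed inputs reproduce them to within 0.02
        printed_sr_cr = {"EECR 10": 1.01, "EECR 30": 1.63, "EECR 50": 1.93,
                         "EquRay 1": 0.73, "EquRay 2": 0.86, "EquRay 3": 1.04,
                         "EquRay 4": 1.1, "EquRay 5": 1.45}
        for combo, mix_lc50 in datasets.MIXTURE_LC50.items():
            sr = synergistic_ratio(1.07, mix_lc50, "Cr").sr
            assert abs(sr - printed_sr_cr[combo]) <= 0.02, combo

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            synergistic_ratio(1.0, 0.0)


class TestCompareModels:
    def test_perfect_predictions(self):
        obs = [(1.0, 0.2), (2.0, 0.5), (4.0, 0.9)]
        q = compare_models(obs, {"m": [0.2, 0.5, 0.9]})
        assert q["m"].r2 == 1.0 and q["m"].mse == 0.0

    def test_identifies_ca_truth_on_simulated_rays(self, reference_rays, true_curves):
        cfg = SyntheticStudyConfig(seed=7, truth_model="ca")
        obs, pred = [], {"ca": [], "ia": []}
        for ray in reference_rays:
            recs = simulate_mixture(cfg, ray, 96)
            x, y = pool_records(recs)
            obs.extend(zip(x, y))
            for m in ("ca", "ia"):
                pred[m].extend(predict_ray_effects(ray, true_curves, m, x))
        q = compare_models(obs, pred)
        assert q["ca"].r2 > q["ia"].r2

    def test_deterministic(self, reference_rays, true_curves):
        ray = reference_rays[4]
        x = np.array(ray.series)
        p1 = predict_ray_effects(ray, true_curves, "ca", x)
        p2 = predict_ray_effects(ray, true_curves, "ca", x)
        assert np.array_equal(p1, p2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="three"):
            compare_models([(1.0, 0.1), (2.0, 0.2)], {"m": [0.1, 0.2]})
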