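"""Synthetic-data generator: determinism, noise model, recoverability."""

import numpy as np
import pytest

from toxmix import CRCRegressor
from toxmix.records import pool_records
from toxmix.simulate import (
    SyntheticStudyConfig,
    TrueCRC,
    simulate_mixture,
    simulate_single,
)


class TestDeterminism:
    def test_same_seed_identical_records(self):
        a = simulate_single(SyntheticStudyConfig(seed=5), "Cr", 96)
        b = simulate_single(SyntheticStudyConfig(seed=5), "Cr", 96)
        assert a == b

    def test_different_seeds_differ(self):
        a = simulate_single(SyntheticStudyConfig(seed=5), "Cr", 96)
        b = simulate_single(SyntheticStudyConfig(seed=6), "Cr", 96)
        assert a != b

    def test_mixture_same_seed_identical(self, reference_rays):
        ray = reference_rays[4]
        a = simulate_mixture(SyntheticStudyConfig(seed=2), ray, 96)
        b = simulate_mixture(SyntheticStudyConfig(seed=2), ray, 96)
        assert a == b

    def test_streams_independent_per_component(self):
        # drawing Cr must not perturb Ni's stream
        cfg = SyntheticStudyConfig(seed=3)
        ni_alone = simulate_single(cfg, "Ni", 96)
        simulate_single(cfg, "Cr", 96)
        ni_again = simulate_single(cfg, "Ni", 96)
        assert ni_alone == ni_again


class TestNoiseModel:
    def test_zero_effect_truth_gives_zero_deaths(self):
        cfg = SyntheticStudyConfig(
            truth={("X", 96): TrueCRC("weibull", -80.0, 1.0)},
            single_concentrations={"X": (0.1, 1.0, 10.0)},
            seed=1,
        )
        records = simulate_single(cfg, "X", 96)
        assert all(r.n_dead == 0 for r in records)

    def test_design_shape(self):
        records = simulate_single(SyntheticStudyConfig(seed=0), "Cr", 96)
        assert len(records) == 5 * 3          # 5 levels x 3 replicates
        assert all(r.n_exposed == 10 for r in records)

    def test_pooled_mortality_converges_to_truth(self):
        # with many replicates the pooled fraction approaches f_true
        cfg = SyntheticStudyConfig(seed=9, replicates=500)
        truth = cfg.true_crc("Cr", 96)
        records = simulate_single(cfg, "Cr", 96)
        x, y = pool_records(records)
        f = truth.predict(x)
        se = np.sqrt(f * (1 - f) / (cfg.n_exposed * cfg.replicates))
        assert np.all(np.abs(y - f) <= 3 * np.maximum(se, 1e-3))

    def test_mixture_requires_series(self, true_curves):
        from toxmix import MixtureRay

        ray = MixtureRay(("Cr", "Ni"), (0.5, 0.5), "empty")
        with pytest.raises(ValueError, match="series"):
            simulate_mixture(SyntheticStudyConfig(seed=0), ray, 96)


class TestConfigValidation:
    def test_bad_truth_model(self):
        with pytest.raises(ValueError, match="truth_model"):
            SyntheticStudyConfig(truth_model="loewe")

    def test_bad_counts(self):
        with pytest.raises(ValueError):
            SyntheticStudyConfig(n_exposed=0)
        with pytest.raises(ValueError):
            SyntheticStudyConfig(replicates=0)

    def test_missing_truth_curve(self):
        cfg = SyntheticStudyConfig(seed=0)
        with pytest.raises(ValueError, match="no true curve"):
            cfg.true_crc("Zn", 96)


class TestRecoverability:
    @staticmethod
    def _recovery_errors(component, family, truth, n_seeds):
        truth_lc50 = float(truth.inverse(0.5))
        errors = []
        for seed in range(n_seeds):
            cfg = SyntheticStudyConfig(seed=seed)
            x, y = pool_records(simulate_single(cfg, component, 96))
            try:
                # a selected fit whose LC50 does not exist (e.g. a BCW with
                # a zero-dose baseline above 50%) counts as a failure too
                fit = CRCRegressor(family=family).fit(x, y)
                lc50 = float(fit.inverse(0.5))
            except Exception:
                continue
            errors.append(abs(lc50 - truth_lc50) / truth_lc50)
        return np.array(errors)

    def test_lc50_recovery_steep_curve_at_study_design_size(self):
        # median |relative error| of the refit LC50 under the bench design
        # (5 levels x 3 reps x 10 animals), nickel-like steep GL truth,
        # fitted with the pipeline's best-of-three estimator
        errors = self._recovery_errors(
            "Ni", "auto", TrueCRC("gl", -9.44, 8.94, 0.2), 200)
        assert len(errors) >= 190          # fits almost always converge
        assert np.median(errors) < 0.15

    def test_lc50_recovery_shallow_curve_sanity(self):
        # the shallow chromium-like curve carries less information per
        # level: recovery is materially worse (median near 17%) but must
        # stay within the same order of magnitude
        errors = self._recovery_errors(
            "Cr", "weibull", TrueCRC("weibull", -0.4, 1.21), 100)
        assert len(errors) >= 95
        assert np.median(errors) < 0.25
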