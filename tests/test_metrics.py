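"""Discrimination and calibration metrics against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from speakval import (
    CalibrationParameters,
    SeparationError,
    load_packaged_model,
    calibration_groups,
    calibration_in_the_large,
    calibration_slope,
    concordance,
    concordance_ci,
    external_validation,
)
from speakval.cohort import build_analysis_cohort
from speakval.metrics import risk_groups_to_tsv
from speakval.model import ModelSpecification, ModelTerm
from speakval.simulate import generate_outcomes, simulate_rats3_cohort

from .oracles import grid_search_alpha, nelder_mead_slope, pairwise_concordance


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

class TestConcordance:
    def test_perfect_separation_is_one(self):
        pred = [0.9, 0.8, 0.7, 0.2, 0.1]
        out = [1, 1, 1, 0, 0]
        assert concordance(pred, out) == 1.0

    def test_all_ties_is_half(self):
        assert concordance([0.5] * 8, [1, 0, 1, 0, 1, 0, 1, 0]) == 0.5

    def test_six_patient_toy_set_matches_pair_enumeration(self):
        pred = [0.9, 0.6, 0.6, 0.4, 0.3, 0.2]
        out = [1, 1, 0, 1, 0, 0]
        assert concordance(pred, out) == pytest.approx(
            pairwise_concordance(pred, out), abs=1e-12
        )

    def test_matches_exhaustive_oracle_on_random_inputs(self, rng):
        """Midrank formula == O(n^2) enumeration for n up to 200, with ties."""
        for _ in range(25):
            n = int(rng.integers(4, 201))
            pred = np.round(rng.random(n), 2)  # rounding forces ties
            out = rng.integers(0, 2, n)
            if out.min() == out.max():
                out[0] = 1 - out[0]
            assert concordance(pred, out) == pytest.approx(
                pairwise_concordance(pred, out), abs=1e-12
            )

    def test_invariant_under_strictly_increasing_transform(self, rng):
        pred = rng.normal(size=80)
        out = (rng.random(80) < expit(pred)).astype(int)
        c = concordance(pred, out)
        assert concordance(np.exp(pred), out) == pytest.approx(c, abs=1e-12)
        assert concordance(expit(pred), out) == pytest.approx(c, abs=1e-12)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            concordance([0.1, 0.2, 0.3], [1, 1, 1])

    def test_good_poor_labels_accepted(self):
        assert concordance([0.9, 0.1], np.array(["good", "poor"])) == 1.0


class TestConcordanceCI:
    # Fixture frozen together with the DeLong interval computed by an
    # independent reference implementation (R pROC, ci.auc method="delong").
    PRED = [0.885, 0.99, 0.906, 0.495, 0.449, 0.712, 0.855, 0.792, 0.99,
            0.504, 0.461, 0.535, 0.495, 0.782, 0.317, 0.69, 0.369, 0.258,
            0.692, 0.362]
    OUT = [1] * 9 + [0] * 11

    def test_delong_interval_matches_reference(self):
        assert concordance(self.PRED, self.OUT) == pytest.approx(0.8636364, abs=1e-7)
        lo, hi = concordance_ci(self.PRED, self.OUT, method="analytic_delong")
        assert lo == pytest.approx(0.6861742, abs=1e-6)
        assert hi == 1.0  # clipped at the upper bound

    def test_perfect_separation_degenerates_at_one(self):
        lo, hi = concordance_ci([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0],
                                method="analytic_delong")
        assert (lo, hi) == (1.0, 1.0)

    def test_bootstrap_is_seed_reproducible(self):
        ci1 = concordance_ci(self.PRED, self.OUT, method="bootstrap", seed=7)
        ci2 = concordance_ci(self.PRED, self.OUT, method="bootstrap", seed=7)
        assert ci1 == ci2
        lo, hi = ci1
        assert lo <= 0.8636364 <= hi

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(10):
            pred = rng.random(40)
            out = rng.integers(0, 2, 40)
            if out.min() == out.max():
                out[0] ^= 1
            c = concordance(pred, out)
            for method in ("analytic_delong", "bootstrap"):
                lo, hi = concordance_ci(pred, out, method=method, seed=3, n_boot=200)
                assert lo <= c <= hi
                assert 0.0 <= lo and hi <= 1.0

    def test_coverage_of_binormal_truth(self):
        """DeLong and percentile-bootstrap intervals both cover the binormal
        large-sample truth in >= 90% of replicates and overlap each other."""
        truth = norm.cdf(1 / np.sqrt(2))  # AUC of N(1,1) cases vs N(0,1) controls
        rng = np.random.default_rng(314)
        n_rep, covered_d, covered_b, overlap = 200, 0, 0, 0
        for _ in range(n_rep):
            scores = np.concatenate([rng.normal(1, 1, 250), rng.normal(0, 1, 250)])
            out = np.concatenate([np.ones(250), np.zeros(250)]).astype(int)
            d = concordance_ci(scores, out, method="analytic_delong")
            b = concordance_ci(scores, out, method="bootstrap",
                               seed=int(rng.integers(2**31)), n_boot=300)
            covered_d += d[0] <= truth <= d[1]
            covered_b += b[0] <= truth <= b[1]
            overlap += max(d[0], b[0]) <= min(d[1], b[1])
        assert covered_d >= 0.9 * n_rep
        assert covered_b >= 0.9 * n_rep
        assert overlap >= 0.9 * n_rep


# ---------------------------------------------------------------------------
# Calibration-in-the-large and slope
# ---------------------------------------------------------------------------

class TestCalibrationInTheLarge:
    def test_perfectly_calibrated_limit(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0.5, 1.5, 50_000)
        out = (rng.random(y.size) < expit(y)).astype(int)
        assert abs(calibration_in_the_large(y, out)) < 0.03

    def test_matches_grid_search_oracle_on_toy_set(self):
        y = np.array([-1.2, -0.4, 0.1, 0.5, 0.9, 1.4, 2.0, -2.0])
        out = np.array([0, 0, 1, 0, 1, 1, 1, 0])
        assert calibration_in_the_large(y, out) == pytest.approx(
            grid_search_alpha(y, out), abs=1e-4
        )

    def test_score_equation_satisfied_at_estimate(self, rng):
        y = rng.normal(0, 1, 500)
        out = (rng.random(500) < expit(-1 + y)).astype(int)
        alpha = calibration_in_the_large(y, out)
        score = out.sum() - expit(alpha + y).sum()
        assert abs(score) < 1e-6

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            calibration_in_the_large([0.1, 0.2], [1, 1])


class TestCalibrationSlope:
    def test_perfectly_calibrated_limit(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0.5, 1.5, 50_000)
        out = (rng.random(y.size) < expit(y)).astype(int)
        a, b = calibration_slope(y, out)
        assert abs(b - 1.0) < 0.03
        assert abs(a) < 0.05

    def test_matches_independent_optimizer_on_toy_set(self):
        y = np.array([-1.5, -1.0, -0.5, -0.2, 0.0, 0.3, 0.7, 1.1, 1.6, 2.2])
        out = np.array([0, 1, 0, 0, 1, 0, 1, 1, 0, 1])
        a, b = calibration_slope(y, out)
        a0, b0 = nelder_mead_slope(y, out)
        assert a == pytest.approx(a0, abs=1e-4)
        assert b == pytest.approx(b0, abs=1e-4)

    def test_gradient_vanishes_at_estimate(self, rng):
        y = rng.normal(1, 1.3, 800)
        out = (rng.random(800) < expit(-0.5 + 0.7 * y)).astype(int)
        a, b = calibration_slope(y, out)
        p = expit(a + b * y)
        grad = np.array([(out - p).sum(), (y * (out - p)).sum()])
        assert np.max(np.abs(grad)) < 1e-6

    def test_constant_linear_predictor_is_an_error(self):
        with pytest.raises(ValueError, match="unidentified"):
            calibration_slope([0.3] * 10, [0, 1] * 5)

    def test_complete_separation_is_an_explicit_error(self):
        y = np.arange(10, dtype=float)
        out = (y > 4.5).astype(int)
        with pytest.raises(SeparationError):
            calibration_slope(y, out)

    @pytest.mark.parametrize("alpha", [-2.0, -1.0, 0.0, 1.0])
    @pytest.mark.parametrize("beta", [0.5, 0.88, 1.0, 1.5])
    def test_parameter_recovery_within_three_standard_errors(self, alpha, beta):
        """Generate n=50,000 outcomes at each truth on a grid; the two-parameter
        fit recovers (alpha, beta) within 3 Fisher standard errors."""
        seed = 1000 + int(10 * (alpha + 3)) + int(100 * beta)
        rng = np.random.default_rng(seed)
        y = rng.normal(1.8, 1.2, 50_000)
        out = (rng.random(y.size) < expit(alpha + beta * y)).astype(int)
        a, b = calibration_slope(y, out)
        p = expit(a + b * y)
        w = p * (1 - p)
        info = np.array([[w.sum(), (w * y).sum()], [(w * y).sum(), (w * y * y).sum()]])
        se = np.sqrt(np.diag(np.linalg.inv(info)))
        assert abs(a - alpha) < 3 * se[0]
        assert abs(b - beta) < 3 * se[1]
        if beta == 1.0:
            alpha_off = calibration_in_the_large(y, out)
            se_off = 1.0 / np.sqrt(w.sum())
            assert abs(alpha_off - alpha) < 4 * se_off


# ---------------------------------------------------------------------------
# Risk groups
# ---------------------------------------------------------------------------

class TestCalibrationGroups:
    def test_divisible_case_gives_equal_groups(self, rng):
        pred = rng.random(125)
        out = rng.integers(0, 2, 125)
        groups = calibration_groups(pred, out, k=5)
        assert [g.n for g in groups] == [25] * 5

    def test_remainder_goes_to_lowest_probability_groups(self, rng):
        groups = calibration_groups(rng.random(12), rng.integers(0, 2, 12), k=5)
        assert [g.n for g in groups] == [3, 3, 2, 2, 2]

    def test_groups_partition_and_preserve_sorted_order(self, rng):
        pred = np.round(rng.random(83), 2)
        out = rng.integers(0, 2, 83)
        groups = calibration_groups(pred, out, k=5)
        assert sum(g.n for g in groups) == 83
        means = [g.mean_predicted for g in groups]
        assert means == sorted(means)
        # concatenating group members in order reproduces the sorted predictions
        order = np.argsort(pred, kind="stable")
        start, reconstructed = 0, []
        for g in groups:
            reconstructed.extend(pred[order[start:start + g.n]])
            start += g.n
        assert reconstructed == sorted(pred)

    def test_observed_proportion_is_exact_count_ratio(self):
        pred = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        out = [0, 1, 0, 1, 1, 1]
        groups = calibration_groups(pred, out, k=3)
        assert [g.observed_proportion for g in groups] == [0.5, 0.5, 1.0]

    def test_too_few_observations_is_an_error(self):
        with pytest.raises(ValueError):
            calibration_groups([0.1, 0.2, 0.3], [1, 0, 1], k=5)

    def test_tsv_export(self, rng):
        groups = calibration_groups(rng.random(25), rng.integers(0, 2, 25), k=5)
        tsv = risk_groups_to_tsv(groups)
        assert tsv.splitlines()[0] == "n\tmean_predicted\tobserved_proportion"
        assert len(tsv.splitlines()) == 6


# ---------------------------------------------------------------------------
# Composite external validation
# ---------------------------------------------------------------------------

def _toy_validation_spec():
    return ModelSpecification(
        name="sim", outcome_horizon_months=6, intercept=0.2,
        terms=[
            ModelTerm(predictor_id="screeling_phonology", coefficient=0.2),
            ModelTerm(predictor_id="barthel_index", coefficient=0.1),
            ModelTerm(predictor_id="age_years", coefficient=-0.03),
        ],
    )


class TestExternalValidation:
    def test_self_consistency_under_perfect_calibration(self):
        spec = _toy_validation_spec()
        df = simulate_rats3_cohort(
            n=50_000, spec=spec, truth=CalibrationParameters(0.0, 1.0), seed=5
        )
        res = external_validation(spec, build_analysis_cohort(df), seed=1)
        assert abs(res.calibration.alpha) < 0.03
        assert abs(res.calibration.beta - 1.0) < 0.03
        for g in res.risk_groups:
            assert abs(g.mean_predicted - g.observed_proportion) < 0.05

    def test_emulation_profile_recovers_generating_slope(self):
        """Under the default miscalibration truth the two-parameter fit
        recovers the generating slope 0.88; the offset alpha is strongly
        negative (the model overestimates good outcome).  With a slope truth
        below 1 the offset fit folds part of the slope misfit into alpha, so
        alpha lands below the generating -1.98 on this population."""
        df = simulate_rats3_cohort(n=50_000, seed=6)
        res = external_validation(
            load_packaged_model("speak12"), build_analysis_cohort(df), seed=2
        )
        assert abs(res.calibration.beta - 0.88) < 0.05
        assert -2.6 < res.calibration.alpha < -1.7
        assert res.mean_predicted == pytest.approx(0.88, abs=0.01)
        assert res.mean_predicted > res.observed_proportion

    def test_every_field_matches_independent_oracles_on_fixed_cohort(self):
        """End-to-end 20-row check: each reported quantity equals its
        independently computed oracle value."""
        rng = np.random.default_rng(77)
        spec = _toy_validation_spec()
        df = simulate_rats3_cohort(
            n=20, spec=spec, truth=CalibrationParameters(-0.5, 0.9), seed=8
        )
        cohort = build_analysis_cohort(df)
        res = external_validation(spec, cohort, k=5, seed=3)

        from speakval.model import linear_predictor_frame
        y = linear_predictor_frame(spec, cohort.records)
        p = expit(y)
        out = cohort.outcome_array()

        assert res.n == 20
        assert res.c_index == pytest.approx(pairwise_concordance(p, out), abs=1e-12)
        assert res.calibration.alpha == pytest.approx(grid_search_alpha(y, out), abs=1e-4)
        a0, b0 = nelder_mead_slope(y, out)
        assert res.slope_model_intercept == pytest.approx(a0, abs=1e-4)
        assert res.calibration.beta == pytest.approx(b0, abs=1e-4)
        assert res.mean_predicted == pytest.approx(p.mean(), abs=1e-12)
        assert res.observed_proportion == pytest.approx(out.mean(), abs=1e-12)
        assert [g.n for g in res.risk_groups] == [4] * 5
        assert sum(g.n * g.observed_proportion for g in res.risk_groups) == out.sum()

    def test_result_serializes_to_json(self):
        df = simulate_rats3_cohort(n=60, seed=10)
        res = external_validation(
            load_packaged_model("speak12"), build_analysis_cohort(df), seed=0
        )
        payload = res.to_dict()
        assert set(payload) >= {
            "c_index", "c_index_ci", "calibration_in_the_large",
            "calibration_slope", "risk_groups", "n",
        }
        import json
        json.loads(res.to_json())
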