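"""Tests of the univariate/effect-size statistics.

Hand-computed step-up FDR values, the pooled-SD t example, the binormal
AUC<->d anchors, a simulation oracle for the Mahalanobis small-sample
correction, and a statsmodels cross-check of the power solver.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parcelmark.stats import (
    auc_to_d,
    bh_fdr,
    cohens_d,
    d_to_auc,
    detectable_d,
    flattening_correlation,
    mahalanobis_D,
    power_two_sample,
    region_ttests,
)


class TestRegionTtests:
    def test_identical_groups_are_null(self, rng):
        x = rng.normal(size=(10, 6))
        rs = region_ttests(x, x.copy())
        np.testing.assert_allclose(rs.table["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(rs.table["p"], 1.0)
        np.testing.assert_allclose(rs.table["cohens_d"], 0.0, atol=1e-12)

    def test_hand_computed_example(self):
        rs = region_ttests(np.array([[1.0], [2.0], [3.0]]),
                           np.array([[4.0], [5.0], [6.0]]))
        assert rs.table["t"].iloc[0] == pytest.approx(-3.674, abs=5e-4)
        assert rs.table["df"].iloc[0] == 4
        assert rs.table["cohens_d"].iloc[0] == pytest.approx(-3.0)

    def test_zero_pooled_variance_names_region(self):
        a = np.ones((5, 3))
        b = np.ones((5, 3))
        a[:, 1] = b[:, 1] = 2.0
        a[:, 0] += np.arange(5) * 0.1
        b[:, 0] += np.arange(5) * 0.1
        with pytest.raises(ValueError, match="'r2'"):
            region_ttests(a, b, region_names=["r1", "r2", "r3"])

    def test_planted_effects_detected_with_fdr_control(self):
        """Power oracle (noncentral t): d=0.8 at n=150/group is detected
        with near-certain per-parcel power, so >= 8/10 planted parcels
        reach q<0.05 while false positives stay near the nominal rate."""
        rng = np.random.default_rng(17)
        hits = fps = 0
        for _ in range(3):
            a = rng.normal(size=(150, 360))
            b = rng.normal(size=(150, 360))
            a[:, :10] += 0.8
            rs = region_ttests(a, b)
            sig = rs.table["q"] < 0.05
            hits += sig[:10].sum() >= 8
            fps += sig[10:].sum() <= 5
        assert hits == 3 and fps == 3


class TestBhFdr:
    def test_hand_computed_step_up_values(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(bh_fdr([0.005, 0.03, 0.5]),
                                   [0.015, 0.045, 0.5])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_never_decreases_and_preserves_order(self, pvals):
        q = bh_fdr(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        # step-up order statistics are monotone after sorting by p
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestAucDConversion:
    @pytest.mark.parametrize("auc,d,dp", [(0.806, 1.221, 3), (0.8, 1.19, 2),
                                          (0.9, 1.81, 2), (0.5, 0.0, 9)])
    def test_binormal_anchors(self, auc, d, dp):
        assert round(auc_to_d(auc), dp) == d

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_round_trip(self, auc):
        assert d_to_auc(auc_to_d(auc)) == pytest.approx(auc, abs=1e-9)

    def test_degenerate_auc_rejected(self):
        for bad in (0.0, 1.0):
            with pytest.raises(ValueError):
                auc_to_d(bad)


class TestMahalanobis:
    def test_univariate_reduction_to_cohens_d(self, rng):
        a = rng.normal(1.0, 1.0, size=(200, 1))
        b = rng.normal(0.0, 1.0, size=(200, 1))
        d = abs(cohens_d(a, b)[0])
        assert mahalanobis_D(a, b, bias_correct=False) == pytest.approx(d)

    def test_large_sample_limit(self, rng):
        a = rng.normal(0, 1, size=(20000, 2))
        a[:, 0] += 1.0
        b = rng.normal(0, 1, size=(20000, 2))
        assert mahalanobis_D(a, b) == pytest.approx(1.0, abs=0.05)

    def test_bias_correction_recenters_null(self):
        """Simulation oracle: at p=35, n=128/109 the uncorrected null
        D^2 is inflated well above 0 while the corrected D^2 (unfloored)
        averages ~0."""
        from parcelmark.stats import _mahalanobis_d2

        rng = np.random.default_rng(23)
        raw, corrected = [], []
        for _ in range(500):
            a = rng.normal(size=(128, 35))
            b = rng.normal(size=(109, 35))
            raw.append(_mahalanobis_d2(a, b, bias_correct=False))
            corrected.append(_mahalanobis_d2(a, b, bias_correct=True))
        assert np.mean(raw) > 0.2
        assert abs(np.mean(corrected)) < 0.05

    def test_too_many_features_rejected(self, rng):
        a = rng.normal(size=(10, 30))
        b = rng.normal(size=(10, 30))
        with pytest.raises(ValueError, match="singular"):
            mahalanobis_D(a, b)


class TestDetectableD:
    def test_reference_design_value(self):
        assert round(detectable_d(0.05, 0.8, 100), 2) == 0.40

    def test_self_consistency(self):
        d = detectable_d(0.05, 0.8, 100)
        assert power_two_sample(d, 100, 0.05) == pytest.approx(0.8, abs=1e-4)

    def test_small_sample_value_against_grid_search(self):
        """Brute-force oracle: scan the power curve over a d grid."""
        d = detectable_d(0.05, 0.8, 26)
        assert 0.78 <= d <= 0.82
        grid = np.arange(0.70, 0.90, 0.0005)
        powers = np.array([power_two_sample(g, 26, 0.05) for g in grid])
        d_grid = grid[np.searchsorted(powers, 0.8)]
        assert d == pytest.approx(d_grid, abs=1e-3)

    def test_agrees_with_statsmodels_power_solver(self):
        from statsmodels.stats.power import TTestIndPower

        for n in (30, 100, 400):
            ours = detectable_d(0.05, 0.8, n)
            theirs = TTestIndPower().solve_power(nobs1=n, alpha=0.05, power=0.8,
                                                 ratio=1.0, alternative="two-sided")
            assert ours == pytest.approx(theirs, abs=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            detectable_d(0.0, 0.8, 100)
        with pytest.raises(ValueError):
            detectable_d(0.05, 0.04, 100)
        with pytest.raises(ValueError):
            detectable_d(0.05, 0.8, 1)


class TestFlatteningCorrelation:
    def test_perfect_anticorrelation(self, rng):
        cent = rng.uniform(1, 5, size=360)
        r, p = flattening_correlation(cent, -(cent - cent.mean()))
        assert r == pytest.approx(-1.0)

    def test_null_is_mostly_uncorrelated(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            r, _ = flattening_correlation(rng.uniform(1, 5, 360),
                                          rng.normal(0, 0.1, 360))
            hits += abs(r) < 0.15
        assert hits >= 9

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            flattening_correlation(np.ones(10), np.arange(10.0))


def test_type_one_error_calibration_on_null_cohorts():
    """On null data the per-parcel rejection rate at alpha=0.05 stays at
    the nominal level (within 2 SE over 20 seeds x 360 parcels)."""
    from parcelmark.synthetic import CohortConfig, generate_cohort

    rates = []
    for seed in range(20):
        config = CohortConfig(n_cases=30, n_controls_per_batch=(30,),
                              include_timeseries=False, seed=100 + seed)
        samples, _ = generate_cohort(config)
        x = np.vstack([s.thickness for s in samples])
        case = np.array([s.group == "case" for s in samples])
        rs = region_ttests(x[case], x[~case])
        rates.append((rs.table["p"] < 0.05).mean())
    assert np.mean(rates) == pytest.approx(0.05, abs=0.01)
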