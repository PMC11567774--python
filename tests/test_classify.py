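"""Tests of the staged-split and cross-validated classification protocol."""

import numpy as np
import pandas as pd
import pytest

from parcelmark.classify import (
    BiomarkerResult,
    _downsample_train,
    evaluate_biomarker,
    permutation_null,
    rank_auc,
    staged_evaluate,
    staged_split,
    vote_share_correlates,
)
from parcelmark.core import FeatureMatrix


def _study_metadata(seed=0, n_multi=60):
    """102 cases (n_multi with 3+ types) and 25/25/300/300 controls."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(102):
        n_types = int(rng.integers(3, 8)) if i < n_multi else int(rng.integers(1, 3))
        rows.append((f"case{i:03d}", "case", 1, n_types))
    cid = 0
    for batch, n in zip((1, 2, 3, 4), (25, 25, 300, 300)):
        for _ in range(n):
            rows.append((f"ctrl{cid:03d}", "control", batch, 0))
            cid += 1
    meta = pd.DataFrame(rows, columns=["subject_id", "group", "batch", "n_types"])
    return meta.set_index("subject_id")


class TestStagedSplit:
    def test_study_sized_cohort_splits_25_25_52(self):
        meta = _study_metadata()
        plan = staged_split(meta, seed=3)
        case_counts = plan.stage_counts(meta["group"] == "case")
        assert case_counts == {"discovery": 25, "demonstration": 25,
                               "generalization": 52}
        # every discovery/demonstration case reports 3+ types
        for stage in ("discovery", "demonstration"):
            ids = [s for s in plan.stage_ids(stage) if meta.loc[s, "group"] == "case"]
            assert all(meta.loc[s, "n_types"] >= 3 for s in ids)

    def test_external_controls_halved_local_to_discovery(self):
        meta = _study_metadata()
        plan = staged_split(meta, seed=3)
        ctrl = meta["group"] == "control"
        for b in (3, 4):
            in_batch = ctrl & (meta["batch"] == b)
            stages = plan.assignment[in_batch]
            assert (stages == "discovery").sum() == 150
            assert (stages == "demonstration").sum() == 150
        local = ctrl & meta["batch"].isin([1, 2])
        assert (plan.assignment[local] == "discovery").all()
        assert plan.assignment.notna().all()  # exhaustive partition

    def test_same_seed_same_plan(self):
        meta = _study_metadata()
        a = staged_split(meta, seed=5).assignment
        b = staged_split(meta, seed=5).assignment
        assert a.equals(b)
        c = staged_split(meta, seed=6).assignment
        assert not a.equals(c)

    def test_proportional_fallback_with_few_multitype_cases(self):
        meta = _study_metadata(n_multi=20)
        with pytest.warns(UserWarning, match="proportional fallback"):
            plan = staged_split(meta, seed=0)
        assert any("fallback" in line for line in plan.rule_trace)
        counts = plan.stage_counts(meta["group"] == "case")
        assert counts["discovery"] + counts["demonstration"] <= 20
        assert sum(counts.values()) == 102


class TestRankAuc:
    def test_known_value_with_tie(self):
        assert rank_auc(np.array([0.6, 0.6, 0.2]), np.array([1, 0, 0])) == 0.75

    def test_matches_exhaustive_pair_counting(self, rng):
        scores = rng.integers(0, 5, size=60).astype(float)  # many ties
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert rank_auc(scores, y) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_matches_sklearn_on_continuous_scores(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=100)
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        assert rank_auc(scores, y) == pytest.approx(roc_auc_score(y, scores))


def test_perfectly_separated_clusters_classify_perfectly(rng):
    x = np.vstack([rng.normal(0, 0.1, (30, 5)), rng.normal(5, 0.1, (40, 5))])
    y = np.array([1] * 30 + [0] * 40)
    res = evaluate_biomarker(x, y, k=5, seed=0, n_trees=100)
    assert res.auc == 1.0
    assert res.sensitivity == 1.0 and res.specificity == 1.0


def test_downsampling_balances_training_only(rng):
    y = np.array([1] * 20 + [0] * 80)
    train_idx = np.arange(80)  # 20 cases, 60 controls
    balanced = _downsample_train(train_idx, y, rng)
    assert (y[balanced] == 1).sum() == (y[balanced] == 0).sum() == 20
    assert set(balanced) <= set(train_idx)
    # held-out subjects all receive votes regardless of imbalance
    x = rng.normal(size=(100, 10))
    res = evaluate_biomarker(x, y, k=5, downsample=True, seed=1, n_trees=50)
    assert np.all(np.isfinite(res.vote_share))
    assert len(res.vote_share) == 100


def test_k_exceeding_minority_count_rejected(rng):
    x = rng.normal(size=(30, 4))
    y = np.array([1] * 4 + [0] * 26)
    with pytest.raises(ValueError, match="minority"):
        evaluate_biomarker(x, y, k=5)


def test_constant_columns_dropped_not_fatal(rng):
    x = rng.normal(size=(40, 6))
    x[:, 2] = 1.0
    y = np.array([1] * 20 + [0] * 20)
    res = evaluate_biomarker(x, y, k=4, seed=0, n_trees=50)
    assert np.isfinite(res.auc)


def test_fold_safe_reduction_of_wide_features(rng):
    x = rng.normal(size=(60, 300))
    fm = FeatureMatrix(biomarker_id="myelin-pairwise", values=x,
                       feature_names=[f"p{i}" for i in range(300)],
                       subject_ids=[f"s{i}" for i in range(60)],
                       needs_reduction=True)
    y = np.array([1] * 30 + [0] * 30)
    res = evaluate_biomarker(fm, y, k=5, seed=2, n_trees=50)
    comps = res.tuned_params["n_components"]
    assert len(comps) == 5
    assert all(c <= 48 for c in comps)  # capped below the training size


def test_hyperparameter_tuning_records_choice(rng):
    x = rng.normal(size=(60, 12))
    x[:30, :4] += 1.0
    y = np.array([1] * 30 + [0] * 30)
    res = evaluate_biomarker(x, y, k=3, tune_grid=(2, 6), seed=0, n_trees=30)
    assert set(res.tuned_params["max_features"]) <= {2, 6}
    assert len(res.tuned_params["max_features"]) == 3


def test_null_features_calibrated_against_own_permutation_null(rng):
    """On pure-noise features the observed AUC falls inside the
    permutation-null 95% CI and the null mean sits at chance."""
    x = rng.normal(size=(80, 20))
    y = np.array([1] * 40 + [0] * 40)
    res = permutation_null(x, y, n_perm=100, k=5, seed=0, n_trees=50)
    lo, hi = res.null_ci95
    assert lo <= res.auc <= hi
    assert 0.45 <= res.null_aucs.mean() <= 0.55
    assert res.p_value > 0.05


def test_permutation_p_value_tail_definition():
    res = BiomarkerResult(auc=0.9, sensitivity=1, specificity=1,
                          vote_share=np.ones(4), labels=np.array([1, 1, 0, 0]),
                          subject_ids=list("abcd"), folds=2, tuned_params={},
                          seed=0, null_aucs=np.linspace(0.3, 0.7, 199))
    assert res.p_value == pytest.approx(1 / 200)


def test_signal_beats_null_distribution(rng):
    x = rng.normal(size=(80, 20))
    x[:40] += 0.8
    y = np.array([1] * 40 + [0] * 40)
    res = permutation_null(x, y, n_perm=100, k=5, seed=1, n_trees=50)
    assert res.auc > res.null_ci95[1]
    assert res.p_value == pytest.approx(1 / 101)


def test_staged_evaluate_freezes_discovery_hyperparameter(rng):
    meta = _study_metadata()
    # shrink the cohort for speed: keep 40 external controls per batch
    keep = [s for s in meta.index
            if meta.loc[s, "group"] == "case"
            or meta.loc[s, "batch"] in (1, 2)
            or int(s[4:]) % 8 == 0]
    meta = meta.loc[keep]
    plan = staged_split(meta, seed=0)
    x = rng.normal(size=(len(meta), 15))
    y = (meta["group"] == "case").astype(int).to_numpy()
    x[y == 1] += 0.6
    fm = FeatureMatrix(biomarker_id="thickness", values=x,
                       feature_names=[f"f{i}" for i in range(15)],
                       subject_ids=list(meta.index))
    results = staged_evaluate(fm, y, plan, tune_grid=(3, 8), k=5,
                              seed=0, n_trees=40)
    assert set(results) == {"discovery", "demonstration", "generalization"}
    frozen = results["demonstration"].tuned_params["frozen_max_features"]
    assert results["generalization"].tuned_params["frozen_max_features"] == frozen
    assert results["generalization"].auc > 0.6  # planted signal generalizes


class TestVoteShareCorrelates:
    def _result(self, votes, labels):
        return BiomarkerResult(auc=0.5, sensitivity=0, specificity=0,
                               vote_share=votes, labels=labels,
                               subject_ids=[str(i) for i in range(len(votes))],
                               folds=2, tuned_params={}, seed=0)

    def test_identity_covariate(self):
        votes = np.linspace(0.1, 0.9, 20)
        labels = np.ones(20, dtype=int)
        r, p = vote_share_correlates(self._result(votes, labels), votes)
        assert r == pytest.approx(1.0)

    def test_independent_covariate_mostly_null(self, rng):
        votes = rng.uniform(size=128)
        labels = np.ones(128, dtype=int)
        hits = 0
        for seed in range(10):
            cov = np.random.default_rng(seed).normal(size=128)
            r, _ = vote_share_correlates(self._result(votes, labels), cov)
            hits += abs(r) < 0.2
        assert hits >= 9

    def test_zero_variance_covariate_rejected(self):
        votes = np.linspace(0, 1, 10)
        with pytest.raises(ValueError, match="zero-variance"):
            vote_share_correlates(self._result(votes, np.ones(10, dtype=int)),
                                  np.ones(10))

    def test_types_linked_effects_yield_positive_correlation(self):
        """When the generator scales planted effects with the number of
        trait types, multi-type cases are easier to classify."""
        from parcelmark.synthetic import CohortConfig, generate_cohort

        config = CohortConfig(
            n_cases=64, n_controls_per_batch=(64,), include_timeseries=False,
            effect_map={"myelin": [(list(range(30)), 0.6)]},
            effect_scales_with_types=True, seed=13,
        )
        samples, _ = generate_cohort(config)
        x = np.vstack([s.myelin for s in samples])
        y = np.array([s.group == "case" for s in samples]).astype(int)
        res = evaluate_biomarker(x, y, k=5, seed=0, n_trees=150)
        n_types = np.array([s.n_types for s in samples if s.group == "case"])
        r, _ = vote_share_correlates(res, n_types)
        assert r > 0
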