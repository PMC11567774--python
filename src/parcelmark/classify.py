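"""Biomarker validation protocol.

Staged sample splits (discovery / demonstration / generalization),
stratified k-fold cross-validated random-forest classification with
training-fold down-sampling, per-subject vote shares, AUC / sensitivity
/ specificity, and permutation-null calibration.

The ensemble learner is a 500-tree random forest with per-tree feature
subsampling; the tested artifact is the protocol around it (fold-safe
reduction, balanced training folds, rank-based AUC with half-credit
ties, label-shuffle nulls), not the learner itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from parcelmark.core import FeatureMatrix
from parcelmark.features import PCAReducer

logger = logging.getLogger(__name__)

N_TREES = 500
STAGES = ("discovery", "demonstration", "generalization")


@dataclass
class SplitPlan:
    """Assignment of subjects to protocol stages with an audit trace."""

    assignment: pd.Series  # subject_id -> stage
    rule_trace: list[str] = field(default_factory=list)

    def stage_ids(self, stage: str) -> list[str]:
        return self.assignment.index[self.assignment == stage].tolist()

    def stage_counts(self, group_mask: pd.Series | None = None) -> dict[str, int]:
        a = self.assignment if group_mask is None else self.assignment[group_mask]
        return {s: int((a == s).sum()) for s in STAGES}


@dataclass
class BiomarkerResult:
    """Cross-validated classification outcome for one biomarker."""

    auc: float
    sensitivity: float
    specificity: float
    vote_share: np.ndarray          # per evaluated subject, P(case) over trees
    labels: np.ndarray              # 1 = case, 0 = control, evaluation order
    subject_ids: list[str]
    folds: int
    tuned_params: dict
    seed: int
    null_aucs: np.ndarray | None = None
    null_ci95: tuple[float, float] | None = None

    @property
    def p_value(self) -> float | None:
        """Empirical upper-tail permutation p with +1 correction."""
        if self.null_aucs is None:
            return None
        return float((1 + (self.null_aucs >= self.auc).sum())
                     / (len(self.null_aucs) + 1))


def staged_split(
    metadata: pd.DataFrame,
    seed: int = 0,
    n_discovery_cases: int = 25,
    n_demonstration_cases: int = 25,
    external_batches: Sequence[int] = (3, 4),
) -> SplitPlan:
    """Assign subjects to discovery / demonstration / generalization.

    Cases reporting three or more trait types fill discovery and then
    demonstration (25 each by default, seeded random tie-break); all
    remaining cases (1+ types) form the generalization sample. Controls
    from the external batches are randomly halved between discovery and
    demonstration; locally acquired controls go to discovery alone.

    ``metadata`` needs columns ``group`` (case/control), ``n_types``
    (cases) and ``batch`` (controls), indexed by subject id. With fewer
    than 50 eligible multi-type cases a proportional fallback is used
    and recorded in the rule trace.
    """
    rng = np.random.default_rng(seed)
    trace: list[str] = []
    assignment = pd.Series(index=metadata.index, dtype=object, name="stage")

    cases = metadata.index[metadata["group"] == "case"]
    multi = [s for s in cases if metadata.loc[s, "n_types"] >= 3]
    n_disc, n_demo = n_discovery_cases, n_demonstration_cases
    if len(multi) < n_disc + n_demo:
        scale = len(multi) / (n_disc + n_demo)
        n_disc = max(1, int(round(n_disc * scale)))
        n_demo = max(1, min(len(multi) - n_disc, int(round(n_demo * scale))))
        msg = (f"only {len(multi)} cases with 3+ types; proportional fallback "
               f"to {n_disc}/{n_demo} discovery/demonstration cases")
        warnings.warn(msg, stacklevel=2)
        trace.append(msg)
    multi = list(np.array(multi)[rng.permutation(len(multi))])
    disc_cases = multi[:n_disc]
    demo_cases = multi[n_disc:n_disc + n_demo]
    gen_cases = [s for s in cases if s not in set(disc_cases) | set(demo_cases)]
    assignment[disc_cases] = "discovery"
    assignment[demo_cases] = "demonstration"
    assignment[gen_cases] = "generalization"
    trace.append(
        f"cases: {len(disc_cases)} discovery / {len(demo_cases)} demonstration "
        f"(3+ types, seeded shuffle) / {len(gen_cases)} generalization (1+ types)"
    )

    controls = metadata.index[metadata["group"] == "control"]
    for b in sorted(pd.unique(metadata.loc[controls, "batch"])):
        ids = [s for s in controls if metadata.loc[s, "batch"] == b]
        if int(b) in set(int(x) for x in external_batches):
            perm = list(np.array(ids)[rng.permutation(len(ids))])
            half = len(perm) // 2
            assignment[perm[:half]] = "discovery"
            assignment[perm[half:]] = "demonstration"
            trace.append(f"controls batch {b}: randomly halved "
                         f"{half}/{len(perm) - half} discovery/demonstration")
        else:
            assignment[ids] = "discovery"
            trace.append(f"controls batch {b}: local, all {len(ids)} to discovery")
    return SplitPlan(assignment=assignment, rule_trace=trace)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def _coerce_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == "case").astype(int)
    return y.astype(int)


def _downsample_train(train_idx: np.ndarray, y: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Balance the training fold by down-sampling the majority class."""
    cls, counts = np.unique(y[train_idx], return_counts=True)
    n_min = counts.min()
    keep = []
    for c in cls:
        members = train_idx[y[train_idx] == c]
        if len(members) > n_min:
            members = rng.choice(members, size=n_min, replace=False)
        keep.append(members)
    out = np.concatenate(keep)
    return np.sort(out)


def _tune_max_features(
    x: np.ndarray, y: np.ndarray, tune_grid: Sequence[int],
    seed: int, n_trees: int,
) -> int:
    """Inner 3-fold selection of the features-per-tree parameter."""
    inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed % (2 ** 31))
    best, best_auc = None, -np.inf
    for mtry in tune_grid:
        mtry_eff = min(int(mtry), x.shape[1])
        aucs = []
        for tr, te in inner.split(x, y):
            clf = RandomForestClassifier(
                n_estimators=n_trees, max_features=mtry_eff,
                random_state=(seed + mtry_eff) % (2 ** 31), n_jobs=1,
            ).fit(x[tr], y[tr])
            proba = clf.predict_proba(x[te])[:, list(clf.classes_).index(1)]
            aucs.append(rank_auc(proba, y[te]))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:  # ties resolved toward the smaller grid value
            best, best_auc = mtry_eff, mean_auc
    return best


def evaluate_biomarker(
    features: FeatureMatrix | np.ndarray,
    labels,
    k: int = 5,
    downsample: bool = True,
    tune_grid: Sequence[int] | None = None,
    seed: int = 0,
    var_target: float = 0.95,
    n_trees: int = N_TREES,
    max_features: int | str = "sqrt",
) -> BiomarkerResult:
    """Stratified k-fold cross-validated ensemble classification.

    Within each training fold the majority class is down-sampled to the
    minority count (seeded) when ``downsample`` is set, any PCA
    reduction is fitted on that training fold only, and the tuned
    features-per-tree parameter is selected by inner 3-fold resampling
    over ``tune_grid`` when given. Held-out vote shares are pooled over
    folds; AUC is the rank statistic with half-credit ties, and
    sensitivity/specificity use the 0.5 vote threshold.
    """
    if isinstance(features, FeatureMatrix):
        x_all = features.values
        subject_ids = features.subject_ids or [str(i) for i in range(x_all.shape[0])]
        needs_reduction = features.needs_reduction
    else:
        x_all = np.asarray(features, dtype=float)
        subject_ids = [str(i) for i in range(x_all.shape[0])]
        needs_reduction = False
    y = _coerce_labels(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the minority class count {counts.min()}")

    const = np.where(x_all.std(axis=0) == 0)[0]
    if const.size:
        logger.info("dropping %d constant feature column(s)", const.size)
        x_all = np.delete(x_all, const, axis=1)
    x_all = np.ascontiguousarray(x_all, dtype=np.float32)

    rng = np.random.default_rng(seed)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 31))
    vote = np.full(len(y), np.nan)
    tuned: dict = {}
    for fold, (train_idx, test_idx) in enumerate(cv.split(x_all, y)):
        if downsample:
            train_idx = _downsample_train(train_idx, y, rng)
        x_train, y_train = x_all[train_idx], y[train_idx]
        x_test = x_all[test_idx]
        if needs_reduction:
            reducer = PCAReducer(var_target=var_target).fit(x_train)
            x_train = reducer.transform(x_train).astype(np.float32)
            x_test = reducer.transform(x_test).astype(np.float32)
            tuned.setdefault("n_components", []).append(reducer.n_components)
        if tune_grid is not None:
            mtry = _tune_max_features(x_train, y_train, tune_grid,
                                      seed * 1000 + fold, n_trees)
            tuned.setdefault("max_features", []).append(mtry)
        else:
            mtry = max_features
        clf = RandomForestClassifier(
            n_estimators=n_trees, max_features=mtry,
            random_state=(seed * 1000 + fold) % (2 ** 31), n_jobs=1,
        ).fit(x_train, y_train)
        proba = clf.predict_proba(x_test)
        vote[test_idx] = proba[:, list(clf.classes_).index(1)]

    auc = rank_auc(vote, y)
    pred = (vote >= 0.5).astype(int)
    sens = float((pred[y == 1] == 1).mean())
    spec = float((pred[y == 0] == 0).mean())
    return BiomarkerResult(
        auc=auc, sensitivity=sens, specificity=spec, vote_share=vote,
        labels=y, subject_ids=list(subject_ids), folds=k, tuned_params=tuned,
        seed=seed,
    )


def permutation_null(
    features: FeatureMatrix | np.ndarray,
    labels,
    n_perm: int = 1000,
    k: int = 5,
    downsample: bool = True,
    seed: int = 0,
    n_trees: int = N_TREES,
    observed: BiomarkerResult | None = None,
) -> BiomarkerResult:
    """Chance baseline by shuffling group labels ``n_perm`` times.

    Each permutation re-runs the full cross-validated protocol on the
    shuffled labels. Returns the observed result (computed here when not
    supplied) with ``null_aucs`` and the percentile 95% CI attached.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for CI reporting")
    y = _coerce_labels(labels)
    if observed is None:
        observed = evaluate_biomarker(features, y, k=k, downsample=downsample,
                                      seed=seed, n_trees=n_trees)
    rng = np.random.default_rng(seed)
    null_aucs = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        res = evaluate_biomarker(
            features, y_perm, k=k, downsample=downsample,
            seed=int(rng.integers(2 ** 31)), n_trees=n_trees,
        )
        null_aucs[i] = res.auc
    observed.null_aucs = null_aucs
    lo, hi = np.percentile(null_aucs, [2.5, 97.5])
    observed.null_ci95 = (float(lo), float(hi))
    return observed


def _subset_ids(x_all, y, ids, keep_ids):
    mask = np.isin(ids, list(keep_ids))
    if isinstance(x_all, FeatureMatrix):
        fm = FeatureMatrix(
            biomarker_id=x_all.biomarker_id, values=x_all.values[mask],
            feature_names=x_all.feature_names,
            subject_ids=list(np.asarray(x_all.subject_ids)[mask]),
            needs_reduction=x_all.needs_reduction,
        )
        return fm, y[mask]
    return x_all[mask], y[mask]


def staged_evaluate(
    features: FeatureMatrix | np.ndarray,
    labels,
    plan: SplitPlan,
    tune_grid: Sequence[int] = (3, 5, 8, 12, 19),
    k: int = 5,
    downsample: bool = True,
    seed: int = 0,
    n_trees: int = N_TREES,
) -> dict[str, BiomarkerResult]:
    """Staged protocol: tune on discovery, freeze, then evaluate each stage.

    The features-per-tree parameter is selected by inner resampling on
    the discovery sample and frozen for the demonstration and
    generalization evaluations.
    """
    if isinstance(features, FeatureMatrix):
        ids = np.asarray(features.subject_ids)
        x_all = features
    else:
        x_all = np.asarray(features, dtype=float)
        ids = np.arange(x_all.shape[0]).astype(str)
    y = _coerce_labels(labels)

    def subset(stage):
        return _subset_ids(x_all, y, ids, plan.stage_ids(stage))

    results: dict[str, BiomarkerResult] = {}
    x_disc, y_disc = subset("discovery")
    disc = evaluate_biomarker(x_disc, y_disc, k=k, downsample=downsample,
                              tune_grid=tune_grid, seed=seed, n_trees=n_trees)
    results["discovery"] = disc
    chosen = disc.tuned_params.get("max_features")
    frozen = int(np.median(chosen)) if chosen else "sqrt"
    for stage in ("demonstration", "generalization"):
        stage_ids = plan.stage_ids(stage)
        if stage == "generalization":
            # the generalization stage holds cases only; pair them with
            # the demonstration controls for a two-class evaluation
            demo_mask = np.isin(ids, plan.stage_ids("demonstration"))
            stage_ids = stage_ids + list(ids[demo_mask & (y == 0)])
        x_s, y_s = _subset_ids(x_all, y, ids, stage_ids)
        if len(np.unique(y_s)) < 2 or np.bincount(y_s).min() < k:
            continue
        results[stage] = evaluate_biomarker(
            x_s, y_s, k=k, downsample=downsample, seed=seed + 1,
            n_trees=n_trees, max_features=frozen,
        )
        results[stage].tuned_params["frozen_max_features"] = frozen
    return results


def vote_share_correlates(
    result: BiomarkerResult, covariate: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation between case vote shares and a per-case
    covariate (e.g. number of trait types), with two-sided p."""
    votes = result.vote_share[result.labels == 1]
    cov = np.asarray(covariate, dtype=float)
    if cov.shape != votes.shape:
        raise ValueError("covariate must be defined for every case")
    if np.std(cov) == 0:
        raise ValueError("zero-variance covariate")
    r, p = sps.pearsonr(votes, cov)
    return float(r), float(p)
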