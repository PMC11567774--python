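"""Structural biomarker feature-set builders.

Thirteen biomarkers are defined over parcellated phenotypes: four global
variables (total surface area, eTIV, sex, age), regional surface area as
percent of total, subcortical volumes as percent of eTIV, cortical
thickness and intracortical myelin per parcel, their inter-regional
absolute pairwise differences (PCA-reduced) and per-region sums, and
four functional-connectome sets built in :mod:`parcelmark.connectome`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from parcelmark.core import FeatureMatrix, ParcellatedSample, parcel_labels

SEX_CODES = {"F": 0.0, "M": 1.0}  # documented coding: F=0, M=1

#: Registry of the thirteen biomarkers: id -> (feature count, source).
#: "pairs" entries are n(n-1)/2-wide and PCA-reduced inside training
#: folds; counts are for the default 360-parcel / 34-structure layout.
BIOMARKER_REGISTRY: dict[str, tuple[int | str, str]] = {
    "global-sa-etiv": (4, "global surface area, eTIV, sex, age"),
    "regional-area": (360, "parcel surface area as % of total"),
    "subcortical": (34, "structure volumes as % of eTIV"),
    "thickness": (360, "parcel cortical thickness (mm)"),
    "thickness-pairwise": ("pca:64620", "abs pairwise thickness differences"),
    "thickness-summed": (360, "per-parcel sum of abs thickness differences"),
    "myelin": (360, "parcel T1w/T2w myelin ratio"),
    "myelin-pairwise": ("pca:64620", "abs pairwise myelin differences"),
    "myelin-summed": (360, "per-parcel sum of abs myelin differences"),
    "fc-partial": ("pca:64620", "partial-correlation edge weights"),
    "fc-centrality": (360, "degree centrality of the partial connectome"),
    "gradient-1": (360, "first principal connectome gradient score"),
    "gradient-2": (360, "second principal connectome gradient score"),
}


def global_sa_etiv_features(samples: Sequence[ParcellatedSample]) -> FeatureMatrix:
    """Global biomarker: [global_area mm^2, eTIV mm^3, sex code, age]."""
    values = np.array(
        [[s.global_area, s.etiv, SEX_CODES[s.sex], s.age] for s in samples]
    )
    return FeatureMatrix(
        biomarker_id="global-sa-etiv",
        values=values,
        feature_names=["global_area", "etiv", "sex_coded", "age"],
        subject_ids=[s.subject_id for s in samples],
    )


def area_etiv_ratio(sample: ParcellatedSample) -> float:
    """Surface area per intracranial volume, cm^2 per cm^3."""
    return (sample.global_area / 100.0) / (sample.etiv / 1000.0)


def regional_area_percent(sample: ParcellatedSample) -> np.ndarray:
    """Parcel surface areas rescaled to percent of total (sums to 100)."""
    area = np.asarray(sample.area, dtype=float)
    if np.any(area < 0):
        raise ValueError("negative parcel area")
    total = area.sum()
    if total == 0:
        raise ValueError("all-zero surface area")
    return 100.0 * area / total


def volumes_percent_etiv(sample: ParcellatedSample) -> np.ndarray:
    """Subcortical volumes rescaled to percent of eTIV."""
    v = np.asarray(sample.subcortical, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative structure volume")
    return 100.0 * v / sample.etiv


def pairwise_abs_diff(map360: np.ndarray) -> np.ndarray:
    """Absolute difference of a parcel map between every pair of regions.

    Ordering is the fixed upper-triangle (i < j) row-major convention;
    for n parcels the result has length n(n-1)/2 (64,620 for n=360).
    """
    x = np.asarray(map360, dtype=float)
    iu, ju = np.triu_indices(x.size, k=1)
    return np.abs(x[iu] - x[ju])


def summed_abs_diff(map360: np.ndarray) -> np.ndarray:
    """Per-region sum of absolute differences to all other regions.

    Satisfies ``summed.sum() == 2 * pairwise.sum()`` since every pair is
    counted once from each end.
    """
    x = np.asarray(map360, dtype=float)
    return np.abs(x[:, None] - x[None, :]).sum(axis=1)


def pair_feature_names(n_parcels: int) -> list[str]:
    labels = parcel_labels(n_parcels)
    iu, ju = np.triu_indices(n_parcels, k=1)
    return [f"{labels[i]}|{labels[j]}" for i, j in zip(iu, ju)]


@dataclass
class PCAReducer:
    """Centered principal-component reducer fit on training folds only.

    Retains the smallest number of components reaching ``var_target``
    (default 0.95) of the training variance, capped at n_train - 1.
    """

    var_target: float = 0.95
    mean_: np.ndarray | None = None
    components_: np.ndarray | None = None
    explained_variance_ratio_: np.ndarray | None = None

    def fit(self, train: np.ndarray) -> "PCAReducer":
        if not 0.0 < self.var_target <= 1.0:
            raise ValueError("var_target must lie in (0, 1]")
        x = np.asarray(train, dtype=float)
        if x.shape[0] < 3:
            raise ValueError("PCA reduction needs at least 3 training subjects")
        self.mean_ = x.mean(axis=0)
        xc = x - self.mean_
        # economy SVD: at most n_train-1 informative components
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        var = s ** 2
        total = var.sum()
        ratios = var / total if total > 0 else var
        cum = np.cumsum(ratios)
        k = int(np.searchsorted(cum, self.var_target - 1e-12) + 1)
        k = min(k, x.shape[0] - 1, (s > 1e-12 * s[0]).sum() if s[0] > 0 else 1)
        k = max(k, 1)
        self.components_ = vt[:k]
        self.explained_variance_ratio_ = ratios[:k]
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.components_ is None:
            raise RuntimeError("reducer has not been fitted")
        return (np.asarray(x, dtype=float) - self.mean_) @ self.components_.T

    @property
    def n_components(self) -> int:
        return 0 if self.components_ is None else self.components_.shape[0]


def fit_reducer(train: np.ndarray, var_target: float = 0.95) -> PCAReducer:
    return PCAReducer(var_target=var_target).fit(train)


def apply_reducer(state: PCAReducer, x: np.ndarray) -> np.ndarray:
    return state.transform(x)


@dataclass
class CovarianceSummary:
    """Across-subject inter-regional correlation matrix for one group."""

    group_label: str
    r_matrix: np.ndarray
    resample_spec: tuple[int, int, int] | None = None  # (n_per, n_resamples, seed)

    def mean_offdiagonal(self) -> float:
        n = self.r_matrix.shape[0]
        iu = np.triu_indices(n, k=1)
        return float(self.r_matrix[iu].mean())


def _corr_across_subjects(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.where(sd == 0)[0][0])
        raise ValueError(f"zero-variance region {bad} in structural covariance input")
    r = np.corrcoef(x, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def structural_covariance(
    samples: Sequence[ParcellatedSample],
    measure: str = "thickness",
    resample_spec: tuple[int, int, int] | None = None,
    group_label: str = "",
) -> CovarianceSummary:
    """Structural covariance: across-subject correlation of a measure
    between every pair of regions.

    With ``resample_spec = (n_per, n_resamples, seed)`` the returned
    matrix is the mean over seeded subsamples of ``n_per`` subjects,
    which balances group sizes when comparing groups of unequal n.
    """
    x = np.vstack([getattr(s, measure) for s in samples])
    if x.shape[0] < 3:
        raise ValueError("structural covariance needs at least 3 subjects")
    if resample_spec is None:
        r = _corr_across_subjects(x)
    else:
        n_per, n_resamples, seed = resample_spec
        if n_per > x.shape[0]:
            raise ValueError("resample size exceeds group size")
        rng = np.random.default_rng(seed)
        acc = np.zeros((x.shape[1], x.shape[1]))
        for _ in range(n_resamples):
            idx = rng.choice(x.shape[0], size=n_per, replace=False)
            acc += _corr_across_subjects(x[idx])
        r = acc / n_resamples
        np.fill_diagonal(r, 1.0)
    return CovarianceSummary(group_label=group_label, r_matrix=r,
                             resample_spec=resample_spec)


def structural_feature_matrix(
    samples: Sequence[ParcellatedSample], biomarker_id: str
) -> FeatureMatrix:
    """Build any of the nine structural biomarkers for a cohort.

    Pairwise biomarkers return the full n(n-1)/2-wide matrix with
    ``needs_reduction`` set; PCA happens fold-safely at evaluation time.
    """
    ids = [s.subject_id for s in samples]
    n_parcels = samples[0].area.size
    labels = parcel_labels(n_parcels)
    if biomarker_id == "global-sa-etiv":
        return global_sa_etiv_features(samples)
    if biomarker_id == "regional-area":
        values = np.vstack([regional_area_percent(s) for s in samples])
        names = labels
    elif biomarker_id == "subcortical":
        values = np.vstack([volumes_percent_etiv(s) for s in samples])
        from parcelmark.core import SUBCORTICAL_LABELS

        names = list(SUBCORTICAL_LABELS[: values.shape[1]])
    elif biomarker_id in ("thickness", "myelin"):
        values = np.vstack([getattr(s, biomarker_id) for s in samples])
        names = labels
    elif biomarker_id in ("thickness-pairwise", "myelin-pairwise"):
        measure = biomarker_id.split("-")[0]
        values = np.vstack([pairwise_abs_diff(getattr(s, measure)) for s in samples])
        return FeatureMatrix(
            biomarker_id=biomarker_id,
            values=values,
            feature_names=pair_feature_names(n_parcels),
            subject_ids=ids,
            needs_reduction=True,
        )
    elif biomarker_id in ("thickness-summed", "myelin-summed"):
        measure = biomarker_id.split("-")[0]
        values = np.vstack([summed_abs_diff(getattr(s, measure)) for s in samples])
        names = labels
    else:
        raise KeyError(f"not a structural biomarker: {biomarker_id!r}")
    return FeatureMatrix(
        biomarker_id=biomarker_id, values=values, feature_names=list(names),
        subject_ids=ids,
    )
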