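"""Functional-connectome derivations.

Pearson correlation connectomes from parcel time series, partial
correlations via a shrinkage-regularized precision matrix, degree
centrality (sum of absolute edge weights), and the first two connectome
gradients with Procrustes alignment to a control-derived reference.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.linalg import orthogonal_procrustes

from parcelmark.core import Connectome, FeatureMatrix, GradientSet, RestingTimeseries


def pearson_connectome(ts: RestingTimeseries) -> Connectome:
    """Pearson correlation between every pair of parcel time series."""
    sd = ts.data.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.where(sd == 0)[0][0])
        raise ValueError(f"zero-variance parcel {bad} in timeseries {ts.subject_id}")
    r = np.corrcoef(ts.data)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return Connectome(weights=r, kind="pearson")


def _analytic_shrinkage(z: np.ndarray) -> float:
    """Ledoit-Wolf-style analytic shrinkage intensity of the sample
    correlation matrix toward the identity (Schafer & Strimmer 2005).

    ``z`` is the standardized (parcels x timepoints) data. The optimal
    intensity is the ratio of the summed sampling variances of the
    off-diagonal correlations to their summed squares.
    """
    p, t = z.shape
    r = (z @ z.T) / (t - 1)
    iu = np.triu_indices(p, k=1)
    r_off = r[iu]
    # var(r_ij) from the time-resolved products w_t = z_it * z_jt:
    # sum_t (w_t - r)^2 = sum_t w_t^2 - (t - 2) r^2  since sum_t w_t = (t-1) r
    s2 = (z ** 2) @ (z ** 2).T
    var_r = (s2[iu] - (t - 2) * r_off ** 2) * t / ((t - 1) ** 3)
    denom = (r_off ** 2).sum()
    if denom <= 0:
        return 1.0
    return float(np.clip(var_r.sum() / denom, 0.0, 1.0))


def partial_connectome(ts: RestingTimeseries, shrinkage: str | float = "auto") -> Connectome:
    """Partial correlations from a shrinkage-regularized correlation matrix.

    The sample correlation matrix R is replaced by
    ``(1 - lam) R + lam I`` and inverted; the partial correlation is
    ``-Omega_ij / sqrt(Omega_ii Omega_jj)``. ``shrinkage="auto"`` uses
    the analytic optimal intensity; a float fixes ``lam`` directly.
    With p parcels and modest scan lengths the unregularized inverse is
    ill-posed, which the shrinkage remedies.
    """
    x = ts.data
    p, t = x.shape
    if t < 30:
        raise ValueError("partial correlations need at least 30 timepoints")
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = int(np.where(sd == 0)[0][0])
        raise ValueError(f"zero-variance parcel {bad} in timeseries {ts.subject_id}")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    r = (z @ z.T) / (t - 1)
    np.fill_diagonal(r, 1.0)
    lam = _analytic_shrinkage(z) if shrinkage == "auto" else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    r_shrunk = (1.0 - lam) * r + lam * np.eye(p)
    try:
        omega = np.linalg.inv(r_shrunk)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - shrinkage>0 prevents this
        raise ValueError("regularized correlation matrix is singular") from exc
    d = np.sqrt(np.diag(omega))
    pc = -omega / np.outer(d, d)
    pc = (pc + pc.T) / 2.0
    np.fill_diagonal(pc, 0.0)
    return Connectome(weights=pc, kind="partial")


def degree_centrality(c: Connectome, allow_pearson: bool = False) -> np.ndarray:
    """Per-region sum of absolute edge weights (network hub strength).

    Defined on partial-correlation connectomes; pass
    ``allow_pearson=True`` to accept a Pearson connectome anyway.
    """
    if c.kind != "partial" and not allow_pearson:
        raise ValueError("degree centrality is defined on partial connectomes "
                         "(pass allow_pearson=True to override)")
    return np.abs(c.weights).sum(axis=1)


def _row_pca(weights: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """PCA over connectome rows (each region's connectivity profile)."""
    x = weights - weights.mean(axis=0, keepdims=True)
    if np.allclose(x, 0):
        raise ValueError("degenerate connectome: all rows equal")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    var = s ** 2
    explained = var[:n_components] / var.sum()
    # deterministic sign: largest-magnitude score positive
    for g in range(n_components):
        j = int(np.argmax(np.abs(scores[:, g])))
        if scores[j, g] < 0:
            scores[:, g] = -scores[:, g]
    return scores, explained


def gradient_reference(connectomes: Sequence[Connectome]) -> GradientSet:
    """Reference gradients from the mean (control-group) connectome.

    Requires at least 10 connectomes so the reference is a stable group
    mean rather than an individual solution.
    """
    if len(connectomes) < 10:
        raise ValueError("gradient reference needs >= 10 connectomes")
    mean_w = np.mean([c.weights for c in connectomes], axis=0)
    scores, explained = _row_pca(mean_w)
    return GradientSet(scores=scores, explained_variance=explained,
                       reference_aligned=True)


def gradients(c: Connectome, reference: GradientSet) -> GradientSet:
    """Subject gradients aligned to a reference by orthogonal Procrustes.

    Per-subject PCA axes carry a sign/rotation indeterminacy; aligning
    the first two components to the reference makes scores comparable
    across subjects.
    """
    scores, explained = _row_pca(c.weights)
    rot, _scale = orthogonal_procrustes(scores, reference.scores)
    return GradientSet(scores=scores @ rot, explained_variance=explained,
                       reference_aligned=True)


def connectome_feature_matrix(
    connectomes: Sequence[Connectome],
    biomarker_id: str,
    subject_ids: Sequence[str],
    reference: GradientSet | None = None,
    pearson_connectomes: Sequence[Connectome] | None = None,
) -> FeatureMatrix:
    """Build the four functional biomarkers from per-subject connectomes.

    ``fc-partial`` / ``fc-centrality`` consume partial-correlation
    connectomes; the gradient biomarkers consume Pearson connectomes
    (pass them via ``pearson_connectomes`` or as ``connectomes``).
    """
    from parcelmark.features import pair_feature_names
    from parcelmark.core import parcel_labels

    n_parcels = connectomes[0].n_parcels
    if biomarker_id == "fc-partial":
        values = np.vstack([c.upper_triangle() for c in connectomes])
        return FeatureMatrix(
            biomarker_id=biomarker_id, values=values,
            feature_names=pair_feature_names(n_parcels),
            subject_ids=list(subject_ids), needs_reduction=True,
        )
    if biomarker_id == "fc-centrality":
        values = np.vstack([degree_centrality(c) for c in connectomes])
        return FeatureMatrix(
            biomarker_id=biomarker_id, values=values,
            feature_names=parcel_labels(n_parcels), subject_ids=list(subject_ids),
        )
    if biomarker_id in ("gradient-1", "gradient-2"):
        source = pearson_connectomes if pearson_connectomes is not None else connectomes
        if reference is None:
            raise ValueError("gradient biomarkers need a reference GradientSet")
        g = int(biomarker_id[-1]) - 1
        values = np.vstack([gradients(c, reference).scores[:, g] for c in source])
        return FeatureMatrix(
            biomarker_id=biomarker_id, values=values,
            feature_names=parcel_labels(n_parcels), subject_ids=list(subject_ids),
        )
    raise KeyError(f"not a connectome biomarker: {biomarker_id!r}")
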