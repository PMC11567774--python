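"""Empirical-Bayes batch harmonization (parametric ComBat).

Removes additive (location) and multiplicative (scale) batch effects
from a subjects x features table while preserving modeled covariates
(age, sex, and optionally group status). The additive effects carry a
Normal prior and the multiplicative effects an Inverse-Gamma prior, with
hyperparameters estimated per batch by method of moments and posterior
estimates found by the standard iterative fixed-point update.

Whether group status enters the covariate design is a caller choice
(``preserve-group``): including it protects genuine group differences
from being absorbed as batch effects; omitting it emulates harmonizing
against unlabeled reference data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONVERGENCE_TOL = 1e-6
MAX_ITER = 500


@dataclass
class CombatModel:
    """Fitted empirical-Bayes location/scale harmonization model."""

    alpha: np.ndarray            # per-feature grand intercept
    beta: np.ndarray             # covariates x features coefficients
    gamma_star: np.ndarray       # batches x features shrunken additive effects
    delta_star: np.ndarray       # batches x features shrunken variance ratios (>0)
    pooled_var: np.ndarray       # per-feature variance used for standardization
    batch_levels: list
    covariate_names: list[str]
    adjusted: np.ndarray | None = None  # adjusted training data

    def __post_init__(self) -> None:
        if np.any(self.delta_star <= 0):
            raise ValueError("delta_star must be positive")
        if self.gamma_star.shape != self.delta_star.shape:
            raise ValueError("gamma_star/delta_star shapes differ")
        if self.gamma_star.shape[0] != len(self.batch_levels):
            raise ValueError("one gamma_star/delta_star row per batch level required")


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), [str(c) for c in features.columns]
    x = np.asarray(features, dtype=float)
    return x, [f"f{i}" for i in range(x.shape[1])]


def _covariate_matrix(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), [str(c) for c in covariates.columns]
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    return c, [f"c{i}" for i in range(c.shape[1])]


def combat_fit(features, batch, covariates=None) -> CombatModel:
    """Fit the parametric EB location/scale model.

    Parameters
    ----------
    features
        Subjects x features array or DataFrame.
    batch
        Batch label per subject (any hashable level; >=2 subjects each).
    covariates
        Optional subjects x c design columns (e.g. age, coded sex,
        coded group). Must be full rank together with the batch design.

    Returns a :class:`CombatModel` whose ``adjusted`` attribute holds the
    harmonized training data.
    """
    y, feature_names = _as_matrix(features)
    n, p = y.shape
    batch = np.asarray(batch)
    levels = sorted(pd.unique(batch).tolist())
    n_per = np.array([(batch == b).sum() for b in levels])
    if np.any(n_per < 2):
        bad = levels[int(np.argmin(n_per))]
        raise ValueError(f"batch {bad!r} has a single subject; variance undefined")
    c, cov_names = _covariate_matrix(covariates, n)

    onehot = np.column_stack([(batch == b).astype(float) for b in levels])
    design = np.column_stack([onehot, c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix (batch + covariates)")

    # per-batch zero-variance features break standardization
    for b in levels:
        sub = y[batch == b]
        zero = np.where(sub.std(axis=0) == 0)[0]
        if zero.size:
            raise ValueError(
                f"zero-variance feature {feature_names[zero[0]]!r} within batch {b!r}"
            )

    b_hat, *_ = np.linalg.lstsq(design, y, rcond=None)
    k = len(levels)
    alpha = (n_per / n) @ b_hat[:k]          # weighted grand intercept
    beta = b_hat[k:]
    resid = y - design @ b_hat
    pooled_var = (resid ** 2).mean(axis=0)

    stand_mean = alpha[None, :] + c @ beta
    z = (y - stand_mean) / np.sqrt(pooled_var)[None, :]

    gamma_hat = np.vstack([z[batch == b].mean(axis=0) for b in levels])
    delta_hat = np.vstack([z[batch == b].var(axis=0, ddof=1) for b in levels])

    if len(levels) == 1:
        # a single batch carries no between-batch variation to remove;
        # the adjustment is the identity
        gamma_star = np.zeros_like(gamma_hat)
        delta_star = np.ones_like(delta_hat)
    else:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i, b in enumerate(levels):
            g, d = _eb_fixed_point(z[batch == b], gamma_hat[i], delta_hat[i])
            gamma_star[i], delta_star[i] = g, d

    model = CombatModel(
        alpha=alpha, beta=beta, gamma_star=gamma_star, delta_star=delta_star,
        pooled_var=pooled_var, batch_levels=levels, covariate_names=cov_names,
    )
    model.adjusted = _adjust(model, y, batch, c)
    return model


def _eb_fixed_point(z_b: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray,
                    tol: float = CONVERGENCE_TOL, max_iter: int = MAX_ITER):
    """Posterior additive/scale estimates for one batch.

    Normal prior on the additive effect (moments ``gamma_bar``, ``tau2``
    across features) and Inverse-Gamma prior on the variance ratio
    (shape/scale from the method of moments); iterated to convergence.
    """
    n_b = z_b.shape[0]
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1)
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    a_prior = (2 * s2 + m ** 2) / s2 if s2 > 0 else 2.0 + 1e-8
    b_prior = (m * s2 + m ** 3) / s2 if s2 > 0 else m

    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for _ in range(max_iter):
        if tau2 > 0:
            g_new = (n_b * tau2 * gamma_hat + d_old * gamma_bar) / (n_b * tau2 + d_old)
        else:
            g_new = np.full_like(gamma_hat, gamma_bar)
        sum2 = ((z_b - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b_prior) / (n_b / 2.0 + a_prior - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / (np.abs(g_old).max() + 1e-12),
            np.abs(d_new - d_old).max() / (np.abs(d_old).max() + 1e-12),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, np.maximum(d_old, 1e-12)


def _adjust(model: CombatModel, y: np.ndarray, batch: np.ndarray, c: np.ndarray) -> np.ndarray:
    stand_mean = model.alpha[None, :] + c @ model.beta
    z = (y - stand_mean) / np.sqrt(model.pooled_var)[None, :]
    out = np.empty_like(z)
    for i, b in enumerate(model.batch_levels):
        rows = batch == b
        out[rows] = (z[rows] - model.gamma_star[i][None, :]) / np.sqrt(
            model.delta_star[i]
        )[None, :]
    return out * np.sqrt(model.pooled_var)[None, :] + stand_mean


def combat_apply(model: CombatModel, features, batch, covariates=None) -> np.ndarray:
    """Apply a fitted model to (possibly new) data.

    Batch levels must be a subset of the fitted levels. Applying to the
    training data reproduces ``model.adjusted`` exactly.
    """
    y, feature_names = _as_matrix(features)
    batch = np.asarray(batch)
    unseen = set(pd.unique(batch)) - set(model.batch_levels)
    if unseen:
        raise ValueError(f"unseen batch level(s): {sorted(unseen)}")
    for b in pd.unique(batch):
        sub = y[batch == b]
        if sub.shape[0] >= 2:
            zero = np.where(sub.std(axis=0) == 0)[0]
            if zero.size:
                raise ValueError(
                    f"zero-variance feature {feature_names[zero[0]]!r} within batch {b!r}"
                )
    c, _ = _covariate_matrix(covariates, y.shape[0])
    if c.shape[1] != model.beta.shape[0]:
        raise ValueError("covariate columns do not match the fitted design")
    return _adjust(model, y, batch, c)


def harmonize_cohort_measures(
    measures: dict[str, np.ndarray],
    batch,
    covariates=None,
) -> tuple[dict[str, np.ndarray], dict[str, CombatModel]]:
    """Harmonize a dict of subjects x features measure tables jointly
    indexed by the same subjects; returns adjusted tables and models.

    Only raw input measures should pass through here — biomarkers
    derived from them (percentages, pairwise differences, centrality,
    gradients) are computed from harmonized inputs, never re-harmonized.
    """
    adjusted, models = {}, {}
    for name, table in measures.items():
        model = combat_fit(table, batch, covariates)
        adjusted[name] = model.adjusted
        models[name] = model
    return adjusted, models
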