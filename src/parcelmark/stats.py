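"""Mass-univariate group comparisons and the effect-size calculus.

Per-region pooled-variance t-tests with Benjamini-Hochberg FDR control
and Cohen's d, the binormal AUC <-> Cohen's d conversion, a
bias-corrected multivariate Mahalanobis D, the minimum detectable effect
size of a two-sample design, and the hub-flattening correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests


@dataclass
class RegionStats:
    """Per-region two-sample test results with FDR-adjusted q-values."""

    table: pd.DataFrame  # columns: t, df, p, q, cohens_d, direction

    @property
    def n_significant(self) -> int:
        return int((self.table["q"] < 0.05).sum())

    @property
    def n_significant_positive(self) -> int:
        return int(((self.table["q"] < 0.05) & (self.table["cohens_d"] > 0)).sum())

    @property
    def n_significant_negative(self) -> int:
        return int(((self.table["q"] < 0.05) & (self.table["cohens_d"] < 0)).sum())


def cohens_d(a: np.ndarray, b: np.ndarray, axis: int = 0) -> np.ndarray:
    """Cohen's d with the pooled-variance SD, mean(a) - mean(b)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = a.shape[axis], b.shape[axis]
    va = a.var(axis=axis, ddof=1)
    vb = b.var(axis=axis, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    return (a.mean(axis=axis) - b.mean(axis=axis)) / sp


def region_ttests(
    group_a: np.ndarray,
    group_b: np.ndarray,
    region_names: list[str] | None = None,
    equal_var: bool = True,
) -> RegionStats:
    """Independent t-test per region (column) with BH-FDR correction.

    ``equal_var=True`` is the pooled-variance (Student) test matching
    the pooled-SD Cohen's d; a Welch variant is available via the flag.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    na, nb = a.shape[0], b.shape[0]
    pooled = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1))
    if np.any(pooled == 0):
        bad = int(np.where(pooled == 0)[0][0])
        name = region_names[bad] if region_names else str(bad)
        raise ValueError(f"zero pooled variance in region {name!r}")
    t, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    df = (na + nb - 2) if equal_var else np.nan
    d = cohens_d(a, b)
    q = bh_fdr(p)
    table = pd.DataFrame(
        {
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "cohens_d": d,
            "direction": np.sign(d).astype(int),
        },
        index=region_names if region_names else pd.RangeIndex(a.shape[1]),
    )
    return RegionStats(table=table)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def auc_to_d(auc: float) -> float:
    """Convert a classifier AUC to Cohen's d under the binormal model:
    ``d = sqrt(2) * Phi^-1(AUC)``. AUC must lie strictly in (0, 1)."""
    if not 0.0 < auc < 1.0:
        raise ValueError("AUC must lie strictly in (0, 1)")
    return float(np.sqrt(2.0) * sps.norm.ppf(auc))


def d_to_auc(d: float) -> float:
    """Inverse of :func:`auc_to_d`: ``AUC = Phi(d / sqrt(2))``."""
    return float(sps.norm.cdf(d / np.sqrt(2.0)))


def mahalanobis_D(
    group_a: np.ndarray, group_b: np.ndarray, bias_correct: bool = True
) -> float:
    """Multivariate standardized group separation (Mahalanobis D).

    ``D = sqrt((m_a - m_b)' S^-1 (m_a - m_b))`` with the pooled
    covariance S. The sample D^2 is upward-biased in small samples; the
    corrected squared distance is
    ``D_u^2 = ((N - p - 3)/(N - 2)) D^2 - p N / (n_a n_b)`` (floored at
    zero), the standard unbiased estimator.
    """
    d2 = _mahalanobis_d2(group_a, group_b, bias_correct=bias_correct)
    return float(np.sqrt(max(d2, 0.0)))


def _mahalanobis_d2(group_a, group_b, bias_correct: bool = True) -> float:
    """Squared Mahalanobis distance; the bias-corrected value is left
    unfloored (it can be negative under the null)."""
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    na, nb = a.shape[0], b.shape[0]
    n = na + nb
    p = a.shape[1]
    if p >= n - 2:
        raise ValueError(
            f"pooled covariance singular: p={p} features with N={n} subjects "
            "(needs p < N - 2); reduce dimensionality first"
        )
    diff = a.mean(axis=0) - b.mean(axis=0)
    s = (((na - 1) * np.cov(a, rowvar=False) + (nb - 1) * np.cov(b, rowvar=False))
         / (n - 2))
    d2 = float(diff @ np.linalg.solve(np.atleast_2d(s), diff))
    if not bias_correct:
        return d2
    return (n - p - 3) / (n - 2) * d2 - p * n / (na * nb)


def _power_two_sample(d: float, n_per_group: float, alpha: float) -> float:
    """Power of the two-sided two-sample t-test via the noncentral t."""
    df = 2 * n_per_group - 2
    nc = d * np.sqrt(n_per_group / 2.0)
    t_crit = sps.t.ppf(1 - alpha / 2.0, df)
    power = sps.nct.sf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc)
    if np.isnan(power):  # scipy's nct underflows deep in the power ~ 1 regime
        return 1.0 if nc > t_crit else 0.0
    return float(power)


def detectable_d(alpha: float, power: float, n_per_group: int) -> float:
    """Smallest Cohen's d detectable with the stated power in a
    two-sided, two-sample t-test, solved by bisection on the
    noncentral-t power function (tolerance 1e-6)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if not alpha < power < 1.0:
        raise ValueError("power must lie in (alpha, 1)")
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    f = lambda d: _power_two_sample(d, n_per_group, alpha) - power
    hi = 0.5
    while f(hi) < 0 and hi < 64:
        hi *= 2
    return float(brentq(f, 1e-9, hi, xtol=1e-6))


def power_two_sample(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Public power function (see :func:`detectable_d`)."""
    return _power_two_sample(d, n_per_group, alpha)


def flattening_correlation(
    control_centrality: np.ndarray, group_d: np.ndarray
) -> tuple[float, float]:
    """Correlation across parcels between control-group mean centrality
    and the group difference (Cohen's d) in centrality.

    A negative correlation is the hub-flattening signature: regions that
    are hubs in controls show reduced centrality in cases, while
    low-centrality regions show the reverse.
    """
    x = np.asarray(control_centrality, dtype=float)
    y = np.asarray(group_d, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have the same length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has no defined correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
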