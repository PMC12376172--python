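"""Beta-diversity and hypothesis-testing statistics.

Self-contained implementations of the statistics the analysis rests on:
Bray–Curtis dissimilarity, pairwise distance matrices, principal coordinates
analysis (PCoA) via Gower double-centering, one-way permutational multivariate
ANOVA (permANOVA) with an eta-squared effect size, the Wilcoxon rank-sum test
(normal approximation with tie and continuity corrections), one- and
two-sample t tests, and Bonferroni correction.

Distance matrices are held in :class:`skbio.DistanceMatrix`, the field's
standard container; p-value tail probabilities come from ``scipy.stats``
distributions.  The test statistics themselves are computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix

from .core import AbundanceTable

#: Number of label permutations used for permANOVA p-values by default.
DEFAULT_PERMUTATIONS = 10_000


# ----------------------------------------------------------------------
# Bray–Curtis
# ----------------------------------------------------------------------

def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity: ``1 - 2 * sum(min(x, y)) / (sum(x) + sum(y))``.

    0 means identical composition, 1 means no shared taxa.  Both vectors must
    be non-negative with at least one positive entry each.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if np.any(xa < 0) or np.any(ya < 0):
        raise ValueError("abundance vectors must be non-negative")
    sx, sy = xa.sum(), ya.sum()
    if sx == 0 or sy == 0:
        raise ValueError("Bray–Curtis undefined for an all-zero vector")
    return float(1.0 - 2.0 * np.minimum(xa, ya).sum() / (sx + sy))


def pairwise_distances(table: AbundanceTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarities between every pair of samples."""
    values = table.values.to_numpy(dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    row_sums = values.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("all-zero abundance row")
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        shared = np.minimum(values[i], values[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = 1.0 - 2.0 * shared / (row_sums[i] + row_sums[i + 1 :])
    d = d + d.T
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return DistanceMatrix(d, ids=list(table.values.index))


# ----------------------------------------------------------------------
# permANOVA
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    eta_squared: float
    p_value: float
    n_permutations: int
    ss_between: float
    ss_within: float
    ss_total: float


def _ss_within(d2: np.ndarray, groups: np.ndarray, codes: np.ndarray) -> float:
    ssw = 0.0
    for g in codes:
        ix = np.flatnonzero(groups == g)
        ssw += d2[np.ix_(ix, ix)].sum() / (2.0 * len(ix))
    return ssw


def permanova(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
) -> PermanovaResult:
    """One-way permANOVA on a distance matrix.

    Sums of squares follow the distance-based decomposition
    ``SS_total = (1/N) * sum_{i<j} d_ij^2`` and
    ``SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2``; the pseudo-F
    statistic is ``(SS_between/(a-1)) / (SS_within/(N-a))`` and
    ``eta_squared = SS_between / SS_total`` is the fraction of community
    variance explained by the grouping.

    The p-value uses the add-one estimator
    ``(1 + #{permuted F >= observed F}) / (1 + n_permutations)`` over uniform
    random relabelings, so it is never exactly 0.  ``SS_within == 0`` yields
    ``pseudo_F = +inf`` with the p-value still computed from permutations.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labels = np.asarray(list(groups))
    dm = d.data
    n = dm.shape[0]
    if len(labels) != n:
        raise ValueError(
            f"groups length {len(labels)} does not match matrix size {n}"
        )
    codes, counts = np.unique(labels, return_counts=True)
    a = len(codes)
    if a < 2:
        raise ValueError("need at least 2 groups")
    d2 = dm**2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, labels, codes)
    ss_between = ss_total - ss_within

    def f_stat(ssw: float) -> float:
        ssb = ss_total - ssw
        if ssw <= 0:
            return math.inf if ssb > 0 else 0.0
        return (ssb / (a - 1)) / (ssw / (n - a))

    f_obs = f_stat(ss_within)
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if f_stat(_ss_within(d2, perm, codes)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    eta = ss_between / ss_total if ss_total > 0 else 0.0
    return PermanovaResult(
        pseudo_F=float(f_obs),
        eta_squared=float(eta),
        p_value=float(p),
        n_permutations=n_permutations,
        ss_between=float(max(ss_between, 0.0)),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
    )


# ----------------------------------------------------------------------
# PCoA
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame  # samples x k
    eigenvalues: np.ndarray  # non-increasing, all eigenvalues (incl. negative)
    proportion_explained: np.ndarray  # over positive eigenvalues only
    padded: bool  # True when k exceeded the number of positive eigenvalues


def pcoa(d: DistanceMatrix, k: int = 2) -> PcoaResult:
    """Principal coordinates analysis by Gower double-centering.

    ``B = -1/2 * J D^2 J`` with ``J = I - 11'/N`` is eigendecomposed;
    coordinates are eigenvectors scaled by the square root of their (positive)
    eigenvalues, ordered by decreasing eigenvalue.  Negative eigenvalues —
    expected for the non-Euclidean Bray–Curtis measure — are excluded from
    ``proportion_explained``; no Cailliez/Lingoes correction is applied.  When
    ``k`` exceeds the number of positive eigenvalues the remaining axes are
    zero and ``padded`` is flagged.
    """
    dm = d.data
    n = dm.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    positive = eigvals > tol
    n_pos = int(positive.sum())
    coords = np.zeros((n, k))
    take = min(k, n_pos)
    coords[:, :take] = eigvecs[:, :take] * np.sqrt(eigvals[:take])
    prop = (
        eigvals[positive] / eigvals[positive].sum()
        if n_pos
        else np.zeros(0)
    )
    return PcoaResult(
        coordinates=pd.DataFrame(
            coords, index=list(d.ids), columns=[f"PC{i + 1}" for i in range(k)]
        ),
        eigenvalues=eigvals,
        proportion_explained=prop,
        padded=k > n_pos,
    )


# ----------------------------------------------------------------------
# Univariate tests
# ----------------------------------------------------------------------

def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon rank-sum test, two-sided, normal approximation.

    Pooled mid-ranks; the variance carries the standard tie correction and a
    0.5 continuity correction is applied.  Returns ``(rank_sum_of_x, p)``.
    If every pooled value is identical the p-value is 1.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if len(xa) < 1 or len(ya) < 1:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(xa), len(ya)
    pooled = np.concatenate([xa, ya])
    n = n1 + n2
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    mean_w = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    if n > 1:
        var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    else:
        var_w = 0.0
    if var_w <= 0:
        return w, 1.0
    diff = w - mean_w
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var_w)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return w, min(p, 1.0)


def t_tests(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    mu0: float | None = None,
    welch: bool = False,
) -> tuple[float, float]:
    """One- or two-sample t test, two-tailed.

    One-sample mode (``mu0`` given): ``t = (mean - mu0) / (sd / sqrt(n))``.
    Two-sample mode (``y`` given): classic pooled-variance Student t by
    default; ``welch=True`` switches to the unequal-variance form.
    """
    xa = np.asarray(x, dtype=float)
    if y is None and mu0 is None:
        raise ValueError("provide y (two-sample) or mu0 (one-sample)")
    if y is not None and mu0 is not None:
        raise ValueError("provide only one of y and mu0")
    if y is None:
        n = len(xa)
        if n < 2:
            raise ValueError("one-sample t needs n >= 2")
        sd = xa.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance in sample x")
        t = (xa.mean() - mu0) / (sd / math.sqrt(n))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
        return float(t), p
    ya = np.asarray(y, dtype=float)
    n1, n2 = len(xa), len(ya)
    if n1 < 2 or n2 < 2:
        raise ValueError("two-sample t needs n >= 2 per sample")
    v1, v2 = xa.var(ddof=1), ya.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("zero variance in both samples")
    if welch:
        se2 = v1 / n1 + v2 / n2
        t = (xa.mean() - ya.mean()) / math.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (xa.mean() - ya.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    p = float(2.0 * sps.t.sf(abs(t), df=df))
    return float(t), p


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Multiply each p-value by the family size, capping at 1."""
    ps = list(p_values)
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value out of range: {p}")
    m = len(ps)
    return [min(p * m, 1.0) for p in ps]


# ----------------------------------------------------------------------
# Distance-matrix I/O
# ----------------------------------------------------------------------

def write_distance_matrix(d: DistanceMatrix, path) -> None:
    df = pd.DataFrame(d.data, index=list(d.ids), columns=list(d.ids))
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index.astype(str)))
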