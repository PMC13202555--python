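"""Alpha diversity, group tests, dissimilarities, PCoA and PERMANOVA.

Alpha diversity of communities and gene profiles is summarized by the
Shannon index (natural log), richness and Pielou's evenness; group contrasts
use Student's t or the Wilcoxon rank-sum test.  Beta diversity uses
Bray–Curtis or Horn (1 − Morisita–Horn) dissimilarity, principal coordinate
analysis, and a permutation PERMANOVA with Anderson's pseudo-F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Alpha diversity

def _proportions(row) -> np.ndarray:
    x = np.asarray(row, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("row sum must be positive for diversity computation")
    return x / total


def shannon(row) -> float:
    """Shannon index H = −Σ p ln p in nats; zero abundances contribute 0."""
    p = _proportions(row)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def richness(row) -> int:
    """Number of features with strictly positive abundance."""
    x = np.asarray(row, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    if x.sum() <= 0:
        raise ValueError("row sum must be positive")
    return int((x > 0).sum())


def pielou(row) -> float:
    """Evenness J = H / ln(richness); NaN (undefined) when richness is 1."""
    s = richness(row)
    if s == 1:
        return float("nan")
    return shannon(row) / math.log(s)


def alpha_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Shannon/richness/Pielou for every row of a samples × features table."""
    rows = {
        sid: {
            "shannon": shannon(matrix.loc[sid]),
            "richness": richness(matrix.loc[sid]),
            "pielou": pielou(matrix.loc[sid]),
        }
        for sid in matrix.index
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


# ---------------------------------------------------------------------------
# Group comparison

def _ranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def group_compare(values_by_group: Mapping[str, Sequence[float]], method: str = "t"):
    """Two-sided two-group comparison.

    ``method="t"`` is Student's t (equal variances); a pooled zero variance
    raises.  ``method="wilcoxon"`` is the rank-sum test: exact enumeration of
    the rank-sum distribution (two-sided via distance from its mean, average
    ranks for ties) when the combined n is <= 12, otherwise the normal
    approximation with tie correction.

    Returns ``(statistic, p_value)``.
    """
    if len(values_by_group) != 2:
        raise ValueError("group_compare expects exactly two groups")
    (name_a, a), (name_b, b) = values_by_group.items()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if method == "t":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test needs >= 2 observations per group")
        if np.var(np.concatenate([a, b])) == 0:
            raise ValueError("zero pooled variance: t statistic undefined")
        res = stats.ttest_ind(a, b, equal_var=True)
        return float(res.statistic), float(res.pvalue)
    if method == "wilcoxon":
        if len(a) < 1 or len(b) < 1:
            raise ValueError("wilcoxon needs >= 1 observation per group")
        return _rank_sum(a, b)
    raise ValueError(f"unknown method {method!r}")


def _rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    n1, n = len(a), len(a) + len(b)
    pooled = np.concatenate([a, b])
    ranks = _ranks(pooled)
    w_obs = ranks[:n1].sum()
    mean_w = ranks.sum() * n1 / n
    if n <= 12:
        # Exact permutation distribution of the rank sum over all
        # C(n, n1) assignments of the (tied) ranks to group 1.
        d_obs = abs(w_obs - mean_w)
        total = hits = 0
        for idx in combinations(range(n), n1):
            w = ranks[list(idx)].sum()
            total += 1
            if abs(w - mean_w) >= d_obs - 1e-12:
                hits += 1
        return float(w_obs), hits / total
    n2 = n - n1
    tie_counts = pd.Series(pooled).value_counts().to_numpy()
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_w == 0:
        return float(w_obs), 1.0
    z = (w_obs - mean_w) / math.sqrt(var_w)
    return float(w_obs), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Dissimilarities

def _check_abundance(matrix: pd.DataFrame) -> np.ndarray:
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("abundance matrix must be non-negative")
    if (x.sum(axis=1) <= 0).any():
        raise ValueError("abundance matrix has an all-zero row")
    return x


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray–Curtis dissimilarity d = Σ|x−y| / Σ(x+y) between all row pairs."""
    x = _check_abundance(matrix)
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def horn(matrix: pd.DataFrame) -> pd.DataFrame:
    """Horn dissimilarity, 1 − Morisita–Horn similarity.

    Similarity between rows x and y with totals X, Y:
    ``2 Σ x_i y_i / ((Σx_i²/X² + Σy_i²/Y²) · X · Y)``.  Invariant to
    rescaling either row (relative-abundance property).
    """
    x = _check_abundance(matrix)
    totals = x.sum(axis=1)
    simpson = (x**2).sum(axis=1) / totals**2  # Σ p² per row
    cross = x @ x.T
    denom = (simpson[:, None] + simpson[None, :]) * totals[:, None] * totals[None, :]
    sim = 2 * cross / denom
    d = 1 - sim
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def _check_dissimilarity(dm: pd.DataFrame) -> np.ndarray:
    d = dm.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return d


# ---------------------------------------------------------------------------
# Principal coordinate analysis

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples × retained axes
    eigenvalues: np.ndarray    # all eigenvalues, descending (negatives kept)
    explained: np.ndarray      # fraction of positive-eigenvalue sum, per retained axis


def pcoa(dm: pd.DataFrame, *, eps: float = 1e-10) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a dissimilarity matrix.

    Gower double-centering of −D²/2, eigendecomposition, axes ordered by
    eigenvalue.  Negative eigenvalues are reported unchanged; coordinates are
    returned only for eigenvalues > ``eps``.  Axis signs are fixed by making
    each axis's largest-magnitude coordinate positive.
    """
    d = _check_dissimilarity(dm)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > eps
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    for k in range(coords.shape[1]):
        i_max = np.argmax(np.abs(coords[:, k]))
        if coords[i_max, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigvals[keep].sum()
    explained = eigvals[keep] / pos_sum if pos_sum > 0 else np.zeros(keep.sum())
    cols = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=dm.index, columns=cols),
        eigenvalues=eigvals,
        explained=explained,
    )


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False
    degenerate: bool = False


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Total and within-group sums of squared distances (Anderson)."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(d2, labels, k, n) -> tuple[float, float]:
    ss_total, ss_within = _permanova_ss(d2, labels)
    ss_between = ss_total - ss_within
    if ss_total <= 0 or n - k <= 0:
        return float("nan"), float("nan")
    f = (ss_between / (k - 1)) / (ss_within / (n - k)) if ss_within > 0 else float("inf")
    return f, ss_between / ss_total


def _distinct_assignments(labels: np.ndarray):
    """Yield all distinct reorderings of a label multiset (lexicographic)."""
    uniq, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    out = np.empty(n, dtype=labels.dtype)

    def rec(pos: int, remaining: np.ndarray):
        if pos == n:
            yield out.copy()
            return
        for i, u in enumerate(uniq):
            if remaining[i] > 0:
                out[pos] = u
                remaining[i] -= 1
                yield from rec(pos + 1, remaining)
                remaining[i] += 1

    yield from rec(0, counts.copy())


def n_distinct_assignments(labels) -> int:
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    total = math.factorial(int(counts.sum()))
    for c in counts:
        total //= math.factorial(int(c))
    return total


def permanova(
    dm: pd.DataFrame,
    grouping: Sequence,
    n_permutations: int = 999,
    seed: int | None = None,
    *,
    exhaustive_limit: int = 10_000,
) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    pseudo-F follows Anderson's sums-of-squared-distances formulation; the
    p-value counts permuted statistics >= the observed one with the observed
    arrangement included, so p is never 0 and has resolution
    1/(n_permutations + 1).  When the number of distinct relabelings is at
    most ``exhaustive_limit`` the full set is enumerated instead of sampling.
    All points coincident is reported as degenerate with p = 1.
    """
    labels = np.asarray(grouping)
    if len(labels) != dm.shape[0]:
        raise ValueError("grouping length must match the dissimilarity matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    k, n = len(uniq), len(labels)
    if k < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 1).any():
        raise ValueError("every group must be non-empty")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    d2 = _check_dissimilarity(dm) ** 2
    f_obs, r2 = _pseudo_f(d2, labels, k, n)
    if math.isnan(f_obs):
        return PermanovaResult(float("nan"), float("nan"), 1.0, 0, seed, degenerate=True)

    n_distinct = n_distinct_assignments(labels)
    if n_distinct <= exhaustive_limit:
        hits = total = 0
        for perm in _distinct_assignments(labels):
            f_perm, _ = _pseudo_f(d2, perm, k, n)
            total += 1
            if f_perm >= f_obs - 1e-12:
                hits += 1
        return PermanovaResult(f_obs, r2, hits / total, total, seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        f_perm, _ = _pseudo_f(d2, rng.permutation(labels), k, n)
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(f_obs, r2, p, n_permutations, seed)


# ---------------------------------------------------------------------------
# Composition summaries

def shared_unique_fractions(n_shared: int, n_unique_a: int, n_unique_b: int) -> dict:
    """Venn-style shared/unique percentages of a two-group feature universe.

    E.g. 3,169 shared, 2,384 group-A-unique and 631 group-B-unique features
    out of 6,184 give 51.2% / 38.6% / 10.2% after rounding to one decimal.
    """
    total = n_shared + n_unique_a + n_unique_b
    if total <= 0:
        raise ValueError("feature universe is empty")
    return {
        "total": total,
        "shared_pct": 100 * n_shared / total,
        "unique_a_pct": 100 * n_unique_a / total,
        "unique_b_pct": 100 * n_unique_b / total,
    }


def abundance_from_hits(hits: pd.DataFrame, gene_class: str) -> pd.DataFrame:
    """Samples × gene-name count matrix for one gene class of a hit table."""
    sub = hits.loc[hits["gene_class"] == gene_class]
    if sub.empty:
        raise ValueError(f"no hits of class {gene_class!r}")
    counts = (
        sub.groupby(["sample_id", "gene_name"]).size().unstack(fill_value=0).sort_index()
    )
    counts.columns.name = None
    return counts.astype(float)


def relative_abundance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a samples × features table to sum to 1."""
    x = _check_abundance(matrix)
    return pd.DataFrame(
        x / x.sum(axis=1, keepdims=True), index=matrix.index, columns=matrix.columns
    )
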