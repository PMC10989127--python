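"""Alpha diversity, Bray-Curtis beta diversity, ordination and group tests.

Alpha indices follow the vegan conventions: Shannon-Wiener with natural
logarithm, Pielou's evenness J = H / ln(richness).  Between-sample
diversity is Bray-Curtis dissimilarity, with community similarity defined
as its complement (1 - dissimilarity).  Group significance is assessed by
three permutation procedures (PERMANOVA, ANOSIM, MRPP) with seedable,
reproducible permutation p-values of the form (1 + #{perm >= obs}) / (1 + n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
import skbio
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .profile_io import AbundanceTable

_SYM_TOL = 1e-12
_EIG_TOL = 1e-10


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise matrix over samples.

    ``is_similarity`` distinguishes a similarity matrix (unit diagonal)
    from a distance/dissimilarity matrix (zero diagonal).
    """

    sample_ids: tuple
    values: np.ndarray
    metric: str
    is_similarity: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} sample ids")
        if not np.isfinite(v).all():
            raise ValueError("non-finite entries in pairwise matrix")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("matrix is not symmetric")
        diag_target = 1.0 if self.is_similarity else 0.0
        if np.abs(np.diag(v) - diag_target).max(initial=0.0) > _SYM_TOL:
            raise ValueError(f"diagonal must be {diag_target}")
        if not self.is_similarity and (v < 0).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(tuple(ids), self.values[np.ix_(idx, idx)],
                              self.metric, self.is_similarity)


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA coordinates for retained (positive-eigenvalue) axes."""

    sample_ids: tuple
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def __post_init__(self) -> None:
        eig = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(eig) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        prop = np.asarray(self.proportion_explained, dtype=float)
        if ((prop < -1e-12) | (prop > 1 + 1e-12)).any():
            raise ValueError("proportions outside [0, 1]")


@dataclass(frozen=True)
class GroupTestResult:
    method: str
    statistic: float
    p_value: float
    n_permutations: int
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Alpha diversity


def _proportions(table: AbundanceTable) -> np.ndarray:
    vals = table.values
    row_sums = vals.sum(axis=1)
    zero = row_sums == 0
    if zero.any():
        ids = list(np.asarray(table.sample_ids)[zero])
        raise ValueError(f"all-zero sample(s): {ids}")
    return vals / row_sums[:, None]


def richness(table: AbundanceTable) -> pd.Series:
    """Number of features with non-zero abundance per sample."""
    return pd.Series((table.values > 0).sum(axis=1), index=table.data.index,
                     name="richness")


def shannon(table: AbundanceTable) -> pd.Series:
    """Shannon-Wiener index H = -sum p_i ln p_i over non-zero proportions."""
    p = _proportions(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return pd.Series(-terms.sum(axis=1), index=table.data.index, name="shannon")


def pielou(table: AbundanceTable) -> pd.Series:
    """Pielou's evenness J = H / ln(S); NaN where richness < 2."""
    H = shannon(table)
    S = richness(table)
    J = pd.Series(np.full(len(H), np.nan), index=table.data.index, name="pielou")
    ok = S >= 2
    J[ok] = H[ok] / np.log(S[ok])
    return J


# ---------------------------------------------------------------------------
# Beta diversity


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC(x,y) = sum|x-y| / sum(x+y)."""
    vals = table.values
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    zero_rows = int((vals.sum(axis=1) == 0).sum())
    if zero_rows >= 2:
        raise ValueError("Bray-Curtis undefined for a pair of all-zero samples")
    d = squareform(pdist(vals, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, d, metric="braycurtis")


def similarity(d: DistanceMatrix) -> DistanceMatrix:
    """Community similarity = 1 - dissimilarity, elementwise (unit diagonal)."""
    if d.is_similarity:
        raise ValueError("input is already a similarity matrix")
    return DistanceMatrix(d.sample_ids, 1.0 - d.values,
                          metric=f"{d.metric}_similarity", is_similarity=True)


# ---------------------------------------------------------------------------
# Ordination


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Eigendecomposition of the Gower-centred matrix; only axes with
    eigenvalue > 1e-10 are retained, and proportions are computed over the
    positive eigenvalues (no negative-eigenvalue correction).
    """
    if d.is_similarity:
        raise ValueError("pcoa expects a distance matrix, not similarity")
    res = _skbio_pcoa(skbio.DistanceMatrix(d.values, ids=[str(s) for s in d.sample_ids]))
    eig = np.asarray(res.eigvals, dtype=float)
    order = np.argsort(eig)[::-1]
    eig = eig[order]
    coords = res.samples.to_numpy()[:, order]
    keep = eig > _EIG_TOL
    eig_kept = eig[keep]
    pos_sum = eig[eig > 0].sum()
    prop = eig_kept / pos_sum if pos_sum > 0 else np.zeros(0)
    return OrdinationResult(d.sample_ids, coords[:, keep], eig_kept, prop)


# ---------------------------------------------------------------------------
# Permutation group tests


def _group_masks(sample_ids: Sequence, groups: Mapping | pd.Series) -> tuple[np.ndarray, list]:
    g = pd.Series(groups).loc[list(sample_ids)]
    labels = list(pd.unique(g))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    codes = np.asarray(pd.Categorical(g, categories=labels).codes)
    return codes, labels


def _within_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss


def permanova(d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> GroupTestResult:
    """Permutational multivariate ANOVA (pseudo-F) on a distance matrix."""
    codes, labels = _group_masks(d.sample_ids, groups)
    sizes = np.bincount(codes, minlength=len(labels))
    if (sizes < 2).any():
        small = [labels[i] for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"singleton group(s) not allowed in PERMANOVA: {small}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n, a = d.n, len(labels)
    d2 = d.values ** 2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def pseudo_f(c: np.ndarray) -> float:
        ss_w = _within_ss(d2, c, a)
        ss_a = ss_total - ss_w
        return (ss_a / (a - 1)) / (ss_w / (n - a))

    obs = pseudo_f(codes)
    rng = np.random.default_rng(seed)
    exceed = sum(pseudo_f(rng.permutation(codes)) >= obs for _ in range(n_perm))
    p = (1 + exceed) / (1 + n_perm)
    return GroupTestResult("permanova", float(obs), float(p), n_perm)


def anosim(d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> GroupTestResult:
    """Analysis of similarities; R = (rb - rw) / (M/2) on distance ranks.

    Singleton groups are tolerated (they contribute only between-group
    ranks), which degrades power but keeps R well defined.
    """
    codes, _ = _group_masks(d.sample_ids, groups)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = d.n
    iu = np.triu_indices(n, 1)
    ranks = rankdata(d.values[iu])
    M = len(ranks)

    def r_stat(c: np.ndarray) -> float:
        within = c[iu[0]] == c[iu[1]]
        if within.all() or not within.any():
            return 0.0
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2)

    obs = r_stat(codes)
    rng = np.random.default_rng(seed)
    exceed = sum(r_stat(rng.permutation(codes)) >= obs for _ in range(n_perm))
    p = (1 + exceed) / (1 + n_perm)
    return GroupTestResult("anosim", float(obs), float(p), n_perm)


def mrpp(d: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> GroupTestResult:
    """Multi-response permutation procedure.

    delta is the group-size-weighted mean within-group distance; the
    chance-corrected effect size A = 1 - delta / mean(permuted deltas);
    small observed delta is evidence of group structure, so
    p = (1 + #{perm delta <= obs}) / (1 + n_perm).
    """
    codes, labels = _group_masks(d.sample_ids, groups)
    sizes = np.bincount(codes, minlength=len(labels))
    if (sizes < 2).any():
        small = [labels[i] for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"singleton group(s) not allowed in MRPP: {small}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = d.n
    vals = d.values

    def delta(c: np.ndarray) -> float:
        total = 0.0
        for g in range(len(labels)):
            idx = np.flatnonzero(c == g)
            sub = vals[np.ix_(idx, idx)]
            mean_within = sub[np.triu_indices(len(idx), 1)].mean()
            total += (len(idx) / n) * mean_within
        return total

    obs = delta(codes)
    rng = np.random.default_rng(seed)
    perm_deltas = np.array([delta(rng.permutation(codes)) for _ in range(n_perm)])
    p = (1 + int((perm_deltas <= obs).sum())) / (1 + n_perm)
    A = 1.0 - obs / perm_deltas.mean()
    return GroupTestResult("mrpp", float(A), float(p), n_perm,
                           extra={"delta": float(obs)})
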