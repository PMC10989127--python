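"""Richness-constrained null models and the community stochasticity ratio.

The stochasticity ratio ST compares the observed pairwise community
similarity C_ij (Bray-Curtis complement) to its expectation under a null
model that preserves each sample's richness and the regional feature pool.
With D_ij = 1 - C_ij, G_ij = 1 - E_ij:

    ST_ij = (E_ij / C_ij) * (D_ij / G_ij)   if C_ij >= E_ij   (branch A)
    ST_ij = (G_ij / D_ij) * (C_ij / E_ij)   if C_ij <  E_ij   (branch B)

ST_ij is 1 exactly when the observed similarity matches the null
expectation (assembly indistinguishable from stochastic), and decreases
towards 0 the further observation departs from the null in either
direction (deterministic clustering or over-dispersion).  A group-level ST
is the arithmetic mean over evaluated pairs, ST = (sum ST^A + sum ST^B) /
(nA + nB).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .profile_io import AbundanceTable

logger = logging.getLogger(__name__)

ABUNDANCE_RULES = ("regional_proportional", "sample_shuffle")


@dataclass(frozen=True)
class NullModelConfig:
    """Settings for the null ensemble.

    n_reps:
        Number of randomized communities averaged into the expectation
        (1000 in the reference analysis; scale down for quick runs).
    abundance_rule:
        How counts are assigned to the features drawn for a null sample.
        ``sample_shuffle`` (default): the sample's own non-zero counts
        permuted onto the drawn features, preserving each sample's
        abundance distribution.  ``regional_proportional``: one count to
        each drawn feature, remainder multinomial with probabilities
        proportional to regional abundance — note this makes every null
        sample a draw around the same regional vector, so the null
        ensemble is much more homogeneous than the data.
    """

    n_reps: int = 1000
    seed: int = 0
    abundance_rule: str = "sample_shuffle"

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.abundance_rule not in ABUNDANCE_RULES:
            raise ValueError(f"abundance_rule must be one of {ABUNDANCE_RULES}")


@dataclass(frozen=True)
class NullEnsemble:
    """Mean pairwise similarity over the null replicates."""

    sample_ids: tuple
    expected_similarity: np.ndarray
    n_reps: int

    def __post_init__(self) -> None:
        e = self.expected_similarity
        if ((e < -1e-12) | (e > 1 + 1e-12)).any():
            raise ValueError("expected similarities outside [0, 1]")

    @property
    def expected_dissimilarity(self) -> np.ndarray:
        return 1.0 - self.expected_similarity


@dataclass(frozen=True)
class StochasticityResult:
    """Pairwise and group-averaged stochasticity ratios."""

    pairs: pd.DataFrame  # sample_i, sample_j, group, C, E, branch, ST
    group_st: dict
    overall_st: float
    n_branch_a: int
    n_branch_b: int
    config: NullModelConfig = field(repr=False, default=NullModelConfig())


# ---------------------------------------------------------------------------
# Null randomization


def randomize_community(table: AbundanceTable, seed: int,
                        abundance_rule: str = "regional_proportional") -> AbundanceTable:
    """One richness-constrained randomization of a count table.

    Constraints enforced exactly:

    * each null sample occupies exactly as many features as observed
      (local richness), drawn without replacement with probability
      proportional to regional occupancy frequency;
    * each null sample's total count equals the observed total;
    * the union of occupied features equals the observed regional pool
      (missing features are swapped in for a multiply-occurring feature,
      preserving the two constraints above).
    """
    if abundance_rule not in ABUNDANCE_RULES:
        raise ValueError(f"abundance_rule must be one of {ABUNDANCE_RULES}")
    counts = table.counts()
    n_samples, n_features = counts.shape
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    occupancy = (counts > 0).sum(axis=0)
    pool = np.flatnonzero(occupancy > 0)
    if len(pool) == 0:
        raise ValueError("empty regional pool (all-zero table)")
    richness = (counts > 0).sum(axis=1)
    if (richness == 0).any():
        bad = list(np.asarray(table.sample_ids)[richness == 0])
        raise ValueError(f"all-zero sample(s) cannot be randomized: {bad}")
    weights = occupancy[pool] / occupancy[pool].sum()
    regional = counts.sum(axis=0).astype(float)

    rng = np.random.default_rng(seed)
    null = np.zeros_like(counts)
    for s in range(n_samples):
        k = int(richness[s])
        total = int(counts[s].sum())
        if k > len(pool):  # cannot happen for a valid table, guard anyway
            raise ValueError("sample richness exceeds regional pool size")
        if k == len(pool):
            chosen = pool.copy()
        else:
            chosen = pool[rng.choice(len(pool), size=k, replace=False, p=weights)]
        if abundance_rule == "regional_proportional":
            p = regional[chosen] / regional[chosen].sum()
            null[s, chosen] = 1 + rng.multinomial(total - k, p)
        else:  # sample_shuffle
            vals = counts[s, counts[s] > 0]
            null[s, chosen] = rng.permutation(vals)

    _repair_pool_coverage(null, pool, rng)
    df = pd.DataFrame(null, index=table.data.index, columns=table.data.columns)
    return AbundanceTable(df, kind=table.kind, is_relative=False)


def _repair_pool_coverage(null: np.ndarray, pool: np.ndarray,
                          rng: np.random.Generator) -> None:
    """Swap occurrences so every regional-pool feature occupies >= 1 sample.

    For each feature absent from the null table, one occurrence of a
    feature present in >= 2 samples is relabelled in a random sample not
    already containing the absent feature.  Per-sample richness and totals
    are unchanged.
    """
    occ = null > 0
    counts_per_feature = occ.sum(axis=0)
    missing = [f for f in pool if counts_per_feature[f] == 0]
    rng.shuffle(missing)
    for f in missing:
        donors = np.flatnonzero(counts_per_feature >= 2)
        rng.shuffle(donors)
        done = False
        for g in donors:
            candidates = np.flatnonzero(occ[:, g] & ~occ[:, f])
            if len(candidates) == 0:
                continue
            s = int(rng.choice(candidates))
            null[s, f] = null[s, g]
            null[s, g] = 0
            occ[s, f], occ[s, g] = True, False
            counts_per_feature[f] += 1
            counts_per_feature[g] -= 1
            done = True
            break
        if not done:  # pragma: no cover - only if pool size > sum of richness
            raise RuntimeError("cannot place regional feature "
                               f"{f} without breaking richness constraints")


def _similarity_from_counts(values: np.ndarray) -> np.ndarray:
    return 1.0 - squareform(pdist(values, metric="braycurtis"))


def null_expected_similarity(table: AbundanceTable,
                             config: NullModelConfig) -> NullEnsemble:
    """Mean Bray-Curtis complement over ``n_reps`` null randomizations.

    Replicate r is seeded as ``config.seed + r`` for reproducibility.
    """
    acc = np.zeros((len(table.sample_ids),) * 2)
    for r in range(config.n_reps):
        null = randomize_community(table, seed=config.seed + r,
                                   abundance_rule=config.abundance_rule)
        acc += _similarity_from_counts(null.values)
    e = acc / config.n_reps
    np.fill_diagonal(e, 1.0)
    return NullEnsemble(tuple(table.sample_ids), e, config.n_reps)


# ---------------------------------------------------------------------------
# Stochasticity ratio


def pairwise_st(c: float, e: float) -> tuple[float, str]:
    """Stochasticity ratio for one sample pair.

    Returns (ST, branch) with branch "A" when C >= E and "B" otherwise.
    The degenerate boundary cases (C = E = 0 or 1, yielding 0/0) return 1:
    the observation sits exactly on the null expectation.
    """
    if not (0.0 <= c <= 1.0) or not (0.0 <= e <= 1.0):
        raise ValueError(f"C and E must lie in [0, 1], got C={c}, E={e}")
    d = 1.0 - c
    g = 1.0 - e
    if c >= e:
        if c == e:  # includes the 0/0 boundaries
            return 1.0, "A"
        return (e / c) * (d / g), "A"
    return (g / d) * (c / e), "B"


def stochasticity_ratio(table: AbundanceTable, groups,
                        config: NullModelConfig) -> StochasticityResult:
    """Group-averaged stochasticity ratio over within-group sample pairs.

    ``groups`` maps sample id -> group label (e.g. ocean layer); groups of
    size 1 are skipped with a warning.  One null ensemble is computed over
    the full table, so the regional pool spans all samples.
    """
    groups = pd.Series(groups).loc[table.sample_ids]
    obs_sim = _similarity_from_counts(table.counts().astype(float))
    ensemble = null_expected_similarity(table, config)
    ids = list(table.sample_ids)
    pos = {s: i for i, s in enumerate(ids)}

    rows = []
    for label in pd.unique(groups):
        members = [s for s in ids if groups[s] == label]
        if len(members) < 2:
            logger.warning("stochasticity_ratio: skipping singleton group %r", label)
            continue
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = pos[members[i]], pos[members[j]]
                c = float(np.clip(obs_sim[a, b], 0.0, 1.0))
                e = float(np.clip(ensemble.expected_similarity[a, b], 0.0, 1.0))
                st, branch = pairwise_st(c, e)
                rows.append((members[i], members[j], label, c, e, branch, st))
    if not rows:
        raise ValueError("no group with >= 2 samples")
    pairs = pd.DataFrame(rows, columns=["sample_i", "sample_j", "group",
                                        "C", "E", "branch", "ST"])
    group_st = pairs.groupby("group", sort=False)["ST"].mean().to_dict()
    n_a = int((pairs["branch"] == "A").sum())
    n_b = int((pairs["branch"] == "B").sum())
    overall = float(pairs["ST"].sum() / (n_a + n_b))
    return StochasticityResult(pairs, group_st, overall, n_a, n_b, config)
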