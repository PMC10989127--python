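"""Environment-community association and chlorophyll-a prediction.

Covers the (partial) Mantel machinery relating community dissimilarity to
environmental distance while controlling for geography, a deterministic
collinearity screen replacing ordination-based factor selection, per-factor
diversity regressions, the metH / chlorophyll-a correlations, and
random-forest prediction of chlorophyll-a from community profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .biogeography import RegressionFit, _linregress
from .diversity import DistanceMatrix
from .profile_io import AbundanceTable, SampleMetadata

logger = logging.getLogger(__name__)

#: Default significance threshold for chlorophyll-a / metH correlations.
CHLA_ALPHA = 0.005
#: Conventional threshold used everywhere else.
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    controlled_for: str | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("Mantel r outside [-1, 1]")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p outside (0, 1]")


@dataclass(frozen=True)
class PredictionResult:
    """Observed vs predicted chlorophyll-a on the held-out partition."""

    observed: pd.Series
    predicted: pd.Series
    spearman_rho: float
    spearman_p: float
    rmse: float
    split: str


# ---------------------------------------------------------------------------
# Mantel machinery


def _check_matched(*mats: DistanceMatrix) -> None:
    ids = mats[0].sample_ids
    for m in mats[1:]:
        if m.sample_ids != ids:
            raise ValueError("sample ids differ between matrices")


def env_distance_matrix(metadata: SampleMetadata,
                        factors: Sequence[str]) -> DistanceMatrix:
    """Euclidean distance between samples over z-scored factors."""
    df = metadata.data[list(factors)].astype(float)
    if df.isna().any().any():
        raise ValueError("missing values in environmental factors")
    z = (df - df.mean()) / df.std(ddof=0).replace(0, 1.0)
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return DistanceMatrix(tuple(metadata.sample_ids), d, metric="env_euclidean")


def mantel(dA: DistanceMatrix, dB: DistanceMatrix, n_perm: int = 9999,
           seed: int = 0) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal vectors; the one-sided
    (greater) permutation p permutes rows/columns of the first matrix.
    """
    _check_matched(dA, dB)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    a, b = dA.condensed(), dB.condensed()
    obs = float(stats.pearsonr(a, b).statistic)
    rng = np.random.default_rng(seed)
    n = dA.n
    exceed = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        ap = _condensed_permuted(dA.values, idx)
        if stats.pearsonr(ap, b).statistic >= obs:
            exceed += 1
    return MantelResult(obs, (1 + exceed) / (1 + n_perm), n_perm)


def partial_mantel(dA: DistanceMatrix, dB: DistanceMatrix,
                   dControl: DistanceMatrix, n_perm: int = 9999,
                   seed: int = 0) -> MantelResult:
    """Partial Mantel correlation of dA and dB controlling for dControl.

    The statistic is the first-order partial Pearson correlation of the
    off-diagonal vectors; significance permutes rows/columns of the first
    matrix jointly and recomputes the partial correlation (the standard
    permutation variant used by vegan).
    """
    _check_matched(dA, dB, dControl)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    b, c = dB.condensed(), dControl.condensed()
    obs = _partial_r(dA.condensed(), b, c)
    rng = np.random.default_rng(seed)
    n = dA.n
    exceed = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        ap = _condensed_permuted(dA.values, idx)
        if _partial_r(ap, b, c) >= obs:
            exceed += 1
    return MantelResult(float(obs), (1 + exceed) / (1 + n_perm), n_perm,
                        controlled_for=dControl.metric)


def _condensed_permuted(full: np.ndarray, idx: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import squareform
    return squareform(full[np.ix_(idx, idx)], checks=False)


def _partial_r(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    r_ab = np.corrcoef(a, b)[0, 1]
    r_ac = np.corrcoef(a, c)[0, 1]
    r_bc = np.corrcoef(b, c)[0, 1]
    denom = np.sqrt((1 - r_ac ** 2) * (1 - r_bc ** 2))
    if denom == 0:
        return 0.0
    return float((r_ab - r_ac * r_bc) / denom)


# ---------------------------------------------------------------------------
# Collinearity screen and per-factor regressions


def screen_collinear_factors(metadata: SampleMetadata, factors: Sequence[str],
                             threshold: float = 0.9) -> list[str]:
    """Greedy removal of collinear factors by pairwise |Spearman rho|.

    While any retained pair exceeds ``threshold``, the member of the worst
    pair with the larger mean absolute correlation to the other retained
    factors is dropped (ties: the factor later in the input order).
    Constant factors are dropped up-front with a warning.
    """
    if len(factors) < 2:
        raise ValueError("need at least 2 factors")
    df = metadata.data[list(factors)].astype(float)
    retained = []
    for f in factors:
        if df[f].nunique(dropna=True) <= 1:
            logger.warning("screen_collinear_factors: dropping constant factor %r", f)
        else:
            retained.append(f)
    while len(retained) > 1:
        rho = df[retained].corr(method="spearman").abs()
        np.fill_diagonal(rho.values, 0.0)
        worst = rho.stack().idxmax()
        if rho.loc[worst] <= threshold:
            break
        f1, f2 = worst
        mean1, mean2 = rho[f1].mean(), rho[f2].mean()
        if mean1 > mean2:
            drop = f1
        elif mean2 > mean1:
            drop = f2
        else:
            drop = f1 if retained.index(f1) > retained.index(f2) else f2
        retained.remove(drop)
    return retained


def diversity_factor_regressions(metadata: SampleMetadata, diversity: pd.Series,
                                 factors: Sequence[str],
                                 layer: str | None = None) -> pd.DataFrame:
    """OLS fit and Spearman rho of diversity against each factor.

    Missing values are dropped pairwise; factor/layer combinations with
    fewer than 3 complete cases are skipped with a warning.  Returns one
    row per factor: slope, intercept, r, r2, p, rho, rho_p, n.
    """
    df = metadata.data
    if layer is not None:
        df = df[df["layer"] == layer]
    rows = []
    for factor in factors:
        sub = pd.DataFrame({"x": df[factor].astype(float),
                            "y": diversity.reindex(df.index)}).dropna()
        if len(sub) < 3:
            logger.warning("diversity_factor_regressions: skipping %r in layer %r "
                           "(<3 complete cases)", factor, layer)
            continue
        fit = _linregress(sub["x"].to_numpy(), sub["y"].to_numpy())
        rho, rho_p = stats.spearmanr(sub["x"], sub["y"])
        rows.append({"factor": factor, "layer": layer, "slope": fit.slope,
                     "intercept": fit.intercept, "r": fit.r, "r2": fit.r2,
                     "p": fit.p, "rho": float(rho), "rho_p": float(rho_p),
                     "n": fit.n})
    return pd.DataFrame(rows)


def correlate_metH(functional_diversity: pd.Series, metadata: SampleMetadata,
                   alpha: float = CHLA_ALPHA) -> tuple[float, float, bool]:
    """Spearman correlation of metH relative abundance with trait diversity.

    Returns (rho, p, significant) where significance uses the stringent
    threshold (P < 0.005 by default) applied to the chlorophyll-a family
    of correlations.  Samples with missing metH values are dropped.
    """
    if "metH_relative_abundance" not in metadata.data.columns:
        raise ValueError("metadata has no metH_relative_abundance column")
    sub = pd.DataFrame({
        "metH": metadata.data["metH_relative_abundance"].astype(float),
        "div": functional_diversity.reindex(metadata.data.index),
    }).dropna()
    rho, p = stats.spearmanr(sub["metH"], sub["div"])
    return float(rho), float(p), bool(p < alpha)


# ---------------------------------------------------------------------------
# Random-forest chlorophyll-a prediction


def rf_predict_chla(table: AbundanceTable, metadata: SampleMetadata,
                    mode: str = "half_split", seed: int = 0,
                    train_layer: str = "SRF",
                    n_estimators: int = 300) -> PredictionResult:
    """Predict chlorophyll-a from community profiles with a random forest.

    ``half_split``: a seeded random half of the epipelagic (SRF + DCM)
    samples trains the forest, the other half is predicted.
    ``cross_layer``: samples from ``train_layer`` train, the other
    epipelagic layer is predicted.  The forest never sees held-out labels.
    """
    if mode not in ("half_split", "cross_layer"):
        raise ValueError(f"unknown mode {mode!r}")
    meta = metadata.data
    chla = meta["chlorophyll_a"].astype(float)
    epi = [s for s in table.sample_ids
           if meta.loc[s, "layer"] in ("SRF", "DCM") and np.isfinite(chla[s])]
    if mode == "half_split":
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(epi))
        half = len(epi) // 2
        train_ids = [epi[i] for i in order[:half]]
        test_ids = [epi[i] for i in order[half:]]
        split = f"half_split(n_train={len(train_ids)})"
    else:
        other = "DCM" if train_layer == "SRF" else "SRF"
        train_ids = [s for s in epi if meta.loc[s, "layer"] == train_layer]
        test_ids = [s for s in epi if meta.loc[s, "layer"] == other]
        split = f"cross_layer({train_layer}->{other})"
    if len(train_ids) < 10:
        raise ValueError(f"training partition too small ({len(train_ids)} < 10)")
    if len(test_ids) < 3:
        raise ValueError("held-out partition too small")

    X = table.data.astype(float)
    model = RandomForestRegressor(n_estimators=n_estimators,
                                  random_state=seed % (2 ** 31))
    model.fit(X.loc[train_ids].to_numpy(), chla[train_ids].to_numpy())
    pred = model.predict(X.loc[test_ids].to_numpy())
    obs = chla[test_ids]
    rho, p = stats.spearmanr(obs.to_numpy(), pred)
    rmse = float(np.sqrt(np.mean((obs.to_numpy() - pred) ** 2)))
    return PredictionResult(obs, pd.Series(pred, index=test_ids), float(rho),
                            float(p), rmse, split)
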