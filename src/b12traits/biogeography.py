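"""Geodesic distances, latitudinal diversity gradients and distance decay.

Geographic distance between stations is the inverse Vincenty geodesic on
the WGS-84 ellipsoid.  The latitudinal diversity gradient (LDG) is an OLS
regression of per-sample richness on absolute latitude; the distance-decay
relationship (DDR) regresses log10 community similarity on log10
geographic distance over unordered sample pairs, the slope being the
decay rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform

from .diversity import DistanceMatrix
from .profile_io import SampleMetadata

logger = logging.getLogger(__name__)

# WGS-84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_B = _A * (1.0 - _F)

_CONV_TOL = 1e-12
_MAX_ITER = 200


class GeoCoordinate(NamedTuple):
    latitude: float
    longitude: float


@dataclass(frozen=True)
class RegressionFit:
    """OLS summary: slope, intercept, Pearson r, r^2, two-sided p, n."""

    slope: float
    intercept: float
    r: float
    r2: float
    p: float
    n: int
    n_excluded: int = 0


def _check_coord(c: GeoCoordinate) -> None:
    if abs(c.latitude) > 90 or abs(c.longitude) > 180:
        raise ValueError(f"invalid coordinate {c}")


def vincenty_distance(a: GeoCoordinate, b: GeoCoordinate,
                      full_output: bool = False):
    """Inverse Vincenty geodesic distance in metres on WGS-84.

    Iterates the longitude difference on the auxiliary sphere to
    |dLambda| < 1e-12 (max 200 iterations).  For near-antipodal pairs the
    iteration may not converge; the current estimate is then returned with
    ``converged=False`` (and a warning) when ``full_output`` is set.
    """
    a = GeoCoordinate(*a)
    b = GeoCoordinate(*b)
    _check_coord(a)
    _check_coord(b)
    if a == b:
        return (0.0, True) if full_output else 0.0

    phi1, phi2 = math.radians(a.latitude), math.radians(b.latitude)
    L = math.radians(b.longitude - a.longitude)
    U1 = math.atan((1 - _F) * math.tan(phi1))
    U2 = math.atan((1 - _F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    converged = False
    for _ in range(_MAX_ITER):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cosU2 * sin_lam,
                               cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0.0:
            return (0.0, True) if full_output else 0.0  # coincident
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha ** 2
        if cos2_alpha == 0.0:
            cos_2sigma_m = 0.0  # equatorial line
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = _F / 16.0 * cos2_alpha * (4.0 + _F * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * _F * sin_alpha * (
            sigma + C * sin_sigma * (
                cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)))
        if abs(lam - lam_prev) < _CONV_TOL:
            converged = True
            break
    if not converged:
        logger.warning("vincenty: no convergence for %s - %s (near-antipodal); "
                       "returning last iterate", a, b)

    u2 = cos2_alpha * (_A ** 2 - _B ** 2) / _B ** 2
    A_ = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B_ = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = B_ * sin_sigma * (
        cos_2sigma_m + B_ / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)
            - B_ / 6.0 * cos_2sigma_m * (-3.0 + 4.0 * sin_sigma ** 2)
            * (-3.0 + 4.0 * cos_2sigma_m ** 2)))
    dist = _B * A_ * (sigma - delta_sigma)
    return (dist, converged) if full_output else dist


def geographic_distance_matrix(metadata: SampleMetadata) -> DistanceMatrix:
    """Pairwise Vincenty distances (metres) between all samples."""
    ids = metadata.sample_ids
    coords = [GeoCoordinate(float(metadata.data.loc[s, "latitude"]),
                            float(metadata.data.loc[s, "longitude"])) for s in ids]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = vincenty_distance(coords[i], coords[j])
    return DistanceMatrix(tuple(ids), d, metric="vincenty_m")


def _linregress(x: np.ndarray, y: np.ndarray, n_excluded: int = 0) -> RegressionFit:
    if len(x) < 3:
        raise ValueError(f"need >= 3 points for a regression, got {len(x)}")
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        # degenerate: no variance in one variable; r treated as 0
        return RegressionFit(0.0, float(np.mean(y)), 0.0, 0.0, 1.0, len(x), n_excluded)
    res = stats.linregress(x, y)
    return RegressionFit(float(res.slope), float(res.intercept), float(res.rvalue),
                         float(res.rvalue ** 2), float(res.pvalue), len(x), n_excluded)


def ldg_regression(metadata: SampleMetadata, richness: pd.Series,
                   layer: str | None = None) -> RegressionFit:
    """Latitudinal diversity gradient: OLS of richness on |latitude|."""
    df = metadata.data
    ids = df.index if layer is None else df.index[df["layer"] == layer]
    ids = [s for s in ids if s in richness.index]
    if len(ids) < 3:
        raise ValueError(f"fewer than 3 samples with richness in layer {layer!r}")
    x = df.loc[ids, "latitude"].astype(float).abs().to_numpy()
    y = richness.loc[ids].astype(float).to_numpy()
    return _linregress(x, y)


def ddr_regression(similarity: DistanceMatrix, geo: DistanceMatrix,
                   sample_ids: Sequence[str] | None = None) -> RegressionFit:
    """Distance-decay: OLS of log10 similarity on log10 geographic distance.

    Pairs with zero similarity or zero distance are excluded (log
    undefined); the count of excluded pairs is reported in the fit.
    """
    if not similarity.is_similarity:
        raise ValueError("first argument must be a similarity matrix")
    ids = list(sample_ids) if sample_ids is not None else list(similarity.sample_ids)
    sim = similarity.subset(ids).condensed()
    dist = geo.subset(ids).condensed()
    usable = (sim > 0) & (dist > 0)
    n_excluded = int((~usable).sum())
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable (non-zero) pairs for the log-log fit")
    return _linregress(np.log10(dist[usable]), np.log10(sim[usable]),
                       n_excluded=n_excluded)
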