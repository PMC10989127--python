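"""Reading, writing and preprocessing of sample x feature profile tables.

Profiles come in two granularities: functional gene families (54 cobalamin
biosynthesis families grouped into 5 pathway modules) and the taxa carrying
them.  All tables are plain TSV: first column sample id, header row of
feature ids, non-negative values.  Sample metadata carries geography
(latitude/longitude/depth/layer) and the environmental factors used
downstream; missing values are encoded as ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

TABLE_KINDS = ("gene", "pathway", "taxon")
LAYERS = ("SRF", "DCM", "MES")

#: Environmental factor columns recognized in metadata (beyond geography).
ENV_FACTORS = (
    "depth",
    "temperature",
    "oxygen",
    "nitrates",
    "NO2NO3",
    "PO4",
    "salinity",
    "Si",
)
RESPONSE_COLUMNS = ("chlorophyll_a", "metH_relative_abundance")

_REL_TOL = 1e-9


class ProfileFormatError(ValueError):
    """Raised when a profile table violates the format contract."""


@dataclass(frozen=True)
class AbundanceTable:
    """Samples x features abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with feature-id columns; values are
        non-negative counts or relative abundances.
    kind:
        One of ``gene``, ``pathway``, ``taxon``.
    is_relative:
        If True, each row must sum to 1 within 1e-9.
    """

    data: pd.DataFrame
    kind: str
    is_relative: bool = False

    def __post_init__(self) -> None:
        if self.kind not in TABLE_KINDS:
            raise ValueError(f"kind must be one of {TABLE_KINDS}, got {self.kind!r}")
        if self.data.shape[1] == 0:
            raise ProfileFormatError("empty feature set")
        if self.data.shape[0] == 0:
            raise ProfileFormatError("table has no samples")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ProfileFormatError(f"duplicate sample ids: {dup}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ProfileFormatError(f"duplicate feature ids: {dup}")
        vals = self.values
        if not np.isfinite(vals).all():
            raise ProfileFormatError("non-finite values in table")
        if (vals < 0).any():
            raise ProfileFormatError("negative values in table")
        if self.is_relative:
            row_sums = vals.sum(axis=1)
            bad = np.abs(row_sums - 1.0) > _REL_TOL
            if bad.any():
                ids = list(self.data.index[bad])
                raise ProfileFormatError(
                    f"is_relative set but rows do not sum to 1: {ids[:5]}"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def counts(self) -> np.ndarray:
        """Integer view of the values; raises if the table is not counts."""
        if self.is_relative:
            raise ValueError("table holds relative abundances, not counts")
        vals = self.values
        rounded = np.rint(vals)
        if not np.allclose(vals, rounded, atol=1e-6):
            raise ValueError("table does not hold integer counts")
        return rounded.astype(np.int64)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample geography, layer, environmental factors and responses."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ProfileFormatError("duplicate sample ids in metadata")
        for col in ("latitude", "longitude", "layer"):
            if col not in df.columns:
                raise ProfileFormatError(f"metadata missing required column {col!r}")
        lat = df["latitude"].astype(float)
        lon = df["longitude"].astype(float)
        if (lat.abs() > 90).any():
            raise ProfileFormatError("latitude outside [-90, 90]")
        if (lon.abs() > 180).any():
            raise ProfileFormatError("longitude outside [-180, 180]")
        bad_layer = ~df["layer"].isin(LAYERS)
        if bad_layer.any():
            raise ProfileFormatError(
                f"unknown layer codes: {sorted(df.loc[bad_layer, 'layer'].unique())}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    def layer_groups(self) -> pd.Series:
        return self.data["layer"]

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)].copy())


# ---------------------------------------------------------------------------
# I/O


def read_table(path, kind: str) -> AbundanceTable:
    """Read a TSV abundance table (first column sample id, header features)."""
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    if raw.shape[1] < 2:
        raise ProfileFormatError(f"{path}: no feature columns")
    id_col = raw.columns[0]
    dup = raw[id_col].duplicated()
    if dup.any():
        # +2: one for header line, one for 1-based numbering
        rows = [int(i) + 2 for i in np.flatnonzero(dup)]
        raise ProfileFormatError(f"{path}: duplicate sample id at row(s) {rows}")
    df = raw.set_index(id_col)
    df.index.name = "sample_id"
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ProfileFormatError(f"{path}: non-numeric abundance value: {exc}") from exc
    is_rel = bool(np.allclose(df.to_numpy().sum(axis=1), 1.0, atol=_REL_TOL))
    return AbundanceTable(df, kind=kind, is_relative=is_rel)


def write_table(table: AbundanceTable, path) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype={"layer": str})
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    df = metadata.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# Transforms


def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample each sample without replacement to a fixed depth.

    Samples whose total count is below ``depth`` are dropped (and logged).
    Each surviving row is a multivariate-hypergeometric draw, so row sums
    equal ``depth`` exactly.
    """
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    counts = table.counts()
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = [sid for sid, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    if not keep.any():
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    kept = counts[keep]
    out = np.empty_like(kept)
    for i, row in enumerate(kept):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    df = pd.DataFrame(out, index=table.data.index[keep], columns=table.data.columns)
    return AbundanceTable(df, kind=table.kind, is_relative=False)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Row-normalize to relative abundances (idempotent)."""
    if table.is_relative:
        return replace(table, data=table.data.copy())
    vals = table.values
    row_sums = vals.sum(axis=1)
    zero = row_sums == 0
    if zero.any():
        ids = list(table.data.index[zero])
        raise ValueError(f"cannot normalize all-zero sample(s): {ids}")
    df = pd.DataFrame(vals / row_sums[:, None], index=table.data.index,
                      columns=table.data.columns)
    return AbundanceTable(df, kind=table.kind, is_relative=True)


def aggregate_genes_to_pathways(table: AbundanceTable, catalog) -> AbundanceTable:
    """Sum gene-family columns into their 5 pathway modules.

    ``catalog`` is either a TraitCatalog or a plain mapping
    gene_family -> module name.  Row totals are conserved exactly.
    """
    if table.kind != "gene":
        raise ValueError(f"expected a gene table, got kind={table.kind!r}")
    mapping = catalog if isinstance(catalog, Mapping) else catalog.pathway_module_of
    unmapped = [f for f in table.feature_ids if f not in mapping]
    if unmapped:
        raise ValueError(f"gene families missing from catalog: {unmapped}")
    modules = pd.Index([mapping[f] for f in table.feature_ids], name="module")
    grouped = table.data.T.groupby(modules).sum().T
    # stable, canonical module order where available
    order = [m for m in _module_order(mapping) if m in grouped.columns]
    grouped = grouped[order]
    return AbundanceTable(grouped, kind="pathway", is_relative=table.is_relative)


def _module_order(mapping: Mapping[str, str]) -> list[str]:
    seen: dict[str, None] = {}
    for m in mapping.values():
        seen.setdefault(m, None)
    return list(seen)


def aggregate_taxa(table: AbundanceTable, lineage_of: Mapping[str, Sequence[str]],
                   level: int) -> AbundanceTable:
    """Aggregate a taxon table to a coarser rank.

    ``level`` is the 1-based prefix length of the lineage (1 = phylum with
    the default synthetic lineages).  Taxa without a lineage, or with a
    lineage shorter than ``level``, are grouped under ``unclassified``.
    Totals are conserved.
    """
    if table.kind != "taxon":
        raise ValueError(f"expected a taxon table, got kind={table.kind!r}")
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    max_depth = max((len(v) for v in lineage_of.values()), default=0)
    if level > max_depth:
        raise ValueError(f"level {level} exceeds lineage depth {max_depth}")
    labels = []
    for taxon in table.feature_ids:
        lineage = lineage_of.get(taxon)
        if lineage is None or len(lineage) < level:
            labels.append("unclassified")
        else:
            labels.append(";".join(lineage[:level]))
    grouped = table.data.T.groupby(pd.Index(labels, name="lineage")).sum().T
    return AbundanceTable(grouped, kind="taxon", is_relative=table.is_relative)


# ---------------------------------------------------------------------------
# Layer-wise differential-abundance screen


def kruskal_wallis_screen(table: AbundanceTable, groups: Mapping[str, str] | pd.Series,
                          fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis H per feature between sample groups, BH-adjusted.

    Returns a DataFrame (feature, H, p, q, significant) sorted by q.  The
    screen is typically run between the epipelagic (SRF/DCM) zone and the
    mesopelagic layer on relative abundances.
    """
    groups = pd.Series(groups)
    groups = groups.loc[table.sample_ids]
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    masks = [np.asarray(groups == g) for g in labels]
    for g, m in zip(labels, masks):
        if m.sum() < 1:
            raise ValueError(f"group {g!r} is empty")
    vals = table.values
    H = np.empty(vals.shape[1])
    p = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        samples = [vals[m, j] for m in masks]
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            H[j], p[j] = 0.0, 1.0
            continue
        H[j], p[j] = stats.kruskal(*samples)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame({
        "feature": table.feature_ids,
        "H": H,
        "p": p,
        "q": q,
        "significant": q < fdr_alpha,
    })
    return out.sort_values(["q", "p", "feature"], kind="mergesort").reset_index(drop=True)
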