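"""Synthetic metacommunities where the environment selects traits, not taxa.

The generator emulates the statistical structure of the field data the
downstream analyses assume: a pool of gene families (54 cobalamin-pathway
families in 5 pathway modules by default), taxa defined by the subset of
families they carry (functional redundancy = several taxa sharing one
trait profile), and per-sample communities assembled by a controllable
mixture of trait-based environmental selection and a neutral lottery.

Assembly model.  Each gene family has a Gaussian niche on a 1-D
environmental axis; a taxon's fitness in a sample with environment ``e``
is the mean niche match exp(-(e - opt)^2 / (2 breadth^2)) over its carried
families.  The neutral component is a multinomial lottery over a regional
log-normal relative-abundance vector, perturbed per sample by log-normal
drift noise whose scale is controlled by ``dispersal_kernel_scale``
(large scale = well-mixed metacommunity, small scale = strong local
drift).  Sampling probabilities mix the two components with weight
``determinism_w``: w = 1 is pure trait selection, w = 0 a pure neutral
lottery.  Gene profiles are derived from taxon profiles through the
incidence matrix, so permuting abundance among functionally redundant
taxa leaves the gene table unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profile_io import AbundanceTable, SampleMetadata, LAYERS

PATHWAY_MODULES = ("precorrin2", "aerobic", "anaerobic", "salvage", "post_adocbip")

#: Split of the 54 default gene families over the five pathway modules.
DEFAULT_MODULE_SIZES = {
    "precorrin2": 12,
    "aerobic": 15,
    "anaerobic": 15,
    "salvage": 8,
    "post_adocbip": 4,
}

_ENV_AXIS = (-2.0, 2.0)
#: Mean position of each ocean layer on the latent environmental axis.
LAYER_ENV_MEANS = {"SRF": 1.2, "DCM": 0.4, "MES": -1.4}
_LAYER_DEPTH_RANGE = {"SRF": (5, 10), "DCM": (17, 180), "MES": (250, 1000)}

EFFECT_KEYS = ("chla_taxonomic", "chla_functional", "meth_functional", "noise_sd")
DEFAULT_EFFECTS = {"chla_taxonomic": 1.0, "chla_functional": -1.0,
                   "meth_functional": 1.0, "noise_sd": 0.3}


@dataclass(frozen=True)
class TraitCatalog:
    """Gene families, their pathway modules and Gaussian niche parameters."""

    gene_family_ids: tuple
    pathway_module_of: dict
    niche_optimum: dict
    niche_breadth: dict

    def __post_init__(self) -> None:
        for f in self.gene_family_ids:
            if f not in self.pathway_module_of:
                raise ValueError(f"family {f!r} has no pathway module")
            if self.niche_breadth[f] <= 0:
                raise ValueError(f"niche_breadth must be positive for {f!r}")
        modules = set(self.pathway_module_of.values())
        unknown = modules - set(PATHWAY_MODULES)
        if unknown:
            raise ValueError(f"unknown pathway modules: {sorted(unknown)}")

    @property
    def n_families(self) -> int:
        return len(self.gene_family_ids)


@dataclass(frozen=True)
class TaxonTraitMap:
    """Taxa, their lineages, and the taxon x gene-family incidence matrix.

    With redundancy R, every distinct trait profile is carried by exactly
    R taxa with distinct ids and lineages.
    """

    taxon_ids: tuple
    lineage_of: dict
    incidence: pd.DataFrame  # taxa x gene families, 0/1
    redundancy_R: int

    def __post_init__(self) -> None:
        inc = self.incidence.to_numpy()
        if not np.isin(inc, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")
        if (inc.sum(axis=0) < 1).any():
            empty = list(self.incidence.columns[inc.sum(axis=0) < 1])
            raise ValueError(f"gene families carried by no taxon: {empty}")
        profiles = [tuple(row) for row in inc]
        counts = pd.Series(profiles).value_counts()
        if (counts != self.redundancy_R).any():
            raise ValueError("each distinct trait profile must be carried by "
                             f"exactly {self.redundancy_R} taxa")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


@dataclass(frozen=True)
class AssemblyParams:
    """Knobs of the assembly simulation.

    determinism_w:
        Weight in [0, 1] of trait-based selection vs the neutral lottery.
    n_samples_per_layer:
        Samples drawn for each ocean layer.
    community_size:
        Total individuals (counts) per sample.
    dispersal_kernel_scale:
        Controls neutral drift: per-sample log-normal noise on the
        regional abundances has sigma = 1 / dispersal_kernel_scale.
    regional_sigma:
        Log-normal sigma of the fixed regional relative-abundance vector.
        Kept small by default so that, under pure neutrality, which taxa
        dominate a sample is decided by the local lottery rather than by a
        shared regional backbone.
    env_values:
        Optional explicit sample -> environment mapping; generated from
        layer means (sd 0.4) when absent.
    """

    determinism_w: float
    n_samples_per_layer: Mapping[str, int] = field(
        default_factory=lambda: {"SRF": 16, "DCM": 12, "MES": 12})
    community_size: int = 20000
    dispersal_kernel_scale: float = 1.0
    regional_sigma: float = 0.3
    seed: int = 0
    env_values: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.determinism_w <= 1.0:
            raise ValueError("determinism_w must lie in [0, 1]")
        if self.community_size <= 0:
            raise ValueError("community_size must be positive")
        if self.dispersal_kernel_scale <= 0:
            raise ValueError("dispersal_kernel_scale must be positive")
        unknown = set(self.n_samples_per_layer) - set(LAYERS)
        if unknown:
            raise ValueError(f"unknown layers: {sorted(unknown)}")


@dataclass(frozen=True)
class SyntheticDataset:
    """Paired taxon and gene tables, metadata, and the generating truth."""

    taxon_table: AbundanceTable
    gene_table: AbundanceTable
    metadata: SampleMetadata
    truth_params: AssemblyParams
    truth_map: TaxonTraitMap
    truth_catalog: TraitCatalog

    def __post_init__(self) -> None:
        ids = self.taxon_table.sample_ids
        if self.gene_table.sample_ids != ids or self.metadata.sample_ids != ids:
            raise ValueError("sample ids/order differ between tables and metadata")


# ---------------------------------------------------------------------------
# Catalog and trait map construction


def build_trait_catalog(n_families: int = 54,
                        module_sizes: Mapping[str, int] | None = None,
                        seed: int = 0) -> TraitCatalog:
    """Create a gene-family catalog with niche optima spread over the axis.

    Optima are an RNG-permuted even grid over the environmental axis, so
    every catalog covers the axis; breadths are uniform in [0.15, 0.4] —
    narrow relative to the axis span, so that environmental selection
    meaningfully differentiates habitats.
    """
    if n_families < 5:
        raise ValueError("need at least 5 families (one per pathway module)")
    if module_sizes is None:
        if n_families == 54:
            module_sizes = dict(DEFAULT_MODULE_SIZES)
        else:
            base, extra = divmod(n_families, len(PATHWAY_MODULES))
            module_sizes = {m: base + (1 if i < extra else 0)
                            for i, m in enumerate(PATHWAY_MODULES)}
    if sum(module_sizes.values()) != n_families:
        raise ValueError(f"module sizes {module_sizes} do not sum to {n_families}")
    if any(v < 1 for v in module_sizes.values()):
        raise ValueError("every pathway module must be non-empty")

    rng = np.random.default_rng(seed)
    ids, module_of = [], {}
    for module in PATHWAY_MODULES:
        for i in range(module_sizes.get(module, 0)):
            fid = f"{module}_{i + 1:02d}"
            ids.append(fid)
            module_of[fid] = module
    lo, hi = _ENV_AXIS
    optima = rng.permutation(np.linspace(lo, hi, n_families))
    breadths = rng.uniform(0.15, 0.4, n_families)
    return TraitCatalog(tuple(ids), module_of,
                        dict(zip(ids, optima.tolist())),
                        dict(zip(ids, breadths.tolist())))


def build_taxon_trait_map(catalog: TraitCatalog, n_profiles: int,
                          redundancy_R: int, seed: int = 0) -> TaxonTraitMap:
    """Draw distinct trait profiles and replicate each over R taxa.

    Each profile carries 3-12 gene families drawn uniformly without
    replacement; families left uncovered are appended to random profiles
    so every family is carried by at least one taxon.
    """
    if n_profiles < 1:
        raise ValueError("n_profiles must be >= 1")
    if redundancy_R < 1:
        raise ValueError("redundancy_R must be >= 1")
    rng = np.random.default_rng(seed)
    n_fam = catalog.n_families
    k_max = min(12, n_fam)
    k_min = min(3, k_max)

    for _ in range(1000):
        profiles = []
        seen = set()
        while len(profiles) < n_profiles:
            k = int(rng.integers(k_min, k_max + 1))
            fams = frozenset(rng.choice(n_fam, size=k, replace=False).tolist())
            if fams not in seen:
                seen.add(fams)
                profiles.append(set(fams))
        covered = set().union(*profiles)
        missing = [f for f in range(n_fam) if f not in covered]
        rng.shuffle(missing)
        for f in missing:
            profiles[int(rng.integers(n_profiles))].add(f)
        if len({frozenset(p) for p in profiles}) == n_profiles:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not draw distinct trait profiles")

    inc = np.zeros((n_profiles * redundancy_R, n_fam), dtype=np.int64)
    taxon_ids, lineage_of = [], {}
    t = 0
    for p_idx, fams in enumerate(profiles):
        for r in range(redundancy_R):
            tid = f"t{t + 1:04d}"
            taxon_ids.append(tid)
            inc[t, sorted(fams)] = 1
            # synthetic lineage: redundant taxa diverge below phylum
            phylum = f"P{p_idx % 8 + 1:02d}"
            lineage_of[tid] = (phylum,
                               f"{phylum};C{p_idx + 1:03d}",
                               f"{phylum};C{p_idx + 1:03d};O{r + 1:02d}",
                               f"{phylum};C{p_idx + 1:03d};O{r + 1:02d};F{t + 1:04d}",
                               f"{phylum};C{p_idx + 1:03d};O{r + 1:02d};F{t + 1:04d};G{t + 1:04d}")
            t += 1
    df = pd.DataFrame(inc, index=taxon_ids, columns=list(catalog.gene_family_ids))
    return TaxonTraitMap(tuple(taxon_ids), lineage_of, df, redundancy_R)


# ---------------------------------------------------------------------------
# Assembly simulation


def _sample_layout(params: AssemblyParams, rng: np.random.Generator):
    """Sample ids, layers and environmental values for one metacommunity."""
    sample_ids, layers, env = [], [], []
    for layer in LAYERS:
        n = int(params.n_samples_per_layer.get(layer, 0))
        for i in range(n):
            sid = f"{layer}{i + 1:03d}"
            sample_ids.append(sid)
            layers.append(layer)
            if params.env_values is not None:
                env.append(float(params.env_values[sid]))
            else:
                env.append(float(rng.normal(LAYER_ENV_MEANS[layer], 0.4)))
    if not sample_ids:
        raise ValueError("no samples requested")
    return sample_ids, layers, np.asarray(env)


def simulate_metacommunity(tmap: TaxonTraitMap, catalog: TraitCatalog,
                           params: AssemblyParams) -> SyntheticDataset:
    """Assemble per-sample taxon counts and derive the paired gene table.

    For each sample, counts are a multinomial draw of ``community_size``
    individuals with probability proportional to
    ``w * fitness + (1 - w) * neutral``, both components normalized to sum
    to one.  A fixed seed reproduces the dataset bit-for-bit.
    """
    if tmap.n_taxa == 0:
        raise ValueError("empty taxon pool")
    rng = np.random.default_rng(params.seed)
    sample_ids, layers, env = _sample_layout(params, rng)
    n_taxa = tmap.n_taxa
    inc = tmap.incidence.to_numpy().astype(float)

    opt = np.array([catalog.niche_optimum[f] for f in catalog.gene_family_ids])
    br = np.array([catalog.niche_breadth[f] for f in catalog.gene_family_ids])
    # family x sample Gaussian niche match
    match = np.exp(-((env[None, :] - opt[:, None]) ** 2) / (2.0 * br[:, None] ** 2))
    fam_per_taxon = inc.sum(axis=1)
    fitness = (inc @ match) / fam_per_taxon[:, None]  # taxa x samples

    regional = rng.lognormal(mean=0.0, sigma=params.regional_sigma, size=n_taxa)
    drift_sigma = 1.0 / params.dispersal_kernel_scale
    w = params.determinism_w

    counts = np.zeros((len(sample_ids), n_taxa), dtype=np.int64)
    for s in range(len(sample_ids)):
        neutral = regional * rng.lognormal(0.0, drift_sigma, n_taxa)
        p = w * fitness[:, s] / fitness[:, s].sum() + (1 - w) * neutral / neutral.sum()
        counts[s] = rng.multinomial(params.community_size, p / p.sum())

    taxon_df = pd.DataFrame(counts, index=sample_ids,
                            columns=list(tmap.taxon_ids))
    taxon_table = AbundanceTable(taxon_df, kind="taxon")
    gene_table = derive_gene_profile(taxon_table, tmap)
    metadata = _base_metadata(sample_ids, layers, env, rng)
    return SyntheticDataset(taxon_table, gene_table, metadata, params, tmap, catalog)


def _base_metadata(sample_ids, layers, env, rng) -> SampleMetadata:
    """Geography and environmental factors driven by the latent axis.

    The axis is read as a warm/shallow-to-cold/deep gradient: temperature
    increases with it, |latitude| and nutrient concentrations decrease.
    """
    n = len(sample_ids)
    abs_lat = np.clip(35.0 - 15.0 * env + rng.normal(0, 8, n), 0.0, 78.0)
    sign = rng.choice([-1.0, 1.0], n)
    depth = np.array([rng.uniform(*_LAYER_DEPTH_RANGE[l]) for l in layers])
    df = pd.DataFrame({
        "latitude": sign * abs_lat,
        "longitude": rng.uniform(-180.0, 180.0, n),
        "layer": layers,
        "depth": depth,
        "temperature": 12.0 + 6.0 * env + rng.normal(0, 0.5, n),
        "oxygen": 220.0 + 25.0 * env + rng.normal(0, 10, n),
        "nitrates": np.clip(8.0 - 3.0 * env + rng.normal(0, 1, n), 0, None),
        "NO2NO3": np.clip(9.0 - 3.2 * env + rng.normal(0, 1, n), 0, None),
        "PO4": np.clip(0.8 - 0.25 * env + rng.normal(0, 0.1, n), 0, None),
        "salinity": 35.0 + rng.normal(0, 0.5, n),
        "Si": np.clip(10.0 - 2.0 * env + rng.normal(0, 2, n), 0, None),
    }, index=pd.Index(sample_ids, name="sample_id"))
    return SampleMetadata(df)


def derive_gene_profile(taxon_table: AbundanceTable, tmap: TaxonTraitMap,
                        noise_seed: int | None = None,
                        depth: int | None = None) -> AbundanceTable:
    """Gene-family counts implied by taxon abundances and trait incidence.

    ``gene[s, g] = sum_t abundance[s, t] * incidence[t, g]``; with
    ``depth`` set, each row is additionally resampled multinomially at
    that depth (finite sequencing effort), seeded by ``noise_seed``.
    Because the projection only sees trait profiles, permuting abundance
    among functionally redundant taxa leaves the output unchanged.
    """
    unknown = [t for t in taxon_table.feature_ids if t not in set(tmap.taxon_ids)]
    if unknown:
        raise ValueError(f"taxa absent from the trait map: {unknown[:5]}")
    inc = tmap.incidence.loc[taxon_table.feature_ids].to_numpy()
    gene = taxon_table.values @ inc
    if depth is not None:
        if noise_seed is None:
            raise ValueError("noise_seed required when resampling depth is set")
        rng = np.random.default_rng(noise_seed)
        resampled = np.empty_like(gene)
        for s in range(gene.shape[0]):
            p = gene[s] / gene[s].sum()
            resampled[s] = rng.multinomial(depth, p)
        gene = resampled
    df = pd.DataFrame(gene, index=taxon_table.data.index,
                      columns=list(tmap.incidence.columns))
    return AbundanceTable(df, kind="gene")


# ---------------------------------------------------------------------------
# Metadata responses


def synth_metadata(dataset: SyntheticDataset, effect_spec: Mapping[str, float],
                   seed: int = 0) -> SampleMetadata:
    """Plant chlorophyll-a and metH responses into the dataset's metadata.

    ``effect_spec`` keys: ``chla_taxonomic`` and ``chla_functional`` (signed
    strengths of the chlorophyll-a association with taxonomic and
    functional Shannon diversity), ``meth_functional`` (metH relative
    abundance vs functional diversity) and ``noise_sd``.  Responses are
    monotone transforms of the planted linear predictor, so noiseless
    effects give |Spearman rho| = 1.
    """
    unknown = set(effect_spec) - set(EFFECT_KEYS)
    if unknown:
        raise ValueError(f"unknown effect keys: {sorted(unknown)}")
    spec = {**DEFAULT_EFFECTS, **effect_spec}
    rng = np.random.default_rng(seed)

    from .diversity import shannon  # local import avoids a cycle at import time

    z_tax = _zscore(shannon(dataset.taxon_table).to_numpy())
    z_fun = _zscore(shannon(dataset.gene_table).to_numpy())
    n = len(z_tax)
    noise = spec["noise_sd"]
    chla_lin = (spec["chla_taxonomic"] * z_tax + spec["chla_functional"] * z_fun
                + rng.normal(0, noise, n))
    meth_lin = spec["meth_functional"] * z_fun + rng.normal(0, noise, n)

    df = dataset.metadata.data.copy()
    df["chlorophyll_a"] = 0.2 * np.exp(0.5 * chla_lin)      # mg m^-3 scale
    df["metH_relative_abundance"] = 1e-3 * np.exp(0.4 * meth_lin)
    return SampleMetadata(df)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# Scenario convenience


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to generate one benchmark dataset."""

    determinism_w: float = 0.5
    n_profiles: int = 40
    redundancy_R: int = 5
    n_families: int = 54
    community_size: int = 20000
    n_samples_per_layer: Mapping[str, int] = field(
        default_factory=lambda: {"SRF": 16, "DCM": 12, "MES": 12})
    dispersal_kernel_scale: float = 1.0
    effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0


def generate_scenario(spec: ScenarioSpec) -> SyntheticDataset:
    """Build catalog, trait map, metacommunity and full metadata in one call."""
    catalog = build_trait_catalog(spec.n_families, seed=spec.seed)
    tmap = build_taxon_trait_map(catalog, spec.n_profiles, spec.redundancy_R,
                                 seed=spec.seed + 1)
    params = AssemblyParams(determinism_w=spec.determinism_w,
                            n_samples_per_layer=dict(spec.n_samples_per_layer),
                            community_size=spec.community_size,
                            dispersal_kernel_scale=spec.dispersal_kernel_scale,
                            seed=spec.seed + 2)
    dataset = simulate_metacommunity(tmap, catalog, params)
    metadata = synth_metadata(dataset, dict(spec.effects), seed=spec.seed + 3)
    return SyntheticDataset(dataset.taxon_table, dataset.gene_table, metadata,
                            params, tmap, catalog)
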