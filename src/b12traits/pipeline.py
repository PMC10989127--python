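"""End-to-end orchestration of the trait-vs-taxonomy community analysis.

A run takes either a synthetic scenario specification or three input files
(gene table, taxon table, metadata), then executes the stages in order:
rarefaction, aggregation, alpha/beta diversity with ordination and group
tests, latitudinal and distance-decay regressions, the partial-Mantel
environment screen, richness-constrained null models with the
stochasticity ratio, and the metH / chlorophyll-a association and
prediction analyses.  Every artifact is a TSV under the run directory and
is listed in ``manifest.json`` together with the global seed and a hash of
the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, assembly_null, biogeography, diversity, profile_io
from .profile_io import ENV_FACTORS
from . import synthetic_community as synth

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one of ``scenario`` (generator settings) or the three input
    paths must be provided.  ``null_n_reps`` and the permutation counts
    are desk-scale defaults; raise them for production-size analyses.
    """

    output_dir: str
    seed: int = 0
    scenario: dict | None = None
    gene_table_path: str | None = None
    taxon_table_path: str | None = None
    metadata_path: str | None = None
    rarefaction_depth: int | None = None
    taxonomic_level: int = 1
    group_variable: str = "layer"
    null_n_reps: int = 200
    n_perm: int = 999
    mantel_n_perm: int = 999
    collinearity_threshold: float = 0.9

    def __post_init__(self) -> None:
        has_paths = all(p is not None for p in (self.gene_table_path,
                                                self.taxon_table_path,
                                                self.metadata_path))
        some_paths = any(p is not None for p in (self.gene_table_path,
                                                 self.taxon_table_path,
                                                 self.metadata_path))
        if self.scenario is not None and some_paths:
            raise ValueError("give either a scenario or input paths, not both")
        if self.scenario is None and not has_paths:
            raise ValueError("need either a scenario or all three input paths")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.artifacts: dict[str, list[str]] = {}
        self.timings: dict[str, float] = {}

    def write(self, stage: str, name: str, df: pd.DataFrame) -> None:
        path = self.outdir / name
        df.to_csv(path, sep="\t", index=True)
        self.artifacts.setdefault(stage, []).append(name)


def run_full_analysis(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    run = _Run(config)
    t0 = time.time()

    # -- stage: load or generate ------------------------------------------
    t = time.time()
    catalog = tmap = None
    if config.scenario is not None:
        spec = synth.ScenarioSpec(**{**config.scenario, "seed": config.seed})
        dataset = synth.generate_scenario(spec)
        gene_table, taxon_table = dataset.gene_table, dataset.taxon_table
        metadata = dataset.metadata
        catalog, tmap = dataset.truth_catalog, dataset.truth_map
        profile_io.write_table(gene_table, run.outdir / "gene_table.tsv")
        profile_io.write_table(taxon_table, run.outdir / "taxon_table.tsv")
        profile_io.write_metadata(metadata, run.outdir / "metadata.tsv")
        run.artifacts["generate"] = ["gene_table.tsv", "taxon_table.tsv",
                                     "metadata.tsv"]
    else:
        gene_table = profile_io.read_table(config.gene_table_path, kind="gene")
        taxon_table = profile_io.read_table(config.taxon_table_path, kind="taxon")
        metadata = profile_io.read_metadata(config.metadata_path)
        run.artifacts["load"] = []
    run.timings["load_or_generate"] = time.time() - t

    # -- stage: rarefy -----------------------------------------------------
    t = time.time()
    if config.rarefaction_depth is not None:
        gene_table = profile_io.rarefy(gene_table, config.rarefaction_depth,
                                       seed=config.seed + 101)
        taxon_table = profile_io.rarefy(taxon_table, config.rarefaction_depth,
                                        seed=config.seed + 102)
        common = [s for s in gene_table.sample_ids if s in set(taxon_table.sample_ids)]
        gene_table = profile_io.AbundanceTable(gene_table.data.loc[common],
                                               "gene", gene_table.is_relative)
        taxon_table = profile_io.AbundanceTable(taxon_table.data.loc[common],
                                                "taxon", taxon_table.is_relative)
        metadata = metadata.subset(common)
        profile_io.write_table(gene_table, run.outdir / "gene_table_rarefied.tsv")
        profile_io.write_table(taxon_table, run.outdir / "taxon_table_rarefied.tsv")
        run.artifacts["rarefy"] = ["gene_table_rarefied.tsv",
                                   "taxon_table_rarefied.tsv"]
    gene_rel = profile_io.to_relative(gene_table)
    taxon_rel = profile_io.to_relative(taxon_table)
    run.timings["rarefy"] = time.time() - t

    tables = {"gene": (gene_table, gene_rel), "taxon": (taxon_table, taxon_rel)}
    groups = metadata.data[config.group_variable]

    # -- stage: aggregate --------------------------------------------------
    t = time.time()
    if catalog is not None:
        pathway = profile_io.aggregate_genes_to_pathways(gene_table, catalog)
        run.write("aggregate", "pathway_table.tsv", pathway.data)
    if tmap is not None:
        phylum = profile_io.aggregate_taxa(taxon_table, tmap.lineage_of,
                                           config.taxonomic_level)
        run.write("aggregate", "taxon_table_aggregated.tsv", phylum.data)
    kw = profile_io.kruskal_wallis_screen(
        gene_rel, groups.map(lambda g: "EPI" if g in ("SRF", "DCM") else "MES"))
    run.write("aggregate", "kruskal_wallis_gene.tsv", kw)
    run.timings["aggregate"] = time.time() - t

    # -- stage: diversity --------------------------------------------------
    t = time.time()
    bc = {}
    for kind, (_counts, rel) in tables.items():
        alpha = pd.DataFrame({"richness": diversity.richness(rel),
                              "shannon": diversity.shannon(rel),
                              "pielou": diversity.pielou(rel)})
        run.write("diversity", f"alpha_{kind}.tsv", alpha)
        bc[kind] = diversity.bray_curtis(rel)
        run.write("diversity", f"braycurtis_{kind}.tsv",
                  pd.DataFrame(bc[kind].values, index=bc[kind].sample_ids,
                               columns=bc[kind].sample_ids))
        ord_res = diversity.pcoa(bc[kind])
        n_axes = min(2, ord_res.coordinates.shape[1])
        coords = pd.DataFrame(ord_res.coordinates[:, :n_axes],
                              index=list(ord_res.sample_ids),
                              columns=[f"PCo{i+1}" for i in range(n_axes)])
        run.write("diversity", f"pcoa_{kind}.tsv", coords)
        group_rows = []
        for test in (diversity.permanova, diversity.anosim, diversity.mrpp):
            res = test(bc[kind], groups, n_perm=config.n_perm,
                       seed=config.seed + 201)
            group_rows.append({"method": res.method, "statistic": res.statistic,
                               "p": res.p_value, "n_perm": res.n_permutations})
        run.write("diversity", f"group_tests_{kind}.tsv", pd.DataFrame(group_rows))
    run.timings["diversity"] = time.time() - t

    # -- stage: biogeography ----------------------------------------------
    t = time.time()
    geo = biogeography.geographic_distance_matrix(metadata)
    rows = []
    for kind, (_counts, rel) in tables.items():
        rich = diversity.richness(rel)
        sim = diversity.similarity(bc[kind])
        for layer in profile_io.LAYERS:
            ids = [s for s in rel.sample_ids
                   if metadata.data.loc[s, "layer"] == layer]
            if len(ids) < 3:
                continue
            ldg = biogeography.ldg_regression(metadata, rich, layer)
            rows.append({"pattern": "LDG", "kind": kind, "layer": layer,
                         **dataclasses.asdict(ldg)})
            try:
                ddr = biogeography.ddr_regression(sim, geo, ids)
                rows.append({"pattern": "DDR", "kind": kind, "layer": layer,
                             **dataclasses.asdict(ddr)})
            except ValueError as exc:
                logger.warning("DDR skipped for %s/%s: %s", kind, layer, exc)
    run.write("biogeo", "biogeography_regressions.tsv", pd.DataFrame(rows))
    run.timings["biogeo"] = time.time() - t

    # -- stage: environmental association ---------------------------------
    t = time.time()
    retained = association.screen_collinear_factors(
        metadata, list(ENV_FACTORS), threshold=config.collinearity_threshold)
    env_d = association.env_distance_matrix(metadata, retained)
    mantel_rows = []
    for kind, (_counts, _rel) in tables.items():
        for layer in profile_io.LAYERS:
            ids = [s for s in bc[kind].sample_ids
                   if metadata.data.loc[s, "layer"] == layer]
            if len(ids) < 4:
                continue
            res = association.partial_mantel(
                bc[kind].subset(ids), env_d.subset(ids), geo.subset(ids),
                n_perm=config.mantel_n_perm, seed=config.seed + 301)
            mantel_rows.append({"kind": kind, "layer": layer, "r": res.r,
                                "p": res.p, "n_perm": res.n_perm,
                                "controlled_for": res.controlled_for})
    run.write("associate", "mantel_results.tsv", pd.DataFrame(mantel_rows))
    run.write("associate", "retained_factors.tsv",
              pd.DataFrame({"factor": retained}))
    reg_rows = []
    for kind, (_counts, rel) in tables.items():
        sh = diversity.shannon(rel)
        for layer in (None, *profile_io.LAYERS):
            df = association.diversity_factor_regressions(metadata, sh,
                                                          retained, layer)
            if len(df):
                df.insert(0, "kind", kind)
                reg_rows.append(df)
    run.write("associate", "factor_regressions.tsv",
              pd.concat(reg_rows, ignore_index=True))
    run.timings["associate"] = time.time() - t

    # -- stage: null models / stochasticity ratio --------------------------
    t = time.time()
    st_rows = []
    for kind, (counts, _rel) in tables.items():
        cfg = assembly_null.NullModelConfig(n_reps=config.null_n_reps,
                                            seed=config.seed + 401)
        res = assembly_null.stochasticity_ratio(counts, groups, cfg)
        run.write("nullmodel", f"st_pairs_{kind}.tsv", res.pairs)
        for g, v in res.group_st.items():
            st_rows.append({"kind": kind, "group": g, "ST": v})
        st_rows.append({"kind": kind, "group": "overall", "ST": res.overall_st})
    run.write("nullmodel", "st_summary.tsv", pd.DataFrame(st_rows))
    run.timings["nullmodel"] = time.time() - t

    # -- stage: metH / chlorophyll-a ---------------------------------------
    t = time.time()
    if "chlorophyll_a" in metadata.data.columns:
        gene_sh = diversity.shannon(gene_rel)
        taxon_sh = diversity.shannon(taxon_rel)
        from scipy import stats as _stats
        chla = metadata.data["chlorophyll_a"].astype(float)
        rows = []
        for label, div in (("functional", gene_sh), ("taxonomic", taxon_sh)):
            rho, p = _stats.spearmanr(chla[div.index], div)
            rows.append({"response": "chlorophyll_a", "diversity": label,
                         "rho": rho, "p": p,
                         "significant": p < association.CHLA_ALPHA})
        if "metH_relative_abundance" in metadata.data.columns:
            rho, p, sig = association.correlate_metH(gene_sh, metadata)
            rows.append({"response": "metH", "diversity": "functional",
                         "rho": rho, "p": p, "significant": sig})
        run.write("predict", "chla_meth_correlations.tsv", pd.DataFrame(rows))
        pred_rows = []
        for kind, (_counts, rel) in tables.items():
            for mode in ("half_split", "cross_layer"):
                try:
                    pr = association.rf_predict_chla(rel, metadata, mode=mode,
                                                     seed=config.seed + 501)
                except ValueError as exc:
                    logger.warning("RF %s skipped for %s: %s", mode, kind, exc)
                    continue
                pred_rows.append({"kind": kind, "split": pr.split,
                                  "rho": pr.spearman_rho, "p": pr.spearman_p,
                                  "rmse": pr.rmse})
                scatter = pd.DataFrame({"observed": pr.observed,
                                        "predicted": pr.predicted})
                run.write("predict", f"prediction_scatter_{kind}_{mode}.tsv",
                          scatter)
        run.write("predict", "prediction_summary.tsv", pd.DataFrame(pred_rows))
    run.timings["predict"] = time.time() - t

    # -- manifest ----------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": run.artifacts,
        "timings_s": {k: round(v, 3) for k, v in run.timings.items()},
        "total_s": round(time.time() - t0, 3),
    }
    with open(run.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return run.outdir
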