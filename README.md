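# b12traits

Trait-vs-taxonomy community analysis for cobalamin (B12) biosynthesis
gene profiles.

Only a small cohort of prokaryotes can synthesize B12 de novo, yet the
cofactor underpins primary production across the ocean.  The gene
families of the B12 pathway and the taxa carrying them therefore form a
natural test case for a central question of microbial ecology: does the
environment select *functions* or *taxa*?  Because many different taxa
carry the same gene families (functional redundancy), taxonomic turnover
can be largely stochastic while the functional composition stays
deterministically pinned to the environment.

`b12traits` implements the full statistical pipeline for asking that
question from paired sample × gene-family and sample × taxon abundance
tables, plus a synthetic metacommunity generator that lets every stage be
tested without downloading ocean metagenomes.  It is aimed at microbial
ecologists working with functional-subcommunity profiles (here: 54 B12
pathway gene families in five modules — precorrin-2 synthesis, aerobic,
anaerobic, salvage/remodeling, post-AdoCbi-P).

## The core statistic

For each sample pair, observed Bray–Curtis similarity `C` is compared to
its expectation `Ē` under a null model that preserves each sample's
richness and the regional feature pool (averaged over many
randomizations).  With `D = 1 − C`, `Ḡ = 1 − Ē`, the stochasticity ratio
is

    ST = (Ē/C)·(D/Ḡ)   if C ≥ Ē
    ST = (Ḡ/D)·(C/Ē)   if C < Ē

`ST = 1` means assembly is indistinguishable from the null (stochastic);
values toward 0 mean deterministic departure — communities more similar
*or* more dissimilar than chance.  Group-level ST averages within-group
pairs (e.g. per ocean layer SRF/DCM/MES).

Around it, the package provides: rarefaction and gene→pathway/taxon-rank
aggregation with a Kruskal–Wallis + FDR layer screen; alpha diversity
(richness, Shannon–Wiener, Pielou), Bray–Curtis, PCoA and
PERMANOVA/ANOSIM/MRPP; latitudinal diversity gradients and log–log
distance decay over inverse-Vincenty WGS-84 geodesics; partial Mantel
tests of community vs environment correcting for geography, with a
deterministic collinearity screen; and Spearman/random-forest analyses
linking community profiles to chlorophyll-a and metH (B12-dependent
methionine synthase) abundance.

The generator inverts the hypothesis into a model: gene families have
Gaussian niches on an environmental axis, taxa are bundles of families
replicated `R`-fold (redundancy), and samples are assembled by a
multinomial mixture of trait-based selection (weight `w`) and a neutral
lottery.  `w` and `R` are the knobs the acceptance checks recover.  See
`docs/methods.md` for model details and limitations.

## Worked example

Generate a strongly selective, highly redundant metacommunity and
compare the stochasticity of taxa vs gene families:

```python
from b12traits import (ScenarioSpec, generate_scenario, NullModelConfig,
                       stochasticity_ratio)

spec = ScenarioSpec(determinism_w=0.75, n_profiles=20, redundancy_R=10,
                    community_size=20000,
                    n_samples_per_layer={"SRF": 14, "DCM": 13, "MES": 13},
                    seed=1)
ds = generate_scenario(spec)
cfg = NullModelConfig(n_reps=200, seed=1)
for label, table in (("taxa", ds.taxon_table), ("genes", ds.gene_table)):
    res = stochasticity_ratio(table, ds.metadata.layer_groups(), cfg)
    per_layer = "  ".join(f"{g}={v:.3f}" for g, v in res.group_st.items())
    print(f"{label:5s} overall ST = {res.overall_st:.3f}   {per_layer}")
```

prints

```
taxa  overall ST = 0.650   SRF=0.701  DCM=0.642  MES=0.599
genes overall ST = 0.269   SRF=0.301  DCM=0.203  MES=0.299
```

Both assemblies are partly deterministic (ST < 1), but the taxa carrying
the genes are markedly more stochastic (0.65) than the gene families
themselves (0.27): the environment pins down the functional composition,
while redundancy lets the taxonomic make-up drift — the signature the
pipeline is built to detect.

The same analysis runs from the shell:

```
b12traits generate --out demo --determinism-w 0.75 --redundancy-r 10 --seed 1
b12traits nullmodel demo/taxon_table.tsv demo/metadata.tsv --kind taxon \
    --n-reps 200 --seed 1 --out st_taxon.tsv
b12traits run-all config.yaml      # full pipeline from a YAML config
```

`run-all` executes every stage (generate/load → rarefy → aggregate →
diversity/ordination/group tests → LDG/DDR → Mantel screen → null models
→ chlorophyll-a/metH associations → random-forest prediction) and writes
TSV artifacts plus a manifest with the seed and config hash; reruns with
the same config are bit-identical.

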