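# Methods

`b12traits` analyses paired community profiles of a functional
subcommunity — gene families of the cobalamin (B12) biosynthesis pathway
and the taxa carrying them — and asks whether their assembly is governed
by deterministic (environmental selection) or stochastic (drift,
dispersal, lottery) processes.  This note records the models, the choices
made where the design was genuinely open, and the limits of what the
synthetic benchmarks can show.

## The stochasticity ratio and its null model

Between-sample diversity is Bray–Curtis dissimilarity
`BC(x, y) = Σ|x_i − y_i| / Σ(x_i + y_i)`; community similarity is its
complement `C = 1 − BC`.  For each unordered sample pair, the observed
similarity `C_ij` is compared against the expectation `Ē_ij` under a
richness-constrained null model, averaged over `n_reps` randomizations
(1000 by convention; desk-scale runs use 100–200, which the
Monte-Carlo-error test shows converges as 1/√n).  With `D = 1 − C` and
`Ḡ = 1 − Ē`:

    ST_ij = (Ē/C)·(D/Ḡ)   if C ≥ Ē        (branch A, deterministic convergence)
    ST_ij = (Ḡ/D)·(C/Ē)   if C < Ē        (branch B, deterministic divergence)
    ST     = (Σ ST_A + Σ ST_B) / (n_A + n_B)

`ST_ij = 1` exactly when observation matches the null (assembly
indistinguishable from stochastic); it decreases towards 0 as the
observation departs in either direction.  The `0/0` boundary cases
(`C = Ē ∈ {0, 1}`) return 1 — the observation sits on the expectation —
and the branch logic avoids any epsilon inflation.  Group-level ST
averages within-group pairs only (e.g. per ocean layer); the null
ensemble is computed once over the full table, so the regional pool spans
all samples.

### Null randomization

Each randomized table preserves, exactly:

1. every sample's richness — the number of occupied features is drawn
   without replacement with probability proportional to *regional
   occupancy frequency* (in how many samples a feature occurs);
2. every sample's total count;
3. the regional pool — after drawing, any pool feature left unoccupied is
   swapped in for one occurrence of a feature occupying ≥ 2 samples, in
   an RNG-chosen sample that lacks it.  The swap relabels a column within
   one sample, so richness and totals are untouched.  The repair step is
   rare for dense tables and biases marginal selection frequencies only
   when it fires.

Two abundance-assignment rules are implemented:

* `sample_shuffle` (default): the sample's own non-zero counts are
  permuted onto the drawn features.  Each null sample keeps its observed
  abundance distribution; only identities are randomized.  This is the
  convention of the richness-constrained null-model family this statistic
  comes from.
* `regional_proportional`: each drawn feature receives one count and the
  remainder is multinomial with probability proportional to regional
  abundance.  Because every null sample is then a draw around the *same*
  regional vector, the null ensemble is far more homogeneous than real
  data (Ē ≈ 0.95 almost regardless of input in our benchmarks).  It is
  retained as an explicit alternative but is a poor default: against such
  a null, even purely neutral data registers as strongly "deterministic",
  and the ST statistic loses its meaning as a stochasticity measure.

Replicate `r` is seeded `seed + r`, making ensembles reproducible and
trivially parallelizable.

## Synthetic metacommunities

The generator emulates profile-level data (not reads): a trait catalog,
a taxon–trait incidence map, per-sample taxon counts and the projected
gene table.

* **Trait catalog** — 54 gene families split over the five pathway
  modules (precorrin-2 synthesis 12, aerobic 15, anaerobic 15,
  salvage/remodeling 8, post-AdoCbi-P 4; the split across modules is an
  artifact choice).  Each family has a Gaussian niche on a latent
  environmental axis spanning [−2, 2]: optima are an RNG-permuted even
  grid (every catalog covers the axis), breadths uniform in [0.15, 0.4].
  Narrow niches relative to the axis span are what make environmental
  selection *differentiate* habitats; with broad niches, weak selection
  merely reshapes the abundance distribution identically everywhere and
  is statistically invisible.
* **Functional redundancy** — `n_profiles` distinct trait profiles
  (3–12 families each, every family covered), each carried by exactly
  `redundancy_R` taxa with distinct ids and synthetic lineages.  Gene
  profiles are the incidence-weighted sum of taxon counts, so permuting
  abundance among taxa of one profile provably leaves the gene table
  unchanged — the mechanism by which taxon-level drift cancels at the
  functional level.
* **Assembly** — sample counts are multinomial with probability
  `w·fitness + (1 − w)·neutral` (both normalized).  Fitness is a taxon's
  mean niche match over carried families at the sample's environment.
  The neutral term is a regional log-normal abundance vector (σ = 0.3)
  perturbed per sample by log-normal drift noise with
  σ = 1/`dispersal_kernel_scale` (default 1).  These two scales were set
  so that *pure neutrality is statistically commensurate with the
  identity-shuffled null*: drift, not a shared regional backbone, decides
  which taxa dominate a neutral sample, so at `w = 0` the observed
  similarity matches the null expectation (ST ≈ 0.9) and ST declines
  strictly as `w` rises.  A strong shared backbone (large regional σ) or
  weak drift would instead make neutral data depart from the null and
  break the interpretation of the knob.
* **Environment and layers** — samples belong to SRF/DCM/MES layers with
  latent-axis means 1.2/0.4/−1.4 (sd 0.4).  Metadata reads the axis as a
  warm-shallow-to-cold-deep gradient: temperature and oxygen increase
  with it, |latitude| and nutrient concentrations decrease, with additive
  noise; depth is uniform within the layer's range.
* **Planted responses** — chlorophyll-a and metH relative abundance are
  monotone (exponential) transforms of signed linear combinations of the
  z-scored taxonomic and functional Shannon diversities plus Gaussian
  noise, so a noiseless planted effect yields |Spearman ρ| = 1 and signs
  are recoverable even when the two diversities are correlated.

What the generator does **not** emulate: real taxonomies or phylogeny,
sequence-level noise other than optional multinomial resampling of gene
profiles, spatially explicit dispersal (the kernel scale is a drift
magnitude, not a distance kernel), covarying environmental axes, or the
heavy-tailed sparsity of real metagenomic tables.  Passing benchmarks
therefore show that the *statistics* behave as designed under a known
generative model — not that real ocean profiles satisfy that model.

## Standard analyses

* **Rarefaction** subsamples counts without replacement (multivariate
  hypergeometric) to a fixed depth; shallower samples are dropped and
  logged.  Layer screens use Kruskal–Wallis with tie correction and
  Benjamini–Hochberg FDR, run on relative abundances after rarefaction.
* **Alpha diversity**: richness, Shannon–Wiener (natural log), Pielou
  `J = H/ln S` (undefined below richness 2, reported missing).
* **Ordination**: PCoA of the Gower-centred matrix (via scikit-bio);
  axes with eigenvalue > 1e-10 retained, proportions over positive
  eigenvalues, no negative-eigenvalue correction (only the first two
  axes are used downstream).
* **Group tests**: PERMANOVA (pseudo-F), ANOSIM (rank R) and MRPP
  (weighted within-group δ, chance-corrected A) with seedable label
  permutations and `p = (1 + #{perm ≥ obs})/(1 + n_perm)` (≤ for MRPP,
  where small δ is extreme).  Default 999 permutations.
* **Geodesics**: inverse Vincenty on WGS-84, iterated to |Δλ| < 1e-12
  (≤ 200 iterations); near-antipodal non-convergence returns the last
  iterate with a flag and warning.  Verified to < 1 mm against an
  independent geodesic oracle on 20 fixed pairs.
* **LDG**: OLS of richness on |latitude| per layer.  Degenerate inputs
  (no variance) report slope 0, r = 0, p = 1.
* **DDR**: OLS of log10 similarity on log10 geodesic distance over
  unordered within-layer pairs.  Pairs with zero similarity or zero
  distance are excluded (log undefined) and counted.  The OLS p-value is
  reported with the usual caveat that pairs are not independent; a
  Mantel-style permutation is available through the Mantel machinery.
* **Mantel / partial Mantel**: Pearson correlation of off-diagonal
  vectors; the partial statistic is the first-order partial correlation
  given the control (geographic distance).  Significance permutes
  rows/columns of the first matrix jointly, one-sided "greater" (the
  vegan convention), default 9999 permutations.  Environmental distance
  is Euclidean on z-scored factors (z-scoring prevents unit dominance).
* **Collinearity screen**: greedy removal by pairwise |Spearman ρ| above
  a 0.9 threshold, dropping the factor with the larger mean absolute
  correlation (ties: later input order).  Deterministic, replaces an
  ordination-based factor evaluation.
* **Random forest**: scikit-learn regressor (300 trees), seeded half
  split of epipelagic samples or cross-layer transfer; the model never
  sees held-out labels (verified by a label-shuffle leakage test).
  Correlations in the chlorophyll-a family use the stringent P < 0.005
  significance threshold; other analyses use P < 0.05.

## Problem sizes and reproducibility

Benchmarks use 40-sample metacommunities (14/13/13 per layer), 200 taxa
(40 profiles × R 5, or 20 × 10 for the redundancy contrast), communities
of 20 000 individuals, and 100–200 null replicates — sizes chosen so the
full suite and the acceptance script each run in minutes on one core
while keeping Monte-Carlo error well below the effect sizes examined.
Every stochastic step takes an explicit seed; the pipeline writes a
manifest with the global seed and a configuration hash, and repeated runs
are bit-identical.

## Known limitations

* ST is a relative measure: its absolute level depends on the null's
  abundance rule, so only comparisons under a fixed configuration (e.g.
  taxa vs genes, layer vs layer) are meaningful.
* The pool-coverage repair slightly perturbs occupancy-proportional
  selection frequencies when it fires (sparse tables with rare features).
* The partial Mantel permutation scheme (permuting the community matrix)
  is one of several variants in use; with strong autocorrelation in the
  control matrix its type-I error can drift from nominal.
* ANOSIM tolerates singleton groups by construction but loses power;
  PERMANOVA and MRPP reject them.
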