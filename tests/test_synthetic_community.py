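import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from b12traits import (AbundanceTable, AssemblyParams, bray_curtis,
                       build_taxon_trait_map, build_trait_catalog,
                       derive_gene_profile, shannon, simulate_metacommunity,
                       synth_metadata, to_relative)
from b12traits.synthetic_community import (PATHWAY_MODULES, ScenarioSpec,
                                           TraitCatalog, generate_scenario)


class TestTraitCatalog:
    def test_default_catalog_structure(self):
        cat = build_trait_catalog(54, seed=0)
        assert cat.n_families == 54
        modules = pd.Series(cat.pathway_module_of)
        assert set(modules.unique()) == set(PATHWAY_MODULES)
        assert (modules.value_counts() >= 1).all()

    def test_minimal_one_family_per_module(self):
        cat = build_trait_catalog(5, seed=1)
        assert sorted(cat.pathway_module_of.values()) == sorted(PATHWAY_MODULES)

    def test_seeding_contract(self):
        a = build_trait_catalog(54, seed=7)
        b = build_trait_catalog(54, seed=7)
        c = build_trait_catalog(54, seed=8)
        assert a.niche_optimum == b.niche_optimum
        assert a.niche_optimum != c.niche_optimum

    def test_bad_module_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_trait_catalog(10, module_sizes={"aerobic": 3, "salvage": 3},
                                seed=0)


class TestTaxonTraitMap:
    def test_no_redundancy_gives_distinct_rows(self):
        cat = build_trait_catalog(20, seed=0)
        tmap = build_taxon_trait_map(cat, n_profiles=10, redundancy_R=1, seed=0)
        assert tmap.n_taxa == 10
        assert len(set(map(tuple, tmap.incidence.to_numpy()))) == 10

    def test_redundancy_replicates_profiles(self):
        cat = build_trait_catalog(20, seed=0)
        tmap = build_taxon_trait_map(cat, n_profiles=10, redundancy_R=10, seed=0)
        assert tmap.n_taxa == 100
        rows = list(map(tuple, tmap.incidence.to_numpy()))
        counts = pd.Series(rows).value_counts()
        assert len(counts) == 10 and (counts == 10).all()
        # distinct ids and lineages for redundant taxa
        assert len(set(tmap.taxon_ids)) == 100
        assert len({tmap.lineage_of[t][-1] for t in tmap.taxon_ids}) == 100

    def test_carried_family_column_sums_at_least_r(self):
        cat = build_trait_catalog(30, seed=3)
        r = 4
        tmap = build_taxon_trait_map(cat, n_profiles=8, redundancy_R=r, seed=3)
        col_sums = tmap.incidence.to_numpy().sum(axis=0)
        carried = col_sums > 0
        assert carried.all()  # every family covered by construction
        assert (col_sums[carried] >= r).all()

    def test_invalid_redundancy(self):
        cat = build_trait_catalog(10, seed=0)
        with pytest.raises(ValueError):
            build_taxon_trait_map(cat, n_profiles=5, redundancy_R=0, seed=0)


class TestSimulate:
    def test_seeding_contract(self):
        cat = build_trait_catalog(20, seed=0)
        tmap = build_taxon_trait_map(cat, 15, 2, seed=1)
        params = AssemblyParams(determinism_w=0.5, community_size=2000, seed=5)
        a = simulate_metacommunity(tmap, cat, params)
        b = simulate_metacommunity(tmap, cat, params)
        pd.testing.assert_frame_equal(a.taxon_table.data, b.taxon_table.data)

    def test_neutral_assembly_uncorrelated_with_environment(self):
        # w = 0: Bray-Curtis should not track environmental distance
        cat = build_trait_catalog(30, seed=0)
        tmap = build_taxon_trait_map(cat, 40, 2, seed=1)
        rs = []
        for seed in range(20):
            params = AssemblyParams(
                determinism_w=0.0, community_size=20000, seed=seed,
                n_samples_per_layer={"SRF": 14, "DCM": 13, "MES": 13})
            ds = simulate_metacommunity(tmap, cat, params)
            temp = ds.metadata.data["temperature"].to_numpy()
            de = squareform(np.abs(temp[:, None] - temp[None, :]), checks=False)
            bc = bray_curtis(to_relative(ds.taxon_table)).condensed()
            rs.append(np.corrcoef(de, bc)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_full_selection_separates_environmental_extremes(self):
        cat = build_trait_catalog(20, seed=2)
        # disjoint niches: families sit at the two ends of the axis
        opt = {f: (-1.8 if i < 10 else 1.8)
               for i, f in enumerate(cat.gene_family_ids)}
        br = {f: 0.3 for f in cat.gene_family_ids}
        cat = TraitCatalog(cat.gene_family_ids, cat.pathway_module_of, opt, br)
        tmap = build_taxon_trait_map(cat, 30, 2, seed=3)
        env = {}
        for i in range(8):
            env[f"SRF{i + 1:03d}"] = 1.8 if i < 4 else -1.8
        params = AssemblyParams(determinism_w=1.0, community_size=20000,
                                n_samples_per_layer={"SRF": 8}, seed=4,
                                env_values=env)
        ds = simulate_metacommunity(tmap, cat, params)
        bc = bray_curtis(to_relative(ds.taxon_table)).values
        between = bc[:4, 4:].ravel()
        within = np.r_[squareform(bc[:4, :4], checks=False),
                       squareform(bc[4:, 4:], checks=False)]
        assert between.min() > np.median(within)

    def test_determinism_knob_monotone_mantel(self):
        # mean rank-based env-composition matrix correlation non-decreasing in w
        means = []
        for w in (0, 0.25, 0.5, 0.75, 1.0):
            rs = []
            for seed in range(10):
                spec = ScenarioSpec(determinism_w=w, n_profiles=30,
                                    redundancy_R=3, community_size=10000,
                                    n_samples_per_layer={"SRF": 8, "DCM": 7,
                                                         "MES": 7},
                                    seed=seed * 17)
                ds = generate_scenario(spec)
                temp = ds.metadata.data["temperature"].to_numpy()
                de = squareform(np.abs(temp[:, None] - temp[None, :]),
                                checks=False)
                bc = bray_curtis(to_relative(ds.taxon_table)).condensed()
                rs.append(spearmanr(de, bc).statistic)
            means.append(np.mean(rs))
        assert all(np.diff(means) >= -1e-9)


class TestGeneProfile:
    def test_projection_of_single_taxon(self):
        cat = build_trait_catalog(6, seed=0)
        inc = pd.DataFrame(0, index=["t0001", "t0002"],
                           columns=list(cat.gene_family_ids))
        inc.iloc[0, [0, 1]] = 1
        inc.iloc[1, 2:] = 1
        from b12traits.synthetic_community import TaxonTraitMap
        tmap = TaxonTraitMap(("t0001", "t0002"),
                             {"t0001": ("P1",), "t0002": ("P2",)}, inc, 1)
        taxa = AbundanceTable(pd.DataFrame([[10, 0]], index=["s1"],
                                           columns=["t0001", "t0002"]),
                              kind="taxon")
        gene = derive_gene_profile(taxa, tmap)
        vals = gene.data.loc["s1"]
        assert vals.iloc[0] == 10 and vals.iloc[1] == 10
        assert (vals.iloc[2:] == 0).all()

    def test_redundancy_invariance(self):
        # swapping abundance between taxa with identical incidence rows
        # cannot change the gene table (the module's key property)
        cat = build_trait_catalog(20, seed=1)
        tmap = build_taxon_trait_map(cat, 10, 2, seed=2)
        params = AssemblyParams(determinism_w=0.5, community_size=5000, seed=3)
        ds = simulate_metacommunity(tmap, cat, params)
        inc = tmap.incidence
        rows = list(map(tuple, inc.to_numpy()))
        # find a redundant pair
        first = rows.index(rows[-1])
        t_a, t_b = inc.index[first], inc.index[-1]
        assert t_a != t_b
        swapped = ds.taxon_table.data.copy()
        swapped[[t_a, t_b]] = swapped[[t_b, t_a]].to_numpy()
        g1 = derive_gene_profile(ds.taxon_table, tmap)
        g2 = derive_gene_profile(AbundanceTable(swapped, kind="taxon"), tmap)
        pd.testing.assert_frame_equal(g1.data, g2.data)

    def test_noise_converges_to_exact_profile(self):
        cat = build_trait_catalog(20, seed=4)
        tmap = build_taxon_trait_map(cat, 10, 2, seed=5)
        params = AssemblyParams(determinism_w=0.5, community_size=3000, seed=6,
                                n_samples_per_layer={"SRF": 4})
        ds = simulate_metacommunity(tmap, cat, params)
        exact = to_relative(derive_gene_profile(ds.taxon_table, tmap))
        noisy = to_relative(derive_gene_profile(ds.taxon_table, tmap,
                                                noise_seed=1, depth=10 ** 6))
        gap = np.abs(exact.values - noisy.values).sum(axis=1)
        assert gap.max() < 0.01

    def test_unknown_taxon_rejected(self):
        cat = build_trait_catalog(10, seed=0)
        tmap = build_taxon_trait_map(cat, 4, 1, seed=0)
        taxa = AbundanceTable(pd.DataFrame([[1]], columns=["stranger"]),
                              kind="taxon")
        with pytest.raises(ValueError, match="stranger"):
            derive_gene_profile(taxa, tmap)


class TestSynthMetadata:
    def test_noiseless_positive_effect_gives_perfect_rank_correlation(self,
                                                                      demo_dataset):
        meta = synth_metadata(demo_dataset,
                              {"chla_taxonomic": 1.0, "chla_functional": 0.0,
                               "meth_functional": 1.0, "noise_sd": 0.0},
                              seed=0)
        h = shannon(demo_dataset.taxon_table)
        rho, _ = spearmanr(meta.data["chlorophyll_a"], h)
        assert rho == pytest.approx(1.0)

    def test_opposite_planted_signs_recovered(self, demo_dataset):
        meta = synth_metadata(demo_dataset,
                              {"chla_taxonomic": 1.0, "chla_functional": -1.0,
                               "noise_sd": 0.1}, seed=1)
        h_tax = shannon(demo_dataset.taxon_table)
        h_fun = shannon(demo_dataset.gene_table)
        rho_tax, _ = spearmanr(meta.data["chlorophyll_a"], h_tax)
        rho_fun, _ = spearmanr(meta.data["chlorophyll_a"], h_fun)
        assert rho_tax > 0 > rho_fun

    def test_null_effects_well_calibrated(self, demo_dataset):
        # all effects zero: responses are pure noise, p ~ Uniform(0,1)
        h = shannon(demo_dataset.taxon_table)
        pvals = []
        for seed in range(200):
            meta = synth_metadata(demo_dataset,
                                  {"chla_taxonomic": 0.0, "chla_functional": 0.0,
                                   "meth_functional": 0.0, "noise_sd": 1.0},
                                  seed=seed)
            _, p = spearmanr(meta.data["chlorophyll_a"], h)
            pvals.append(p)
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").pvalue > 0.01
        assert np.mean(np.array(pvals) < 0.05) < 0.1

    def test_unknown_effect_key_rejected(self, demo_dataset):
        with pytest.raises(ValueError, match="typo"):
            synth_metadata(demo_dataset, {"typo": 1.0}, seed=0)
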