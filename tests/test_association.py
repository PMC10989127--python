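import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import mantel as skbio_mantel

from b12traits import (SampleMetadata, correlate_metH,
                       diversity_factor_regressions, mantel, partial_mantel,
                       rf_predict_chla, screen_collinear_factors)
from b12traits.association import env_distance_matrix
from b12traits.diversity import DistanceMatrix
from b12traits.profile_io import AbundanceTable


def _dm(vals, ids=None):
    vals = np.asarray(vals, dtype=float)
    ids = ids or tuple(f"s{i}" for i in range(vals.shape[0]))
    return DistanceMatrix(tuple(ids), vals, "test")


def _random_dm(rng, n=12):
    pts = rng.normal(size=(n, 3))
    return _dm(squareform(pdist(pts)))


class TestMantel:
    def test_self_correlation_with_random_control(self, rng):
        d = _random_dm(rng)
        ctrl = _random_dm(rng)
        res = partial_mantel(d, d, ctrl, n_perm=199, seed=0)
        assert res.r > 0.99
        assert res.p == pytest.approx(1 / 200)

    def test_statistic_matches_skbio(self, rng):
        a, b = _random_dm(rng), _random_dm(rng)
        ref_r, _, _ = skbio_mantel(skbio.DistanceMatrix(a.values),
                                   skbio.DistanceMatrix(b.values),
                                   permutations=0)
        assert mantel(a, b, n_perm=99, seed=0).r == pytest.approx(ref_r, abs=1e-12)

    def test_planted_dependence_close_to_plain_mantel(self, rng):
        n = 14
        base = _random_dm(rng, n)
        noise = squareform(np.abs(rng.normal(0, 0.05, n * (n - 1) // 2)))
        dep = _dm(base.values + noise)
        ctrl = _random_dm(rng, n)
        plain = mantel(base, dep, n_perm=99, seed=1).r
        part = partial_mantel(base, dep, ctrl, n_perm=99, seed=1).r
        assert abs(plain - part) < 0.05

    def test_seed_reproducible(self, rng):
        a, b = _random_dm(rng), _random_dm(rng)
        assert (mantel(a, b, n_perm=199, seed=5).p
                == mantel(a, b, n_perm=199, seed=5).p)

    def test_mismatched_ids_rejected(self, rng):
        a = _random_dm(rng, 5)
        b = _dm(_random_dm(rng, 5).values, ids=tuple("vwxyz"))
        with pytest.raises(ValueError):
            mantel(a, b, n_perm=99, seed=0)


def _factor_meta(cols: dict) -> SampleMetadata:
    n = len(next(iter(cols.values())))
    df = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    df["latitude"] = 0.0
    df["longitude"] = 0.0
    df["layer"] = "SRF"
    return SampleMetadata(df)


class TestCollinearityScreen:
    def test_identical_factors_reduced_to_one(self, rng):
        x = rng.normal(size=30)
        meta = _factor_meta({"a": x, "b": x.copy(), "c": rng.normal(size=30)})
        kept = screen_collinear_factors(meta, ["a", "b", "c"], threshold=0.9)
        assert "c" in kept and len([f for f in kept if f in ("a", "b")]) == 1

    def test_independent_factors_all_retained(self, rng):
        meta = _factor_meta({k: rng.normal(size=40) for k in "abcd"})
        assert screen_collinear_factors(meta, list("abcd")) == list("abcd")

    def test_collinear_triple_reduced_to_single_representative(self, rng):
        x = rng.normal(size=200)
        triple = {f"t{i}": x + rng.normal(0, 0.02, 200) for i in range(3)}
        triple["free"] = rng.normal(size=200)
        meta = _factor_meta(triple)
        kept = screen_collinear_factors(meta, list(triple), threshold=0.9)
        assert "free" in kept
        assert len([f for f in kept if f.startswith("t")]) == 1

    def test_constant_factor_dropped(self, rng):
        meta = _factor_meta({"flat": np.ones(20), "x": rng.normal(size=20)})
        with pytest.raises(ValueError):
            screen_collinear_factors(meta, ["flat"])  # <2 factors
        kept = screen_collinear_factors(meta, ["flat", "x"])
        assert kept == ["x"]


class TestFactorRegressions:
    def test_monotone_relation_gives_perfect_rho(self):
        temp = np.arange(10, 30, 2.0)
        meta = _factor_meta({"temperature": temp})
        div = pd.Series(np.exp(temp / 10), index=meta.sample_ids)
        out = diversity_factor_regressions(meta, div, ["temperature"])
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_layer_specific_opposite_signs_recovered(self, rng):
        n = 30
        temp = rng.uniform(5, 25, 2 * n)
        layer = ["SRF"] * n + ["MES"] * n
        df = pd.DataFrame({"temperature": temp, "latitude": 0.0,
                           "longitude": 0.0, "layer": layer},
                          index=[f"s{i}" for i in range(2 * n)])
        meta = SampleMetadata(df)
        div = pd.Series(np.where(np.arange(2 * n) < n, temp, -temp)
                        + rng.normal(0, 0.5, 2 * n), index=meta.sample_ids)
        srf = diversity_factor_regressions(meta, div, ["temperature"], "SRF")
        mes = diversity_factor_regressions(meta, div, ["temperature"], "MES")
        assert srf.loc[0, "rho"] > 0 > mes.loc[0, "rho"]

    def test_ols_matches_closed_form(self, rng):
        x = rng.uniform(0, 10, 25)
        y = 2.5 * x + rng.normal(0, 1, 25)
        meta = _factor_meta({"oxygen": x})
        div = pd.Series(y, index=meta.sample_ids)
        out = diversity_factor_regressions(meta, div, ["oxygen"])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert out.loc[0, "slope"] == pytest.approx(slope, abs=1e-10)


class TestMetH:
    def test_monotone_planting_gives_perfect_rho(self):
        div = pd.Series(np.linspace(1, 3, 20), index=[f"s{i}" for i in range(20)])
        meta = _factor_meta({"metH_relative_abundance": np.exp(div.to_numpy())})
        rho, p, sig = correlate_metH(div, meta)
        assert rho == pytest.approx(1.0)
        assert sig

    def test_null_significance_rate_calibrated(self, rng):
        div = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        flags = 0
        n_rep = 1000
        for _ in range(n_rep):
            meta = _factor_meta(
                {"metH_relative_abundance": rng.normal(size=40)})
            _, _, sig = correlate_metH(div, meta)
            flags += sig
        # nominal rate 0.005; allow generous Monte-Carlo slack
        assert flags / n_rep < 0.0125

    def test_sign_recovery_under_strong_effects(self, rng):
        hits = 0
        for i in range(50):
            div = pd.Series(rng.normal(size=30),
                            index=[f"s{i}" for i in range(30)])
            sign = 1 if i % 2 == 0 else -1
            meta = _factor_meta({"metH_relative_abundance":
                                 sign * div.to_numpy() + rng.normal(0, 0.1, 30)})
            rho, _, _ = correlate_metH(div, meta)
            hits += (rho > 0) == (sign > 0)
        assert hits == 50


def _rf_fixture(rng, n=200, signal=True):
    feats = rng.dirichlet(np.ones(20), size=n)
    ids = [f"s{i}" for i in range(n)]
    table = AbundanceTable(pd.DataFrame(feats, index=ids,
                                        columns=[f"g{j}" for j in range(20)]),
                           kind="gene", is_relative=True)
    if signal:
        chla = 5 * feats[:, 0] + 3 * feats[:, 1]
    else:
        chla = rng.normal(size=n)
    df = pd.DataFrame({"latitude": 0.0, "longitude": 0.0,
                       "layer": ["SRF", "DCM"] * (n // 2),
                       "chlorophyll_a": chla}, index=ids)
    return table, SampleMetadata(df)


class TestRandomForest:
    def test_noiseless_signal_learnable(self, rng):
        table, meta = _rf_fixture(rng, n=200, signal=True)
        res = rf_predict_chla(table, meta, mode="half_split", seed=0)
        assert res.spearman_rho > 0.95

    def test_pure_noise_centered_on_zero(self, rng):
        rhos = []
        for seed in range(20):
            table, meta = _rf_fixture(rng, n=80, signal=False)
            rhos.append(rf_predict_chla(table, meta, mode="half_split",
                                        seed=seed).spearman_rho)
        assert abs(np.mean(rhos)) < 0.15

    def test_fixed_seed_reproducible(self, rng):
        table, meta = _rf_fixture(rng, n=100)
        r1 = rf_predict_chla(table, meta, seed=3)
        r2 = rf_predict_chla(table, meta, seed=3)
        pd.testing.assert_series_equal(r1.predicted, r2.predicted)

    def test_no_label_leakage(self, rng):
        # shuffling held-out labels cannot change the predictions
        table, meta = _rf_fixture(rng, n=100)
        res = rf_predict_chla(table, meta, seed=4)
        shuffled = meta.data.copy()
        held = res.predicted.index
        rng2 = np.random.default_rng(0)
        shuffled.loc[held, "chlorophyll_a"] = rng2.permutation(
            shuffled.loc[held, "chlorophyll_a"].to_numpy())
        res2 = rf_predict_chla(table, SampleMetadata(shuffled), seed=4)
        pd.testing.assert_series_equal(res.predicted, res2.predicted)

    def test_cross_layer_mode(self, rng):
        table, meta = _rf_fixture(rng, n=120, signal=True)
        res = rf_predict_chla(table, meta, mode="cross_layer", seed=0,
                              train_layer="SRF")
        assert res.split.startswith("cross_layer(SRF->DCM)")
        assert res.spearman_rho > 0.9

    def test_small_training_partition_rejected(self, rng):
        table, meta = _rf_fixture(rng, n=12)
        with pytest.raises(ValueError):
            rf_predict_chla(table, meta, mode="half_split", seed=0)


class TestEnvDistance:
    def test_zscored_euclidean(self, rng):
        meta = _factor_meta({"temperature": rng.normal(10, 3, 8),
                             "oxygen": rng.normal(200, 20, 8)})
        d = env_distance_matrix(meta, ["temperature", "oxygen"])
        z = meta.data[["temperature", "oxygen"]]
        z = (z - z.mean()) / z.std(ddof=0)
        ref = squareform(pdist(z.to_numpy()))
        assert np.allclose(d.values, ref, atol=1e-12)
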