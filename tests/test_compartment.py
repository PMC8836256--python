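"""Serum-CSF pairing, two-population split, and correlations."""

import numpy as np
import pandas as pd
import pytest

from evmir.compartment import (CompartmentPairs, pair_compartments,
                               per_mirna_correlation, split_populations,
                               correlate_population)
from evmir.matrix import NormalizedMatrix, ValidationError


def _norm(df):
    ones = pd.Series(1.0, index=df.columns)
    return NormalizedMatrix(df, ones, ones * 1e6, 0.0)


def _pairs_from_d(d, seed=0):
    """Build CompartmentPairs whose log10 difference is exactly d."""
    rng = np.random.default_rng(seed)
    log_serum = rng.uniform(0, 4, len(d))
    serum = 10.0 ** log_serum
    csf = 10.0 ** (log_serum - np.asarray(d))
    tab = pd.DataFrame({
        "serum_mean": serum, "csf_mean": csf,
        "log10_serum": np.log10(serum), "log10_csf": np.log10(csf),
        "population": "unassigned",
    }, index=[f"m{i}" for i in range(len(d))])
    return CompartmentPairs(table=tab)


class TestPairCompartments:
    def test_identical_matrices_identity_line(self):
        df = pd.DataFrame(np.arange(1, 13).reshape(3, 4) * 10.0,
                          index=list("abc"), columns=[f"s{i}" for i in range(4)])
        pairs = pair_compartments(_norm(df), _norm(df),
                                  {f"s{i}": f"s{i}" for i in range(4)})
        assert np.allclose(pairs.table["serum_mean"], pairs.table["csf_mean"])

    def test_one_compartment_mirnas_counted_not_paired(self):
        serum = pd.DataFrame([[10.0], [20.0]], index=["a", "b"], columns=["s"])
        csf = pd.DataFrame([[10.0]], index=["a"], columns=["c"])
        pairs = pair_compartments(_norm(serum), _norm(csf), {"s": "c"})
        assert list(pairs.table.index) == ["a"]
        assert pairs.n_serum_only == 1 and pairs.n_csf_only == 0

    def test_hand_computed_means(self):
        serum = pd.DataFrame([[1.0, 3.0], [10.0, 30.0], [5.0, 5.0]],
                             index=list("xyz"), columns=["s1", "s2"])
        csf = serum * 2
        csf.columns = ["c1", "c2"]
        pairs = pair_compartments(_norm(serum), _norm(csf), {"s1": "c1", "s2": "c2"})
        assert pairs.table.loc["x", "serum_mean"] == pytest.approx(2.0)
        assert pairs.table.loc["y", "csf_mean"] == pytest.approx(40.0)

    def test_non_bijective_map_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["s1", "s2"])
        with pytest.raises(ValidationError):
            pair_compartments(_norm(df), _norm(df), {"s1": "s1", "s2": "s1"})


class TestSplitPopulations:
    def test_bimodal_recovery(self):
        rng = np.random.default_rng(1)
        d = np.concatenate([rng.normal(0, 0.2, 2038), rng.normal(2, 0.2, 128)])
        pairs = split_populations(_pairs_from_d(d))
        sizes = pairs.cluster_sizes
        assert abs(sizes["similar"] - 2038) <= 0.02 * 2166
        assert abs(sizes["high_serum"] - 128) <= 0.02 * 2166
        assert sizes["similar"] + sizes["high_serum"] == 2166

    def test_unimodal_degenerate_warns(self):
        pairs = _pairs_from_d(np.zeros(20))
        with pytest.warns(UserWarning):
            out = split_populations(pairs)
        assert (out.table["population"] == "similar").all()

    def test_two_points_threshold_between(self):
        d = np.array([0.0, 3.0] * 5)  # needs >= 10 miRNAs
        out = split_populations(_pairs_from_d(d))
        assert 0.0 < out.split_threshold < 3.0
        assert out.cluster_sizes["high_serum"] == 5

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        d = np.concatenate([rng.normal(0, 0.2, 100), rng.normal(2, 0.2, 20)])
        a = split_populations(_pairs_from_d(d, seed=3))
        b = _pairs_from_d(d, seed=3)
        b.table[["log10_serum", "log10_csf"]] += 1.7  # same constant, both compartments
        b.table["serum_mean"] *= 10 ** 1.7
        b.table["csf_mean"] *= 10 ** 1.7
        b = split_populations(b)
        assert (a.table["population"] == b.table["population"]).all()


class TestCorrelations:
    def test_identical_compartments_r_one(self):
        rng = np.random.default_rng(4)
        d = np.zeros(50)
        pairs = _pairs_from_d(d, seed=5)
        pairs.table["population"] = "similar"
        r, ci, p = correlate_population(pairs, "similar")
        assert r == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        serum = rng.uniform(1, 1000, 60)
        tab = pd.DataFrame({
            "serum_mean": serum, "csf_mean": serum ** 1.7,  # monotone
            "log10_serum": np.log10(serum), "log10_csf": 1.7 * np.log10(serum),
            "population": "similar",
        }, index=[f"m{i}" for i in range(60)])
        r, _, _ = correlate_population(CompartmentPairs(table=tab), "similar")
        assert r == pytest.approx(1.0)

    def test_independent_compartments_low_r(self):
        low = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tab = pd.DataFrame({
                "serum_mean": rng.uniform(1, 100, 500),
                "csf_mean": rng.uniform(1, 100, 500),
                "population": "similar",
            })
            tab["log10_serum"] = np.log10(tab["serum_mean"])
            tab["log10_csf"] = np.log10(tab["csf_mean"])
            r, _, _ = correlate_population(CompartmentPairs(table=tab), "similar")
            low += abs(r) < 0.2
        assert low >= 9

    def test_too_few_points_rejected(self):
        pairs = _pairs_from_d(np.zeros(12))
        pairs.table["population"] = "similar"
        pairs.table.iloc[:10, pairs.table.columns.get_loc("population")] = "high_serum"
        with pytest.raises(ValidationError):
            correlate_population(pairs, "similar")


class TestPerMirnaCorrelation:
    def test_identical_columns_r_one(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.uniform(1, 100, (3, 10)), index=list("abc"),
                          columns=[f"s{i}" for i in range(10)])
        res = per_mirna_correlation(_norm(df), _norm(df),
                                    ["a", "b"], {f"s{i}": f"s{i}" for i in range(10)})
        assert np.allclose(res["r"], 1.0)

    def test_coupled_mirna_recovered(self):
        rng = np.random.default_rng(8)
        latent = rng.uniform(10, 1000, 16)
        serum = pd.DataFrame({f"s{i}": [latent[i] * (1 + rng.normal(0, 0.05))]
                              for i in range(16)}, index=["m"])
        csf = pd.DataFrame({f"c{i}": [latent[i] * (1 + rng.normal(0, 0.05))]
                            for i in range(16)}, index=["m"])
        res = per_mirna_correlation(_norm(serum), _norm(csf), ["m"],
                                    {f"s{i}": f"c{i}" for i in range(16)})
        assert res.loc["m", "r"] > 0.8

    def test_missing_mirna_reported_not_fatal(self):
        df = pd.DataFrame(np.ones((1, 8)) * np.arange(1, 9), index=["a"],
                          columns=[f"s{i}" for i in range(8)])
        res = per_mirna_correlation(_norm(df), _norm(df), ["a", "ghost"],
                                    {f"s{i}": f"s{i}" for i in range(8)})
        assert res.loc["ghost", "method"] == "missing"
        assert np.isnan(res.loc["ghost", "r"])

    def test_uncoupled_mirna_usually_nonsignificant(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            serum = pd.DataFrame(rng.uniform(1, 100, (1, 12)), index=["m"],
                                 columns=[f"s{i}" for i in range(12)])
            csf = pd.DataFrame(rng.uniform(1, 100, (1, 12)), index=["m"],
                               columns=[f"c{i}" for i in range(12)])
            res = per_mirna_correlation(_norm(serum), _norm(csf), ["m"],
                                        {f"s{i}": f"c{i}" for i in range(12)})
            ok += res.loc["m", "p"] > 0.05
        assert ok >= 9
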