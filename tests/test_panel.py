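"""ROC/AUC, marker ranking, panel construction, group test, covariate gate."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evmir.matrix import NormalizedMatrix, ValidationError
from evmir.panel import (build_panel, correlate_panel_covariate, panel_group_test,
                         rank_markers, roc_auc, zscore_markers)


def _norm_matrix(values, sample_ids=None):
    values = pd.DataFrame(values) if not isinstance(values, pd.DataFrame) else values
    if sample_ids is not None:
        values.columns = sample_ids
    ones = pd.Series(1.0, index=values.columns)
    return NormalizedMatrix(values, ones, ones * 1e6, 0.5)


class TestZscore:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        norm = _norm_matrix(pd.DataFrame(rng.uniform(1, 100, (5, 12)),
                                         index=[f"m{i}" for i in range(5)]))
        z = zscore_markers(norm, [f"m{i}" for i in range(5)], norm.values.columns)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_two_subjects_sample_sd(self):
        norm = _norm_matrix(pd.DataFrame([[3.0, 7.0]], index=["m"]))
        z = zscore_markers(norm, ["m"], norm.values.columns)
        # sample sd convention: (x - mean)/sd with ddof=1 gives +-1/sqrt(2)
        assert np.allclose(z.to_numpy(), [[-0.7071067811865475, 0.7071067811865475]])

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 50, (1, 9))
        za = zscore_markers(_norm_matrix(pd.DataFrame(base, index=["m"])), ["m"],
                            range(9))
        zb = zscore_markers(_norm_matrix(pd.DataFrame(3.5 * base + 11, index=["m"])),
                            ["m"], range(9))
        assert np.allclose(za, zb)

    def test_zero_sd_named_error(self):
        norm = _norm_matrix(pd.DataFrame([[5.0, 5.0, 5.0]], index=["flatliner"]))
        with pytest.raises(ValidationError, match="flatliner"):
            zscore_markers(norm, ["flatliner"], norm.values.columns)


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == pytest.approx(1.0)

    def test_hand_counted_concordant_pairs(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == pytest.approx(1.0)
        assert roc_auc([1, 3, 2, 4], [0, 0, 1, 1]).auc == pytest.approx(0.75)

    def test_exhaustive_2v2_mean_half(self):
        """Over all placements of 2 positives among 4 distinct scores, the
        average AUC is exactly 1/2 (label-score independence)."""
        scores = np.array([0.3, 1.2, 2.7, 3.1])
        aucs = []
        for pos in itertools.combinations(range(4), 2):
            labels = np.zeros(4, dtype=int)
            labels[list(pos)] = 1
            aucs.append(roc_auc(scores, labels).auc)
        assert np.mean(aucs) == pytest.approx(0.5)

    def test_trapezoidal_oracle_equivalence(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(6, 30))
            scores = rng.choice([0.1, 0.5, 1.0, 2.0, 3.0, 4.0], size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            ours = roc_auc(scores, labels).auc
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = roc_auc(scores, labels)
        b = roc_auc(scores, 1 - labels)
        assert a.auc == pytest.approx(1.0 - b.auc)
        assert a.p == pytest.approx(b.p)

    def test_p_matches_mannwhitney(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=30)
        labels = np.array([0] * 15 + [1] * 15)
        scores[labels == 1] += 1.0
        ours = roc_auc(scores, labels)
        ref = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                                 alternative="two-sided", method="asymptotic")
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_one_class_empty(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestRankMarkers:
    def test_sorted_by_auc(self):
        z = pd.DataFrame({
            "a": [-1.2, -0.8, -1.0, 0.8, 1.0, 1.2],   # perfect
            "b": [-1.2, 0.8, -1.0, -0.8, 1.0, 1.2],   # good
            "c": [0.8, -0.8, -1.0, -1.2, 1.0, 1.2],   # weaker
        }).T
        z.columns = [f"s{i}" for i in range(6)]
        labels = [0, 0, 0, 1, 1, 1]
        ranked, rocs = rank_markers(z, labels)
        assert ranked[0] == "a"
        assert rocs["a"].auc >= rocs["b"].auc >= rocs["c"].auc

    def test_orientation_flip(self):
        z = pd.DataFrame({"inv": [1.0, 0.8, 1.2, -0.8, -1.0, -1.2]}).T
        z.columns = [f"s{i}" for i in range(6)]
        ranked, rocs = rank_markers(z, [0, 0, 0, 1, 1, 1])
        assert rocs["inv"].auc == pytest.approx(1.0)
        assert rocs["inv"].orientation == -1

    def test_tie_broken_by_smaller_p(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 1, 8), rng.normal(2, 1, 8)])
        z = pd.DataFrame({"big_n": x, "small_n": x}).T
        z.columns = [f"s{i}" for i in range(16)]
        ranked, rocs = rank_markers(z, [0] * 8 + [1] * 8)
        # identical markers: tie falls through to lexicographic ID
        assert ranked == ["big_n", "small_n"]


class TestBuildPanel:
    def test_single_marker(self):
        z = pd.DataFrame({"only": [-1.0, -0.5, 0.5, 1.0]}).T
        z.columns = list("abcd")
        res = build_panel(z, [0, 0, 1, 1])
        assert res.selected_panel == ["only"]
        assert len(res.trajectory) >= 1

    def test_noise_marker_not_included(self):
        rng = np.random.default_rng(7)
        signal = np.concatenate([rng.normal(-1, 0.1, 10), rng.normal(1, 0.1, 10)])
        z = pd.DataFrame({
            "good1": signal, "good2": signal + rng.normal(0, 0.05, 20),
            "noise": rng.normal(0, 1, 20),
        }).T
        z.columns = [f"s{i}" for i in range(20)]
        labels = [0] * 10 + [1] * 10
        res = build_panel(z, labels)
        assert "noise" not in res.selected_panel

    def test_selected_auc_geq_best_single(self):
        rng = np.random.default_rng(8)
        z = pd.DataFrame(rng.normal(size=(6, 24)),
                         index=[f"m{i}" for i in range(6)],
                         columns=[f"s{i}" for i in range(24)])
        z.iloc[:3, 12:] += 1.5
        labels = [0] * 12 + [1] * 12
        ranked, rocs = rank_markers(z, labels)
        res = build_panel(z, labels, ranked, rocs)
        k = len(res.selected_panel)
        assert res.trajectory[k - 1][1] >= max(r.auc for r in rocs.values()) - 1e-12

    def test_selected_is_prefix_of_ranking(self):
        rng = np.random.default_rng(9)
        z = pd.DataFrame(rng.normal(size=(5, 20)),
                         index=[f"m{i}" for i in range(5)],
                         columns=[f"s{i}" for i in range(20)])
        labels = [0] * 10 + [1] * 10
        res = build_panel(z, labels)
        assert res.ranked_markers[: len(res.selected_panel)] == res.selected_panel


class TestPanelGroupTest:
    def test_identical_groups_t_zero(self):
        t, df, p = panel_group_test([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                                    [0, 0, 0, 1, 1, 1])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        a = np.array([1.1, 2.3, 0.7, 1.9])
        b = np.array([3.2, 4.1, 2.8])
        t, df, p = panel_group_test(np.concatenate([a, b]),
                                    [1, 1, 1, 1, 0, 0, 0])
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / 5
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 3))
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert df == 5
        ref = stats.ttest_ind(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_separated_groups_significant(self):
        t, df, p = panel_group_test([0.0, 0.01, 1.0, 1.01], [0, 0, 1, 1])
        assert p < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            panel_group_test([1.0, 1.0, 1.0, 1.0], [0, 0, 1, 1])


class TestCovariateCorrelation:
    def test_linear_gaussian_selects_pearson(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=40)
        method, r, ci, p = correlate_panel_covariate(x, 2 * x + 1)
        assert method == "pearson"
        assert r == pytest.approx(1.0)

    def test_skewed_data_selects_spearman(self):
        rng = np.random.default_rng(11)
        x = rng.lognormal(0, 2.0, 60)  # fails the K^2 normality test
        y = x ** 2
        method, r, ci, p = correlate_panel_covariate(x, y)
        assert method == "spearman"
        assert r == pytest.approx(1.0)

    def test_null_covariate_usually_nonsignificant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            method, r, ci, p = correlate_panel_covariate(
                rng.normal(size=25), rng.normal(size=25))
            hits += p > 0.05
        assert hits >= 18

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            correlate_panel_covariate([1, 2, 3], [1, 2, 3])
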