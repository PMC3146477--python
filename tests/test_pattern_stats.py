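import numpy as np
import pandas as pd
import pytest

from ghufinder.pattern_stats import (
    PairwiseComparison,
    classify_residues,
    expression_profile,
    mann_whitney,
    randomize_dataset,
    randomization_test,
    run_sdal,
    sdal_anova,
    tf_score,
    tukey_kramer,
)
from .conftest import make_matrix


class TestTFScore:
    def test_all_bound_scores_one(self):
        tr = make_matrix(np.ones((3, 2)), tag="TR", features=["TF1", "TF2"])
        table = tf_score(tr, tr.gene_ids)
        assert (table.scores == 1.0).all()
        assert table.significant == ["TF1", "TF2"]

    def test_boundary_is_strict(self):
        tr = make_matrix([[0.9], [0.9], [0.6]], tag="TR", features=["TF1"])
        table = tf_score(tr, tr.gene_ids)
        assert table.scores["TF1"] == pytest.approx(0.8)
        assert table.significant == []

    def test_gene_order_invariance_and_bounds(self):
        rng = np.random.default_rng(0)
        tr = make_matrix(rng.uniform(size=(6, 3)), tag="TR")
        genes = tr.gene_ids
        a = tf_score(tr, genes).scores
        b = tf_score(tr, genes[::-1]).scores
        pd.testing.assert_series_equal(a, b)
        assert (a >= tr.data.min()).all() and (a <= tr.data.max()).all()

    def test_empty_element_is_error(self):
        tr = make_matrix(np.ones((2, 1)), tag="TR")
        with pytest.raises(ValueError):
            tf_score(tr, [])


class TestSDALAnova:
    def test_hand_computed_two_group_anova(self):
        # residue A observations (1, 2); residue B observations (5, 6)
        ahplus = make_matrix(
            [[1.0, 5.0], [2.0, 6.0]], features=["H3K9", "H4K16"], tag="AHplus"
        )
        res = sdal_anova(ahplus, ahplus.gene_ids, alpha=0.05)
        assert res.f_statistic == pytest.approx(32.0)
        assert res.anova_p == pytest.approx(0.0299, abs=2e-4)
        assert res.anova_passed  # 0.0299 < 0.05

    def test_null_noise_rarely_passes(self):
        rng = np.random.default_rng(1)
        passes = 0
        for _ in range(40):
            ahplus = make_matrix(rng.normal(0, 1, (50, 11)), tag="AHplus",
                                 features=[f"H3K{i}" for i in range(11)])
            passes += sdal_anova(ahplus, ahplus.gene_ids, alpha=0.01).anova_passed
        assert passes <= 4

    def test_constant_table_is_non_pass(self):
        ahplus = make_matrix(np.zeros((3, 2)), features=["H3K9", "H4K16"], tag="AHplus")
        res = sdal_anova(ahplus, ahplus.gene_ids)
        assert not res.anova_passed


class TestTukeyKramer:
    def test_identical_residues_nothing_significant(self):
        rng = np.random.default_rng(2)
        col = rng.normal(size=20)
        ahplus = make_matrix(
            np.tile(col[:, None], (1, 4)), features=["H3K9", "H3K14", "H4K8", "H4K16"],
            tag="AHplus",
        )
        pairs = tukey_kramer(ahplus, ahplus.gene_ids)
        assert not any(p.significant for p in pairs)

    def test_covers_all_unordered_pairs(self):
        rng = np.random.default_rng(3)
        residues = [f"H3K{i}" for i in range(11)]
        ahplus = make_matrix(rng.normal(size=(5, 11)), features=residues, tag="AHplus")
        pairs = tukey_kramer(ahplus, ahplus.gene_ids)
        assert len(pairs) == 55
        seen = {frozenset((p.residue_a, p.residue_b)) for p in pairs}
        assert len(seen) == 55

    def test_matches_statsmodels_tukey_hsd(self):
        """Balanced groups: our pairwise p-values equal an independent
        Tukey HSD implementation."""
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(4)
        values = rng.normal(size=(12, 4))
        values[:, 2] += 1.5
        residues = ["H3K9", "H3K14", "H4K8", "H4K16"]
        ahplus = make_matrix(values, features=residues, tag="AHplus")
        pairs = tukey_kramer(ahplus, ahplus.gene_ids)

        flat = values.T.ravel()
        groups = np.repeat(residues, 12)
        sm_res = statsmodels.pairwise_tukeyhsd(flat, groups, alpha=0.05)
        sm_p = {
            frozenset((a, b)): p
            for (a, b), p in zip(
                [(r[0], r[1]) for r in sm_res.summary().data[1:]], sm_res.pvalues
            )
        }
        for pair in pairs:
            key = frozenset((pair.residue_a, pair.residue_b))
            assert pair.p_value == pytest.approx(sm_p[key], abs=1e-4)


class TestClassifyResidues:
    def _pair(self, a, b, diff, sig=True):
        return PairwiseComparison(a, b, diff, 0.01 if sig else 0.5, sig)

    def test_no_significant_pairs_all_yellow(self):
        classes = classify_residues([self._pair("a", "b", 1.0, sig=False)], ["a", "b", "c"])
        assert set(classes.values()) == {"yellow"}

    def test_dominant_residue_red_dominated_blue(self):
        pairs = [self._pair("a", "b", 2.0), self._pair("a", "c", 2.0)]
        classes = classify_residues(pairs, ["a", "b", "c", "d"])
        assert classes == {"a": "red", "b": "blue", "c": "blue", "d": "yellow"}

    def test_mixed_direction_residue_is_yellow(self):
        # b sits above c but below a: neither red nor blue; c is dominated
        # only by the non-red b, so it stays yellow as well
        pairs = [self._pair("a", "b", 1.0), self._pair("b", "c", 1.0)]
        classes = classify_residues(pairs, ["a", "b", "c"])
        assert classes == {"a": "red", "b": "yellow", "c": "yellow"}

    def test_blue_requires_a_red_dominator(self):
        # a above b, but a also below c ⇒ a not red ⇒ b not blue
        pairs = [self._pair("a", "b", 1.0), self._pair("c", "a", 1.0)]
        classes = classify_residues(pairs, ["a", "b", "c"])
        assert classes == {"a": "yellow", "b": "yellow", "c": "red"}


class TestRunSDAL:
    def test_shifted_residue_detected_and_colored(self):
        rng = np.random.default_rng(5)
        residues = [f"H3K{i + 1}" for i in range(5)]
        values = rng.normal(5, 1, size=(30, 5))
        values[:, 0] += 8.0
        ahplus = make_matrix(values, features=residues, tag="AHplus")
        res = run_sdal(ahplus, ahplus.gene_ids)
        assert res.anova_passed
        assert res.residue_classes["H3K1"] == "red"
        assert all(res.residue_classes[r] == "blue" for r in residues[1:])


class TestExpressionProfile:
    def test_single_gene_profile_is_its_row(self):
        expr = make_matrix([[1.0, 3.0], [5.0, 7.0]], tag="EXPR")
        prof = expression_profile(expr, ["G1"])
        np.testing.assert_allclose(prof.means.to_numpy(), [1.0, 3.0])

    def test_mean_of_two_genes(self):
        expr = make_matrix([[1.0, 3.0], [3.0, 1.0]], tag="EXPR")
        prof = expression_profile(expr, expr.gene_ids)
        np.testing.assert_allclose(prof.means.to_numpy(), [2.0, 2.0])
        assert prof.traces.shape == (2, 2)


class TestRandomizeDataset:
    def test_single_cell_unchanged(self):
        gm = make_matrix([[3.0]], tag="TR")
        out = randomize_dataset(gm, seed=0)
        assert out.data.iloc[0, 0] == 3.0

    def test_row_and_column_multisets_preserved(self):
        rng = np.random.default_rng(6)
        gm = make_matrix(rng.normal(size=(7, 5)), tag="TR")
        out = randomize_dataset(gm, seed=1)
        assert out.gene_ids == gm.gene_ids
        assert out.feature_ids == gm.feature_ids
        orig_rows = {frozenset(np.round(r, 9)) for r in gm.values}
        new_rows = {frozenset(np.round(r, 9)) for r in out.values}
        assert orig_rows == new_rows
        orig_cols = {frozenset(np.round(c, 9)) for c in gm.values.T}
        new_cols = {frozenset(np.round(c, 9)) for c in out.values.T}
        assert orig_cols == new_cols

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(7)
        gm = make_matrix(rng.normal(size=(6, 4)), tag="TR")
        a = randomize_dataset(gm, seed=42)
        b = randomize_dataset(gm, seed=42)
        np.testing.assert_array_equal(a.values, b.values)


class TestMannWhitney:
    def test_identical_samples_near_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_fully_separated_small_samples_exact(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_large_samples_use_asymptotic_with_ties(self):
        rng = np.random.default_rng(8)
        x = np.round(rng.uniform(size=50), 1)
        y = np.round(rng.uniform(size=60) + 0.3, 1)
        _, p = mann_whitney(x, y)
        assert 0 < p < 0.01


class TestRandomizationTest:
    def test_identical_run_fn_not_rejected(self):
        def run_fn(tables):
            return np.array([0.1, 0.5, 0.9])

        gm = make_matrix(np.random.default_rng(9).normal(size=(5, 3)), tag="TR")
        res = randomization_test(run_fn, {"TR": gm}, n_rand=5, seed=0)
        assert res.p_value > 0.5
        assert not res.reject

    def test_empty_observed_is_inconclusive(self):
        def run_fn(tables):
            return np.array([])

        gm = make_matrix(np.random.default_rng(10).normal(size=(4, 3)), tag="TR")
        res = randomization_test(run_fn, {"TR": gm}, n_rand=3, seed=0)
        assert res.p_value == 1.0
        assert not res.reject

    def test_replicate_count_respected(self):
        calls = []

        def run_fn(tables):
            calls.append(1)
            return np.array([0.5])

        gm = make_matrix(np.random.default_rng(11).normal(size=(4, 3)), tag="TR")
        res = randomization_test(run_fn, {"TR": gm}, n_rand=4, seed=0)
        assert len(res.randomized_pvalues) == 4
        assert len(calls) == 5  # observed + 4 replicates
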