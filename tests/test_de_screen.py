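import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from impulscreen import de_screen as de
from impulscreen.errors import ConfigurationError
from impulscreen.io_formats import ExpressionDataset


def make_ds(matrix, genes=None, cells=None):
    matrix = np.asarray(matrix, dtype=float)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    cells = cells or [f"c{i}" for i in range(matrix.shape[1])]
    return ExpressionDataset(
        sp.csr_matrix(matrix), np.array(genes, dtype=object), np.array(cells, dtype=object)
    )


# ---------------------------------------------------------------------------
# brute-force rank-sum oracle (independent of the implementation under test)
# ---------------------------------------------------------------------------


def rank_sum_p_exact(x, y):
    """Two-sided exact Wilcoxon rank-sum p by enumerating every assignment of
    the pooled values to the two groups (distinct values only)."""
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1.0
    n_x = len(x)
    obs = ranks[:n_x].sum()
    sums = [
        sum(combo)
        for combo in itertools.combinations(ranks, n_x)
    ]
    sums = np.asarray(sums)
    p_le = np.mean(sums <= obs)
    p_ge = np.mean(sums >= obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_constant_gene_gives_p_one(self):
        ds = make_ds([[5.0] * 6])
        comp = de.ComparisonDefinition("c", "cluster", 1, ("c0", "c1", "c2"), ("c3", "c4", "c5"))
        assert de.wilcoxon_de(ds, comp)[0] == 1.0

    def test_complete_separation_3v3_exact(self):
        """3-vs-3 complete separation: 2 of the 20 rank assignments are as
        extreme, so the two-sided exact p is 0.1."""
        ds = make_ds([[10.0, 11.0, 12.0, 0.0, 1.0, 2.0]])
        comp = de.ComparisonDefinition("c", "cluster", 1, ("c0", "c1", "c2"), ("c3", "c4", "c5"))
        assert de.wilcoxon_de(ds, comp)[0] == pytest.approx(0.1, abs=1e-12)

    def test_exact_matches_enumeration_oracle(self):
        """On every 2..6-vs-2..6 distinct-value instance tried, the exact
        path equals full enumeration to 12 decimal places."""
        rng = np.random.default_rng(42)
        for n_t in range(2, 7):
            for n_c in range(2, 7):
                vals = rng.uniform(0.1, 50.0, size=n_t + n_c)
                ds = make_ds(vals[None, :])
                comp = de.ComparisonDefinition(
                    "c", "cluster", 1,
                    tuple(f"c{i}" for i in range(n_t)),
                    tuple(f"c{i}" for i in range(n_t, n_t + n_c)),
                )
                expected = rank_sum_p_exact(vals[:n_t], vals[n_t:])
                assert de.wilcoxon_de(ds, comp)[0] == pytest.approx(expected, abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        """Asymptotic p agrees with the enumeration oracle within 0.02 on
        50 random 5-vs-5 genes."""
        rng = np.random.default_rng(7)
        mat = rng.uniform(0.1, 50.0, size=(50, 10))
        ds = make_ds(mat)
        comp = de.ComparisonDefinition(
            "c", "cluster", 1,
            tuple(f"c{i}" for i in range(5)), tuple(f"c{i}" for i in range(5, 10)),
        )
        approx = de.wilcoxon_de(ds, comp, force_asymptotic=True)
        for g in range(50):
            exact = rank_sum_p_exact(mat[g, :5], mat[g, 5:])
            assert abs(approx[g] - exact) < 0.02

    def test_small_set_raises(self):
        ds = make_ds([[1.0, 2.0, 3.0]])
        comp = de.ComparisonDefinition("c", "cluster", 1, ("c0",), ("c1", "c2"))
        with pytest.raises(ValueError, match="at least 2"):
            de.wilcoxon_de(ds, comp)


class TestMeasures:
    def test_mean_expression_examples(self, toy_dataset):
        ge, expr = de.set_mean_expression(toy_dataset, ["c1", "c4"])
        # gene2 has CPM {0,0}: mean 0, log2(1+0) = 0
        assert ge[2] == 0.0 and expr[2] == 0.0
        # gene1 has CPM {10,10}
        assert ge[1] == 10.0 and expr[1] == pytest.approx(math.log2(11))

    def test_mean_expression_arithmetic(self):
        ds = make_ds([[3.0, 5.0]])
        ge, expr = de.set_mean_expression(ds, ["c0", "c1"])
        assert ge[0] == 4.0
        assert expr[0] == pytest.approx(math.log2(5), abs=1e-9)

    def test_single_cell_set_is_identity(self, toy_dataset):
        ge, _ = de.set_mean_expression(toy_dataset, ["c0"])
        np.testing.assert_allclose(ge, [50.0, 10.0, 0.0, 0.5])

    def test_empty_set_raises(self, toy_dataset):
        with pytest.raises(ValueError, match="empty"):
            de.set_mean_expression(toy_dataset, [])

    def test_diff_mean_pseudocount(self):
        # GE_T = 3, GE_C = 0 -> log2(4/1) = 2
        assert de.diff_mean(math.log2(4), math.log2(1)) == pytest.approx(2.0)
        # threefold change in the well-expressed limit approaches log2(3) = 1.58
        assert de.diff_mean(math.log2(1 + 3000), math.log2(1 + 1000)) == pytest.approx(
            math.log2(3), abs=0.01
        )
        assert de.diff_mean(1.7, 1.7) == 0.0

    def test_detection_fraction(self):
        ds = make_ds([[0.0, 1.0, 2.0, 0.5], [0.0, 0.0, 0.0, 0.0]])
        cells = ["c0", "c1", "c2", "c3"]
        frac = de.detection_fraction(ds, cells, threshold=1.0)
        assert frac[0] == 0.5  # counts the two cells at CPM >= 1
        assert frac[1] == 0.0
        assert (de.detection_fraction(ds, cells, threshold=0.0) == 1.0).all()

    def test_beta_statistic_sign_convention(self):
        assert de.beta_statistic(0.8, 0.1, 1.0) == pytest.approx(0.7)
        assert de.beta_statistic(0.1, 0.8, -1.0) == pytest.approx(-0.7)
        assert de.beta_statistic(0.9, 0.1, 0.0) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(
        pct_t=st.floats(0, 1), pct_c=st.floats(0, 1),
        dm=st.floats(-10, 10, allow_nan=False),
    )
    def test_beta_bounded_and_sign_matches_diff(self, pct_t, pct_c, dm):
        beta = de.beta_statistic(pct_t, pct_c, dm)
        assert -1.0 <= beta <= 1.0
        if beta != 0 and dm != 0:
            assert np.sign(beta) == np.sign(dm)

    def test_bonferroni(self):
        assert de.bonferroni(0.001, 10) == pytest.approx(0.01)
        assert de.bonferroni(0.5, 10) == 1.0
        assert de.bonferroni(0.2, 1) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            de.bonferroni(0.1, 0)


class TestBuildComparison:
    def test_reporter_mode_level_counts(self, toy_annotation):
        comp = de.build_comparison(toy_annotation, "reporter", 1)
        assert len(comp.set_T) == 4 and len(comp.set_C) == 3

    def test_level2_adds_nonneuronal_and_l6(self, toy_annotation):
        extra = pd.DataFrame(
            [("l6a", "glutamatergic", "L6 IT", False, "ACA"),
             ("l6b", "glutamatergic", "L6 CT", False, "ACA")],
            columns=["cell_id", "cell_class", "cluster", "reporter_positive", "region"],
        ).set_index("cell_id")
        ann = pd.concat([toy_annotation, extra])
        comp = de.build_comparison(ann, "reporter", 2)
        assert len(comp.set_C) == 7  # 3 GABA + 2 non-neuronal + 2 L6

    def test_level3_adds_l23_and_keeps_disjoint(self, toy_annotation):
        extra = pd.DataFrame(
            [("l23a", "glutamatergic", "L2/3 IT", True, "ACA")],
            columns=["cell_id", "cell_class", "cluster", "reporter_positive", "region"],
        ).set_index("cell_id")
        ann = pd.concat([toy_annotation, extra])
        comp = de.build_comparison(ann, "reporter", 3)
        # the reporter-positive L2/3 cell is dual-eligible and goes to Set-T
        assert "l23a" in comp.set_T and "l23a" not in comp.set_C
        assert not set(comp.set_T) & set(comp.set_C)

    def test_cluster_mode_without_l45_cluster_errors(self, toy_annotation):
        ann = toy_annotation.copy()
        ann["cluster"] = ann["cluster"].replace("L4/5 IT", "L5 NP")
        with pytest.raises(ConfigurationError, match="L4/5-IT"):
            de.build_comparison(ann, "cluster", 1)

    def test_custom_layer_patterns_for_other_taxonomies(self, toy_annotation):
        ann = toy_annotation.copy()
        ann["cluster"] = ann["cluster"].replace("L4/5 IT", "Exc L5-6 FEZF2")
        comp = de.build_comparison(
            ann, "cluster", 1, layer_patterns={"L4/5-IT": r"Exc L5"}
        )
        assert len(comp.set_T) == 4


class TestScreenAndRanking:
    def _planted_ds(self, n=100, seed=0):
        """Planted gene ~50-fold up and well-detected; flat housekeeping; a
        2.5-fold gene below the fold criterion."""
        rng = np.random.default_rng(seed)
        t = np.arange(n)
        mat = np.zeros((3, 2 * n))
        mat[0, :n] = rng.lognormal(np.log(50), 0.3, n) * (rng.random(n) < 0.9)
        mat[0, n:] = rng.lognormal(np.log(20), 0.3, n) * (rng.random(n) < 0.05)
        mat[1] = rng.lognormal(np.log(10), 0.2, 2 * n)
        mat[2, :n] = rng.lognormal(np.log(25), 0.1, n)
        mat[2, n:] = rng.lognormal(np.log(10), 0.1, n)
        ds = make_ds(mat, genes=["planted", "flat", "weak"])
        comp = de.ComparisonDefinition(
            "c", "cluster", 1,
            tuple(f"c{i}" for i in range(n)), tuple(f"c{i}" for i in range(n, 2 * n)),
        )
        return ds, comp

    def test_planted_gene_passes_with_tenfold(self):
        ds, comp = self._planted_ds()
        rec = de.screen_comparison(ds, comp).set_index("gene")
        assert bool(rec.loc["planted", "passes_primary"])
        assert bool(rec.loc["planted", "tenfold_flag"])
        assert rec.loc["planted", "beta"] > 0.5

    def test_housekeeping_gene_fails(self):
        ds, comp = self._planted_ds()
        rec = de.screen_comparison(ds, comp).set_index("gene")
        assert not rec.loc["flat", "passes_primary"]

    def test_fold_criterion_boundary(self):
        """~2.5-fold gene is significant but fails the threefold criterion."""
        ds, comp = self._planted_ds()
        rec = de.screen_comparison(ds, comp).set_index("gene")
        assert rec.loc["weak", "p_bonf"] < 0.05
        assert not rec.loc["weak", "passes_primary"]

    def test_record_invariants(self):
        ds, comp = self._planted_ds()
        rec = de.screen_comparison(ds, comp)
        assert (rec["p_bonf"] >= rec["p_raw"] - 1e-15).all()
        assert (rec["p_bonf"] <= 1.0).all()
        assert rec["beta"].between(-1, 1).all()
        nz = (rec["beta"] != 0) & (rec["diff_mean"] != 0)
        assert (np.sign(rec["beta"][nz]) == np.sign(rec["diff_mean"][nz])).all()

    def test_identical_sets_give_zero_diff_and_beta(self):
        mat = np.tile(np.array([[3.0, 7.0, 0.0]]), (2, 2)).reshape(2, -1)
        ds = make_ds(np.column_stack([mat[:, :3], mat[:, :3]]))
        comp = de.ComparisonDefinition(
            "c", "cluster", 1, ("c0", "c1", "c2"), ("c3", "c4", "c5")
        )
        rec = de.screen_comparison(ds, comp)
        np.testing.assert_allclose(rec["diff_mean"], 0, atol=1e-12)
        np.testing.assert_allclose(rec["beta"], 0, atol=1e-12)

    def test_scale_invariance_of_pvalue(self):
        """Rank tests are invariant under multiplying all CPM by a constant."""
        ds, comp = self._planted_ds()
        scaled = make_ds(ds.matrix.toarray() * 7.3, genes=list(ds.gene_ids))
        np.testing.assert_allclose(
            de.wilcoxon_de(ds, comp), de.wilcoxon_de(scaled, comp), atol=1e-12
        )

    def _annot(self):
        return pd.DataFrame(
            {
                "is_gpcr": [True, True, True, False],
                "coupling": ["Gi", "Gq", "Gi", "unknown"],
                "is_sensory": [False, False, True, False],
            },
            index=pd.Index(["planted", "gq_gene", "sens", "flat"], name="gene"),
        )

    def _records(self, passers):
        rows = []
        for comp in ("a", "b"):
            for gene in ("planted", "gq_gene", "sens", "flat"):
                rows.append(
                    dict(comparison=comp, gene=gene, diff_mean=3.0, beta=0.7,
                         expr_C=0.5, tenfold_flag=True,
                         passes_primary=gene in passers)
                )
        return pd.DataFrame(rows)

    def test_single_gi_passer_ranked_first(self):
        table = de.rank_candidates(self._records({"planted"}), self._annot(), "Gi")
        assert len(table) == 1
        assert table.loc[0, "gene"] == "planted" and table.loc[0, "rank"] == 1

    def test_gq_passer_excluded_by_coupling_filter(self):
        table = de.rank_candidates(
            self._records({"planted", "gq_gene"}), self._annot(), "Gi"
        )
        assert "gq_gene" not in set(table["gene"])
        any_table = de.rank_candidates(
            self._records({"planted", "gq_gene"}), self._annot(), "any"
        )
        assert "gq_gene" in set(any_table["gene"])

    def test_sensory_exclusion_flag(self):
        table = de.rank_candidates(
            self._records({"planted", "sens"}), self._annot(), "Gi",
            exclude_sensory=True,
        )
        assert set(table["gene"]) == {"planted"}

    def test_no_passers_gives_empty_table(self):
        table = de.rank_candidates(self._records(set()), self._annot(), "Gi")
        assert len(table) == 0

    def test_unknown_required_comparison_raises(self):
        with pytest.raises(ValueError, match="not present"):
            de.rank_candidates(
                self._records({"planted"}), self._annot(), "Gi",
                require_all=["a", "zzz"],
            )
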