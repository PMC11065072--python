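import logging
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from comorbid_repurpose.core import MendelianDisease
from comorbid_repurpose.similarity import (
    ExpressionMatrix,
    coexpression_test,
    gene_overlap_test,
    similarity_call,
    similarity_table,
)
from comorbid_repurpose.stat_tests import bh_adjust
from comorbid_repurpose.synthetic import SyntheticConfig, generate_expression


def hypergeom_tail_oracle(k, K1, K2, N):
    """Direct summation: P(overlap >= k) for sets of sizes K1, K2 in N."""
    total = comb(N, K2)
    return sum(comb(K1, j) * comb(N - K1, K2 - j) for j in range(k, min(K1, K2) + 1)) / total


class TestGeneOverlap:
    def test_matches_direct_summation(self):
        universe = {f"g{i}" for i in range(20)}
        mend = {"g1", "g2", "g3"}
        cancer = {"g1", "g2", "g4", "g5"}
        p = gene_overlap_test(mend, cancer, universe)
        assert p == pytest.approx(hypergeom_tail_oracle(2, 3, 4, 20), rel=1e-12)

    def test_zero_overlap_gives_one(self):
        universe = {f"g{i}" for i in range(10)}
        assert gene_overlap_test({"g1"}, {"g2"}, universe) == pytest.approx(1.0)

    def test_mendelian_equals_universe_gives_one(self):
        universe = {f"g{i}" for i in range(10)}
        assert gene_overlap_test(universe, {"g1", "g2"}, universe) == pytest.approx(1.0)

    def test_symmetric_in_the_two_sets(self):
        universe = {f"g{i}" for i in range(30)}
        a = {"g1", "g2", "g3", "g4"}
        b = {"g2", "g4", "g9"}
        assert gene_overlap_test(a, b, universe) == pytest.approx(
            gene_overlap_test(b, a, universe), rel=1e-12
        )

    def test_genes_outside_universe_listed(self):
        with pytest.raises(ValueError, match="gX"):
            gene_overlap_test({"g1", "gX"}, {"g1"}, {"g1", "g2"})

    @pytest.mark.parametrize("seed", range(4))
    def test_random_fixtures_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(15)]
        a = set(rng.choice(genes, size=4, replace=False))
        b = set(rng.choice(genes, size=6, replace=False))
        k = len(a & b)
        assert gene_overlap_test(a, b, set(genes)) == pytest.approx(
            hypergeom_tail_oracle(k, 4, 6, 15), rel=1e-12
        )


def make_expr(data: dict[str, list[float]]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(data).T.astype(float))


class TestCoexpression:
    def test_exact_minimum_p_for_top_correlations(self):
        """Two Mendelian genes holding the two largest correlations among
        12 pooled comparison genes -> exact one-sided p = 1 / C(12, 2)."""
        rng = np.random.default_rng(0)
        t = 8
        anchor = np.linspace(1, 5, t)
        data = {"CG": anchor}
        # mendelian genes: monotone transforms of the anchor (Spearman rho = 1)
        data["m1"] = anchor**1.5
        data["m2"] = anchor * 2 + 0.1
        for i in range(10):  # background: random profiles
            data[f"b{i}"] = rng.permutation(anchor) + rng.random(t)
        expr = make_expr(data)
        p = coexpression_test("CG", {"m1", "m2"}, expr)
        assert p == pytest.approx(1 / comb(12, 2))

    def test_anchor_excluded_and_background_required(self):
        data = {"CG": [1.0, 2.0, 3.0, 4.0], "m1": [1.0, 2.0, 3.0, 5.0]}
        expr = make_expr(data)
        with pytest.raises(ValueError, match="background"):
            coexpression_test("CG", {"m1"}, expr)

    def test_no_expressed_mendelian_gene_rejected(self):
        data = {
            "CG": [1.0, 2.0, 3.0],
            "b1": [3.0, 1.0, 2.0],
            "b2": [2.0, 3.0, 1.0],
        }
        expr = make_expr(data)
        with pytest.raises(ValueError, match="no Mendelian gene"):
            coexpression_test("CG", {"absent"}, expr)

    def test_constant_gene_dropped_from_background(self, caplog):
        rng = np.random.default_rng(3)
        data = {f"g{i}": rng.random(6).tolist() for i in range(8)}
        data["flat"] = [2.0] * 6
        expr = make_expr(data)
        with caplog.at_level(logging.INFO):
            coexpression_test("g0", {"g1"}, expr)
        assert "constant-expression" in caplog.text

    def test_constant_anchor_rejected(self):
        data = {"CG": [1.0, 1.0, 1.0, 1.0], "m1": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 1.0, 4.0, 3.0]}
        with pytest.raises(ValueError, match="constant"):
            coexpression_test("CG", {"m1"}, make_expr(data))

    def test_invariant_to_monotone_per_gene_transforms(self):
        rng = np.random.default_rng(11)
        data = {f"g{i}": rng.random(9).tolist() for i in range(14)}
        expr = make_expr(data)
        p_before = coexpression_test("g0", {"g1", "g2", "g3"}, expr)
        transformed = {
            g: (np.asarray(v) ** (1 + (i % 3))).tolist()
            for i, (g, v) in enumerate(data.items())
        }
        p_after = coexpression_test("g0", {"g1", "g2", "g3"}, make_expr(transformed))
        assert p_before == pytest.approx(p_after, rel=1e-12)

    def test_calibration_under_null(self):
        """Random Mendelian sets from the background -> roughly uniform p."""
        rng = np.random.default_rng(2)
        ps = []
        for rep in range(100):
            data = {f"g{i}": rng.random(10).tolist() for i in range(25)}
            expr = make_expr(data)
            mend = set(rng.choice([f"g{i}" for i in range(1, 25)], size=4, replace=False))
            ps.append(coexpression_test("g0", mend, expr))
        ps = np.asarray(ps)
        assert 0.35 < ps.mean() < 0.65
        assert (ps < 0.05).mean() < 0.13


class TestExpressionMatrix:
    def test_incomplete_genes_dropped_at_load(self, caplog):
        long = pd.DataFrame(
            {
                "gene": ["a", "a", "a", "b", "b", "c", "c", "c"],
                "tissue": ["t1", "t2", "t3", "t1", "t2", "t1", "t2", "t3"],
                "value": [1.0, 2, 3, 4, 5, 6, 7, 8],
            }
        )
        with caplog.at_level(logging.INFO):
            expr = ExpressionMatrix.from_long(long)
        assert set(expr.genes) == {"a", "c"}
        assert "dropped 1 genes" in caplog.text

    def test_fewer_than_three_tissues_rejected(self):
        with pytest.raises(ValueError, match="3 tissues"):
            make_expr({"a": [1.0, 2.0], "b": [2.0, 1.0]})

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_expr({"a": [1.0, -2.0, 3.0], "b": [1.0, 2.0, 3.0]})

    def test_round_trip_long_tsv(self, tmp_path):
        world = generate_expression(
            SyntheticConfig(n_genes=20, n_cancers=1, n_tissues=5, seed=0)
        )
        long = (
            world.expr.values.stack()
            .rename("value")
            .reset_index()
            .rename(columns={"level_1": "tissue"})
        )
        path = tmp_path / "expr.tsv"
        long.to_csv(path, sep="\t", index=False)
        again = ExpressionMatrix.from_tsv(path)
        pd.testing.assert_frame_equal(
            again.values.sort_index(), world.expr.values.sort_index(), check_names=False
        )


class TestBH:
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_adjusted_at_least_raw_and_order_preserving(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestSimilarityCall:
    def _world(self, rho, seed=0):
        return generate_expression(
            SyntheticConfig(
                n_genes=80,
                n_cancers=1,
                n_tissues=12,
                genes_per_cancer=4,
                mendelian_set_size=4,
                module_correlation=rho,
                seed=seed,
            )
        )

    def test_overlap_only_suffices(self):
        world = self._world(rho=0.0)
        drivers = world.cancer_genes["K00"]
        # mendelian set = the drivers themselves: overlap p tiny, coexpr null
        md = MendelianDisease("M0", "m", drivers)
        call = similarity_call(md, "K00", drivers, world.expr)
        assert call.overlap_p < 0.05
        assert call.similar

    def test_coexpression_only_suffices(self):
        world = self._world(rho=0.97, seed=3)
        md = MendelianDisease("M0", "m", world.mendelian_sets["K00"])
        call = similarity_call(md, "K00", world.cancer_genes["K00"], world.expr)
        assert call.overlap_p > 0.05  # disjoint sets
        assert call.coexpr_min_adj_p is not None and call.coexpr_min_adj_p < 0.05
        assert call.similar

    def test_neither_metric_no_call(self):
        world = self._world(rho=0.0, seed=4)
        background = sorted(
            set(world.expr.genes) - world.module_genes["K00"]
        )[:4]
        md = MendelianDisease("M0", "m", frozenset(background))
        call = similarity_call(md, "K00", world.cancer_genes["K00"], world.expr)
        assert not call.similar
        assert call.overlap_p == pytest.approx(1.0)

    def test_no_expression_data_falls_back_to_overlap(self):
        world = self._world(rho=0.0)
        md = MendelianDisease("M0", "m", frozenset({"NOT_IN_EXPR"}))
        universe = frozenset(world.expr.genes) | {"NOT_IN_EXPR"}
        call = similarity_call(
            md, "K00", world.cancer_genes["K00"], world.expr, universe=universe
        )
        assert call.coexpr_min_adj_p is None
        assert not call.similar

    def test_empty_driver_set_rejected(self):
        world = self._world(rho=0.0)
        md = MendelianDisease("M0", "m", frozenset({"X0000"}))
        with pytest.raises(ValueError, match="empty driver"):
            similarity_call(md, "K00", frozenset(), world.expr)

    def test_similarity_table_shape(self):
        world = generate_expression(
            SyntheticConfig(
                n_genes=60, n_cancers=2, n_tissues=8, module_correlation=0.9, seed=9
            )
        )
        mendelian = {
            f"M{i}": MendelianDisease(f"M{i}", "m", world.mendelian_sets[c])
            for i, c in enumerate(world.cancer_genes)
        }
        table = similarity_table(mendelian, world.cancer_genes, world.expr)
        assert len(table) == 4  # 2 mendelian x 2 cancers
        assert set(table.columns) >= {"mendelian_id", "cancer_id", "similar"}
        # each planted mendelian set should be similar to its own cancer
        own = table[
            (table["mendelian_id"] == "M0") & (table["cancer_id"] == "K00")
        ].iloc[0]
        assert own["similar"]
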