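import itertools

import numpy as np
import pandas as pd
import pytest

from ratiometric import (
    ExpressionMatrix,
    MeasureConfig,
    all_pairs,
    inclusion_profile,
    invariance_diagnostic,
    measure_correlation_matrix,
    method_overlap,
    pair_measures,
    rank_pairs,
    ranking_consistency,
    select_graph_at_size,
    stringency_sweep,
    two_regime_flag,
)
from ratiometric.measures import DegenerateInputError
from ratiometric.pairscan import GeneGraph

LOOSE = MeasureConfig(min_used_fraction=0.0)


class TestAllPairs:
    def test_pair_count(self, small_matrix):
        table = all_pairs(small_matrix, LOOSE)
        assert len(table) == 20 * 19 // 2

    def test_matches_naive_double_loop(self, small_matrix):
        """The vectorised scan equals per-pair recomputation exactly."""
        table = all_pairs(small_matrix, LOOSE)
        indexed = table.frame.set_index(["gene_a", "gene_b"])
        genes = sorted(small_matrix.gene_ids)
        for ga, gb in itertools.combinations(genes, 2):
            pm = pair_measures(
                small_matrix.gene(ga), small_matrix.gene(gb), LOOSE, ga, gb
            )
            row = indexed.loc[(ga, gb)]
            for attr in (
                "cv_ab", "cv_ba", "delta_cv", "mean_ab", "mean_ba",
                "pearson_r", "pearson_r2", "spearman_r2", "mi",
            ):
                assert row[attr] == pytest.approx(getattr(pm, attr), rel=1e-9), attr
            assert row["n_used"] == pm.n_used

    def test_deterministic_rerun(self, small_matrix):
        t1 = all_pairs(small_matrix, LOOSE)
        t2 = all_pairs(small_matrix, LOOSE)
        pd.testing.assert_frame_equal(t1.frame, t2.frame)

    def test_zero_heavy_pair_flagged_not_dropped(self, rng):
        values = np.exp(rng.normal(3, 0.5, (3, 20)))
        values[0, :10] = 0.0  # half the samples unusable for ratios with gene 0
        m = ExpressionMatrix(("g0", "g1", "g2"), tuple(f"s{i}" for i in range(20)), values)
        table = all_pairs(m, MeasureConfig(min_used_fraction=0.95))
        f = table.frame
        assert len(f) == 3
        flagged = f[~f["ra_evaluable"]]
        assert set(flagged["gene_a"]) == {"g0"}
        assert flagged["cv_ab"].isna().all()

    def test_single_gene_matrix_rejected(self):
        m = ExpressionMatrix(("g0",), ("s0", "s1", "s2"), np.ones((1, 3)) * 2)
        with pytest.raises(ValueError, match="at least two genes"):
            all_pairs(m, LOOSE)

    def test_constant_gene_rejected(self):
        values = np.vstack([np.ones(10), np.arange(1.0, 11)])
        m = ExpressionMatrix(("flat", "var"), tuple(f"s{i}" for i in range(10)), values)
        with pytest.raises(DegenerateInputError, match="flat"):
            all_pairs(m, LOOSE)


class TestRankings:
    def test_planted_perfect_pair_ranks_first_under_ra(self, rng):
        values = np.exp(rng.normal(3, 0.5, (9, 30)))
        values = np.vstack([values, 3.0 * values[0]])  # exact ratio with gene 0
        genes = tuple(f"g{i}" for i in range(10))
        m = ExpressionMatrix(genes, tuple(f"s{i}" for i in range(30)), values)
        table = all_pairs(m, LOOSE)
        ra = rank_pairs(table, "RA")
        assert {ra.iloc[0]["gene_a"], ra.iloc[0]["gene_b"]} == {"g0", "g9"}
        assert len(ra) <= len(table)

    def test_ranking_equals_sorted_brute_force(self, small_matrix):
        table = all_pairs(small_matrix, LOOSE)
        pe = rank_pairs(table, "PE")
        expected = table.frame.sort_values(
            ["pearson_r2", "gene_a", "gene_b"], ascending=[False, True, True]
        )["pearson_r2"].to_numpy()
        np.testing.assert_allclose(pe["pearson_r2"].to_numpy(), expected)
        mi = rank_pairs(table, "MI")
        assert (np.diff(mi["mi"].to_numpy()) <= 1e-12).all()
        ra = rank_pairs(table, "RA")
        assert (np.diff(ra["stability"].to_numpy()) >= -1e-12).all()
        assert (ra["delta_cv"] < LOOSE.delta_cv_threshold).all()


@pytest.fixture(scope="module")
def table(small_matrix):
    return all_pairs(small_matrix, LOOSE)


class TestStringencySweep:
    @pytest.mark.parametrize("method", ["RA", "PE", "MI", "SP"])
    def test_nestedness(self, table, method):
        sweep = stringency_sweep(table, method, n_steps=20)
        e = sweep.edge_counts()
        v = sweep.vertex_counts()
        assert (np.diff(e) >= 0).all()
        assert (np.diff(v) >= 0).all()
        g_early = sweep.step(5)
        g_late = sweep.step(15)
        assert g_early.edges <= g_late.edges

    def test_final_pe_step_accepts_all_pairs(self, table):
        sweep = stringency_sweep(table, "PE", n_steps=20)
        assert sweep.edge_counts()[-1] == len(table)
        assert sweep.thresholds[-1] == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "method,column,span,direction",
        [
            ("PE", "pearson_r2", 1.0, "ge"),
            ("MI", "mi", 2.0, "ge"),
            ("RA", "delta_cv", 1.0, "le"),
        ],
    )
    def test_edge_counts_match_direct_threshold_counting(
        self, table, method, column, span, direction
    ):
        n_steps = 25
        sweep = stringency_sweep(table, method, n_steps=n_steps)
        stat = table.frame[column].to_numpy()
        for i in range(1, n_steps + 1):
            if direction == "ge":
                thr = span * (1 - i / n_steps)
                expected = int(np.sum(stat >= thr - 1e-12))
            else:
                thr = span * i / n_steps
                expected = int(np.sum(stat <= thr + 1e-12))
            assert sweep.edge_counts()[i - 1] == expected, (method, i)

    def test_gated_cv_mode_sweeps_only_gate_passing_pairs(self, table):
        sweep = stringency_sweep(table, "RA", n_steps=10, ra_sweep_mode="gated_cv")
        f = table.frame
        gated = f[f["ra_evaluable"] & (f["delta_cv"] < LOOSE.delta_cv_threshold)]
        assert sweep.edge_counts()[-1] == len(gated)

    def test_vertex_counts_match_materialised_graphs(self, table):
        sweep = stringency_sweep(table, "PE", n_steps=10)
        for i in (1, 5, 10):
            assert sweep.vertex_counts()[i - 1] == sweep.step(i).n_vertices


class TestInclusionProfile:
    def test_boundary_steps(self, small_matrix):
        table = all_pairs(small_matrix, LOOSE)
        sweep = stringency_sweep(table, "PE", n_steps=10)
        profile, target_step = inclusion_profile(sweep, total_genes=20)
        assert profile["percent_genes"].iloc[-1] == pytest.approx(100.0)
        assert profile["n_edges"].iloc[-1] == len(table)
        # the reported step is the first reaching 95% of genes
        v = sweep.vertex_counts()
        assert v[target_step - 1] >= 0.95 * 20
        assert target_step == 1 or v[target_step - 2] < 0.95 * 20

    def test_profile_equals_per_step_recount(self, small_matrix):
        table = all_pairs(small_matrix, LOOSE)
        sweep = stringency_sweep(table, "MI", n_steps=8)
        profile, _ = inclusion_profile(sweep, total_genes=20)
        for i in range(1, 9):
            g = sweep.step(i)
            assert profile["n_edges"].iloc[i - 1] == g.n_edges
            assert profile["percent_genes"].iloc[i - 1] == pytest.approx(
                100 * g.n_vertices / 20
            )


def _graph(edges, idx=1):
    return GeneGraph(
        stringency_index=idx,
        threshold=0.5,
        edges=frozenset(tuple(sorted(e)) for e in edges),
    )


class TestMethodOverlap:
    def test_identical_graphs_all_in_triple_intersection(self):
        g = _graph([("a", "b"), ("b", "c")])
        out = method_overlap({"RA": g, "PE": g, "MI": g}, match_on="pairs")
        triple = out[out["region"] == "RA&PE&MI"].iloc[0]
        assert triple["count"] == 2
        assert triple["union_fraction"] == 1.0
        assert out[out["region"] != "RA&PE&MI"]["count"].sum() == 0

    def test_disjoint_graphs_have_empty_intersections(self):
        gs = {
            "RA": _graph([("a", "b")]),
            "PE": _graph([("c", "d")]),
            "MI": _graph([("e", "f")]),
        }
        out = method_overlap(gs, match_on="pairs")
        assert out.set_index("region").loc[["RA&PE", "RA&MI", "PE&MI", "RA&PE&MI"], "count"].sum() == 0

    def test_matches_explicit_set_algebra(self):
        gs = {
            "RA": _graph([("a", "b"), ("b", "c"), ("c", "d")]),
            "PE": _graph([("b", "c"), ("c", "d"), ("d", "e")]),
            "MI": _graph([("c", "d"), ("x", "y")]),
        }
        out = method_overlap(gs, match_on="pairs").set_index("region")["count"]
        sets = {k: set(g.edges) for k, g in gs.items()}
        assert out["RA&PE&MI"] == len(sets["RA"] & sets["PE"] & sets["MI"])
        assert out["RA&PE"] == len((sets["RA"] & sets["PE"]) - sets["MI"])
        assert out["RA"] == len(sets["RA"] - sets["PE"] - sets["MI"])
        # gene-level partition too
        out_g = method_overlap(gs, match_on="genes").set_index("region")["count"]
        vs = {k: set(g.vertices) for k, g in gs.items()}
        assert out_g["RA&PE&MI"] == len(vs["RA"] & vs["PE"] & vs["MI"])

    def test_size_matching_picks_most_stringent_step(self, small_matrix):
        table = all_pairs(small_matrix, LOOSE)
        sweep = stringency_sweep(table, "PE", n_steps=20)
        graph = select_graph_at_size(sweep, target_size=10, match_on="genes")
        assert graph.n_vertices >= 10
        if graph.stringency_index > 1:
            assert sweep.step(graph.stringency_index - 1).n_vertices < 10


class TestMeasureCorrelations:
    def test_grid_shape_symmetry_and_diagonal(self, small_matrix):
        table = all_pairs(small_matrix, LOOSE)
        grid = measure_correlation_matrix(table)
        assert list(grid.columns) == ["I", "R2", "r", "delta_CV", "CV(A/B)", "CV(B/A)"]
        np.testing.assert_allclose(grid.to_numpy(), grid.to_numpy().T, atol=1e-12)
        np.testing.assert_allclose(np.diag(grid.to_numpy()), 1.0)

    def test_duplicated_statistic_correlates_perfectly(self, small_matrix):
        table = all_pairs(small_matrix, LOOSE)
        dup = table.frame.copy()
        dup["mi"] = dup["pearson_r2"]
        from ratiometric.pairscan import PairTable

        table2 = PairTable(dup, table.config, table.n_genes, table.n_samples)
        grid = measure_correlation_matrix(table2)
        assert grid.loc["I", "R2"] == pytest.approx(1.0)


class TestInvarianceDiagnostic:
    def test_independent_stability_gives_low_r2(self, rng):
        # Planted ratio pairs whose stability is unrelated to the base
        # gene's own expression CV.
        n = 60
        rows, genes = [], []
        for i in range(15):
            b = np.exp(rng.normal(np.log(50), 0.3, n))
            noise = rng.uniform(0.005, 0.03)
            a = 2.0 * b * (1 + rng.normal(0, noise, n))
            rows += [a, b]
            genes += [f"p{i:02d}a", f"p{i:02d}b"]
        m = ExpressionMatrix(tuple(genes), tuple(f"s{j}" for j in range(n)), np.vstack(rows))
        table = all_pairs(m, LOOSE)
        frame, r2 = invariance_diagnostic(m, table)
        assert set(frame.columns) == {"gene", "gene_cv", "best_stability"}
        assert 0 <= r2 < 0.5
        # oracle: best stability is the minimum over each gene's gated pairs
        f = table.frame
        gated = f[f["delta_cv"] < LOOSE.delta_cv_threshold]
        some_gene = frame.iloc[0]["gene"]
        involved = gated[(gated["gene_a"] == some_gene) | (gated["gene_b"] == some_gene)]
        assert frame.iloc[0]["best_stability"] == pytest.approx(involved["stability"].min())


class TestTwoRegime:
    def test_homogeneous_correlated_pair_not_flagged(self, rng):
        b = rng.uniform(10, 100, 100)
        a = 2 * b + rng.normal(0, 5, 100)
        assert not two_regime_flag(a, b)

    def test_constructed_two_regime_pair_flagged(self, rng):
        a = rng.uniform(1, 3, 100)
        b = rng.uniform(1, 3, 100)
        a[90:] = np.linspace(50, 80, 10)
        b[90:] = a[90:] * (1 + rng.normal(0, 0.05, 10))
        assert two_regime_flag(a, b)
        assert two_regime_flag(b, a)  # symmetric in gene order


class TestRankingConsistency:
    def test_identical_rankings(self):
        pairs = [(f"g{i}", f"h{i}") for i in range(20)]
        out = ranking_consistency(pairs, pairs, depths=[1, 5, 10])
        assert (out["overlap_fraction"] == 1.0).all()

    def test_disjoint_top_k(self):
        pairs = [(f"g{i}", f"h{i}") for i in range(20)]
        out = ranking_consistency(pairs, pairs[::-1], depths=[10])
        assert out["overlap_fraction"].iloc[0] == 0.0

    def test_random_rankings_overlap_near_k_over_n(self, rng):
        n, k, reps = 200, 20, 200
        pairs = [(f"g{i}", f"h{i}") for i in range(n)]
        fracs = []
        for _ in range(reps):
            perm = rng.permutation(n)
            shuffled = [pairs[i] for i in perm]
            fracs.append(
                ranking_consistency(pairs, shuffled, [k])["overlap_fraction"].iloc[0]
            )
        # expected overlap fraction = k/n = 0.1
        assert np.mean(fracs) == pytest.approx(k / n, abs=0.02)

    def test_canonicalises_pair_order(self):
        out = ranking_consistency([("b", "a")], [("a", "b")], depths=[1])
        assert out["overlap_fraction"].iloc[0] == 1.0
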