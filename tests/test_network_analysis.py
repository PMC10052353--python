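"""Thermodynamic-cycle combination, additivity, correlation and cost model."""

import math

import networkx as nx
import numpy as np
import pytest

from reedsnet import network_analysis as na
from reedsnet.estimators import FreeEnergyMatrix
from reedsnet.states import enumerate_states
from reedsnet.toy_model import log_partition


def exact_matrix(system, sd=0.1):
    """Quadrature-exact per-state free energies wrapped as a matrix."""
    kt = system.conditions.kt
    g = np.array([-kt * log_partition(system, st) for st in system.states])
    g -= g[0]
    n = len(g)
    sd_mat = np.full((n, n), sd)
    np.fill_diagonal(sd_mat, 0.0)
    return FreeEnergyMatrix(system.labels, g, sd_mat, system.environment_tag, 0)


@pytest.fixture(scope="module")
def coupled_replacement(coupled_pair):
    return na.replacement_matrix(
        exact_matrix(coupled_pair.pocket), exact_matrix(coupled_pair.bulk)
    )


@pytest.fixture(scope="module")
def null_replacement(uncoupled_pair):
    pocket = exact_matrix(uncoupled_pair.pocket)
    bulk = exact_matrix(uncoupled_pair.bulk)
    return na.replacement_matrix(pocket, bulk)


class TestReplacementMatrix:
    def test_identical_environments_cancel(self, coupled_pair):
        m = exact_matrix(coupled_pair.pocket)
        repl = na.replacement_matrix(m, m)
        np.testing.assert_allclose(repl.ddg, 0.0, atol=1e-12)

    def test_uncoupled_benchmark_gives_zero_replacement(self, null_replacement):
        # pocket and bulk are identical when no couplings are implanted
        np.testing.assert_allclose(null_replacement.ddg, 0.0, atol=1e-9)

    def test_antisymmetry_and_zero_diagonal(self, coupled_replacement):
        np.testing.assert_allclose(
            coupled_replacement.ddg, -coupled_replacement.ddg.T, atol=1e-12
        )
        assert np.all(np.diag(coupled_replacement.ddg) == 0)

    def test_uncertainties_propagate_in_quadrature(self, coupled_pair):
        repl = na.replacement_matrix(
            exact_matrix(coupled_pair.pocket, sd=0.3), exact_matrix(coupled_pair.bulk, sd=0.4)
        )
        assert repl.value_sd("apo", "(1)") == pytest.approx(0.5)

    def test_state_set_mismatch_lists_difference(self, coupled_pair):
        pocket = exact_matrix(coupled_pair.pocket)
        small = FreeEnergyMatrix(
            pocket.labels[:4], pocket.g[:4], pocket.sd[:4, :4], "bulk", 0
        )
        with pytest.raises(ValueError, match=r"\(1,2\)"):
            na.replacement_matrix(pocket, small)


class TestConditionalReplacement:
    def test_empty_context_is_the_apo_single(self, coupled_replacement):
        v, _ = na.conditional_replacement(coupled_replacement, 1, set())
        assert v == pytest.approx(coupled_replacement.value("apo", "(1)"), abs=1e-12)

    def test_path_sums_close_the_cycle_exactly(self, coupled_replacement):
        total = coupled_replacement.value("apo", "(1,2,3)")
        for order in ((1, 2, 3), (3, 1, 2), (2, 3, 1)):
            ctx, acc = set(), 0.0
            for site in order:
                v, _ = na.conditional_replacement(coupled_replacement, site, ctx)
                acc += v
                ctx.add(site)
            assert acc == pytest.approx(total, abs=1e-10)

    def test_uncoupled_conditionals_are_context_independent(self, null_replacement):
        v0, _ = na.conditional_replacement(null_replacement, 1, set())
        v1, _ = na.conditional_replacement(null_replacement, 1, {2})
        v2, _ = na.conditional_replacement(null_replacement, 1, {2, 3})
        assert v0 == pytest.approx(v1, abs=1e-9)
        assert v0 == pytest.approx(v2, abs=1e-9)

    def test_site_already_in_context_rejected(self, coupled_replacement):
        with pytest.raises(ValueError):
            na.conditional_replacement(coupled_replacement, 1, {1, 2})


class TestAdditivityGap:
    def test_published_style_totals_arithmetic(self):
        # sum of singles 22.0 +/- 2.1 vs simultaneous 5.5 +/- 0.6
        gap, sd = na.gap_from_totals(22.0, 2.1, 5.5, 0.6)
        assert gap == pytest.approx(16.5)
        assert sd == pytest.approx(math.hypot(2.1, 0.6), abs=1e-12)
        assert sd == pytest.approx(2.2, abs=0.02)

    def test_uncoupled_network_has_zero_gap(self, null_replacement):
        (_, _), (_, _), (gap, _) = na.additivity_gap(null_replacement, {1, 2, 3})
        assert gap == pytest.approx(0.0, abs=1e-9)

    def test_coupled_pair_gap_matches_quadrature_cycle(self, coupled_replacement):
        (s, _), (c, _), (gap, _) = na.additivity_gap(coupled_replacement, {1, 2})
        v1, _ = na.conditional_replacement(coupled_replacement, 1, set())
        v2, _ = na.conditional_replacement(coupled_replacement, 2, set())
        assert s == pytest.approx(v1 + v2, abs=1e-12)
        assert gap == pytest.approx(s - c, abs=1e-12)
        assert gap > 1.0  # the implanted coupling penalizes single replacements

    def test_small_subsets_rejected(self, coupled_replacement):
        with pytest.raises(ValueError):
            na.additivity_gap(coupled_replacement, {1})


class TestCorrelationGraph:
    def test_single_implanted_coupling_yields_single_signed_edge(self, coupled_replacement):
        edges = {e.site_pair: e for e in na.correlation_graph(coupled_replacement)}
        assert set(edges) == {(1, 2), (1, 3), (2, 3)}
        # the coupled 1-2 pair: replacing one water makes the other easier
        assert edges[(1, 2)].delta < -1.0
        assert edges[(1, 2)].sign_class == "positive-cooperative"
        assert abs(edges[(1, 3)].delta) < 1e-9
        assert abs(edges[(2, 3)].delta) < 1e-9
        sig = [e for e in edges.values() if e.significant()]
        assert [e.site_pair for e in sig] == [(1, 2)]

    def test_directional_deltas_both_retained(self, coupled_replacement):
        edge = [e for e in na.correlation_graph(coupled_replacement) if e.site_pair == (1, 2)][0]
        assert edge.delta == pytest.approx(0.5 * (edge.delta_ab + edge.delta_ba), abs=1e-12)
        # symmetric system: both directions carry the same signal
        assert edge.delta_ab == pytest.approx(edge.delta_ba, abs=1e-9)

    def test_identical_environments_give_empty_signal(self, coupled_pair):
        m = exact_matrix(coupled_pair.pocket)
        edges = na.correlation_graph(na.replacement_matrix(m, m))
        assert all(abs(e.delta) < 1e-12 for e in edges)

    def test_graph_export_round_trip(self, tmp_path, coupled_replacement):
        edges = na.correlation_graph(coupled_replacement)
        gml = tmp_path / "corr.graphml"
        jsn = tmp_path / "corr.json"
        na.write_correlation_graph(edges, str(gml), str(jsn))
        back = nx.read_graphml(str(gml))
        assert back.number_of_nodes() == 3 and back.number_of_edges() == 3
        attrs = back.edges[("1", "2")] if ("1", "2") in back.edges else back.edges[(1, 2)]
        assert attrs["sign_class"] == "positive-cooperative"
        assert jsn.read_text().startswith("{")


class TestSpearman:
    def test_identical_profiles(self):
        rho, p = na.rank_by_spearman([1.0, 2.0, 5.0, 3.0], [1.0, 2.0, 5.0, 3.0],
                                     n_permutations=200, seed=0)
        assert rho == pytest.approx(1.0)

    def test_reversed_profiles(self):
        rho, _ = na.rank_by_spearman([1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0],
                                     n_permutations=200, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_tied_profile_matches_average_rank_formula(self):
        # ranks of b with one tie: (1, 2.5, 2.5, 4, 5); hand-computed
        # Pearson correlation of rank vectors = sqrt(1.9/2)
        rho, _ = na.rank_by_spearman([1.0, 2.0, 3.0, 4.0, 5.0], [10.0, 20.0, 20.0, 40.0, 50.0],
                                     n_permutations=200, seed=0)
        assert rho == pytest.approx(math.sqrt(1.9 / 2.0), abs=1e-12)

    def test_permutation_p_value_detects_strong_correlation(self):
        rng = np.random.default_rng(1)
        a = np.arange(10.0)
        b = a + rng.normal(0, 0.5, size=10)
        rho, p = na.rank_by_spearman(a, b, n_permutations=2000, seed=2)
        assert rho > 0.9 and p < 0.01

    def test_input_validation(self):
        with pytest.raises(ValueError):
            na.rank_by_spearman([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            na.rank_by_spearman([1.0, 2.0, 3.0], [1.0, 2.0])


class TestCostModel:
    def test_minimal_pairwise_protocol_totals(self):
        sol, prot, tot = na.cost_model(na.CostProtocol(8, 11, 5.0, 0.5, "minimal"))
        assert (sol, prot, tot) == (38.5, 385.0, 423.5)

    def test_trivial_protocol(self):
        assert na.cost_model(na.CostProtocol(2, 1, 1.0, 1.0, "minimal")) == (1.0, 1.0, 2.0)

    def test_all_pairs_mode_counts_28_for_8_states(self):
        sol, _, _ = na.cost_model(na.CostProtocol(8, 1, 1.0, 1.0, "all-pairs"))
        assert sol == 28.0

    def test_cumulative_stage_accounting(self):
        stages = {"solution_prep": 33.6, "solution_prod": 37.8,
                  "protein_prep": 84.0, "protein_prod": 88.2}
        assert na.cumulative_time(stages) == pytest.approx(243.6)
        with pytest.raises(ValueError):
            na.cumulative_time([-1.0])

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            na.CostProtocol(0, 11, 5.0, 0.5)
        with pytest.raises(ValueError):
            na.CostProtocol(8, 11, 5.0, 0.5, "bogus")
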