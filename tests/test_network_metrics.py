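"""Density, centralization and in-degree statistics against independent oracles."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _builders import make_dyad_network, make_netset
from shiftnet.errors import UndefinedMetricError
from shiftnet.network_metrics import (
    compute_shift_metrics,
    degree_centralization,
    density,
    identify_stars_and_isolates,
    in_degree_centrality,
    in_degree_centralization,
)
from shiftnet.survey_io import ShiftNetworkSet, dichotomize_symmetrize

SETTINGS = settings(max_examples=60, deadline=None, derandomize=True)


@st.composite
def tie_sets(draw, min_n=3, max_n=7):
    n = draw(st.integers(min_n, max_n))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ties = draw(st.sets(st.sampled_from(pairs)))
    return n, ties


def _nx_graph(n, ties):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(ties)
    return g


class TestDensity:
    def test_worked_example_is_83_3(self, worked_example):
        dyads = dichotomize_symmetrize(worked_example, "medication_advice")
        assert round(density(dyads), 1) == 83.3

    def test_complete_four_node_network_is_100(self):
        net = make_dyad_network(4, {(i, j) for i in range(4) for j in range(i + 1, 4)})
        assert density(net) == 100.0

    def test_random_tie_sets_match_networkx(self):
        rng = np.random.default_rng(0)
        pairs = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        for _ in range(25):
            k = rng.integers(1, len(pairs) + 1)
            ties = {pairs[i] for i in rng.choice(len(pairs), size=k, replace=False)}
            net = make_dyad_network(6, ties)
            assert density(net) == pytest.approx(100 * nx.density(_nx_graph(6, ties)))

    def test_undefined_below_two_nodes(self):
        with pytest.raises(UndefinedMetricError):
            density(make_dyad_network(1, set()))


class TestDegreeCentralization:
    def test_worked_example_is_33_33(self, worked_example):
        dyads = dichotomize_symmetrize(worked_example, "medication_advice")
        assert round(degree_centralization(dyads), 2) == 33.33

    @pytest.mark.parametrize("n", [4, 5, 8])
    def test_star_network_is_maximal(self, n):
        net = make_dyad_network(n, {(0, j) for j in range(1, n)})
        assert degree_centralization(net) == pytest.approx(100.0)

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_complete_graph_is_zero(self, n):
        ties = {(i, j) for i in range(n) for j in range(i + 1, n)}
        assert degree_centralization(make_dyad_network(n, ties)) == 0.0

    def test_cycle_is_zero(self):
        n = 6
        ties = {(i, (i + 1) % n) if i + 1 < n else (0, n - 1) for i in range(n)}
        ties = {(min(a, b), max(a, b)) for a, b in ties}
        assert degree_centralization(make_dyad_network(n, ties)) == 0.0

    def test_undefined_below_three_nodes(self):
        with pytest.raises(UndefinedMetricError):
            degree_centralization(make_dyad_network(2, {(0, 1)}))

    @SETTINGS
    @given(tie_sets())
    def test_bounded_and_100_iff_star(self, data):
        n, ties = data
        value = degree_centralization(make_dyad_network(n, ties))
        assert 0.0 <= value <= 100.0 + 1e-9
        is_star = any(
            ties == {(min(hub, k), max(hub, k)) for k in range(n) if k != hub}
            for hub in range(n)
        )
        assert math.isclose(value, 100.0, abs_tol=1e-9) == is_star

    @SETTINGS
    @given(tie_sets(), st.randoms(use_true_random=False))
    def test_invariant_under_relabeling(self, data, rnd):
        n, ties = data
        perm = list(range(n))
        rnd.shuffle(perm)
        relabeled = {
            (min(perm[i], perm[j]), max(perm[i], perm[j])) for i, j in ties
        }
        a = degree_centralization(make_dyad_network(n, ties))
        b = degree_centralization(make_dyad_network(n, relabeled))
        assert a == pytest.approx(b)
        assert density(make_dyad_network(n, ties)) == pytest.approx(
            density(make_dyad_network(n, relabeled))
        ) or not ties


class TestInDegree:
    def test_full_receiver_scores_one_and_isolate_zero(self):
        arcs = {"problem_solving": [(i, 0) for i in range(1, 5)]}
        net = make_netset(5, arcs)
        scores = in_degree_centrality(net, "problem_solving")
        assert scores["P00"] == 1.0
        assert scores["P04"] == 0.0

    def test_random_binary_matrix_matches_column_tally(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            w = (rng.random((5, 5)) < 0.5).astype(float)
            np.fill_diagonal(w, np.nan)
            net = make_netset(5)
            net = ShiftNetworkSet(
                roster=net.roster,
                matrices={rel: w.copy() for rel in net.matrices},
                missing_rows=frozenset(),
            )
            scores = in_degree_centrality(net, "socializing")
            for j, pid in enumerate(net.roster.ids):
                col = [w[i, j] for i in range(5) if i != j]
                assert scores[pid] == pytest.approx(sum(col) / 4)

    def test_missing_rows_shrink_sender_pool(self):
        # senders: rows 0 and 1 only; node 2's potential senders = 2
        arcs = {"socializing": [(0, 2, 3), (1, 2, 1)]}
        net = make_netset(4, arcs, missing=(3,))
        scores = in_degree_centrality(net, "socializing")
        assert scores["P02"] == pytest.approx(2 / 2)
        # node 3 (nonrespondent) can still receive; its senders are rows 0,1
        assert scores["P03"] == 0.0

    def test_no_potential_senders_is_nan(self):
        net = make_netset(2, missing=(0,))
        scores = in_degree_centrality(net, "socializing")
        assert math.isnan(scores["P01"])  # only possible sender is missing


class TestInDegreeCentralization:
    def test_directed_star_is_100(self):
        n = 6
        arcs = {"problem_solving": [(i, 0) for i in range(1, n)]}
        assert in_degree_centralization(
            make_netset(n, arcs), "problem_solving"
        ) == pytest.approx(100.0)

    def test_uniform_in_degree_is_zero(self):
        n = 5
        arcs = {"problem_solving": [(i, (i + 1) % n) for i in range(n)]}
        assert in_degree_centralization(make_netset(n, arcs), "problem_solving") == 0.0

    def test_random_directed_network_matches_formula(self):
        rng = np.random.default_rng(11)
        n = 6
        for _ in range(20):
            w = (rng.random((n, n)) < 0.4).astype(float)
            np.fill_diagonal(w, np.nan)
            net = make_netset(n)
            net = ShiftNetworkSet(
                roster=net.roster,
                matrices={rel: w.copy() for rel in net.matrices},
                missing_rows=frozenset(),
            )
            counts = [np.nansum(w[:, j]) for j in range(n)]
            expected = 100 * sum(max(counts) - c for c in counts) / ((n - 1) ** 2)
            got = in_degree_centralization(net, "medication_advice")
            assert got == pytest.approx(expected)


class TestStarsAndIsolates:
    def test_empty_network_all_isolates_no_stars(self):
        m = compute_shift_metrics(make_netset(4), "socializing")
        stars, isolates = identify_stars_and_isolates(m)
        assert stars == ()
        assert set(isolates) == set(m.in_degree)

    def test_directed_star_hub_is_unique_star(self):
        arcs = {"socializing": [(i, 0) for i in range(1, 5)]}
        m = compute_shift_metrics(make_netset(5, arcs), "socializing")
        stars, isolates = identify_stars_and_isolates(m)
        assert stars == ("P00",)
        assert isolates == ()

    def test_unattached_members_reported_as_isolates(self):
        # core of 4 communicating members plus 4 unattached ones
        arcs = {"medication_advice": [(0, 1, 2), (1, 2, 3), (2, 3, 1), (3, 0, 4)]}
        m = compute_shift_metrics(make_netset(8, arcs), "medication_advice")
        assert set(m.isolates) == {"P04", "P05", "P06", "P07"}

    def test_tied_maxima_report_all_roles(self, worked_example):
        m = compute_shift_metrics(worked_example, "medication_advice")
        # A (SRN) and B (PCT) each receive from both reporters
        assert set(m.stars) == {"A", "B"}
        assert set(m.top_in_degree_roles) == {"SRN", "PCT"}


def test_adding_a_tie_strictly_increases_density():
    ties = {(0, 1), (1, 2)}
    before = density(make_dyad_network(5, ties))
    after = density(make_dyad_network(5, ties | {(2, 3)}))
    assert after > before
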