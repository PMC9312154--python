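"""The incentive walk: elementary steps, belief machinery, full runs."""

import numpy as np
import pytest

import rwdir.walk as walk_mod
from rwdir.hetnet import HeteroNetwork, Label, RNAType, build_adjacency
from rwdir.walk import (
    BeliefState,
    StartError,
    WalkConfig,
    WalkState,
    apply_incentive,
    apply_penalty,
    detect_newly_visited,
    entropy,
    entropy_transition_update,
    init_beliefs,
    init_walk,
    propagate_beliefs,
    run_rwdir,
    run_rwdir_no_entropy,
    run_trwr,
    rwr_step,
)

from conftest import random_network

SWAP = np.array([[0.0, 1.0], [1.0, 0.0]])


def closed_form(W, P0, alpha):
    n = W.shape[0]
    return np.linalg.solve(np.eye(n) - alpha * W.T, (1 - alpha) * P0)


class TestRwrStep:
    def test_alpha_zero_returns_restart(self):
        out = rwr_step(SWAP, np.array([0.3, 0.7]), np.array([1.0, 0.0]), 0.0)
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_one_step_hand_value(self):
        out = rwr_step(SWAP, np.array([1.0, 0.0]), np.array([1.0, 0.0]), 0.5)
        np.testing.assert_allclose(out, [0.5, 0.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_mass_conserved(self, seed):
        net, _ = random_network(seed)
        adj = build_adjacency(net)
        from rwdir.transition import degree_transition_matrix

        W = degree_transition_matrix(adj).W
        # confine to positive-degree vertices so W is fully stochastic
        keep = adj.degrees() > 0
        W = W[np.ix_(keep, keep)]
        W = W / W.sum(axis=1, keepdims=True)
        rng = np.random.default_rng(seed)
        Pt = rng.dirichlet(np.ones(W.shape[0]))
        P0 = rng.dirichlet(np.ones(W.shape[0]))
        out = rwr_step(W, Pt, P0, 0.6)
        assert abs(out.sum() - 1.0) < 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            rwr_step(SWAP, np.ones(3) / 3, np.ones(2) / 2, 0.5)


class TestRunTrwr:
    def test_two_cycle_stationary(self):
        pt, _, conv = run_trwr(SWAP, np.array([1.0, 0.0]), alpha=0.5)
        assert conv
        np.testing.assert_allclose(pt, [2 / 3, 1 / 3], atol=1e-8)

    def test_small_alpha_stays_near_restart(self):
        P0 = np.array([1.0, 0.0])
        pt, _, _ = run_trwr(SWAP, P0, alpha=1e-6)
        np.testing.assert_allclose(pt, P0, atol=1e-5)

    def test_symmetric_restart_on_vertex_transitive_graph(self):
        # 4-cycle, uniform restart -> uniform stationary
        W = np.roll(np.eye(4), 1, axis=1) * 0.5 + np.roll(np.eye(4), -1, axis=1) * 0.5
        pt, _, _ = run_trwr(W, np.full(4, 0.25), alpha=0.85)
        np.testing.assert_allclose(pt, 0.25, atol=1e-8)

    def test_nonconvergence_flagged(self):
        with pytest.warns(UserWarning, match="did not converge"):
            pt, iters, conv = run_trwr(SWAP, np.array([1.0, 0.0]), alpha=0.9, tol=1e-15, max_iter=3)
        assert not conv and iters == 3


class TestInitWalk:
    def test_max_degree_related_seed(self, three_vertex_net):
        labels = [Label.RELATED, Label.RELATED, Label.UNLABELED]  # g1 deg 2, g2 deg 1
        state = init_walk(three_vertex_net, labels, 0.85)
        assert state.P0[0] == 1.0 and state.P0.sum() == 1.0
        assert state.visited == {0}

    def test_tie_breaks_to_lowest_canonical_index(self):
        net = HeteroNetwork.from_members(
            {"a": RNAType.MRNA, "b": RNAType.MRNA, "c": RNAType.MRNA},
            [("a", "c"), ("b", "c")],
        )
        state = init_walk(net, [Label.RELATED, Label.RELATED, Label.UNLABELED], 0.85)
        assert state.P0[0] == 1.0

    def test_no_related_vertex_raises(self, three_vertex_net):
        with pytest.raises(StartError):
            init_walk(three_vertex_net, [Label.UNLABELED] * 3, 0.85)


class TestVisitDetection:
    def test_no_change_gives_empty_set(self):
        p = np.array([0.5, 0.5])
        assert detect_newly_visited(p, p, set(), 1e-12) == set()

    def test_first_step_reaches_seed_neighbors(self, three_vertex_net):
        labels = [Label.RELATED, Label.UNLABELED, Label.UNLABELED]
        state = init_walk(three_vertex_net, labels, 0.5)
        from rwdir.transition import degree_transition_matrix

        W = degree_transition_matrix(build_adjacency(three_vertex_net))
        nxt = rwr_step(W, state.Pt, state.P0, 0.5)
        assert detect_newly_visited(nxt, state.Pt, state.visited, 1e-12) == {1, 2}

    def test_subthreshold_changes_excluded(self):
        prev = np.array([0.5, 0.5, 0.0])
        cur = np.array([0.5, 0.5 - 1e-15, 1e-15])
        assert detect_newly_visited(cur, prev, set(), 1e-12) == set()


class TestIncentivePenalty:
    def _state(self, P0, Pt=None):
        P0 = np.asarray(P0, dtype=float)
        return WalkState(P0=P0, Pt=np.asarray(Pt if Pt is not None else P0, dtype=float),
                         visited=set())

    def test_incentive_renormalizes(self):
        state = self._state([1.0, 0.0, 0.0])
        apply_incentive(state, 1, [Label.RELATED, Label.RELATED, Label.UNLABELED])
        np.testing.assert_allclose(state.P0, [1 / 1.1, 0.1 / 1.1, 0.0])
        assert abs(state.P0.sum() - 1.0) < 1e-12

    def test_incentive_idempotent(self):
        labels = [Label.RELATED, Label.RELATED, Label.UNLABELED]
        state = self._state([1.0, 0.0, 0.0])
        apply_incentive(state, 1, labels)
        snapshot = state.P0.copy()
        apply_incentive(state, 1, labels)
        np.testing.assert_array_equal(state.P0, snapshot)

    def test_incentive_rejects_non_related(self):
        with pytest.raises(ValueError):
            apply_incentive(self._state([1.0, 0.0]), 1, [Label.RELATED, Label.IRRELEVANT])

    def test_penalty_divides_by_degree(self):
        state = self._state([0.0, 0.0], Pt=[0.6, 0.4])
        apply_penalty(state, 1, 4)
        # 0.4 / 4 = 0.1 before renormalization; then rescaled to sum 1
        np.testing.assert_allclose(state.Pt, np.array([0.6, 0.1]) / 0.7)

    def test_penalty_degree_one_is_noop(self):
        state = self._state([0.0, 0.0], Pt=[0.6, 0.4])
        apply_penalty(state, 1, 1)
        np.testing.assert_allclose(state.Pt, [0.6, 0.4])

    def test_penalty_zero_degree_skipped_with_warning(self):
        state = self._state([0.0, 0.0], Pt=[0.6, 0.4])
        with pytest.warns(UserWarning, match="zero-degree"):
            apply_penalty(state, 1, 0)
        np.testing.assert_allclose(state.Pt, [0.6, 0.4])


class TestBeliefs:
    def test_rank_formula(self):
        Pt = np.array([0.4, 0.3, 0.2, 0.1])
        labels = [Label.UNLABELED] * 4
        b = init_beliefs(Pt, labels, 4)
        np.testing.assert_allclose(b.m1, [3 / 4, 2 / 4, 1 / 4, 0.0])
        np.testing.assert_allclose(b.m1 + b.m2, 1.0)

    def test_labeled_vertices_clamped(self):
        Pt = np.array([0.4, 0.3, 0.3])
        b = init_beliefs(Pt, [Label.RELATED, Label.IRRELEVANT, Label.UNLABELED], 3)
        assert b.m1[0] == 1.0 and b.m2[0] == 0.0
        assert b.m1[1] == 0.0 and b.m2[1] == 1.0

    def test_rank_ties_ordinal_by_index(self):
        Pt = np.array([0.5, 0.5])
        b = init_beliefs(Pt, [Label.UNLABELED] * 2, 2)
        np.testing.assert_allclose(b.m1, [1 / 2, 0.0])

    def test_entropy_values(self):
        b = BeliefState(m1=np.array([0.5, 1.0, 0.25]), m2=np.array([0.5, 0.0, 0.75]))
        E = entropy(b)
        np.testing.assert_allclose(E, [1.0, 0.0, 0.8112781244591328], atol=1e-12)


class TestEntropyTransition:
    def _pair(self):
        net = HeteroNetwork.from_members(
            {"a": RNAType.MRNA, "v": RNAType.MRNA}, [("a", "v")]
        )
        return build_adjacency(net)

    def test_destination_proportional_row(self):
        adj = self._pair()  # canonical order: a then v
        W = entropy_transition_update(adj, np.array([0.8, 0.2])).W
        np.testing.assert_allclose(W[1], [0.8, 0.2])  # row of v
        np.testing.assert_allclose(W[0], [0.8, 0.2])  # row of a (same closed nbhd)

    def test_equal_entropies_give_uniform_rows(self):
        adj = self._pair()
        W = entropy_transition_update(adj, np.array([0.7, 0.7])).W
        np.testing.assert_allclose(W, 0.5)

    def test_zero_entropy_fallback_uniform(self):
        adj = self._pair()
        W = entropy_transition_update(adj, np.zeros(2)).W
        np.testing.assert_allclose(W, 0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_stochastic(self, seed):
        net, _ = random_network(seed)
        adj = build_adjacency(net)
        rng = np.random.default_rng(seed)
        E = rng.uniform(0, 1, net.h)
        W = entropy_transition_update(adj, E).W
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-12)


class TestPropagation:
    def test_unlabeled_moves_toward_related_neighbor(self):
        W = np.full((2, 2), 0.5)
        labels = [Label.RELATED, Label.UNLABELED]
        b = BeliefState(m1=np.array([1.0, 0.2]), m2=np.array([0.0, 0.8]))
        nxt = propagate_beliefs(b, W, labels)
        assert 0.2 < nxt.m1[1] <= 1.0
        assert nxt.m1[0] == 1.0

    def test_uniform_beliefs_are_fixed_point(self):
        W = np.full((3, 3), 1 / 3)
        labels = [Label.UNLABELED] * 3
        b = BeliefState(m1=np.full(3, 0.5), m2=np.full(3, 0.5))
        nxt = propagate_beliefs(b, W, labels)
        np.testing.assert_allclose(nxt.m1, 0.5)

    def test_path_between_opposite_labels_converges_to_half(self):
        # a(related) - b(unlabeled) - c(irrelevant), uniform W over closed nbhds
        net = HeteroNetwork.from_members(
            {"a": RNAType.MRNA, "b": RNAType.MRNA, "c": RNAType.MRNA},
            [("a", "b"), ("b", "c")],
        )
        adj = build_adjacency(net)
        W = entropy_transition_update(adj, np.zeros(3)).W  # uniform fallback
        labels = [Label.RELATED, Label.UNLABELED, Label.IRRELEVANT]
        b = BeliefState(m1=np.array([1.0, 0.9, 0.0]), m2=np.array([0.0, 0.1, 1.0]))
        for _ in range(200):
            b = propagate_beliefs(b, W, labels)
        assert abs(b.m1[1] - 0.5) < 1e-6

    def test_isolated_vertex_keeps_beliefs(self):
        W = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        labels = [Label.UNLABELED] * 3
        b = BeliefState(m1=np.array([0.6, 0.4, 0.3]), m2=np.array([0.4, 0.6, 0.7]))
        nxt = propagate_beliefs(b, W, labels)
        assert nxt.m1[2] == 0.3


class TestFullRuns:
    def test_lone_unlabeled_among_related_scores_high(self):
        members = {f"r{i}": RNAType.MRNA for i in range(4)}
        members["u"] = RNAType.MRNA
        edges = [(a, b) for i, a in enumerate(sorted(members)) for b in sorted(members)[i + 1:]]
        net = HeteroNetwork.from_members(members, edges)
        labels = [Label.RELATED if v != "u" else Label.UNLABELED for v in net.ids]
        result = run_rwdir(net, labels)
        assert result.scores["u"] > 0.9

    def test_deterministic_across_runs(self, tiny_fixture):
        net, labels = tiny_fixture
        a = run_rwdir(net, labels)
        b = run_rwdir(net, labels)
        assert a.scores == b.scores and a.ranking == b.ranking
        assert a.iterations_run == b.iterations_run

    def test_invariants_hold_throughout(self, tiny_fixture):
        net, labels = tiny_fixture
        result = run_rwdir(net, labels, WalkConfig(check_invariants=True))
        assert result.converged

    def test_seed_community_tops_ranking(self):
        from rwdir.synthetic import FixtureSpec, generate_hetnet

        spec = FixtureSpec(
            sizes=(20, 5, 5),
            within_density=(0.3, 0.4, 0.4),
            cross_density=(0.05, 0.02, 0.08),
            n_related=2,
            n_irrelevant=5,
            n_unlabeled_community=4,
            homophily=3.0,
            rng_seed=11,
        )
        net, labels = generate_hetnet(spec)
        resolved = labels.resolve(net)
        result = run_rwdir(net, resolved)
        # both related seeds end up in the restart support
        related_ids = [v for v, lab in zip(net.ids, resolved) if lab is Label.RELATED]
        assert all(result.final_p0[v] > 0 for v in related_ids)

    def test_no_entropy_never_allocates_beliefs(self, tiny_fixture, monkeypatch):
        net, labels = tiny_fixture

        def boom(*args, **kwargs):  # pragma: no cover
            raise AssertionError("belief machinery touched in the ablation")

        monkeypatch.setattr(walk_mod, "init_beliefs", boom)
        monkeypatch.setattr(walk_mod, "BeliefState", boom)
        result = run_rwdir_no_entropy(net, labels)
        assert result.final_m1 is None

    def test_rwdir_equals_ablation_when_no_unlabeled(self):
        net = HeteroNetwork.from_members(
            {"a": RNAType.MRNA, "b": RNAType.MRNA, "c": RNAType.MRNA, "d": RNAType.MIRNA},
            [("a", "b"), ("b", "c"), ("a", "d")],
        )
        labels = [Label.RELATED, Label.RELATED, Label.IRRELEVANT, Label.IRRELEVANT]
        full = run_rwdir(net, labels)
        ablated = run_rwdir_no_entropy(net, labels)
        assert full.final_pt == ablated.final_pt
        assert full.iterations_run == ablated.iterations_run

    def test_incentive_inclusion_monotone_under_relabeling(self):
        """Labeling a seed-adjacent vertex related adds it to P0 support."""
        net, assignment = random_network(7)
        resolved = assignment.resolve(net)
        result = run_rwdir(net, resolved)
        seed_id = max(
            (v for v, lab in zip(net.ids, resolved) if lab is Label.RELATED),
            key=lambda v: (net.degree(v), -net.index[v]),
        )
        neighbor = next(
            v for v, lab in zip(net.ids, resolved)
            if lab is Label.UNLABELED
            and ((seed_id, v) in net.edges or (v, seed_id) in net.edges)
        )
        assert result.final_p0[neighbor] == 0.0
        relabeled = [
            Label.RELATED if v == neighbor else lab for v, lab in zip(net.ids, resolved)
        ]
        promoted = run_rwdir(net, relabeled)
        assert promoted.final_p0[neighbor] > 0.0
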