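"""Tests for the recursive theory-of-mind choice model on game trees."""

import math

import numpy as np
import pytest

from expertsde import (
    ConvergenceError,
    GameTree,
    InvalidParameterError,
    ScenarioSpec,
    StructuralError,
    ToMModel,
    TreeNode,
    batch_decisions,
    choice_distribution,
    coupled_map,
    decide_by_threshold,
    chess_scenario_tree,
    random_scenario,
    simulate_tom_dynamics,
    solve_equilibrium,
    validate_tree,
)


def make_tree(nodes, values, weights, root_player="Black", base=None):
    return GameTree(root_player=root_player,
                    nodes={n.id: n for n in nodes},
                    leaf_values=values, edge_weights=weights,
                    base_moves=tuple(base) if base else ())


class TestValidation:
    def test_canonical_chess_tree_passes(self, chess_tree):
        assert validate_tree(chess_tree) is chess_tree

    def test_single_node_tree_has_no_opponent_ply(self):
        tree = make_tree([TreeNode("a", "Black", "a")], {"a": 1.0}, {})
        with pytest.raises(StructuralError):
            validate_tree(tree)

    def test_consecutive_same_player_moves_rejected(self):
        tree = make_tree(
            [TreeNode("a", "Black", "a", ("b",)), TreeNode("b", "Black", "b")],
            {"b": 1.0}, {("a", "b"): 1.0})
        with pytest.raises(StructuralError, match="same player"):
            validate_tree(tree)

    def test_missing_edge_weight_names_the_node(self):
        tree = make_tree(
            [TreeNode("a", "Black", "a", ("b",)), TreeNode("b", "White", "b")],
            {"b": 1.0}, {})
        with pytest.raises(StructuralError) as err:
            validate_tree(tree)
        assert err.value.node_id == "b"

    def test_missing_leaf_value_rejected(self):
        tree = make_tree(
            [TreeNode("a", "Black", "a", ("b",)), TreeNode("b", "White", "b")],
            {}, {("a", "b"): 1.0})
        with pytest.raises(StructuralError, match="leaf has no value"):
            validate_tree(tree)

    def test_cycle_rejected(self):
        tree = make_tree(
            [TreeNode("a", "Black", "a", ("b",)), TreeNode("b", "White", "b", ("a",))],
            {}, {("a", "b"): 1.0, ("b", "a"): 1.0}, base=("a",))
        with pytest.raises(StructuralError):
            validate_tree(tree)

    def test_json_round_trip_preserves_structure(self, chess_tree):
        clone = GameTree.from_json_dict(chess_tree.to_json_dict())
        assert validate_tree(clone).to_json_dict() == chess_tree.to_json_dict()


class TestDynamics:
    def test_zero_weights_zero_noise_freeze_all_activity(self, chess_tree):
        weights = {k: 0.0 for k in chess_tree.edge_weights}
        tree = chess_scenario_tree(edge_weights=weights)
        model = ToMModel(tree=tree, noise=0.0, beta=1.0, decision_threshold=1.0)
        traj = simulate_tom_dynamics(model, dt=0.01, horizon=1.0, seed=0)
        assert np.all(traj.states == 0.0)

    def test_noise_free_cascade_matches_polynomial_integration(self, chess_tree):
        # unit weights/values: each White reply integrates 2 leaf payoffs
        # -> N(t) = 2t; each base move integrates 2 replies -> K(t) = 2t^2
        model = ToMModel(tree=chess_tree, noise=0.0, beta=1.0, decision_threshold=10.0)
        traj = simulate_tom_dynamics(model, dt=1e-3, horizon=2.0, seed=0)
        t = traj.times
        for j, node_id in enumerate(traj.labels):
            expected = 2.0 * t**2 if node_id in ("Nf6", "d6") else 2.0 * t
            scale = np.maximum(np.abs(expected), 1e-30)
            rel = np.abs(traj.states[:, j] - expected) / scale
            assert rel[1:].max() < 1e-8

    def test_dynamics_are_seed_deterministic(self, chess_model):
        a = simulate_tom_dynamics(chess_model, dt=0.01, horizon=1.0, seed=5)
        b = simulate_tom_dynamics(chess_model, dt=0.01, horizon=1.0, seed=5)
        assert np.array_equal(a.states, b.states)


class TestThresholdDecision:
    def test_deterministically_stronger_branch_always_wins(self):
        tree = chess_scenario_tree(leaf_values={
            "d6/c3/d5": 0.1, "d6/c3/Bc5": 0.1, "d6/h3/d5": 0.1, "d6/h3/Bc5": 0.1})
        model = ToMModel(tree=tree, noise=0.0, beta=1.0, decision_threshold=4.0)
        for seed in range(3):
            res = decide_by_threshold(model, dt=1e-3, horizon=10.0, seed=seed)
            assert res.winner == "Nf6" and not res.censored

    def test_symmetric_tree_splits_decisions_evenly(self, chess_model):
        batch = batch_decisions(chess_model, dt=2e-3, horizon=20.0,
                                n_trials=1500, seed=8)
        decided = (~batch.censored).sum()
        assert decided == 1500
        frac = batch.fraction("Nf6")
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / decided)

    def test_horizon_too_short_censors(self, chess_model):
        res = decide_by_threshold(
            ToMModel(tree=chess_model.tree, noise=0.0, beta=1.0,
                     decision_threshold=500.0),
            dt=0.01, horizon=1.0, seed=0)
        assert res.censored


class TestChoiceDistribution:
    def test_fully_symmetric_tree_is_uniform(self, chess_model):
        dist = choice_distribution(chess_model)
        assert dist.as_dict() == {"Nf6": 0.5, "d6": 0.5}

    def test_vanishing_beta_is_uniform_despite_asymmetry(self, asymmetric_chess_model):
        model = ToMModel(tree=asymmetric_chess_model.tree, noise=1.0,
                         beta=1e-12, decision_threshold=3.0)
        dist = choice_distribution(model)
        assert np.allclose(dist.probabilities, 0.5, atol=1e-9)

    def test_backward_induction_matches_hand_rolled_arithmetic(self):
        # Base move A: White replies r1, r2 with edge weights 1.0, 0.5;
        # leaf payoffs chosen so f(r1) = 0.5, f(r2) = 0, hence White's
        # probabilities at beta = 2 are (e/(e+1), 1/(e+1)).
        tree = chess_scenario_tree(
            edge_weights={("Nf6", "Nf6/Ng5"): 1.0, ("Nf6", "Nf6/Nc3"): 0.5},
            leaf_values={
                "Nf6/Ng5/d5": 0.25, "Nf6/Ng5/Bc5": 0.25,
                "Nf6/Nc3/d5": 0.0, "Nf6/Nc3/Bc5": 0.0,
                "d6/c3/d5": 0.1, "d6/c3/Bc5": 0.1,
                "d6/h3/d5": 0.1, "d6/h3/Bc5": 0.1,
            },
        )
        model = ToMModel(tree=tree, noise=1.0, beta=2.0, decision_threshold=3.0)

        p_r1 = math.exp(2 * 0.5) / (math.exp(2 * 0.5) + math.exp(0.0))
        f_A = 1.0 * p_r1 * 0.5 + 0.5 * (1 - p_r1) * 0.0
        f_B = 1.0 * 0.5 * 0.2 + 1.0 * 0.5 * 0.2  # symmetric sub-branch
        expected_A = math.exp(2 * f_A) / (math.exp(2 * f_A) + math.exp(2 * f_B))

        dist = choice_distribution(model)
        assert dist["Nf6"] == pytest.approx(expected_A, abs=1e-12)

    def test_relabeling_base_moves_permutes_probabilities(self, asymmetric_chess_model):
        dist = choice_distribution(asymmetric_chess_model)
        tree = asymmetric_chess_model.tree
        swapped = GameTree(root_player=tree.root_player, nodes=tree.nodes,
                           leaf_values=tree.leaf_values,
                           edge_weights=tree.edge_weights,
                           base_moves=("d6", "Nf6"))
        dist_swapped = choice_distribution(
            ToMModel(tree=swapped, noise=1.0, beta=2.0, decision_threshold=3.0))
        assert dist_swapped.labels == ("d6", "Nf6")
        assert dist_swapped["Nf6"] == pytest.approx(dist["Nf6"], abs=1e-15)
        assert dist_swapped["d6"] == pytest.approx(dist["d6"], abs=1e-15)

    def test_heavier_edge_to_better_subtree_helps_the_move(self):
        for seed in range(4):
            spec = ScenarioSpec(kind="tom", branching=2, depth=2, seed=seed,
                                ranges={"leaf_value": (0.1, 1.0)})
            model = random_scenario(spec)
            base = model.tree.base_moves[0]
            reply = model.tree.children(base)[0]
            before = choice_distribution(model)[base]
            bumped = dict(model.tree.edge_weights)
            bumped[(base, reply)] += 0.5
            tree2 = GameTree(root_player=model.tree.root_player,
                             nodes=model.tree.nodes,
                             leaf_values=model.tree.leaf_values,
                             edge_weights=bumped,
                             base_moves=model.tree.base_moves)
            after = choice_distribution(
                ToMModel(tree=tree2, noise=model.noise, beta=model.beta,
                         decision_threshold=model.decision_threshold))[base]
            assert after >= before - 1e-12


def symmetric_coupling(tree):
    # every leaf's payoff leans equally on both base-move probabilities
    return {leaf: {"const": 0.5, "Nf6": 0.3, "d6": 0.3}
            for leaf in tree.leaf_values}


class TestEquilibrium:
    def test_hierarchical_tree_solves_in_one_iteration(self, asymmetric_chess_model):
        result = solve_equilibrium(asymmetric_chess_model)
        direct = choice_distribution(asymmetric_chess_model)
        assert result.iterations == 1
        assert result.multistart_agreement
        assert np.array_equal(result.root.probabilities, direct.probabilities)

    def test_symmetric_coupled_system_settles_on_uniform(self, chess_tree):
        model = ToMModel(tree=chess_tree, noise=1.0, beta=2.0,
                         decision_threshold=3.0,
                         coupling=symmetric_coupling(chess_tree))
        result = solve_equilibrium(model, tolerance=1e-12)
        assert np.allclose(result.root.probabilities, 0.5, atol=1e-10)
        assert result.multistart_agreement

    def test_coupled_fixed_point_survives_direct_substitution(self, asymmetric_chess_model):
        tree = asymmetric_chess_model.tree
        coupling = {leaf: {"const": v, "Nf6": 0.2}
                    for leaf, v in tree.leaf_values.items()}
        model = ToMModel(tree=tree, noise=1.0, beta=0.8, decision_threshold=3.0,
                         coupling=coupling)
        result = solve_equilibrium(model, tolerance=1e-10)
        reapplied = coupled_map(model, result.root.as_dict())
        residual = np.max(np.abs(reapplied.probabilities - result.root.probabilities))
        assert residual < 1e-10
        assert result.multistart_agreement

    def test_exhausted_iterations_report_last_residual(self, chess_tree):
        coupling = {leaf: {"const": 0.5, "Nf6": 0.4} for leaf in chess_tree.leaf_values}
        model = ToMModel(tree=chess_tree, noise=1.0, beta=2.0,
                         decision_threshold=3.0, coupling=coupling)
        with pytest.raises(ConvergenceError) as err:
            solve_equilibrium(model, tolerance=1e-10, max_iterations=1)
        assert err.value.residual > 0.0


class TestModelValidation:
    def test_nonpositive_beta_rejected(self, chess_tree):
        with pytest.raises(InvalidParameterError):
            ToMModel(tree=chess_tree, noise=1.0, beta=0.0, decision_threshold=1.0)

    def test_negative_noise_rejected(self, chess_tree):
        with pytest.raises(InvalidParameterError):
            ToMModel(tree=chess_tree, noise=-1.0, beta=1.0, decision_threshold=1.0)

    def test_positive_state_gain_rejected(self, chess_tree):
        with pytest.raises(InvalidParameterError):
            ToMModel(tree=chess_tree, noise=1.0, beta=1.0,
                     decision_threshold=1.0, state_gain=0.5)
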