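"""Strategic theory of mind on two-player game trees.

A player deciding on a move (the *root player*, "Black" in the packaged
chess fixture) encodes each candidate base move as a level of neural
activity.  The activity of a move grows as a weighted sum of the
activities encoding the opponent's possible replies, which in turn grow
as weighted sums of the (learned, fixed) payoffs attached to the moves
below them — a cascade of coupled linear-drift (Ornstein-Uhlenbeck type)
SDEs, one per non-leaf node of the game tree:

    dX_i = ( sum_j w_ij a_j  +  lambda X_i ) dt + sigma_i dW_i,

where j ranges over node i's children, w_ij is the subjective edge
weight, and a_j is the child's current activity (internal child) or its
fixed leaf payoff (leaf child).  A decision is reached when the absolute
activity of some base move hits a threshold.

Because the drift is linear in the activities, the stationary choice
behaviour takes a softmax form at every decision level:

    p(x_i) = exp(beta f_i) / sum_k exp(beta f_k),

with f_i the backward-propagated valuation of move i: at the deepest
level f_i is the weight-scaled sum of leaf payoffs; one level up, each
valuation is the probability-weighted, weight-scaled valuation of the
opponent's replies — the opponent's own softmax probabilities entering
the player's valuation is precisely the recursive theory-of-mind step.
:func:`solve_equilibrium` handles the optionally *coupled* variant in
which deep payoffs refer back to the root player's own choice
probabilities, so the two players' distributions must be solved as a
fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import sde_core
from .categorization import ChoiceDistribution, _stable_softmax
from .errors import ConvergenceError, InvalidParameterError, StructuralError

__all__ = [
    "TreeNode",
    "GameTree",
    "ToMModel",
    "EquilibriumResult",
    "validate_tree",
    "simulate_tom_dynamics",
    "decide_by_threshold",
    "batch_decisions",
    "choice_distribution",
    "coupled_map",
    "solve_equilibrium",
]


@dataclass(frozen=True)
class TreeNode:
    """One move in the game tree."""

    id: str
    player: str
    move: str
    children: tuple[str, ...] = ()


@dataclass(frozen=True)
class GameTree:
    """Alternating-player move tree with subjective edge weights.

    ``base_moves`` are the root player's candidate first moves (the
    parentless nodes, in declaration order).  ``edge_weights`` maps
    (parent_id, child_id) to the subjective strength/payoff weight of
    that continuation; ``leaf_values`` maps each leaf id to its terminal
    subjective value.
    """

    root_player: str
    nodes: dict[str, TreeNode]
    leaf_values: dict[str, float]
    edge_weights: dict[tuple[str, str], float]
    base_moves: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.base_moves:
            with_parent = {c for n in self.nodes.values() for c in n.children}
            object.__setattr__(
                self, "base_moves",
                tuple(i for i in self.nodes if i not in with_parent))

    def children(self, node_id: str) -> tuple[str, ...]:
        return self.nodes[node_id].children

    def is_leaf(self, node_id: str) -> bool:
        return not self.nodes[node_id].children

    def internal_ids(self) -> list[str]:
        """Non-leaf node ids in breadth-first order from the base moves."""
        order, frontier = [], list(self.base_moves)
        while frontier:
            nxt = []
            for i in frontier:
                if not self.is_leaf(i):
                    order.append(i)
                    nxt.extend(self.nodes[i].children)
            frontier = nxt
        return order

    def to_json_dict(self) -> dict:
        return {
            "root_player": self.root_player,
            "nodes": [
                {"id": n.id, "player": n.player, "move": n.move,
                 "children": list(n.children)}
                for n in self.nodes.values()
            ],
            "leaf_values": dict(self.leaf_values),
            "edge_weights": {f"{a}->{b}": w for (a, b), w in self.edge_weights.items()},
        }

    @classmethod
    def from_json_dict(cls, payload: dict) -> "GameTree":
        nodes = {
            d["id"]: TreeNode(id=d["id"], player=d["player"], move=d.get("move", d["id"]),
                              children=tuple(d.get("children", ())))
            for d in payload["nodes"]
        }
        weights = {}
        for key, w in payload.get("edge_weights", {}).items():
            parent, _, child = key.partition("->")
            weights[(parent, child)] = float(w)
        return cls(root_player=payload["root_player"], nodes=nodes,
                   leaf_values={k: float(v) for k, v in payload.get("leaf_values", {}).items()},
                   edge_weights=weights)


def validate_tree(tree: GameTree) -> GameTree:
    """Verify every structural invariant, returning the tree unchanged.

    Raises :class:`StructuralError` (naming the offending node) on:
    unknown child ids, multiple parents or cycles, a leaf base move
    (no opponent ply), non-alternating players, a missing edge weight,
    or a leaf without a value.
    """
    if not tree.nodes:
        raise StructuralError("tree has no nodes")
    graph = nx.DiGraph()
    graph.add_nodes_from(tree.nodes)
    for node in tree.nodes.values():
        for child in node.children:
            if child not in tree.nodes:
                raise StructuralError("unknown child id", child)
            graph.add_edge(node.id, child)
    if not nx.is_directed_acyclic_graph(graph):
        cycle_node = next(iter(nx.find_cycle(graph)))[0]
        raise StructuralError("tree contains a cycle", cycle_node)
    for node_id in tree.nodes:
        if graph.in_degree(node_id) > 1:
            raise StructuralError("node has multiple parents", node_id)
    if not tree.base_moves:
        raise StructuralError("tree has no parentless base moves")
    opponents = set()
    for base in tree.base_moves:
        if tree.nodes[base].player != tree.root_player:
            raise StructuralError("base move does not belong to the root player", base)
        if tree.is_leaf(base):
            raise StructuralError("base move has no opponent ply below it", base)
    for node in tree.nodes.values():
        for child in node.children:
            if tree.nodes[child].player == node.player:
                raise StructuralError("consecutive moves by the same player", child)
            if (node.id, child) not in tree.edge_weights:
                raise StructuralError("missing edge weight", child)
        if node.player != tree.root_player:
            opponents.add(node.player)
    if len(opponents) > 1:
        raise StructuralError(f"more than one opponent: {sorted(opponents)}")
    for node_id, node in tree.nodes.items():
        if not node.children and node_id not in tree.leaf_values:
            raise StructuralError("leaf has no value", node_id)
        if node.children and node_id in tree.leaf_values:
            raise StructuralError("internal node carries a leaf value", node_id)
    return tree


@dataclass(frozen=True)
class ToMModel:
    """A game tree plus the dynamical/choice parameters of both players.

    ``noise`` and ``beta`` may be scalars (shared) or ``{player: value}``
    mappings.  ``state_gain`` is an optional self-decay lambda <= 0 on
    every activity (0 = pure integrator).  ``coupling`` optionally makes
    leaf payoffs depend on the root player's own choice probabilities:
    ``{leaf_id: {"const": c, base_move_id: coef, ...}}`` means the leaf's
    effective value is ``c + sum coef * p(base move)``; this is what
    turns the strictly hierarchical recursion into a genuine fixed-point
    problem.
    """

    tree: GameTree
    noise: float | dict[str, float] = 1.0
    beta: float | dict[str, float] = 1.0
    decision_threshold: float = 1.0
    state_gain: float = 0.0
    coupling: dict[str, dict[str, float]] | None = None

    def __post_init__(self):
        betas = self.beta.values() if isinstance(self.beta, dict) else [self.beta]
        if any(not (float(v) > 0) for v in betas):
            raise InvalidParameterError("beta must be positive")
        noises = self.noise.values() if isinstance(self.noise, dict) else [self.noise]
        # noise 0 is the deterministic cascade limit, used by analytic checks
        if any(float(v) < 0 for v in noises):
            raise InvalidParameterError("noise must be >= 0")
        if not (float(self.decision_threshold) > 0):
            raise InvalidParameterError("decision_threshold must be positive")
        if float(self.state_gain) > 0:
            raise InvalidParameterError("state_gain must be <= 0")

    def player_noise(self, player: str) -> float:
        return float(self.noise[player] if isinstance(self.noise, dict) else self.noise)

    def player_beta(self, player: str) -> float:
        return float(self.beta[player] if isinstance(self.beta, dict) else self.beta)


def _affine_system(model: ToMModel):
    """(node order, W, b, sigma) of the activity SDE dX = (WX + b) dt + ...

    W collects internal-child weights plus the self-decay on the
    diagonal; b collects the weight-scaled payoffs of leaf children.
    """
    tree = model.tree
    order = tree.internal_ids()
    index = {nid: i for i, nid in enumerate(order)}
    n = len(order)
    W = np.zeros((n, n))
    b = np.zeros(n)
    sigma = np.zeros(n)
    for nid in order:
        i = index[nid]
        sigma[i] = model.player_noise(tree.nodes[nid].player)
        W[i, i] += model.state_gain
        for child in tree.children(nid):
            w = tree.edge_weights[(nid, child)]
            if tree.is_leaf(child):
                b[i] += w * tree.leaf_values[child]
            else:
                W[i, index[child]] += w
    return order, W, b, sigma


def simulate_tom_dynamics(model: ToMModel, dt: float = sde_core.DEFAULT_DT,
                          horizon: float = 1.0, seed: int = 0) -> sde_core.Trajectory:
    """Integrate the coupled activity SDEs for every non-leaf node.

    The drift (affine in the activities) is advanced with an explicit
    trapezoidal (Heun) stage, which integrates the noise-free cascade of
    a two-ply tree exactly; the additive noise enters as independent
    Gaussian increments, one stream per node keyed on the node's
    breadth-first index.  Returns a :class:`~expertsde.sde_core.Trajectory`
    whose columns follow ``GameTree.internal_ids()`` order.
    """
    validate_tree(model.tree)
    order, W, b, sigma = _affine_system(model)
    n_steps = sde_core._check_grid(dt, horizon)
    rngs = [sde_core._rng(seed, j) for j in range(len(order))]
    times = np.arange(n_steps + 1) * dt
    states = np.zeros((n_steps + 1, len(order)))
    x = states[0].copy()
    sqdt = math.sqrt(dt)
    for step in range(1, n_steps + 1):
        f0 = W @ x + b
        f1 = W @ (x + f0 * dt) + b
        x = x + 0.5 * dt * (f0 + f1)
        for j, rng in enumerate(rngs):
            if sigma[j] > 0:
                x[j] += sigma[j] * sqdt * rng.standard_normal()
        states[step] = x
    return sde_core.Trajectory(times=times, states=states, seed=int(seed),
                               dt=float(dt), labels=tuple(order))


def batch_decisions(model: ToMModel, dt: float = sde_core.DEFAULT_DT,
                    horizon: float = 10.0, n_trials: int = 1,
                    seed: int = 0) -> sde_core.BatchFirstPassage:
    """Threshold decisions over many trials, vectorized.

    A trial commits to the first base move whose |activity| reaches the
    decision threshold (checked at step endpoints); simultaneous
    crossings go to the larger |overshoot|, exact ties to the lowest
    base-move index.  Trials with no crossing by the horizon are
    censored.
    """
    validate_tree(model.tree)
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    order, W, b, sigma = _affine_system(model)
    base = list(model.tree.base_moves)
    base_idx = np.array([order.index(bm) for bm in base])
    n_steps = sde_core._check_grid(dt, horizon)
    rngs = [sde_core._rng(seed, j) for j in range(len(order))]
    sqdt = math.sqrt(dt)
    thr = float(model.decision_threshold)

    winners = np.full(n_trials, -1, dtype=np.int64)
    times = np.full(n_trials, float(n_steps * dt))
    censored = np.ones(n_trials, dtype=bool)

    x = np.zeros((n_trials, len(order)))
    active = np.arange(n_trials)
    WT = W.T
    for step in range(1, n_steps + 1):
        if active.size == 0:
            break
        f0 = x @ WT + b
        f1 = (x + f0 * dt) @ WT + b
        x = x + 0.5 * dt * (f0 + f1)
        for j, rng in enumerate(rngs):
            if sigma[j] > 0:
                x[:, j] += sigma[j] * sqdt * rng.standard_normal(active.size)
        mag = np.abs(x[:, base_idx])
        crossed = mag >= thr
        done = crossed.any(axis=1)
        if done.any():
            overshoot = np.where(crossed, mag, -np.inf)
            champ = np.argmax(overshoot, axis=1)
            idx = active[done]
            winners[idx] = champ[done]
            times[idx] = step * dt
            censored[idx] = False
            keep = ~done
            active = active[keep]
            x = x[keep]
    return sde_core.BatchFirstPassage(winners=winners, crossing_times=times,
                                      censored=censored, winner_labels=tuple(base))


def decide_by_threshold(model: ToMModel, dt: float = sde_core.DEFAULT_DT,
                        horizon: float = 10.0, seed: int = 0) -> sde_core.FirstPassageResult:
    """Single-trial threshold decision over the base moves."""
    batch = batch_decisions(model, dt=dt, horizon=horizon, n_trials=1, seed=seed)
    if batch.censored[0]:
        return sde_core.FirstPassageResult(None, float(batch.crossing_times[0]),
                                           math.nan, True)
    code = int(batch.winners[0])
    return sde_core.FirstPassageResult(batch.winner_labels[code],
                                       float(batch.crossing_times[0]),
                                       float(model.decision_threshold), False)


def _backward_sweep(model: ToMModel, leaf_values: dict[str, float]):
    """One bottom-up pass: valuations f and softmax distributions.

    Returns (root ChoiceDistribution, {internal node id: ChoiceDistribution
    over its internal children}, {node id: f}).  Leaf children contribute
    weight * value directly; internal children contribute
    weight * probability * valuation, with the sibling softmax taken at
    the children's player's beta.
    """
    tree = model.tree
    f_cache: dict[str, float] = {}
    conditionals: dict[str, ChoiceDistribution] = {}

    def group_distribution(parent: str, internal_children: list[str]) -> np.ndarray:
        player = tree.nodes[internal_children[0]].player
        beta = model.player_beta(player)
        logits = beta * np.array([f_cache[c] for c in internal_children])
        return _stable_softmax(logits)

    def valuation(node_id: str) -> float:
        if tree.is_leaf(node_id):
            return leaf_values[node_id]
        internal = [c for c in tree.children(node_id) if not tree.is_leaf(c)]
        total = 0.0
        for child in tree.children(node_id):
            if tree.is_leaf(child):
                total += tree.edge_weights[(node_id, child)] * leaf_values[child]
        if internal:
            for child in internal:
                f_cache[child] = valuation(child)
            probs = group_distribution(node_id, internal)
            conditionals[node_id] = ChoiceDistribution(tuple(internal), probs)
            for child, p in zip(internal, probs):
                total += tree.edge_weights[(node_id, child)] * p * f_cache[child]
        return total

    base = list(tree.base_moves)
    for bm in base:
        f_cache[bm] = valuation(bm)
    beta_root = model.player_beta(tree.root_player)
    root_probs = _stable_softmax(beta_root * np.array([f_cache[bm] for bm in base]))
    root = ChoiceDistribution(tuple(base), root_probs)
    return root, conditionals, f_cache


def choice_distribution(model: ToMModel) -> ChoiceDistribution:
    """Softmax choice probabilities over the root player's base moves.

    Computed by backward propagation of valuations through the tree with
    the leaf payoffs taken at face value (no coupling): each player's
    valuation of a move is the probability-weighted, weight-scaled
    valuation of the opponent's replies beneath it.
    """
    validate_tree(model.tree)
    root, _, _ = _backward_sweep(model, dict(model.tree.leaf_values))
    return root


@dataclass(frozen=True)
class EquilibriumResult:
    """A mutually consistent pair of choice systems.

    ``root`` is the root player's distribution over base moves;
    ``conditionals`` the opponent's distribution over internal replies at
    each internal node.  ``residual`` is the max-norm change under one
    more application of the coupled softmax map (direct substitution),
    ``multistart_agreement`` whether 5 random initializations landed on
    the same fixed point to within 10x the tolerance.
    """

    root: ChoiceDistribution
    conditionals: dict[str, ChoiceDistribution]
    residual: float
    iterations: int
    multistart_agreement: bool
    converged: bool = True


def _coupled_leaf_values(model: ToMModel, root_probs: dict[str, float]) -> dict[str, float]:
    values = dict(model.tree.leaf_values)
    for leaf, terms in (model.coupling or {}).items():
        v = 0.0
        for key, coef in terms.items():
            v += coef if key == "const" else coef * root_probs[key]
        values[leaf] = v
    return values


def coupled_map(model: ToMModel, root_probs: dict[str, float]) -> ChoiceDistribution:
    """One application of the coupled softmax map F.

    Resolves any coupled leaf payoffs at the supplied root probabilities,
    then runs the backward sweep; the fixed point of this map is the
    equilibrium, so ``max |p - coupled_map(model, p)|`` is the direct
    substitution residual of a candidate solution ``p``.
    """
    root, _, _ = _backward_sweep(model, _coupled_leaf_values(model, root_probs))
    return root


def solve_equilibrium(model: ToMModel, tolerance: float = 1e-10,
                      max_iterations: int = 10_000, damping: float = 0.5,
                      n_starts: int = 5, seed: int = 0) -> EquilibriumResult:
    """Fixed point of the coupled softmax systems of the two players.

    Without coupling the backward recursion is strictly hierarchical and
    the map does not depend on its input, so the exact solution is
    returned in one iteration and equals :func:`choice_distribution`.
    With coupling, a damped fixed-point iteration is run from the
    uniform start until the direct-substitution residual
    ``max |p - F(p)|`` falls below ``tolerance``; ``n_starts`` additional
    random initializations check uniqueness of the attractor.
    """
    validate_tree(model.tree)
    base = list(model.tree.base_moves)

    def step_map(root_probs: dict[str, float]):
        leaves = _coupled_leaf_values(model, root_probs)
        return _backward_sweep(model, leaves)

    if not model.coupling:
        root, conditionals, _ = step_map({})
        return EquilibriumResult(root=root, conditionals=conditionals,
                                 residual=0.0, iterations=1,
                                 multistart_agreement=True)

    def iterate(p0: np.ndarray):
        p = p0
        for iteration in range(1, max_iterations + 1):
            root, conditionals, _ = step_map(dict(zip(base, p)))
            q = root.probabilities
            residual = float(np.max(np.abs(q - p)))
            if residual < tolerance:
                return root, conditionals, residual, iteration
            p = (1.0 - damping) * p + damping * q
        raise ConvergenceError(
            f"no fixed point after {max_iterations} iterations", residual)

    uniform = np.full(len(base), 1.0 / len(base))
    root, conditionals, residual, iterations = iterate(uniform)

    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(97,)))
    agreement = True
    for _ in range(n_starts):
        start = rng.dirichlet(np.ones(len(base)))
        other_root, _, _, _ = iterate(start)
        if np.max(np.abs(other_root.probabilities - root.probabilities)) > 10 * tolerance:
            agreement = False
    return EquilibriumResult(root=root, conditionals=conditionals,
                             residual=residual, iterations=iterations,
                             multistart_agreement=agreement)
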