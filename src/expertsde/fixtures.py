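"""Fully specified synthetic model instances for every module.

No external data is needed anywhere in the package: the canonical
two-ply chess scenario (Black weighing Knight-to-f6 against pawn-to-d6,
each answered by two White replies, each of those answered by the same
two Black continuations) is encoded symbolically here, and
:func:`random_scenario` draws seed-deterministic instances of any model
family with parameters sampled uniformly from configurable ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .categorization import CategoryEnsemble
from .errors import InvalidParameterError
from .sde_core import AccumulatorSpec
from .strategic_tom import GameTree, ToMModel, TreeNode, validate_tree

__all__ = ["ScenarioSpec", "chess_scenario_tree", "random_scenario"]

_KINDS = ("ddm", "race", "ou", "categorization", "tom")

#: Default sampling ranges.  Drifts and weights are kept small enough
#: that beta * drift stays within roughly +-10, so softmax choice
#: probabilities do not saturate to 0/1 in generated test scenarios.
_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "drift": (-1.0, 1.0),
    "diffusion": (0.5, 1.5),
    "state_gain": (-2.0, -0.2),
    "boundary": (0.5, 2.0),
    "weight": (0.2, 1.5),
    "leaf_value": (-1.0, 1.0),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """What to generate: a model family, its size, and parameter ranges."""

    kind: str
    k: int = 2                 # categories (categorization) / accumulators (race)
    branching: int = 2         # children per node (tom)
    depth: int = 2             # plies below the root choice (tom)
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidParameterError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        minima = {"ddm": 1, "ou": 1, "race": 2, "categorization": 2, "tom": 2}
        if self.k < minima.get(self.kind, 1):
            raise InvalidParameterError(f"k={self.k} too small for kind {self.kind!r}")
        if self.kind == "tom" and (self.branching < 1 or self.depth < 2):
            raise InvalidParameterError("tom scenarios need branching >= 1 and depth >= 2")
        merged = dict(_DEFAULT_RANGES)
        for key, (low, high) in self.ranges.items():
            if key not in merged:
                raise InvalidParameterError(f"unknown range {key!r}")
            if not (float(low) <= float(high)):
                raise InvalidParameterError(f"range {key!r} has min > max")
            merged[key] = (float(low), float(high))
        object.__setattr__(self, "ranges", merged)


def chess_scenario_tree(edge_weights: dict[tuple[str, str], float] | None = None,
                 leaf_values: dict[str, float] | None = None) -> GameTree:
    """The canonical two-ply, binary-branching chess scenario.

    Black chooses between the base moves Nf6 and d6.  White answers Nf6
    with Ng5 or Nc3, and d6 with c3 or h3.  Below every White reply
    Black's continuations are the same two moves, d5 and Bc5 (their
    appeal to White, however, depends on which reply White is
    considering, which is why each leaf carries its own edge weight).
    All weights and leaf values default to 1; pass ``edge_weights`` /
    ``leaf_values`` overrides keyed like the defaults to break the
    symmetry.
    """
    nodes: dict[str, TreeNode] = {}
    weights: dict[tuple[str, str], float] = {}
    values: dict[str, float] = {}

    replies = {"Nf6": ("Ng5", "Nc3"), "d6": ("c3", "h3")}
    for base, white_moves in replies.items():
        reply_ids = tuple(f"{base}/{w}" for w in white_moves)
        nodes[base] = TreeNode(id=base, player="Black", move=base, children=reply_ids)
        for reply_id, white_move in zip(reply_ids, white_moves):
            leaf_ids = tuple(f"{reply_id}/{m}" for m in ("d5", "Bc5"))
            nodes[reply_id] = TreeNode(id=reply_id, player="White",
                                       move=white_move, children=leaf_ids)
            weights[(base, reply_id)] = 1.0
            for leaf_id, black_move in zip(leaf_ids, ("d5", "Bc5")):
                nodes[leaf_id] = TreeNode(id=leaf_id, player="Black", move=black_move)
                weights[(reply_id, leaf_id)] = 1.0
                values[leaf_id] = 1.0

    if edge_weights:
        for key, w in edge_weights.items():
            if key not in weights:
                raise InvalidParameterError(f"unknown edge {key!r}")
            weights[key] = float(w)
    if leaf_values:
        for key, v in leaf_values.items():
            if key not in values:
                raise InvalidParameterError(f"unknown leaf {key!r}")
            values[key] = float(v)

    return validate_tree(GameTree(root_player="Black", nodes=nodes,
                                  leaf_values=values, edge_weights=weights,
                                  base_moves=("Nf6", "d6")))


def _uniform(rng: np.random.Generator, rg: tuple[float, float], size=None):
    low, high = rg
    if low == high:
        return low if size is None else np.full(size, low)
    return rng.uniform(low, high, size=size)


def _random_accumulator(rng: np.random.Generator, ranges, state_gain_range=None) -> AccumulatorSpec:
    upper = float(_uniform(rng, ranges["boundary"]))
    lower = -float(_uniform(rng, ranges["boundary"]))
    return AccumulatorSpec(
        drift=float(_uniform(rng, ranges["drift"])),
        diffusion=float(_uniform(rng, ranges["diffusion"])),
        state_gain=float(_uniform(rng, state_gain_range)) if state_gain_range else 0.0,
        upper_boundary=upper,
        lower_boundary=lower,
        initial_state=0.0,
    )


def _random_tree(rng: np.random.Generator, spec: ScenarioSpec) -> GameTree:
    ranges = spec.ranges
    players = ("Black", "White")
    nodes: dict[str, TreeNode] = {}
    weights: dict[tuple[str, str], float] = {}
    values: dict[str, float] = {}

    def grow(parent_id: str | None, prefix: str, depth: int) -> str:
        player = players[depth % 2]
        node_id = prefix
        if depth == spec.depth:
            nodes[node_id] = TreeNode(id=node_id, player=player, move=prefix)
            values[node_id] = float(_uniform(rng, ranges["leaf_value"]))
        else:
            children = tuple(f"{prefix}/{j}" for j in range(spec.branching))
            nodes[node_id] = TreeNode(id=node_id, player=player, move=prefix,
                                      children=children)
            for child in children:
                grow(node_id, child, depth + 1)
                weights[(node_id, child)] = float(_uniform(rng, ranges["weight"]))
        return node_id

    base = tuple(grow(None, f"m{i}", 0) for i in range(spec.k))
    return validate_tree(GameTree(root_player="Black", nodes=nodes,
                                  leaf_values=values, edge_weights=weights,
                                  base_moves=base))


def random_scenario(spec: ScenarioSpec):
    """Seed-deterministic model instance of the requested kind.

    Returns an :class:`AccumulatorSpec` (``ddm``/``ou``), a list of them
    (``race``), a :class:`CategoryEnsemble` (``categorization``) or a
    :class:`ToMModel` (``tom``).  Every instance passes its module's
    validation by construction.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(int(spec.seed), spawn_key=(_KINDS.index(spec.kind),)))
    ranges = spec.ranges
    if spec.kind == "ddm":
        return _random_accumulator(rng, ranges)
    if spec.kind == "ou":
        return _random_accumulator(rng, ranges, state_gain_range=ranges["state_gain"])
    if spec.kind == "race":
        return [_random_accumulator(rng, ranges) for _ in range(spec.k)]
    if spec.kind == "categorization":
        z = float(_uniform(rng, ranges["boundary"]))
        sigma = float(_uniform(rng, ranges["diffusion"]))
        drifts = _uniform(rng, ranges["drift"], size=spec.k)
        labels = tuple(f"cat{i}" for i in range(spec.k))
        return CategoryEnsemble(labels=labels, net_drifts=np.asarray(drifts),
                                threshold=z, diffusion=sigma)
    if spec.kind == "tom":
        tree = _random_tree(rng, spec)
        return ToMModel(tree=tree,
                        noise=float(_uniform(rng, ranges["diffusion"])),
                        beta=2.0,
                        decision_threshold=float(_uniform(rng, ranges["boundary"])) + 0.5)
    raise InvalidParameterError(f"unknown kind {spec.kind!r}")  # pragma: no cover
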