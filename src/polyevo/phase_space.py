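"""Exact outcome frequencies of nondeterministic assembly via decision trees.

Every stochastic assembly is a walk down a decision tree whose nodes are
partial assemblies and whose branches are feasible next bindings.  A branch
carrying interaction strength ``s`` with multiplicity ``m`` (the number of
indistinguishable attempts realising it) is taken with probability

    w = m * s**T / sum_j m_j * s_j**T

i.e. each step's weight is the strength-derived binding probability
normalised by all possible step strengths (with the temperature exponent
``T``; at ``T = 1`` the weights are the raw strengths themselves).  Outcome
frequencies therefore depend only on ratios of competing interaction
strengths, never on their absolute scale.  Nodes are merged when partial
assemblies coincide (the tree is really a DAG) and subtrees whose every leaf
carries the same outcome are collapsed, which keeps the computation exact
while pruning the exponential branching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from polyevo.interfaces import ModelParams
from polyevo.genotypes import AssemblyGraph
from polyevo.assembly import UNBOUND, Polyomino, canonicalize, DEFAULT_SIZE_CAP

__all__ = ["DecisionTree", "build_tree", "outcome_frequencies",
           "PhaseSpacePoint", "PhaseMap", "phase_map"]

_DIRS = ((0, 1), (1, 0), (0, -1), (-1, 0))


@dataclass
class _Node:
    branches: list = field(default_factory=list)  # (edge_id, multiplicity, child_id)
    outcome: object = None                        # leaf payload (Polyomino | UNBOUND)


@dataclass
class DecisionTree:
    """Seed-rooted assembly decision DAG for one assembly graph.

    ``nodes[i]`` is either a leaf (``outcome`` set) or an internal node with
    branches ``(edge_id, multiplicity, child)``; ``roots`` maps each seed
    tile type to its root node.
    """

    graph: AssemblyGraph
    nodes: list
    roots: dict
    size_cap: int

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def outcomes(self) -> set:
        return {n.outcome for n in self.nodes if n.outcome is not None}


def _partner_entries(graph: AssemblyGraph):
    """site -> list of (partner_type, partner_face, edge_id)."""
    table: dict[int, list[tuple[int, int, int]]] = {}
    for i, (u, v, _) in enumerate(graph.edges):
        table.setdefault(u.flat, []).append((v.tile, int(v.face), i))
        if v.flat != u.flat:
            table.setdefault(v.flat, []).append((u.tile, int(u.face), i))
    return table


def build_tree(
    graph: AssemblyGraph,
    params: ModelParams | None = None,
    size_cap: int = DEFAULT_SIZE_CAP,
    node_budget: int = 500_000,
) -> DecisionTree:
    """Enumerate the full decision DAG of an assembly graph.

    All seeds are enumerated as starting points; distinguishable next
    bindings at a node are grouped by (cell, tile, orientation, interaction)
    with their multiplicity.  States are memoized up to translation, and
    outcome-forced subtrees are collapsed into leaves.  Raises RuntimeError
    when the node budget is exceeded.
    """
    table = _partner_entries(graph)
    nodes: list[_Node] = []
    memo: dict = {}

    def state_key(tiles):
        minx = min(t[0] for t in tiles)
        miny = min(t[1] for t in tiles)
        return frozenset((x - minx, y - miny, tt, rr) for x, y, tt, rr in tiles)

    def expand(tiles, occupied) -> int:
        key = state_key(tiles)
        if key in memo:
            return memo[key]
        if len(nodes) > node_budget:
            raise RuntimeError(
                f"decision tree exceeded node budget ({node_budget} nodes, "
                f"{len(tiles)}-tile state)")
        node_id = len(nodes)
        nodes.append(_Node())
        memo[key] = node_id

        attempts: dict[tuple, int] = {}
        for x, y, ttype, rot in tiles:
            for d, (dx, dy) in enumerate(_DIRS):
                cell = (x + dx, y + dy)
                if cell in occupied:
                    continue
                face = (d - rot) % 4
                for pt, pf, eid in table.get(ttype * 4 + face, ()):
                    k = (cell, pt, (d + 2 - pf) % 4, eid)
                    attempts[k] = attempts.get(k, 0) + 1
        if not attempts:
            nodes[node_id].outcome = canonicalize(
                [(x, y, t) for x, y, t, _ in tiles], n_types=graph.n_tiles)
            return node_id
        if len(tiles) >= size_cap:
            nodes[node_id].outcome = UNBOUND
            return node_id
        for (cell, pt, pr, eid), mult in sorted(attempts.items()):
            child_tiles = tiles + [(cell[0], cell[1], pt, pr)]
            child_occ = occupied | {cell}
            child = expand(child_tiles, child_occ)
            nodes[node_id].branches.append((eid, mult, child))
        return node_id

    roots = {}
    for seed in range(graph.n_tiles):
        roots[seed] = expand([(0, 0, seed, 0)], {(0, 0)})

    _collapse_forced(nodes)
    return DecisionTree(graph=graph, nodes=nodes, roots=roots, size_cap=size_cap)


def _collapse_forced(nodes: list[_Node]) -> None:
    """Turn nodes whose every reachable leaf shares one outcome into leaves."""
    reach: list[set | None] = [None] * len(nodes)

    def visit(i: int) -> set:
        if reach[i] is not None:
            return reach[i]
        node = nodes[i]
        if node.outcome is not None:
            reach[i] = {node.outcome}
        else:
            out: set = set()
            reach[i] = out
            for _, _, child in node.branches:
                out |= visit(child)
        return reach[i]

    for i in range(len(nodes)):
        visit(i)
    for i, node in enumerate(nodes):
        if node.outcome is None and len(reach[i]) == 1:
            node.outcome = next(iter(reach[i]))
            node.branches = []


def outcome_frequencies(
    tree: DecisionTree,
    strengths: Sequence[float] | Mapping | None = None,
    params: ModelParams | None = None,
    weight_exponent: float | None = None,
) -> dict:
    """Exact outcome distribution of a decision tree, seed-averaged.

    ``strengths`` overrides the graph's edge strengths (a sequence in edge
    order); the branch weight exponent defaults to the temperature ``T``.
    """
    params = ModelParams() if params is None else params
    expo = params.T if weight_exponent is None else weight_exponent
    if strengths is None:
        strengths = tree.graph.strengths
    elif isinstance(strengths, Mapping):
        strengths = [strengths.get((u, v), s) for u, v, s in tree.graph.edges]
    strengths = np.asarray(strengths, dtype=float)
    w_edge = strengths ** expo

    dist_cache: dict[int, dict] = {}

    def dist(i: int) -> dict:
        got = dist_cache.get(i)
        if got is not None:
            return got
        node = tree.nodes[i]
        if node.outcome is not None:
            out = {node.outcome: 1.0}
        else:
            weights = np.array([m * w_edge[e] for e, m, _ in node.branches])
            weights = weights / weights.sum()
            out = {}
            for (e, m, child), w in zip(node.branches, weights):
                for o, p in dist(child).items():
                    out[o] = out.get(o, 0.0) + w * p
        dist_cache[i] = out
        return out

    total: dict = {}
    n_seeds = len(tree.roots)
    for seed, root in tree.roots.items():
        for o, p in dist(root).items():
            total[o] = total.get(o, 0.0) + p / n_seeds
    return total


@dataclass(frozen=True)
class PhaseSpacePoint:
    """One grid point: strength ratios and the exact outcome frequencies."""

    coords: tuple[float, ...]
    strengths: tuple[float, ...]
    frequencies: dict


@dataclass
class PhaseMap:
    """Outcome frequencies across a grid of interaction-strength ratios."""

    points: list[PhaseSpacePoint]
    focal: object
    argmax: PhaseSpacePoint
    misassembly: list[PhaseSpacePoint]

    def to_tsv(self, path) -> None:
        outcomes = sorted({o for p in self.points for o in p.frequencies},
                          key=lambda o: (o is UNBOUND, getattr(o, "cells", ())))
        names = ["UNBOUND" if o is UNBOUND else f"mer{o.size}_{i}"
                 for i, o in enumerate(outcomes)]
        with open(path, "w") as fh:
            ncoord = len(self.points[0].coords) if self.points else 0
            head = [f"ratio{i+1}" for i in range(ncoord)] + names
            fh.write("\t".join(head) + "\n")
            for p in self.points:
                row = [f"{c:.6g}" for c in p.coords]
                row += [f"{p.frequencies.get(o, 0.0):.6g}" for o in outcomes]
                fh.write("\t".join(row) + "\n")


def phase_map(
    graph: AssemblyGraph,
    grid: Sequence[Sequence[float]],
    params: ModelParams | None = None,
    focal: Polyomino | None = None,
    size_cap: int = DEFAULT_SIZE_CAP,
) -> PhaseMap:
    """Exact outcome frequencies across a grid of strength-ratio points.

    Each grid point is a tuple of relative strengths (one per edge); since
    frequencies depend only on ratios, every point is rescaled so its
    largest entry is 1.  Coordinates are reported as ratios to the last
    edge's strength.  ``focal`` (default: the modal outcome at equal
    strengths) defines the misassembly region: points where some other
    bounded outcome is more frequent than the focal one.
    """
    params = ModelParams() if params is None else params
    n_edges = graph.n_interactions
    if n_edges == 0:
        raise ValueError("phase map needs at least one interaction")
    tree = build_tree(graph, params, size_cap=size_cap)
    if focal is None:
        eq = outcome_frequencies(tree, [1.0] * n_edges, params)
        bounded = {o: p for o, p in eq.items() if o is not UNBOUND}
        focal = max(bounded, key=bounded.get)
    points = []
    for rel in grid:
        rel = np.asarray(rel, dtype=float)
        if rel.shape != (n_edges,) or np.any(rel <= 0):
            raise ValueError("each grid point needs one positive entry per edge")
        s = rel / rel.max()
        freqs = outcome_frequencies(tree, s, params)
        coords = tuple(float(r) for r in (rel / rel[-1])[:-1])
        points.append(PhaseSpacePoint(coords=coords, strengths=tuple(s),
                                      frequencies=freqs))
    argmax = max(points, key=lambda p: p.frequencies.get(focal, 0.0))
    mis = [p for p in points
           if max((v for o, v in p.frequencies.items()
                   if o is not UNBOUND and o != focal), default=0.0)
           > p.frequencies.get(focal, 0.0)]
    return PhaseMap(points=points, focal=focal, argmax=argmax, misassembly=mis)
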