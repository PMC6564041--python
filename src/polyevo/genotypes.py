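"""Genotypes, assembly graphs, and forging of fixture genotypes.

A genotype is an ordered list of tiles, each tile carrying four interface
strings in clockwise face order (top, right, bottom, left).  The genotype's
*assembly graph* has one edge for every unordered pair of binding sites
(including a site paired with itself) whose interaction strength meets the
critical strength.  The assembly process depends only on this graph, so the
graph is the natural unit for phase-space analysis and fixture construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from polyevo.interfaces import (
    InterfaceString,
    ModelParams,
    hamming_reversed,
    mutate_bits,
)

__all__ = [
    "Face",
    "SiteId",
    "Genotype",
    "AssemblyGraph",
    "EdgeTopology",
    "extract_assembly_graph",
    "classify_topology",
    "forge_genotype",
    "enumerate_two_tile_topologies",
    "TopologyClass",
    "read_genotypes",
    "write_genotypes",
]

_EPS = 1e-9


class Face(IntEnum):
    TOP = 0
    RIGHT = 1
    BOTTOM = 2
    LEFT = 3


class SiteId(NamedTuple):
    """A binding site: a 0-based tile index and a face."""

    tile: int
    face: Face

    @property
    def flat(self) -> int:
        return self.tile * 4 + int(self.face)


def _site_from_flat(flat: int) -> SiteId:
    return SiteId(flat // 4, Face(flat % 4))


class Genotype:
    """Ordered tiles x 4 clockwise interface strings.

    Backed by a ``(n_tiles, 4, L_I)`` uint8 bit array; value semantics.
    """

    __slots__ = ("_bits",)

    def __init__(self, bits: np.ndarray | Sequence[Sequence[InterfaceString]]):
        if isinstance(bits, np.ndarray):
            arr = np.asarray(bits, dtype=np.uint8)
        else:
            arr = np.array(
                [[np.asarray(f.bits if isinstance(f, InterfaceString) else f, dtype=np.uint8)
                  for f in tile] for tile in bits],
                dtype=np.uint8,
            )
        if arr.ndim != 3 or arr.shape[1] != 4:
            raise ValueError("genotype bits must have shape (n_tiles, 4, L_I)")
        if np.any(arr > 1):
            raise ValueError("genotype bits must be 0/1")
        arr = arr.copy()
        arr.setflags(write=False)
        self._bits = arr

    @property
    def bits(self) -> np.ndarray:
        return self._bits

    @property
    def n_tiles(self) -> int:
        return self._bits.shape[0]

    @property
    def L_I(self) -> int:
        return self._bits.shape[2]

    def face(self, site: SiteId) -> InterfaceString:
        return InterfaceString(self._bits[site.tile, int(site.face)])

    def site_bits(self, site: SiteId) -> np.ndarray:
        return self._bits[site.tile, int(site.face)]

    def mutate(self, per_bit_rate: float, rng: np.random.Generator) -> "Genotype":
        return Genotype(mutate_bits(self._bits, per_bit_rate, rng))

    @classmethod
    def random(cls, params: ModelParams, n_tiles: int = 2,
               rng: np.random.Generator | None = None) -> "Genotype":
        rng = np.random.default_rng() if rng is None else rng
        return cls(rng.integers(0, 2, size=(n_tiles, 4, params.L_I), dtype=np.uint8))

    @classmethod
    def random_interactionless(cls, params: ModelParams, n_tiles: int = 2,
                               rng: np.random.Generator | None = None,
                               max_tries: int = 10_000) -> "Genotype":
        """Uniform random genotype conditioned on an empty assembly graph.

        This is the evolutionary initial condition: random sequences with no
        interactions.
        """
        rng = np.random.default_rng() if rng is None else rng
        for _ in range(max_tries):
            g = cls.random(params, n_tiles, rng)
            if not extract_assembly_graph(g, params).edges:
                return g
        raise RuntimeError("could not sample an interactionless genotype")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return self._bits.shape == other._bits.shape and bool(np.all(self._bits == other._bits))

    def __hash__(self) -> int:
        return hash(self._bits.tobytes())

    def to_line(self, hex_form: bool = False) -> str:
        """One-line text form: tiles joined by '|', faces by ','."""
        tiles = []
        for t in range(self.n_tiles):
            faces = [InterfaceString(self._bits[t, f]) for f in range(4)]
            tiles.append(",".join(f.to_hex() if hex_form else f.to_binary() for f in faces))
        return "|".join(tiles)

    @classmethod
    def from_line(cls, line: str, L_I: int | None = None) -> "Genotype":
        tiles = []
        for tile_text in line.strip().split("|"):
            faces = [InterfaceString(ft.strip(), length=L_I) for ft in tile_text.split(",")]
            if len(faces) != 4:
                raise ValueError(f"each tile needs 4 faces, got {len(faces)}")
            tiles.append(faces)
        lengths = {len(f) for tile in tiles for f in tile}
        if len(lengths) != 1:
            raise ValueError("all interfaces must share one L_I")
        return cls(tiles)

    def __repr__(self) -> str:
        return f"Genotype(n_tiles={self.n_tiles}, L_I={self.L_I})"


def read_genotypes(path, L_I: int | None = None) -> list[Genotype]:
    """Read a genotype file: one genotype per line, '#' comments."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(Genotype.from_line(line, L_I=L_I))
    return out


def write_genotypes(path, genotypes: Iterable[Genotype], hex_form: bool = False,
                    header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for h in header.splitlines():
                fh.write(f"# {h}\n")
        for g in genotypes:
            fh.write(g.to_line(hex_form=hex_form) + "\n")


@dataclass(frozen=True)
class EdgeTopology:
    """Interaction-topology class of one assembly-graph edge.

    ``locality``: whether the two sites live on the same tile type
    (intra-subunit, including self-interactions) or on different tiles
    (inter-subunit).  ``sharing``: whether either endpoint participates in
    other interactions (shared_site) or the pair is unique to this edge.
    """

    locality: str  # "inter_subunit" | "intra_subunit"
    sharing: str   # "unique_sites" | "shared_site"


@dataclass(frozen=True)
class AssemblyGraph:
    """Interaction edges ``(u, v, strength)`` with ``u <= v`` in site order.

    Self-edges (``u == v``) are permitted: a site can interact with a copy
    of itself on another tile instance.
    """

    edges: tuple[tuple[SiteId, SiteId, float], ...]
    n_tiles: int = 2

    def __post_init__(self):
        norm = []
        for u, v, s in self.edges:
            u = SiteId(u[0], Face(u[1]))
            v = SiteId(v[0], Face(v[1]))
            if v.flat < u.flat:
                u, v = v, u
            norm.append((u, v, float(s)))
        norm.sort(key=lambda e: (e[0].flat, e[1].flat))
        object.__setattr__(self, "edges", tuple(norm))

    @property
    def n_interactions(self) -> int:
        """N_I, the edge count entering the fitness term F**N_I."""
        return len(self.edges)

    @property
    def strengths(self) -> tuple[float, ...]:
        return tuple(s for _, _, s in self.edges)

    def with_strengths(self, strengths: Sequence[float]) -> "AssemblyGraph":
        if len(strengths) != len(self.edges):
            raise ValueError("strength vector length must equal edge count")
        return AssemblyGraph(
            tuple((u, v, float(s)) for (u, v, _), s in zip(self.edges, strengths)),
            self.n_tiles,
        )

    @property
    def skeleton(self) -> tuple[tuple[int, int], ...]:
        """Edge set as flat site-index pairs, strengths dropped."""
        return tuple((u.flat, v.flat) for u, v, _ in self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        for t in range(self.n_tiles):
            for f in Face:
                g.add_node(SiteId(t, f))
        for u, v, s in self.edges:
            g.add_edge(u, v, strength=s)
        return g

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("u_tile\tu_face\tv_tile\tv_face\tstrength\n")
            for u, v, s in self.edges:
                fh.write(f"{u.tile}\t{u.face.name.lower()}\t{v.tile}\t{v.face.name.lower()}\t{s:.10g}\n")

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = nx.MultiGraph()
        for t in range(self.n_tiles):
            for f in Face:
                g.add_node(f"{t}:{f.name.lower()}")
        for u, v, s in self.edges:
            g.add_edge(f"{u.tile}:{u.face.name.lower()}",
                       f"{v.tile}:{v.face.name.lower()}", strength=s)
        nx.write_graphml(g, path)


def _all_site_pairs(n_tiles: int) -> list[tuple[SiteId, SiteId]]:
    sites = [SiteId(t, Face(f)) for t in range(n_tiles) for f in range(4)]
    pairs = []
    for i, u in enumerate(sites):
        for v in sites[i:]:
            pairs.append((u, v))
    return pairs


def extract_assembly_graph(g: Genotype, params: ModelParams) -> AssemblyGraph:
    """All site pairs (self-pairs included) interacting at ``S >= S_c``."""
    if g.L_I != params.L_I:
        raise ValueError(f"genotype L_I={g.L_I} does not match params L_I={params.L_I}")
    edges = []
    for u, v in _all_site_pairs(g.n_tiles):
        c = hamming_reversed(g.site_bits(u), g.site_bits(v))
        s = c / params.L_I
        if s >= params.S_c - _EPS:
            edges.append((u, v, s))
    return AssemblyGraph(tuple(edges), g.n_tiles)


def classify_topology(graph: AssemblyGraph) -> dict[tuple[SiteId, SiteId], EdgeTopology]:
    """Per-edge locality (inter/intra-subunit) and site-sharing class."""
    participation: dict[int, int] = {}
    for u, v, _ in graph.edges:
        participation[u.flat] = participation.get(u.flat, 0) + 1
        if v.flat != u.flat:
            participation[v.flat] = participation.get(v.flat, 0) + 1
    out = {}
    for u, v, _ in graph.edges:
        locality = "intra_subunit" if u.tile == v.tile else "inter_subunit"
        shared = participation[u.flat] > 1 or participation[v.flat] > 1
        out[(u, v)] = EdgeTopology(locality, "shared_site" if shared else "unique_sites")
    return out


def _forge_self_site(c: int, L: int, rng: np.random.Generator) -> np.ndarray:
    """A string a with d_H(a, reverse(a)) exactly c (c even, <= 2*(L//2))."""
    half = L // 2
    a = rng.integers(0, 2, size=L, dtype=np.uint8)
    mismatch = np.zeros(half, dtype=bool)
    mismatch[rng.permutation(half)[: c // 2]] = True
    for i in range(half):
        a[L - 1 - i] = (1 - a[i]) if mismatch[i] else a[i]
    return a


def _forge_partner(a: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """A string b with d_H(a, reverse(b)) exactly c."""
    L = a.size
    b = (1 - a)[::-1].astype(np.uint8).copy()  # full mismatch: d_H = L
    flip = rng.permutation(L)[: L - c]
    b[flip] = 1 - b[flip]
    return b


def forge_genotype(
    target_edges: Sequence[tuple[SiteId, SiteId, float]],
    params: ModelParams,
    rng: np.random.Generator | None = None,
    n_tiles: int = 2,
    max_tries: int = 10_000,
) -> Genotype:
    """Construct a genotype whose extracted graph equals ``target_edges`` exactly.

    Strengths must be >= S_c and integral multiples of 1/L_I; self-edges need
    an even strength count.  Each try seeds free sites uniformly, realises
    edges constructively (self-edges first, then edges with one determined
    endpoint), and accepts only if the extracted graph matches the target
    edge set with exact strengths and no extra edges.
    """
    rng = np.random.default_rng() if rng is None else rng
    L = params.L_I
    target = AssemblyGraph(tuple(target_edges), n_tiles)
    for u, v, s in target.edges:
        c = s * L
        if abs(c - round(c)) > 1e-6:
            raise ValueError(f"strength {s} is not an integral count over L_I={L}")
        c = round(c)
        if s < params.S_c - _EPS:
            raise ValueError(f"target strength {s} below critical strength {params.S_c}")
        if u == v and c % 2:
            raise ValueError("self-edges require an even strength count")

    want = {((u.flat, v.flat)): round(s * L) for u, v, s in target.edges}
    for _ in range(max_tries):
        bits = rng.integers(0, 2, size=(n_tiles, 4, L), dtype=np.uint8)
        assigned = set()
        ok = True
        # self-edges first: they fully determine the symmetric structure of a site
        for u, v, s in target.edges:
            if u == v:
                bits[u.tile, int(u.face)] = _forge_self_site(round(s * L), L, rng)
                assigned.add(u.flat)
        # then propagate pair edges, preferring those with a determined endpoint
        pending = [(u, v, round(s * L)) for u, v, s in target.edges if u != v]
        while pending and ok:
            idx = next((i for i, (u, v, _) in enumerate(pending)
                        if u.flat in assigned or v.flat in assigned), 0)
            u, v, c = pending.pop(idx)
            if u.flat in assigned and v.flat in assigned:
                # over-constrained pair: accept only if the draw happens to fit
                ok = hamming_reversed(
                    bits[u.tile, int(u.face)], bits[v.tile, int(v.face)]) == c
            elif v.flat in assigned:
                bits[u.tile, int(u.face)] = _forge_partner(bits[v.tile, int(v.face)], c, rng)
                assigned.add(u.flat)
            else:
                # u may be assigned or a fresh random draw; derive v either way
                bits[v.tile, int(v.face)] = _forge_partner(bits[u.tile, int(u.face)], c, rng)
                assigned.update((u.flat, v.flat))
        if not ok:
            continue
        g = Genotype(bits)
        got = extract_assembly_graph(g, params)
        got_map = {(u.flat, v.flat): round(s * L) for u, v, s in got.edges}
        if got_map == want:
            return g
    raise RuntimeError(
        f"forge_genotype: could not realise target graph in {max_tries} tries "
        "(conflicting constraints on a shared site?)"
    )


# ---------------------------------------------------------------------------
# enumeration of two-tile interaction topologies


@dataclass
class TopologyClass:
    """One symmetry class of a two-tile interaction topology (<= 3 edges).

    ``skeleton`` is the canonical flat-site-pair edge set; classification is
    by repeated stochastic assembly at equal strengths.
    """

    skeleton: tuple[tuple[int, int], ...]
    n_edges: int
    modal_size: int | None          # None when no bounded outcome was seen
    deterministic: bool
    phi: float
    unbound_fraction: float
    outcome_sizes: dict[int, float] = field(default_factory=dict)

    def graph(self, strengths: Sequence[float] | float, n_tiles: int = 2) -> AssemblyGraph:
        if np.isscalar(strengths):
            strengths = [float(strengths)] * self.n_edges
        return AssemblyGraph(
            tuple((_site_from_flat(a), _site_from_flat(b), s)
                  for (a, b), s in zip(self.skeleton, strengths)),
            n_tiles,
        )


def _canonical_skeleton(edges: tuple[tuple[int, int], ...]) -> tuple[tuple[int, int], ...]:
    """Minimal image under tile rotations (x4 each) and tile relabeling."""
    best = None
    for r0, r1, swap in itertools.product(range(4), range(4), (0, 1)):
        rot = (r0, r1)

        def m(flat: int) -> int:
            t, f = divmod(flat, 4)
            t2 = t ^ swap
            return t2 * 4 + ((f + rot[t]) % 4)

        image = tuple(sorted(tuple(sorted((m(a), m(b)))) for a, b in edges))
        if best is None or image < best:
            best = image
    return best


def enumerate_two_tile_topologies(
    params: ModelParams | None = None,
    max_edges: int = 3,
    k: int = 64,
    size_cap: int = 40,
    rng: np.random.Generator | None = None,
) -> list[TopologyClass]:
    """Enumerate two-tile interaction topologies with <= ``max_edges`` edges.

    Topologies are deduplicated up to per-tile face rotation and tile
    relabeling, then classified by ``k`` stochastic assemblies at equal
    strengths (the classification is strength-ratio-free, so any common
    strength value gives the same statistics).
    """
    from polyevo.assembly import phenotype_distribution_from_graph, UNBOUND

    params = ModelParams() if params is None else params
    rng = np.random.default_rng(0) if rng is None else rng
    pairs = [(u.flat, v.flat) for u, v in _all_site_pairs(2)]
    seen: dict[tuple, None] = {}
    classes: list[TopologyClass] = []
    s_equal = max(params.S_c, 0.75)
    for n_edges in range(1, max_edges + 1):
        for combo in itertools.combinations(pairs, n_edges):
            canon = _canonical_skeleton(tuple(combo))
            if canon in seen:
                continue
            seen[canon] = None
            graph = AssemblyGraph(
                tuple((_site_from_flat(a), _site_from_flat(b), s_equal) for a, b in canon),
                2,
            )
            dist = phenotype_distribution_from_graph(graph, params, k=k, rng=rng,
                                                     size_cap=size_cap)
            sizes: dict[int, float] = {}
            unbound = 0.0
            for outcome, n in dist.counts.items():
                if outcome is UNBOUND:
                    unbound += n / k
                else:
                    sizes[outcome.size] = sizes.get(outcome.size, 0.0) + n / k
            modal_size = None if dist.modal in (None, UNBOUND) else dist.modal.size
            classes.append(TopologyClass(
                skeleton=canon,
                n_edges=n_edges,
                modal_size=modal_size,
                deterministic=(dist.phi == 1.0 and unbound == 0.0),
                phi=dist.phi,
                unbound_fraction=unbound,
                outcome_sizes=sizes,
            ))
    return classes
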