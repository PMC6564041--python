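"""Stochastic lattice self-assembly and phenotype distributions.

Assembly grows a structure from a single seed tile.  At every step the set of
*feasible attempts* is enumerated: an attempt is a (placed tile, direction,
partner entry) triple whose abutting interface pair interacts at or above the
critical strength and whose target cell is empty.  The model's uniform
attempt/accept race (each attempt accepted with probability ``H(S-S_c) S**T``)
is realised as one categorical draw per step with weights proportional to
``S**T``: repeated uniform attempts until the first acceptance select each
feasible binding with exactly that probability, so the draw is equivalent and
finite-time.  Accepted bindings are irreversible; a placement needs only its
chosen interface pair, other abutting pairs stay unbonded, and occupied cells
block placements (the source of steric nondeterminism).  Assembly stops when
no feasible attempt remains, or is classified UNBOUND once growth would
exceed the size cap.

Phenotypes are polyominoes with per-cell subunit types, identified up to
translation, rotation, reflection, and relabeling of the subunit types (the
assembly map is independent of the order in which subunits appear in the
genotype).  Tracking subunit composition matters: several competing
assembly outcomes -- e.g. a 2x2 tetramer built from one subunit type versus
the same square with a second type blocking a corner -- share a shape and
differ only in composition.  The phenotype of a genotype is the outcome
appearing most often over repeated assemblies (with either subunit as seed);
monomer outcomes are ignored in this vote as the trivial contribution of
seeding a noninteracting subunit, and unbound outcomes can never be the
phenotype.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from polyevo.interfaces import ModelParams
from polyevo.genotypes import AssemblyGraph, Genotype, extract_assembly_graph
from polyevo import _kernels

__all__ = [
    "Polyomino",
    "UNBOUND",
    "AssemblyOutcome",
    "PhenotypeDistribution",
    "canonicalize",
    "assemble_once",
    "assemble_once_from_graph",
    "phenotype_distribution",
    "phenotype_distribution_from_graph",
    "abundance_survey",
    "DEFAULT_SIZE_CAP",
]

DEFAULT_SIZE_CAP = 64  # four times the largest rewarded phenotype


class _Unbound:
    """Sentinel outcome for growth that exceeds the size cap."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNBOUND"

    @property
    def size(self):
        return None


UNBOUND = _Unbound()


def _transform_cell(x: int, y: int, refl: bool, rot: int) -> tuple[int, int]:
    if refl:
        x = -x
    for _ in range(rot):
        x, y = y, -x
    return x, y


def _canonical_cells(cells, n_types: int) -> tuple[tuple[int, int, int], ...]:
    perms = list(itertools.permutations(range(max(n_types, 1))))
    best = None
    for refl in (False, True):
        for rot in range(4):
            moved = [(_transform_cell(x, y, refl, rot), t) for x, y, t in cells]
            minx = min(c[0][0] for c in moved)
            miny = min(c[0][1] for c in moved)
            for perm in perms:
                img = tuple(sorted((x - minx, y - miny, perm[t]) for (x, y), t in moved))
                if best is None or img < best:
                    best = img
    return best


class Polyomino:
    """A connected set of typed tiles on the lattice, canonicalized.

    The canonical form is the lexicographically minimal sorted ``(x, y, type)``
    list over the 8 rotations/reflections (free-polyomino invariance) and all
    permutations of the tile-type labels, with the minimum corner at (0, 0).
    Untyped input cells are given type 0.
    """

    __slots__ = ("_cells", "_n_types")

    def __init__(self, cells: Iterable[tuple], n_types: int | None = None,
                 _canonical: bool = False):
        norm = []
        for c in cells:
            if len(c) == 2:
                norm.append((int(c[0]), int(c[1]), 0))
            else:
                norm.append((int(c[0]), int(c[1]), int(c[2])))
        if n_types is None:
            n_types = max((t for _, _, t in norm), default=0) + 1
        if _canonical:
            self._cells = tuple(sorted(norm))
        else:
            self._cells = _canonical_cells(norm, n_types)
        self._n_types = n_types

    @property
    def cells(self) -> tuple[tuple[int, int, int], ...]:
        return self._cells

    @property
    def size(self) -> int:
        return len(self._cells)

    def shape(self) -> "Polyomino":
        """The uncoloured (shape-only) canonical form."""
        return Polyomino([(x, y, 0) for x, y, _ in self._cells], n_types=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Polyomino):
            return NotImplemented
        return self._cells == other._cells

    def __hash__(self) -> int:
        return hash(self._cells)

    def __repr__(self) -> str:
        return f"Polyomino(size={self.size})"

    def to_text(self) -> str:
        """Sorted "(x,y,t)" list."""
        return " ".join(f"({x},{y},{t})" for x, y, t in self._cells)

    @classmethod
    def from_text(cls, text: str) -> "Polyomino":
        cells = []
        for tok in text.split():
            parts = tok.strip("()").split(",")
            cells.append(tuple(int(p) for p in parts))
        return cls(cells)

    def render(self) -> str:
        """ASCII-art debug rendering: letters per tile type on '.' background."""
        occ = {(x, y): t for x, y, t in self._cells}
        xs = [c[0] for c in self._cells]
        ys = [c[1] for c in self._cells]
        rows = []
        for y in range(max(ys), min(ys) - 1, -1):
            rows.append("".join(
                chr(ord("A") + occ[(x, y)]) if (x, y) in occ else "."
                for x in range(min(xs), max(xs) + 1)))
        return "\n".join(rows)


def canonicalize(cells: Iterable[tuple], n_types: int | None = None) -> Polyomino:
    """Canonical typed polyomino of a connected cell set.

    Accepts ``(x, y)`` or ``(x, y, type)`` cells.  Raises on empty or
    edge-disconnected input (a disconnected set signals an assembly bug, not
    a phenotype).
    """
    cells = list(cells)
    if not cells:
        raise ValueError("empty cell set")
    coords = {(int(c[0]), int(c[1])) for c in cells}
    if len(coords) != len(cells):
        raise ValueError("duplicate cells")
    stack = [next(iter(coords))]
    seen = set(stack)
    while stack:
        x, y = stack.pop()
        for dx, dy in ((0, 1), (1, 0), (0, -1), (-1, 0)):
            nb = (x + dx, y + dy)
            if nb in coords and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    if seen != coords:
        raise ValueError("cell set is not edge-connected")
    return Polyomino(cells, n_types=n_types)


AssemblyOutcome = object  # Polyomino | UNBOUND sentinel


def _graph_partner_table(graph: AssemblyGraph, params: ModelParams):
    """site -> list of (partner_tile, partner_face, strength) with S >= S_c."""
    table: dict[int, list[tuple[int, int, float]]] = {}
    for u, v, s in graph.edges:
        if s < params.S_c - 1e-9:
            continue
        table.setdefault(u.flat, []).append((v.tile, int(v.face), s))
        if v.flat != u.flat:
            table.setdefault(v.flat, []).append((u.tile, int(u.face), s))
    return table


_DIRS = ((0, 1), (1, 0), (0, -1), (-1, 0))


def assemble_once_from_graph(
    graph: AssemblyGraph,
    params: ModelParams,
    seed_tile: int,
    rng: np.random.Generator,
    size_cap: int = DEFAULT_SIZE_CAP,
):
    """Reference (pure-Python) single assembly; returns Polyomino or UNBOUND."""
    if size_cap < 1:
        raise ValueError("size_cap must be >= 1")
    table = _graph_partner_table(graph, params)
    occupied: dict[tuple[int, int], int] = {(0, 0): 0}
    tiles = [(0, 0, seed_tile, 0)]  # x, y, type, rotation
    while True:
        attempts = []
        for x, y, ttype, rot in tiles:
            for d, (dx, dy) in enumerate(_DIRS):
                cell = (x + dx, y + dy)
                if cell in occupied:
                    continue
                face = (d - rot) % 4
                for pt, pf, s in table.get(ttype * 4 + face, ()):
                    attempts.append((cell, pt, (d + 2 - pf) % 4, float(s) ** params.T))
        if not attempts:
            return canonicalize([(x, y, t) for x, y, t, _ in tiles],
                                n_types=graph.n_tiles)
        if len(tiles) >= size_cap:
            return UNBOUND
        weights = np.array([a[3] for a in attempts])
        cell, pt, pr, _ = attempts[rng.choice(len(attempts), p=weights / weights.sum())]
        occupied[cell] = len(tiles)
        tiles.append((cell[0], cell[1], pt, pr))


def assemble_once(
    g: Genotype,
    params: ModelParams,
    seed_tile: int,
    rng: np.random.Generator,
    size_cap: int = DEFAULT_SIZE_CAP,
):
    """Assemble a genotype once from the given seed tile."""
    graph = extract_assembly_graph(g, params)
    return assemble_once_from_graph(graph, params, seed_tile, rng, size_cap)


@dataclass
class PhenotypeDistribution:
    """Outcome counts over k repeated assemblies.

    ``modal`` is the most frequent non-monomer bounded outcome (ties broken
    by smaller cell count, then lexicographic canonical form); monomer
    outcomes are excluded from the vote and from the ``phi`` denominator as
    the trivial contribution of a noninteracting seed.  If only monomers
    (and possibly unbound runs) occur, the phenotype is the monomer with
    ``phi`` its raw frequency; if every repeat is unbound, ``modal`` is None
    and ``phi`` is 0.
    """

    counts: dict
    k: int
    modal: object = None
    phi: float = 0.0

    def __post_init__(self):
        if self.modal is None and self.counts:
            self.modal, self.phi = _modal_and_phi(self.counts, self.k)

    @property
    def n_unbound(self) -> int:
        return self.counts.get(UNBOUND, 0)

    @property
    def n_monomer(self) -> int:
        return self.counts.get(_MONOMER, 0)


_MONOMER = Polyomino([(0, 0, 0)], n_types=1)


def _modal_and_phi(counts: Mapping, k: int):
    bounded = {o: n for o, n in counts.items()
               if o is not UNBOUND and o.size > 1}
    n_monomer = counts.get(_MONOMER, 0)
    if bounded:
        modal = min(bounded, key=lambda o: (-bounded[o], o.size, o.cells))
        denom = k - n_monomer
        return modal, bounded[modal] / denom if denom else 0.0
    if n_monomer:
        return _MONOMER, n_monomer / k
    return None, 0.0


def decode_encoded_cells(enc, stride: int) -> list[tuple[int, int, int]]:
    """Invert the kernel's ``((x*stride)+y)*8 + t`` cell packing."""
    out = []
    for e in enc:
        e = int(e)
        t = e % 8
        xy = e // 8
        out.append((xy // stride, xy % stride, t))
    return out


def phenotype_distribution_from_graph(
    graph: AssemblyGraph,
    params: ModelParams,
    k: int,
    rng: np.random.Generator,
    size_cap: int = DEFAULT_SIZE_CAP,
    engine: str = "numba",
) -> PhenotypeDistribution:
    if k < 1:
        raise ValueError("k must be >= 1")
    seeds = rng.integers(0, graph.n_tiles, size=k)
    counts: dict = {}
    if engine == "python":
        for s in seeds:
            out = assemble_once_from_graph(graph, params, int(s), rng, size_cap)
            counts[out] = counts.get(out, 0) + 1
    else:
        kernel_seed = int(rng.integers(0, 2**31 - 1))
        sizes, hashes, cells, stride = _kernels.assemble_batch(
            graph, params, seeds, size_cap, kernel_seed)
        registry: dict[int, Polyomino] = {}
        for r in range(k):
            if sizes[r] < 0:
                out = UNBOUND
            else:
                h = int(hashes[r])
                out = registry.get(h)
                if out is None:
                    enc = cells[r, : sizes[r]]
                    out = Polyomino(decode_encoded_cells(enc, stride),
                                    n_types=graph.n_tiles, _canonical=True)
                    registry[h] = out
            counts[out] = counts.get(out, 0) + 1
    return PhenotypeDistribution(counts=counts, k=k)


def phenotype_distribution(
    g: Genotype,
    params: ModelParams,
    k: int,
    rng: np.random.Generator,
    size_cap: int = DEFAULT_SIZE_CAP,
    engine: str = "numba",
) -> PhenotypeDistribution:
    """k independent assemblies of a genotype, seed tile uniform per repeat."""
    graph = extract_assembly_graph(g, params)
    return phenotype_distribution_from_graph(graph, params, k, rng, size_cap, engine)


def _single_edge_kind(graph: AssemblyGraph) -> str:
    (u, v, _), = graph.edges
    if u == v:
        return "self"
    if u.tile != v.tile:
        return "inter"
    return "intra_adjacent" if (int(u.face) - int(v.face)) % 2 == 1 else "intra_opposite"


_CLASS_NAMES = {
    ("inter", 2): "dimer",
    ("self", 2): "self_dimer",
    ("intra_adjacent", 4): "homotetramer",
    ("intra_opposite", None): "unbound_chain",
}


def abundance_survey(
    n_genotypes: int,
    params: ModelParams,
    k: int,
    rng: np.random.Generator,
    size_cap: int = DEFAULT_SIZE_CAP,
    batch: int = 20_000,
) -> dict[str, float]:
    """Phenotype-class frequencies among random single-interaction genotypes.

    Samples ``n_genotypes`` uniform random two-tile genotypes, keeps those
    whose assembly graph has exactly one edge, assembles each ``k`` times,
    and classifies by edge topology plus modal phenotype.  Frequencies are
    relative to the single-interaction subset.  The dimer here is the
    inter-subunit heterodimer class; self-interacting homodimers are reported
    separately (``self_dimer``), since the two classes arise from different
    sequence combinatorics.
    """
    L = params.L_I
    c_min = params.min_matching_bits
    iu, ju = np.triu_indices(8, k=0)
    counts: dict[str, int] = {}
    total_single = 0
    done = 0
    while done < n_genotypes:
        b = min(batch, n_genotypes - done)
        done += b
        bits = rng.integers(0, 2, size=(b, 8, L), dtype=np.uint8)
        gf = bits.astype(np.float32)
        rev = gf[:, :, ::-1]
        dots = np.einsum("nil,njl->nij", gf, rev)
        pop = gf.sum(axis=2)
        d = pop[:, :, None] + pop[:, None, :] - 2.0 * dots
        strengths = d[:, iu, ju]
        is_edge = strengths >= c_min - 0.5
        n_edges = is_edge.sum(axis=1)
        for idx in np.nonzero(n_edges == 1)[0]:
            total_single += 1
            g = Genotype(bits[idx].reshape(2, 4, L))
            graph = extract_assembly_graph(g, params)
            kind = _single_edge_kind(graph)
            dist = phenotype_distribution_from_graph(graph, params, k, rng, size_cap)
            msize = None if dist.modal in (None, UNBOUND) else dist.modal.size
            if msize == 1:
                msize = None  # monomer-only outcomes: classify by topology alone
            label = _CLASS_NAMES.get((kind, msize), f"{kind}:{msize}")
            counts[label] = counts.get(label, 0) + 1
    if total_single == 0:
        return {}
    return {lbl: n / total_single for lbl, n in counts.items()}
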