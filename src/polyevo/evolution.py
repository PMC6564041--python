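"""Mutation--selection population dynamics on binary-interface genotypes.

A fixed-size haploid population evolves through discrete generations of
evaluation, fitness-proportional selection, and per-bit mutation.  Each
generation every individual's assembly graph is extracted, its genotype is
assembled ``k_assemblies`` times (seed subunit uniform per repeat), and its
fitness is

    F ** N_I * phi ** gamma

where ``N_I`` is the interaction count of the assembly graph, ``phi`` the
fraction of (non-monomer) assemblies producing the modal phenotype, ``F``
the fitness jump between higher-order assembly graphs and ``gamma`` the
nondeterminism punishment.  Fitness is restricted to a table of rewarded
phenotypes (all others, including monomers, score zero), and a landscape
schedule may blend several tables per generation by summing their fitness
contributions (an l1 combination, used for dynamic landscapes).

The population is initialized with random interactionless genotypes, so all
interactions and phenotypes arise de novo; full ancestry, assembly graphs,
phenotypes and fitnesses are recorded every generation for lineage analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from polyevo.interfaces import ModelParams
from polyevo.genotypes import AssemblyGraph
from polyevo.assembly import (
    DEFAULT_SIZE_CAP,
    Polyomino,
    PhenotypeDistribution,
    UNBOUND,
    decode_encoded_cells,
)
from polyevo import _kernels
from polyevo.lineage import LineageRecord

__all__ = [
    "EvolutionParams",
    "PhenotypeTable",
    "LandscapeSchedule",
    "fitness",
    "select_parents",
    "run_evolution",
    "strength_trajectories",
    "reference_table",
]


@dataclass(frozen=True)
class EvolutionParams:
    """Evolution run parameters.

    ``mu`` is the expected number of bit flips per genotype per generation;
    the per-bit rate is ``mu / (n_tiles * 4 * L_I)``, making the flip count
    binomial with mean ``mu``.
    """

    pop_size: int = 250
    generations: int = 1000
    k_assemblies: int = 25
    mu: float = 1.0
    gamma: float = 5.0
    F: float = 5.0

    def per_bit_rate(self, params: ModelParams, n_tiles: int = 2) -> float:
        return self.mu / (n_tiles * 4 * params.L_I)


@dataclass(frozen=True)
class PhenotypeTable:
    """Rewarded phenotypes: canonical polyominoes with their native N_I.

    A rewarded entry is the pair (phenotype, interaction count of the graph
    that natively produces it): an individual scores only when its modal
    phenotype AND its graph's N_I match an entry.  Requiring the native
    interaction count keeps redundant extra edges (which can reproduce a
    rewarded shape while inflating ``F ** N_I``) out of the rewarded set.
    """

    entries: tuple[tuple[Polyomino, int], ...]

    def __contains__(self, phenotype) -> bool:
        return any(p == phenotype for p, _ in self.entries)

    def rewards(self, phenotype, n_interactions: int) -> bool:
        return any(p == phenotype and n == n_interactions
                   for p, n in self.entries)

    def required_n_i(self, phenotype) -> int | None:
        for p, n in self.entries:
            if p == phenotype:
                return n
        return None


@dataclass(frozen=True)
class LandscapeSchedule:
    """Per-generation weights over one or more phenotype tables.

    ``weight_fn(t)`` returns one weight per table at generation ``t``;
    fitness is the weighted sum (l1 combination) of per-table fitnesses.
    The default is a single static table with weight 1.
    """

    tables: tuple[PhenotypeTable, ...]
    weight_fn: Callable[[int], Sequence[float]] | None = None

    @classmethod
    def static(cls, table: PhenotypeTable) -> "LandscapeSchedule":
        return cls(tables=(table,))

    @classmethod
    def periodic(cls, table_a: PhenotypeTable, table_b: PhenotypeTable,
                 period: int = 100) -> "LandscapeSchedule":
        """Smoothly alternating two-table landscape.

        The period defaults to 100 generations, well above the one-mutation-
        per-generation timescale, so strengths can track the moving optimum.
        """

        def weights(t: int):
            w = 0.5 * (1.0 + math.cos(2.0 * math.pi * t / period))
            return (w, 1.0 - w)

        return cls(tables=(table_a, table_b), weight_fn=weights)

    def weights(self, t: int) -> Sequence[float]:
        if self.weight_fn is None:
            return (1.0,) * len(self.tables)
        return self.weight_fn(t)


def reference_table(params: ModelParams | None = None) -> PhenotypeTable:
    """The six-phenotype rewarded table of the reference system."""
    from polyevo.reference import reference_system

    params = ModelParams() if params is None else params
    rs = reference_system(params.L_I, params.S_c, params.T)
    return PhenotypeTable(tuple((rt.phenotype, rt.n_interactions)
                                for rt in rs.values()))


def fitness(dist: PhenotypeDistribution, graph: AssemblyGraph,
            table: PhenotypeTable, ep: EvolutionParams) -> float:
    """``F**N_I * phi**gamma`` for rewarded modal phenotypes, else 0.

    Monomers are never rewarded (their contribution is trivial), and the
    interaction count is the evaluated graph's own edge count.
    """
    modal = dist.modal
    if modal is None or modal is UNBOUND or modal.size <= 1:
        return 0.0
    if not table.rewards(modal, graph.n_interactions):
        return 0.0
    return float(ep.F) ** graph.n_interactions * dist.phi ** ep.gamma


def select_parents(fitnesses: np.ndarray, pop_size: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Fitness-proportional parent draws; uniform drift when all are zero."""
    f = np.asarray(fitnesses, dtype=float)
    if np.any(f < 0):
        raise ValueError("fitnesses must be non-negative")
    total = f.sum()
    if total <= 0:
        return rng.integers(0, f.size, size=pop_size)
    return rng.choice(f.size, size=pop_size, p=f / total)


def _sample_interactionless(pop: int, params: ModelParams, n_tiles: int,
                            rng: np.random.Generator) -> np.ndarray:
    """(pop, n_sites, L_I) uint8 bits, each genotype with an empty graph."""
    n_sites = n_tiles * 4
    c_min = params.min_matching_bits
    out = np.empty((pop, n_sites, params.L_I), dtype=np.uint8)
    have = 0
    iu, ju = np.triu_indices(n_sites, k=0)
    while have < pop:
        b = max(pop - have, 16)
        bits = rng.integers(0, 2, size=(b, n_sites, params.L_I), dtype=np.uint8)
        gf = bits.astype(np.float32)
        dots = np.einsum("nil,njl->nij", gf, gf[:, :, ::-1])
        pop_counts = gf.sum(axis=2)
        d = pop_counts[:, :, None] + pop_counts[:, None, :] - 2.0 * dots
        ok = np.nonzero((d[:, iu, ju] < c_min - 0.5).all(axis=1))[0]
        take = ok[: pop - have]
        out[have:have + take.size] = bits[take]
        have += take.size
    return out


def _pair_strengths(bits: np.ndarray) -> np.ndarray:
    """(pop, n_sites, n_sites) head-to-tail Hamming distances (counts)."""
    gf = bits.astype(np.float32)
    dots = np.einsum("nil,njl->nij", gf, gf[:, :, ::-1])
    pc = gf.sum(axis=2)
    return pc[:, :, None] + pc[:, None, :] - 2.0 * dots


def _genotype_hashes(bits: np.ndarray) -> np.ndarray:
    pop = bits.shape[0]
    out = np.empty(pop, dtype=np.int64)
    for i in range(pop):
        out[i] = hash(bits[i].tobytes())
    return out


def run_evolution(
    ep: EvolutionParams,
    mp: ModelParams,
    schedule: LandscapeSchedule,
    rng: np.random.Generator,
    n_tiles: int = 2,
    size_cap: int = DEFAULT_SIZE_CAP,
    initial_bits: np.ndarray | None = None,
) -> LineageRecord:
    """Evolve a population and record its full per-generation history.

    The returned record holds, for every generation: parent indices, genotype
    hashes, assembly-graph edge lists (flat site pairs with strength counts),
    modal phenotype ids, phi, N_I and fitness, plus the registry mapping
    phenotype ids to canonical polyominoes -- enough to reconstruct ancestry
    and every transition.  ``initial_bits`` overrides the default random
    interactionless initial population (it is used as given).
    """
    pop = ep.pop_size
    n_sites = n_tiles * 4
    L = mp.L_I
    c_min = mp.min_matching_bits
    p_bit = ep.per_bit_rate(mp, n_tiles)
    iu, ju = np.triu_indices(n_sites, k=0)
    perms = _kernels._perm_array(n_tiles)
    record = LineageRecord(pop_size=pop, n_tiles=n_tiles, L_I=L,
                           model_params=mp, evolution_params=ep)

    if initial_bits is None:
        bits = _sample_interactionless(pop, mp, n_tiles, rng)
    else:
        bits = np.array(initial_bits, dtype=np.uint8, copy=True)
        if bits.shape != (pop, n_sites, L):
            raise ValueError("initial_bits has the wrong shape")

    parents = np.full(pop, -1, dtype=np.int32)
    k = ep.k_assemblies
    sizes = np.empty(k, dtype=np.int64)
    hashes = np.empty(k, dtype=np.int64)
    cells = np.zeros((k, size_cap + 1), dtype=np.int64)
    stride = 2 * size_cap + 3

    for gen in range(ep.generations + 1):
        d = _pair_strengths(bits)
        weights_t = schedule.weights(gen)
        fits = np.zeros(pop)
        n_int = np.zeros(pop, dtype=np.int16)
        phis = np.zeros(pop)
        modal_ids = np.full(pop, -1, dtype=np.int32)
        edge_lists: list[tuple] = [()] * pop

        for i in range(pop):
            du = d[i, iu, ju]
            sel = np.nonzero(du >= c_min - 0.5)[0]
            if sel.size == 0:
                modal_ids[i] = record.register_phenotype(record.MONOMER)
                phis[i] = 1.0
                continue
            edges = tuple((int(iu[e]), int(ju[e]), int(round(du[e])))
                          for e in sel)
            edge_lists[i] = edges
            n_int[i] = len(edges)
            dist = _assemble_individual(edges, n_tiles, L, mp, k, size_cap,
                                        perms, rng, sizes, hashes, cells,
                                        stride, record)
            modal = dist.modal
            phis[i] = dist.phi
            if modal is not None and modal is not UNBOUND:
                modal_ids[i] = record.register_phenotype(modal)
            f = 0.0
            for table, w in zip(schedule.tables, weights_t):
                if w > 0:
                    f += w * fitness(dist, _FakeGraph(len(edges)), table, ep)
            fits[i] = f

        record.append_generation(parents=parents, genotype_hashes=_genotype_hashes(bits),
                                 edges=edge_lists, modal_ids=modal_ids,
                                 phi=phis, n_int=n_int, fitness=fits)
        if gen == ep.generations:
            break
        parents = np.asarray(select_parents(fits, pop, rng), dtype=np.int32)
        bits = bits[parents]
        if p_bit > 0:
            mask = rng.random(bits.shape) < p_bit
            bits = np.where(mask, 1 - bits, bits).astype(np.uint8)

    record.finalize(final_bits=bits)
    return record


@dataclass(frozen=True)
class _FakeGraph:
    """Minimal stand-in carrying only the interaction count for fitness()."""

    n_interactions: int


def _assemble_individual(edges, n_tiles, L, mp, k, size_cap, perms, rng,
                         sizes, hashes, cells, stride, record) -> PhenotypeDistribution:
    """k kernel assemblies of one individual's graph; counts via hash registry."""
    n_sites = n_tiles * 4
    partners = [[] for _ in range(n_sites)]
    for (uf, vf, c) in edges:
        s = c / L
        w = s ** mp.T
        partners[uf].append((vf // 4, vf % 4, w))
        if vf != uf:
            partners[vf].append((uf // 4, uf % 4, w))
    site_off = np.zeros(n_sites + 1, dtype=np.int64)
    for si, pl in enumerate(partners):
        site_off[si + 1] = site_off[si] + len(pl)
    total = int(site_off[-1])
    p_type = np.empty(total, dtype=np.int64)
    p_face = np.empty(total, dtype=np.int64)
    p_weight = np.empty(total, dtype=np.float64)
    pos = 0
    for pl in partners:
        for t, f, w in pl:
            p_type[pos] = t
            p_face[pos] = f
            p_weight[pos] = w
            pos += 1
    seeds = rng.integers(0, n_tiles, size=k).astype(np.int64)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    _kernels.assemble_batch_kernel(site_off, p_type, p_face, p_weight, seeds,
                                   perms, np.int64(size_cap),
                                   np.int64(kernel_seed), sizes, hashes, cells)
    counts: dict = {}
    bounded = sizes >= 0
    n_ub = k - int(bounded.sum())
    if n_ub:
        counts[UNBOUND] = n_ub
    uniq, first, n_each = np.unique(hashes[bounded], return_index=True,
                                    return_counts=True)
    ridx = np.nonzero(bounded)[0]
    for h, fi, n in zip(uniq, first, n_each):
        out = record.phenotype_by_hash(int(h))
        if out is None:
            r = int(ridx[fi])
            out = Polyomino(decode_encoded_cells(cells[r, : sizes[r]], stride),
                            n_types=n_tiles, _canonical=True)
            record.cache_hash(int(h), out)
        counts[out] = int(n)
    return PhenotypeDistribution(counts=counts, k=k)


def strength_trajectories(
    record: LineageRecord,
    align: tuple,
    horizon: int = 250,
) -> dict:
    """Mean interface strength per edge-topology class, aligned at discovery.

    ``align`` is a phenotype class ``(phenotype_id, n_interactions)``; the
    series starts at the generation that class first appears in the record
    (its discovery) and runs for ``horizon`` generations.  Edges of every
    individual expressing the class are grouped by (locality, sharing) and
    averaged per generation; returns ``{edge_class: (mean_strengths, counts)}``
    with NaN where no individual expressed the class.  An empty dict (with a
    discovery of None) is returned when the class never appears.
    """
    phen_id, n_i = align
    disc = record.discovery_generation(phen_id, n_i)
    out: dict = {}
    if disc is None:
        return {"discovery": None, "series": {}}
    L = record.L_I
    n_gens = record.n_generations
    t_end = min(n_gens - 1, disc + horizon)
    series: dict = {}
    for t in range(disc, t_end + 1):
        dt = t - disc
        gen = record.generation(t)
        hit = np.nonzero((gen.modal_ids == phen_id) & (gen.n_int == n_i))[0]
        for i in hit:
            edges = gen.edges[i]
            participation: dict[int, int] = {}
            for u, v, _ in edges:
                participation[u] = participation.get(u, 0) + 1
                if v != u:
                    participation[v] = participation.get(v, 0) + 1
            for u, v, c in edges:
                locality = ("intra_subunit" if u // 4 == v // 4
                            else "inter_subunit")
                shared = participation[u] > 1 or participation[v] > 1
                key = (locality,
                       "shared_site" if shared else "unique_sites")
                if key not in series:
                    series[key] = (np.zeros(horizon + 1),
                                   np.zeros(horizon + 1, dtype=int))
                sums, counts = series[key]
                sums[dt] += c / L
                counts[dt] += 1
    result = {}
    for key, (sums, counts) in series.items():
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        result[key] = (mean, counts)
    return {"discovery": disc, "series": result}
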