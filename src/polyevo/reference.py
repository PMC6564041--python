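"""The six-phenotype reference system of two-tile assembly graphs.

The study system consists of six interaction topologies over two tile types,
grouped by interaction count: a heterodimer and a homotetramer (one
interaction); a heterotetramer and an octomer (two interactions); a 12-mer
and a 16-mer (three interactions).  The heterotetramer, 12-mer and 16-mer
are nondeterministic: competing binding orders produce different phenotypes
(the heterotetramer's misassembly is the pure homotetramer square; the
12-mer graph can also produce a 10-mer or the square).  Rather than
hard-coding edge lists, the topologies are selected programmatically from
the exhaustive enumeration of <=3-edge two-tile topologies by their
structural signatures, so the choice is reproducible and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

import numpy as np

from polyevo.interfaces import ModelParams
from polyevo.genotypes import (
    AssemblyGraph,
    TopologyClass,
    classify_topology,
    enumerate_two_tile_topologies,
    forge_genotype,
    _site_from_flat,
)

__all__ = ["ReferenceTopology", "reference_system", "REFERENCE_NAMES",
           "transition_ancestor_edges"]

REFERENCE_NAMES = ("dimer", "homotetramer", "heterotetramer", "octomer",
                   "twelve_mer", "sixteen_mer")


@dataclass(frozen=True)
class ReferenceTopology:
    """One reference assembly-graph topology with its modal phenotype."""

    name: str
    skeleton: tuple[tuple[int, int], ...]
    n_interactions: int
    deterministic: bool
    modal_size: int
    phenotype: object            # canonical Polyomino at equal strengths
    alternatives: tuple = ()     # other bounded outcomes at equal strengths

    def graph(self, strengths, n_tiles: int = 2) -> AssemblyGraph:
        if np.isscalar(strengths):
            strengths = [float(strengths)] * self.n_interactions
        return AssemblyGraph(
            tuple((_site_from_flat(a), _site_from_flat(b), s)
                  for (a, b), s in zip(self.skeleton, strengths)),
            n_tiles,
        )

    def forge(self, strengths, params: ModelParams, rng: np.random.Generator):
        """A genotype realising this topology at the given strengths."""
        graph = self.graph(strengths)
        return forge_genotype(graph.edges, params, rng)


def _symmetry_images(skeleton):
    """All images of a flat-pair edge set under tile rotation/relabeling."""
    out = set()
    for r0, r1, swap in product(range(4), range(4), (0, 1)):
        rot = (r0, r1)

        def m(flat):
            t, f = divmod(flat, 4)
            return (t ^ swap) * 4 + ((f + rot[t]) % 4)

        out.add(tuple(sorted(tuple(sorted((m(a), m(b)))) for a, b in skeleton)))
    return out


def _contains_up_to_symmetry(big, small) -> bool:
    big_set = set(big)
    return any(set(img) <= big_set for img in _symmetry_images(small))


def _edge_localities(tc: TopologyClass):
    g = tc.graph(0.75)
    return sorted(t.locality for t in classify_topology(g).values())


@lru_cache(maxsize=4)
def reference_system(L_I: int = 64, S_c: float = 0.671875, T: float = 25.0,
                     ) -> dict[str, ReferenceTopology]:
    """Select the six reference topologies from the full enumeration.

    Selection predicates (applied to the colored-phenotype classification of
    every <=3-edge two-tile topology at equal strengths):

    * dimer: one inter-subunit edge, deterministic 2-mer;
    * homotetramer: one intra-subunit edge, deterministic 4-mer;
    * heterotetramer: one inter- + one intra-subunit edge, nondeterministic
      bounded 4-mer (steric competition with the pure square);
    * octomer: one inter- + one intra-subunit edge, deterministic 8-mer;
    * 12-mer / 16-mer: three edges containing the heterotetramer's edge set,
      nondeterministic bounded modal 12 / 16.

    Mirror-image classes (the enumeration's symmetry group excludes
    reflections) are resolved by the lexicographically smallest skeleton,
    with the 12-/16-mer constrained to extend the chosen heterotetramer.
    """
    params = ModelParams(L_I=L_I, S_c=S_c, T=T)
    classes = enumerate_two_tile_topologies(
        params, max_edges=3, k=600, size_cap=40, rng=np.random.default_rng(20_200_406))

    def pick(pred, order=None):
        sel = [c for c in classes if pred(c)]
        if not sel:
            raise RuntimeError("reference topology not found in enumeration")
        sel.sort(key=order or (lambda c: c.skeleton))
        return sel[0]

    bounded = lambda c: c.unbound_fraction == 0.0 and c.modal_size is not None

    dimer = pick(lambda c: c.n_edges == 1 and c.deterministic and c.modal_size == 2
                 and _edge_localities(c) == ["inter_subunit"])
    homotet = pick(lambda c: c.n_edges == 1 and c.deterministic and c.modal_size == 4
                   and _edge_localities(c) == ["intra_subunit"])
    mixed = ["inter_subunit", "intra_subunit"]
    het = pick(lambda c: c.n_edges == 2 and not c.deterministic and bounded(c)
               and c.modal_size == 4 and _edge_localities(c) == mixed)
    octo = pick(lambda c: c.n_edges == 2 and c.deterministic and c.modal_size == 8
                and _edge_localities(c) == mixed)
    twelve = pick(lambda c: c.n_edges == 3 and not c.deterministic and bounded(c)
                  and c.modal_size == 12
                  and _contains_up_to_symmetry(c.skeleton, het.skeleton))
    sixteen = pick(lambda c: c.n_edges == 3 and not c.deterministic and bounded(c)
                   and c.modal_size == 16
                   and _contains_up_to_symmetry(c.skeleton, het.skeleton))

    from polyevo.assembly import phenotype_distribution_from_graph, UNBOUND

    out = {}
    rng = np.random.default_rng(4)
    for name, tc in zip(REFERENCE_NAMES, (dimer, homotet, het, octo, twelve, sixteen)):
        dist = phenotype_distribution_from_graph(
            tc.graph(max(S_c, 0.75)), params, k=2000, rng=rng, size_cap=40)
        alts = tuple(o for o in dist.counts
                     if o is not UNBOUND and o.size > 1 and o != dist.modal)
        out[name] = ReferenceTopology(
            name=name,
            skeleton=tc.skeleton,
            n_interactions=tc.n_edges,
            deterministic=tc.deterministic,
            modal_size=tc.modal_size,
            phenotype=dist.modal,
            alternatives=alts,
        )
    return out


def transition_ancestor_edges(anc_name: str, desc_name: str,
                              L_I: int = 64, S_c: float = 0.671875,
                              T: float = 25.0) -> tuple[tuple[int, int], ...]:
    """The ancestor's concrete edge set on the descendant's skeleton.

    A phenotype transition is founded by a single mutation adding one edge,
    so the ancestor population compatible with a given descendant must
    realise the descendant's skeleton minus one edge -- and phenotype
    classes admit several concrete (mirror-image) realisations.  E.g. the
    octomer phenotype is realised both by "16-mer minus the black intra
    edge" and by "12-mer minus the black intra edge".  This returns the
    edge subset of the descendant skeleton whose modal phenotype (at equal
    strengths) is the ancestor's; raises if no one-edge-removed subset
    produces it.
    """
    from polyevo.assembly import phenotype_distribution_from_graph
    from polyevo.genotypes import AssemblyGraph, _site_from_flat

    params = ModelParams(L_I=L_I, S_c=S_c, T=T)
    rs = reference_system(L_I, S_c, T)
    anc, desc = rs[anc_name], rs[desc_name]
    rng = np.random.default_rng(13)
    for drop in range(desc.n_interactions):
        subset = tuple(e for i, e in enumerate(desc.skeleton) if i != drop)
        if len(subset) != anc.n_interactions:
            continue
        graph = AssemblyGraph(
            tuple((_site_from_flat(a), _site_from_flat(b), max(S_c, 0.75))
                  for a, b in subset), 2)
        dist = phenotype_distribution_from_graph(graph, params, k=400, rng=rng,
                                                 size_cap=40)
        if dist.modal == anc.phenotype:
            return subset
    raise RuntimeError(
        f"no single-edge-removed realisation of {desc_name} has the "
        f"{anc_name} phenotype")
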