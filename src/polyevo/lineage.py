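"""Ancestry reconstruction, phenotype transitions, and genealogy export.

With asexual reproduction every new phenotype traces back to a unique
founding mutation.  The per-generation record written by the evolution
module (parents, genotype hashes, assembly graphs, phenotypes) supports
full ancestry reconstruction: a *transition event* is an individual whose
phenotype class -- the pair (modal phenotype, interaction count) -- differs
from its parent's while its genotype differs too.  Tracking the founder's
clade classifies each event:

* fixation: some descendant of the founder is alive at the final generation;
* failure: the clade goes extinct within a short horizon even though the
  descendant phenotype has strictly higher fitness potential (a larger
  ``F ** N_I`` at perfect determinism) than the ancestor's;
* other: everything else -- artifacts of finite population size, ignored in
  success statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["LineageRecord", "GenerationSlice", "TransitionEvent",
           "detect_transitions", "classify_transition",
           "transition_success_table", "export_newick"]


@dataclass
class GenerationSlice:
    """One generation's per-individual state."""

    parents: np.ndarray        # (pop,) int32; -1 at generation 0
    genotype_hashes: np.ndarray
    edges: list                # per individual: tuple of (u_flat, v_flat, count)
    modal_ids: np.ndarray      # (pop,) int32; registry ids; -1 = no phenotype
    phi: np.ndarray
    n_int: np.ndarray
    fitness: np.ndarray


class LineageRecord:
    """Full per-generation history of one evolution run.

    Phenotypes are interned in a registry (id -> canonical Polyomino); the
    pair ``(modal_id, n_int)`` is an individual's phenotype class.
    """

    def __init__(self, pop_size: int, n_tiles: int, L_I: int,
                 model_params=None, evolution_params=None):
        self.pop_size = pop_size
        self.n_tiles = n_tiles
        self.L_I = L_I
        self.model_params = model_params
        self.evolution_params = evolution_params
        self._generations: list[GenerationSlice] = []
        self._registry: list = []
        self._phen_index: dict = {}
        self._hash_cache: dict = {}
        self.final_bits = None
        from polyevo.assembly import _MONOMER

        self.MONOMER = _MONOMER
        self.register_phenotype(_MONOMER)

    # -- construction ------------------------------------------------------

    def register_phenotype(self, phenotype) -> int:
        got = self._phen_index.get(phenotype)
        if got is None:
            got = len(self._registry)
            self._registry.append(phenotype)
            self._phen_index[phenotype] = got
        return got

    def phenotype_by_hash(self, h: int):
        return self._hash_cache.get(h)

    def cache_hash(self, h: int, phenotype) -> None:
        self._hash_cache[h] = phenotype
        self.register_phenotype(phenotype)

    def append_generation(self, parents, genotype_hashes, edges, modal_ids,
                          phi, n_int, fitness) -> None:
        self._generations.append(GenerationSlice(
            parents=np.array(parents, dtype=np.int32),
            genotype_hashes=np.array(genotype_hashes, dtype=np.int64),
            edges=list(edges),
            modal_ids=np.array(modal_ids, dtype=np.int32),
            phi=np.array(phi, dtype=float),
            n_int=np.array(n_int, dtype=np.int16),
            fitness=np.array(fitness, dtype=float),
        ))

    def finalize(self, final_bits=None) -> None:
        self.final_bits = final_bits

    # -- access ------------------------------------------------------------

    @property
    def n_generations(self) -> int:
        return len(self._generations)

    def generation(self, t: int) -> GenerationSlice:
        return self._generations[t]

    def phenotype(self, phen_id: int):
        return self._registry[phen_id]

    def phenotype_id(self, phenotype) -> int | None:
        return self._phen_index.get(phenotype)

    def phenotype_class(self, t: int, i: int) -> tuple[int, int]:
        gen = self._generations[t]
        return (int(gen.modal_ids[i]), int(gen.n_int[i]))

    def discovery_generation(self, phen_id: int, n_i: int | None = None) -> int | None:
        """First generation where an individual expresses the class."""
        for t, gen in enumerate(self._generations):
            hit = gen.modal_ids == phen_id
            if n_i is not None:
                hit &= gen.n_int == n_i
            if hit.any():
                return t
        return None

    def children_of(self, t: int, i: int) -> np.ndarray:
        if t + 1 >= self.n_generations:
            return np.empty(0, dtype=np.int64)
        return np.nonzero(self._generations[t + 1].parents == i)[0]

    def mean_fitness(self) -> np.ndarray:
        return np.array([g.fitness.mean() for g in self._generations])

    def max_fitness(self) -> np.ndarray:
        return np.array([g.fitness.max() for g in self._generations])

    def phenotype_census(self, t: int) -> dict:
        gen = self._generations[t]
        out: dict = {}
        for i in range(self.pop_size):
            key = (int(gen.modal_ids[i]), int(gen.n_int[i]))
            out[key] = out.get(key, 0) + 1
        return out

    def clade_members(self, founder: tuple[int, int]):
        """Per-generation index arrays of the founder's descendants."""
        t0, i0 = founder
        members = [np.array([i0], dtype=np.int64)]
        t = t0
        while t + 1 < self.n_generations and members[-1].size:
            cur = set(members[-1].tolist())
            nxt = np.nonzero(np.isin(self._generations[t + 1].parents,
                                     list(cur)))[0]
            members.append(nxt)
            t += 1
        if members[-1].size == 0:
            members.pop()
        return members

    def save(self, path) -> None:
        """Persist the record (compressed npz + JSON for ragged fields)."""
        import json

        gens = self._generations
        meta = {
            "pop_size": self.pop_size,
            "n_tiles": self.n_tiles,
            "L_I": self.L_I,
            "model_params": None if self.model_params is None else {
                "L_I": self.model_params.L_I, "S_c": self.model_params.S_c,
                "T": self.model_params.T},
            "evolution_params": None if self.evolution_params is None else {
                "pop_size": self.evolution_params.pop_size,
                "generations": self.evolution_params.generations,
                "k_assemblies": self.evolution_params.k_assemblies,
                "mu": self.evolution_params.mu,
                "gamma": self.evolution_params.gamma,
                "F": self.evolution_params.F},
            "registry": [p.to_text() for p in self._registry],
            "edges": [[list(map(list, e)) for e in g.edges] for g in gens],
        }
        np.savez_compressed(
            path,
            meta=json.dumps(meta),
            parents=np.stack([g.parents for g in gens]),
            genotype_hashes=np.stack([g.genotype_hashes for g in gens]),
            modal_ids=np.stack([g.modal_ids for g in gens]),
            phi=np.stack([g.phi for g in gens]),
            n_int=np.stack([g.n_int for g in gens]),
            fitness=np.stack([g.fitness for g in gens]),
            final_bits=self.final_bits if self.final_bits is not None
            else np.empty(0, dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "LineageRecord":
        import json

        from polyevo.assembly import Polyomino
        from polyevo.interfaces import ModelParams

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            mp = (ModelParams(**meta["model_params"])
                  if meta["model_params"] else None)
            ep = None
            if meta["evolution_params"]:
                from polyevo.evolution import EvolutionParams

                ep = EvolutionParams(**meta["evolution_params"])
            rec = cls(meta["pop_size"], meta["n_tiles"], meta["L_I"],
                      model_params=mp, evolution_params=ep)
            rec._registry = []
            rec._phen_index = {}
            for text in meta["registry"]:
                rec.register_phenotype(Polyomino.from_text(text))
            for t in range(z["parents"].shape[0]):
                rec.append_generation(
                    parents=z["parents"][t],
                    genotype_hashes=z["genotype_hashes"][t],
                    edges=[tuple(tuple(e) for e in ind)
                           for ind in meta["edges"][t]],
                    modal_ids=z["modal_ids"][t],
                    phi=z["phi"][t],
                    n_int=z["n_int"][t],
                    fitness=z["fitness"][t],
                )
            fb = z["final_bits"]
            rec.finalize(final_bits=None if fb.size == 0 else fb)
        return rec

    def to_run_log(self):
        """Per-generation summary DataFrame (mean/max fitness, census size)."""
        import pandas as pd

        rows = []
        for t, g in enumerate(self._generations):
            strengths = [c / self.L_I for e in g.edges for _, _, c in e]
            rows.append({
                "generation": t,
                "mean_fitness": g.fitness.mean(),
                "max_fitness": g.fitness.max(),
                "n_phenotypes": len({(int(m), int(n))
                                     for m, n in zip(g.modal_ids, g.n_int)}),
                "mean_n_int": float(g.n_int.mean()),
                "mean_phi": float(g.phi.mean()),
                "mean_strength": (float(np.mean(strengths))
                                  if strengths else np.nan),
            })
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TransitionEvent:
    """A founding mutation changing a lineage's phenotype class."""

    generation: int
    founder: int
    ancestor_class: tuple[int, int]     # (phenotype id, N_I) of the parent
    descendant_class: tuple[int, int]
    founder_edges: tuple                # (u_flat, v_flat, strength count)
    ancestor_edges: tuple
    classification: str = "unclassified"

    def shared_and_new_strengths(self, L_I: int):
        """Founding strengths split into ancestor-shared vs new edges."""
        anc_pairs = {(u, v) for u, v, _ in self.ancestor_edges}
        shared, new = [], []
        for u, v, c in self.founder_edges:
            (shared if (u, v) in anc_pairs else new).append(c / L_I)
        return shared, new


def detect_transitions(record: LineageRecord,
                       classes: Iterable[tuple] | None = None
                       ) -> list[TransitionEvent]:
    """All founding mutations that change the modal phenotype class.

    An event requires a genotype change relative to the parent (the founding
    mutation) and a different (modal phenotype, N_I) class.  ``classes``
    optionally restricts events to descendant classes in the given set.
    """
    wanted = set(classes) if classes is not None else None
    events = []
    for t in range(1, record.n_generations):
        gen = record.generation(t)
        prev = record.generation(t - 1)
        for i in range(record.pop_size):
            p = int(gen.parents[i])
            cls = (int(gen.modal_ids[i]), int(gen.n_int[i]))
            anc = (int(prev.modal_ids[p]), int(prev.n_int[p]))
            if cls == anc:
                continue
            if gen.genotype_hashes[i] == prev.genotype_hashes[p]:
                continue  # phenotype flicker without mutation (sampling noise)
            if wanted is not None and cls not in wanted:
                continue
            events.append(TransitionEvent(
                generation=t,
                founder=i,
                ancestor_class=anc,
                descendant_class=cls,
                founder_edges=tuple(gen.edges[i]),
                ancestor_edges=tuple(prev.edges[p]),
            ))
    return events


def classify_transition(event: TransitionEvent, record: LineageRecord,
                        extinct_horizon: int = 10) -> str:
    """fixation / failure / other for one transition event.

    Fixation: a descendant of the founder is alive at the final recorded
    generation.  Failure: the founder's clade is extinct within
    ``extinct_horizon`` generations although the descendant phenotype's
    fitness potential ``F**N_I`` (at perfect determinism) exceeds the
    ancestor's.  Everything else is "other".
    """
    members = record.clade_members((event.generation, event.founder))
    last_gen = event.generation + len(members) - 1
    alive_at_end = last_gen == record.n_generations - 1 and members[-1].size > 0
    if alive_at_end:
        return "fixation"
    ep = record.evolution_params
    F = ep.F if ep is not None else 5.0
    higher_potential = (F ** event.descendant_class[1]
                       > F ** event.ancestor_class[1])
    if len(members) <= extinct_horizon and higher_potential:
        return "failure"
    return "other"


def transition_success_table(records: Sequence[LineageRecord],
                             classes: Iterable[tuple] | None = None,
                             extinct_horizon: int = 10):
    """Per (ancestor, descendant) class-pair success rates over many runs.

    Success rate = fixations / (fixations + failures); "other" events are
    excluded.  Returns a DataFrame with binomial (normal-approximation)
    confidence intervals and the mean founding strengths of ancestor-shared
    and new edges (the phase-space location proxy of the founding events).
    """
    import pandas as pd

    agg: dict = {}
    for rec in records:
        for ev in detect_transitions(rec, classes=classes):
            cls = classify_transition(ev, rec, extinct_horizon)
            key = (ev.ancestor_class, ev.descendant_class)
            a = agg.setdefault(key, {"fixation": 0, "failure": 0, "other": 0,
                                     "shared": [], "new": []})
            a[cls] += 1
            if cls in ("fixation", "failure"):
                shared, new = ev.shared_and_new_strengths(rec.L_I)
                a["shared"].extend(shared)
                a["new"].extend(new)
    rows = []
    for (anc, desc), a in sorted(agg.items()):
        n = a["fixation"] + a["failure"]
        rate = a["fixation"] / n if n else np.nan
        se = np.sqrt(rate * (1 - rate) / n) if n else np.nan
        rows.append({
            "ancestor": anc, "descendant": desc,
            "fixations": a["fixation"], "failures": a["failure"],
            "other": a["other"], "n_classified": n,
            "success_rate": rate,
            "ci_low": max(0.0, rate - 1.96 * se) if n else np.nan,
            "ci_high": min(1.0, rate + 1.96 * se) if n else np.nan,
            "mean_shared_strength": float(np.mean(a["shared"])) if a["shared"] else np.nan,
            "mean_new_strength": float(np.mean(a["new"])) if a["new"] else np.nan,
        })
    return pd.DataFrame(rows)


def export_newick(record: LineageRecord, focal: tuple[int, int]) -> str:
    """Newick genealogy of a founder's clade, branch lengths in generations.

    Every individual is a node named ``g<generation>i<index>``; an
    individual's children are its offspring in the next generation.  Raises
    KeyError for a founder outside the record.
    """
    t0, i0 = focal
    if not (0 <= t0 < record.n_generations) or not (0 <= i0 < record.pop_size):
        raise KeyError(f"unknown founder {focal}")

    def subtree(t: int, i: int) -> str:
        name = f"g{t}i{i}"
        kids = record.children_of(t, i)
        if kids.size == 0:
            return f"{name}:1"
        inner = ",".join(subtree(t + 1, int(k)) for k in kids)
        return f"({inner}){name}:1"

    # root branch length 0 (the founder itself)
    body = subtree(t0, i0)
    if body.endswith(":1"):
        body = body[:-2] + ":0"
    return body + ";"
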