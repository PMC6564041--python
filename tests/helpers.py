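"""Shared measurement protocols for the system-level acceptance checks."""

from __future__ import annotations

import numpy as np

from polyevo.interfaces import ModelParams
from polyevo.evolution import (EvolutionParams, LandscapeSchedule,
                               PhenotypeTable, run_evolution,
                               strength_trajectories)
from polyevo.genotypes import forge_genotype, _site_from_flat
from polyevo.lineage import classify_transition, detect_transitions
from polyevo.markov import build_chain, quasi_stationary_mean_strength
from polyevo.reference import reference_system, transition_ancestor_edges


def pooled_trajectories(n_reps: int, pop: int, gens: int, seed0: int,
                        horizon: int = 250):
    """Strength trajectories pooled over replicates, plus founding strengths.

    Returns (pooled, shared, new): ``pooled[(phenotype_name, edge_class)] =
    (count-weighted strength sums, counts)`` over generations since that
    phenotype's per-replicate discovery, and the founding strengths of
    ancestor-shared vs new edges over all transitions into two-interaction
    phenotypes from one-interaction ancestors.
    """
    from polyevo.evolution import reference_table

    mp = ModelParams()
    rs = reference_system()
    table = reference_table(mp)
    ep = EvolutionParams(pop_size=pop, generations=gens)
    pooled: dict = {}
    shared_all: list = []
    new_all: list = []
    for rep in range(n_reps):
        rng = np.random.default_rng(seed0 + rep)
        rec = run_evolution(ep, mp, LandscapeSchedule.static(table), rng)
        for name, rt in rs.items():
            pid = rec.phenotype_id(rt.phenotype)
            if pid is None:
                continue
            res = strength_trajectories(rec, (pid, rt.n_interactions),
                                        horizon=horizon)
            if res["discovery"] is None:
                continue
            for cls, (mean, cnt) in res["series"].items():
                sums, ns = pooled.setdefault(
                    (name, cls), (np.zeros(horizon + 1), np.zeros(horizon + 1)))
                ok = cnt > 0
                sums[ok] += mean[ok] * cnt[ok]
                ns[ok] += cnt[ok]
        two_edge = {}
        one_edge = {}
        for name in ("heterotetramer", "octomer"):
            pid = rec.phenotype_id(rs[name].phenotype)
            if pid is not None:
                two_edge[(pid, 2)] = name
        for name in ("dimer", "homotetramer"):
            pid = rec.phenotype_id(rs[name].phenotype)
            if pid is not None:
                one_edge[(pid, 1)] = name
        for ev in detect_transitions(rec, classes=set(two_edge)):
            if ev.ancestor_class not in one_edge:
                continue
            sh, nw = ev.shared_and_new_strengths(64)
            shared_all.extend(sh)
            new_all.extend(nw)
    return pooled, shared_all, new_all


def measure_transition_pair(anc_name: str, desc_name: str, seed: int,
                            pop: int = 100, burn: int = 400, obs: int = 120,
                            margin: int = 50, min_events: int = 50,
                            max_runs: int = 80, n_burnins: int = 6):
    """Success rate of one phenotype transition, ancestor at equilibrium.

    Several independent burn-in runs evolve populations of the ancestor's
    concrete graph realisation (the descendant's skeleton minus one edge) to
    equilibrium under a landscape rewarding the ancestor alone; observation
    replicates cycle over the burn-ins (success is sensitive to each
    equilibrium population's exact strength composition, so pooling
    independent burn-ins is essential), also reward the descendant, and
    every founding transition event is classified.  Events are counted only
    while the descendant class is not yet established (<10% of the
    population) and early enough (``margin``) for fixation to be
    meaningful.  Returns (fixations, failures, other, runs, success rate).
    """
    mp = ModelParams()
    rs = reference_system()
    qs_c = int(round(quasi_stationary_mean_strength(
        build_chain(mp, 1.0 / 512)) * 64))
    anc, desc = rs[anc_name], rs[desc_name]
    anc_edges = transition_ancestor_edges(anc_name, desc_name)
    t_anc = PhenotypeTable(((anc.phenotype, anc.n_interactions),))
    t_both = PhenotypeTable(((anc.phenotype, anc.n_interactions),
                             (desc.phenotype, desc.n_interactions)))
    s0 = qs_c / 64
    graph_edges = tuple((_site_from_flat(a), _site_from_flat(b), s0)
                        for a, b in anc_edges)
    burns = []
    for bi in range(n_burnins):
        rng = np.random.default_rng(seed + 100 * bi)
        base = np.stack([forge_genotype(graph_edges, mp, rng).bits.reshape(8, 64)
                         for _ in range(8)])
        init = base[rng.integers(0, 8, size=pop)]
        rec = run_evolution(EvolutionParams(pop_size=pop, generations=burn),
                            mp, LandscapeSchedule.static(t_anc), rng,
                            initial_bits=init)
        burns.append(rec.final_bits)
    fx = fl = ot = runs = 0
    while fx + fl < min_events and runs < max_runs:
        rng_o = np.random.default_rng(seed + 1000 + runs)
        r = run_evolution(EvolutionParams(pop_size=pop, generations=obs), mp,
                          LandscapeSchedule.static(t_both), rng_o,
                          initial_bits=burns[runs % n_burnins])
        runs += 1
        anc_cls = (r.phenotype_id(anc.phenotype), anc.n_interactions)
        dp = r.phenotype_id(desc.phenotype)
        if dp is None:
            continue
        desc_cls = (dp, desc.n_interactions)
        for ev in detect_transitions(r):
            if ev.ancestor_class != anc_cls or ev.descendant_class != desc_cls:
                continue
            if ev.generation > obs - margin:
                continue
            gen = r.generation(ev.generation)
            frac = ((gen.modal_ids == dp)
                    & (gen.n_int == desc.n_interactions)).mean()
            if frac > 0.10:
                continue
            c = classify_transition(ev, r)
            if c == "fixation":
                fx += 1
            elif c == "failure":
                fl += 1
            else:
                ot += 1
    n = fx + fl
    return fx, fl, ot, runs, (fx / n if n else float("nan"))
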