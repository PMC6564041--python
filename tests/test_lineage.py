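"""Transition detection/classification, genealogy export, record persistence."""

import numpy as np
import pytest

from polyevo.interfaces import ModelParams
from polyevo.assembly import Polyomino
from polyevo.evolution import (EvolutionParams, LandscapeSchedule,
                               reference_table, run_evolution)
from polyevo.lineage import (LineageRecord, classify_transition,
                             detect_transitions, export_newick,
                             transition_success_table)

DIMER = Polyomino([(0, 0, 0), (0, 1, 1)])
SQUARE = Polyomino([(0, 0), (1, 0), (0, 1), (1, 1)])


def scripted_record(pop=4, gens=8, change_gen=3, founder=0, revert_after=None):
    """A hand-built record: everyone a dimer except one founding mutation."""
    rec = LineageRecord(pop_size=pop, n_tiles=2, L_I=64,
                        evolution_params=EvolutionParams(pop_size=pop,
                                                         generations=gens))
    d_id = rec.register_phenotype(DIMER)
    s_id = rec.register_phenotype(SQUARE)
    base_edges = ((0, 4, 45),)
    new_edges = ((0, 4, 45), (0, 1, 43))
    for t in range(gens + 1):
        parents = np.full(pop, -1) if t == 0 else np.arange(pop)
        hashes = np.arange(pop) + 100
        edges = [base_edges] * pop
        modal = np.full(pop, d_id)
        n_int = np.ones(pop)
        if t >= change_gen and (revert_after is None
                                or t < change_gen + revert_after):
            hashes = hashes.copy()
            hashes[founder] = 999
            edges = list(edges)
            edges[founder] = new_edges
            modal = modal.copy()
            modal[founder] = s_id
            n_int = n_int.copy()
            n_int[founder] = 2
        if revert_after is not None and t == change_gen + revert_after:
            # founder's line is dropped: parent of every slot is a non-founder
            parents = np.full(pop, (founder + 1) % pop)
        rec.append_generation(parents=parents, genotype_hashes=hashes,
                              edges=edges, modal_ids=modal,
                              phi=np.ones(pop), n_int=n_int,
                              fitness=np.ones(pop))
    return rec, d_id, s_id


class TestDetectTransitions:
    def test_single_scripted_change_yields_one_event(self):
        rec, d_id, s_id = scripted_record()
        events = detect_transitions(rec)
        assert len(events) == 1
        ev = events[0]
        assert ev.generation == 3
        assert ev.founder == 0
        assert ev.ancestor_class == (d_id, 1)
        assert ev.descendant_class == (s_id, 2)

    def test_no_mutation_no_event(self):
        # phenotype flicker without genotype change is sampling noise
        rec, d_id, s_id = scripted_record()
        gen = rec.generation(5)
        gen.genotype_hashes[:] = rec.generation(4).genotype_hashes
        gen.modal_ids[1] = s_id  # flicker with identical genotype
        events = detect_transitions(rec)
        assert all(ev.founder == 0 for ev in events)

    def test_every_event_founder_differs_from_parent(self, params):
        ep = EvolutionParams(pop_size=40, generations=60)
        rec = run_evolution(ep, params,
                            LandscapeSchedule.static(reference_table(params)),
                            np.random.default_rng(5))
        for ev in detect_transitions(rec):
            parent = int(rec.generation(ev.generation).parents[ev.founder])
            assert rec.generation(ev.generation).genotype_hashes[ev.founder] \
                != rec.generation(ev.generation - 1).genotype_hashes[parent]

    def test_ancestry_is_total(self, params):
        ep = EvolutionParams(pop_size=25, generations=30)
        rec = run_evolution(ep, params,
                            LandscapeSchedule.static(reference_table(params)),
                            np.random.default_rng(6))
        for t in range(1, rec.n_generations):
            parents = rec.generation(t).parents
            assert np.all((parents >= 0) & (parents < rec.pop_size))


class TestClassifyTransition:
    def test_clade_alive_at_end_is_fixation(self):
        rec, *_ = scripted_record()
        ev, = detect_transitions(rec)
        assert classify_transition(ev, rec) == "fixation"

    def test_quick_extinction_with_higher_potential_is_failure(self):
        rec, *_ = scripted_record(revert_after=3)
        ev, = detect_transitions(rec)
        assert classify_transition(ev, rec, extinct_horizon=10) == "failure"

    def test_equal_potential_extinction_is_other(self):
        rec, d_id, s_id = scripted_record(revert_after=3)
        ev, = detect_transitions(rec)
        # pretend the descendant had the same interaction count
        ev2 = type(ev)(generation=ev.generation, founder=ev.founder,
                       ancestor_class=(d_id, 1), descendant_class=(s_id, 1),
                       founder_edges=ev.founder_edges,
                       ancestor_edges=ev.ancestor_edges)
        assert classify_transition(ev2, rec) == "other"

    def test_shared_and_new_strength_split(self):
        rec, *_ = scripted_record()
        ev, = detect_transitions(rec)
        shared, new = ev.shared_and_new_strengths(64)
        assert shared == [45 / 64]
        assert new == [43 / 64]


class TestSuccessTable:
    def test_counts_and_rate(self):
        fix_rec, d_id, s_id = scripted_record()
        fail_rec, *_ = scripted_record(revert_after=3)
        df = transition_success_table([fix_rec, fail_rec])
        assert len(df) == 1
        row = df.iloc[0]
        assert row.fixations == 1 and row.failures == 1
        assert row.success_rate == pytest.approx(0.5)
        assert row.mean_shared_strength == pytest.approx(45 / 64)
        assert row.mean_new_strength == pytest.approx(43 / 64)


class TestNewick:
    def test_surviving_chain_has_expected_depth(self):
        rec, *_ = scripted_record(pop=1, gens=3, change_gen=0)
        nwk = export_newick(rec, (0, 0))
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = tree.leaf_nodes()
        assert len(leaves) == 1
        assert leaves[0].distance_from_root() == pytest.approx(3.0)

    def test_two_siblings_parse_as_two_leaves(self):
        rec = LineageRecord(pop_size=2, n_tiles=2, L_I=64)
        for t in range(2):
            rec.append_generation(
                parents=np.full(2, -1) if t == 0 else np.zeros(2),
                genotype_hashes=np.arange(2), edges=[(), ()],
                modal_ids=np.zeros(2), phi=np.ones(2),
                n_int=np.zeros(2), fitness=np.ones(2))
        nwk = export_newick(rec, (0, 0))
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 2

    def test_round_trip_preserves_topology_and_depths(self, params):
        ep = EvolutionParams(pop_size=15, generations=15)
        rec = run_evolution(ep, params,
                            LandscapeSchedule.static(reference_table(params)),
                            np.random.default_rng(8))
        nwk = export_newick(rec, (0, 0))
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        members = rec.clade_members((0, 0))
        assert len(tree.leaf_nodes()) >= members[-1].size
        for leaf in tree.leaf_nodes():
            assert leaf.distance_from_root() <= rec.n_generations

    def test_unknown_founder_raises(self):
        rec, *_ = scripted_record()
        with pytest.raises(KeyError):
            export_newick(rec, (99, 0))


class TestPersistence:
    def test_save_load_round_trip(self, params, tmp_path):
        ep = EvolutionParams(pop_size=20, generations=25)
        rec = run_evolution(ep, params,
                            LandscapeSchedule.static(reference_table(params)),
                            np.random.default_rng(9))
        path = tmp_path / "rec.npz"
        rec.save(path)
        rec2 = LineageRecord.load(path)
        assert rec2.n_generations == rec.n_generations
        for t in range(rec.n_generations):
            ga, gb = rec.generation(t), rec2.generation(t)
            assert np.array_equal(ga.parents, gb.parents)
            assert np.array_equal(ga.modal_ids, gb.modal_ids)
            assert ga.edges == gb.edges
        assert [rec2.phenotype(i) for i in range(3)] == \
            [rec.phenotype(i) for i in range(3)]
        assert detect_transitions(rec2, classes=None) == \
            detect_transitions(rec, classes=None)
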