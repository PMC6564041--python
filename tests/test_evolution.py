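"""Fitness, selection, full runs, reproducibility, landscape schedules."""

import numpy as np
import pytest

from polyevo.interfaces import ModelParams
from polyevo.genotypes import AssemblyGraph, Face, SiteId, forge_genotype
from polyevo.assembly import PhenotypeDistribution, Polyomino, UNBOUND
from polyevo.evolution import (
    EvolutionParams,
    LandscapeSchedule,
    PhenotypeTable,
    fitness,
    reference_table,
    run_evolution,
    select_parents,
)


def _graph(n_edges):
    edges = tuple(
        (SiteId(0, Face(i)), SiteId(1, Face(i)), 0.75) for i in range(n_edges))
    return AssemblyGraph(edges, 2)


@pytest.fixture(scope="module")
def het_phenotype():
    from polyevo.reference import reference_system

    return reference_system()["heterotetramer"].phenotype


class TestFitness:
    def test_het_twenty_of_twentyfive_scores_8_192(self, het_phenotype):
        # F**2 * (20/25)**5 with F=5, gamma=5
        dist = PhenotypeDistribution(counts={het_phenotype: 20,
                                             UNBOUND: 5}, k=25)
        table = PhenotypeTable(((het_phenotype, 2),))
        assert fitness(dist, _graph(2), table, EvolutionParams()) == \
            pytest.approx(8.192)

    def test_unlisted_phenotype_scores_zero(self, het_phenotype):
        dist = PhenotypeDistribution(counts={het_phenotype: 25}, k=25)
        other = Polyomino([(0, 0), (1, 0)])
        table = PhenotypeTable(((other, 1),))
        assert fitness(dist, _graph(2), table, EvolutionParams()) == 0.0

    def test_perfect_dimer_scores_F(self):
        dimer = Polyomino([(0, 0, 0), (0, 1, 1)])
        dist = PhenotypeDistribution(counts={dimer: 25}, k=25)
        table = PhenotypeTable(((dimer, 1),))
        assert fitness(dist, _graph(1), table, EvolutionParams()) == 5.0

    def test_monomer_scores_zero(self):
        mono = Polyomino([(0, 0)])
        dist = PhenotypeDistribution(counts={mono: 25}, k=25)
        table = PhenotypeTable(((mono, 0),))
        assert fitness(dist, _graph(0), table, EvolutionParams()) == 0.0

    def test_excess_interactions_are_not_rewarded(self, het_phenotype):
        # same modal shape via a graph with an extra edge: not the rewarded class
        dist = PhenotypeDistribution(counts={het_phenotype: 25}, k=25)
        table = PhenotypeTable(((het_phenotype, 2),))
        assert fitness(dist, _graph(3), table, EvolutionParams()) == 0.0


class TestSelection:
    def test_single_fit_individual_takes_all(self, rng):
        idx = select_parents(np.array([1.0, 0.0, 0.0]), 50, rng)
        assert np.all(idx == 0)

    def test_proportional_probabilities(self, rng):
        n = 100_000
        idx = select_parents(np.array([2.0, 1.0]), n, rng)
        p0 = np.mean(idx == 0)
        se = np.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(p0 - 2 / 3) < 3 * se

    def test_all_zero_fitness_falls_back_to_uniform(self, rng):
        n = 90_000
        idx = select_parents(np.zeros(3), n, rng)
        counts = np.bincount(idx, minlength=3) / n
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert np.all(np.abs(counts - 1 / 3) < 4 * se)

    def test_negative_fitness_rejected(self, rng):
        with pytest.raises(ValueError):
            select_parents(np.array([1.0, -0.5]), 5, rng)


class TestRunEvolution:
    def test_zero_generations_records_initial_monomers(self, params, rng):
        ep = EvolutionParams(pop_size=20, generations=0)
        table = reference_table(params)
        rec = run_evolution(ep, params, LandscapeSchedule.static(table), rng)
        assert rec.n_generations == 1
        gen = rec.generation(0)
        assert np.all(gen.n_int == 0)
        assert np.all(gen.fitness == 0.0)
        assert np.all(gen.parents == -1)

    def test_population_size_constant(self, params, rng):
        ep = EvolutionParams(pop_size=30, generations=20)
        rec = run_evolution(ep, params, LandscapeSchedule.static(
            reference_table(params)), rng)
        for t in range(rec.n_generations):
            assert rec.generation(t).fitness.shape == (30,)

    def test_mu_zero_single_fit_clone_fixes(self, params, rng):
        # one dimer genotype among interactionless: drift-free sweep
        table = reference_table(params)
        ep = EvolutionParams(pop_size=30, generations=12, mu=0.0)
        from polyevo.evolution import _sample_interactionless

        bits = _sample_interactionless(30, params, 2, rng)
        dimer = forge_genotype(
            [(SiteId(0, Face.TOP), SiteId(1, Face.TOP), 45 / 64)], params, rng)
        bits[0] = dimer.bits.reshape(8, 64)
        rec = run_evolution(ep, params, LandscapeSchedule.static(table), rng,
                            initial_bits=bits)
        mf = rec.mean_fitness()
        assert np.all(np.diff(mf) >= -1e-12)
        last = rec.generation(rec.n_generations - 1)
        assert np.all(last.n_int == 1)
        assert np.all(last.fitness == 5.0)

    def test_seed_reproducibility_byte_for_byte(self, params):
        ep = EvolutionParams(pop_size=25, generations=25)
        table = reference_table(params)
        recs = []
        for _ in range(2):
            rng = np.random.default_rng(2024)
            recs.append(run_evolution(ep, params,
                                      LandscapeSchedule.static(table), rng))
        a, b = recs
        assert a.final_bits.tobytes() == b.final_bits.tobytes()
        for t in range(a.n_generations):
            ga, gb = a.generation(t), b.generation(t)
            assert ga.parents.tobytes() == gb.parents.tobytes()
            assert ga.genotype_hashes.tobytes() == gb.genotype_hashes.tobytes()
            assert ga.fitness.tobytes() == gb.fitness.tobytes()
            assert ga.modal_ids.tobytes() == gb.modal_ids.tobytes()

    def test_mutation_count_is_binomial_mean_mu(self, params, rng):
        ep = EvolutionParams(pop_size=200, generations=1)
        rate = ep.per_bit_rate(params)
        assert rate == pytest.approx(1 / 512)
        flips = rng.random((4000, 512)) < rate
        counts = flips.sum(axis=1)
        assert abs(counts.mean() - 1.0) < 3 * np.sqrt(1.0 / 4000)

    def test_dimer_discovered_from_interactionless_start(self, params):
        ep = EvolutionParams(pop_size=60, generations=120)
        table = reference_table(params)
        rng = np.random.default_rng(321)
        rec = run_evolution(ep, params, LandscapeSchedule.static(table), rng)
        from polyevo.reference import reference_system

        dimer = reference_system()["dimer"].phenotype
        pid = rec.phenotype_id(dimer)
        assert pid is not None
        assert rec.discovery_generation(pid, 1) is not None


class TestLandscapeSchedule:
    def test_static_weight_is_one(self):
        table = PhenotypeTable(((Polyomino([(0, 0), (1, 0)]), 1),))
        sched = LandscapeSchedule.static(table)
        assert sched.weights(0) == (1.0,)
        assert sched.weights(999) == (1.0,)

    def test_periodic_weights_complementary(self):
        t = PhenotypeTable(((Polyomino([(0, 0), (1, 0)]), 1),))
        sched = LandscapeSchedule.periodic(t, t, period=100)
        for gen in (0, 25, 50, 75, 100):
            w = sched.weights(gen)
            assert sum(w) == pytest.approx(1.0)
        assert sched.weights(0)[0] == pytest.approx(1.0)
        assert sched.weights(50)[0] == pytest.approx(0.0)

    def test_l1_combination_sums_table_fitnesses(self, het_phenotype):
        dist = PhenotypeDistribution(counts={het_phenotype: 25}, k=25)
        graph = _graph(2)
        ep = EvolutionParams()
        t1 = PhenotypeTable(((het_phenotype, 2),))
        t2 = PhenotypeTable(((het_phenotype, 2),))
        f1 = fitness(dist, graph, t1, ep)
        sched = LandscapeSchedule(tables=(t1, t2),
                                  weight_fn=lambda t: (1.0, 1.0))
        combined = sum(w * fitness(dist, graph, tb, ep)
                       for tb, w in zip(sched.tables, sched.weights(0)))
        assert combined == pytest.approx(2 * f1)
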