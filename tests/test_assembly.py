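"""Canonicalization, stochastic assembly, phenotype votes, engine agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyevo.interfaces import ModelParams
from polyevo.genotypes import AssemblyGraph, Face, SiteId, forge_genotype
from polyevo.assembly import (
    UNBOUND,
    PhenotypeDistribution,
    Polyomino,
    assemble_once,
    assemble_once_from_graph,
    canonicalize,
    phenotype_distribution,
    phenotype_distribution_from_graph,
)


def graph_from(edges, n_tiles=2):
    return AssemblyGraph(
        tuple((SiteId(a // 4, Face(a % 4)), SiteId(b // 4, Face(b % 4)), s)
              for a, b, s in edges), n_tiles)


class TestCanonicalize:
    def test_dominoes_are_rotations_of_each_other(self):
        assert canonicalize([(0, 0), (1, 0)]) == canonicalize([(0, 0), (0, 1)])

    def test_l_tromino_equals_its_mirror(self):
        l3 = canonicalize([(0, 0), (1, 0), (0, 1)])
        mirror = canonicalize([(0, 0), (-1, 0), (0, 1)])
        assert l3 == mirror

    def test_translation_invariance(self):
        a = canonicalize([(5, 7), (6, 7), (6, 8)])
        b = canonicalize([(0, 0), (1, 0), (1, 1)])
        assert a == b

    def test_colored_cells_distinguish_composition(self):
        mono = canonicalize([(0, 0, 0), (1, 0, 0)])
        hetero = canonicalize([(0, 0, 0), (1, 0, 1)])
        assert mono != hetero

    def test_color_relabeling_invariance(self):
        ab = canonicalize([(0, 0, 0), (1, 0, 1)], n_types=2)
        ba = canonicalize([(0, 0, 1), (1, 0, 0)], n_types=2)
        assert ab == ba

    @given(st.sets(st.tuples(st.integers(0, 4), st.integers(0, 4)),
                   min_size=1, max_size=10))
    @settings(max_examples=60, deadline=None)
    def test_all_eight_symmetry_images_share_one_canonical_form(self, cells):
        # keep only one connected component
        cells = list(cells)
        keep = {cells[0]}
        frontier = [cells[0]]
        while frontier:
            x, y = frontier.pop()
            for dx, dy in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                nb = (x + dx, y + dy)
                if nb in cells and nb not in keep:
                    keep.add(nb)
                    frontier.append(nb)
        base = canonicalize(keep)
        for refl in (False, True):
            for rot in range(4):
                img = []
                for x, y in keep:
                    if refl:
                        x = -x
                    for _ in range(rot):
                        x, y = y, -x
                    img.append((x, y))
                assert canonicalize(img) == base

    def test_disconnected_input_raises(self):
        with pytest.raises(ValueError, match="connected"):
            canonicalize([(0, 0), (2, 0)])

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            canonicalize([])

    def test_text_round_trip(self):
        p = canonicalize([(0, 0, 0), (1, 0, 1), (1, 1, 0)])
        assert Polyomino.from_text(p.to_text()) == p


class TestAssembleOnce:
    def test_interactionless_genotype_yields_monomer(self, params, rng):
        g = forge_genotype([], params, rng)
        out = assemble_once(g, params, 0, rng)
        assert out.size == 1

    def test_single_self_edge_always_dimer_from_carrier_seed(self, params, rng):
        g = forge_genotype([(SiteId(0, Face.TOP), SiteId(0, Face.TOP), 44 / 64)],
                           params, rng)
        for _ in range(20):
            out = assemble_once(g, params, 0, rng)
            assert out.size == 2

    def test_opposite_face_intra_edge_is_unbound_at_any_cap(self, params, rng):
        g = forge_genotype([(SiteId(0, Face.TOP), SiteId(0, Face.BOTTOM), 44 / 64)],
                           params, rng)
        for cap in (8, 16, 64, 128):
            assert assemble_once(g, params, 0, rng, size_cap=cap) is UNBOUND

    def test_size_cap_must_be_positive(self, params, rng):
        g = forge_genotype([], params, rng)
        with pytest.raises(ValueError):
            assemble_once(g, params, 0, rng, size_cap=0)


class TestEngineAgreement:
    """The numba kernel and the pure-Python reference implement one process."""

    @pytest.mark.parametrize("edges", [
        [(0, 4, 0.75)],                       # heterodimer
        [(0, 1, 0.75)],                       # homotetramer
        [(0, 1, 0.75), (0, 4, 0.75)],         # heterotetramer (nondet)
        [(0, 1, 0.75), (2, 4, 0.75)],         # octomer
    ])
    def test_outcome_sets_and_frequencies_match(self, params, rng, edges):
        graph = graph_from(edges)
        k = 600
        d_py = phenotype_distribution_from_graph(graph, params, k, rng,
                                                 engine="python")
        d_nb = phenotype_distribution_from_graph(graph, params, k, rng,
                                                 engine="numba")
        assert set(d_py.counts) == set(d_nb.counts)
        for o in d_py.counts:
            p1, p2 = d_py.counts[o] / k, d_nb.counts[o] / k
            se = np.sqrt(max(p1 * (1 - p1), 1e-4) / k)
            assert abs(p1 - p2) < 4 * np.sqrt(2) * se

    def test_deterministic_fixture_identical_canonical_forms(self, params, rng):
        graph = graph_from([(0, 1, 0.75), (2, 4, 0.75)])
        out_py = assemble_once_from_graph(graph, params, 0, rng)
        d_nb = phenotype_distribution_from_graph(graph, params, 20, rng)
        assert d_nb.modal == out_py


class TestPhenotypeDistribution:
    def test_deterministic_genotype_has_phi_one(self, params, rng):
        g = forge_genotype([(SiteId(0, Face.TOP), SiteId(1, Face.TOP), 48 / 64)],
                           params, rng)
        d = phenotype_distribution(g, params, 40, rng)
        assert d.phi == 1.0 and d.modal.size == 2

    def test_interactionless_genotype_modal_monomer(self, params, rng):
        g = forge_genotype([], params, rng)
        d = phenotype_distribution(g, params, 25, rng)
        assert d.modal.size == 1 and d.phi == 1.0

    def test_monomers_excluded_from_vote(self, params, rng):
        # homotetramer genotype: inert-seed monomers do not dilute phi
        g = forge_genotype([(SiteId(0, Face.TOP), SiteId(0, Face.RIGHT), 48 / 64)],
                           params, rng)
        d = phenotype_distribution(g, params, 101, rng)
        assert d.modal.size == 4
        assert d.phi == 1.0
        assert d.n_monomer > 0

    def test_unbound_counts_against_phi(self):
        square = Polyomino([(0, 0), (1, 0), (0, 1), (1, 1)])
        d = PhenotypeDistribution(counts={square: 6, UNBOUND: 4}, k=10)
        assert d.modal == square
        assert d.phi == pytest.approx(0.6)

    def test_modal_tie_breaks_to_smaller(self):
        big = Polyomino([(0, 0), (1, 0), (0, 1), (1, 1)])
        small = Polyomino([(0, 0), (1, 0)])
        d = PhenotypeDistribution(counts={big: 5, small: 5}, k=10)
        assert d.modal == small

    def test_outcome_distribution_invariant_under_tile_relabeling(self, params):
        from polyevo.phase_space import build_tree, outcome_frequencies

        g1 = graph_from([(0, 1, 0.75), (0, 4, 0.8125)])
        # swap tile labels: site s -> (s + 4) % 8
        g2 = graph_from([(4, 5, 0.75), (0, 4, 0.8125)])
        f1 = outcome_frequencies(build_tree(g1, params), params=params)
        f2 = outcome_frequencies(build_tree(g2, params), params=params)
        assert {o: round(p, 12) for o, p in f1.items()} == \
            {o: round(p, 12) for o, p in f2.items()}

    def test_unbound_stable_under_cap_doubling(self, params, rng):
        g = forge_genotype([(SiteId(0, Face.TOP), SiteId(0, Face.BOTTOM), 44 / 64)],
                           params, rng)
        d32 = phenotype_distribution(g, params, 30, rng, size_cap=32)
        d64 = phenotype_distribution(g, params, 30, rng, size_cap=64)
        assert d32.n_unbound > 0 and d64.n_unbound > 0
        # the chain never terminates into a bounded non-monomer shape
        assert all(o is UNBOUND or o.size == 1 for o in d64.counts)


class TestInteractionFrequency:
    def test_any_interaction_probability_matches_binomial_closed_form(self):
        # P(>=1 edge) = 1 - (1-p_pair)^28 (1-p_self)^8 with binomial tails:
        # 28 two-site pairs with P(Bin(L,1/2) >= c_min), 8 self-pairs with
        # P(2*Bin(L/2,1/2) >= c_min)
        from scipy.stats import binom

        L, S_c = 16, 0.75
        params = ModelParams(L_I=L, S_c=S_c)
        c_min = params.min_matching_bits
        p_pair = float(binom.sf(c_min - 1, L, 0.5))
        p_self = float(binom.sf(int(np.ceil(c_min / 2)) - 1, L // 2, 0.5))
        closed = 1.0 - (1.0 - p_pair) ** 28 * (1.0 - p_self) ** 8
        rng = np.random.default_rng(99)
        n = 40_000
        bits = rng.integers(0, 2, size=(n, 8, L), dtype=np.uint8)
        gf = bits.astype(np.float32)
        dots = np.einsum("nil,njl->nij", gf, gf[:, :, ::-1])
        pc = gf.sum(axis=2)
        d = pc[:, :, None] + pc[:, None, :] - 2.0 * dots
        iu, ju = np.triu_indices(8)
        frac = float((d[:, iu, ju] >= c_min - 0.5).any(axis=1).mean())
        se = np.sqrt(closed * (1 - closed) / n)
        assert abs(frac - closed) <= 3 * se


class TestTemperature:
    def test_T_zero_makes_feasible_bindings_equiprobable(self, params):
        from polyevo.phase_space import build_tree, outcome_frequencies

        graph = graph_from([(0, 1, 0.703125), (0, 4, 0.90625)])
        tree = build_tree(graph, params)
        f_t0 = outcome_frequencies(tree, params=ModelParams(T=0.0))
        f_eq = outcome_frequencies(tree, strengths=[0.75, 0.75],
                                   params=ModelParams(T=25.0))
        for o, p in f_t0.items():
            assert p == pytest.approx(f_eq[o], abs=1e-12)

    def test_higher_T_favours_strength_favoured_pathway(self, params):
        from polyevo.phase_space import build_tree, outcome_frequencies

        graph = graph_from([(0, 1, 0.703125), (0, 4, 0.90625)])
        tree = build_tree(graph, params)
        het = None
        freqs = []
        for T in (0.0, 1.0, 25.0):
            f = outcome_frequencies(tree, params=ModelParams(T=T))
            if het is None:
                het = max((o for o in f if o is not UNBOUND),
                          key=lambda o: len({t for _, _, t in o.cells}))
            freqs.append(f[het])
        assert freqs[0] < freqs[1] < freqs[2]
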