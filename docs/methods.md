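# Methods

`polyevo` implements a coarse-grained lattice model of protein quaternary
structure assembly and its evolution.  Subunits are square tiles on a 2-D
lattice; each face carries a binary string of `L_I` bits, written clockwise
around the tile.  This note records the model, the numerical choices, and
what the synthetic study system does and does not capture.

## Interfaces and binding

When two tiles abut, their facing strings meet in reversed index order
("head to tail", a consequence of the common clockwise writing convention).
The interaction strength is

    S(a, b) = d_H(a, reverse(b)) / L_I  in  [0, 1],

the Hamming distance between one string and the reversal of the other.
Mismatches under this alignment therefore *bind* (a complementarity rule,
analogous to charge pairing).  The prose of strength definitions is
ambiguous between complementarity and identity conventions;
the complementarity convention is fixed here because it reproduces every
desk-scale identity used in the tests (a half-mismatched pair of 8-bit sites
has S = 0.5; exactly 5 of the 16 4-bit strings bind a fixed partner at
S_c = 0.75, i.e. C(4,3) + C(4,4)).  The alignment is applied in a single
function (`interfaces.hamming_reversed`), so the alternative convention is a
one-line swap.

Binding requires `S >= S_c` and happens per attempt with probability

    Pr(bind) = H(S - S_c) * S**T,      H(0) = 1,

with temperature `T >= 0`.  Equality at the critical strength binds.  At
`T = 0` all feasible bindings are equally likely; larger `T` makes stronger
bonds bind disproportionately sooner.  Defaults are `L_I = 64`,
`S_c = 43/64 = 0.671875`, `T = 25`.

A site interacting with its own copy (a self-edge) is supported: the string
faces its own reversal, which pairs bit `i` with bit `L_I - 1 - i`, so its
strength count is always even and effectively only `L_I / 2` positions are
free.

## Assembly

Assembly starts from a single seed tile and grows by irreversible
attachment.  At each step the feasible *attempts* are enumerated: every
(placed tile, direction, partner entry) whose abutting interface pair
interacts at or above `S_c` and whose target cell is empty.  The model's
uniform attempt/accept race -- pick a random attempt, accept with
probability `S**T`, repeat -- selects each feasible attempt with probability
proportional to `S**T` once an acceptance occurs, so the implementation
draws the next binding directly from that categorical distribution (one draw
per step, no unbounded rejection loop; the ordering statistics are
identical).  Attempts that produce the same placement through
indistinguishable routes accumulate multiplicity and weight accordingly.

A placement needs only its chosen interface pair; other abutting pairs stay
unbonded.  Occupied cells block placements -- the source of *steric
nondeterminism*, where the final structure depends on the order in which
competing interactions bind.  Assembly stops when no feasible attempt
remains; if growth would continue past a size cap (default 64 cells, four
times the largest rewarded phenotype) the outcome is classified UNBOUND.
Doubling the cap never converts periodically growing structures into
bounded phenotypes, so the cap's exact value is immaterial for the study
system.

### Phenotypes

A phenotype is the assembled polyomino *with its per-cell subunit types*,
identified up to translation, the 8 rotations/reflections, and permutation
of the subunit-type labels (assembly is independent of the order in which
subunits appear in the genotype).  Tracking composition matters: the
heterotetramer (a 2x2 square with one cell of the second subunit type) and
the homotetramer (the same square from one type alone) are competing
outcomes of one assembly graph and differ only in composition.  The
canonical form is the lexicographically smallest sorted (x, y, type) list
over the invariance group; a shape-only view remains available
(`Polyomino.shape()`).

The phenotype of a genotype is the modal outcome of `k` repeated assemblies
with the seed subunit drawn uniformly per repeat.  Monomer outcomes are
excluded from the vote and from the denominator of the determinism fraction
`phi`: seeding the noninteracting subunit of a genotype trivially yields a
monomer, and counting those would halve `phi` for every genotype with a
one-sided interaction (and distort the abundance statistics by a factor of
two).  UNBOUND outcomes can never be the phenotype but do count against
`phi` as misassembly.  Ties break toward fewer cells, then lexicographic
canonical form.  If only monomers (or nothing bounded) appear, the phenotype
is the monomer (or undefined, `phi = 0`).

## Genotypes, graphs and forging

A two-subunit genotype carries 8 binding sites (2 tiles x 4 faces).  Its
*assembly graph* has an edge for every unordered site pair (self-pairs
included) with `S >= S_c`.  Edges are classified by locality (inter- vs
intra-subunit) and site sharing (whether an endpoint participates in other
interactions).

Fixture genotypes realising a target graph exactly (no extra edges, exact
strengths) are built constructively: free sites are drawn uniformly; a
partner is set to the bit-flipped reversal of its mate and then `L_I - c`
positions are flipped back to hit the strength count `c`; self-edges choose
`c/2` mismatching bit pairs.  A rejection loop (budget 10,000) discards
draws with accidental extra edges; shared-site targets that over-constrain a
site fail explicitly.

## The six-phenotype study system

All two-tile interaction topologies with at most 3 edges are enumerated up
to per-tile face rotation and tile relabeling (313 classes) and classified
by repeated assembly at equal strengths.  The study system is selected from
this enumeration by structural signature rather than hard-coded:

| phenotype      | edges | signature | deterministic |
|----------------|-------|-----------|---------------|
| dimer          | 1     | inter-subunit | yes |
| homotetramer   | 1     | intra-subunit adjacent faces | yes |
| heterotetramer | 2     | inter + intra, shared site | no (competes with the pure square) |
| octomer        | 2     | inter + intra, unique sites | yes |
| 12-mer         | 3     | heterotetramer + gray-core edge | no (10-mer and square alternatives) |
| 16-mer         | 3     | heterotetramer + non-competing gray-core edge | no (square alternative) |

The heterotetramer's steric competition: its intra-subunit edge builds a
2x2 core of the first subunit while the shared-site inter-subunit edge lets
the second ("gray") subunit occupy a core cell first; once a gray subunit is
placed, the remaining growth is forced and the heterotetramer results, while
pure-core completion yields the homotetramer square.  The 16-mer adds a
gray-core edge that never competes for a cell, so its decision structure is
exactly the heterotetramer's; the 12-mer's gray-core edge does compete,
giving three competing interactions and a 10-mer misassembly channel.  One
phenotype can be realised by mirror-image edge sets; which descendant a
mutation can found depends on the concrete realisation (e.g. the octomer
realisation "16-mer minus the black intra edge" vs "12-mer minus it"), and
`reference.transition_ancestor_edges` resolves this programmatically.

## Evolution

A fixed-size haploid population (default 250) evolves for a fixed number of
generations (default 1000).  Each generation every individual is assembled
`k = 25` times; fitness is

    F**N_I * phi**gamma,

with `F = 5` (the fitness jump between higher-order assembly graphs), `N_I`
the individual's graph edge count, and `gamma = 5` punishing nondeterminism.
Fitness is restricted to a table of rewarded phenotypes; all others
(monomers included) score zero.  A rewarded entry is the *pair* (phenotype,
native interaction count): with shape-only membership, redundant extra edges
that reproduce a rewarded shape (e.g. a second adjacent intra-subunit edge
that still yields the 2x2 square) would each multiply fitness by `F`,
producing an open-ended edge ratchet that swamps the strength dynamics; the
native-count requirement keeps the rewarded classes identical to the study
system's graphs.  Selection is fitness-proportional with uniform fallback
when every fitness is zero (required for the interactionless initial
population to drift at all); mutation flips each bit independently so that
flips per genotype are binomial with mean `mu = 1`.  Populations are
initialized with random *interactionless* genotypes, so every interaction
arises de novo.  phi is resampled every generation for every individual.

Dynamic landscapes blend several phenotype tables per generation by summing
their fitness contributions (an l1 combination); the default schedule
alternates two tables smoothly with period 100 generations, long against
the one-mutation-per-generation timescale.

Runs record, per generation, parents, genotype hashes, edge lists with
strength counts, modal phenotype ids, phi, N_I and fitness -- sufficient to
reconstruct all ancestry, strength trajectories and transitions.

## Neutral baseline

Absent selection on assembly order, a surviving interface evolves neutrally
under four assumptions: no fitness advantage for stronger binding (selection
sees only the phenotype), lethality below `S_c`, infinite population, and
weak per-generation mutation.  The interface decomposes into independent
complementarity pairs (`L_I` pairs for a two-site edge, `L_I/2` for a
self-edge; strength = bound pairs / pairs in both cases).  A pair toggles
when exactly one of its two bits flips: probability `q = 2p(1-p)` for
per-bit rate `p`, exactly (pairs occupy disjoint bits), so breaking/forming
pair counts are binomial and the bound-pair count `c` is a Markov chain.

Survival conditioning: states below `c_min = ceil(S_c * n_pairs)` are
removed, and the *state distribution* is propagated through the resulting
substochastic matrix and renormalised each step.  This (not row
renormalisation of the matrix, which defines a different process) is the
infinite-population limit of "dead lineages are replaced in proportion to
survivors" and is what the bit-level Monte Carlo oracle implements; the
row-renormalised matrix is still exposed for inspection.  The
quasi-stationary distribution is the normalized leading left eigenvector of
the substochastic matrix.  At the defaults a freshly discovered edge sits at
the threshold 0.6719 and relaxes upward to a quasi-stationary mean of
0.7022 within ~200 generations.

The "single mutations only" assumption is honoured approximately through
small `q`; the chain itself allows multi-pair events with their binomial
weights, as does the bit-level simulation, so the two agree exactly rather
than approximately.

## Decision trees and phase spaces

For a fixed assembly graph the exact outcome distribution is computed from
the decision DAG of partial assemblies: nodes are partial structures
(memoized up to translation), branches are distinguishable next bindings
with multiplicities, and a branch with strength `s` and multiplicity `m` is
taken with probability `m s**T / sum_j m_j s_j**T`.  Frequencies therefore
depend only on ratios of competing strengths.  Subtrees whose every leaf
yields one outcome are collapsed; the heterotetramer's DAG has 16 nodes, the
16-mer's 578.  The branch-weight exponent is configurable (at `T = 1` the
weights are literally the strengths normalised by all possible step
strengths); the default is the assembly temperature, which the Monte Carlo
oracle test pins as the consistent choice.  Phase maps evaluate the tree
across a grid of strength ratios and report the determinism-maximising
point and the misassembly region (where another bounded outcome beats the
focal phenotype).

## Transition statistics

A transition event is an individual whose (phenotype, N_I) class differs
from its parent's while its genotype differs (the founding mutation).
Classification follows the clade of the founder: *fixation* if a descendant
is alive at the final recorded generation; *failure* if the clade is
extinct within 10 generations (configurable; no canonical value exists)
despite higher fitness potential, operationalised as `F**N_I` at perfect
determinism; anything else is *other* (finite-population artifacts,
excluded from success rates).

Success rates are measured pairwise: the ancestor's concrete realisation
(descendant skeleton minus one edge) is forged at the neutral
quasi-stationary strength and evolved for 400 generations under a landscape
rewarding the ancestor alone (reaching its selective equilibrium -- e.g.
the heterotetramer's inter-subunit edge strengthens to ~0.77).  Several
independent burn-ins are used per pair and observation replicates cycle
over them: success is steeply sensitive (through `phi**gamma`) to the
founding strength ratio, which varies between equilibrium populations, so a
single shared burn-in would make the rate estimator far noisier than its
binomial interval suggests.  Observation replicates reward ancestor and
descendant while every founding event is classified; events are only
counted while the descendant holds <10% of the population (later
re-foundings compete against an established resident and measure drift, not
the transition) and early enough that survival-to-end is meaningful.

## Problem sizes and statistical tolerances

The package's system-level checks run at desk scale: evolution dynamics use
20 replicates of population 100 for 300 generations; transition statistics
use population 100 with a 400-generation burn-in and 120-generation
observation windows, targeting 50 classified events per pair (the 16-mer
pairs are supplied by the discovery rate of one specific third edge and
accumulate fewer events within the run caps, with correspondingly wider
binomial intervals).  Monte Carlo versus exact comparisons use 1e5
assemblies and 3-standard-error bands; the neutral-baseline comparison uses
independent batches so the standard errors are unbiased despite the
survivor-resampling correlation within a batch.  Trajectory comparisons
align each (phenotype, edge-class) series at its own discovery and compare
against the chain transient started from the series' own initial state --
edges inherited from an ancestor start near the quasi-stationary mean, not
at the threshold -- using only time points supported by >=400 pooled
individuals.

## What the synthetic system does not capture

Interfaces are symmetric binary complementarity scores: no amino-acid
chemistry, no cooperative or multi-site binding, no binding-strength
dependence on geometry beyond face adjacency, no detachment (binding is
irreversible), no concentration effects, and a 2-D lattice only.  Passing
tests show that the implementation reproduces the model's internal
mathematics (exact tree = simulation; neutral chain = bit-level process)
and its qualitative evolutionary phenomenology at reduced scale; they do
not validate the model against real protein complexes.

## Known limitations

* Decision-tree enumeration is exponential in principle; graphs whose
  growth is not sharply constrained (e.g. grid-filling edge sets) exhaust
  the node budget and raise rather than silently truncate.
* `phi` resampling every generation is assumed (the alternative, caching
  phi for unmutated individuals, would change drift noise slightly).
* Transition success rates at population 100 carry finite-population drift
  loss; rates rise toward their infinite-population limits with larger
  populations.
* Genotypes with more than two subunit types are supported structurally,
  but the study system and all calibrated statistics are two-type.
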