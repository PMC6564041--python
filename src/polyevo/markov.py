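"""Neutral Markov-chain baseline for interface-strength evolution.

In the absence of selection on assembly order, an interface's strength
performs a mutation--selection random walk governed by four assumptions: no
direct fitness advantage for stronger interactions; falling below the
critical strength is fatal; infinite population; and per-generation mutation
weak enough that single-bit events dominate.

An interface of length ``L_I`` facing a partner interface decomposes into
independent complementarity pairs: bit ``i`` of one string against bit
``L_I - 1 - i`` of the other.  A two-site edge has ``L_I`` such pairs (two
mutable strings); a self-interacting site has ``L_I / 2`` pairs (the string
against its own reversal).  Writing ``c`` for the number of bound
(mismatching, i.e. complementary) pairs, the strength is ``c / n_pairs`` in
both cases.  Each generation a pair toggles its state when exactly one of
its two bits flips, with probability ``q = 2 p (1 - p)`` for per-bit rate
``p``; the number of breaking/forming pairs is binomial.  States with
``c < c_min = ceil(S_c * n_pairs)`` are lethal.  Conditioning on survival --
propagating the substochastic transition matrix restricted to surviving
states and renormalising the state distribution -- yields transient
expectations, and the leading left eigenvector yields the quasi-stationary
distribution.

The module also ships a bit-level Monte Carlo of the same neutral process
(actual bits, mutation, lethal threshold, dead lineages replaced by copies
of random survivors), used as the independent oracle for the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from polyevo.interfaces import ModelParams

__all__ = ["NeutralChain", "build_chain", "transient_expectation",
           "quasi_stationary_distribution", "quasi_stationary_mean_strength",
           "neutral_monte_carlo"]


@dataclass(frozen=True)
class NeutralChain:
    """Survival-conditioned neutral chain over bound-pair counts.

    ``matrix`` is the substochastic transition matrix restricted to the
    surviving states ``c_min .. n_pairs`` (row deficits are the
    per-generation death probabilities).
    """

    n_pairs: int
    c_min: int
    q: float
    matrix: np.ndarray  # (n_surv, n_surv), substochastic
    self_edge: bool = False

    @property
    def states(self) -> np.ndarray:
        return np.arange(self.c_min, self.n_pairs + 1)

    @property
    def strengths(self) -> np.ndarray:
        return self.states / self.n_pairs

    @property
    def conditioned_matrix(self) -> np.ndarray:
        """Row-renormalized matrix (each row conditioned on that step's survival)."""
        rows = self.matrix.sum(axis=1, keepdims=True)
        return self.matrix / rows


def build_chain(params: ModelParams, per_bit_rate: float,
                self_edge: bool = False) -> NeutralChain:
    """Exact one-generation transition matrix of the neutral pair process."""
    if not (0.0 <= per_bit_rate < 0.5):
        raise ValueError("per_bit_rate must lie in [0, 0.5)")
    if self_edge and params.L_I % 2:
        raise ValueError("self-edges require an even L_I")
    n = params.L_I // 2 if self_edge else params.L_I
    q = 2.0 * per_bit_rate * (1.0 - per_bit_rate)
    c_min = int(np.ceil(params.S_c * n - 1e-9))
    if c_min > n:
        raise ValueError("critical strength admits no surviving state")
    # P(c -> c') = sum_b Bin(c, q)(b) * Bin(n - c, q)(c' - c + b)
    full = np.zeros((n + 1, n + 1))
    for ci in range(n + 1):
        b = np.arange(ci + 1)
        pb = stats.binom.pmf(b, ci, q)
        f = np.arange(n - ci + 1)
        pf = stats.binom.pmf(f, n - ci, q)
        for bi, pbi in zip(b, pb):
            lo = ci - bi
            full[ci, lo:lo + len(f)] += pbi * pf
    sub = full[c_min:, c_min:]
    return NeutralChain(n_pairs=n, c_min=c_min, q=q, matrix=sub, self_edge=self_edge)


def transient_expectation(chain: NeutralChain, c0: int, t_max: int) -> np.ndarray:
    """E[strength | survival to t] for t = 0..t_max, starting from count c0.

    The state distribution is propagated through the substochastic matrix
    and renormalised, which is the infinite-population limit of lethal
    selection (dead lineages replaced in proportion to survivors).
    """
    if c0 < chain.c_min:
        raise ValueError(f"initial count {c0} is below the survival "
                         f"threshold {chain.c_min} (dead at birth)")
    if c0 > chain.n_pairs:
        raise ValueError("initial count exceeds the number of pairs")
    n_surv = chain.matrix.shape[0]
    v = np.zeros(n_surv)
    v[c0 - chain.c_min] = 1.0
    out = np.empty(t_max + 1)
    s = chain.strengths
    for t in range(t_max + 1):
        out[t] = float(v @ s)
        v = v @ chain.matrix
        v /= v.sum()
    return out


def quasi_stationary_distribution(chain: NeutralChain) -> np.ndarray:
    """Long-run distribution over surviving states, conditioned on survival.

    The normalized leading left eigenvector of the substochastic matrix.
    Raises if the conditioned chain is reducible on the surviving states.
    """
    if chain.q == 0.0:
        raise ValueError("q = 0 chain is reducible (identity); no unique "
                         "quasi-stationary distribution")
    m = chain.matrix
    w, vl = np.linalg.eig(m.T)
    i = int(np.argmax(w.real))
    v = vl[:, i].real
    if np.all(v <= 1e-12):
        v = -v
    if np.any(v < -1e-9) or v.sum() <= 0:
        raise ValueError("leading eigenvector is not sign-definite; "
                         "chain appears reducible")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


def quasi_stationary_mean_strength(chain: NeutralChain) -> float:
    return float(quasi_stationary_distribution(chain) @ chain.strengths)


def neutral_monte_carlo(
    params: ModelParams,
    per_bit_rate: float,
    n_lineages: int,
    t_max: int,
    rng: np.random.Generator,
    self_edge: bool = False,
    c0: int | None = None,
) -> np.ndarray:
    """Bit-level neutral simulation; returns mean strength per generation.

    Each lineage carries the complementarity state of every aligned bit
    pair, updated by flipping the underlying bits: a pair toggles exactly
    when one of its two bits flips, and pairs occupy disjoint bits, so
    simulating per-bit flips on the pair representation is bit-level exact
    (a self-edge simply has half as many pairs).  Lineages whose strength
    falls below the critical strength die and are replaced by copies of
    uniformly chosen survivors (the finite-sample version of survival
    conditioning).  ``c0`` sets the initial bound-pair count (default: the
    survival threshold, the typical state of a freshly discovered
    interaction).
    """
    L = params.L_I
    n = L // 2 if self_edge else L
    c_min = int(np.ceil(params.S_c * n - 1e-9))
    c0 = c_min if c0 is None else c0
    if c0 < c_min:
        raise ValueError("initial count below survival threshold")

    pairs = np.zeros((n_lineages, n), dtype=bool)
    pairs[:, :c0] = True
    out = np.empty(t_max + 1)
    p = per_bit_rate
    for t in range(t_max + 1):
        out[t] = pairs.sum(axis=1).mean() / n
        flips = rng.random((n_lineages, n, 2)) < p
        toggle = flips[:, :, 0] ^ flips[:, :, 1]
        pairs ^= toggle
        dead = pairs.sum(axis=1) < c_min
        if dead.any():
            alive = np.nonzero(~dead)[0]
            if alive.size == 0:
                raise RuntimeError("all lineages died; increase n_lineages")
            repl = rng.choice(alive, size=int(dead.sum()))
            pairs[dead] = pairs[repl]
    return out
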