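"""Binary-string binding interfaces and their interaction rules.

Each face of a square tile carries an ordered string of ``L_I`` bits, written
clockwise around the tile.  When two tiles abut, the facing strings meet in
reversed index order ("head to tail"), and the interaction strength is the
Hamming distance between one string and the reversal of the other, normalised
by ``L_I``:

    S(a, b) = d_H(a, reverse(b)) / L_I

so that *mismatches under the head-to-tail alignment bind* (complementarity).
Binding requires ``S >= S_c`` and occurs per attempt with probability
``H(S - S_c) * S**T`` where ``H`` is the Heaviside step with ``H(0) = 1``:
equality at the critical strength binds.

The alternative convention (matches bind, i.e. ``1 - d_H/L_I``) is a single
swap point: :func:`hamming_reversed` is the only place the alignment is
evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "InterfaceString",
    "ModelParams",
    "strength_count",
    "interaction_strength",
    "binding_probability",
    "count_partners_above_threshold",
    "mutate_bits",
]

_EPS = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """Global model parameters.

    Parameters
    ----------
    L_I : int
        Bits per binding site (default 64).
    S_c : float
        Critical interaction strength in (0, 1]; binding requires
        ``S >= S_c`` (default 43/64 = 0.671875).
    T : float
        Abstract temperature >= 0.  Per-attempt binding probability is
        ``S**T``, so ``T > 0`` makes strong bonds bind disproportionately
        sooner; ``T = 0`` makes all feasible bindings equiprobable.
        Default 25.
    """

    L_I: int = 64
    S_c: float = 0.671875
    T: float = 25.0

    def __post_init__(self) -> None:
        if self.L_I <= 0:
            raise ValueError("L_I must be a positive integer")
        if not (0.0 < self.S_c <= 1.0):
            raise ValueError("S_c must lie in (0, 1]")
        if self.T < 0:
            raise ValueError("T must be >= 0")

    @property
    def min_matching_bits(self) -> int:
        """Smallest integer bit count c with c / L_I >= S_c."""
        return int(np.ceil(self.S_c * self.L_I - _EPS))


def _coerce_bits(bits: Union["InterfaceString", Sequence[int], np.ndarray]) -> np.ndarray:
    if isinstance(bits, InterfaceString):
        return bits.bits
    arr = np.asarray(bits, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError("interface bits must be one-dimensional")
    if np.any(arr > 1):
        raise ValueError("interface bits must be 0/1")
    return arr


class InterfaceString:
    """Immutable fixed-length bit string; one binding site on one tile face.

    Accepts an iterable of 0/1, a binary text string ("0101..."), or hex
    shorthand prefixed with ``0x`` (big-endian; requires an explicit
    ``length`` when leading zeros matter beyond the hex digit count).
    """

    __slots__ = ("_bits", "_hash")

    def __init__(self, bits: Union[str, Iterable[int]], length: int | None = None):
        if isinstance(bits, str):
            s = bits.strip()
            if s.startswith(("0x", "0X")):
                nhex = len(s) - 2
                n = length if length is not None else 4 * nhex
                value = int(s, 16)
                arr = np.array([(value >> (n - 1 - i)) & 1 for i in range(n)], dtype=np.uint8)
            else:
                if not set(s) <= {"0", "1"}:
                    raise ValueError(f"not a binary string: {bits!r}")
                arr = np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
                arr = arr.astype(np.uint8)
        else:
            arr = _coerce_bits(np.fromiter(bits, dtype=np.uint8) if not isinstance(bits, np.ndarray) else bits)
        if length is not None and arr.size != length:
            raise ValueError(f"expected {length} bits, got {arr.size}")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "_bits", arr)
        object.__setattr__(self, "_hash", hash(arr.tobytes()))

    @property
    def bits(self) -> np.ndarray:
        return self._bits

    def __len__(self) -> int:
        return self._bits.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InterfaceString):
            return NotImplemented
        return self._bits.size == other._bits.size and bool(np.all(self._bits == other._bits))

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"InterfaceString({self.to_binary()!r})"

    def to_binary(self) -> str:
        """Big-endian binary text form (the default serialisation)."""
        return "".join("01"[b] for b in self._bits)

    def to_hex(self) -> str:
        """Hex shorthand; only defined when the length is a multiple of 4."""
        if self._bits.size % 4:
            raise ValueError("hex form requires a bit length divisible by 4")
        return "0x" + "".join(
            f"{int(''.join('01'[b] for b in self._bits[i:i + 4]), 2):x}"
            for i in range(0, self._bits.size, 4)
        )

    def reversed(self) -> "InterfaceString":
        return InterfaceString(self._bits[::-1])

    def complement(self) -> "InterfaceString":
        return InterfaceString(1 - self._bits)


def hamming_reversed(a: np.ndarray, b: np.ndarray) -> int:
    """Hamming distance between ``a`` and the index-reversal of ``b``.

    This is the single point where the head-to-tail alignment convention is
    applied; everything else goes through here.
    """
    return int(np.count_nonzero(a != b[::-1]))


def strength_count(a, b) -> int:
    """Integer strength count ``S * L_I`` for two equal-length interfaces."""
    a = _coerce_bits(a)
    b = _coerce_bits(b)
    if a.size != b.size:
        raise ValueError(
            f"malformed genotype: interface lengths differ ({a.size} vs {b.size})"
        )
    return hamming_reversed(a, b)


def interaction_strength(a, b, params: ModelParams | None = None) -> float:
    """Interaction strength ``d_H(a, reverse(b)) / L_I`` in [0, 1].

    Symmetric in its arguments.  ``params`` is accepted for interface
    uniformity and length validation; the strength itself depends only on
    the two strings.
    """
    a = _coerce_bits(a)
    b = _coerce_bits(b)
    if params is not None and (a.size != params.L_I or b.size != params.L_I):
        raise ValueError(
            f"malformed genotype: expected L_I={params.L_I} bits, "
            f"got {a.size} and {b.size}"
        )
    if a.size != b.size:
        raise ValueError(
            f"malformed genotype: interface lengths differ ({a.size} vs {b.size})"
        )
    return hamming_reversed(a, b) / a.size


def binding_probability(s: float, params: ModelParams) -> float:
    """Per-attempt binding probability ``H(s - S_c) * s**T`` with ``H(0) = 1``.

    Zero below the critical strength; exactly ``S_c**T`` at it (the Heaviside
    step takes value 1 at zero); ``s**T`` above it.
    """
    if not (0.0 <= s <= 1.0 + _EPS):
        raise ValueError("strength must lie in [0, 1]")
    if s < params.S_c - _EPS:
        return 0.0
    return float(s) ** params.T


def count_partners_above_threshold(b, params: ModelParams) -> int:
    """Number of length-``L_I`` strings binding ``b`` at or above ``S_c``.

    A partner x needs ``d_H(x, reverse(b)) >= ceil(S_c * L_I)`` mismatches
    against the fixed reversal of ``b``; the count of such x is a binomial
    tail sum independent of ``b`` itself.
    """
    if b is not None:
        arr = _coerce_bits(b)
        if arr.size != params.L_I:
            raise ValueError(f"expected L_I={params.L_I} bits, got {arr.size}")
    k_min = params.min_matching_bits
    return sum(comb(params.L_I, k) for k in range(k_min, params.L_I + 1))


def mutate_bits(bits: np.ndarray, per_bit_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``per_bit_rate``.

    Works on bit arrays of any shape (a single interface or a whole
    genotype's stacked faces); returns a new array.
    """
    if not (0.0 <= per_bit_rate <= 1.0):
        raise ValueError("per_bit_rate must lie in [0, 1]")
    arr = np.asarray(bits, dtype=np.uint8)
    if per_bit_rate == 0.0:
        return arr.copy()
    mask = rng.random(arr.shape) < per_bit_rate
    return np.where(mask, 1 - arr, arr).astype(np.uint8)
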