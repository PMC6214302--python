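"""A minimal PCG32 generator shared by the Python API and the compiled kernels.

The learning engine must be reproducible from a single integer seed across
both the fine-grained Python operations and the fused numba trial kernels.
Using one hand-rolled generator (O'Neill's PCG-XSH-RR 64/32) that is itself
JIT-compiled guarantees both code paths consume the identical random stream.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MULT = np.uint64(6364136223846793005)
_INC = np.uint64(1442695040888963407)
_U18 = np.uint64(18)
_U27 = np.uint64(27)
_U59 = np.uint64(59)


@njit(cache=True)
def pcg32_next(state):
    """Advance the 64-bit state in place and return the next uint32."""
    old = state[0]
    state[0] = old * _MULT + _INC
    xorshifted = np.uint32(((old >> _U18) ^ old) >> _U27)
    rot = np.uint32(old >> _U59)
    return np.uint32(
        (xorshifted >> rot) | (xorshifted << ((np.uint32(32) - rot) & np.uint32(31)))
    )


@njit(cache=True)
def pcg32_seed(state, seed):
    state[0] = np.uint64(0)
    pcg32_next(state)
    state[0] = state[0] + seed
    pcg32_next(state)


@njit(cache=True)
def rand_uniform(state):
    """Uniform float in [0, 1)."""
    return pcg32_next(state) / 4294967296.0


@njit(cache=True)
def rand_below(state, n):
    """Uniform integer in [0, n) via Lemire's multiply-shift (n < 2**32)."""
    return np.int64((np.uint64(pcg32_next(state)) * np.uint64(n)) >> np.uint64(32))


class Rng:
    """Seeded random source handed to every stochastic operation.

    Parameters
    ----------
    seed : int
        Any non-negative integer; equal seeds give equal streams.
    """

    __slots__ = ("state",)

    def __init__(self, seed: int):
        if seed < 0:
            raise ValueError("seed must be non-negative")
        self.state = np.zeros(1, np.uint64)
        pcg32_seed(self.state, np.uint64(seed & 0xFFFFFFFFFFFFFFFF))

    def random(self) -> float:
        """Uniform float in [0, 1)."""
        return float(rand_uniform(self.state))

    def randbelow(self, n: int) -> int:
        """Uniform integer in [0, n)."""
        if n <= 0:
            raise ValueError("n must be positive")
        return int(rand_below(self.state, n))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Rng(state={int(self.state[0])})"
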