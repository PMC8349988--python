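"""Independent brute-force oracles used by the tests.

These deliberately avoid any FFT: plain nested-sum DFTs and roll-based
circular autocorrelations, usable only at tiny sizes.
"""

import numpy as np


def dft2_direct(x: np.ndarray) -> np.ndarray:
    """O(N^4) nested-sum 2D DFT."""
    n0, n1 = x.shape
    out = np.zeros((n0, n1), dtype=complex)
    for k0 in range(n0):
        for k1 in range(n1):
            acc = 0.0 + 0.0j
            for m0 in range(n0):
                for m1 in range(n1):
                    acc += x[m0, m1] * np.exp(
                        -2j * np.pi * (k0 * m0 / n0 + k1 * m1 / n1)
                    )
            out[k0, k1] = acc
    return out


def dft4_direct(x: np.ndarray) -> np.ndarray:
    """Quadruple-nested-sum 4D DFT (tiny arrays only)."""
    shape = x.shape
    out = np.zeros(shape, dtype=complex)
    for k in np.ndindex(shape):
        acc = 0.0 + 0.0j
        for m in np.ndindex(shape):
            phase = sum(ki * mi / ni for ki, mi, ni in zip(k, m, shape))
            acc += x[m] * np.exp(-2j * np.pi * phase)
        out[k] = acc
    return out


def circular_autocorrelation(x: np.ndarray) -> np.ndarray:
    """ac[lag] = sum_n x[n] * x[n + lag mod shape], by explicit rolls."""
    out = np.zeros(x.shape)
    for lag in np.ndindex(x.shape):
        shifted = np.roll(x, tuple(-l for l in lag), axis=tuple(range(x.ndim)))
        out[lag] = np.sum(x * shifted)
    return out


def pairwise_win_counts(ranks: np.ndarray) -> np.ndarray:
    """Exhaustive pair enumeration: fraction of cells where i out-ranks j."""
    n_obs, n_items, m = ranks.shape
    wins = np.zeros((m, m))
    total = n_obs * n_items
    for o in range(n_obs):
        for t in range(n_items):
            for i in range(m):
                for j in range(m):
                    if i != j and ranks[o, t, i] < ranks[o, t, j]:
                        wins[i, j] += 1
    wins /= total
    np.fill_diagonal(wins, 0.5)
    return wins
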