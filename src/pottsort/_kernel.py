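"""Numba-compiled Metropolis kernel for the Cellular Potts Model.

The kernel mutates the lattice label field and the per-cell bookkeeping
arrays (area, coordinate sums) in place. Randomness comes from an
explicit xorshift128+ state array created with :func:`rng_state`, so a
run is reproducible from its integer seed and independent of any global
RNG; the Metropolis acceptance statistics of the generator are verified
against exp(-dH/T) in the test suite.
"""

import numba as nb
import numpy as np
from numba import float64, uint64

__all__ = ["rng_state", "sweep"]


def rng_state(seed: int) -> np.ndarray:
    """xorshift128+ state from an integer seed via splitmix64."""
    mask = (1 << 64) - 1
    s = int(seed) & mask
    words = []
    for _ in range(2):
        s = (s + 0x9E3779B97F4A7C15) & mask
        z = s
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        words.append(z ^ (z >> 31))
    if words[0] == 0 and words[1] == 0:  # all-zero state is a fixed point
        words[0] = 1
    return np.array(words, dtype=np.uint64)


@nb.njit(inline="always")
def _next(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << uint64(23)
    s1 ^= s1 >> uint64(17)
    s1 ^= s0
    s1 ^= s0 >> uint64(26)
    state[1] = s1
    return s0 + s1


@nb.njit(inline="always")
def _unit(state):
    # uniform in [0, 1) from the top 53 bits
    return float64(_next(state) >> uint64(11)) * (1.0 / 9007199254740992.0)


@nb.njit(cache=True, fastmath=True)
def sweep(labels, ctype, areas, sumx, sumy, J, mu, lam, T, a_target, C,
          n_attempts, allow_vanish, state):
    """Run ``n_attempts`` elementary copy attempts; return (accepted, sum dH).

    labels : (H, W) int32, 0 = inaccessible boundary ring
    ctype  : (N+1,) int32, type per cell id, ctype[0] = 0 (boundary "type")
    areas, sumx, sumy : (N+1,) int64 incremental bookkeeping
    J  : (n_t+1, n_t+1) float64 contact energy, row/col 0 = boundary
    mu : (n_t+1,) float64 chemotactic potential, mu[0] = 0
    a_target : (n_t+1,) float64 target area per type
    C  : (H, W) float64 morphogen concentration
    state : (2,) uint64 xorshift128+ state (mutated)
    """
    H, W = labels.shape
    wi = W - 2
    n_int = (H - 2) * wi
    accepted = 0
    de_total = 0.0
    for _ in range(n_attempts):
        rr = _next(state)
        idx = int((rr >> uint64(32)) % uint64(n_int))
        d = int((rr >> uint64(8)) & uint64(3))
        y = 1 + idx // wi
        x = 1 + idx - (idx // wi) * wi
        if d == 0:
            ny, nx = y, x + 1
        elif d == 1:
            ny, nx = y, x - 1
        elif d == 2:
            ny, nx = y + 1, x
        else:
            ny, nx = y - 1, x
        s_src = labels[ny, nx]
        s_old = labels[y, x]
        if s_src == s_old:
            # copying a label onto itself changes nothing: dH = 0, accepted
            accepted += 1
            continue
        if s_src == 0:
            # the boundary ring is not a cell; its label never invades
            continue
        if (not allow_vanish) and areas[s_old] <= 1:
            continue
        t_src = ctype[s_src]
        t_old = ctype[s_old]
        de = 0.0
        sn = labels[y, x + 1]
        tn = ctype[sn]
        if sn != s_old:
            de -= J[t_old, tn]
        if sn != s_src:
            de += J[t_src, tn]
        sn = labels[y, x - 1]
        tn = ctype[sn]
        if sn != s_old:
            de -= J[t_old, tn]
        if sn != s_src:
            de += J[t_src, tn]
        sn = labels[y + 1, x]
        tn = ctype[sn]
        if sn != s_old:
            de -= J[t_old, tn]
        if sn != s_src:
            de += J[t_src, tn]
        sn = labels[y - 1, x]
        tn = ctype[sn]
        if sn != s_old:
            de -= J[t_old, tn]
        if sn != s_src:
            de += J[t_src, tn]
        ao = float(areas[s_old])
        asrc = float(areas[s_src])
        Ao = a_target[t_old]
        As = a_target[t_src]
        de += lam * ((ao - 1.0 - Ao) ** 2 - (ao - Ao) ** 2
                     + (asrc + 1.0 - As) ** 2 - (asrc - As) ** 2)
        de -= (mu[t_src] - mu[t_old]) * C[y, x]
        if de <= 0.0 or _unit(state) < np.exp(-de / T):
            labels[y, x] = s_src
            areas[s_old] -= 1
            areas[s_src] += 1
            sumx[s_old] -= x
            sumx[s_src] += x
            sumy[s_old] -= y
            sumy[s_src] += y
            accepted += 1
            de_total += de
    return accepted, de_total
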