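"""Numba kernels for Wiener first-passage-time densities and path simulation.

The density of a drift-diffusion process (unit diffusion, drift ``v``,
absorbing boundaries at 0 and ``a``, start point ``w*a``) is evaluated with
the small-time / large-time series expansions, switching per evaluation to
whichever series needs fewer terms for the requested truncation error.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

PI = math.pi


@njit(cache=True)
def _f1_lower(s: float, w: float, eps: float) -> float:
    """Density of first passage through the LOWER boundary for the
    normalized process (a=1, v=0, start w) at normalized time s > 0."""
    if s <= 0.0:
        return 0.0
    # number of terms needed by each series for truncation error eps
    if PI * s * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(PI * s * eps) / (PI * PI * s))
        kl = max(kl, 1.0 / (PI * math.sqrt(s)))
    else:
        kl = 1.0 / (PI * math.sqrt(s))
    if 2.0 * math.sqrt(2.0 * PI * s) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * s * math.log(2.0 * eps * math.sqrt(2.0 * PI * s)))
        ks = max(ks, math.sqrt(s) + 1.0)
    else:
        ks = 2.0

    f = 0.0
    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2 + 1
        for k in range(lo, hi):
            z = w + 2.0 * k
            f += z * math.exp(-z * z / (2.0 * s))
        f /= math.sqrt(2.0 * PI * s * s * s)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            f += k * math.exp(-k * k * PI * PI * s / 2.0) * math.sin(k * PI * w)
        f *= PI
    return f


@njit(cache=True)
def _log_density_one(rt: float, choice: int, v: float, a: float, t: float,
                     w: float, eps: float) -> float:
    """Log first-passage density for one trial.

    choice 1 = upper boundary, 0 = lower boundary.  Returns -inf when the
    decision time rt - t is non-positive or parameters are invalid.
    """
    u = rt - t
    if u <= 0.0 or a <= 0.0 or w <= 0.0 or w >= 1.0:
        return -np.inf
    if choice == 1:  # reflect so the hit boundary becomes the lower one
        vv = -v
        ww = 1.0 - w
    else:
        vv = v
        ww = w
    s = u / (a * a)
    f1 = _f1_lower(s, ww, eps)
    if f1 <= 0.0:
        return -np.inf
    return math.log(f1) - math.log(a * a) - vv * a * ww - vv * vv * u / 2.0


@njit(cache=True)
def log_density_arr(rt, choice, v, a, t, w, eps):
    n = rt.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = _log_density_one(rt[i], choice[i], v[i], a[i], t[i], w, eps)
    return out


_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, fastmath=True)
def simulate_paths(v: float, a: float, t0: float, w: float, n: int,
                   dt: float, max_t: float, seed: int):
    """Euler-Maruyama first-passage simulation with unit diffusion.

    Returns (rt, choice) where choice is 1 (upper), 0 (lower) or -1 for
    paths censored at max_t.  Discrete monitoring misses barrier crossings
    that occur between grid points, inflating the effective boundary; the
    standard continuity correction shifts each barrier inward by
    0.5826*sqrt(dt) so first-passage statistics match the continuous
    process.  Uses an inline xorshift64* stream with Box-Muller normals
    (much faster than the library RNG in this tight loop); deterministic
    given the seed.
    """
    # splitmix-style seed scrambling into a non-zero xorshift state
    state = np.uint64(seed) * np.uint64(6364136223846793005) \
        + np.uint64(1442695040888963407)
    if state == np.uint64(0):
        state = np.uint64(88172645463325252)
    rt = np.empty(n)
    choice = np.empty(n, dtype=np.int64)
    sqdt = math.sqrt(dt)
    shift = 0.5826 * sqdt  # continuity correction for discrete monitoring
    if 2.0 * shift >= 0.5 * a:
        shift = 0.0
    upper = a - shift
    lower = shift
    max_steps = int(max_t / dt)
    have_spare = False
    spare = 0.0
    for i in range(n):
        x = w * a
        hit = -1
        steps = 0
        for j in range(max_steps):
            if have_spare:
                z = spare
                have_spare = False
            else:
                state ^= state >> np.uint64(12)
                state ^= state << np.uint64(25)
                state ^= state >> np.uint64(27)
                u1 = ((state * np.uint64(2685821657736338717))
                      >> np.uint64(11)) * _INV_2_53
                state ^= state >> np.uint64(12)
                state ^= state << np.uint64(25)
                state ^= state >> np.uint64(27)
                u2 = ((state * np.uint64(2685821657736338717))
                      >> np.uint64(11)) * _INV_2_53
                if u1 <= 0.0:
                    u1 = 1e-300
                r = math.sqrt(-2.0 * math.log(u1))
                z = r * math.cos(2.0 * math.pi * u2)
                spare = r * math.sin(2.0 * math.pi * u2)
                have_spare = True
            x += v * dt + sqdt * z
            steps = j + 1
            if x >= upper:
                hit = 1
                break
            if x <= lower:
                hit = 0
                break
        choice[i] = hit
        rt[i] = steps * dt + t0
    return rt, choice
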