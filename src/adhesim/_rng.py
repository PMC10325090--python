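"""Counter-free pseudo-random number generation for the simulation kernel.

The production kernel draws ~10^9 Gaussian variates per parameter sweep, which
makes the cost of random-number generation the dominant term in the step loop.
This module provides a self-contained xoshiro256++ bit generator together with
a 128-layer Marsaglia-Tsang ziggurat for standard-normal sampling, both
written so that numba can inline them into the kernel's hot loop.

The generator state is a 4-element uint64 array seeded from a single integer
via SplitMix64 (the seeding procedure recommended by the xoshiro authors).
All stochastic draws of one simulation run -- thermal kicks, unbinding tests,
binding tests and bundling assignments -- consume this one stream in the order
the step loop encounters them.

Distributional correctness of the ziggurat (moments, tail mass,
Kolmogorov-Smirnov against the normal CDF) is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "seed_state",
    "next_u64",
    "random_double",
    "standard_normal",
    "ZIG_KN",
    "ZIG_WN",
    "ZIG_FN",
    "normals",
    "uniforms",
]

_U64 = np.uint64

# tail cut-off of the 128-layer ziggurat for the standard normal
_ZIG_R = 3.442619855899
_ZIG_V = 9.91256303526217e-3


def _build_ziggurat_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # Marsaglia & Tsang (2000) table construction, 128 layers, 2^31 scaling.
    m1 = 2147483648.0
    dn = _ZIG_R
    tn = _ZIG_R
    vn = _ZIG_V
    kn = np.zeros(128, dtype=np.int64)
    wn = np.zeros(128, dtype=np.float64)
    fn = np.zeros(128, dtype=np.float64)
    q = vn / np.exp(-0.5 * dn * dn)
    kn[0] = int((dn / q) * m1)
    kn[1] = 0
    wn[0] = q / m1
    wn[127] = dn / m1
    fn[0] = 1.0
    fn[127] = np.exp(-0.5 * dn * dn)
    for i in range(126, 0, -1):
        dn = np.sqrt(-2.0 * np.log(vn / dn + np.exp(-0.5 * dn * dn)))
        kn[i + 1] = int((dn / tn) * m1)
        tn = dn
        fn[i] = np.exp(-0.5 * dn * dn)
        wn[i] = dn / m1
    return kn, wn, fn


ZIG_KN, ZIG_WN, ZIG_FN = _build_ziggurat_tables()


@njit(cache=True)
def seed_state(seed):
    """Expand an integer seed into a xoshiro256++ state with SplitMix64."""
    st = np.empty(4, dtype=np.uint64)
    z = _U64(seed)
    for i in range(4):
        z = z + _U64(0x9E3779B97F4A7C15)
        w = z
        w = (w ^ (w >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
        w = (w ^ (w >> _U64(27))) * _U64(0x94D049BB133111EB)
        st[i] = w ^ (w >> _U64(31))
    return st


@njit(inline="always")
def next_u64(st):
    """One xoshiro256++ step; mutates ``st`` in place."""
    s0 = st[0]
    s1 = st[1]
    s2 = st[2]
    s3 = st[3]
    t = s0 + s3
    result = ((t << _U64(23)) | (t >> _U64(41))) + s0
    tt = s1 << _U64(17)
    s2 ^= s0
    s3 ^= s1
    s1 ^= s2
    s0 ^= s3
    s2 ^= tt
    s3 = (s3 << _U64(45)) | (s3 >> _U64(19))
    st[0] = s0
    st[1] = s1
    st[2] = s2
    st[3] = s3
    return result


@njit(inline="always")
def random_double(st):
    """Uniform double in [0, 1) with 53 random bits."""
    return (next_u64(st) >> _U64(11)) * 1.1102230246251565e-16


@njit(inline="always")
def standard_normal(st, kn, wn, fn):
    """Standard-normal variate via the 128-layer ziggurat."""
    while True:
        u = next_u64(st)
        hz = np.int64(u >> _U64(32))
        if hz >= 2147483648:
            hz -= 4294967296
        iz = hz & 127
        ahz = hz if hz >= 0 else -hz
        if ahz < kn[iz]:
            return hz * wn[iz]
        # wedge or tail
        if iz == 0:
            while True:
                x = -np.log(random_double(st) + 5e-324) / _ZIG_R
                y = -np.log(random_double(st) + 5e-324)
                if y + y >= x * x:
                    return _ZIG_R + x if hz > 0 else -(_ZIG_R + x)
        x = hz * wn[iz]
        if fn[iz] + random_double(st) * (fn[iz - 1] - fn[iz]) < np.exp(-0.5 * x * x):
            return x
        # rejected: fall through and draw a fresh candidate


@njit(cache=True)
def normals(seed, n, kn, wn, fn):
    """Array of ``n`` ziggurat normals from a fresh stream (test helper)."""
    st = seed_state(seed)
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        out[i] = standard_normal(st, kn, wn, fn)
    return out


@njit(cache=True)
def uniforms(seed, n):
    """Array of ``n`` uniform [0,1) doubles from a fresh stream (test helper)."""
    st = seed_state(seed)
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        out[i] = random_double(st)
    return out
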