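"""Numba production kernel: the whole step loop of one run, compiled.

This is the performance path behind :func:`adhesim.engine.run`.  It
implements exactly the same per-step update as the pure-numpy reference
:func:`adhesim.engine.step` (forces -> Euler move -> unbinding -> binding),
with three well-known exact accelerations:

* thermal kicks come from a xoshiro256++ bit stream transformed by a
  128-layer ziggurat (see :mod:`adhesim._rng` for the reference
  implementation and the distributional tests).  The generator state is kept
  in local registers and the draw is spelled out inline at each site: going
  through a function boundary costs ~20x per draw with numba on this hot
  path, and ~10^9 draws per sweep make that the dominant term;
* the rare Bernoulli events (binding, unbinding) are thinned: a single
  uniform is compared against a cheap upper bound of the per-step
  probability first, and the exact probability (which requires the partner
  search or the rupture-rate exponentials) is evaluated only when the
  uniform falls under the bound -- standard thinning, which leaves every
  event probability exactly unchanged;
* ligand lookup exploits the lattice geometry: only vertices of the cell
  containing the integrin (plus periodic-image columns at the seam) can lie
  within the 20-nm capture radius on a 50-nm lattice.

Status codes returned: 0 ok, 1 non-finite position encountered, 2 event
capacity exceeded.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._rng import seed_state

__all__ = ["simulate"]

_U64 = np.uint64
_U11 = np.uint64(11)
_U17 = np.uint64(17)
_U19 = np.uint64(19)
_U23 = np.uint64(23)
_U32 = np.uint64(32)
_U41 = np.uint64(41)
_U45 = np.uint64(45)
_INV53 = 1.1102230246251565e-16  # 2^-53
_ZIG_R = 3.442619855899


@njit(inline="never")
def _zig_rare(hz, s0, s1, s2, s3, kn, wn, fn):
    """Ziggurat wedge/tail path (a few % of draws); returns (x, state...)."""
    iz = hz & 127
    while True:
        if iz == 0:
            while True:
                t = s0 + s3
                res = ((t << _U23) | (t >> _U41)) + s0
                tt = s1 << _U17
                s2 ^= s0
                s3 ^= s1
                s1 ^= s2
                s0 ^= s3
                s2 ^= tt
                s3 = (s3 << _U45) | (s3 >> _U19)
                u1 = (res >> _U11) * _INV53
                t = s0 + s3
                res = ((t << _U23) | (t >> _U41)) + s0
                tt = s1 << _U17
                s2 ^= s0
                s3 ^= s1
                s1 ^= s2
                s0 ^= s3
                s2 ^= tt
                s3 = (s3 << _U45) | (s3 >> _U19)
                u2 = (res >> _U11) * _INV53
                x = -np.log(u1 + 5e-324) / _ZIG_R
                y = -np.log(u2 + 5e-324)
                if y + y >= x * x:
                    return (_ZIG_R + x if hz > 0 else -(_ZIG_R + x)), s0, s1, s2, s3
        x = hz * wn[iz]
        t = s0 + s3
        res = ((t << _U23) | (t >> _U41)) + s0
        tt = s1 << _U17
        s2 ^= s0
        s3 ^= s1
        s1 ^= s2
        s0 ^= s3
        s2 ^= tt
        s3 = (s3 << _U45) | (s3 >> _U19)
        u = (res >> _U11) * _INV53
        if fn[iz] + u * (fn[iz - 1] - fn[iz]) < np.exp(-0.5 * x * x):
            return x, s0, s1, s2, s3
        # fresh candidate
        t = s0 + s3
        res = ((t << _U23) | (t >> _U41)) + s0
        tt = s1 << _U17
        s2 ^= s0
        s3 ^= s1
        s1 ^= s2
        s0 ^= s3
        s2 ^= tt
        s3 = (s3 << _U45) | (s3 >> _U19)
        hz = np.int64(res >> _U32)
        if hz >= 2147483648:
            hz -= 4294967296
        iz = hz & 127
        ahz = hz if hz >= 0 else -hz
        if ahz < kn[iz]:
            return hz * wn[iz], s0, s1, s2, s3


@njit(cache=True)
def _all_finite(pos):
    # separate function: the main kernel is compiled with fastmath, under
    # which NaN checks would be folded away
    for i in range(pos.shape[0]):
        if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])):
            return False
    return True


@njit(cache=True, fastmath=True)
def simulate(
    # state (mutated in place)
    pos, bound_to, bond_start,
    # ligand lattice
    lig, occ, rows, spacing,
    # geometry / integration
    side, dt, n_steps, sample_every,
    # mechanics
    therm_sd, therm_sd_fiber, idt_free, idt_fiber, idt_bound, k_um, L0_um, rbind_um,
    # kinetics (precomputed per-step probabilities and thinning bounds)
    p_on_base, p_on_fiber, p_bind_cap, a1, b1, a2, b2, T_thin, p_off_cap,
    # fiber
    fiber_on, half_w, fiber_c, myo_global, F_myo, flow_dx, P_b,
    # rng
    seed, kn, wn, fn,
    # outputs
    samp_count, samp_bound, samp_pos,
    bind_t, bind_i, bind_j,
    rup_t, rup_i, rup_j, rup_T, rup_dur,
):
    n = pos.shape[0]
    half = side / 2.0
    st = seed_state(seed)
    s0 = st[0]
    s1 = st[1]
    s2 = st[2]
    s3 = st[3]
    myo_on = F_myo > 0.0
    flow_on = flow_dx != 0.0
    rbind2 = rbind_um * rbind_um
    inv_spacing = 1.0 / spacing

    nb = 0
    nr = 0
    cap_b = bind_t.shape[0]
    cap_r = rup_t.shape[0]
    n_samp = 0

    # scratch for the binding pass
    cand_i = np.empty(n, dtype=np.int64)
    cand_u = np.empty(n, dtype=np.float64)

    for step in range(n_steps):
        t_now = (step + 1) * dt

        # ---- pass 1: forces, Euler move, wrap, flow, unbinding --------
        for i in range(n):
            x = pos[i, 0]
            y = pos[i, 1]
            j = bound_to[i]
            infib = fiber_on and (abs(y - fiber_c) <= half_w)
            # thermal noise std follows the local friction
            # (fluctuation-dissipation; the multiplier applies to free
            # in-fiber integrins only)
            sd = therm_sd_fiber if (j < 0 and infib) else therm_sd
            # thermal force components: two ziggurat normals (inline draw)
            t = s0 + s3
            res = ((t << _U23) | (t >> _U41)) + s0
            tt = s1 << _U17
            s2 ^= s0
            s3 ^= s1
            s1 ^= s2
            s0 ^= s3
            s2 ^= tt
            s3 = (s3 << _U45) | (s3 >> _U19)
            hz = np.int64(res >> _U32)
            if hz >= 2147483648:
                hz -= 4294967296
            iz = hz & 127
            ahz = hz if hz >= 0 else -hz
            if ahz < kn[iz]:
                z = hz * wn[iz]
            else:
                z, s0, s1, s2, s3 = _zig_rare(hz, s0, s1, s2, s3, kn, wn, fn)
            fx = sd * z
            t = s0 + s3
            res = ((t << _U23) | (t >> _U41)) + s0
            tt = s1 << _U17
            s2 ^= s0
            s3 ^= s1
            s1 ^= s2
            s0 ^= s3
            s2 ^= tt
            s3 = (s3 << _U45) | (s3 >> _U19)
            hz = np.int64(res >> _U32)
            if hz >= 2147483648:
                hz -= 4294967296
            iz = hz & 127
            ahz = hz if hz >= 0 else -hz
            if ahz < kn[iz]:
                z = hz * wn[iz]
            else:
                z, s0, s1, s2, s3 = _zig_rare(hz, s0, s1, s2, s3, kn, wn, fn)
            fy = sd * z

            if j >= 0:
                lx = lig[j, 0]
                ly = lig[j, 1]
                dx = x - lx
                if dx > half:
                    dx -= side
                elif dx < -half:
                    dx += side
                dy = y - ly
                if dy > half:
                    dy -= side
                elif dy < -half:
                    dy += side
                dist = np.sqrt(dx * dx + dy * dy)
                dL = dist - L0_um
                if dL > 0.0:
                    f = k_um * dL / dist
                    fx -= f * dx
                    fy -= f * dy
                if myo_on and (myo_global or infib):
                    fx += F_myo
                x += fx * idt_bound
                y += fy * idt_bound
                if flow_on and infib:
                    x += flow_dx
                if x >= half:
                    x -= side
                    if x >= half:
                        x = (x + half) % side - half
                elif x < -half:
                    x += side
                    if x < -half:
                        x = (x + half) % side - half
                if y >= half:
                    y -= side
                    if y >= half:
                        y = (y + half) % side - half
                elif y < -half:
                    y += side
                    if y < -half:
                        y = (y + half) % side - half
                pos[i, 0] = x
                pos[i, 1] = y
                # rupture attempt at the post-move spring tension
                dx = x - lx
                if dx > half:
                    dx -= side
                elif dx < -half:
                    dx += side
                dy = y - ly
                if dy > half:
                    dy -= side
                elif dy < -half:
                    dy += side
                T = k_um * abs(np.sqrt(dx * dx + dy * dy) - L0_um)
                # uniform draw (inline)
                t = s0 + s3
                res = ((t << _U23) | (t >> _U41)) + s0
                tt = s1 << _U17
                s2 ^= s0
                s3 ^= s1
                s1 ^= s2
                s0 ^= s3
                s2 ^= tt
                s3 = (s3 << _U45) | (s3 >> _U19)
                u = (res >> _U11) * _INV53
                if T <= T_thin and u >= p_off_cap:
                    continue
                ko = a1 * np.exp(-b1 * T) + a2 * np.exp(b2 * T)
                xk = ko * dt
                if xk < 1e-3:
                    p = xk - 0.5 * xk * xk  # 1-exp(-x) to O(x^3)
                else:
                    p = 1.0 - np.exp(-xk)
                if u < p:
                    if nr >= cap_r:
                        return 2, nb, nr, n_samp
                    rup_t[nr] = t_now
                    rup_i[nr] = i
                    rup_j[nr] = j
                    rup_T[nr] = T
                    rup_dur[nr] = t_now - bond_start[i]
                    nr += 1
                    occ[j] = -1
                    bound_to[i] = -1
                    bond_start[i] = np.nan
            else:
                idt = idt_fiber if infib else idt_free
                x += fx * idt
                y += fy * idt
                if x >= half:
                    x -= side
                    if x >= half:
                        x = (x + half) % side - half
                elif x < -half:
                    x += side
                    if x < -half:
                        x = (x + half) % side - half
                if y >= half:
                    y -= side
                    if y >= half:
                        y = (y + half) % side - half
                elif y < -half:
                    y += side
                    if y < -half:
                        y = (y + half) % side - half
                pos[i, 0] = x
                pos[i, 1] = y

        # ---- pass 2: binding (thinned; contention resolved in random order)
        nc = 0
        for i in range(n):
            if bound_to[i] >= 0:
                continue
            t = s0 + s3
            res = ((t << _U23) | (t >> _U41)) + s0
            tt = s1 << _U17
            s2 ^= s0
            s3 ^= s1
            s1 ^= s2
            s0 ^= s3
            s2 ^= tt
            s3 = (s3 << _U45) | (s3 >> _U19)
            u = (res >> _U11) * _INV53
            if u < p_bind_cap:
                cand_i[nc] = i
                cand_u[nc] = u
                nc += 1
        if nc > 0:
            # Fisher-Yates shuffle of the (tiny) candidate list
            for a in range(nc - 1, 0, -1):
                t = s0 + s3
                res = ((t << _U23) | (t >> _U41)) + s0
                tt = s1 << _U17
                s2 ^= s0
                s3 ^= s1
                s1 ^= s2
                s0 ^= s3
                s2 ^= tt
                s3 = (s3 << _U45) | (s3 >> _U19)
                b = int(res % _U64(a + 1))
                tmp = cand_i[a]
                cand_i[a] = cand_i[b]
                cand_i[b] = tmp
                tmpu = cand_u[a]
                cand_u[a] = cand_u[b]
                cand_u[b] = tmpu
            for c in range(nc):
                i = cand_i[c]
                u = cand_u[c]
                x = pos[i, 0]
                y = pos[i, 1]
                infib = fiber_on and (abs(y - fiber_c) <= half_w)
                # exact per-step probability; the bundling assignment is a
                # fresh Bernoulli draw per integrin per step
                if infib and P_b > 0.0:
                    t = s0 + s3
                    res = ((t << _U23) | (t >> _U41)) + s0
                    tt = s1 << _U17
                    s2 ^= s0
                    s3 ^= s1
                    s1 ^= s2
                    s0 ^= s3
                    s2 ^= tt
                    s3 = (s3 << _U45) | (s3 >> _U19)
                    v = (res >> _U11) * _INV53
                    p_on = p_on_fiber if v < P_b else p_on_base
                else:
                    p_on = p_on_base
                if u >= p_on:
                    continue
                # nearest free ligand within the capture radius; candidate
                # vertices are the cell corners plus seam-image columns
                # clamp: keeps lattice indexing memory-safe even if a
                # position has gone non-finite (caught at the next sample)
                cx0 = int((x + half) * inv_spacing)
                cy0 = int((y + half) * inv_spacing)
                if cx0 < 0:
                    cx0 = 0
                elif cx0 > rows - 2:
                    cx0 = rows - 2
                if cy0 < 0:
                    cy0 = 0
                elif cy0 > rows - 2:
                    cy0 = rows - 2
                best = 1e30
                bj = -1
                for ax in range(3):
                    if ax == 0:
                        cx = cx0
                    elif ax == 1:
                        cx = cx0 + 1
                    else:
                        if cx0 == 0:
                            cx = rows - 1
                        elif cx0 + 1 == rows - 1:
                            cx = 0
                        else:
                            continue
                    for ay in range(3):
                        if ay == 0:
                            cy = cy0
                        elif ay == 1:
                            cy = cy0 + 1
                        else:
                            if cy0 == 0:
                                cy = rows - 1
                            elif cy0 + 1 == rows - 1:
                                cy = 0
                            else:
                                continue
                        jj = cy * rows + cx
                        if occ[jj] >= 0:
                            continue
                        dx = x - lig[jj, 0]
                        if dx > half:
                            dx -= side
                        elif dx < -half:
                            dx += side
                        dy = y - lig[jj, 1]
                        if dy > half:
                            dy -= side
                        elif dy < -half:
                            dy += side
                        d2 = dx * dx + dy * dy
                        if d2 < best:
                            best = d2
                            bj = jj
                if bj >= 0 and best < rbind2:
                    if nb >= cap_b:
                        return 2, nb, nr, n_samp
                    bind_t[nb] = t_now
                    bind_i[nb] = i
                    bind_j[nb] = bj
                    nb += 1
                    bound_to[i] = bj
                    occ[bj] = i
                    bond_start[i] = t_now

        # ---- sampling --------------------------------------------------
        if (step + 1) % sample_every == 0:
            if not _all_finite(pos):
                return 1, nb, nr, n_samp
            cnt = 0
            for i in range(n):
                if bound_to[i] >= 0:
                    cnt += 1
                    samp_bound[n_samp, i] = 1
                else:
                    samp_bound[n_samp, i] = 0
                samp_pos[n_samp, i, 0] = pos[i, 0]
                samp_pos[n_samp, i, 1] = pos[i, 1]
            samp_count[n_samp] = cnt
            n_samp += 1

    return 0, nb, nr, n_samp
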