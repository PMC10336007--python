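"""Numba kernels for force evaluation and BAOAB Langevin integration.

All kernels work in reduced units (bead diameter sigma = 1, kBT = 1, mass = 1)
on batches of independent chains.  Pair interactions act between every bead
pair, including chain neighbours.  Pair kinds: 0 = none, 1 = WCA, 2 = truncated
and shifted Lennard-Jones, 3 = tabulated piecewise cubic.

Forces from overlapping beads (r < 1e-9) are regularized by capping the pair
force magnitude at ``FORCE_CAP`` along a fixed axis.
"""

import numpy as np
from numba import njit

FORCE_CAP = 1.0e3

# Speed clamp for the integrator: bounds per-step displacement during violent
# transients (e.g. freshly inserted long-range springs driving beads through
# WCA cores).  ~6x the thermal speed at kBT = 1, so equilibrium sampling is
# untouched (clipping probability ~ exp(-50)).
VELOCITY_CAP = 10.0

PAIR_NONE = 0
PAIR_WCA = 1
PAIR_LJ = 2
PAIR_TAB = 3

_WCA_CUT_FACTOR = 2.0 ** (1.0 / 6.0)


@njit(cache=True, fastmath=True)
def _pair_v_dvdr(r, kind, eps, sig, rcut, tx0, tdx, tc, tcut):
    """Pair potential value and radial derivative dV/dr at distance r."""
    if kind == PAIR_WCA:
        rc = _WCA_CUT_FACTOR * sig
        if r >= rc:
            return 0.0, 0.0
        sr2 = (sig / r) ** 2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        v = 4.0 * eps * (sr12 - sr6) + eps
        dvdr = -4.0 * eps * (12.0 * sr12 - 6.0 * sr6) / r
        return v, dvdr
    elif kind == PAIR_LJ:
        if r >= rcut:
            return 0.0, 0.0
        sr2 = (sig / r) ** 2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        src2 = (sig / rcut) ** 2
        src6 = src2 * src2 * src2
        vshift = 4.0 * eps * (src6 * src6 - src6)
        v = 4.0 * eps * (sr12 - sr6) - vshift
        dvdr = -4.0 * eps * (12.0 * sr12 - 6.0 * sr6) / r
        return v, dvdr
    elif kind == PAIR_TAB:
        if r >= tcut:
            return 0.0, 0.0
        n_int = tc.shape[0]
        if r < tx0:
            # continue the left edge linearly (force continuity at the grid start)
            c = tc[0]
            v0 = c[0]
            d0 = c[1]
            return v0 + d0 * (r - tx0), d0
        k = int((r - tx0) / tdx)
        if k >= n_int:
            return 0.0, 0.0
        t = r - (tx0 + k * tdx)
        c = tc[k]
        v = c[0] + t * (c[1] + t * (c[2] + t * c[3]))
        dvdr = c[1] + t * (2.0 * c[2] + 3.0 * t * c[3])
        return v, dvdr
    return 0.0, 0.0


@njit(cache=True, fastmath=True)
def _forces_one(x, f, chain_k, chain_r0,
                pkind, peps, psig, prcut, tx0, tdx, tc, tcut,
                cb_i, cb_j, cb_k, cb_r0):
    """Fill f with forces for one conformation; return potential energy."""
    n = x.shape[0]
    for a in range(n):
        f[a, 0] = 0.0
        f[a, 1] = 0.0
        f[a, 2] = 0.0
    pe = 0.0

    # chain bonds
    for a in range(n - 1):
        dx = x[a + 1, 0] - x[a, 0]
        dy = x[a + 1, 1] - x[a, 1]
        dz = x[a + 1, 2] - x[a, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        pe += 0.5 * chain_k * (r - chain_r0) ** 2
        if r > 1e-9:
            fmag = -chain_k * (r - chain_r0)
            fx = fmag * dx / r
            fy = fmag * dy / r
            fz = fmag * dz / r
        else:
            fx = FORCE_CAP
            fy = 0.0
            fz = 0.0
        f[a + 1, 0] += fx
        f[a + 1, 1] += fy
        f[a + 1, 2] += fz
        f[a, 0] -= fx
        f[a, 1] -= fy
        f[a, 2] -= fz

    # constraint bonds
    for b in range(cb_i.shape[0]):
        a1 = cb_i[b]
        a2 = cb_j[b]
        kb = cb_k[b]
        r0b = cb_r0[b]
        dx = x[a2, 0] - x[a1, 0]
        dy = x[a2, 1] - x[a1, 1]
        dz = x[a2, 2] - x[a1, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        pe += 0.5 * kb * (r - r0b) ** 2
        if r > 1e-9:
            fmag = -kb * (r - r0b)
            fx = fmag * dx / r
            fy = fmag * dy / r
            fz = fmag * dz / r
        else:
            fx = FORCE_CAP
            fy = 0.0
            fz = 0.0
        f[a2, 0] += fx
        f[a2, 1] += fy
        f[a2, 2] += fz
        f[a1, 0] -= fx
        f[a1, 1] -= fy
        f[a1, 2] -= fz

    # non-bonded pairs (all i < j, chain neighbours included)
    if pkind != PAIR_NONE:
        if pkind == PAIR_WCA:
            rc = _WCA_CUT_FACTOR * psig
        elif pkind == PAIR_LJ:
            rc = prcut
        else:
            rc = tcut
        rc2 = rc * rc
        for a1 in range(n - 1):
            for a2 in range(a1 + 1, n):
                dx = x[a2, 0] - x[a1, 0]
                dy = x[a2, 1] - x[a1, 1]
                dz = x[a2, 2] - x[a1, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 >= rc2:
                    continue
                r = np.sqrt(r2)
                if r > 1e-9:
                    v, dvdr = _pair_v_dvdr(r, pkind, peps, psig, prcut,
                                           tx0, tdx, tc, tcut)
                    pe += v
                    fmag = -dvdr
                    fx = fmag * dx / r
                    fy = fmag * dy / r
                    fz = fmag * dz / r
                else:
                    v, _ = _pair_v_dvdr(1e-9, pkind, peps, psig, prcut,
                                        tx0, tdx, tc, tcut)
                    pe += v
                    fx = FORCE_CAP
                    fy = 0.0
                    fz = 0.0
                f[a2, 0] += fx
                f[a2, 1] += fy
                f[a2, 2] += fz
                f[a1, 0] -= fx
                f[a1, 1] -= fy
                f[a1, 2] -= fz
    return pe


@njit(cache=True, fastmath=True)
def _rg_one(x):
    n = x.shape[0]
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for a in range(n):
        cx += x[a, 0]
        cy += x[a, 1]
        cz += x[a, 2]
    cx /= n
    cy /= n
    cz /= n
    s = 0.0
    for a in range(n):
        s += (x[a, 0] - cx) ** 2 + (x[a, 1] - cy) ** 2 + (x[a, 2] - cz) ** 2
    return np.sqrt(s / n)


@njit(cache=True, fastmath=True)
def _max_bond_one(x):
    n = x.shape[0]
    m = 0.0
    for a in range(n - 1):
        dx = x[a + 1, 0] - x[a, 0]
        dy = x[a + 1, 1] - x[a, 1]
        dz = x[a + 1, 2] - x[a, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > m:
            m = r
    return m


@njit(cache=True, fastmath=True)
def _clamp_speed(v, n):
    cap2 = VELOCITY_CAP * VELOCITY_CAP
    for a in range(n):
        s2 = v[a, 0] ** 2 + v[a, 1] ** 2 + v[a, 2] ** 2
        if s2 > cap2:
            sc = VELOCITY_CAP / np.sqrt(s2)
            v[a, 0] *= sc
            v[a, 1] *= sc
            v[a, 2] *= sc


@njit(cache=True)
def baoab_batch(X, V, dt, gamma, kT, n_steps, seed, sample_every,
                chain_k, chain_r0,
                pkind, peps, psig, prcut, tx0, tdx, tc, tcut,
                cb_ptr, cb_i, cb_j, cb_k, cb_r0,
                rg_out, pe_out, ke_out, maxbond_out,
                store_samples, samples_out):
    """BAOAB Langevin integration of a batch of independent chains.

    X, V : (S, N, 3) positions and velocities, updated in place.
    cb_ptr : (S+1,) CSR offsets into the flat constraint-bond arrays.
    rg_out, pe_out, maxbond_out : (S, n_rec) per-sample observables.
    samples_out : (S, n_rec, N, 3), written only when store_samples != 0.

    Returns -1 on success, else the step index at which coordinates became
    non-finite.
    """
    S = X.shape[0]
    n = X.shape[1]
    np.random.seed(seed)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    F = np.empty((S, n, 3))
    pe_cur = np.empty(S)
    for s in range(S):
        pe_cur[s] = _forces_one(X[s], F[s], chain_k, chain_r0,
                                pkind, peps, psig, prcut, tx0, tdx, tc, tcut,
                                cb_i[cb_ptr[s]:cb_ptr[s + 1]],
                                cb_j[cb_ptr[s]:cb_ptr[s + 1]],
                                cb_k[cb_ptr[s]:cb_ptr[s + 1]],
                                cb_r0[cb_ptr[s]:cb_ptr[s + 1]])
    rec = 0
    for step in range(n_steps):
        for s in range(S):
            x = X[s]
            v = V[s]
            f = F[s]
            for a in range(n):
                for d in range(3):
                    v[a, d] += 0.5 * dt * f[a, d]
            _clamp_speed(v, n)
            for a in range(n):
                for d in range(3):
                    x[a, d] += 0.5 * dt * v[a, d]
            if c2 > 0.0:
                for a in range(n):
                    for d in range(3):
                        v[a, d] = c1 * v[a, d] + c2 * np.random.normal(0.0, 1.0)
            else:
                for a in range(n):
                    for d in range(3):
                        v[a, d] = c1 * v[a, d]
            _clamp_speed(v, n)
            for a in range(n):
                for d in range(3):
                    x[a, d] += 0.5 * dt * v[a, d]
            pe_cur[s] = _forces_one(x, f, chain_k, chain_r0,
                                    pkind, peps, psig, prcut,
                                    tx0, tdx, tc, tcut,
                                    cb_i[cb_ptr[s]:cb_ptr[s + 1]],
                                    cb_j[cb_ptr[s]:cb_ptr[s + 1]],
                                    cb_k[cb_ptr[s]:cb_ptr[s + 1]],
                                    cb_r0[cb_ptr[s]:cb_ptr[s + 1]])
            for a in range(n):
                for d in range(3):
                    v[a, d] += 0.5 * dt * f[a, d]
        if (step + 1) % sample_every == 0 and rec < rg_out.shape[1]:
            for s in range(S):
                ok = True
                for a in range(n):
                    for d in range(3):
                        if not np.isfinite(X[s, a, d]):
                            ok = False
                if not ok:
                    return step
                rg_out[s, rec] = _rg_one(X[s])
                pe_out[s, rec] = pe_cur[s]
                ke = 0.0
                for a in range(n):
                    for d in range(3):
                        ke += 0.5 * V[s, a, d] * V[s, a, d]
                ke_out[s, rec] = ke
                maxbond_out[s, rec] = _max_bond_one(X[s])
                if store_samples != 0:
                    for a in range(n):
                        for d in range(3):
                            samples_out[s, rec, a, d] = X[s, a, d]
            rec += 1
    return -1
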