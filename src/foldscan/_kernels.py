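"""Numba kernels: chain geometry and the two Monte Carlo inner loops.

Everything here is deliberately flat and allocation-light; the public
modules (:mod:`foldscan.fvalue`, :mod:`foldscan.go_model`) wrap these in
typed, documented interfaces.  Seeding: callers derive independent 31-bit
seeds (numpy SeedSequence) and pass them in; each kernel reseeds numba's
thread-local generator on entry, so runs are reproducible regardless of
call order.
"""
from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# chain geometry
# ---------------------------------------------------------------------------

@njit(cache=True)
def build_chain(thetas, phis, bond):
    """Cartesian Cα coordinates from bond angles and dihedrals (NeRF).

    thetas: (N-2,) bond angles in (0, π); phis: (N-3,) dihedrals.
    """
    n = thetas.shape[0] + 2
    x = np.zeros((n, 3))
    x[1, 0] = bond
    if n > 2:
        x[2, 0] = bond - bond * np.cos(thetas[0])
        x[2, 1] = bond * np.sin(thetas[0])
    for i in range(3, n):
        theta = thetas[i - 2]
        phi = phis[i - 3]
        a = x[i - 3]
        b = x[i - 2]
        c = x[i - 1]
        bc0 = c[0] - b[0]; bc1 = c[1] - b[1]; bc2 = c[2] - b[2]
        nb = np.sqrt(bc0 * bc0 + bc1 * bc1 + bc2 * bc2)
        bc0 /= nb; bc1 /= nb; bc2 /= nb
        ab0 = b[0] - a[0]; ab1 = b[1] - a[1]; ab2 = b[2] - a[2]
        # n = ab x bc, normalized
        n0 = ab1 * bc2 - ab2 * bc1
        n1 = ab2 * bc0 - ab0 * bc2
        n2 = ab0 * bc1 - ab1 * bc0
        nn = np.sqrt(n0 * n0 + n1 * n1 + n2 * n2)
        if nn < 1e-12:
            # previous three collinear; pick any perpendicular
            if abs(bc0) < 0.9:
                n0, n1, n2 = 0.0, bc2, -bc1
            else:
                n0, n1, n2 = -bc2, 0.0, bc0
            nn = np.sqrt(n0 * n0 + n1 * n1 + n2 * n2)
        n0 /= nn; n1 /= nn; n2 /= nn
        # m = n x bc
        m0 = n1 * bc2 - n2 * bc1
        m1 = n2 * bc0 - n0 * bc2
        m2 = n0 * bc1 - n1 * bc0
        d0 = -bond * np.cos(theta)
        d1 = bond * np.sin(theta) * np.cos(phi)
        d2 = bond * np.sin(theta) * np.sin(phi)
        x[i, 0] = c[0] + d0 * bc0 + d1 * m0 + d2 * n0
        x[i, 1] = c[1] + d0 * bc1 + d1 * m1 + d2 * n1
        x[i, 2] = c[2] + d0 * bc2 + d1 * m2 + d2 * n2
    return x


@njit(cache=True)
def bond_angles(x):
    """Bond angle at each interior residue (length N-2)."""
    n = x.shape[0]
    out = np.empty(n - 2)
    for i in range(1, n - 1):
        u0 = x[i - 1, 0] - x[i, 0]; u1 = x[i - 1, 1] - x[i, 1]; u2 = x[i - 1, 2] - x[i, 2]
        v0 = x[i + 1, 0] - x[i, 0]; v1 = x[i + 1, 1] - x[i, 1]; v2 = x[i + 1, 2] - x[i, 2]
        nu = np.sqrt(u0 * u0 + u1 * u1 + u2 * u2)
        nv = np.sqrt(v0 * v0 + v1 * v1 + v2 * v2)
        c = (u0 * v0 + u1 * v1 + u2 * v2) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        out[i - 1] = np.arccos(c)
    return out


@njit(cache=True)
def dihedral_angles(x):
    """Dihedral over each quadruple (i, i+1, i+2, i+3); length N-3."""
    n = x.shape[0]
    out = np.empty(n - 3)
    for i in range(n - 3):
        b1 = x[i + 1] - x[i]
        b2 = x[i + 2] - x[i + 1]
        b3 = x[i + 3] - x[i + 2]
        c10 = b1[1] * b2[2] - b1[2] * b2[1]
        c11 = b1[2] * b2[0] - b1[0] * b2[2]
        c12 = b1[0] * b2[1] - b1[1] * b2[0]
        c20 = b2[1] * b3[2] - b2[2] * b3[1]
        c21 = b2[2] * b3[0] - b2[0] * b3[2]
        c22 = b2[0] * b3[1] - b2[1] * b3[0]
        nb2 = np.sqrt(b2[0] * b2[0] + b2[1] * b2[1] + b2[2] * b2[2])
        xx = c10 * c20 + c11 * c21 + c12 * c22
        yy = (b1[0] * c20 + b1[1] * c21 + b1[2] * c22) * nb2
        out[i] = np.arctan2(yy, xx)
    return out


# ---------------------------------------------------------------------------
# F-value sampler: Cα chain under the harmonic average-distance potential
# ---------------------------------------------------------------------------

@njit(cache=True)
def harmonic_energy(x, rbar, hw):
    """U = Σ_{i<j} hw_ij (d_ij − rbar_ij)²; hw = 1/(2σ²), 0 = excluded."""
    n = x.shape[0]
    e = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            w = hw[i, j]
            if w > 0.0:
                d0 = x[i, 0] - x[j, 0]
                d1 = x[i, 1] - x[j, 1]
                d2 = x[i, 2] - x[j, 2]
                d = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2) - rbar[i, j]
                e += w * d * d
    return e


@njit(cache=True)
def _reflect_theta(t):
    """Reflect into (0, π) (uniform-perturbation proposals stay symmetric)."""
    t = t % TWO_PI
    if t < 0.0:
        t += TWO_PI
    if t > np.pi:
        t = TWO_PI - t
    if t < 1e-6:
        t = 1e-6
    elif t > np.pi - 1e-6:
        t = np.pi - 1e-6
    return t


@njit(cache=True)
def fvalue_mc(rbar, hw, n_steps, tau, delta, cutoff, seed, accumulate):
    """Metropolis sampling of a Cα chain in a random state.

    One MC step perturbs every bond and dihedral angle by uniform(−δ, δ)
    and applies a single accept/reject on the total energy.  Contacts
    (d < cutoff) of the current structure are counted every step, the
    initial random conformation included.

    Returns (g contact-count matrix, acceptance fraction, end-to-end
    distance series over the run — one sample per step, initial state
    included; handy for distribution checks on toy chains).
    """
    np.random.seed(seed)
    n = rbar.shape[0]
    bond = 3.8
    thetas = np.empty(n - 2)
    for i in range(n - 2):
        thetas[i] = np.random.uniform(1e-3, np.pi - 1e-3)
    phis = np.empty(n - 3)
    for i in range(n - 3):
        phis[i] = np.random.uniform(-np.pi, np.pi)
    x = build_chain(thetas, phis, bond)
    e = harmonic_energy(x, rbar, hw)
    g = np.zeros((n, n), dtype=np.int64)
    if accumulate:
        _count_contacts(x, cutoff, g)
    ree = np.empty(n_steps + 1)
    d0 = x[0, 0] - x[n - 1, 0]; d1 = x[0, 1] - x[n - 1, 1]; d2 = x[0, 2] - x[n - 1, 2]
    ree[0] = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
    n_acc = 0
    new_t = np.empty_like(thetas)
    new_p = np.empty_like(phis)
    for step in range(n_steps):
        for i in range(n - 2):
            new_t[i] = _reflect_theta(thetas[i] + np.random.uniform(-delta, delta))
        for i in range(n - 3):
            p = phis[i] + np.random.uniform(-delta, delta)
            if p > np.pi:
                p -= TWO_PI
            elif p < -np.pi:
                p += TWO_PI
            new_p[i] = p
        xn = build_chain(new_t, new_p, bond)
        en = harmonic_energy(xn, rbar, hw)
        if en <= e or np.random.random() < np.exp(-(en - e) / tau):
            thetas[:] = new_t
            phis[:] = new_p
            x = xn
            e = en
            n_acc += 1
        if accumulate:
            _count_contacts(x, cutoff, g)
        d0 = x[0, 0] - x[n - 1, 0]; d1 = x[0, 1] - x[n - 1, 1]; d2 = x[0, 2] - x[n - 1, 2]
        ree[step + 1] = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
    return g, n_acc / max(n_steps, 1), ree


@njit(cache=True)
def _count_contacts(x, cutoff, g):
    n = x.shape[0]
    c2 = cutoff * cutoff
    for i in range(n - 1):
        for j in range(i + 1, n):
            d0 = x[i, 0] - x[j, 0]
            d1 = x[i, 1] - x[j, 1]
            d2 = x[i, 2] - x[j, 2]
            if d0 * d0 + d1 * d1 + d2 * d2 < c2:
                g[i, j] += 1


# ---------------------------------------------------------------------------
# Gō model: orientation-dependent energy + pivot/crankshaft MC
# ---------------------------------------------------------------------------

@njit(cache=True)
def _h_vectors(x):
    """h_i = r_{i,i-1} + r_{i,i+1}; zero rows at the termini."""
    n = x.shape[0]
    h = np.zeros((n, 3))
    for i in range(1, n - 1):
        h[i, 0] = (x[i - 1, 0] - x[i, 0]) + (x[i + 1, 0] - x[i, 0])
        h[i, 1] = (x[i - 1, 1] - x[i, 1]) + (x[i + 1, 1] - x[i, 1])
        h[i, 2] = (x[i - 1, 2] - x[i, 2]) + (x[i + 1, 2] - x[i, 2])
    return h


@njit(cache=True)
def orientation_angle(h, i, j):
    """Θ_ij: angle between the bisector vectors of residues i and j."""
    hi0, hi1, hi2 = h[i, 0], h[i, 1], h[i, 2]
    hj0, hj1, hj2 = h[j, 0], h[j, 1], h[j, 2]
    ni = np.sqrt(hi0 * hi0 + hi1 * hi1 + hi2 * hi2)
    nj = np.sqrt(hj0 * hj0 + hj1 * hj1 + hj2 * hj2)
    if ni < 1e-10 or nj < 1e-10:
        return 0.0
    c = (hi0 * hj0 + hi1 * hj1 + hi2 * hj2) / (ni * nj)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return np.arccos(c)


@njit(cache=True)
def go_energy(x, theta0, phi0, nc_i, nc_j, nc_r0, nc_c, nc_t0, nc_term,
              is_nc, k_theta, k_phi1, k_phi3, a_theta, sigma_nnc):
    """Total Gō energy in units of ε (Eq. forms in go_model docs).

    Terms: bond-angle harmonic, 1-/3-fold dihedral wells (offset so the
    native state zeroes them), native contacts εC_ij[5x¹² − 6B_ij x¹⁰]
    with the orientation factor B, and a (σ/r)¹² repulsion between
    non-native pairs with |i−j| ≥ 4.
    """
    n = x.shape[0]
    e = 0.0
    th = bond_angles(x)
    for i in range(n - 2):
        d = th[i] - theta0[i]
        e += k_theta * d * d
    ph = dihedral_angles(x)
    for i in range(n - 3):
        d = ph[i] - phi0[i]
        e += k_phi1 * (1.0 - np.cos(d)) + k_phi3 * (1.0 - np.cos(3.0 * d))
    h = _h_vectors(x)
    a2 = a_theta * a_theta
    for c in range(nc_i.shape[0]):
        i = nc_i[c]; j = nc_j[c]
        d0 = x[i, 0] - x[j, 0]; d1 = x[i, 1] - x[j, 1]; d2 = x[i, 2] - x[j, 2]
        r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        if r < 1e-10:
            return 1e30
        if nc_term[c]:
            b = 1.0
        else:
            dth = orientation_angle(h, i, j) - nc_t0[c]
            if dth < 0.0:
                dth = -dth
            b = 1.0 - dth * dth / a2 if dth < a_theta else 0.0
        xr = nc_r0[c] / r
        x10 = xr ** 10
        e += nc_c[c] * (5.0 * x10 * xr * xr - 6.0 * b * x10)
    for i in range(n - 4):
        for j in range(i + 4, n):
            if not is_nc[i, j]:
                d0 = x[i, 0] - x[j, 0]; d1 = x[i, 1] - x[j, 1]; d2 = x[i, 2] - x[j, 2]
                r2 = d0 * d0 + d1 * d1 + d2 * d2
                if r2 < 1e-20:
                    return 1e30
                s2 = sigma_nnc * sigma_nnc / r2
                s6 = s2 * s2 * s2
                e += s6 * s6
    return e


@njit(cache=True)
def q_value_kernel(x, nc_i, nc_j, nc_r0, formed_factor):
    nc = nc_i.shape[0]
    formed = 0
    for c in range(nc):
        i = nc_i[c]; j = nc_j[c]
        d0 = x[i, 0] - x[j, 0]; d1 = x[i, 1] - x[j, 1]; d2 = x[i, 2] - x[j, 2]
        r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        if r < formed_factor * nc_r0[c]:
            formed += 1
    return formed / nc


@njit(cache=True)
def _contact_states(x, nc_i, nc_j, nc_r0, formed_factor, out):
    for c in range(nc_i.shape[0]):
        i = nc_i[c]; j = nc_j[c]
        d0 = x[i, 0] - x[j, 0]; d1 = x[i, 1] - x[j, 1]; d2 = x[i, 2] - x[j, 2]
        r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        out[c] = 1 if r < formed_factor * nc_r0[c] else 0


@njit(cache=True)
def _rotate_about(x, lo, hi, origin, axis, angle):
    """Rodrigues rotation of beads lo..hi (inclusive) about axis at origin."""
    a0, a1, a2 = axis[0], axis[1], axis[2]
    na = np.sqrt(a0 * a0 + a1 * a1 + a2 * a2)
    a0 /= na; a1 /= na; a2 /= na
    ca = np.cos(angle)
    sa = np.sin(angle)
    for i in range(lo, hi + 1):
        v0 = x[i, 0] - origin[0]
        v1 = x[i, 1] - origin[1]
        v2 = x[i, 2] - origin[2]
        # a x v
        c0 = a1 * v2 - a2 * v1
        c1 = a2 * v0 - a0 * v2
        c2 = a0 * v1 - a1 * v0
        dot = a0 * v0 + a1 * v1 + a2 * v2
        x[i, 0] = origin[0] + v0 * ca + c0 * sa + a0 * dot * (1.0 - ca)
        x[i, 1] = origin[1] + v1 * ca + c1 * sa + a1 * dot * (1.0 - ca)
        x[i, 2] = origin[2] + v2 * ca + c2 * sa + a2 * dot * (1.0 - ca)


@njit(cache=True)
def _h_of(x, i):
    """h_i computed on the fly (caller guarantees 0 < i < n-1)."""
    return ((x[i - 1, 0] - x[i, 0]) + (x[i + 1, 0] - x[i, 0]),
            (x[i - 1, 1] - x[i, 1]) + (x[i + 1, 1] - x[i, 1]),
            (x[i - 1, 2] - x[i, 2]) + (x[i + 1, 2] - x[i, 2]))


@njit(cache=True)
def _angle3(x, r):
    u0 = x[r - 1, 0] - x[r, 0]; u1 = x[r - 1, 1] - x[r, 1]; u2 = x[r - 1, 2] - x[r, 2]
    v0 = x[r + 1, 0] - x[r, 0]; v1 = x[r + 1, 1] - x[r, 1]; v2 = x[r + 1, 2] - x[r, 2]
    nu = np.sqrt(u0 * u0 + u1 * u1 + u2 * u2)
    nv = np.sqrt(v0 * v0 + v1 * v1 + v2 * v2)
    c = (u0 * v0 + u1 * v1 + u2 * v2) / (nu * nv)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return np.arccos(c)


@njit(cache=True)
def _dihedral4(x, d):
    b10 = x[d + 1, 0] - x[d, 0]; b11 = x[d + 1, 1] - x[d, 1]; b12 = x[d + 1, 2] - x[d, 2]
    b20 = x[d + 2, 0] - x[d + 1, 0]; b21 = x[d + 2, 1] - x[d + 1, 1]; b22 = x[d + 2, 2] - x[d + 1, 2]
    b30 = x[d + 3, 0] - x[d + 2, 0]; b31 = x[d + 3, 1] - x[d + 2, 1]; b32 = x[d + 3, 2] - x[d + 2, 2]
    c10 = b11 * b22 - b12 * b21
    c11 = b12 * b20 - b10 * b22
    c12 = b10 * b21 - b11 * b20
    c20 = b21 * b32 - b22 * b31
    c21 = b22 * b30 - b20 * b32
    c22 = b20 * b31 - b21 * b30
    nb2 = np.sqrt(b20 * b20 + b21 * b21 + b22 * b22)
    xx = c10 * c20 + c11 * c21 + c12 * c22
    yy = (b10 * c20 + b11 * c21 + b12 * c22) * nb2
    return np.arctan2(yy, xx)


@njit(cache=True)
def _partial_energy(x, lo, hi, theta0, phi0, nc_i, nc_j, nc_r0, nc_c,
                    nc_t0, nc_term, is_nc, k_theta, k_phi1, k_phi3,
                    a_theta, sigma_nnc):
    """Energy terms affected by a rigid rotation of beads lo..hi.

    A rigid rotation leaves distances within the segment and outside it
    unchanged, and rotates the bisector vectors of the segment's strict
    interior rigidly; only boundary-crossing terms can change:
    bond angles/dihedrals whose atom windows span a boundary, native
    contacts that cross it or touch a bead whose h changes intrinsically
    (lo−1, lo, hi, hi+1), and non-native cross pairs.  Returns (partial
    energy, max affected bond angle) so the caller can enforce θ < π.
    """
    n = x.shape[0]
    e = 0.0
    th_max = 0.0
    for r in (lo - 1, lo, hi, hi + 1):
        if 1 <= r <= n - 2 and not (r == lo - 1 and r == hi + 1):
            th = _angle3(x, r)
            if th > th_max:
                th_max = th
            d = th - theta0[r - 1]
            e += k_theta * d * d
    # avoid double counting when hi == lo (sets overlap)
    if hi - lo <= 2:
        # small segments: the four candidates may coincide; recompute cleanly
        e = 0.0
        th_max = 0.0
        r_lo = lo - 1 if lo - 1 >= 1 else 1
        r_hi = hi + 1 if hi + 1 <= n - 2 else n - 2
        for r in range(r_lo, r_hi + 1):
            th = _angle3(x, r)
            if th > th_max:
                th_max = th
            d = th - theta0[r - 1]
            e += k_theta * d * d
    d_lo = lo - 3 if lo - 3 >= 0 else 0
    d_hi = hi if hi <= n - 4 else n - 4
    for dd in range(d_lo, d_hi + 1):
        if dd >= lo and dd + 3 <= hi:
            continue                      # fully inside: rigid
        ph = _dihedral4(x, dd)
        d = ph - phi0[dd]
        e += k_phi1 * (1.0 - np.cos(d)) + k_phi3 * (1.0 - np.cos(3.0 * d))
    a2 = a_theta * a_theta
    for c in range(nc_i.shape[0]):
        i = nc_i[c]; j = nc_j[c]
        mi = lo <= i <= hi
        mj = lo <= j <= hi
        touch = (lo - 1 <= i <= lo) or (hi <= i <= hi + 1) \
            or (lo - 1 <= j <= lo) or (hi <= j <= hi + 1)
        if mi == mj and not touch:
            continue
        d0 = x[i, 0] - x[j, 0]; d1 = x[i, 1] - x[j, 1]; d2 = x[i, 2] - x[j, 2]
        r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        if r < 1e-10:
            return 1e30, th_max
        if nc_term[c]:
            b = 1.0
        else:
            hi0, hi1, hi2 = _h_of(x, i)
            hj0, hj1, hj2 = _h_of(x, j)
            ni = np.sqrt(hi0 * hi0 + hi1 * hi1 + hi2 * hi2)
            nj = np.sqrt(hj0 * hj0 + hj1 * hj1 + hj2 * hj2)
            if ni < 1e-10 or nj < 1e-10:
                return 1e30, np.pi
            cth = (hi0 * hj0 + hi1 * hj1 + hi2 * hj2) / (ni * nj)
            if cth > 1.0:
                cth = 1.0
            elif cth < -1.0:
                cth = -1.0
            dth = np.arccos(cth) - nc_t0[c]
            if dth < 0.0:
                dth = -dth
            b = 1.0 - dth * dth / a2 if dth < a_theta else 0.0
        xr = nc_r0[c] / r
        x10 = xr ** 10
        e += nc_c[c] * (5.0 * x10 * xr * xr - 6.0 * b * x10)
    s2c = sigma_nnc * sigma_nnc
    for i in range(lo, hi + 1):
        for j in range(n):
            if lo <= j <= hi:
                continue
            k = i - j if i > j else j - i
            if k < 4:
                continue
            if is_nc[i, j]:
                continue
            d0 = x[i, 0] - x[j, 0]; d1 = x[i, 1] - x[j, 1]; d2 = x[i, 2] - x[j, 2]
            r2 = d0 * d0 + d1 * d1 + d2 * d2
            if r2 < 1e-20:
                return 1e30, th_max
            s2 = s2c / r2
            s6 = s2 * s2 * s2
            e += s6 * s6
    return e, th_max


@njit(cache=True)
def go_mc_block(x, e_cur, n_steps, kT, theta0, phi0,
                nc_i, nc_j, nc_r0, nc_c, nc_t0, nc_term, is_nc,
                k_theta, k_phi1, k_phi3, a_theta, sigma_nnc,
                formed_factor, record_interval, seed,
                resync_interval=10000):
    """Run ``n_steps`` MC steps of N pivot + N crankshaft moves each.

    ΔE per move is computed incrementally from the boundary-crossing
    terms of the rotated segment; the total is resynchronized against a
    full recomputation every ``resync_interval`` steps.  Records
    (E, Q, per-contact formed flags) every ``record_interval`` steps.
    Returns (E after, recorded E, recorded Q, recorded contact states,
    accepted-move count, attempted-move count).
    """
    np.random.seed(seed)
    n = x.shape[0]
    n_rec = n_steps // record_interval if record_interval > 0 else 0
    rec_e = np.empty(max(n_rec, 1))
    rec_q = np.empty(max(n_rec, 1))
    rec_cs = np.zeros((max(n_rec, 1), nc_i.shape[0]), dtype=np.uint8)
    backup = np.empty_like(x)
    axis = np.empty(3)
    origin = np.empty(3)
    n_acc = 0
    n_try = 0
    rec = 0
    for step in range(n_steps):
        for move in range(2 * n):
            if move < n:
                p = np.random.randint(1, n - 1)
                if np.random.random() < 0.5:
                    lo, hi = p + 1, n - 1
                else:
                    lo, hi = 0, p - 1
                for k in range(3):
                    axis[k] = np.random.standard_normal()
                    origin[k] = x[p, k]
            else:
                a = np.random.randint(0, n - 2)
                lmax = n // 2
                if n - 2 - a < lmax:
                    lmax = n - 2 - a
                if lmax < 1:
                    continue
                seg = np.random.randint(1, lmax + 1)
                b = a + seg + 1
                for k in range(3):
                    axis[k] = x[b, k] - x[a, k]
                    origin[k] = x[a, k]
                if axis[0]**2 + axis[1]**2 + axis[2]**2 < 1e-12:
                    continue
                lo, hi = a + 1, b - 1
            if hi < lo:
                continue
            angle = np.random.uniform(-np.pi, np.pi)
            n_try += 1
            e_old, _ = _partial_energy(x, lo, hi, theta0, phi0, nc_i, nc_j,
                                       nc_r0, nc_c, nc_t0, nc_term, is_nc,
                                       k_theta, k_phi1, k_phi3, a_theta,
                                       sigma_nnc)
            backup[lo:hi + 1] = x[lo:hi + 1]
            _rotate_about(x, lo, hi, origin, axis, angle)
            e_new, th_max = _partial_energy(x, lo, hi, theta0, phi0, nc_i,
                                            nc_j, nc_r0, nc_c, nc_t0,
                                            nc_term, is_nc, k_theta, k_phi1,
                                            k_phi3, a_theta, sigma_nnc)
            de = e_new - e_old
            if e_new < 1e29 and th_max < np.pi - 1e-9 and (
                    de <= 0.0 or np.random.random() < np.exp(-de / kT)):
                e_cur += de
                n_acc += 1
            else:
                x[lo:hi + 1] = backup[lo:hi + 1]
        if resync_interval > 0 and (step + 1) % resync_interval == 0:
            e_cur = go_energy(x, theta0, phi0, nc_i, nc_j, nc_r0, nc_c,
                              nc_t0, nc_term, is_nc, k_theta, k_phi1,
                              k_phi3, a_theta, sigma_nnc)
        if record_interval > 0 and (step + 1) % record_interval == 0:
            rec_e[rec] = e_cur
            rec_q[rec] = q_value_kernel(x, nc_i, nc_j, nc_r0, formed_factor)
            _contact_states(x, nc_i, nc_j, nc_r0, formed_factor, rec_cs[rec])
            rec += 1
    return e_cur, rec_e, rec_q, rec_cs, n_acc, n_try
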