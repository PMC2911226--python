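"""Numba kernel for the Metropolis torsion sampler.

Energies inside the kernel are tracked *relative* to the starting state;
absolute energies of reported poses are recomputed with the pure-numpy
reference scorer in :mod:`cycloscan.energy`, which doubles as an
independent cross-check of the kernel's pair terms.

All randomness comes from an explicit xorshift64* generator so runs are
bit-reproducible from the seed alone.
"""

from __future__ import annotations

import numpy as np
from numba import njit

COULOMB_CONST = 332.0637


@njit(cache=True, inline="always")
def _rng_next(state):
    # xorshift64*: state must be a 1-element uint64 array
    x = state[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    state[0] = x
    return np.float64(x * np.uint64(2685821657736338717) >> np.uint64(11)) / 9007199254740992.0


@njit(cache=True)
def _dihedral(coords, i, j, k, l):
    b0 = coords[i] - coords[j]
    b1 = coords[k] - coords[j]
    b2 = coords[l] - coords[k]
    nb1 = np.sqrt(b1[0] ** 2 + b1[1] ** 2 + b1[2] ** 2)
    b1n = b1 / nb1
    v = b0 - (b0[0] * b1n[0] + b0[1] * b1n[1] + b0[2] * b1n[2]) * b1n
    w = b2 - (b2[0] * b1n[0] + b2[1] * b1n[1] + b2[2] * b1n[2]) * b1n
    x = v[0] * w[0] + v[1] * w[1] + v[2] * w[2]
    cr = np.cross(b1n, v)
    y = cr[0] * w[0] + cr[1] * w[1] + cr[2] * w[2]
    return np.degrees(np.arctan2(y, x))


@njit(cache=True)
def _rotate_inplace(coords, moving, origin, axis, angle_deg):
    norm = np.sqrt(axis[0] ** 2 + axis[1] ** 2 + axis[2] ** 2)
    kx, ky, kz = axis[0] / norm, axis[1] / norm, axis[2] / norm
    th = np.deg2rad(angle_deg)
    c = np.cos(th)
    s = np.sin(th)
    for t in range(moving.shape[0]):
        m = moving[t]
        vx = coords[m, 0] - origin[0]
        vy = coords[m, 1] - origin[1]
        vz = coords[m, 2] - origin[2]
        cx = ky * vz - kz * vy
        cy = kz * vx - kx * vz
        cz = kx * vy - ky * vx
        dot = kx * vx + ky * vy + kz * vz
        coords[m, 0] = origin[0] + vx * c + cx * s + kx * dot * (1 - c)
        coords[m, 1] = origin[1] + vy * c + cy * s + ky * dot * (1 - c)
        coords[m, 2] = origin[2] + vz * c + cz * s + kz * dot * (1 - c)


@njit(cache=True)
def group_env_energy(
    coords, moved, in_moved, excl,
    eps, rmin_half, charge, donor, acceptor, antecedent,
    cutoff, clash_dist, clash_energy, dielectric_slope,
    hb_eps, hb_r0, hb_dist_min, hb_dist_max, hb_cos_max,
):
    """Nonbonded energy of the moved set against every non-moved atom.

    ``excl`` is a flat uint8 matrix (n*n) marking bonded (<=3 bonds) pairs.
    ``hb_cos_max`` is cos(minimum H-bond angle), e.g. cos(100 deg).
    """
    n = coords.shape[0]
    cutoff2 = cutoff * cutoff
    e = 0.0
    for t in range(moved.shape[0]):
        m = moved[t]
        xm = coords[m, 0]
        ym = coords[m, 1]
        zm = coords[m, 2]
        for o in range(n):
            if in_moved[o] == 1:
                continue
            if excl[m * n + o] == 1:
                continue
            dx = xm - coords[o, 0]
            dy = ym - coords[o, 1]
            dz = zm - coords[o, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cutoff2:
                continue
            r = np.sqrt(r2)
            if r < clash_dist:
                e += clash_energy
                r = clash_dist
                r2 = r * r
            rm = rmin_half[m] + rmin_half[o]
            ratio2 = (rm * rm) / r2
            ratio6 = ratio2 * ratio2 * ratio2
            e += np.sqrt(eps[m] * eps[o]) * (ratio6 * ratio6 - 2.0 * ratio6)
            qq = charge[m] * charge[o]
            if qq != 0.0:
                e += COULOMB_CONST * qq / (dielectric_slope * r2)
            if hb_dist_min <= r <= hb_dist_max:
                # donor-acceptor in either direction
                for drc in range(2):
                    if drc == 0:
                        d_at, a_at = m, o
                    else:
                        d_at, a_at = o, m
                    if donor[d_at] == 1 and acceptor[a_at] == 1:
                        ant = antecedent[d_at]
                        v1x = coords[ant, 0] - coords[d_at, 0]
                        v1y = coords[ant, 1] - coords[d_at, 1]
                        v1z = coords[ant, 2] - coords[d_at, 2]
                        v2x = coords[a_at, 0] - coords[d_at, 0]
                        v2y = coords[a_at, 1] - coords[d_at, 1]
                        v2z = coords[a_at, 2] - coords[d_at, 2]
                        n1 = np.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
                        n2 = np.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
                        cosang = (v1x * v2x + v1y * v2y + v1z * v2z) / (n1 * n2)
                        if cosang <= hb_cos_max:
                            ratio0 = hb_r0 / r
                            r10 = ratio0**10
                            r12 = r10 * ratio0 * ratio0
                            e += hb_eps * (5.0 * r12 - 6.0 * r10) * cosang * cosang
    return e


@njit(cache=True)
def _torsion_strain(coords, ttype, a0, a1, a2, a3, theta0, chi_barrier, rotamer_k):
    chi = _dihedral(coords, a0, a1, a2, a3)
    if ttype == 0:  # peptide sidechain chi: 3-fold barrier
        return chi_barrier * (1.0 + np.cos(np.deg2rad(3.0 * chi)))
    if ttype == 2:  # gatekeeper chi: rotamer-deviation penalty
        return rotamer_k * (1.0 - np.cos(np.deg2rad(chi - theta0)))
    return 0.0


@njit(cache=True)
def run_mc(
    coords, excl,
    eps, rmin_half, charge, donor, acceptor, antecedent,
    # torsion tables
    t_atoms, t_sign, t_type, t_theta0, t_cumprob,
    moving_flat, moving_start,
    # params
    n_iter, kt_start, anneal, max_step, seed,
    discrete_angles, use_discrete,
    log_interval,
    cutoff, clash_dist, clash_energy, dielectric_slope,
    hb_eps, hb_r0, hb_dist_min, hb_dist_max, hb_cos_max,
    chi_barrier, rotamer_k,
):
    """Metropolis sampler over the torsion move set.

    Returns (best_rel_energy, best_coords, accepted, trace) where energies
    are relative to the initial state and the trace is best-so-far per
    ``log_interval`` iterations.
    """
    n = coords.shape[0]
    n_t = t_atoms.shape[0]
    state = np.empty(1, dtype=np.uint64)
    state[0] = np.uint64(seed) * np.uint64(2654435761) + np.uint64(1442695040888963407)
    for _ in range(8):
        _rng_next(state)

    in_moved = np.zeros(n, dtype=np.uint8)
    best_coords = coords.copy()
    best_e = 0.0
    e_rel = 0.0
    accepted = 0
    n_log = max(1, n_iter // log_interval) if n_iter > 0 else 0
    trace = np.empty(n_iter // log_interval + 1 if n_iter > 0 else 1, dtype=np.float64)
    trace[0] = 0.0
    kt = kt_start

    max_moved = 0
    for ti in range(n_t):
        sz = moving_start[ti + 1] - moving_start[ti]
        if sz > max_moved:
            max_moved = sz
    saved = np.empty((max_moved, 3), dtype=np.float64)

    for it in range(n_iter):
        u = _rng_next(state)
        ti = n_t - 1
        for j in range(n_t):
            if u <= t_cumprob[j]:
                ti = j
                break
        mstart = moving_start[ti]
        mstop = moving_start[ti + 1]
        moving = moving_flat[mstart:mstop]
        a0, a1, a2, a3 = t_atoms[ti, 0], t_atoms[ti, 1], t_atoms[ti, 2], t_atoms[ti, 3]

        if use_discrete == 1:
            g = int(_rng_next(state) * discrete_angles.shape[0])
            if g >= discrete_angles.shape[0]:
                g = discrete_angles.shape[0] - 1
            current = _dihedral(coords, a0, a1, a2, a3)
            delta = discrete_angles[g] - current
        else:
            delta = (2.0 * _rng_next(state) - 1.0) * max_step

        for t in range(moving.shape[0]):
            in_moved[moving[t]] = 1
            saved[t, 0] = coords[moving[t], 0]
            saved[t, 1] = coords[moving[t], 1]
            saved[t, 2] = coords[moving[t], 2]

        e_old = group_env_energy(
            coords, moving, in_moved, excl,
            eps, rmin_half, charge, donor, acceptor, antecedent,
            cutoff, clash_dist, clash_energy, dielectric_slope,
            hb_eps, hb_r0, hb_dist_min, hb_dist_max, hb_cos_max,
        ) + _torsion_strain(
            coords, t_type[ti], a0, a1, a2, a3, t_theta0[ti], chi_barrier, rotamer_k
        )

        axis = coords[a2] - coords[a1]
        _rotate_inplace(coords, moving, coords[a1], axis, t_sign[ti] * delta)

        e_new = group_env_energy(
            coords, moving, in_moved, excl,
            eps, rmin_half, charge, donor, acceptor, antecedent,
            cutoff, clash_dist, clash_energy, dielectric_slope,
            hb_eps, hb_r0, hb_dist_min, hb_dist_max, hb_cos_max,
        ) + _torsion_strain(
            coords, t_type[ti], a0, a1, a2, a3, t_theta0[ti], chi_barrier, rotamer_k
        )

        d_e = e_new - e_old
        accept = False
        if d_e <= 0.0:
            accept = True
        elif kt > 0.0:
            if _rng_next(state) < np.exp(-d_e / kt):
                accept = True

        if accept:
            accepted += 1
            e_rel += d_e
            if e_rel < best_e - 1e-12:
                best_e = e_rel
                for a in range(n):
                    best_coords[a, 0] = coords[a, 0]
                    best_coords[a, 1] = coords[a, 1]
                    best_coords[a, 2] = coords[a, 2]
        else:
            for t in range(moving.shape[0]):
                coords[moving[t], 0] = saved[t, 0]
                coords[moving[t], 1] = saved[t, 1]
                coords[moving[t], 2] = saved[t, 2]

        for t in range(moving.shape[0]):
            in_moved[moving[t]] = 0

        kt *= anneal
        if (it + 1) % log_interval == 0:
            trace[(it + 1) // log_interval] = best_e

    if n_iter > 0 and n_iter % log_interval != 0:
        trace[-1] = best_e
    return best_e, best_coords, accepted, trace
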