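"""Numba force/neighbor kernels operating on plain arrays.

All kernels use the minimum-image convention on an orthorhombic box
(non-periodic axes are given a huge box length so the image shift is
always zero).  Pair styles are encoded as integers: 0 = LJ (shifted to
zero at the cutoff), 1 = WCA, 2 = LJHB (shifted LJ plus inverted
Gaussian hydrogen-bond well).

Each force routine accumulates the diagonal of the virial tensor
(sum of f_x dx etc. over interacting partners), which the barostat
turns into per-axis pressures.
"""

import numpy as np
from numba import njit

NB_OPTS = dict(cache=True, fastmath=True)


@njit(**NB_OPTS)
def build_neighbor_list(pos, box, rlist, excl, max_pairs):
    """All-pairs neighbor search with exclusion filtering.

    ``excl`` is an (N, m) int array of excluded partner indices padded
    with -1.  Returns (pairs, n_pairs); pairs is (max_pairs, 2).
    """
    n = pos.shape[0]
    pairs = np.empty((max_pairs, 2), dtype=np.int64)
    count = 0
    r2max = rlist * rlist
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < r2max:
                skip = False
                for e in range(excl.shape[1]):
                    if excl[i, e] == j:
                        skip = True
                        break
                    if excl[i, e] < 0:
                        break
                if not skip:
                    if count >= max_pairs:
                        return pairs, -1  # overflow flag
                    pairs[count, 0] = i
                    pairs[count, 1] = j
                    count += 1
    return pairs, count


@njit(**NB_OPTS)
def nonbonded_forces(pos, box, pairs, n_pairs, tidx, style, eps44, sig44,
                     shift44, mu, kappa, eta, cutoff, forces, virial):
    """Pair forces/energies over the neighbor list.

    Returns (E_lj, E_ljhb): the plain-LJ/WCA sum and the H-bond-pair sum.
    """
    e_lj = 0.0
    e_hb = 0.0
    rc2 = cutoff * cutoff
    rmin_fac2 = 2.0 ** (1.0 / 3.0)
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2 or r2 <= 0.0:
            continue
        ti = tidx[i]
        tj = tidx[j]
        st = style[ti, tj]
        epsv = eps44[ti, tj]
        sigv = sig44[ti, tj]
        s2 = sigv * sigv / r2
        s6 = s2 * s2 * s2
        if st == 1:  # WCA: zero beyond its own minimum
            if r2 >= rmin_fac2 * sigv * sigv:
                continue
            e = 4.0 * epsv * (s6 * s6 - s6) + epsv
            fr = 24.0 * epsv * (2.0 * s6 * s6 - s6) / r2
            e_lj += e
        else:
            e = 4.0 * epsv * (s6 * s6 - s6) - shift44[ti, tj]
            fr = 24.0 * epsv * (2.0 * s6 * s6 - s6) / r2
            if st == 2:
                r = np.sqrt(r2)
                dr = r - mu
                g = eta * np.exp(-0.5 * dr * dr / (kappa * kappa))
                e -= g
                # radial force -dV/dr contributes g' term; convert to /r2 scale
                fr += (-g * dr / (kappa * kappa)) / r
                e_hb += e
            else:
                e_lj += e
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += fx * dx
        virial[1] += fy * dy
        virial[2] += fz * dz
    return e_lj, e_hb


@njit(**NB_OPTS)
def bond_forces(pos, box, bond_i, bond_j, bond_r0, bond_k, forces, virial):
    e = 0.0
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - bond_r0[b]
        e += 0.5 * bond_k[b] * d * d
        fr = -bond_k[b] * d / r
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0] += fx * dx
        virial[1] += fy * dy
        virial[2] += fz * dz
    return e


@njit(**NB_OPTS)
def _angle_geometry(pos, box, i, j, k):
    """Minimum-image arms u = r_i - r_j, v = r_k - r_j and the angle."""
    ux = pos[i, 0] - pos[j, 0]
    uy = pos[i, 1] - pos[j, 1]
    uz = pos[i, 2] - pos[j, 2]
    vx = pos[k, 0] - pos[j, 0]
    vy = pos[k, 1] - pos[j, 1]
    vz = pos[k, 2] - pos[j, 2]
    ux -= box[0] * np.rint(ux / box[0])
    uy -= box[1] * np.rint(uy / box[1])
    uz -= box[2] * np.rint(uz / box[2])
    vx -= box[0] * np.rint(vx / box[0])
    vy -= box[1] * np.rint(vy / box[1])
    vz -= box[2] * np.rint(vz / box[2])
    ru = np.sqrt(ux * ux + uy * uy + uz * uz)
    rv = np.sqrt(vx * vx + vy * vy + vz * vz)
    c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    theta = np.arccos(c)
    return ux, uy, uz, vx, vy, vz, ru, rv, c, theta


@njit(**NB_OPTS)
def _apply_angle_force(forces, virial, i, j, k, dvdtheta,
                       ux, uy, uz, vx, vy, vz, ru, rv, c):
    s = np.sqrt(1.0 - c * c)
    if s < 1e-8:
        s = 1e-8
    # dtheta/dr_i and dtheta/dr_k
    gix = (c * ux / (ru * ru) - vx / (ru * rv)) / s
    giy = (c * uy / (ru * ru) - vy / (ru * rv)) / s
    giz = (c * uz / (ru * ru) - vz / (ru * rv)) / s
    gkx = (c * vx / (rv * rv) - ux / (ru * rv)) / s
    gky = (c * vy / (rv * rv) - uy / (ru * rv)) / s
    gkz = (c * vz / (rv * rv) - uz / (ru * rv)) / s
    fix = -dvdtheta * gix
    fiy = -dvdtheta * giy
    fiz = -dvdtheta * giz
    fkx = -dvdtheta * gkx
    fky = -dvdtheta * gky
    fkz = -dvdtheta * gkz
    forces[i, 0] += fix
    forces[i, 1] += fiy
    forces[i, 2] += fiz
    forces[k, 0] += fkx
    forces[k, 1] += fky
    forces[k, 2] += fkz
    forces[j, 0] -= fix + fkx
    forces[j, 1] -= fiy + fky
    forces[j, 2] -= fiz + fkz
    virial[0] += fix * ux + fkx * vx
    virial[1] += fiy * uy + fky * vy
    virial[2] += fiz * uz + fkz * vz


@njit(**NB_OPTS)
def harmonic_angle_forces(pos, box, ai, aj, ak, theta0, ktheta, forces, virial):
    e = 0.0
    for a in range(ai.shape[0]):
        ux, uy, uz, vx, vy, vz, ru, rv, c, theta = _angle_geometry(
            pos, box, ai[a], aj[a], ak[a])
        d = theta - theta0[a]
        e += 0.5 * ktheta[a] * d * d
        _apply_angle_force(forces, virial, ai[a], aj[a], ak[a], ktheta[a] * d,
                           ux, uy, uz, vx, vy, vz, ru, rv, c)
    return e


@njit(**NB_OPTS)
def double_angle_forces(pos, box, ai, aj, ak, t1, t2, xi, A, D, forces, virial):
    e = 0.0
    for a in range(ai.shape[0]):
        ux, uy, uz, vx, vy, vz, ru, rv, c, th = _angle_geometry(
            pos, box, ai[a], aj[a], ak[a])
        g = (0.25 * th ** 4
             - (t1[a] + t2[a] + xi[a]) * th ** 3 / 3.0
             + 0.5 * (t1[a] * t2[a] + t1[a] * xi[a] + t2[a] * xi[a]) * th ** 2
             - t1[a] * t2[a] * xi[a] * th)
        e += A[a] * g + D[a]
        dvdtheta = A[a] * (th - t1[a]) * (th - t2[a]) * (th - xi[a])
        _apply_angle_force(forces, virial, ai[a], aj[a], ak[a], dvdtheta,
                           ux, uy, uz, vx, vy, vz, ru, rv, c)
    return e


@njit(**NB_OPTS)
def max_displacement(pos, ref, box):
    m = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d > m:
            m = d
    return m


@njit(**NB_OPTS)
def probe_environment_energy(pos, box, probe, env_mask, tidx, style, eps44,
                             sig44, shift44, mu, kappa, eta, cutoff):
    """Nonbonded energy between one probe particle and all masked particles."""
    e = 0.0
    rc2 = cutoff * cutoff
    rmin_fac2 = 2.0 ** (1.0 / 3.0)
    ti = tidx[probe]
    for j in range(pos.shape[0]):
        if not env_mask[j] or j == probe:
            continue
        dx = pos[probe, 0] - pos[j, 0]
        dy = pos[probe, 1] - pos[j, 1]
        dz = pos[probe, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2 or r2 <= 0.0:
            continue
        tj = tidx[j]
        st = style[ti, tj]
        epsv = eps44[ti, tj]
        sigv = sig44[ti, tj]
        s2 = sigv * sigv / r2
        s6 = s2 * s2 * s2
        if st == 1:
            if r2 >= rmin_fac2 * sigv * sigv:
                continue
            e += 4.0 * epsv * (s6 * s6 - s6) + epsv
        else:
            e += 4.0 * epsv * (s6 * s6 - s6) - shift44[ti, tj]
            if st == 2:
                r = np.sqrt(r2)
                dr = r - mu
                e -= eta * np.exp(-0.5 * dr * dr / (kappa * kappa))
    return e
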