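"""Numba kernels for the sampler hot path.

Pure-arithmetic inner loops (pairwise nonbonded energy over a replica stack,
in-place block rotation) that the Monte Carlo sampler calls tens of thousands
of times per run.
"""

import math

import numpy as np
from numba import njit

__all__ = ["nb_energy_batch", "torsion_energy_batch", "rotate_block"]


@njit(cache=True)
def nb_energy_batch(
    coords,  # (R, n_atoms, 3)
    pair_i,
    pair_j,
    pair_kind,  # 0 = steric, 1 = contact, 2 = charge
    pair_q,  # q_i*q_j for charge pairs, 0 otherwise
    soft_sigma,
    soft_k,
    contact_depth,
    contact_r0,
    contact_w,
    coulomb_k,
    out,  # (R,)
):
    n_rep = coords.shape[0]
    n_pairs = pair_i.shape[0]
    sig2 = soft_sigma * soft_sigma
    inv_2w2 = 1.0 / (2.0 * contact_w * contact_w)
    for r in range(n_rep):
        e = 0.0
        for p in range(n_pairs):
            i = pair_i[p]
            j = pair_j[p]
            dx = coords[r, i, 0] - coords[r, j, 0]
            dy = coords[r, i, 1] - coords[r, j, 1]
            dz = coords[r, i, 2] - coords[r, j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            k = pair_kind[p]
            if k == 0:
                if r2 < sig2:
                    ov = soft_sigma - math.sqrt(r2)
                    e += soft_k * ov * ov
            elif k == 1:
                d = math.sqrt(r2) - contact_r0
                e -= contact_depth * math.exp(-d * d * inv_2w2)
            else:
                if r2 < 1e-18:
                    out[r] = np.inf  # coincident charges; caller raises
                    break
                e += coulomb_k * pair_q[p] / math.sqrt(r2)
        else:
            out[r] = e
    return out


@njit(cache=True)
def torsion_energy_batch(
    phis,  # (R, n_interior) degrees
    psis,
    centres_phi,  # (n_basins,)
    centres_psi,
    inv_two_w2,
    depths,  # (n_interior, n_basins)
    coop_delta,
    coop,  # (n_basins,) bonus per consecutive member pair
    allowed,  # (n_interior, n_basins) 0/1; alpha zeroed at proline sites
    pro_mask,  # (n_interior,) 0/1
    pro_centre,
    pro_half,
    pro_k,
    out,
):
    n_rep, n_int = phis.shape
    n_b = centres_phi.shape[0]
    prev = np.zeros(n_b, dtype=np.bool_)
    cur = np.zeros(n_b, dtype=np.bool_)
    for r in range(n_rep):
        e = 0.0
        for b in range(n_b):
            prev[b] = False
        for i in range(n_int):
            ph = phis[r, i]
            ps = psis[r, i]
            for b in range(n_b):
                dph = abs(ph - centres_phi[b]) % 360.0
                if dph > 180.0:
                    dph = 360.0 - dph
                dps = abs(ps - centres_psi[b]) % 360.0
                if dps > 180.0:
                    dps = 360.0 - dps
                e -= depths[i, b] * math.exp(-(dph * dph + dps * dps) * inv_two_w2[b])
                cur[b] = dph <= coop_delta and dps <= coop_delta and allowed[i, b]
                if i > 0 and prev[b] and cur[b]:
                    e -= coop[b]
            for b in range(n_b):
                prev[b] = cur[b]
            if pro_mask[i]:
                dev = abs(ph - pro_centre) % 360.0
                if dev > 180.0:
                    dev = 360.0 - dev
                dev -= pro_half
                if dev > 0.0:
                    e += pro_k * dev * dev
        out[r] = e
    return out


@njit(cache=True)
def ehss_trace(centres, radii, rays_xy, z0, max_reflections):
    """Trace hard-sphere specular-reflection trajectories along +z.

    Returns (sum of (1 - cos chi) over rays, rays that hit the reflection cap,
    rays discarded because they started inside a sphere).
    """
    n_atoms = centres.shape[0]
    n_rays = rays_xy.shape[0]
    total = 0.0
    capped = 0
    discarded = 0
    for k in range(n_rays):
        px = rays_xy[k, 0]
        py = rays_xy[k, 1]
        pz = z0
        dx = 0.0
        dy = 0.0
        dz = 1.0
        inside = False
        for i in range(n_atoms):
            ex = centres[i, 0] - px
            ey = centres[i, 1] - py
            ez = centres[i, 2] - pz
            if ex * ex + ey * ey + ez * ez < radii[i] * radii[i]:
                inside = True
                break
        if inside:
            discarded += 1
            continue
        n_refl = 0
        while n_refl < max_reflections:
            best_t = 1e300
            best_i = -1
            for i in range(n_atoms):
                ex = centres[i, 0] - px
                ey = centres[i, 1] - py
                ez = centres[i, 2] - pz
                b = dx * ex + dy * ey + dz * ez
                disc = b * b - (ex * ex + ey * ey + ez * ez - radii[i] * radii[i])
                if disc >= 0.0:
                    t = b - math.sqrt(disc)
                    if 1e-9 < t < best_t:
                        best_t = t
                        best_i = i
            if best_i < 0:
                break  # escaped
            px += best_t * dx
            py += best_t * dy
            pz += best_t * dz
            nx = (px - centres[best_i, 0]) / radii[best_i]
            ny = (py - centres[best_i, 1]) / radii[best_i]
            nz = (pz - centres[best_i, 2]) / radii[best_i]
            dot = dx * nx + dy * ny + dz * nz
            dx -= 2.0 * dot * nx
            dy -= 2.0 * dot * ny
            dz -= 2.0 * dot * nz
            n_refl += 1
        if n_refl >= max_reflections:
            capped += 1
        if n_refl > 0:
            total += 1.0 - dz  # chi measured against the incoming +z direction
    return total, capped, discarded


@njit(cache=True)
def rotate_block(coords, start, stop, origin, axis, angle_deg):
    ax, ay, az = axis[0], axis[1], axis[2]
    n = math.sqrt(ax * ax + ay * ay + az * az)
    if n == 0.0:
        return False
    kx, ky, kz = ax / n, ay / n, az / n
    th = math.radians(angle_deg)
    c = math.cos(th)
    s = math.sin(th)
    ic = 1.0 - c
    r00 = c + kx * kx * ic
    r01 = kx * ky * ic - kz * s
    r02 = kx * kz * ic + ky * s
    r10 = ky * kx * ic + kz * s
    r11 = c + ky * ky * ic
    r12 = ky * kz * ic - kx * s
    r20 = kz * kx * ic - ky * s
    r21 = kz * ky * ic + kx * s
    r22 = c + kz * kz * ic
    ox, oy, oz = origin[0], origin[1], origin[2]
    for a in range(start, stop):
        x = coords[a, 0] - ox
        y = coords[a, 1] - oy
        z = coords[a, 2] - oz
        coords[a, 0] = r00 * x + r01 * y + r02 * z + ox
        coords[a, 1] = r10 * x + r11 * y + r12 * z + oy
        coords[a, 2] = r20 * x + r21 * y + r22 * z + oz
    return True
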