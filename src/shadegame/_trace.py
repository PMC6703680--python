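"""Numba kernels for toroidal canopy ray tracing.

All patches are planar ellipses; the stand is treated as an infinite toroidal
tiling with horizontal periods (Lx, Ly): every ray-patch test is done against
the patch replica nearest the ray's crossing point at the patch's height
(exact for patches smaller than half a period, which holds for rosette-scale
organs).  Bands are (red, far-red, PAR); a single geometric path carries all
three band weights, which is valid because the per-band reflectance and
transmittance are equal (the scatter side is sampled 50/50 and the weight is
multiplied by the band's total scattered fraction).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS_T = 1e-9


@njit(cache=True, fastmath=True)
def _nearest_hit(ox, oy, oz, dx, dy, dz, C, N, UA, VB, Lx, Ly):
    """Index and distance of the first patch hit, toroidal wrap; -1 if none."""
    best_t = 1.0e30
    best = -1
    for j in range(C.shape[0]):
        nx = N[j, 0]; ny = N[j, 1]; nz = N[j, 2]
        denom = dx * nx + dy * ny + dz * nz
        if denom < 1e-12 and denom > -1e-12:
            continue
        # choose replica nearest the ray's horizontal position at patch height
        if dz > 1e-9 or dz < -1e-9:
            tz = (C[j, 2] - oz) / dz
            if tz < 0.0:
                tz = 0.0
        else:
            tz = 0.0
        hx = ox + tz * dx
        hy = oy + tz * dy
        cx = C[j, 0] + np.round((hx - C[j, 0]) / Lx) * Lx
        cy = C[j, 1] + np.round((hy - C[j, 1]) / Ly) * Ly
        t = ((cx - ox) * nx + (cy - oy) * ny + (C[j, 2] - oz) * nz) / denom
        if t <= _EPS_T or t >= best_t:
            continue
        px = ox + t * dx - cx
        py = oy + t * dy - cy
        pz = oz + t * dz - C[j, 2]
        e1 = px * UA[j, 0] + py * UA[j, 1] + pz * UA[j, 2]
        e2 = px * VB[j, 0] + py * VB[j, 1] + pz * VB[j, 2]
        if e1 * e1 + e2 * e2 <= 1.0:
            best_t = t
            best = j
    return best, best_t


@njit(cache=True, fastmath=True)
def _lambert_dir(nx, ny, nz):
    """Cosine-weighted direction about unit normal (nx, ny, nz)."""
    # orthonormal tangent frame
    if nx > 0.9 or nx < -0.9:
        t1x, t1y, t1z = 0.0, 1.0, 0.0
    else:
        t1x, t1y, t1z = 1.0, 0.0, 0.0
    # t1 = normalize(t1 - (t1.n) n)
    d = t1x * nx + t1y * ny + t1z * nz
    t1x -= d * nx; t1y -= d * ny; t1z -= d * nz
    inv = 1.0 / np.sqrt(t1x * t1x + t1y * t1y + t1z * t1z)
    t1x *= inv; t1y *= inv; t1z *= inv
    t2x = ny * t1z - nz * t1y
    t2y = nz * t1x - nx * t1z
    t2z = nx * t1y - ny * t1x
    u1 = np.random.random()
    u2 = np.random.random()
    st = np.sqrt(u1)
    ct = np.sqrt(1.0 - u1)
    ph = 2.0 * np.pi * u2
    cp = np.cos(ph); sp = np.sin(ph)
    return (st * cp * t1x + st * sp * t2x + ct * nx,
            st * cp * t1y + st * sp * t2y + ct * ny,
            st * cp * t1z + st * sp * t2z + ct * nz)


@njit(cache=True)
def trace_mc(seed, n_x, n_y, Lx, Ly, z_top, w0,
             C, N, UA, VB, ABS, REM, max_bounce):
    """Stratified cosine-weighted diffuse sky traced through the scene.

    w0: per-band flux carried by one ray (band source intensity * cell area
    / ray count).  Returns per-patch incident and absorbed band tallies plus
    the soil / escaped / truncated energy ledgers (emitted = sum of all).
    """
    np.random.seed(seed)
    P = C.shape[0]
    incident = np.zeros((P, 3))
    absorbed = np.zeros((P, 3))
    soil = np.zeros(3)
    escaped = np.zeros(3)
    truncated = np.zeros(3)
    w = np.zeros(3)
    for i in range(n_x):
        for j in range(n_y):
            ox = (i + np.random.random()) * Lx / n_x - 0.5 * Lx
            oy = (j + np.random.random()) * Ly / n_y - 0.5 * Ly
            oz = z_top
            u1 = np.random.random()
            u2 = np.random.random()
            st = np.sqrt(u1)
            ct = np.sqrt(1.0 - u1)
            ph = 2.0 * np.pi * u2
            dx = st * np.cos(ph)
            dy = st * np.sin(ph)
            dz = -ct
            for b in range(3):
                w[b] = w0[b]
            bounce = 0
            while True:
                idx, t = _nearest_hit(ox, oy, oz, dx, dy, dz,
                                      C, N, UA, VB, Lx, Ly)
                if idx < 0:
                    if dz < 0.0:
                        for b in range(3):
                            soil[b] += w[b]
                    else:
                        for b in range(3):
                            escaped[b] += w[b]
                    break
                wsum = 0.0
                for b in range(3):
                    incident[idx, b] += w[b]
                    absorbed[idx, b] += w[b] * ABS[idx, b]
                    w[b] *= REM[idx, b]
                    wsum += w[b]
                if wsum <= 0.0:
                    break
                if bounce >= max_bounce:
                    for b in range(3):
                        truncated[b] += w[b]
                    break
                # scatter: reflect/transmit side 50/50, weight keeps the full
                # scattered fraction (valid since rho == tau per band)
                side = 1.0 if np.random.random() < 0.5 else -1.0
                # orient normal against incoming ray, then pick side
                ndotd = N[idx, 0] * dx + N[idx, 1] * dy + N[idx, 2] * dz
                sgn = -1.0 if ndotd > 0.0 else 1.0
                nx = N[idx, 0] * sgn * side
                ny = N[idx, 1] * sgn * side
                nz = N[idx, 2] * sgn * side
                ox = ox + t * dx
                oy = oy + t * dy
                oz = oz + t * dz
                dx, dy, dz = _lambert_dir(nx, ny, nz)
                ox += 1e-9 * dx
                oy += 1e-9 * dy
                oz += 1e-9 * dz
                bounce += 1
    return incident, absorbed, soil, escaped, truncated


@njit(cache=True)
def sense(seed, S, self_idx, C, N, UA, VB, TAU, EXITANCE,
          Lx, Ly, z_top, sky, n_up, n_down):
    """Per-sensor perceived band fluxes.

    Upward cosine-weighted rays estimate transmitted sky irradiance (the
    product of band transmittances of every crossed patch; the sensor's own
    patch is excluded); downward rays gather first-order scattered light from
    the nearest patch's Lambertian exitance EXITANCE[j, b] (per-band reflected
    flux density, precomputed from the Monte Carlo incident tallies).
    """
    np.random.seed(seed)
    Q = S.shape[0]
    P = C.shape[0]
    perceived = np.zeros((Q, 3))
    for q in range(Q):
        ox = S[q, 0]; oy = S[q, 1]; oz = S[q, 2]
        own = self_idx[q]
        for r in range(n_up):
            dx, dy, dz = _lambert_dir(0.0, 0.0, 1.0)
            tr0 = 1.0; tr1 = 1.0; tr2 = 1.0
            for j in range(P):
                if j == own:
                    continue
                nx = N[j, 0]; ny = N[j, 1]; nz = N[j, 2]
                denom = dx * nx + dy * ny + dz * nz
                if denom < 1e-12 and denom > -1e-12:
                    continue
                tz = (C[j, 2] - oz) / dz if (dz > 1e-9 or dz < -1e-9) else 0.0
                if tz < 0.0:
                    tz = 0.0
                hx = ox + tz * dx
                hy = oy + tz * dy
                cx = C[j, 0] + np.round((hx - C[j, 0]) / Lx) * Lx
                cy = C[j, 1] + np.round((hy - C[j, 1]) / Ly) * Ly
                t = ((cx - ox) * nx + (cy - oy) * ny
                     + (C[j, 2] - oz) * nz) / denom
                if t <= _EPS_T:
                    continue
                px = ox + t * dx - cx
                py = oy + t * dy - cy
                pz = oz + t * dz - C[j, 2]
                e1 = px * UA[j, 0] + py * UA[j, 1] + pz * UA[j, 2]
                e2 = px * VB[j, 0] + py * VB[j, 1] + pz * VB[j, 2]
                if e1 * e1 + e2 * e2 <= 1.0:
                    tr0 *= TAU[j, 0]
                    tr1 *= TAU[j, 1]
                    tr2 *= TAU[j, 2]
            perceived[q, 0] += sky[0] * tr0 / n_up
            perceived[q, 1] += sky[1] * tr1 / n_up
            perceived[q, 2] += sky[2] * tr2 / n_up
        for r in range(n_down):
            dx, dy, dz = _lambert_dir(0.0, 0.0, -1.0)
            idx, t = _nearest_hit(ox, oy, oz, dx, dy, dz,
                                  C, N, UA, VB, Lx, Ly)
            if idx >= 0 and idx != own:
                for b in range(3):
                    perceived[q, b] += EXITANCE[idx, b] / n_down
    return perceived
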