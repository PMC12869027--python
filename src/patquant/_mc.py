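"""Numba kernel for voxel Monte-Carlo photon transport.

The medium is a 2-D voxel grid in (x, z) that is invariant along y; photon
directions are sampled in full 3-D (Henyey-Greenstein phase function), so for
the planar sources used here the transport statistics — in particular the
deep-region effective attenuation mu_eff = sqrt(3 mu_a (mu_a + mu_s')) — match
3-D diffusion theory while the bookkeeping stays on a desk-scale 2-D grid.

Variance reduction: implicit capture (weight w loses a fraction mu_a/mu_t at
every interaction) with Russian roulette below weight 1e-4 (survival chance
0.1, survivors boosted 10x).  Fluence is tallied with the track-length
estimator (sum of w * path length per voxel), which stays unbiased in voxels
with mu_a = 0.  The kernel also returns an exact weight ledger
(absorbed, escaped, roulette losses and boosts) so that
launched + gained - lost == absorbed + escaped to float roundoff.
"""

import numpy as np
from numba import njit

_ROULETTE_THRESHOLD = 1e-4
_ROULETTE_SURVIVAL = 0.1


@njit(cache=True)
def run_mc(mu_a, mu_s, g, voxel_cm, seg_lo, seg_hi, cos_half, n_photons, seed):
    """Trace ``n_photons`` through one wavelength's (nz, nx) property maps.

    seg_lo/seg_hi: arrays of source segment x-extents (cm) on the z=0 surface.
    cos_half: cosine of the emission half-angle (1.0 = pencil beam along +z).
    Returns (tally, absorbed, escaped, lost, gained); fluence per launched
    photon is tally / (n_photons * voxel_cm**2).
    """
    np.random.seed(seed)
    nz, nx = mu_a.shape
    dv = voxel_cm
    xmax = nx * dv
    zmax = nz * dv

    tally = np.zeros((nz, nx))
    absorbed = 0.0
    escaped = 0.0
    lost = 0.0
    gained = 0.0

    nseg = seg_lo.shape[0]
    seg_len = np.empty(nseg)
    total_len = 0.0
    for k in range(nseg):
        seg_len[k] = seg_hi[k] - seg_lo[k]
        total_len += seg_len[k]

    for _ in range(n_photons):
        # --- launch ---
        if total_len <= 0.0:
            x = seg_lo[0]
        else:
            r = np.random.random() * total_len
            x = seg_lo[0]
            for k in range(nseg):
                if r <= seg_len[k]:
                    x = seg_lo[k] + r
                    break
                r -= seg_len[k]
        z = 0.0
        if cos_half >= 1.0:
            ux, uy, uz = 0.0, 0.0, 1.0
        else:
            ct = 1.0 - (1.0 - cos_half) * np.random.random()
            st = np.sqrt(max(0.0, 1.0 - ct * ct))
            ph = 2.0 * np.pi * np.random.random()
            ux = st * np.cos(ph)
            uy = st * np.sin(ph)
            uz = ct
        if x <= 0.0:
            x = 1e-9
        if x >= xmax:
            x = xmax - 1e-9
        ix = int(x / dv)
        iz = 0
        w = 1.0
        alive = True
        tau = -np.log(np.random.random())

        while alive:
            mt = mu_a[iz, ix] + mu_s[iz, ix]

            # distance to the next voxel boundary along the 3-D direction
            if ux > 1e-12:
                dbx = ((ix + 1) * dv - x) / ux
            elif ux < -1e-12:
                dbx = (ix * dv - x) / ux
            else:
                dbx = 1e30
            if uz > 1e-12:
                dbz = ((iz + 1) * dv - z) / uz
            elif uz < -1e-12:
                dbz = (iz * dv - z) / uz
            else:
                dbz = 1e30
            if dbx < 0.0:
                dbx = 0.0
            if dbz < 0.0:
                dbz = 0.0
            db = dbx if dbx < dbz else dbz

            ds = tau / mt if mt > 0.0 else 1e30

            if ds < db:
                # interaction inside the current voxel
                tally[iz, ix] += w * ds
                x += ux * ds
                z += uz * ds
                dep = w * mu_a[iz, ix] / mt
                absorbed += dep
                w -= dep
                if w < 1e-12:
                    alive = False
                    break
                # Henyey-Greenstein scatter
                gv = g[iz, ix]
                if gv > 1e-6 or gv < -1e-6:
                    tmp = (1.0 - gv * gv) / (1.0 - gv + 2.0 * gv * np.random.random())
                    ct = (1.0 + gv * gv - tmp * tmp) / (2.0 * gv)
                else:
                    ct = 2.0 * np.random.random() - 1.0
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
                st = np.sqrt(1.0 - ct * ct)
                ph = 2.0 * np.pi * np.random.random()
                cp = np.cos(ph)
                sp = np.sin(ph)
                if uz > 0.99999 or uz < -0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct * (1.0 if uz > 0.0 else -1.0)
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    ux_n = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    uy_n = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    uz_n = -st * cp * den + uz * ct
                    ux, uy, uz = ux_n, uy_n, uz_n
                tau = -np.log(np.random.random())
                if w < _ROULETTE_THRESHOLD:
                    if np.random.random() < _ROULETTE_SURVIVAL:
                        gained += w * (1.0 / _ROULETTE_SURVIVAL - 1.0)
                        w /= _ROULETTE_SURVIVAL
                    else:
                        lost += w
                        alive = False
            else:
                # cross into the neighbouring voxel
                tally[iz, ix] += w * db
                x += ux * db
                z += uz * db
                if mt > 0.0:
                    tau -= db * mt
                if dbx < dbz:
                    ix += 1 if ux > 0.0 else -1
                else:
                    iz += 1 if uz > 0.0 else -1
                if ix < 0 or ix >= nx or iz < 0 or iz >= nz:
                    escaped += w
                    alive = False

    return tally, absorbed, escaped, lost, gained
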