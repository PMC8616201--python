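"""Numba transport kernel: photon-packet random walk through the label grid.

Implements the classic variance-reduced packet scheme on a voxelized
heterogeneous medium: dimensionless step s = -ln(xi) consumed across voxels as
physical length s / mu_t with exact boundary sub-stepping, partial absorption
(weight x mu_a / mu_t) at each interaction, Henyey-Greenstein scattering, and
Russian roulette below a weight threshold.  Two fluence estimators are
tallied: the track-length estimator (sum of weight x chord per voxel) and the
absorption estimator (deposited weight per voxel).

Background voxels (label 0) and the grid's exterior boundary terminate packets
as escapes: all cerebral tissue shares a refractive index of 1.40, so no
internal Fresnel events occur and the exterior is treated as matched.

Each packet owns an independent xorshift64* stream seeded from a splitmix64
hash of (base seed, packet index), which makes the tallies bit-reproducible
for a fixed seed regardless of any future batching of the packet loop.
"""

import math

import numpy as np
from numba import njit

_MULT = np.uint64(0x2545F4914F6CDD1D)
_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)
_S12 = np.uint64(12)
_S25 = np.uint64(25)
_S27 = np.uint64(27)
_S30 = np.uint64(30)
_S31 = np.uint64(31)
_S11 = np.uint64(11)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=False, inline="always", fastmath=True)
def _seed_state(base, i):
    z = base + _SM_GAMMA * (np.uint64(i) + np.uint64(1))
    z = (z ^ (z >> _S30)) * _SM_M1
    z = (z ^ (z >> _S27)) * _SM_M2
    z = z ^ (z >> _S31)
    if z == np.uint64(0):
        z = _SM_GAMMA
    return z


@njit(cache=False, inline="always", fastmath=True)
def _next_u(state):
    """Advance an xorshift64* state; return (state, uniform in [0, 1))."""
    x = state
    x ^= x >> _S12
    x ^= x << _S25
    x ^= x >> _S27
    u = float((x * _MULT) >> _S11) * _INV53
    return x, u


@njit(cache=False, inline="always", fastmath=True)
def _hg_cosine(g, u):
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=False, fastmath=True)
def run_packets(
    labels,            # (nx, ny, nz) int16/int32 label grid
    mu_a, mu_s, g_fac, # per-label property arrays (per mm)
    sx, sy, sz,        # voxel spacing, mm
    px, py, pz,        # (n,) launch positions, corner-frame mm
    ux0, uy0, uz0,     # (n,) launch directions (unit)
    base_seed,         # uint64
    w_threshold,       # roulette trigger weight
    p_survive,         # roulette survival probability
    use_roulette,      # bool; when False, residual weight is deposited locally
    max_steps,         # safety cap on sub-steps per packet
    track,             # (nx, ny, nz) float64 out: sum of weight x chord (mm)
    absorbed,          # (nx, ny, nz) float64 out: deposited weight
):
    nx, ny, nz = labels.shape
    n = px.shape[0]
    escaped = 0.0

    for i in range(n):
        state = _seed_state(base_seed, i)
        x = px[i]; y = py[i]; z = pz[i]
        ux = ux0[i]; uy = uy0[i]; uz = uz0[i]
        ix = int(math.floor(x / sx))
        iy = int(math.floor(y / sy))
        iz = int(math.floor(z / sz))
        w = 1.0
        alive = True
        state, u = _next_u(state)
        s = -math.log(1.0 - u)  # dimensionless step remaining
        steps = 0

        while alive:
            steps += 1
            if steps > max_steps:
                # safety: deposit the stuck packet locally (never seen in practice)
                absorbed[ix, iy, iz] += w
                break
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                escaped += w
                break
            lab = labels[ix, iy, iz]
            if lab == 0:
                escaped += w
                break
            mua = mu_a[lab]
            mus = mu_s[lab]
            mut = mua + mus

            # distance to the nearest voxel boundary along the direction
            if ux > 0.0:
                tx = ((ix + 1) * sx - x) / ux
                stepx = 1
            elif ux < 0.0:
                tx = (ix * sx - x) / ux
                stepx = -1
            else:
                tx = 1e30
                stepx = 0
            if uy > 0.0:
                ty = ((iy + 1) * sy - y) / uy
                stepy = 1
            elif uy < 0.0:
                ty = (iy * sy - y) / uy
                stepy = -1
            else:
                ty = 1e30
                stepy = 0
            if uz > 0.0:
                tz = ((iz + 1) * sz - z) / uz
                stepz = 1
            elif uz < 0.0:
                tz = (iz * sz - z) / uz
                stepz = -1
            else:
                tz = 1e30
                stepz = 0

            db = tx
            axis = 0
            if ty < db:
                db = ty
                axis = 1
            if tz < db:
                db = tz
                axis = 2
            if db < 0.0:
                db = 0.0

            if mut <= 0.0 or db * mut < s:
                # free flight to the voxel boundary (fluence still accumulates)
                track[ix, iy, iz] += w * db
                x += ux * db
                y += uy * db
                z += uz * db
                if mut > 0.0:
                    s -= db * mut
                if axis == 0:
                    ix += stepx
                elif axis == 1:
                    iy += stepy
                else:
                    iz += stepz
                continue

            # interaction inside this voxel
            travel = s / mut
            track[ix, iy, iz] += w * travel
            x += ux * travel
            y += uy * travel
            z += uz * travel

            dw = w * mua / mut
            absorbed[ix, iy, iz] += dw
            w -= dw

            # scatter (Henyey-Greenstein polar angle, uniform azimuth)
            state, u = _next_u(state)
            cost = _hg_cosine(g_fac[lab], u)
            sint = math.sqrt(max(0.0, 1.0 - cost * cost))
            state, u = _next_u(state)
            phi = 2.0 * math.pi * u
            cosp = math.cos(phi)
            sinp = math.sin(phi)
            if abs(uz) > 0.99999:
                nux = sint * cosp
                nuy = sint * sinp
                nuz = cost if uz >= 0.0 else -cost
            else:
                denom = math.sqrt(1.0 - uz * uz)
                nux = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
                nuy = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
                nuz = -denom * sint * cosp + uz * cost
            norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
            ux = nux / norm
            uy = nuy / norm
            uz = nuz / norm

            # termination handling
            if w <= 0.0:
                alive = False
            elif w < w_threshold:
                if use_roulette:
                    state, u = _next_u(state)
                    if u < p_survive:
                        w /= p_survive
                    else:
                        alive = False  # weight lost; unbiased in expectation
                else:
                    # deposit the residual so the bookkeeping identity
                    # launched = deposited + escaped holds exactly
                    absorbed[ix, iy, iz] += w
                    alive = False

            state, u = _next_u(state)
            s = -math.log(1.0 - u)

    return escaped
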