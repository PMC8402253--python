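"""Numba transport kernel.

Private module: flat-array photon transport with per-depth-slab (or per-voxel)
path-length recording keyed to the exit-radius ring of each detected photon.

Conventions
-----------
* z = 0 at the tissue surface, increasing downward; photons launch at the
  origin as a pencil beam along +z.
* Depth slab k covers [k*dz, (k+1)*dz).
* Detector rings are the half-open annuli [edges[k], edges[k+1]).
* Each photon draws from its own counter-based substream (SplitMix64 keyed by
  seed and photon index), so tallies are bit-reproducible and independent of
  tally mode or photon-count changes.
* Boundary reflection is all-or-none Fresnel (MCML convention): every photon
  has exactly one terminal event, so the weight ledger closes exactly.
* The scattering azimuth is drawn by unit-disk rejection sampling (no
  trigonometry in the hot loop); the deflection cosine is Henyey-Greenstein.

Two absorption-weighting schemes:

* ``discrete`` (0): collisions at rate mu_t, weight *= mu_s/mu_t per
  collision (MCML albedo weighting).
* ``continuous`` (1): collisions at rate mu_s, weight *= exp(-mu_a * step)
  along each flight. Trajectories are then independent of mu_a, which makes
  absorption reweighting (lookup-table fast mode, phantom sweeps) exact and
  enables common-random-number perturbation studies.
"""

import math

import numpy as np
from numba import njit, uint64

U64 = np.uint64

# ledger slots
LG_LAUNCHED = 0
LG_ABSORBED = 1
LG_TRANSMITTED = 2
LG_ESCAPED = 3
LG_TERMINATED = 4
LG_ROULETTED = 5
LG_DETECTED = 6
N_LEDGER = 7

# photon terminal status codes
ST_DETECTED = 0
ST_ESCAPED = 1
ST_TRANSMITTED = 2
ST_ROULETTED = 3
ST_TERMINATED = 4

WEIGHT_DISCRETE = 0
WEIGHT_CONTINUOUS = 1

_INV_2P53 = 1.0 / 9007199254740992.0


@njit(uint64(uint64), cache=True, inline="always", fastmath=True)
def _mix64(z):
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always", fastmath=True)
def _rand(state):
    """SplitMix64 step; returns (new_state, uniform in (0, 1])."""
    state = state + U64(0x9E3779B97F4A7C15)
    z = _mix64(state)
    return state, (float(z >> U64(11)) + 1.0) * _INV_2P53


@njit(cache=True, inline="always", fastmath=True)
def _photon_state(seed, index):
    s = _mix64(U64(seed) * U64(0x9E3779B97F4A7C15) + U64(0xD1B54A32D192ED03))
    return _mix64(s ^ (U64(index) + U64(1)) * U64(0xA24BAED4963EE407))


@njit(cache=True, inline="always", fastmath=True)
def _hg_cos(state, g):
    """Sample the Henyey-Greenstein deflection cosine."""
    state, u = _rand(state)
    if g < 1e-6:
        ct = 2.0 * u - 1.0
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
    return state, ct


@njit(cache=True, fastmath=True)
def hg_sample_batch(n, g, seed, out_cos, out_phi):
    """Batch HG sampler for statistical tests of the phase function."""
    state = _photon_state(seed, 0)
    for i in range(n):
        state, ct = _hg_cos(state, g)
        state, u = _rand(state)
        out_cos[i] = ct
        out_phi[i] = 2.0 * math.pi * (1.0 - u)  # [0, 2pi)


@njit(cache=True, inline="always", fastmath=True)
def _fresnel(n1, n2, cosi):
    """Unpolarized Fresnel reflectance for incidence cosine cosi (n1 -> n2)."""
    if n1 == n2:
        return 0.0
    if cosi > 1.0:
        cosi = 1.0
    sint2 = (n1 / n2) * (n1 / n2) * (1.0 - cosi * cosi)
    if sint2 >= 1.0:
        return 1.0
    cost = math.sqrt(1.0 - sint2)
    rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
    rp = (n1 * cost - n2 * cosi) / (n1 * cost + n2 * cosi)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, inline="always", fastmath=True)
def _ring_of(edges, r):
    n = edges.shape[0]
    if r < edges[0] or r >= edges[n - 1]:
        return -1
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) >> 1
        if r < edges[mid]:
            hi = mid
        else:
            lo = mid
    return lo


@njit(cache=True, fastmath=True)
def transport(
    n_photons,
    start_index,
    seed,
    # model (flat per-layer arrays; zb has n_layers + 1 entries, zb[0] = 0)
    zb,
    mus,
    mua,
    g_arr,
    n_arr,
    n_top,
    n_bottom,
    # detector
    edges,
    # depth-slab tally grid
    dz,
    n_slabs,
    # full-3D tally grid (voxel cube of side dz); ignored when mode3d == 0.
    mode3d,
    x0,
    y0,
    nx,
    ny,
    nz3,
    # physics options
    weighting,
    roulette_on,
    w_thresh,
    p_surv,
    max_path,
    # per-photon record outputs (record_mode != 0 fills them)
    record_mode,
    n_rec,
    rec_status,
    rec_ring,
    rec_w,
    rec_r,
    rec_tot,
    rec_paths,
    # tallies
    det_w,
    det_w2,
    path_w,
    vox_w,
    ledger,
    # scratch
    depth_rec,
    seg_buf,
):
    n_layers = mus.shape[0]
    z_bottom = zb[n_layers]
    inv_dz = 1.0 / dz
    inv_p_surv = 1.0 / p_surv if p_surv > 0.0 else 0.0

    # per-layer precomputation
    rate = np.empty(n_layers)
    inv_rate = np.empty(n_layers)
    albedo = np.empty(n_layers)
    absfrac = np.empty(n_layers)
    for i in range(n_layers):
        mt = mus[i] + mua[i]
        r_i = mt if weighting == WEIGHT_DISCRETE else mus[i]
        rate[i] = r_i
        inv_rate[i] = 1.0 / r_i if r_i > 0.0 else 1e30
        albedo[i] = mus[i] / mt if mt > 0.0 else 1.0
        absfrac[i] = mua[i] / mt if mt > 0.0 else 0.0

    sum_absorbed = 0.0
    sum_transmitted = 0.0
    sum_escaped = 0.0
    sum_terminated = 0.0
    sum_rouletted = 0.0
    sum_detected = 0.0

    for ip in range(n_photons):
        state = _photon_state(seed, ip + start_index)

        w = 1.0
        # specular reflection of the pencil beam at the top surface
        if n_top != n_arr[0]:
            rsp = (n_arr[0] - n_top) / (n_arr[0] + n_top)
            rsp = rsp * rsp
            sum_escaped += rsp
            w -= rsp

        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        total = 0.0

        # per-photon depth record (touched range only is reset afterwards)
        smin = n_slabs
        smax = -1
        nseg = 0

        alive = True
        status = ST_TERMINATED
        exit_r = -1.0
        exit_ring = -1

        inv_uz = 1.0  # 1/|uz|, refreshed whenever |uz| changes
        while alive:
            state, u = _rand(state)
            sd = -math.log(u)  # dimensionless optical step

            # propagate, possibly across layer boundaries
            while True:
                sgeo = sd * inv_rate[layer]
                if uz > 1e-12:
                    db = (zb[layer + 1] - z) * inv_uz
                elif uz < -1e-12:
                    db = (z - zb[layer]) * inv_uz
                else:
                    db = 1e30
                hit_boundary = db < sgeo
                step = db if hit_boundary else sgeo
                if step < 0.0:
                    step = 0.0

                # ---- advance with depth-slab path recording ----
                if step > 0.0:
                    z_new = z + uz * step
                    k0 = int(z * inv_dz)
                    if k0 >= n_slabs:
                        k0 = n_slabs - 1
                    k1 = int(z_new * inv_dz)
                    if k1 >= n_slabs:
                        k1 = n_slabs - 1
                    if k1 == k0 and mode3d == 0:
                        # fast path: whole step inside one slab
                        depth_rec[k0] += step
                        if k0 < smin:
                            smin = k0
                        if k0 > smax:
                            smax = k0
                        x += ux * step
                        y += uy * step
                        z = z_new
                    elif abs(uz) < 1e-10:
                        depth_rec[k0] += step
                        if k0 < smin:
                            smin = k0
                        if k0 > smax:
                            smax = k0
                        if mode3d == 1 and nseg < seg_buf.shape[0]:
                            seg_buf[nseg, 0] = x + 0.5 * step * ux
                            seg_buf[nseg, 1] = y + 0.5 * step * uy
                            seg_buf[nseg, 2] = z
                            seg_buf[nseg, 3] = step
                            nseg += 1
                        x += ux * step
                        y += uy * step
                        z = z_new
                    else:
                        # split the step at slab boundaries
                        remaining = step
                        zz = z
                        xx = x
                        yy = y
                        k = k0
                        if uz < 0.0 and zz - k * dz < 1e-12:
                            k -= 1
                            if k < 0:
                                k = 0
                        while remaining > 0.0:
                            if uz > 0.0:
                                tb = ((k + 1) * dz - zz) / uz
                            else:
                                tb = (zz - k * dz) / (-uz)
                            if tb < 0.0:
                                tb = 0.0
                            at_edge = (uz > 0.0 and k == n_slabs - 1) or (
                                uz < 0.0 and k == 0
                            )
                            if tb >= remaining or at_edge:
                                # at_edge: clamp rounding residue into edge slab
                                seg = remaining
                            else:
                                seg = tb
                            depth_rec[k] += seg
                            if k < smin:
                                smin = k
                            if k > smax:
                                smax = k
                            if mode3d == 1 and nseg < seg_buf.shape[0]:
                                seg_buf[nseg, 0] = xx + 0.5 * seg * ux
                                seg_buf[nseg, 1] = yy + 0.5 * seg * uy
                                seg_buf[nseg, 2] = zz + 0.5 * seg * uz
                                seg_buf[nseg, 3] = seg
                                nseg += 1
                            zz += uz * seg
                            xx += ux * seg
                            yy += uy * seg
                            remaining -= seg
                            if remaining <= 0.0:
                                break
                            if uz > 0.0:
                                k += 1
                                zz = k * dz
                            else:
                                zz = k * dz
                                k -= 1
                        x = xx
                        y = yy
                        z = zz
                    total += step
                    if weighting == WEIGHT_CONTINUOUS and mua[layer] > 0.0:
                        f = math.exp(-mua[layer] * step)
                        sum_absorbed += w * (1.0 - f)
                        w *= f

                if total >= max_path:
                    sum_terminated += w
                    status = ST_TERMINATED
                    alive = False
                    break

                if not hit_boundary:
                    break  # interact at current position

                sd -= db * rate[layer]

                # ---- boundary handling ----
                if uz < 0.0 and layer == 0:
                    z = 0.0
                    refl = _fresnel(n_arr[0], n_top, -uz)
                    state, u = _rand(state)
                    if u > refl:
                        r = math.sqrt(x * x + y * y)
                        ring = _ring_of(edges, r)
                        exit_r = r
                        exit_ring = ring
                        if ring >= 0:
                            sum_detected += w
                            det_w[ring] += w
                            det_w2[ring] += w * w
                            if mode3d == 0:
                                for k in range(smin, smax + 1):
                                    path_w[ring, k] += w * depth_rec[k]
                            else:
                                if r > 0.0:
                                    cph = x / r
                                    sph = y / r
                                else:
                                    cph = 1.0
                                    sph = 0.0
                                for s in range(nseg):
                                    xm = seg_buf[s, 0]
                                    ym = seg_buf[s, 1]
                                    zm = seg_buf[s, 2]
                                    xr = xm * cph + ym * sph
                                    yr = -xm * sph + ym * cph
                                    ix = int((xr - x0) * inv_dz)
                                    if ix < 0:
                                        ix = 0
                                    elif ix >= nx:
                                        ix = nx - 1
                                    iy = int((yr - y0) * inv_dz)
                                    if iy < 0:
                                        iy = 0
                                    elif iy >= ny:
                                        iy = ny - 1
                                    iz = int(zm * inv_dz)
                                    if iz < 0:
                                        iz = 0
                                    elif iz >= nz3:
                                        iz = nz3 - 1
                                    vox_w[ring, ix, iy, iz] += w * seg_buf[s, 3]
                            status = ST_DETECTED
                        else:
                            sum_escaped += w
                            status = ST_ESCAPED
                        alive = False
                        break
                    uz = -uz  # reflected back into the tissue
                elif uz > 0.0 and layer == n_layers - 1:
                    z = z_bottom
                    refl = _fresnel(n_arr[layer], n_bottom, uz)
                    state, u = _rand(state)
                    if u > refl:
                        sum_transmitted += w
                        status = ST_TRANSMITTED
                        exit_r = math.sqrt(x * x + y * y)
                        alive = False
                        break
                    uz = -uz
                else:
                    # internal interface
                    if uz > 0.0:
                        nxt = layer + 1
                        z = zb[layer + 1]
                    else:
                        nxt = layer - 1
                        z = zb[layer]
                    n1 = n_arr[layer]
                    n2 = n_arr[nxt]
                    if n1 == n2:
                        layer = nxt
                    else:
                        cosi = abs(uz)
                        refl = _fresnel(n1, n2, cosi)
                        state, u = _rand(state)
                        if u > refl:
                            ratio = n1 / n2
                            sint2 = ratio * ratio * (1.0 - cosi * cosi)
                            cost = math.sqrt(max(0.0, 1.0 - sint2))
                            ux *= ratio
                            uy *= ratio
                            uz = cost if uz > 0.0 else -cost
                            inv_uz = 1.0 / cost if cost > 1e-12 else 1e30
                            layer = nxt
                        else:
                            uz = -uz
                # continue inner loop with leftover sd

            if not alive:
                break

            # ---- interaction ----
            if weighting == WEIGHT_DISCRETE:
                sum_absorbed += w * absfrac[layer]
                w *= albedo[layer]

            state, ct = _hg_cos(state, g_arr[layer])
            st_ = math.sqrt(max(0.0, 1.0 - ct * ct))
            # azimuth by unit-disk rejection (no trig)
            while True:
                state, u1 = _rand(state)
                state, u2 = _rand(state)
                ax = 2.0 * u1 - 1.0
                ay = 2.0 * u2 - 1.0
                rr = ax * ax + ay * ay
                if 1e-12 < rr <= 1.0:
                    break
            inv_r = 1.0 / math.sqrt(rr)
            cp = ax * inv_r
            sp = ay * inv_r
            if abs(uz) > 0.99999:
                ux = st_ * cp
                uy = st_ * sp
                uz = ct if uz > 0.0 else -ct
            else:
                den = math.sqrt(1.0 - uz * uz)
                inv_den = 1.0 / den
                nux = st_ * (ux * uz * cp - uy * sp) * inv_den + ux * ct
                nuy = st_ * (uy * uz * cp + ux * sp) * inv_den + uy * ct
                nuz = -den * st_ * cp + uz * ct
                inv_norm = 1.0 / math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux = nux * inv_norm
                uy = nuy * inv_norm
                uz = nuz * inv_norm
            auz = abs(uz)
            inv_uz = 1.0 / auz if auz > 1e-12 else 1e30

            if roulette_on == 1 and w < w_thresh:
                state, u = _rand(state)
                if u < p_surv:
                    w *= inv_p_surv
                else:
                    sum_rouletted += w
                    status = ST_ROULETTED
                    alive = False

        # ---- per-photon record ----
        if record_mode == 1:
            rec_status[ip] = status
            rec_ring[ip] = exit_ring
            rec_w[ip] = w
            rec_r[ip] = exit_r
            rec_tot[ip] = total
            over = 0.0
            for k in range(smin, smax + 1):
                if k < n_rec:
                    rec_paths[ip, k] = depth_rec[k]
                else:
                    over += depth_rec[k]
            rec_paths[ip, n_rec] = over

        # reset touched slabs for the next photon
        for k in range(smin, smax + 1):
            depth_rec[k] = 0.0

    ledger[LG_LAUNCHED] += float(n_photons)
    ledger[LG_ABSORBED] += sum_absorbed
    ledger[LG_TRANSMITTED] += sum_transmitted
    ledger[LG_ESCAPED] += sum_escaped
    ledger[LG_TERMINATED] += sum_terminated
    ledger[LG_ROULETTED] += sum_rouletted
    ledger[LG_DETECTED] += sum_detected
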