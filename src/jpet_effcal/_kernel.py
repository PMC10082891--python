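"""Compiled Monte-Carlo transport of annihilation and prompt photons.

Compton-only transport through the strip barrel: photons fly along straight
rays, chords through candidate strips are found by intersecting the ray with
each layer cylinder and box-testing the nearest strips, and an interaction is
placed at an exponentially sampled optical depth.  At each interaction the
scattering angle is drawn from the Klein-Nishina law by rejection (the
forward value 2 bounds the unnormalized density), the energy transfer
follows Compton kinematics, and the degraded photon continues until escape,
an energy floor, or the interaction cap.

The geometry maths mirrors :mod:`jpet_effcal.geometry`; it is repeated here
in scalar form because this loop dominates the runtime of every study.
"""

import numpy as np
from numba import njit

# truth-origin codes: 1/2 = first interaction of annihilation photon 1/2,
# 3 = first interaction of the prompt photon, +3 for later generations.
ORIGIN_ANNIH_1 = 1
ORIGIN_ANNIH_2 = 2
ORIGIN_PROMPT = 3

_MEC2 = 511.0
_C = 29.98
_RE2 = 7.940787e-26
_E_FLOOR_KEV = 2.0


@njit(inline="always")
def _kn_sigma_total(e_kev):
    a = e_kev / _MEC2
    t1 = (1.0 + a) / (a * a) * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - np.log(1.0 + 2.0 * a) / a)
    t2 = np.log(1.0 + 2.0 * a) / (2.0 * a)
    t3 = (1.0 + 3.0 * a) / (1.0 + 2.0 * a) ** 2
    return 2.0 * np.pi * _RE2 * (t1 + t2 - t3)


@njit(inline="always")
def _box_chord(ox, oy, oz, dx, dy, dz, cp, sp, r, half_t, half_w, half_l):
    """Entry/exit ray parameters of the chord inside one strip box (or (-1,-1))."""
    lox = ox * cp + oy * sp
    loy = -ox * sp + oy * cp
    ldx = dx * cp + dy * sp
    ldy = -dx * sp + dy * cp
    t_near = -1.0e300
    t_far = 1.0e300
    # radial slab
    if np.abs(ldx) < 1.0e-14:
        if lox < r - half_t or lox > r + half_t:
            return -1.0, -1.0
    else:
        t1 = (r - half_t - lox) / ldx
        t2 = (r + half_t - lox) / ldx
        if t1 > t2:
            t1, t2 = t2, t1
        t_near = max(t_near, t1)
        t_far = min(t_far, t2)
    # tangential slab
    if np.abs(ldy) < 1.0e-14:
        if loy < -half_w or loy > half_w:
            return -1.0, -1.0
    else:
        t1 = (-half_w - loy) / ldy
        t2 = (half_w - loy) / ldy
        if t1 > t2:
            t1, t2 = t2, t1
        t_near = max(t_near, t1)
        t_far = min(t_far, t2)
    # axial slab
    if np.abs(dz) < 1.0e-14:
        if oz < -half_l or oz > half_l:
            return -1.0, -1.0
    else:
        t1 = (-half_l - oz) / dz
        t2 = (half_l - oz) / dz
        if t1 > t2:
            t1, t2 = t2, t1
        t_near = max(t_near, t1)
        t_far = min(t_far, t2)
    entry = max(t_near, 0.0)
    if t_far <= entry + 1.0e-12:
        return -1.0, -1.0
    return entry, t_far


@njit
def _transport_events(
    n_events,
    seed,
    layer_radius,
    layer_nstrips,
    layer_pitch_rad,
    layer_offset_rad,
    layer_base,
    strip_cos,
    strip_sin,
    half_t,
    half_w,
    half_l,
    extent_radius,
    prompt_enabled,
    prompt_energy,
    pair_cos_max,
    mu_mode,
    mu_const,
    ne_density,
    max_interactions,
    out_event,
    out_strip,
    out_time,
    out_z,
    out_x,
    out_y,
    out_e,
    out_origin,
    out_gen,
    out_src,
):
    np.random.seed(seed)
    n_layers = layer_radius.shape[0]
    nhit = 0
    cap = out_event.shape[0]
    cand_sid = np.empty(24, dtype=np.int64)
    cand_sin = np.empty(24, dtype=np.float64)
    cand_len = np.empty(24, dtype=np.float64)
    r_outer = 0.0
    for li in range(n_layers):
        if layer_radius[li] + half_t > r_outer:
            r_outer = layer_radius[li] + half_t

    for ev in range(n_events):
        # emission point: uniform ball of the source extent
        sx = 0.0
        sy = 0.0
        sz = 0.0
        if extent_radius > 0.0:
            while True:
                sx = (2.0 * np.random.random() - 1.0) * extent_radius
                sy = (2.0 * np.random.random() - 1.0) * extent_radius
                sz = (2.0 * np.random.random() - 1.0) * extent_radius
                if sx * sx + sy * sy + sz * sz <= extent_radius * extent_radius:
                    break
        out_src[ev, 0] = sx
        out_src[ev, 1] = sy
        out_src[ev, 2] = sz
        # back-to-back pair axis
        cpol = (2.0 * np.random.random() - 1.0) * pair_cos_max
        aphi = 2.0 * np.pi * np.random.random()
        spol = np.sqrt(1.0 - cpol * cpol)
        axx = spol * np.cos(aphi)
        axy = spol * np.sin(aphi)
        axz = cpol
        n_photons = 3 if prompt_enabled else 2
        for kind in range(1, n_photons + 1):
            if kind == 1:
                e = _MEC2
                dx, dy, dz = axx, axy, axz
            elif kind == 2:
                e = _MEC2
                dx, dy, dz = -axx, -axy, -axz
            else:
                e = prompt_energy
                c2 = 2.0 * np.random.random() - 1.0
                p2 = 2.0 * np.pi * np.random.random()
                s2 = np.sqrt(1.0 - c2 * c2)
                dx = s2 * np.cos(p2)
                dy = s2 * np.sin(p2)
                dz = c2
            px, py, pz = sx, sy, sz
            t_cum = 0.0
            cur_strip = -1
            for inter in range(max_interactions):
                # --- collect candidate chords ---
                ncand = 0
                for li in range(n_layers):
                    r = layer_radius[li]
                    a = dx * dx + dy * dy
                    if a < 1.0e-14:
                        continue
                    b = 2.0 * (px * dx + py * dy)
                    c = px * px + py * py - r * r
                    disc = b * b - 4.0 * a * c
                    if disc <= 0.0:
                        continue
                    sq = np.sqrt(disc)
                    for sgn in range(2):
                        t_root = (-b - sq) / (2.0 * a) if sgn == 0 else (-b + sq) / (2.0 * a)
                        if t_root < -1.0e-9:
                            continue
                        cx = px + t_root * dx
                        cy = py + t_root * dy
                        phi_x = np.arctan2(cy, cx)
                        kc = int(np.round((phi_x - layer_offset_rad[li]) / layer_pitch_rad[li]))
                        for dk in range(-1, 2):
                            k = (kc + dk) % layer_nstrips[li]
                            sid = layer_base[li] + k
                            dup = False
                            for q in range(ncand):
                                if cand_sid[q] == sid:
                                    dup = True
                                    break
                            if dup:
                                continue
                            s_in, s_out = _box_chord(
                                px, py, pz, dx, dy, dz,
                                strip_cos[sid], strip_sin[sid],
                                r, half_t, half_w, half_l,
                            )
                            if s_out > 0.0 and ncand < 24:
                                cand_sid[ncand] = sid
                                cand_sin[ncand] = s_in
                                cand_len[ncand] = s_out - s_in
                                ncand += 1
                # current strip (photon scattered inside it) may be missed by
                # the cylinder-crossing search when the ray exits sideways
                if cur_strip >= 0:
                    dup = False
                    for q in range(ncand):
                        if cand_sid[q] == cur_strip:
                            dup = True
                            break
                    if not dup:
                        li = 0
                        for lj in range(n_layers):
                            if cur_strip < layer_base[lj] + layer_nstrips[lj]:
                                li = lj
                                break
                        s_in, s_out = _box_chord(
                            px, py, pz, dx, dy, dz,
                            strip_cos[cur_strip], strip_sin[cur_strip],
                            layer_radius[li], half_t, half_w, half_l,
                        )
                        if s_out > 0.0 and ncand < 24:
                            cand_sid[ncand] = cur_strip
                            cand_sin[ncand] = s_in
                            cand_len[ncand] = s_out - s_in
                            ncand += 1
                if ncand == 0:
                    break
                # insertion sort by entry parameter
                for i in range(1, ncand):
                    ks = cand_sid[i]
                    ki = cand_sin[i]
                    kl = cand_len[i]
                    j = i - 1
                    while j >= 0 and cand_sin[j] > ki:
                        cand_sid[j + 1] = cand_sid[j]
                        cand_sin[j + 1] = cand_sin[j]
                        cand_len[j + 1] = cand_len[j]
                        j -= 1
                    cand_sid[j + 1] = ks
                    cand_sin[j + 1] = ki
                    cand_len[j + 1] = kl
                # --- exponential optical depth walk ---
                mu = mu_const if mu_mode == 0 else ne_density * _kn_sigma_total(e)
                tau = -np.log(1.0 - np.random.random())
                hit_idx = -1
                s_int = 0.0
                for q in range(ncand):
                    lam = mu * cand_len[q]
                    if tau <= lam:
                        hit_idx = q
                        s_int = cand_sin[q] + tau / mu
                        break
                    tau -= lam
                if hit_idx < 0:
                    break  # escape
                sid = cand_sid[hit_idx]
                ix = px + s_int * dx
                iy = py + s_int * dy
                iz = pz + s_int * dz
                t_cum += s_int / _C
                # --- Klein-Nishina scatter ---
                alpha = e / _MEC2
                cos_t = 1.0
                while True:
                    cos_p = 2.0 * np.random.random() - 1.0
                    pp = 1.0 / (1.0 + alpha * (1.0 - cos_p))
                    kn = pp * pp * (pp + 1.0 / pp - (1.0 - cos_p * cos_p))
                    if 2.0 * np.random.random() <= kn:
                        cos_t = cos_p
                        break
                pp = 1.0 / (1.0 + alpha * (1.0 - cos_t))
                de = e * (1.0 - pp)
                if nhit >= cap:
                    return -1
                out_event[nhit] = ev
                out_strip[nhit] = sid
                out_time[nhit] = t_cum
                out_z[nhit] = iz
                out_x[nhit] = ix
                out_y[nhit] = iy
                out_e[nhit] = de
                out_origin[nhit] = kind if inter == 0 else kind + 3
                out_gen[nhit] = inter
                nhit += 1
                e = e - de
                if e < _E_FLOOR_KEV:
                    break
                # rotate direction by theta around a uniform azimuth
                sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
                psi = 2.0 * np.pi * np.random.random()
                if np.abs(dx) < 0.9:
                    hx, hy, hz = 1.0, 0.0, 0.0
                else:
                    hx, hy, hz = 0.0, 1.0, 0.0
                e1x = dy * hz - dz * hy
                e1y = dz * hx - dx * hz
                e1z = dx * hy - dy * hx
                n1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
                e1x /= n1
                e1y /= n1
                e1z /= n1
                e2x = dy * e1z - dz * e1y
                e2y = dz * e1x - dx * e1z
                e2z = dx * e1y - dy * e1x
                ca = np.cos(psi)
                sa = np.sin(psi)
                ndx = cos_t * dx + sin_t * (ca * e1x + sa * e2x)
                ndy = cos_t * dy + sin_t * (ca * e1y + sa * e2y)
                ndz = cos_t * dz + sin_t * (ca * e1z + sa * e2z)
                nn = np.sqrt(ndx * ndx + ndy * ndy + ndz * ndz)
                dx, dy, dz = ndx / nn, ndy / nn, ndz / nn
                px, py, pz = ix, iy, iz
                cur_strip = sid
    return nhit
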