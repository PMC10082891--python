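"""Three-hit coincidence analysis chain.

The analysis isolates events in which the two primary back-to-back 511 keV
annihilation photons each produced one hit and exactly one of their
scattered photons produced a third hit.  Stages:

1. greedy coincidence grouping in a fixed time window (default 200 ns),
   keeping groups of exactly three hits;
2. energy-band preselection: at least two hits inside the annihilation
   deposit band, no hit above the prompt veto;
3. back-to-back labeling from the azimuthal angular correlation — the sum
   of the two smallest folded pairwise separations clusters at 180 deg for
   genuine annihilation pairs;
4. the scatter test S = dt - D/c for the scatter hit against each primary
   hypothesis: S vanishes when the scattered photon truly originated at
   that primary's interaction;
5. annihilation-vertex reconstruction along the line of response from the
   time-of-flight difference, with a transverse-distance check;
6. the scattering angle at the assigned primary hit, which maps one-to-one
   to the primary's energy deposit through Compton kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .compton import deposited_energy
from .constants import C_CM_PER_NS, E_ANNIH_KEV

__all__ = [
    "SelectionConfig",
    "group_events",
    "energy_band_preselect",
    "angular_correlation",
    "select_back_to_back",
    "scatter_test",
    "assign_scatter",
    "reconstruct_annihilation_point",
    "scattering_angle",
    "select_events",
]


@dataclass
class SelectionConfig:
    """Cuts of the 3-hit chain.

    The deposit bands act on *smeared* energies.  With the fractional
    resolution sigma(E)/E = 0.44/sqrt(E[MeV]) the smeared annihilation
    Compton edge (341 keV true) has a one-sigma spread of ~260 keV, so the
    default band and veto sit ~2 sigma above the edge: tighter bands would
    reject mostly genuine annihilation deposits rather than prompt ones,
    and the discrimination burden falls on the angular correlation, the
    scatter test and the vertex check.
    """

    ctw_ns: float = 200.0
    annih_band_kev: tuple = (70.0, 850.0)
    veto_above_kev: float = 900.0
    window_deg: float = 4.0          # half-width of the back-to-back band
    accept_radius_ns: float = 1.0    # |S| acceptance for the scatter test
    require_s_exclusive: bool = True  # competing hypothesis must fail the cut
    vertex_check: bool = True
    chamber_radius_cm: float = 1.58
    vertex_margin_cm: float = 10.0   # allowance for TOF-driven vertex resolution
    use_true_positions: bool = False
    use_reconstructed_vertex: bool = True
    source_position: tuple = (0.0, 0.0, 0.0)


@njit
def _greedy_groups(times, ctw):
    """Group boundaries: window opens at the earliest unconsumed hit."""
    n = times.shape[0]
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    ng = 0
    i = 0
    while i < n:
        j = i + 1
        while j < n and times[j] - times[i] <= ctw:
            j += 1
        starts[ng] = i
        ends[ng] = j
        ng += 1
        i = j
    return starts[:ng], ends[:ng]


def group_events(hits, ctw_ns=200.0):
    """Greedy time-ordered coincidence grouping; keeps 3-hit groups only.

    ``hits`` is a time-sorted DataFrame; returns a list of integer index
    triples (positions into ``hits``).
    """
    times = np.asarray(hits["time_ns"], dtype=float)
    if len(times) and np.any(np.diff(times) < 0):
        raise ValueError("hits must be sorted by time")
    starts, ends = _greedy_groups(times, float(ctw_ns))
    return [list(range(s, e)) for s, e in zip(starts, ends) if e - s == 3]


def energy_band_preselect(energies_kev, annih_band=(70.0, 341.0), veto_above=400.0):
    """True iff no deposit exceeds the veto and >= 2 fall in the band (closed)."""
    e = np.asarray(energies_kev, dtype=float)
    if np.any(e > veto_above):
        return False
    lo, hi = annih_band
    return int(np.sum((e >= lo) & (e <= hi))) >= 2


def _fold_separation(a_deg, b_deg):
    d = np.abs(np.asarray(a_deg) - np.asarray(b_deg)) % 360.0
    return np.where(d > 180.0, 360.0 - d, d)


def angular_correlation(azimuths_deg):
    """(sum, |difference|) of the two smallest folded pairwise separations."""
    a = np.asarray(azimuths_deg, dtype=float)
    seps = np.sort(
        [
            float(_fold_separation(a[0], a[1])),
            float(_fold_separation(a[0], a[2])),
            float(_fold_separation(a[1], a[2])),
        ]
    )
    return seps[0] + seps[1], abs(seps[1] - seps[0])


def select_back_to_back(azimuths_deg, window_deg=4.0):
    """Back-to-back labeling: accept iff the two smallest separations sum to
    180 deg within ``window_deg``; primaries are the most separated pair.

    Returns ``(i_primary_1, i_primary_2, i_scatter)`` or ``None``.
    """
    a = np.asarray(azimuths_deg, dtype=float)
    pairs = ((0, 1), (0, 2), (1, 2))
    seps = np.array([_fold_separation(a[i], a[j]) for i, j in pairs], dtype=float)
    order = np.argsort(seps)
    if abs(seps[order[0]] + seps[order[1]] - 180.0) > window_deg:
        return None
    i, j = pairs[int(order[2])]
    k = 3 - i - j
    return i, j, k


def scatter_test(t_scatter, p_scatter, t_primary, p_primary):
    """S = (t_scatter - t_primary) - |p_scatter - p_primary| / c [ns]."""
    d = np.linalg.norm(np.asarray(p_scatter, dtype=float) - np.asarray(p_primary, dtype=float))
    return float(t_scatter - t_primary) - d / C_CM_PER_NS


def assign_scatter(s_1, s_2, accept_radius_ns=1.0):
    """Exclusive assignment: the hypothesis nearer zero wins iff it lies
    inside the acceptance and the competing one lies outside.

    Returns 1, 2 or 0 (rejected).
    """
    a1, a2 = abs(s_1), abs(s_2)
    near, far, label = (a1, a2, 1) if a1 <= a2 else (a2, a1, 2)
    if near <= accept_radius_ns < far:
        return label
    return 0


def reconstruct_annihilation_point(p1, t1, p2, t2):
    """Vertex on the line of response, displaced from the midpoint toward the
    earlier hit by c * |dt| / 2."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    sep = p2 - p1
    norm = np.linalg.norm(sep)
    if norm < 1e-9:
        raise ValueError("coincident hit positions: undefined line of response")
    u = sep / norm
    return 0.5 * (p1 + p2) - u * (C_CM_PER_NS * (t2 - t1) / 2.0)


def scattering_angle(vertex, p_primary, p_scatter):
    """Angle [deg] between the incident ray (vertex -> primary hit) and the
    scattered ray (primary hit -> scatter hit)."""
    a = np.asarray(p_primary, dtype=float) - np.asarray(vertex, dtype=float)
    b = np.asarray(p_scatter, dtype=float) - np.asarray(p_primary, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-9 or nb < 1e-9:
        raise ValueError("degenerate geometry for the scattering angle")
    return float(np.degrees(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0))))


# ----------------------------------------------------------------------
# vectorized driver


def select_events(hits, geometry, config: SelectionConfig = None):
    """Run the full 3-hit chain over a hit table.

    Returns a DataFrame with one row per event that survives every stage,
    carrying the scatter-test values, the assignment, the reconstructed
    vertex, the scattering angle and its Compton-equivalent deposit, and
    truth bookkeeping columns for simulation studies.  A second DataFrame
    reports the per-stage event counts (the selection funnel).
    """
    cfg = config or SelectionConfig()
    hits = hits.reset_index(drop=True)
    groups = group_events(hits, cfg.ctw_ns)
    funnel = {"hits": len(hits), "three_hit_groups": len(groups)}
    if not groups:
        return _empty_selection(), pd.DataFrame([funnel])
    idx = np.array(groups, dtype=np.int64)  # [n, 3]

    if cfg.use_true_positions:
        x = hits["true_x_cm"].to_numpy()[idx]
        y = hits["true_y_cm"].to_numpy()[idx]
        z = hits["true_z_cm"].to_numpy()[idx]
        t = hits["true_time_ns"].to_numpy()[idx]
    else:
        x = hits["x_cm"].to_numpy()[idx]
        y = hits["y_cm"].to_numpy()[idx]
        z = hits["z_cm"].to_numpy()[idx]
        t = hits["time_ns"].to_numpy()[idx]
    e_sm = hits["e_smeared_kev"].to_numpy()[idx]
    e_true = hits["e_true_kev"].to_numpy()[idx]
    origin = hits["truth_origin"].to_numpy()[idx]
    generation = hits["truth_generation"].to_numpy()[idx]
    merged = hits["merged"].to_numpy()[idx]
    event_id = hits["event_id"].to_numpy()[idx[:, 0]]
    azim = np.degrees(np.arctan2(y, x)) % 360.0

    # stage: energy-band preselection
    lo, hi = cfg.annih_band_kev
    in_band = (e_sm >= lo) & (e_sm <= hi)
    pre = (in_band.sum(axis=1) >= 2) & (e_sm <= cfg.veto_above_kev).all(axis=1)
    funnel["band_preselected"] = int(pre.sum())

    # stage: back-to-back labeling from folded azimuthal separations
    pairs = ((0, 1), (0, 2), (1, 2))
    seps = np.stack([_fold_separation(azim[:, i], azim[:, j]) for i, j in pairs], axis=1)
    s_sorted = np.sort(seps, axis=1)
    sum2 = s_sorted[:, 0] + s_sorted[:, 1]
    b2b = np.abs(sum2 - 180.0) <= cfg.window_deg
    keep = pre & b2b
    funnel["back_to_back"] = int(keep.sum())

    largest = np.argmax(seps, axis=1)
    pair_arr = np.array(pairs, dtype=np.int64)
    i1 = pair_arr[largest, 0]
    i2 = pair_arr[largest, 1]
    isc = 3 - i1 - i2
    rows = np.arange(len(idx))

    def take(arr, which):
        return arr[rows, which]

    # stage: scatter test against both primary hypotheses
    def s_value(which_primary):
        dx = take(x, isc) - take(x, which_primary)
        dy = take(y, isc) - take(y, which_primary)
        dz = take(z, isc) - take(z, which_primary)
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        return (take(t, isc) - take(t, which_primary)) - dist / C_CM_PER_NS

    s1 = s_value(i1)
    s2 = s_value(i2)
    a1, a2 = np.abs(s1), np.abs(s2)
    nearer_is_1 = a1 <= a2
    near = np.where(nearer_is_1, a1, a2)
    far = np.where(nearer_is_1, a2, a1)
    if cfg.require_s_exclusive:
        accepted = (near <= cfg.accept_radius_ns) & (far > cfg.accept_radius_ns)
    else:
        accepted = near <= cfg.accept_radius_ns
    assigned = np.where(accepted, np.where(nearer_is_1, 1, 2), 0)
    keep = keep & (assigned > 0)
    funnel["scatter_assigned"] = int(keep.sum())

    # stage: vertex reconstruction and transverse check
    p1x, p1y, p1z = take(x, i1), take(y, i1), take(z, i1)
    p2x, p2y, p2z = take(x, i2), take(y, i2), take(z, i2)
    t1, t2 = take(t, i1), take(t, i2)
    ux, uy, uz = p2x - p1x, p2y - p1y, p2z - p1z
    norm = np.sqrt(ux * ux + uy * uy + uz * uz)
    norm = np.where(norm < 1e-9, np.nan, norm)
    ux, uy, uz = ux / norm, uy / norm, uz / norm
    shift = C_CM_PER_NS * (t2 - t1) / 2.0
    vx = 0.5 * (p1x + p2x) - ux * shift
    vy = 0.5 * (p1y + p2y) - uy * shift
    vz = 0.5 * (p1z + p2z) - uz * shift
    if cfg.vertex_check:
        r_limit = cfg.chamber_radius_cm + cfg.vertex_margin_cm
        keep = keep & (np.hypot(vx, vy) <= r_limit)
    funnel["vertex_accepted"] = int(keep.sum())

    # scattering angle at the assigned primary
    ipri = np.where(assigned == 2, i2, i1)
    if not cfg.use_reconstructed_vertex:
        vx = np.full_like(vx, cfg.source_position[0])
        vy = np.full_like(vy, cfg.source_position[1])
        vz = np.full_like(vz, cfg.source_position[2])
    ax = take(x, ipri) - vx
    ay = take(y, ipri) - vy
    az = take(z, ipri) - vz
    bx = take(x, isc) - take(x, ipri)
    by = take(y, isc) - take(y, ipri)
    bz = take(z, isc) - take(z, ipri)
    na = np.sqrt(ax * ax + ay * ay + az * az)
    nb = np.sqrt(bx * bx + by * by + bz * bz)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = (ax * bx + ay * by + az * bz) / (na * nb)
    theta = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    de_reco = deposited_energy(E_ANNIH_KEV, theta)

    # truth bookkeeping: a clean event has the two annihilation-photon first
    # interactions as primaries and a daughter of one of them as scatter
    o1, o2, osc = take(origin, i1), take(origin, i2), take(origin, isc)
    clean = (np.minimum(o1, o2) == 1) & (np.maximum(o1, o2) == 2) & ((osc == 4) | (osc == 5))
    # scatter origin 4 descends from annihilation photon 1
    parent = np.where(osc == 4, 1, np.where(osc == 5, 2, 0))
    # map the parent photon label to the primary slot it occupies
    parent_slot = np.where(
        parent == 0, 0, np.where((o1 == parent), 1, np.where(o2 == parent, 2, 0))
    )
    minS_pick = np.where(nearer_is_1, 1, 2)

    out = pd.DataFrame(
        {
            "event_id": event_id,
            "s_to_1_ns": s1,
            "s_to_2_ns": s2,
            "assigned_primary": assigned,
            "theta_deg": theta,
            "de_reco_kev": de_reco,
            "vertex_x_cm": vx,
            "vertex_y_cm": vy,
            "vertex_z_cm": vz,
            "e_true_p1_kev": take(e_true, i1),
            "e_true_p2_kev": take(e_true, i2),
            "e_true_scatter_kev": take(e_true, isc),
            "e_sm_p1_kev": take(e_sm, i1),
            "e_sm_p2_kev": take(e_sm, i2),
            "e_sm_scatter_kev": take(e_sm, isc),
            "origin_p1": o1,
            "origin_p2": o2,
            "origin_scatter": osc,
            "gen_scatter": take(generation, isc),
            "any_merged": take(merged, i1) | take(merged, i2) | take(merged, isc),
            "clean_topology": clean,
            "true_parent_slot": parent_slot,
            "min_s_pick": minS_pick,
        }
    )
    selected = out[keep].reset_index(drop=True)
    funnel["selected"] = len(selected)
    return selected, pd.DataFrame([funnel])


def _empty_selection():
    cols = [
        "event_id", "s_to_1_ns", "s_to_2_ns", "assigned_primary", "theta_deg",
        "de_reco_kev", "vertex_x_cm", "vertex_y_cm", "vertex_z_cm",
        "e_true_p1_kev", "e_true_p2_kev", "e_true_scatter_kev",
        "e_sm_p1_kev", "e_sm_p2_kev", "e_sm_scatter_kev",
        "origin_p1", "origin_p2", "origin_scatter",
        "gen_scatter", "any_merged",
        "clean_topology", "true_parent_slot", "min_s_pick",
    ]
    return pd.DataFrame({c: [] for c in cols})
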