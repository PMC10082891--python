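"""Synthetic hit-stream generator.

Each simulated decay emits two back-to-back 511 keV annihilation photons
from a point drawn inside the source extent, plus (by default) an isotropic
1274.6 keV prompt photon.  Photons undergo Compton-only transport through
the barrel; every interaction deposits energy in one strip.  Digitization
smears time, axial position and energy, applies the registration threshold
to the smeared energy, and — in ``detector`` mode — additionally keeps each
hit with a probability given by the injected registration-efficiency curve
evaluated at the true deposit.

``ideal`` and ``detector`` mode share every random number except the
thinning decision itself (common random numbers), so for a common seed the
detector hit table is an exact thinned subset of the ideal table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import compton
from .constants import (
    C_CM_PER_NS,
    E_ANNIH_KEV,
    E_PROMPT_KEV,
    ENERGY_RES_COEFF,
    PVT_ELECTRON_DENSITY,
    SIGMA_T_NS,
    SIGMA_Z_CM,
    THRESHOLD_KEV,
)
from .geometry import ScannerGeometry, ray_strip_intersection
from ._kernel import _transport_events

__all__ = [
    "SourceConfig",
    "SmearingModel",
    "RegistrationModel",
    "TransportConfig",
    "generate_annihilation_event",
    "transport_photon",
    "digitize_hit",
    "pmt_times",
    "simulate_dataset",
    "simulate_both",
    "HIT_COLUMNS",
]

# documented header of the columnar hit table; columns prefixed ``true_``
# plus ``truth_origin``/``truth_generation``/``merged`` are ground truth
HIT_COLUMNS = [
    "event_id",
    "strip_id",
    "time_ns",
    "z_cm",
    "x_cm",
    "y_cm",
    "e_true_kev",
    "e_smeared_kev",
    "truth_origin",
    "truth_generation",
    "merged",
    "true_x_cm",
    "true_y_cm",
    "true_z_cm",
    "true_time_ns",
]

# spacing between successive decays on the global clock; comfortably larger
# than the 200 ns coincidence window, so events never merge
EVENT_SPACING_NS = 1000.0


@dataclass
class SourceConfig:
    position: tuple = (0.0, 0.0, 0.0)
    extent_radius_cm: float = 1.58  # half the 3.16 cm chamber diameter
    n_events: int = 10000
    prompt_enabled: bool = True
    prompt_energy_kev: float = E_PROMPT_KEV
    # back-to-back pairs whose axis satisfies |cos(polar)| > this bound can
    # never reach a strip (|z| <= 25 cm at radius >= 42.15 cm even from the
    # edge of the source extent), so emission may be restricted to the
    # geometrically live cone without changing any registered distribution;
    # 1.0 reproduces fully isotropic emission
    pair_cos_max: float = 1.0

    def __post_init__(self):
        if self.extent_radius_cm < 0:
            raise ValueError("source extent must be non-negative")
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        if not 0 < self.pair_cos_max <= 1.0:
            raise ValueError("pair_cos_max must be in (0, 1]")


@dataclass
class SmearingModel:
    sigma_t_ns: float = SIGMA_T_NS
    sigma_z_cm: float = SIGMA_Z_CM
    energy_res_coeff: float = ENERGY_RES_COEFF  # sigma(E)/E = coeff/sqrt(E[MeV])

    def __post_init__(self):
        if min(self.sigma_t_ns, self.sigma_z_cm, self.energy_res_coeff) < 0:
            raise ValueError("resolutions must be non-negative; zero disables smearing")

    def energy_sigma(self, e_kev):
        e_kev = np.asarray(e_kev, dtype=float)
        if self.energy_res_coeff == 0:
            return np.zeros_like(e_kev)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = self.energy_res_coeff / np.sqrt(e_kev / 1000.0) * e_kev
        return np.where(e_kev > 0, s, 0.0)


@dataclass
class RegistrationModel:
    threshold_kev: float = THRESHOLD_KEV
    mode: str = "ideal"  # "ideal" | "detector"
    thinning_curve: Optional[Callable] = None  # true deposit [keV] -> prob in [0,1]

    def __post_init__(self):
        if self.mode not in ("ideal", "detector"):
            raise ValueError("mode must be 'ideal' or 'detector'")
        if self.mode == "detector" and self.thinning_curve is None:
            raise ValueError("detector mode requires a thinning curve")


@dataclass
class TransportConfig:
    """Attenuation model of the plastic.

    ``mu_mode='kn'`` (default) derives the energy-dependent linear
    attenuation coefficient from the total Klein-Nishina cross-section and
    the electron density of polyvinyltoluene — self-consistent with the
    Compton-only transport (mu(511 keV) ~ 0.0956 /cm).  ``mu_mode='const'``
    uses ``mu_const`` at every energy.
    """

    mu_mode: str = "kn"
    mu_const: float = 0.096
    electron_density: float = PVT_ELECTRON_DENSITY
    max_interactions: int = 3

    def __post_init__(self):
        if self.mu_mode not in ("kn", "const"):
            raise ValueError("mu_mode must be 'kn' or 'const'")
        if self.mu_const <= 0 or self.electron_density <= 0:
            raise ValueError("attenuation parameters must be positive")

    def mu(self, e_kev):
        if self.mu_mode == "const":
            return self.mu_const * np.ones_like(np.asarray(e_kev, dtype=float))
        return self.electron_density * compton.kn_total_cross_section(e_kev)


def generate_annihilation_event(source: SourceConfig, rng):
    """One decay: list of (energy keV, origin, unit direction, emission time ns).

    Two exactly antiparallel 511 keV photons plus an optional independent
    isotropic prompt photon, all from a common origin inside the extent.
    """
    if source.extent_radius_cm > 0:
        while True:
            p = rng.uniform(-source.extent_radius_cm, source.extent_radius_cm, 3)
            if p @ p <= source.extent_radius_cm**2:
                break
    else:
        p = np.zeros(3)
    origin = np.asarray(source.position, dtype=float) + p
    c = rng.uniform(-source.pair_cos_max, source.pair_cos_max)
    ph = rng.uniform(0.0, 2.0 * np.pi)
    s = np.sqrt(1.0 - c * c)
    d = np.array([s * np.cos(ph), s * np.sin(ph), c])
    photons = [
        (E_ANNIH_KEV, origin.copy(), d, 0.0),
        (E_ANNIH_KEV, origin.copy(), -d, 0.0),
    ]
    if source.prompt_enabled:
        c2 = rng.uniform(-1.0, 1.0)
        p2 = rng.uniform(0.0, 2.0 * np.pi)
        s2 = np.sqrt(1.0 - c2 * c2)
        d2 = np.array([s2 * np.cos(p2), s2 * np.sin(p2), c2])
        photons.append((source.prompt_energy_kev, origin.copy(), d2, 0.0))
    return photons


def transport_photon(photon, geometry: ScannerGeometry, transport: TransportConfig, rng,
                     max_interactions=None):
    """Reference (pure-Python) Compton random walk of a single photon.

    Returns a list of interaction dicts with keys ``strip_id``, ``point``,
    ``time_ns``, ``deposit_kev``, ``scattered_energy_kev``.  The compiled
    kernel used by :func:`simulate_dataset` implements the same walk; this
    routine exists for unit-level validation and small studies.
    """
    e, pos, d, t0 = photon
    pos = np.asarray(pos, dtype=float)
    d = np.asarray(d, dtype=float) / np.linalg.norm(d)
    cap = max_interactions if max_interactions is not None else transport.max_interactions
    interactions = []
    t_cum = float(t0)
    for _ in range(cap):
        chords = []
        for strip in geometry.strips():
            hit = ray_strip_intersection(pos, d, strip, geometry)
            if hit is not None:
                entry, _, length = hit
                s_in = float((entry - pos) @ d)
                chords.append((s_in, length, strip.strip_id))
        chords.sort()
        mu = float(transport.mu(e))
        tau = -np.log(1.0 - rng.random())
        s_int = None
        sid = None
        for s_in, length, strip_id in chords:
            lam = mu * length
            if tau <= lam:
                s_int = s_in + tau / mu
                sid = strip_id
                break
            tau -= lam
        if s_int is None:
            break
        point = pos + s_int * d
        t_cum += s_int / C_CM_PER_NS
        theta = compton.sample_scatter_angle(e, rng)
        de = compton.deposited_energy(e, theta)
        interactions.append(
            {
                "strip_id": sid,
                "point": point,
                "time_ns": t_cum,
                "deposit_kev": de,
                "scattered_energy_kev": e - de,
            }
        )
        e = e - de
        if e < 2.0:
            break
        # new direction: theta around the flight axis, uniform azimuth
        h = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(d, h)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        psi = rng.uniform(0.0, 2.0 * np.pi)
        th = np.radians(theta)
        d = np.cos(th) * d + np.sin(th) * (np.cos(psi) * e1 + np.sin(psi) * e2)
        d /= np.linalg.norm(d)
        pos = point
    return interactions


def digitize_hit(interaction, smearing: SmearingModel, registration: RegistrationModel, rng):
    """Smear one interaction and apply threshold (and thinning in detector mode).

    ``interaction`` is a mapping with ``time_ns``, ``z_cm``, ``deposit_kev``.
    Order: smear -> threshold -> thin.  Returns the digitized dict or None.
    """
    t = interaction["time_ns"] + (rng.normal(0.0, smearing.sigma_t_ns) if smearing.sigma_t_ns else 0.0)
    z = interaction["z_cm"] + (rng.normal(0.0, smearing.sigma_z_cm) if smearing.sigma_z_cm else 0.0)
    e_true = interaction["deposit_kev"]
    sig_e = float(smearing.energy_sigma(e_true))
    e_sm = e_true + (rng.normal(0.0, sig_e) if sig_e else 0.0)
    if e_sm < registration.threshold_kev:
        return None
    if registration.mode == "detector":
        if rng.random() >= float(registration.thinning_curve(e_true)):
            return None
    out = dict(interaction)
    out.update(time_ns=t, z_cm=z, e_smeared_kev=e_sm)
    return out


def pmt_times(hit, geometry: ScannerGeometry):
    """Readout times at the two strip ends for a hit (time ns, z cm).

    Conventions: mean of the two times = hit time + L/(2 v_eff), and
    (t_right - t_left) * v_eff / 2 = z.  The inverse mapping is exact.
    """
    t = hit["time_ns"]
    z = hit["z_cm"]
    v = geometry.v_eff_cm_per_ns
    half = geometry.strip_length_cm / (2.0 * v)
    return t + half - z / v, t + half + z / v


def hit_from_pmt_times(t_left, t_right, geometry: ScannerGeometry):
    v = geometry.v_eff_cm_per_ns
    t = 0.5 * (t_left + t_right) - geometry.strip_length_cm / (2.0 * v)
    z = 0.5 * (t_right - t_left) * v
    return t, z


# ----------------------------------------------------------------------
# dataset-level generation


def _child_seed(seed, *tags):
    """Deterministic sub-seed below 2^31 derived from the master seed."""
    mask = (1 << 64) - 1
    h = (int(seed) * 2654435761) & mask
    for t in tags:
        h = ((h ^ (int(t) * 40503 & mask)) * 2654435761) & mask
    return int(h % (2**31 - 1)) + 1


def _run_kernel(geometry, source, transport, seed, n_events):
    n_layers = len(geometry.layers)
    layer_radius = np.array([l.radius_cm for l in geometry.layers])
    layer_nstrips = np.array([l.n_strips for l in geometry.layers], dtype=np.int64)
    layer_pitch = np.radians(np.array([l.pitch_deg for l in geometry.layers]))
    layer_offset = np.radians(np.array([l.offset_deg for l in geometry.layers]))
    layer_base = np.concatenate([[0], np.cumsum(layer_nstrips)[:-1]]).astype(np.int64)
    phi = np.radians(geometry.strip_azimuth_deg)
    strip_cos = np.cos(phi)
    strip_sin = np.sin(phi)
    cap = max(4096, int(n_events * 0.7))
    while True:
        ev = np.empty(cap, dtype=np.int64)
        st = np.empty(cap, dtype=np.int64)
        tt = np.empty(cap, dtype=np.float64)
        zz = np.empty(cap, dtype=np.float64)
        xx = np.empty(cap, dtype=np.float64)
        yy = np.empty(cap, dtype=np.float64)
        ee = np.empty(cap, dtype=np.float64)
        og = np.empty(cap, dtype=np.int64)
        gg = np.empty(cap, dtype=np.int64)
        src = np.empty((n_events, 3), dtype=np.float64)
        n = _transport_events(
            n_events,
            seed,
            layer_radius,
            layer_nstrips,
            layer_pitch,
            layer_offset,
            layer_base,
            strip_cos,
            strip_sin,
            geometry.strip_thickness_cm / 2.0,
            geometry.strip_width_cm / 2.0,
            geometry.strip_length_cm / 2.0,
            source.extent_radius_cm,
            source.prompt_enabled,
            source.prompt_energy_kev,
            source.pair_cos_max,
            0 if transport.mu_mode == "const" else 1,
            transport.mu_const,
            transport.electron_density,
            transport.max_interactions,
            ev,
            st,
            tt,
            zz,
            xx,
            yy,
            ee,
            og,
            gg,
            src,
        )
        if n >= 0:
            break
        cap *= 2
    return (
        ev[:n].copy(),
        st[:n].copy(),
        tt[:n].copy(),
        zz[:n].copy(),
        xx[:n].copy(),
        yy[:n].copy(),
        ee[:n].copy(),
        og[:n].copy(),
        gg[:n].copy(),
        src,
    )


def _merge_same_strip(ev, st, tt, zz, xx, yy, ee, og, gg):
    """Sum deposits of multiple interactions in one strip within one event.

    A strip produces a single signal per event, so coincident deposits pile
    up.  The merged hit keeps the earliest time and the coordinates, origin
    and generation of the largest deposit; ``merged`` flags pile-ups.
    """
    key = ev * np.int64(1 << 20) + st
    order = np.lexsort((-ee, key))
    key_s = key[order]
    uniq, first_idx, counts = np.unique(key_s, return_index=True, return_counts=True)
    if len(uniq) == len(key):
        return ev, st, tt, zz, xx, yy, ee, og, gg, np.zeros(len(ev), dtype=bool)
    grp = np.searchsorted(uniq, key_s)
    e_sum = np.zeros(len(uniq))
    np.add.at(e_sum, grp, ee[order])
    t_min = np.full(len(uniq), np.inf)
    np.minimum.at(t_min, grp, tt[order])
    lead = order[first_idx]  # largest deposit in each group
    return (
        ev[lead],
        st[lead],
        t_min,
        zz[lead],
        xx[lead],
        yy[lead],
        e_sum,
        og[lead],
        gg[lead],
        counts > 1,
    )


def simulate_both(geometry, source, smearing, registration_ideal, thinning_curve,
                  transport=None, seed=0):
    """Run one transport pass and digitize into ideal and detector tables.

    Returns ``(hits_ideal, hits_detector, truth)``; the detector table is the
    thinned subset of the ideal one (common random numbers).
    """
    transport = transport or TransportConfig()
    raw = _run_kernel(geometry, source, transport, _child_seed(seed, 1), source.n_events)
    ev, st, tt, zz, xx, yy, ee, og, gg, merged = _merge_same_strip(*raw[:9])
    src = raw[9]

    rng_dig = np.random.default_rng(_child_seed(seed, 2))
    n = len(ev)
    t_sm = tt + ev * EVENT_SPACING_NS
    if smearing.sigma_t_ns:
        t_sm = t_sm + rng_dig.normal(0.0, smearing.sigma_t_ns, n)
    z_sm = zz.copy()
    if smearing.sigma_z_cm:
        z_sm = z_sm + rng_dig.normal(0.0, smearing.sigma_z_cm, n)
        half_l = geometry.strip_length_cm / 2.0
        z_sm = np.clip(z_sm, -half_l, half_l)
    e_sm = ee.copy()
    if smearing.energy_res_coeff:
        e_sm = e_sm + rng_dig.normal(0.0, 1.0, n) * smearing.energy_sigma(ee)
    keep = e_sm >= registration_ideal.threshold_kev

    rng_thin = np.random.default_rng(_child_seed(seed, 3))
    thin_u = rng_thin.random(n)

    phi = np.radians(geometry.strip_azimuth_deg[st])
    r = geometry.strip_radius_cm[st]
    frame = pd.DataFrame(
        {
            "event_id": ev,
            "strip_id": st,
            "time_ns": t_sm,
            "z_cm": z_sm,
            "x_cm": r * np.cos(phi),
            "y_cm": r * np.sin(phi),
            "e_true_kev": ee,
            "e_smeared_kev": e_sm,
            "truth_origin": og,
            "truth_generation": gg,
            "merged": merged,
            "true_x_cm": xx,
            "true_y_cm": yy,
            "true_z_cm": zz,
            "true_time_ns": tt + ev * EVENT_SPACING_NS,
            "thin_u": thin_u,
        }
    )
    ideal = frame[keep].sort_values(["time_ns", "event_id"], kind="mergesort").reset_index(drop=True)
    if thinning_curve is not None:
        probs = np.clip(np.asarray(thinning_curve(ideal["e_true_kev"].to_numpy())), 0.0, 1.0)
        detector = ideal[ideal["thin_u"].to_numpy() < probs].reset_index(drop=True)
    else:
        detector = ideal.copy()
    truth = pd.DataFrame(
        {
            "event_id": np.arange(source.n_events, dtype=np.int64),
            "src_x_cm": src[:, 0],
            "src_y_cm": src[:, 1],
            "src_z_cm": src[:, 2],
        }
    )
    return ideal.drop(columns="thin_u"), detector.drop(columns="thin_u"), truth


def simulate_dataset(geometry, source, smearing, registration, transport=None, seed=0):
    """Columnar (hit table, truth table) for one mode, time-sorted, reproducible.

    ``registration.mode`` selects the stream; both modes reuse identical
    upstream randomness for a given seed, so the detector-mode table is the
    Bernoulli-thinned subset of the ideal-mode one.
    """
    curve = registration.thinning_curve if registration.mode == "detector" else None
    ideal, detector, truth = simulate_both(
        geometry, source, smearing, registration, curve, transport=transport, seed=seed
    )
    return (detector if registration.mode == "detector" else ideal), truth
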