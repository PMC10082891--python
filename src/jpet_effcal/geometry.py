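"""Three-layer scintillator-barrel geometry.

Coordinate frame: right-handed, ``z`` along the scanner axis, origin at the
barrel centre, azimuth measured from +x.  Strips are axis-aligned rectangular
boxes of dimensions thickness (radial) x width (tangential) x length (axial),
centred on their layer cylinder: a strip at azimuth ``phi`` in a layer of
radius ``r`` occupies radii ``[r - t/2, r + t/2]``, so hit positions snapped
to the strip axis sit exactly at the layer radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "LayerSpec",
    "Strip",
    "ScannerGeometry",
    "build_scanner",
    "default_layout",
    "load_layout",
    "ray_strip_intersection",
    "hit_global_position",
]


class ConfigurationError(ValueError):
    """Raised for ill-formed scanner layouts."""


@dataclass(frozen=True)
class LayerSpec:
    radius_cm: float
    n_strips: int
    pitch_deg: float
    offset_deg: float = 0.0


@dataclass(frozen=True)
class Strip:
    strip_id: int
    layer_index: int
    center_azimuth_deg: float
    center_radius_cm: float


def default_layout():
    """Layout of the 192-strip prototype: 48 + 48 + 96 strips in 3 layers.

    Layer radii are half the published diameters (85, 93.5, 115 cm); strips
    are 50 x 1.9 x 0.7 cm.  Inter-layer azimuthal offsets default to zero
    (the real device staggers layers by an unpublished amount).
    """
    return {
        "layers": [
            {"radius_cm": 42.5, "n_strips": 48, "pitch_deg": 7.5, "offset_deg": 0.0},
            {"radius_cm": 46.75, "n_strips": 48, "pitch_deg": 7.5, "offset_deg": 0.0},
            {"radius_cm": 57.5, "n_strips": 96, "pitch_deg": 3.75, "offset_deg": 0.0},
        ],
        "strip": {"length_cm": 50.0, "width_cm": 1.9, "thickness_cm": 0.7},
        "v_eff_cm_per_ns": 12.0,
    }


def load_layout(path):
    """Read a layout config (YAML or JSON — YAML is a superset) from ``path``."""
    with open(path) as fh:
        return yaml.safe_load(fh)


@dataclass
class ScannerGeometry:
    layers: list
    strip_length_cm: float
    strip_width_cm: float
    strip_thickness_cm: float
    v_eff_cm_per_ns: float = 12.0
    # derived flat per-strip arrays
    strip_layer: np.ndarray = field(init=False, repr=False)
    strip_azimuth_deg: np.ndarray = field(init=False, repr=False)
    strip_radius_cm: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if min(self.strip_length_cm, self.strip_width_cm, self.strip_thickness_cm) <= 0:
            raise ConfigurationError("strip dimensions must be positive")
        if self.v_eff_cm_per_ns <= 0:
            raise ConfigurationError("effective light speed must be positive")
        layer_idx, azim, radii = [], [], []
        for li, layer in enumerate(self.layers):
            if layer.radius_cm <= 0 or layer.n_strips <= 0 or layer.pitch_deg <= 0:
                raise ConfigurationError("layer radius, strip count and pitch must be positive")
            # tangential footprint of a box: the inner corners subtend the
            # widest angle as seen from the axis
            inner_r = layer.radius_cm - self.strip_thickness_cm / 2.0
            if inner_r <= 0:
                raise ConfigurationError("strip thickness exceeds layer radius")
            half_span = np.degrees(np.arctan2(self.strip_width_cm / 2.0, inner_r))
            if layer.pitch_deg < 2.0 * half_span - 1e-12:
                raise ConfigurationError(
                    f"strips in layer {li} overlap: pitch {layer.pitch_deg} deg "
                    f"< footprint {2 * half_span:.3f} deg"
                )
            for k in range(layer.n_strips):
                layer_idx.append(li)
                azim.append((layer.offset_deg + k * layer.pitch_deg) % 360.0)
                radii.append(layer.radius_cm)
        self.strip_layer = np.array(layer_idx, dtype=np.int64)
        self.strip_azimuth_deg = np.array(azim, dtype=float)
        self.strip_radius_cm = np.array(radii, dtype=float)

    @property
    def n_strips(self):
        return len(self.strip_layer)

    def strip(self, strip_id):
        if not 0 <= strip_id < self.n_strips:
            raise IndexError(f"strip_id {strip_id} out of range")
        return Strip(
            strip_id=int(strip_id),
            layer_index=int(self.strip_layer[strip_id]),
            center_azimuth_deg=float(self.strip_azimuth_deg[strip_id]),
            center_radius_cm=float(self.strip_radius_cm[strip_id]),
        )

    def strips(self):
        return [self.strip(i) for i in range(self.n_strips)]


def build_scanner(layout_config=None):
    """Construct a :class:`ScannerGeometry` from a layout dict (default: 192-strip barrel)."""
    cfg = layout_config if layout_config is not None else default_layout()
    layers = [
        LayerSpec(
            radius_cm=float(l["radius_cm"]),
            n_strips=int(l["n_strips"]),
            pitch_deg=float(l["pitch_deg"]),
            offset_deg=float(l.get("offset_deg", 0.0)),
        )
        for l in cfg["layers"]
    ]
    strip = cfg["strip"]
    return ScannerGeometry(
        layers=layers,
        strip_length_cm=float(strip["length_cm"]),
        strip_width_cm=float(strip["width_cm"]),
        strip_thickness_cm=float(strip["thickness_cm"]),
        v_eff_cm_per_ns=float(cfg.get("v_eff_cm_per_ns", 12.0)),
    )


def ray_strip_intersection(origin, direction, strip, geometry):
    """Chord of a ray inside one strip box, or ``None``.

    Returns ``(entry_point, exit_point, path_length_cm)``.  If the origin lies
    inside the strip the chord starts at the origin.  ``direction`` must be a
    unit vector.
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(d) - 1.0) > 1e-9:
        raise ValueError("direction must be normalized")
    phi = np.radians(strip.center_azimuth_deg)
    cp, sp = np.cos(phi), np.sin(phi)
    # rotate into the strip frame: x' radial, y' tangential
    ox = o[0] * cp + o[1] * sp
    oy = -o[0] * sp + o[1] * cp
    dx = d[0] * cp + d[1] * sp
    dy = -d[0] * sp + d[1] * cp
    r = strip.center_radius_cm
    half = (
        geometry.strip_thickness_cm / 2.0,
        geometry.strip_width_cm / 2.0,
        geometry.strip_length_cm / 2.0,
    )
    lo = (r - half[0], -half[1], -half[2])
    hi = (r + half[0], half[1], half[2])
    t_near, t_far = -np.inf, np.inf
    for oo, dd, l, h in ((ox, dx, lo[0], hi[0]), (oy, dy, lo[1], hi[1]), (o[2], d[2], lo[2], hi[2])):
        if abs(dd) < 1e-300:
            if oo < l or oo > h:
                return None
            continue
        t1, t2 = (l - oo) / dd, (h - oo) / dd
        if t1 > t2:
            t1, t2 = t2, t1
        t_near = max(t_near, t1)
        t_far = min(t_far, t2)
    t_entry = max(t_near, 0.0)
    if t_far <= t_entry + 1e-12:
        return None
    entry = o + t_entry * d
    exit_ = o + t_far * d
    return entry, exit_, float(t_far - t_entry)


def hit_global_position(strip, z_local, geometry):
    """Global point on the strip centre axis displaced by ``z_local`` [cm]."""
    if abs(z_local) > geometry.strip_length_cm / 2.0 + 1e-12:
        raise ValueError("z_local outside the strip")
    phi = np.radians(strip.center_azimuth_deg)
    r = strip.center_radius_cm
    return np.array([r * np.cos(phi), r * np.sin(phi), float(z_local)])
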