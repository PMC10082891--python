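"""Compton energy-transfer kinematics and Klein-Nishina sampling.

A photon of energy ``E_inc`` scattering off a quasi-free electron through an
angle ``theta`` transfers

    dE = E_inc * [1 - 1 / (1 + (E_inc / 511 keV) * (1 - cos theta))]

to the electron; the scintillator registers ``dE``.  The maximum transfer
(``theta`` = 180 deg) is the Compton edge.  The angular distribution of the
scatter follows the unpolarized Klein-Nishina differential cross-section,
which, pushed through the dE <-> theta change of variables, yields the
probability density ``f(dE)`` of energy depositions for a photon that
interacted once.  Everything in this module is analytic except the pdf
normalization (adaptive quadrature) and the inverse-CDF sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .constants import MEC2_KEV, RE2_CM2

__all__ = [
    "deposited_energy",
    "scattering_angle_from_deposit",
    "compton_edge",
    "klein_nishina_dcs",
    "kn_total_cross_section",
    "DepositionPDF",
    "energy_deposit_pdf",
    "sample_scatter_angle",
]


def compton_edge(e_inc):
    """Maximum single-scatter energy transfer [keV] for incident ``e_inc`` [keV].

    Equals ``deposited_energy(e_inc, 180)`` = 2 E^2 / (m_e c^2 + 2 E).
    """
    e_inc = np.asarray(e_inc, dtype=float)
    if np.any(e_inc < 0):
        raise ValueError("incident energy must be non-negative")
    out = 2.0 * e_inc * e_inc / (MEC2_KEV + 2.0 * e_inc)
    return float(out) if out.ndim == 0 else out


def deposited_energy(e_inc, theta_deg):
    """Energy [keV] transferred to the electron at scattering angle ``theta_deg``."""
    e_inc = np.asarray(e_inc, dtype=float)
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(e_inc <= 0):
        raise ValueError("incident energy must be positive")
    if np.any((theta < 0.0) | (theta > 180.0)):
        raise ValueError("scattering angle must lie in [0, 180] degrees")
    p = 1.0 / (1.0 + (e_inc / MEC2_KEV) * (1.0 - np.cos(np.radians(theta))))
    out = e_inc * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def scattering_angle_from_deposit(e_inc, delta_e):
    """Invert the energy-transfer relation: angle [deg] producing ``delta_e`` [keV]."""
    e_inc = np.asarray(e_inc, dtype=float)
    delta_e = np.asarray(delta_e, dtype=float)
    edge = 2.0 * e_inc * e_inc / (MEC2_KEV + 2.0 * e_inc)
    if np.any(delta_e < 0) or np.any(delta_e > edge * (1.0 + 1e-12)):
        raise ValueError("deposit outside [0, compton_edge]")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - delta_e / e_inc
        cos_t = 1.0 - (1.0 / p - 1.0) * (MEC2_KEV / e_inc)
    out = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def klein_nishina_dcs(e_inc, theta_deg):
    """Relative unpolarized Klein-Nishina d(sigma)/d(Omega) at ``theta_deg``.

    Proportional to P^2 (P + 1/P - sin^2 theta) with
    P = 1 / (1 + (E/511)(1 - cos theta)); the caller normalizes.
    """
    e_inc = np.asarray(e_inc, dtype=float)
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(e_inc <= 0):
        raise ValueError("incident energy must be positive")
    if np.any((theta < 0.0) | (theta > 180.0)):
        raise ValueError("scattering angle must lie in [0, 180] degrees")
    c = np.cos(np.radians(theta))
    p = 1.0 / (1.0 + (e_inc / MEC2_KEV) * (1.0 - c))
    out = p * p * (p + 1.0 / p - (1.0 - c * c))
    return float(out) if out.ndim == 0 else out


def kn_total_cross_section(e_inc_kev):
    """Total Klein-Nishina cross-section per electron [cm^2]."""
    a = np.asarray(e_inc_kev, dtype=float) / MEC2_KEV
    t1 = (1.0 + a) / (a * a) * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - np.log1p(2.0 * a) / a)
    t2 = np.log1p(2.0 * a) / (2.0 * a)
    t3 = (1.0 + 3.0 * a) / (1.0 + 2.0 * a) ** 2
    out = 2.0 * np.pi * RE2_CM2 * (t1 + t2 - t3)
    return float(out) if out.ndim == 0 else out


def _deposit_density_raw(e_inc, delta_e):
    """Unnormalized d(sigma)/d(dE).

    With P = 1 - dE/E and cos(theta) = 1 - (1/P - 1) * 511/E, the Jacobian
    d(dE)/d(cos theta) = (E^2/511) P^2 cancels the P^2 prefactor of the
    cross-section, leaving (P + 1/P - sin^2 theta) / (E^2/511).
    """
    delta_e = np.asarray(delta_e, dtype=float)
    p = 1.0 - delta_e / e_inc
    c = 1.0 - (1.0 / p - 1.0) * (MEC2_KEV / e_inc)
    s2 = 1.0 - c * c
    return (p + 1.0 / p - s2) / (e_inc * e_inc / MEC2_KEV)


@dataclass
class DepositionPDF:
    """Normalized probability density of single-scatter energy deposits.

    Attributes
    ----------
    e_inc : incident photon energy [keV]
    delta_e_max : Compton edge [keV]; support is [0, delta_e_max]
    norm : normalization constant dividing the raw density
    """

    e_inc: float
    delta_e_max: float = field(init=False)
    norm: float = field(init=False)

    def __post_init__(self):
        if self.e_inc <= 0:
            raise ValueError("incident energy must be positive")
        self.delta_e_max = compton_edge(self.e_inc)
        self.norm, _ = quad(
            lambda d: _deposit_density_raw(self.e_inc, d),
            0.0,
            self.delta_e_max,
            epsabs=1e-10,
            limit=300,
        )

    @property
    def support(self):
        return (0.0, self.delta_e_max)

    def pdf(self, delta_e):
        """Density [1/keV]; zero outside the kinematic support."""
        delta_e = np.asarray(delta_e, dtype=float)
        inside = (delta_e >= 0.0) & (delta_e <= self.delta_e_max)
        out = np.zeros_like(delta_e, dtype=float)
        d = np.where(inside, delta_e, 0.0)
        out = np.where(inside, _deposit_density_raw(self.e_inc, d) / self.norm, 0.0)
        return float(out) if out.ndim == 0 else out

    def cdf(self, delta_e):
        delta_e = float(np.clip(delta_e, 0.0, self.delta_e_max))
        val, _ = quad(self.pdf, 0.0, delta_e, epsabs=1e-9, limit=300)
        return min(max(val, 0.0), 1.0)

    def grid_cdf(self, n=4097):
        """(deposit grid, CDF values) via trapezoidal accumulation."""
        xs = np.linspace(0.0, self.delta_e_max, n)
        ys = self.pdf(xs)
        c = np.concatenate([[0.0], np.cumsum(0.5 * (ys[1:] + ys[:-1]) * np.diff(xs))])
        return xs, c / c[-1]

    def as_table(self, n=351):
        """Two-column array (deposit keV, density per keV) for export."""
        xs = np.linspace(0.0, self.delta_e_max, n)
        return np.column_stack([xs, self.pdf(xs)])


def energy_deposit_pdf(e_inc):
    """Normalized deposition density for incident energy ``e_inc`` [keV]."""
    return DepositionPDF(float(e_inc))


def sample_scatter_angle(e_inc, rng, size=None, _grid_n=4096):
    """Sample scattering angles [deg] with density ~ KN(theta) sin(theta).

    Inverse-CDF sampling on a precomputed deposit grid: deposits are drawn
    from ``f(dE)`` and mapped back through the kinematic relation, which is
    equivalent to sampling theta with the solid-angle-weighted KN density.
    """
    pdf = energy_deposit_pdf(e_inc)
    xs, cdf = pdf.grid_cdf(_grid_n + 1)
    u = rng.random(size if size is not None else 1)
    deposits = np.interp(u, cdf, xs)
    theta = scattering_angle_from_deposit(e_inc, deposits)
    if size is None:
        return float(theta[0])
    return theta
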