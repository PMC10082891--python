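"""Intrinsic efficiency versus incident photon energy.

Given the registration efficiency xi(dE) measured against energy deposition,
the intrinsic efficiency of the scanner for a photon of incident energy E —
the probability that a photon which interacted is actually registered — is
the Klein-Nishina-weighted average

    Eff(E) = integral_0^{dE_max(E)} f(dE; E) * xi(dE) d(dE),

with f the normalized single-scatter deposition density.  The measured
curve only covers deposits above the 70 keV registration threshold, so the
behaviour of xi below threshold is an explicit extrapolation mode:

* ``"zero"`` (default) — deposits below threshold are never registered,
  which is what the hardware threshold enforces;
* ``"sigmoid"`` — evaluate the fitted sigmoid everywhere (it plateaus near
  the floor A0 at low deposit);
* ``"clamp_a0"`` — constant floor A0 below threshold.

The resulting curve over 150-511 keV is summarized by a Gaussian bell fit
p0 * exp(-(x - p1)^2 / (2 p2^2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import curve_fit

from .compton import energy_deposit_pdf
from .constants import THRESHOLD_KEV

__all__ = ["IntrinsicCurve", "BellFit", "intrinsic_efficiency", "intrinsic_curve", "fit_bell",
           "make_xi", "default_grid"]


def make_xi(curve, extrapolation="zero", threshold_kev=THRESHOLD_KEV, cap=1.0):
    """Wrap a registration curve with a below-threshold extrapolation mode.

    ``curve`` maps deposit [keV] -> efficiency; values are capped at ``cap``.
    """
    if extrapolation not in ("zero", "sigmoid", "clamp_a0"):
        raise ValueError("extrapolation must be 'zero', 'sigmoid' or 'clamp_a0'")

    def xi(de):
        de = np.asarray(de, dtype=float)
        val = np.minimum(np.asarray(curve(de), dtype=float), cap)
        if extrapolation == "zero":
            val = np.where(de < threshold_kev, 0.0, val)
        elif extrapolation == "clamp_a0":
            floor = float(np.minimum(curve(np.array(0.0)), cap))
            val = np.where(de < threshold_kev, floor, val)
        out = np.maximum(val, 0.0)
        return float(out) if out.ndim == 0 else out

    return xi


def intrinsic_efficiency(e_inc_kev, xi, tol=1e-8):
    """Klein-Nishina-weighted average of xi over the deposit spectrum at ``e_inc_kev``."""
    pdf = energy_deposit_pdf(e_inc_kev)
    lo, hi = pdf.support

    def integrand(de):
        v = float(xi(de))
        if not 0.0 <= v <= 1.0 + 1e-9:
            raise ValueError(f"xi({de}) = {v} outside [0, 1]")
        return pdf.pdf(de) * v

    val, _ = quad(integrand, lo, hi, epsabs=tol, limit=400)
    return float(val)


def default_grid(lo=150.0, hi=511.0, step=5.0):
    g = np.arange(lo, hi, step)
    if g[-1] < hi:
        g = np.append(g, hi)
    return g


@dataclass
class IntrinsicCurve:
    grid_kev: np.ndarray
    efficiency: np.ndarray
    extrapolation: str = "zero"
    tol: float = 1e-8

    def to_dict(self):
        return {
            "grid_kev": np.asarray(self.grid_kev).tolist(),
            "efficiency": np.asarray(self.efficiency).tolist(),
            "extrapolation": self.extrapolation,
        }


def intrinsic_curve(xi, grid_kev=None, extrapolation_label="zero", tol=1e-8):
    """Evaluate the intrinsic efficiency on an incident-energy grid."""
    grid = default_grid() if grid_kev is None else np.asarray(grid_kev, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("incident energies must be positive")
    eff = np.array([intrinsic_efficiency(e, xi, tol=tol) for e in grid])
    return IntrinsicCurve(grid, eff, extrapolation=extrapolation_label, tol=tol)


@dataclass
class BellFit:
    p0: float
    p1_kev: float
    p2_kev: float
    covariance: np.ndarray = field(default_factory=lambda: np.full((3, 3), np.nan))

    @property
    def params(self):
        return (self.p0, self.p1_kev, self.p2_kev)

    def __call__(self, e_kev):
        e = np.asarray(e_kev, dtype=float)
        out = self.p0 * np.exp(-((e - self.p1_kev) ** 2) / (2.0 * self.p2_kev**2))
        return float(out) if out.ndim == 0 else out

    def errors(self):
        return tuple(np.sqrt(np.diag(self.covariance)))

    def to_dict(self):
        return {
            "p0": self.p0,
            "p1_kev": self.p1_kev,
            "p2_kev": self.p2_kev,
            "covariance": np.asarray(self.covariance).tolist(),
        }


def fit_bell(curve: IntrinsicCurve, p0=None):
    """Unweighted Gaussian fit p0*exp(-(x-p1)^2/(2 p2^2)) to the curve."""
    x = np.asarray(curve.grid_kev, dtype=float)
    y = np.asarray(curve.efficiency, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 grid points for the bell fit")
    if p0 is None:
        p0 = (float(y.max()), float(x[np.argmax(y)]), float((x.max() - x.min()) / 2.0))

    def model(e, a, m, s):
        return a * np.exp(-((e - m) ** 2) / (2.0 * s * s))

    try:
        popt, pcov = curve_fit(model, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"bell fit failed to converge: {exc}") from exc
    return BellFit(p0=float(popt[0]), p1_kev=float(popt[1]), p2_kev=float(abs(popt[2])), covariance=pcov)
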