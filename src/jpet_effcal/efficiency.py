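"""Registration-efficiency extraction from deposit spectra.

The per-event scattering angles of the selected sample are converted to
energy deposits through Compton kinematics and histogrammed.  The ratio of
the "experimental" (thinned) spectrum to the reference (unthinned) spectrum,
after normalizing both at the most probable deposit (~270 keV), measures the
registration efficiency, which is parameterized by the Boltzmann sigmoid

    BSF(E) = A1 + (A0 - A1) / (1 + exp((E - A2) / A3))

rising from floor A0 to plateau A1 with midpoint A2 and slope scale A3.
(The decreasing-in-energy variant, with exponent (A2 - E)/A3, is retained
behind ``convention='decreasing'`` for compatibility.)

Because every selected event requires all three of its hits to survive the
registration response, the raw spectrum ratio estimates the *event-level*
acceptance — the product of the per-hit efficiencies of the binned primary,
the opposite primary and the scatter hit — and the deposit of the scatter
hit anticorrelates with the binned deposit.  :func:`recover_thinning_curve`
therefore fits the per-hit sigmoid through the event survival model
P(event) = prod_i BSF(dE_i), using the reference stream's per-event true
deposits, which deconvolves the accompanying-hit acceptance from the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

__all__ = [
    "DepositionHistogram",
    "BoltzmannSigmoid",
    "deposition_histogram",
    "normalize_at_mode",
    "efficiency_ratio",
    "fit_bsf",
    "bsf_eval",
    "recover_thinning_curve",
]

from .compton import deposited_energy
from .constants import E_ANNIH_KEV


@dataclass
class DepositionHistogram:
    edges_kev: np.ndarray
    counts: np.ndarray
    normalization: float = 1.0

    def __post_init__(self):
        self.edges_kev = np.asarray(self.edges_kev, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.edges_kev) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.edges_kev) - 1:
            raise ValueError("counts/edges length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative bin content")

    @property
    def centers_kev(self):
        return 0.5 * (self.edges_kev[:-1] + self.edges_kev[1:])

    def values(self):
        """Bin contents divided by the normalization factor."""
        return self.counts / self.normalization

    def bin_of(self, e_kev):
        i = int(np.searchsorted(self.edges_kev, e_kev, side="right") - 1)
        if not 0 <= i < len(self.counts):
            raise ValueError(f"{e_kev} keV outside the histogram range")
        return i


def default_edges(lo=0.0, hi=350.0, width=1.0):
    return np.arange(lo, hi + width / 2.0, width)


def deposition_histogram(thetas_deg, e_inc=E_ANNIH_KEV, edges=None):
    """Histogram of Compton deposits for per-event scattering angles."""
    thetas = np.asarray(thetas_deg, dtype=float)
    if thetas.size and (thetas.min() < 0 or thetas.max() > 180):
        raise ValueError("scattering angles must lie in [0, 180] deg")
    edges = default_edges() if edges is None else np.asarray(edges, dtype=float)
    deposits = deposited_energy(e_inc, thetas) if thetas.size else np.array([])
    counts, _ = np.histogram(deposits, bins=edges)
    return DepositionHistogram(edges, counts.astype(float))


def normalize_at_mode(hist: DepositionHistogram, reference_kev=270.0, use_global_mode=False):
    """Scale so the reference bin (default: the bin containing 270 keV, or
    the global mode) has unit content."""
    i = int(np.argmax(hist.counts)) if use_global_mode else hist.bin_of(reference_kev)
    ref = hist.counts[i]
    if ref <= 0:
        raise ValueError("empty reference bin")
    return DepositionHistogram(hist.edges_kev.copy(), hist.counts.copy(), normalization=float(ref))


def efficiency_ratio(exp_hist: DepositionHistogram, sim_hist: DepositionHistogram):
    """Bin-wise exp/sim ratio with Poisson-propagated errors.

    Returns an array of (bin centre keV, ratio, error); bins with empty
    simulated content are excluded.
    """
    if not np.array_equal(exp_hist.edges_kev, sim_hist.edges_kev):
        raise ValueError("histograms must share binning")
    ok = sim_hist.counts > 0
    ce = exp_hist.counts[ok]
    cs = sim_hist.counts[ok]
    ratio = (ce / exp_hist.normalization) / (cs / sim_hist.normalization)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt(np.where(ce > 0, 1.0 / ce, 0.0) + 1.0 / cs)
    err = np.where(ce > 0, ratio * rel, (1.0 / exp_hist.normalization) / (cs / sim_hist.normalization))
    return np.column_stack([exp_hist.centers_kev[ok], ratio, err])


def bsf_eval(params, e_dep_kev, convention="increasing"):
    """Evaluate the Boltzmann sigmoid at ``e_dep_kev``.

    ``params`` is (A0, A1, A2, A3) or a :class:`BoltzmannSigmoid`.
    """
    if isinstance(params, BoltzmannSigmoid):
        a0, a1, a2, a3 = params.a0, params.a1, params.a2_kev, params.a3_kev
    else:
        a0, a1, a2, a3 = params
    e = np.asarray(e_dep_kev, dtype=float)
    if convention == "increasing":
        arg = (e - a2) / a3
    elif convention == "decreasing":
        arg = (a2 - e) / a3
    else:
        raise ValueError("convention must be 'increasing' or 'decreasing'")
    # 1/(1+exp(arg)) = expit(-arg), overflow-safe for large |arg|
    out = a1 + (a0 - a1) * expit(-arg)
    return float(out) if out.ndim == 0 else out


@dataclass
class BoltzmannSigmoid:
    a0: float
    a1: float
    a2_kev: float
    a3_kev: float
    covariance: np.ndarray = field(default_factory=lambda: np.full((4, 4), np.nan))
    chi2: float = np.nan
    ndf: int = 0
    convention: str = "increasing"

    @property
    def params(self):
        return (self.a0, self.a1, self.a2_kev, self.a3_kev)

    def __call__(self, e_dep_kev):
        return bsf_eval(self.params, e_dep_kev, convention=self.convention)

    def errors(self):
        d = np.diag(self.covariance)
        with np.errstate(invalid="ignore"):
            return tuple(np.where(d >= 0, np.sqrt(np.abs(d)), np.nan))

    def band_3sigma(self, e_dep_kev):
        """First-order 3-sigma confidence band from the covariance."""
        e = np.atleast_1d(np.asarray(e_dep_kev, dtype=float))
        eps = 1e-6
        grads = []
        p = np.array(self.params)
        for k in range(4):
            dp = p.copy()
            dp[k] += eps * max(1.0, abs(p[k]))
            step = dp[k] - p[k]
            grads.append((bsf_eval(dp, e, self.convention) - bsf_eval(p, e, self.convention)) / step)
        g = np.stack(grads, axis=-1)
        var = np.einsum("...i,ij,...j->...", g, self.covariance, g)
        return 3.0 * np.sqrt(np.maximum(var, 0.0))

    def to_dict(self):
        return {
            "A0": self.a0,
            "A1": self.a1,
            "A2_kev": self.a2_kev,
            "A3_kev": self.a3_kev,
            "covariance": np.asarray(self.covariance).tolist(),
            "chi2": self.chi2,
            "ndf": self.ndf,
            "convention": self.convention,
        }


def fit_bsf(ratio_points, fit_range_kev=(70.0, 270.0), p0=None, convention="increasing"):
    """Weighted least-squares Boltzmann-sigmoid fit to ratio points.

    ``ratio_points`` is the (E, ratio, error) array from
    :func:`efficiency_ratio`.  Initial values default to data-driven
    estimates (floor = min, plateau = max, midpoint = centre of range).
    """
    pts = np.asarray(ratio_points, dtype=float)
    lo, hi = fit_range_kev
    sel = (pts[:, 0] >= lo) & (pts[:, 0] <= hi) & np.isfinite(pts[:, 2]) & (pts[:, 2] > 0)
    if sel.sum() < 10:
        raise ValueError("fewer than 10 usable points inside the fit range")
    x, y, s = pts[sel, 0], pts[sel, 1], pts[sel, 2]
    if p0 is None:
        p0 = (float(y.min()), float(y.max()), 0.5 * (lo + hi), 20.0)

    def model(e, a0, a1, a2, a3):
        return bsf_eval((a0, a1, a2, a3), e, convention=convention)

    try:
        popt, pcov = curve_fit(model, x, y, p0=p0, sigma=s, absolute_sigma=True, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"sigmoid fit failed to converge: {exc}") from exc
    resid = (y - model(x, *popt)) / s
    return BoltzmannSigmoid(
        a0=float(popt[0]),
        a1=float(popt[1]),
        a2_kev=float(popt[2]),
        a3_kev=float(popt[3]),
        covariance=pcov,
        chi2=float(resid @ resid),
        ndf=int(sel.sum() - 4),
        convention=convention,
    )


def fit_survival_model(
    deposits,
    survived,
    p0=(0.2, 1.0, 150.0, 20.0),
    bounds=((0.0, 1.0), (0.2, 1.2), (50.0, 400.0), (1.0, 200.0)),
):
    """Binomial maximum-likelihood fit of the per-hit sigmoid to event survival.

    ``deposits`` is an (n, 3) array of the true per-hit energy deposits of
    matched 3-hit coincidences from the reference stream; ``survived`` marks
    the events that appear intact in the thinned stream.  Each event
    survives with probability BSF(d1) * BSF(d2) * BSF(d3) regardless of its
    physical composition, so the likelihood is exact for any matched 3-hit
    population.
    """
    from scipy.optimize import minimize

    deposits = np.asarray(deposits, dtype=float)
    survived = np.asarray(survived, dtype=bool)
    if len(deposits) < 100:
        raise ValueError("too few reference events for the survival fit")
    eps = 1e-9

    def nll(params):
        p = np.clip(bsf_eval(tuple(params), deposits), eps, 1.0)
        surv_p = np.clip(p[:, 0] * p[:, 1] * p[:, 2], eps, 1.0 - eps)
        return -(
            np.log(surv_p[survived]).sum() + np.log1p(-surv_p[~survived]).sum()
        )

    res = minimize(nll, x0=np.asarray(p0, dtype=float), method="L-BFGS-B", bounds=bounds)
    if not res.success:
        raise RuntimeError(f"survival-model fit failed: {res.message}")
    cov = _numeric_covariance(nll, res.x)
    return BoltzmannSigmoid(
        a0=float(res.x[0]),
        a1=float(res.x[1]),
        a2_kev=float(res.x[2]),
        a3_kev=float(res.x[3]),
        covariance=cov,
        chi2=float(2.0 * res.fun),
        ndf=int(len(deposits) - 4),
    )


def recover_thinning_curve(selected_ideal, selected_detector, **kwargs):
    """Fit the per-hit registration sigmoid through the event survival model.

    For a common-seed pair of selected samples the detector stream is a
    Bernoulli subsample of the reference stream: a reference event whose
    three hits truly deposited (d1, d2, d3) appears in the detector stream
    iff all three hits survived thinning, i.e. with probability
    BSF(d1) * BSF(d2) * BSF(d3).  The parameters maximize the per-event
    binomial likelihood of the survival indicators (matched on event id).
    Unlike a direct sigmoid fit of the spectrum ratio, this deconvolves the
    acceptance of the two accompanying hits from the recovered curve.

    Requires globally unique event ids across the two tables.
    """
    ids_ideal = selected_ideal["event_id"].to_numpy()
    if len(np.unique(ids_ideal)) != len(ids_ideal):
        raise ValueError("event ids must be unique across the reference sample")
    survived = np.isin(ids_ideal, selected_detector["event_id"].to_numpy())
    deposits = selected_ideal[
        ["e_true_p1_kev", "e_true_p2_kev", "e_true_scatter_kev"]
    ].to_numpy()
    return fit_survival_model(deposits, survived, **kwargs)


def survival_sample_from_hits(ideal_hits, detector_hits, ctw_ns=200.0):
    """Matched 3-hit survival sample straight from common-seed hit tables.

    Returns ``(deposits, survived)``: for every 3-hit coincidence group of
    the reference stream, the true deposits of its three hits and whether
    the same event is still a 3-hit group in the thinned stream (it is iff
    all three hits survived thinning, since the thinned table is a subset).
    """
    from .selection import group_events

    gi = group_events(ideal_hits, ctw_ns)
    gd = group_events(detector_hits, ctw_ns)
    ev_i = ideal_hits["event_id"].to_numpy()
    e_i = ideal_hits["e_true_kev"].to_numpy()
    ids_ideal = np.array([ev_i[g[0]] for g in gi], dtype=np.int64)
    deposits = np.array([[e_i[g[0]], e_i[g[1]], e_i[g[2]]] for g in gi], dtype=float)
    ev_d = detector_hits["event_id"].to_numpy()
    ids_det = np.array([ev_d[g[0]] for g in gd], dtype=np.int64)
    survived = np.isin(ids_ideal, ids_det)
    return deposits, survived


def _numeric_covariance(nll, x, rel_step=1e-4):
    """Inverse of the central-difference Hessian of the negative log-likelihood."""
    n = len(x)
    h = np.maximum(np.abs(x), 1.0) * rel_step
    hess = np.empty((n, n))
    f0 = nll(x)
    for i in range(n):
        for j in range(i, n):
            xi = x.copy()
            if i == j:
                xi[i] += h[i]
                fp = nll(xi)
                xi[i] -= 2 * h[i]
                fm = nll(xi)
                hess[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
            else:
                xpp = x.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                hess[i, j] = hess[j, i] = (
                    nll(xpp) - nll(xpm) - nll(xmp) + nll(xmm)
                ) / (4 * h[i] * h[j])
    try:
        return np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return np.full((n, n), np.nan)
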