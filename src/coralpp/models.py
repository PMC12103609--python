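"""Candidate point-process models and their fitting.

Four generative models compete to explain each observed pattern:

* **CSR** — homogeneous Poisson: no structure.
* **HP** — heterogeneous Poisson with piecewise-constant intensity over the
  three substrate categories: abiotic (habitat) structure only.
* **TC** — Thomas cluster process: Poisson parents of intensity kappa, each
  with Poisson(mu) offspring displaced by an isotropic Gaussian of per-axis
  standard deviation sigma — a single dispersal-limited reproductive event.
* **HTC** — Thomas clusters thinned by the substrate intensities: both.

The Thomas PCF has the closed form

    g(r) = 1 + exp(-r^2 / (4 sigma^2)) / (4 pi kappa sigma^2),

and (kappa, sigma) are estimated by minimum contrast: minimising the
integrated squared difference between the fourth-root-transformed empirical
and model PCFs over a fit range. When the empirical PCF was kernel
smoothed, the model curve is smoothed identically before comparison so the
contrast is between like quantities. The mean offspring per parent is
recovered as mu = lambda / kappa.

Models are scikit-learn style estimators: ``fit(X)`` on an (n, 2) array of
positions in cm, fitted attributes with trailing underscores,
``get_params``/``set_params`` via ``BaseEstimator``. The module-level
``fit_*`` functions are thin wrappers accepting package domain objects.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .geometry import Window
from .masks import CategoryMask
from .patterns import PointPattern
from .pcf import PcfEstimate, pair_correlation, smooth_model_curve
from . import simulate as _sim

#: Bounds for the minimum-contrast search (parents/cm^2, cm).
KAPPA_BOUNDS = (1e-6, 1.0)
SIGMA_BOUNDS = (0.1, 50.0)


# ---------------------------------------------------------------------------
# closed forms and reproductive diagnostics

def thomas_pcf_closed_form(r, kappa: float, sigma: float):
    """Pair correlation function of a Thomas process.

    g(r) = 1 + exp(-r^2/(4 sigma^2)) / (4 pi kappa sigma^2); always >= 1,
    strictly decreasing in r, tending to 1 as r grows.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = np.asarray(r, dtype=float)
    return 1.0 + np.exp(-(r**2) / (4.0 * sigma**2)) / (4.0 * math.pi * kappa * sigma**2)


def offspring_in_nonempty_cluster(mu: float) -> float:
    """Mean number of settled offspring in a non-empty cluster.

    Cluster sizes are Poisson(mu); conditioning on the cluster being
    non-empty gives the zero-truncated Poisson mean mu / (1 - e^-mu),
    which tends to 1 as mu -> 0 and to mu from above as mu grows.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if mu == 0:
        return 1.0
    return mu / -math.expm1(-mu)


def prob_in_cluster(mu: float) -> float:
    """Probability that a typical individual has at least one cluster sibling.

    Under the Palm distribution of a Thomas process the number of siblings
    of a typical point is Poisson(mu), so the probability of belonging to a
    (multi-individual) cluster is 1 - e^-mu.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    return -math.expm1(-mu)


# ---------------------------------------------------------------------------
# minimum contrast core

def _contrast(pcf: PcfEstimate, fit_range, q: float, kappa: float, sigma: float) -> float:
    r = pcf.r
    sel = (r >= fit_range[0] - 1e-9) & (r <= fit_range[1] + 1e-9)
    model = smooth_model_curve(
        lambda s: thomas_pcf_closed_form(s, kappa, sigma), r, pcf.step, pcf.bandwidth
    )
    diff = np.clip(pcf.g[sel], 0.0, None) ** q - model[sel] ** q
    return float(np.trapezoid(diff * diff, r[sel]))


def _moment_start(pcf: PcfEstimate, fit_range) -> tuple:
    """Moment-based (kappa, sigma) start: peak excess and its half-decay radius."""
    r, g = pcf.r, pcf.g
    sel = (r >= fit_range[0]) & (r <= fit_range[1])
    excess = g[sel] - 1.0
    rr = r[sel]
    if excess.size == 0 or excess.max() <= 0:
        return 0.05, 5.0
    e0 = float(excess.max())
    below = np.flatnonzero(excess < 0.5 * e0)
    r_half = float(rr[below[0]]) if below.size else float(rr[-1])
    sigma0 = max(SIGMA_BOUNDS[0], min(SIGMA_BOUNDS[1], r_half / (2.0 * math.sqrt(math.log(2.0)))))
    kappa0 = 1.0 / (4.0 * math.pi * sigma0**2 * e0)
    kappa0 = max(KAPPA_BOUNDS[0], min(KAPPA_BOUNDS[1], kappa0))
    return kappa0, sigma0


def _minimise_contrast(pcf: PcfEstimate, fit_range, q: float):
    """Deterministic bounded search over (log kappa, log sigma)."""
    starts = [_moment_start(pcf, fit_range)]
    for sigma0 in (1.0, 2.0, 5.0, 10.0):
        kappa0 = max(KAPPA_BOUNDS[0], min(KAPPA_BOUNDS[1], pcf.intensity / 2.0))
        starts.append((kappa0, sigma0))

    bounds = [tuple(np.log(KAPPA_BOUNDS)), tuple(np.log(SIGMA_BOUNDS))]

    def objective(theta):
        return _contrast(pcf, fit_range, q, math.exp(theta[0]), math.exp(theta[1]))

    best = None
    for kappa0, sigma0 in starts:
        res = optimize.minimize(
            objective,
            x0=[math.log(kappa0), math.log(sigma0)],
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    kappa, sigma = math.exp(best.x[0]), math.exp(best.x[1])
    at_bound = any(
        abs(v - b) < 1e-8
        for v, bb in zip(best.x, bounds)
        for b in bb
    )
    return kappa, sigma, float(best.fun), not at_bound


# ---------------------------------------------------------------------------
# estimators

class _SpatialModel(BaseEstimator):
    """Shared input validation for point-process estimators."""

    name = "?"

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of positions in cm")
        if X.size and not np.all(np.isfinite(X)):
            raise ValueError("positions must be finite")
        return X

    def _window(self) -> Window:
        return self.window if self.window is not None else Window()


class HomogeneousPoissonModel(_SpatialModel):
    """Complete spatial randomness: homogeneous Poisson with fitted intensity.

    Attributes (after fit): ``intensity_`` (points/cm^2), ``n_``.
    """

    name = "CSR"

    def __init__(self, window: Optional[Window] = None):
        self.window = window

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_ = len(X)
        self.intensity_ = self.n_ / self._window().area_cm2
        return self

    def theoretical_pcf(self, r):
        return np.ones_like(np.asarray(r, dtype=float))

    def simulate(self, seed) -> PointPattern:
        return _sim.simulate_csr(self._window(), self.intensity_, seed)


class HeterogeneousPoissonModel(_SpatialModel):
    """Heterogeneous Poisson: constant intensity per substrate category.

    Fitted intensities are maximum likelihood: lambda_c = n_c / area_c.
    Attributes: ``category_intensities_`` (dict), ``intensity_``, ``n_``.
    """

    name = "HP"

    def __init__(self, window: Optional[Window] = None, mask: Optional[CategoryMask] = None):
        self.window = window
        self.mask = mask

    def fit(self, X, y=None):
        if self.mask is None:
            raise ValueError("HeterogeneousPoissonModel requires a substrate mask")
        X = self._validate(X)
        self.n_ = len(X)
        areas = self.mask.category_areas()
        codes = self.mask.category_at(X[:, 0], X[:, 1]) if len(X) else np.empty(0, int)
        counts = np.bincount(codes, minlength=len(self.mask.categories))
        self.category_intensities_ = {}
        for i, cat in enumerate(self.mask.categories):
            if areas[cat] == 0:
                if counts[i] > 0:
                    raise ValueError(
                        f"category {cat!r} has zero area but {counts[i]} points"
                    )
                self.category_intensities_[cat] = 0.0
            else:
                self.category_intensities_[cat] = counts[i] / areas[cat]
        self.intensity_ = self.n_ / self._window().area_cm2
        return self

    def point_intensity(self, X) -> np.ndarray:
        """Plug-in intensity lambda(x) at each position."""
        X = self._validate(X)
        lam = np.array(
            [self.category_intensities_[c] for c in self.mask.categories]
        )
        return lam[self.mask.category_at(X[:, 0], X[:, 1])]

    def simulate(self, seed) -> PointPattern:
        grid = self.mask.intensity_map(self.category_intensities_)
        return _sim.simulate_inhomogeneous_poisson(self._window(), grid, seed)


class ThomasClusterModel(_SpatialModel):
    """Thomas cluster process fitted by minimum contrast on the PCF.

    Parameters mirror the PCF settings used on the data plus the contrast
    settings (``fit_range`` in cm and transform exponent ``q``).

    Attributes (after fit): ``kappa_`` (parents/cm^2), ``sigma_`` (cm),
    ``mu_`` (= intensity_/kappa_, offspring per parent), ``intensity_``,
    ``contrast_``, ``converged_`` (False when the optimiser finished on a
    parameter bound), ``offspring_nonempty_``, ``prob_in_cluster_``.
    """

    name = "TC"

    def __init__(
        self,
        window: Optional[Window] = None,
        fit_range: tuple = (0.1, 25.0),
        q: float = 0.25,
        r_max: float = 50.0,
        step: float = 0.1,
        bandwidth: float = 5.0,
        correction: str = "translation",
    ):
        self.window = window
        self.fit_range = fit_range
        self.q = q
        self.r_max = r_max
        self.step = step
        self.bandwidth = bandwidth
        self.correction = correction

    def fit(self, X, y=None):
        X = self._validate(X)
        pcf = pair_correlation(
            PointPattern(X, self._window()),
            r_max=self.r_max,
            step=self.step,
            bandwidth=self.bandwidth,
            correction=self.correction,
        )
        return self.fit_pcf(pcf)

    def fit_pcf(self, pcf: PcfEstimate):
        """Fit from a precomputed PCF estimate."""
        kappa, sigma, contrast, converged = _minimise_contrast(pcf, self.fit_range, self.q)
        self.kappa_ = kappa
        self.sigma_ = sigma
        self.intensity_ = pcf.intensity
        self.mu_ = pcf.intensity / kappa
        self.contrast_ = contrast
        self.converged_ = converged
        self.n_ = pcf.n
        self.offspring_nonempty_ = offspring_in_nonempty_cluster(self.mu_)
        self.prob_in_cluster_ = prob_in_cluster(self.mu_)
        return self

    def theoretical_pcf(self, r):
        return thomas_pcf_closed_form(r, self.kappa_, self.sigma_)

    def simulate(self, seed) -> PointPattern:
        return _sim.simulate_thomas(self._window(), self.kappa_, self.sigma_, self.mu_, seed)


class HeterogeneousThomasModel(_SpatialModel):
    """Thomas clusters combined with substrate-driven intensity (HTC).

    The substrate intensities are fitted as in the HP model; the
    inhomogeneous PCF with that plug-in intensity is then fitted by minimum
    contrast to the Thomas closed form. Simulation draws a Thomas process
    at the maximum category intensity and thins it by the normalised
    category intensities.
    """

    name = "HTC"

    def __init__(
        self,
        window: Optional[Window] = None,
        mask: Optional[CategoryMask] = None,
        fit_range: tuple = (0.1, 25.0),
        q: float = 0.25,
        r_max: float = 50.0,
        step: float = 0.1,
        bandwidth: float = 5.0,
        correction: str = "translation",
    ):
        self.window = window
        self.mask = mask
        self.fit_range = fit_range
        self.q = q
        self.r_max = r_max
        self.step = step
        self.bandwidth = bandwidth
        self.correction = correction

    def fit(self, X, y=None):
        if self.mask is None:
            raise ValueError("HeterogeneousThomasModel requires a substrate mask")
        X = self._validate(X)
        hp = HeterogeneousPoissonModel(self._window(), self.mask).fit(X)
        lam = hp.point_intensity(X)
        pcf = pair_correlation(
            PointPattern(X, self._window()),
            r_max=self.r_max,
            step=self.step,
            bandwidth=self.bandwidth,
            correction=self.correction,
            point_intensity=lam,
        )
        kappa, sigma, contrast, converged = _minimise_contrast(pcf, self.fit_range, self.q)
        self.category_intensities_ = hp.category_intensities_
        self.kappa_ = kappa
        self.sigma_ = sigma
        self.intensity_ = hp.intensity_
        self.mu_ = self.intensity_ / kappa
        self.contrast_ = contrast
        self.converged_ = converged
        self.n_ = len(X)
        self.offspring_nonempty_ = offspring_in_nonempty_cluster(self.mu_)
        self.prob_in_cluster_ = prob_in_cluster(self.mu_)
        return self

    def theoretical_pcf(self, r):
        return thomas_pcf_closed_form(r, self.kappa_, self.sigma_)

    def simulate(self, seed) -> PointPattern:
        lam = np.array([self.category_intensities_[c] for c in self.mask.categories])
        lam_max = lam.max()
        if lam_max == 0:
            return PointPattern(np.empty((0, 2)), self._window())
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        mu_sim = lam_max / self.kappa_
        pat = _sim.simulate_thomas(self._window(), self.kappa_, self.sigma_, mu_sim, rng)
        if pat.n == 0:
            return pat
        retain = lam[self.mask.category_at(pat.coords[:, 0], pat.coords[:, 1])] / lam_max
        keep = rng.uniform(size=pat.n) < retain
        return PointPattern(pat.coords[keep], self._window())


# ---------------------------------------------------------------------------
# functional wrappers over the estimators

def fit_thomas_min_contrast(
    pcf: PcfEstimate,
    fit_range: tuple = (0.1, 25.0),
    q: float = 0.25,
    window: Optional[Window] = None,
) -> ThomasClusterModel:
    """Fit a Thomas process to a PCF estimate by minimum contrast."""
    model = ThomasClusterModel(
        window=window,
        fit_range=fit_range,
        q=q,
        bandwidth=pcf.bandwidth,
        step=pcf.step,
        r_max=float(pcf.r[-1]),
        correction=pcf.correction,
    )
    return model.fit_pcf(pcf)


def fit_heterogeneous_poisson(pattern: PointPattern, mask: CategoryMask) -> HeterogeneousPoissonModel:
    """Fit per-category intensities to a pattern."""
    return HeterogeneousPoissonModel(pattern.window, mask).fit(pattern.coords)


def fit_heterogeneous_thomas(
    pattern: PointPattern,
    mask: CategoryMask,
    fit_range: tuple = (0.1, 25.0),
    **pcf_kwargs,
) -> HeterogeneousThomasModel:
    """Fit the combined substrate + clustering model to a pattern."""
    return HeterogeneousThomasModel(
        pattern.window, mask, fit_range=fit_range, **pcf_kwargs
    ).fit(pattern.coords)
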