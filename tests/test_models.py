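import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from coralpp import Window
from coralpp.masks import CategoryMask, uniform_mask
from coralpp.models import (
    HeterogeneousPoissonModel,
    HeterogeneousThomasModel,
    HomogeneousPoissonModel,
    ThomasClusterModel,
    fit_heterogeneous_poisson,
    fit_thomas_min_contrast,
    offspring_in_nonempty_cluster,
    prob_in_cluster,
    thomas_pcf_closed_form,
)
from coralpp.patterns import PointPattern
from coralpp.pcf import PcfEstimate, pair_correlation
from coralpp.simulate import simulate_csr, simulate_inhomogeneous_poisson, simulate_thomas

from _oracles import ztp_mean_enumeration


class TestThomasClosedForm:
    def test_limit_at_large_r(self):
        assert thomas_pcf_closed_form(100 * 2.0, 0.004, 2.0) == pytest.approx(1.0, abs=1e-12)

    def test_unit_normalised_excess_at_zero(self):
        # kappa * sigma^2 = 1/(4 pi) makes the excess exactly 1 at r = 0
        sigma = 3.0
        kappa = 1.0 / (4 * math.pi * sigma**2)
        assert thomas_pcf_closed_form(0.0, kappa, sigma) == pytest.approx(2.0)

    def test_monotone_decreasing_in_r_and_kappa(self):
        r = np.linspace(0, 12, 60)  # beyond ~6 sigma the excess underflows
        g = thomas_pcf_closed_form(r, 0.004, 2.0)
        assert np.all(np.diff(g) < 0)
        assert np.all(
            thomas_pcf_closed_form(r, 0.008, 2.0) < thomas_pcf_closed_form(r, 0.004, 2.0)
        )

    def test_zero_kappa_rejected(self):
        with pytest.raises(ValueError):
            thomas_pcf_closed_form(1.0, 0.0, 2.0)


class TestReproductiveParameters:
    def test_ztp_small_mu_limit(self):
        assert offspring_in_nonempty_cluster(0.0) == 1.0
        assert offspring_in_nonempty_cluster(1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_ztp_large_mu_asymptote(self):
        assert offspring_in_nonempty_cluster(10.0) == pytest.approx(10.000454, abs=1e-5)

    def test_ztp_matches_enumeration(self):
        assert offspring_in_nonempty_cluster(1.0) == pytest.approx(
            ztp_mean_enumeration(1.0), abs=1e-12
        )
        assert offspring_in_nonempty_cluster(1.0) == pytest.approx(1.5820, abs=1e-4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=50.0, allow_nan=False))
    def test_ztp_dominates_mu_and_one(self, mu):
        assert offspring_in_nonempty_cluster(mu) >= max(1.0, mu) - 1e-12

    def test_prob_in_cluster_closed_form(self):
        assert prob_in_cluster(0.0) == 0.0
        assert prob_in_cluster(math.log(2.0)) == pytest.approx(0.5)
        assert prob_in_cluster(1.0) == pytest.approx(0.6321, abs=1e-4)

    def test_prob_in_cluster_matches_simulated_siblings(self):
        # a typical point's sibling count is Poisson(mu): size-biased sampling
        # over Poisson(mu) cluster sizes
        rng = np.random.default_rng(0)
        sizes = rng.poisson(1.0, size=100_000)
        weights = sizes / sizes.sum()
        frac = np.sum(weights * (sizes >= 2))
        assert prob_in_cluster(1.0) == pytest.approx(frac, abs=0.01)

    def test_negative_mu_rejected(self):
        with pytest.raises(ValueError):
            offspring_in_nonempty_cluster(-0.1)
        with pytest.raises(ValueError):
            prob_in_cluster(-0.1)


class TestThomasFit:
    def test_exact_closed_form_recovered(self):
        r = (np.arange(500) + 1) * 0.1
        kappa, sigma = 0.004, 2.0
        pcf = PcfEstimate(
            r=r, g=thomas_pcf_closed_form(r, kappa, sigma), bandwidth=0.0,
            correction="translation", intensity=0.012, n=367,
        )
        fit = fit_thomas_min_contrast(pcf)
        assert fit.kappa_ == pytest.approx(kappa, rel=1e-4)
        assert fit.sigma_ == pytest.approx(sigma, rel=1e-4)

    def test_mu_kappa_product_equals_intensity(self, window):
        pat = simulate_thomas(window, 0.004, 2.0, 3.0, 5)
        fit = ThomasClusterModel(window).fit(pat.coords)
        assert fit.mu_ * fit.kappa_ == pytest.approx(pat.intensity, rel=1e-12)

    def test_invariant_to_point_order(self, window):
        pat = simulate_thomas(window, 0.004, 2.0, 3.0, 6)
        rng = np.random.default_rng(1)
        a = ThomasClusterModel(window).fit(pat.coords)
        b = ThomasClusterModel(window).fit(rng.permutation(pat.coords))
        # summation order changes g_hat at ~1e-15, moving the optimum a hair
        assert a.kappa_ == pytest.approx(b.kappa_, rel=1e-6)
        assert a.sigma_ == pytest.approx(b.sigma_, rel=1e-6)

    def test_csr_input_yields_flat_model(self, window):
        """Fitting the cluster model to CSR data leaves ~no integrated
        cluster excess: the fitted curve is flat at the CSR level over the
        fit range (narrow sub-cm spikes that mimic estimator noise aside)."""
        ok = 0
        n_seeds = 50
        r = (np.arange(1, 251)) * 0.1
        for seed in range(n_seeds):
            pat = simulate_csr(window, 400 / window.area_cm2, 60000 + seed)
            fit = ThomasClusterModel(window).fit(pat.coords)
            mean_excess = float(np.mean(fit.theoretical_pcf(r) - 1.0))
            ok += mean_excess < 0.1
        assert ok >= 0.9 * n_seeds

    def test_sklearn_protocol(self, window):
        model = ThomasClusterModel(window, fit_range=(0.1, 20.0))
        cloned = clone(model)
        assert cloned.get_params()["fit_range"] == (0.1, 20.0)
        cloned.set_params(q=0.5)
        assert cloned.q == 0.5


class TestHeterogeneousPoisson:
    def _half_mask(self, window):
        # left half boulder, right half gulley
        grid = np.zeros((50, 50), dtype=int)
        grid[:, 25:] = 2
        return CategoryMask(grid, window)

    def test_points_on_boulder_half(self, window):
        mask = self._half_mask(window)
        rng = np.random.default_rng(2)
        coords = rng.uniform((0, 0), (window.width / 2 - 1, window.height), size=(40, 2))
        fit = fit_heterogeneous_poisson(PointPattern(coords, window), mask)
        assert fit.category_intensities_["boulder"] == pytest.approx(
            2 * 40 / window.area_cm2
        )
        assert fit.category_intensities_["gulley"] == 0.0
        assert fit.category_intensities_["flat"] == 0.0

    def test_uniform_mask_reduces_to_csr(self, window):
        mask = uniform_mask(window, "flat", cell_size=5.0)
        pat = simulate_csr(window, 0.004, 3)
        hp = fit_heterogeneous_poisson(pat, mask)
        csr = HomogeneousPoissonModel(window).fit(pat.coords)
        assert hp.category_intensities_["flat"] == pytest.approx(csr.intensity_)

    def test_recovers_intensity_ratios(self, window):
        # 3:1:0 intensities over vertical thirds
        grid = np.zeros((30, 30))
        grid[:, :10] = 0.003
        grid[:, 10:20] = 0.001
        cat_grid = np.zeros((30, 30), dtype=int)
        cat_grid[:, 10:20] = 1
        cat_grid[:, 20:] = 2
        mask = CategoryMask(cat_grid, window)
        est_b, est_f = [], []
        for seed in range(500):
            pat = simulate_inhomogeneous_poisson(window, grid, 40000 + seed)
            fit = fit_heterogeneous_poisson(pat, mask)
            est_b.append(fit.category_intensities_["boulder"])
            est_f.append(fit.category_intensities_["flat"])
            assert fit.category_intensities_["gulley"] == 0.0
        for est, truth in ((est_b, 0.003), (est_f, 0.001)):
            se = np.std(est, ddof=1) / np.sqrt(len(est))
            assert abs(np.mean(est) - truth) < 3 * se
        assert np.mean(est_b) / np.mean(est_f) == pytest.approx(3.0, rel=0.05)

    def test_requires_mask(self, window):
        with pytest.raises(ValueError, match="mask"):
            HeterogeneousPoissonModel(window).fit(np.zeros((5, 2)))


class TestHeterogeneousThomas:
    def test_uniform_mask_reduces_to_plain_thomas(self, window):
        pat = simulate_thomas(window, 0.004, 2.0, 3.0, 2)
        mask = uniform_mask(window, "flat", cell_size=5.0)
        tc = ThomasClusterModel(window).fit(pat.coords)
        htc = HeterogeneousThomasModel(window, mask).fit(pat.coords)
        assert htc.kappa_ == pytest.approx(tc.kappa_, abs=1e-6)
        assert htc.sigma_ == pytest.approx(tc.sigma_, abs=1e-6)

    def test_recovers_sigma_under_substrate_thinning(self, window):
        """Known clustered pattern thinned by substrate: sigma recovered with
        median relative error below 25%."""
        grid = np.zeros((35, 35), dtype=int)
        grid[:, 12:24] = 1
        grid[:, 24:] = 2
        mask = CategoryMask(grid, window)
        retention = np.array([1.0, 0.6, 0.3])
        errs = []
        for seed in range(200):
            rng = np.random.default_rng(70000 + seed)
            pat = simulate_thomas(window, 0.004, 2.0, 4.0, rng)
            keep = rng.uniform(size=pat.n) < retention[
                mask.category_at(pat.coords[:, 0], pat.coords[:, 1])
            ]
            thinned = PointPattern(pat.coords[keep], window)
            if thinned.n < 30:
                continue
            fit = HeterogeneousThomasModel(window, mask).fit(thinned.coords)
            errs.append(abs(fit.sigma_ - 2.0) / 2.0)
        assert np.median(errs) < 0.25

    def test_homogeneous_poisson_input_flat_fit(self, window):
        mask = uniform_mask(window, "boulder", cell_size=5.0)
        ok = 0
        r = (np.arange(1, 251)) * 0.1
        for seed in range(20):
            pat = simulate_csr(window, 400 / window.area_cm2, 80000 + seed)
            fit = HeterogeneousThomasModel(window, mask).fit(pat.coords)
            ok += float(np.mean(fit.theoretical_pcf(r) - 1.0)) < 0.1
        assert ok >= 18
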