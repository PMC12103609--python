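import numpy as np
import pytest

from coralpp import Window, classify_scales, nearest_neighbour_distances, pair_correlation
from coralpp.envelopes import Envelope
from coralpp.patterns import PointPattern
from coralpp.pcf import GridMismatchError, InsufficientPointsError
from coralpp.simulate import simulate_csr, simulate_thomas

from _oracles import nn_brute_force, pcf_brute_force


class TestPairCorrelation:
    def test_matches_brute_force_oracle(self, small_pattern):
        est = pair_correlation(small_pattern, r_max=50.0, step=0.5, bandwidth=5.0)
        oracle = pcf_brute_force(
            small_pattern.coords, small_pattern.window, est.r, bandwidth=5.0
        )
        scale = np.maximum(np.abs(oracle), 1.0)
        assert np.max(np.abs(est.g - oracle) / scale) < 1e-10

    def test_insufficient_points(self, window):
        with pytest.raises(InsufficientPointsError):
            pair_correlation(PointPattern([[1.0, 1.0]], window))

    def test_r_max_beyond_half_window_warns_and_truncates(self, window):
        pat = simulate_csr(window, 0.005, 1)
        with pytest.warns(UserWarning, match="half the shorter window side"):
            est = pair_correlation(pat, r_max=120.0)
        assert est.r[-1] == pytest.approx(87.5)

    def test_permutation_invariance(self, window):
        pat = simulate_csr(window, 0.004, 2)
        rng = np.random.default_rng(0)
        shuffled = PointPattern(rng.permutation(pat.coords), window)
        a = pair_correlation(pat)
        b = pair_correlation(shuffled)
        np.testing.assert_allclose(a.g, b.g, rtol=1e-12)

    def test_mirror_invariance(self, window):
        pat = simulate_csr(window, 0.004, 3)
        mirrored = PointPattern(
            np.column_stack([window.width - pat.coords[:, 0], pat.coords[:, 1]]), window
        )
        np.testing.assert_allclose(
            pair_correlation(pat).g, pair_correlation(mirrored).g, rtol=1e-12
        )

    def test_scale_equivariance(self, window):
        pat = simulate_csr(window, 0.006, 4)
        c = 2.5
        scaled = PointPattern(pat.coords * c, Window(window.width * c, window.height * c))
        a = pair_correlation(pat, r_max=40.0, step=0.1, bandwidth=5.0)
        b = pair_correlation(scaled, r_max=40.0 * c, step=0.1 * c, bandwidth=5.0 * c)
        np.testing.assert_allclose(a.g, b.g, rtol=1e-9)

    def test_csr_expectation_is_one(self, window):
        """Mean estimate over 5-40 cm, averaged over CSR replicates, is ~1."""
        lam = 400 / window.area_cm2
        means = []
        for seed in range(30):
            est = pair_correlation(simulate_csr(window, lam, 7000 + seed))
            sel = (est.r >= 5) & (est.r <= 40)
            means.append(est.g[sel].mean())
        assert np.mean(means) == pytest.approx(1.0, abs=0.02)

    def test_isotropic_correction_unbiased_under_csr(self, window):
        lam = 400 / window.area_cm2
        means = []
        for seed in range(20):
            est = pair_correlation(
                simulate_csr(window, lam, 8000 + seed), correction="isotropic"
            )
            sel = (est.r >= 5) & (est.r <= 40)
            means.append(est.g[sel].mean())
        assert np.mean(means) == pytest.approx(1.0, abs=0.03)


class TestNearestNeighbour:
    def test_three_four_five_triangle(self, window):
        pat = PointPattern([[0.0, 0.0], [3.0, 4.0]], window)
        np.testing.assert_allclose(nearest_neighbour_distances(pat), [5.0, 5.0])

    def test_matches_brute_force(self, window):
        rng = np.random.default_rng(9)
        coords = rng.uniform((0, 0), (window.width, window.height), size=(50, 2))
        pat = PointPattern(coords, window)
        np.testing.assert_allclose(
            nearest_neighbour_distances(pat), nn_brute_force(coords), rtol=1e-12
        )

    def test_rigid_motion_invariance(self, window):
        rng = np.random.default_rng(10)
        coords = rng.uniform(50, 120, size=(30, 2))
        base = nearest_neighbour_distances(PointPattern(coords, window))
        shifted = nearest_neighbour_distances(PointPattern(coords + [5.0, -7.0], window))
        centre = np.array([window.width / 2, window.height / 2])
        rot = (coords - centre) @ np.array([[0.0, -1.0], [1.0, 0.0]]) + centre
        rotated = nearest_neighbour_distances(PointPattern(rot, window))
        np.testing.assert_allclose(np.sort(base), np.sort(shifted), rtol=1e-12)
        np.testing.assert_allclose(np.sort(base), np.sort(rotated), rtol=1e-12)

    def test_single_point_rejected(self, window):
        with pytest.raises(InsufficientPointsError):
            nearest_neighbour_distances(PointPattern([[1.0, 1.0]], window))


class TestClassifyScales:
    def _envelope(self, r, lo, hi):
        return Envelope(r=r, lower=lo, upper=hi, n_sims=9, n_drop=0, model="CSR")

    def test_all_within_bounds_single_csr_interval(self):
        from coralpp.pcf import PcfEstimate

        r = (np.arange(500) + 1) * 0.1
        pcf = PcfEstimate(r=r, g=np.ones_like(r), bandwidth=5.0,
                          correction="translation", intensity=0.004, n=100)
        env = self._envelope(r, np.zeros_like(r), np.full_like(r, 10.0))
        assert classify_scales(pcf, env) == [((0.1, 50.0), "CSR")]

    def test_constructed_aggregated_interval(self):
        from coralpp.pcf import PcfEstimate

        r = (np.arange(500) + 1) * 0.1
        g = np.ones_like(r)
        g[(r >= 1.0) & (r <= 7.0)] = 3.0
        pcf = PcfEstimate(r=r, g=g, bandwidth=5.0, correction="translation",
                          intensity=0.004, n=100)
        env = self._envelope(r, np.full_like(r, 0.5), np.full_like(r, 1.5))
        agg = [iv for iv, lab in classify_scales(pcf, env) if lab == "aggregated"]
        assert agg == [(1.0, 7.0)]

    def test_grid_mismatch_rejected(self, window):
        pcf = pair_correlation(simulate_csr(window, 0.004, 2))
        r = pcf.r[:-1]
        env = self._envelope(r, np.zeros_like(r), np.ones_like(r))
        with pytest.raises(GridMismatchError):
            classify_scales(pcf, env)

    def test_thomas_patterns_flag_small_scale_aggregation(self, window):
        """Clustered patterns sit above a CSR envelope at small r in >=95%
        of seeds."""
        from coralpp.envelopes import envelope_from_sims, _simulated_pcfs
        from coralpp.models import HomogeneousPoissonModel

        hits = 0
        n_seeds = 100
        pcf_kwargs = dict(r_max=25.0, step=0.1, bandwidth=5.0, correction="translation")
        for seed in range(n_seeds):
            pat = simulate_thomas(window, 0.002, 2.0, 2.0, 90000 + seed)
            if pat.n < 2:
                continue
            obs = pair_correlation(pat, **pcf_kwargs)
            model = HomogeneousPoissonModel(window).fit(pat.coords)
            sims = _simulated_pcfs(model, pat, 39, 91000 + seed, pcf_kwargs)
            env = envelope_from_sims(obs.r, sims, n_drop=0, model="CSR")
            labelled = classify_scales(obs, env)
            if any(lab == "aggregated" and iv[0] <= 5.0 for iv, lab in labelled):
                hits += 1
        assert hits >= 0.95 * n_seeds
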