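"""Baseline subtraction, SG smoothing/tuning, normalization, outliers."""

import numpy as np
import pytest

from ramanstains.errors import (
    DegenerateSpectrumError,
    InsufficientReplicatesError,
    ParameterError,
)
from ramanstains.preprocess import (
    PreprocessConfig,
    normalize_area,
    preprocess_set,
    preprocess_spectrum,
    remove_outliers,
    smooth_sg,
    subtract_baseline,
    tune_sg,
)
from ramanstains.spectra import Spectrum, SpectrumSet
from ramanstains.synthdata import NoiseModel, add_noise, make_reference, make_tuning_set


class TestBaseline:
    def test_constant_spectrum_flattens_to_zero(self, grid):
        s = Spectrum(grid, np.full(grid.size, 5.0))
        out = subtract_baseline(s)
        assert np.max(np.abs(out.intensity)) < 1e-9 * 5.0

    def test_linear_ramp_is_reproduced_and_removed(self, grid):
        s = Spectrum(grid, 0.01 * grid + 2.0)
        out = subtract_baseline(s)
        assert np.max(np.abs(out.intensity)) < 1e-9

    def test_peak_heights_recovered_under_quadratic_background(self, grid, blood):
        t = (grid - grid[0]) / (grid[-1] - grid[0])
        background = 0.002 * (1.0 + 2.0 * t - 1.5 * t**2)
        out = subtract_baseline(Spectrum(grid, blood.intensity + background))
        for center in (1658.0, 1003.0, 754.0):
            i = int(np.argmin(np.abs(grid - center)))
            rel = abs(out.intensity[i] - blood.intensity[i]) / blood.intensity[i]
            assert rel < 0.05, f"peak at {center} recovered to {rel:.1%}"

    def test_too_short_for_two_anchor_windows(self):
        ax = np.arange(400.0, 420.0)
        with pytest.raises(Exception):
            subtract_baseline(Spectrum(ax, np.ones(ax.size)), window=400.0)


class TestSmoothSG:
    @pytest.mark.parametrize("order,coeffs", [(1, (3.0, 0.002)), (2, (1.0, -0.01, 2e-5))])
    def test_reproduces_low_degree_polynomials_exactly(self, grid, order, coeffs):
        y = np.polynomial.polynomial.polyval(grid - 1000.0, coeffs)
        out = smooth_sg(Spectrum(grid, y), 41.0, order)
        np.testing.assert_allclose(out.intensity, y, atol=1e-10 * max(1, np.abs(y).max()))

    def test_reduces_residual_variance_on_noisy_spectrum(self, rng):
        base = make_tuning_set(n=2, seed=0)[0]  # one noisy replicate
        clean = make_tuning_set(n=2, nu=0.0, seed=0)[0]
        sm = smooth_sg(base)
        v_before = np.var(base.intensity - clean.intensity)
        v_after = np.var(sm.intensity - clean.intensity)
        assert v_after < v_before

    def test_window_not_exceeding_order_rejected(self, grid):
        with pytest.raises(ParameterError):
            smooth_sg(Spectrum(grid, np.ones(grid.size)), 3.0, 3)

    def test_smoothing_helps_across_seeds(self):
        """Denoising lowers the residual-to-truth variance, checked
        statistically over 20 independent noise draws."""
        clean = make_tuning_set(n=2, nu=0.0, seed=0)[0]
        wins = 0
        for seed in range(20):
            noisy = make_tuning_set(n=2, seed=seed)[0]
            sm = smooth_sg(noisy)
            wins += np.var(sm.intensity - clean.intensity) < np.var(
                noisy.intensity - clean.intensity
            )
        assert wins == 20


class TestTuneSG:
    def test_r_zero_for_identical_polynomial_spectra(self, grid):
        # SG reproduces a straight line exactly, so each filtered spectrum
        # equals the set mean and r vanishes on the whole grid.
        s = Spectrum(grid, 1.0 + 0.001 * grid)
        ss = SpectrumSet([s.with_intensity(s.intensity, f"r{i}") for i in range(3)])
        res = tune_sg(ss, [21.0, 41.0], [1])
        assert np.nanmax(res.r_grid) < 1e-12

    def test_scale_invariance_of_r(self):
        ss = make_tuning_set(n=5, seed=3)
        scaled = ss.map(lambda s: s.with_intensity(137.0 * s.intensity))
        r1 = tune_sg(ss, [21.0, 41.0], [1, 2]).r_grid
        r2 = tune_sg(scaled, [21.0, 41.0], [1, 2]).r_grid
        np.testing.assert_allclose(r1, r2, rtol=1e-9)

    def test_first_order_beats_higher_orders_at_default_window(self):
        ss = make_tuning_set(seed=0)
        res = tune_sg(ss, [41.0], [1, 2, 3, 4])
        r = res.r_grid[0]
        assert r[0] <= np.nanmin(r[1:])

    def test_argmin_window_falls_in_the_40cm_band(self):
        ss = make_tuning_set(seed=0)
        windows = list(range(5, 102, 4))
        res = tune_sg(ss, windows, [1])
        assert 25.0 <= res.best_window <= 60.0

    def test_single_spectrum_rejected(self, blood):
        with pytest.raises(InsufficientReplicatesError):
            tune_sg(SpectrumSet([blood]), [41.0], [1])


class TestNormalizeArea:
    def test_positive_spectrum_gets_unit_area(self, grid):
        s = normalize_area(Spectrum(grid, np.exp(-((grid - 1000.0) / 50.0) ** 2)))
        assert s.area() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, blood):
        out = normalize_area(blood)
        np.testing.assert_allclose(out.intensity, blood.intensity, rtol=1e-12)

    def test_zero_spectrum_rejected(self, grid):
        with pytest.raises(DegenerateSpectrumError):
            normalize_area(Spectrum(grid, np.zeros(grid.size)))


class TestRemoveOutliers:
    def _spiked_set(self, blood, rng, n=20):
        spectra = []
        for i in range(n):
            y = blood.intensity + 1e-6 * rng.normal(size=blood.n_points)
            spectra.append(blood.with_intensity(y, f"s{i}"))
        spike = blood.intensity.copy()
        j = int(np.argmax(spike))
        spike[j - 6 : j + 6] *= 10.0
        spectra[7] = blood.with_intensity(spike, "s7")
        return SpectrumSet(spectra)

    def test_spiked_spectrum_is_the_one_removed(self, blood, rng):
        ss = self._spiked_set(blood, rng)
        kept, removed = remove_outliers(ss, fraction=0.05, seed=0)
        assert [s.label for s in removed] == ["s7"]
        # independent oracle: s7 is also the farthest from the set mean
        mean = ss.matrix().mean(axis=0)
        dists = np.linalg.norm(ss.matrix() - mean, axis=1)
        assert ss.labels[int(np.argmax(dists))] == "s7"
        assert len(kept) + len(removed) == len(ss)

    def test_fraction_zero_removes_nothing(self, blood, rng):
        ss = self._spiked_set(blood, rng)
        kept, removed = remove_outliers(ss, fraction=0.0, seed=0)
        assert removed == [] and len(kept) == len(ss)

    def test_too_few_spectra_rejected(self, blood, denim):
        ss = SpectrumSet([blood, denim])
        with pytest.raises(InsufficientReplicatesError):
            remove_outliers(ss, 0.1, 0)


class TestPreprocessSet:
    def test_outputs_have_unit_area(self):
        ss = make_tuning_set(n=4, seed=1)
        out = preprocess_set(ss)
        for s in out:
            assert s.area() == pytest.approx(1.0, abs=1e-9)

    def test_normalize_none_leaves_area_to_smoothing_stage(self):
        ss = make_tuning_set(n=4, seed=1)
        cfg = PreprocessConfig(normalize="none")
        out = preprocess_set(ss, cfg)
        manual = smooth_sg(subtract_baseline(ss[0]))
        np.testing.assert_allclose(out[0].intensity, manual.intensity)

    def test_baseline_free_noiseless_input_is_preserved_in_shape(self):
        # wide, well-separated Gaussian bands: negligible tail floor, so the
        # baseline stage has nothing to remove and smoothing barely distorts
        from ramanstains.synthdata import PeakModel, make_reference

        s = make_reference("custom", peaks=[PeakModel(c, fwhm=60.0, shape="gaussian")
                                            for c in (600.0, 900.0, 1200.0, 1500.0)])
        out = preprocess_spectrum(s)
        corr = np.corrcoef(out.intensity, s.intensity)[0, 1]
        assert corr > 0.99

    def test_deterministic_for_fixed_config(self):
        ss = make_tuning_set(n=4, seed=2)
        a = preprocess_set(ss)
        b = preprocess_set(ss)
        np.testing.assert_array_equal(a.matrix(), b.matrix())

    def test_stage_errors_name_the_spectrum(self, grid):
        bad = Spectrum(grid, np.zeros(grid.size), "flatliner")
        ss = SpectrumSet([bad])
        with pytest.raises(DegenerateSpectrumError, match="flatliner"):
            preprocess_set(ss)
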