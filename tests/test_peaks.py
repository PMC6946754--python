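"""Baseline removal, peak detection and modified-Gaussian fitting."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from ptrscreen import DriftConditions, InstrumentParams, IonSource, QuantParams
from ptrscreen.peaks import (FWHM_SIGMA, PeakConfig, detect_peaks,
                             fit_modified_gaussian, integrate_table,
                             modified_gaussian, remove_baseline)
from ptrscreen.simulate import simulate_spectrum
from ptrscreen.tof import CalibrationModel, RawSpectrum, mz_axis

MODEL = CalibrationModel(a=6000.0, t0=900.0)


class TestRemoveBaseline:
    def test_constant_spectrum_residual_near_zero(self):
        sub, base = remove_baseline(np.full(5000, 7.0), window=301)
        assert np.allclose(sub, 0.0)
        assert np.allclose(base, 7.0)

    def test_all_zero_stays_zero(self):
        sub, base = remove_baseline(np.zeros(1000), window=101)
        assert not sub.any() and not base.any()

    def test_window_larger_than_spectrum_rejected(self):
        with pytest.raises(ValueError, match="window"):
            remove_baseline(np.zeros(100), window=200)

    def test_peak_area_preserved_on_constant_offset(self):
        """A Gaussian peak on a constant baseline keeps its area within 2%
        after baseline removal."""
        bins = np.arange(20000, dtype=float)
        sig, height, b = 3.0, 2000.0, 40.0
        peak = height * np.exp(-0.5 * ((bins - 9000) / sig) ** 2)
        sub, _ = remove_baseline(peak + b, window=501)
        true_area = height * sig * np.sqrt(2 * np.pi)
        got = sub[8950:9050].sum()
        assert got == pytest.approx(true_area, rel=0.02)


class TestDetectPeaks:
    def test_two_ions_one_Th_apart_resolved(self, qp, drift):
        params = InstrumentParams(calib_a=6000.0, calib_t0=900.0,
                                  mz_range=(15.0, 80.0), dead_time_bins=0)
        ions = [IonSource(69.0, count_rate=3000.0),
                IonSource(70.0, count_rate=3000.0)]
        spec = simulate_spectrum(ions, params, 30.0, qp, drift, seed=3)
        sub, _ = remove_baseline(correct(spec), 501)
        centers = np.array([b for b in detect_peaks(sub, params.calibration)
                            if b > params.calib_t0], dtype=float)
        mzs = mz_axis(params.calibration, centers)
        assert np.sum((mzs > 68.5) & (mzs < 70.5)) == 2

    def test_baseline_only_rarely_detects_at_snr_5(self, qp, drift):
        """False-positive control: with no ion sources and threshold 5 the
        detector returns zero candidates in >= 95% of seeds."""
        params = InstrumentParams(calib_a=3000.0, calib_t0=500.0,
                                  mz_range=(15.0, 80.0), dead_time_bins=0)
        zero_seeds = 0
        n_seeds = 30
        for seed in range(n_seeds):
            spec = simulate_spectrum([], params, 30.0, qp, drift, seed=seed)
            sub, _ = remove_baseline(spec.counts.astype(float), 501)
            hits = detect_peaks(sub, params.calibration, snr_threshold=5.0)
            zero_seeds += (len(hits) == 0)
        assert zero_seeds >= 0.95 * n_seeds

    def test_full_panel_of_184_ions_all_detected(self, qp, drift):
        """A high-SNR synthetic panel of 184 ions across m/z 15-300 is
        recovered as exactly 184 detections."""
        params = InstrumentParams(dead_time_bins=0, baseline_rate=1e-6)
        rng = np.random.default_rng(42)
        # quasi-random m/z grid with > 3 resolution widths separation
        mzs = np.sort(15.5 + (299.0 - 16.0) * (np.arange(184) + rng.random(184)) / 184)
        ions = [IonSource(float(m), count_rate=800.0) for m in mzs]
        spec = simulate_spectrum(ions, params, 30.0, qp, drift, seed=0)
        sub, _ = remove_baseline(spec.counts.astype(float), 501)
        centers = detect_peaks(sub, params.calibration, snr_threshold=8.0)
        got = mz_axis(params.calibration, np.array(centers, dtype=float))
        got = got[(got >= 15.0) & (got <= 300.0)]
        assert got.size == 184
        # each detection sits on a panel ion
        assert np.all(np.min(np.abs(got[:, None] - mzs[None, :]), axis=1) < 0.05)


def correct(spec):
    from ptrscreen.tof import correct_dead_time

    return correct_dead_time(spec)


def _density_peak(center, sigma, height, wing=0.0, scale=2.5, span=8.0, step=None):
    step = step or sigma / 6
    x = np.arange(center - span * sigma, center + span * sigma, step)
    return x, modified_gaussian(x, height, center, sigma, wing, scale)


class TestFitModifiedGaussian:
    def test_noise_free_gaussian_recovered_to_6_digits(self):
        x, y = _density_peak(69.0699, 0.0042, 1e4)
        (pk,) = fit_modified_gaussian(x, y, [69.0702], resolution=7000)
        assert pk.center_mz == pytest.approx(69.0699, abs=1e-6)
        assert pk.width_sigma == pytest.approx(0.0042, rel=1e-5)
        assert pk.area == pytest.approx(1e4 * 0.0042 * np.sqrt(2 * np.pi), rel=1e-5)
        assert pk.wing_frac < 1e-3

    def test_wings_recovered_when_present(self):
        x, y = _density_peak(100.0, 0.006, 5e3, wing=0.2, scale=3.0)
        (pk,) = fit_modified_gaussian(x, y, [100.001], resolution=7000)
        true_area = 5e3 * np.sqrt(2 * np.pi) * 0.006 * (0.8 + 0.2 * 3.0)
        assert pk.area == pytest.approx(true_area, rel=1e-3)
        assert pk.wing_frac == pytest.approx(0.2, abs=0.02)

    def test_fixed_wings_equals_plain_gaussian_least_squares(self):
        rng = np.random.default_rng(5)
        x, y = _density_peak(69.0699, 0.0042, 1e4)
        y = y + rng.normal(0, 50, y.size)
        (pk,) = fit_modified_gaussian(x, y, [69.0702], resolution=7000,
                                      fix_wings=True)

        def gauss(x, h, c, s, off):
            return h * np.exp(-0.5 * ((x - c) / s) ** 2) + off

        popt, _ = curve_fit(gauss, x, y, p0=[9000, 69.0702, 0.005, 0.0])
        assert pk.center_mz == pytest.approx(popt[1], abs=5e-6)
        assert pk.area == pytest.approx(
            popt[0] * abs(popt[2]) * np.sqrt(2 * np.pi), rel=1e-3)

    def test_overlapping_pair_unbiased_recovery(self):
        """Two peaks 1.5 sigma apart, Poisson counting noise at peak height
        1e4: the joint fit recovers both areas without bias (mean recovery
        within 5% of truth; per-replicate spread is information-limited at
        this separation)."""
        sigma = 0.006
        x = np.arange(99.9, 100.15, sigma / 6)
        lam = (modified_gaussian(x, 1e4, 100.0, sigma, 0, 2.5)
               + modified_gaussian(x, 8e3, 100.0 + 1.5 * sigma, sigma, 0, 2.5))
        a1 = 1e4 * sigma * np.sqrt(2 * np.pi)
        a2 = 8e3 * sigma * np.sqrt(2 * np.pi)
        rel1, rel2 = [], []
        for seed in range(40):
            y = np.random.default_rng(seed).poisson(lam).astype(float)
            pks = fit_modified_gaussian(x, y, [100.0, 100.0 + 1.5 * sigma],
                                        resolution=7000)
            assert len(pks) == 2
            rel1.append(pks[0].area / a1 - 1)
            rel2.append(pks[1].area / a2 - 1)
        assert abs(np.mean(rel1)) < 0.05
        assert abs(np.mean(rel2)) < 0.05

    def test_poisson_noise_center_rmse_below_0p2_mTh(self, qp, drift):
        """Center RMSE of a Poisson-noised peak (height ~1e4 counts) stays
        below 0.2 mTh."""
        params = InstrumentParams(calib_a=6000.0, calib_t0=900.0,
                                  mz_range=(15.0, 80.0), dead_time_bins=0,
                                  baseline_rate=0.0)
        ions = [IonSource(69.0699, count_rate=2500.0)]
        errs = []
        for seed in range(30):
            spec = simulate_spectrum(ions, params, 30.0, qp, drift, seed=seed)
            bins = np.arange(spec.n_bins, dtype=float)
            ok = bins > params.calib_t0
            mz = mz_axis(params.calibration, bins[ok])
            dm = np.gradient(mz)
            dens = spec.counts[ok] / dm
            (pk,) = fit_modified_gaussian(mz, dens, [69.0699], resolution=7000)
            errs.append(pk.center_mz - 69.0699)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse <= 0.2e-3

    def test_empty_centers_empty_result(self):
        x, y = _density_peak(69.0699, 0.0042, 1e4)
        assert fit_modified_gaussian(x, y, []) == []


class TestIntegrateTable:
    def test_empty_spectrum_empty_table(self):
        spec = RawSpectrum(counts=np.zeros(60000, dtype=int), n_extractions=1000)
        table = integrate_table(spec, MODEL, PeakConfig(mz_bounds=(15.0, 80.0)))
        assert table.n_peaks == 0

    def test_area_invariant_to_bin_density(self, qp, drift):
        """Doubling the sampling density at fixed resolution changes fitted
        areas by < 1%."""
        areas = {}
        for a in (6000.0, 12000.0):
            params = InstrumentParams(calib_a=a, calib_t0=900.0,
                                      mz_range=(15.0, 80.0), dead_time_bins=0,
                                      baseline_rate=0.0)
            ions = [IonSource(69.0699, count_rate=3000.0)]
            spec = simulate_spectrum(ions, params, 30.0, qp, drift, seed=21)
            cfg = PeakConfig(mz_bounds=(15.0, 80.0), annotate_tolerance=None)
            table = integrate_table(spec, params.calibration, cfg)
            areas[a] = table.area_at(69.0699, 0.01)
        assert areas[12000.0] == pytest.approx(areas[6000.0], rel=0.01)

    def test_table1_panel_annotated_at_printed_ions(self, qp, drift):
        """Simulating the six tabulated ions yields a table whose peaks are
        annotated with the generating formulas."""
        formulas = ["C4H5+", "C5H9+", "C5H9O+", "C7H11+", "C8H13+", "C10H17+"]
        params = InstrumentParams(dead_time_bins=0, baseline_rate=1e-6)
        ions = [IonSource(f, count_rate=2000.0) for f in formulas]
        spec = simulate_spectrum(ions, params, 30.0, qp, drift, seed=9)
        cfg = PeakConfig(snr_threshold=8.0)
        table = integrate_table(spec, params.calibration, cfg)
        got = {p.annotation.formula.hill() for p in table.peaks if p.annotation}
        assert set(formulas) <= got

    def test_sorted_by_mz_and_deterministic(self, tiny_spectrum, tiny_config):
        t1 = integrate_table(tiny_spectrum, tiny_spectrum_model(), tiny_config.peaks)
        t2 = integrate_table(tiny_spectrum, tiny_spectrum_model(), tiny_config.peaks)
        mzs = [p.center_mz for p in t1.peaks]
        assert mzs == sorted(mzs)
        assert mzs == [p.center_mz for p in t2.peaks]
        assert [p.area for p in t1.peaks] == [p.area for p in t2.peaks]


def tiny_spectrum_model():
    return CalibrationModel(a=6000.0, t0=900.0)


def test_total_fitted_area_bounded_by_counts(qp, drift):
    """Fitted areas cannot exceed the baseline-subtracted counts in the
    region (up to fit tolerance)."""
    params = InstrumentParams(calib_a=6000.0, calib_t0=900.0,
                              mz_range=(15.0, 80.0), dead_time_bins=0)
    ions = [IonSource(69.0699, count_rate=3000.0),
            IonSource(59.0491, count_rate=1000.0)]
    spec = simulate_spectrum(ions, params, 30.0, qp, drift, seed=2)
    cfg = PeakConfig(mz_bounds=(15.0, 80.0), annotate_tolerance=None)
    table = integrate_table(spec, params.calibration, cfg)
    from ptrscreen.peaks import remove_baseline as rb
    from ptrscreen.tof import correct_dead_time

    sub, _ = rb(correct_dead_time(spec), cfg.baseline_window)
    total_fit = sum(p.area for p in table.peaks)
    total_counts = sub.sum() / spec.n_extractions
    assert total_fit <= total_counts * 1.02
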