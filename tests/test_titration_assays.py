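"""Spectral ratios, breakpoint stoichiometry, plateaus, and slope statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendricomplex.synthetic_data import TitrationModel, gen_spectra_series, gen_titration
from dendricomplex.titration_assays import (
    DegenerateSeriesError,
    EmissionSpectrum,
    NoPlateauError,
    TitrationError,
    TitrationSeries,
    fluorescence_ratio,
    job_stoichiometry,
    peak_wavelength,
    singlet_oxygen_rate,
    zeta_saturation,
)


def _spectrum(intensities, wavelengths=None, **kw):
    if wavelengths is None:
        wavelengths = np.arange(540.0, 650.5, 0.5)
    return EmissionSpectrum(np.asarray(wavelengths, float),
                            np.asarray(intensities, float), **kw)


def _series(x, y, kind="zeta"):
    return TitrationSeries(np.asarray(x, float), np.asarray(y, float), kind)


class TestSpectra:
    def test_flat_spectrum_ratio_is_one(self):
        s = _spectrum(np.full(221, 3.7))
        assert fluorescence_ratio(s) == 1.0

    def test_peak_at_numerator_gives_ratio_above_one(self):
        wl = np.arange(540.0, 650.5, 0.5)
        s = _spectrum(np.exp(-0.5 * ((wl - 564) / 10) ** 2))
        assert fluorescence_ratio(s) > 1.0

    def test_ratio_interpolates_between_grid_points(self):
        wl = np.array([560.0, 563.0, 565.0, 574.0, 576.0, 580.0])
        inten = np.array([1.0, 2.0, 4.0, 1.0, 3.0, 1.0])
        s = _spectrum(inten, wl)
        assert fluorescence_ratio(s) == pytest.approx(3.0 / 2.0)

    def test_zero_denominator_rejected(self):
        wl = np.arange(540.0, 650.5, 0.5)
        s = _spectrum(np.where(wl < 570, 1.0, 0.0))
        with pytest.raises(TitrationError, match="zero"):
            fluorescence_ratio(s)

    def test_mixture_ratio_monotone_in_bound_fraction(self):
        spectra = gen_spectra_series(np.arange(1.0, 31.0), n_true=20.0)
        ratios = [fluorescence_ratio(s) for s in spectra]
        assert all(a >= b - 1e-12 for a, b in zip(ratios, ratios[1:]))

    def test_peak_wavelength_limits_and_spike(self):
        free = gen_spectra_series([0.1], n_true=20.0)[0]
        bound = gen_spectra_series([30.0], n_true=20.0)[0]
        assert peak_wavelength(free) == pytest.approx(564.0, abs=0.5)
        assert peak_wavelength(bound) == pytest.approx(575.0, abs=0.5)
        spike = _spectrum([0, 0, 5, 0, 0], [560, 561, 562, 563, 564])
        assert peak_wavelength(spike) == 562.0

    def test_plateaued_maximum_returns_midpoint_with_warning(self):
        s = _spectrum([0, 1, 1, 1, 0], [560, 561, 562, 563, 564])
        with pytest.warns(UserWarning, match="plateau"):
            assert peak_wavelength(s) == 562.0

    def test_flat_spectrum_has_no_peak(self):
        with pytest.raises(TitrationError):
            peak_wavelength(_spectrum(np.ones(221)))


class TestJobStoichiometry:
    def test_exact_on_noiseless_two_segment_curve(self):
        x = np.arange(1.0, 51.0)
        y = np.where(x < 27, -2.0 * (x - 27.0), 0.0) - 30.0
        est = job_stoichiometry(_series(x, y))
        assert est.n == pytest.approx(27.0, abs=1e-9)
        assert est.ratio_string == "1:27"

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(5, 50),
        slope=st.floats(-5.0, -0.5),
        plateau=st.floats(-40.0, 10.0),
    )
    def test_exact_recovery_property(self, n, slope, plateau):
        """Any interior breakpoint with opposite-regime slopes is recovered."""
        x = np.arange(1.0, 56.0)
        y = np.where(x < n, plateau + slope * (x - n), plateau)
        est = job_stoichiometry(_series(x, y))
        assert est.n == pytest.approx(n, abs=1e-6)

    def test_invariant_under_affine_response_rescaling(self):
        x = np.arange(1.0, 41.0)
        y = np.where(x < 22, 50.0 - 3.0 * x, 50.0 - 3.0 * 22)
        n0 = job_stoichiometry(_series(x, y)).n
        n1 = job_stoichiometry(_series(x, 0.013 * y + 7.0)).n
        assert n1 == pytest.approx(n0, abs=1e-9)

    def test_bias_shrinks_with_noise(self):
        """Median error decreases over three noise levels (seeded replicates)."""
        meds = []
        for noise in (3.0, 1.0, 0.1):
            errs = [abs(job_stoichiometry(gen_titration(TitrationModel(
                n=24.0, noise_sd=noise, seed=s))).n - 24.0) for s in range(40)]
            meds.append(np.median(errs))
        assert meds[2] <= meds[1] <= meds[0] + 1e-9
        assert meds[2] < 0.2

    def test_strictly_linear_series_is_degenerate(self):
        x = np.arange(1.0, 21.0)
        with pytest.raises(DegenerateSeriesError):
            job_stoichiometry(_series(x, 40.0 - 2.0 * x))

    def test_step_series_falls_back_to_plateau_onset(self):
        x = np.arange(1.0, 21.0)
        y = np.where(x < 12, 40.0, -30.0)
        est = job_stoichiometry(_series(x, y))
        assert "parallel_segments_plateau_onset_fallback" in est.flags
        assert 10.0 <= est.n <= 13.0

    def test_short_series_rejected(self):
        with pytest.raises(TitrationError):
            _series([1, 2, 3, 4], [1, 2, 3, 4])


class TestZetaSaturation:
    def test_recovers_noiseless_plateau(self):
        series = gen_titration(TitrationModel(n=26.0, plateau=-30.0))
        assert zeta_saturation(series) == pytest.approx(-30.0, abs=1e-9)

    def test_flat_series_is_its_own_plateau(self):
        assert zeta_saturation(_series(np.arange(5), np.full(5, 40.0))) == 40.0

    def test_decreasing_only_series_has_no_plateau(self):
        x = np.arange(1.0, 21.0)
        with pytest.raises((NoPlateauError, DegenerateSeriesError)):
            zeta_saturation(_series(x, 40.0 - 2.0 * x))


class TestSingletOxygenRate:
    def test_identical_series_is_100_percent(self):
        t = np.arange(0.0, 10.0)
        assert singlet_oxygen_rate(t, 2 * t + 1, t, 2 * t + 1) == pytest.approx(100.0)

    def test_triple_slope_is_300_percent(self):
        t = np.arange(0.0, 10.0)
        assert singlet_oxygen_rate(t, 6.0 * t, t, 2.0 * t) == pytest.approx(300.0)

    def test_constant_sample_is_zero(self):
        t = np.arange(0.0, 10.0)
        assert singlet_oxygen_rate(t, np.full(10, 5.0), t, t) == pytest.approx(0.0)

    def test_zero_control_slope_rejected(self):
        t = np.arange(0.0, 10.0)
        with pytest.raises(TitrationError):
            singlet_oxygen_rate(t, t, t, np.full(10, 1.0))

    def test_short_series_rejected(self):
        with pytest.raises(TitrationError):
            singlet_oxygen_rate([0, 1], [0, 1], [0, 1, 2], [0, 1, 2])
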