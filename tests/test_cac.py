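"""Pyrene I1/I3 extraction and segmented-regression cac estimation."""

import hypothesis.strategies as st
import numpy as np
import pytest
from hypothesis import given, settings

from lipoagg import (
    EmissionSpectrum,
    TitrationSeries,
    TitrationSimSpec,
    fit_cac_segmented,
    generate_titration,
    read_ratio_table,
    read_spectra_dir,
    vibronic_ratio,
)


def two_gaussian_spectrum(h1=178.0, h3=100.0, c1=372.0, c3=387.0, sd=3.0):
    wl = np.arange(360.0, 420.5, 0.5)
    inten = h1 * np.exp(-0.5 * ((wl - c1) / sd) ** 2) + \
        h3 * np.exp(-0.5 * ((wl - c3) / sd) ** 2)
    return EmissionSpectrum(wl, inten)


class TestVibronicRatio:
    def test_flat_spectrum_gives_unity(self):
        spec = EmissionSpectrum(np.arange(360.0, 421.0), np.full(61, 5.0))
        assert vibronic_ratio(spec) == pytest.approx(1.0)

    def test_two_gaussian_bands(self):
        assert vibronic_ratio(two_gaussian_spectrum()) == pytest.approx(1.78, rel=5e-3)

    def test_scale_invariance(self):
        spec = two_gaussian_spectrum()
        doubled = EmissionSpectrum(spec.wavelengths_nm, 2 * spec.intensities)
        assert vibronic_ratio(doubled) == pytest.approx(vibronic_ratio(spec), rel=1e-12)

    def test_small_calibration_shift_tolerated(self):
        shifted = two_gaussian_spectrum(c1=373.5, c3=388.5)
        assert vibronic_ratio(shifted) == pytest.approx(1.78, rel=5e-3)

    def test_band_outside_grid_rejected(self):
        spec = EmissionSpectrum(np.arange(380.0, 421.0), np.ones(41))
        with pytest.raises(ValueError, match="outside"):
            vibronic_ratio(spec)

    def test_zero_third_band_rejected(self):
        wl = np.arange(360.0, 421.0)
        inten = np.where(np.abs(wl - 372) <= 2, 1.0, 0.0)
        with pytest.raises(ValueError, match="zero"):
            vibronic_ratio(EmissionSpectrum(wl, inten))


class TestSegmentedFit:
    def test_noiseless_breakpoint_recovered_exactly(self):
        series = generate_titration(TitrationSimSpec(breakpoint_uM=4.3))
        fit = fit_cac_segmented(series, n_bootstrap=0)
        assert fit.flag == "ok"
        assert fit.cac_uM == pytest.approx(4.3, rel=1e-9)

    def test_segments_meet_at_reported_breakpoint(self):
        series = generate_titration(TitrationSimSpec(noise_sd=0.02, seed=3))
        fit = fit_cac_segmented(series, n_bootstrap=0)
        below = fit.slope_below * fit.log10_cac + fit.intercept_below
        above = fit.slope_above * fit.log10_cac + fit.intercept_above
        assert below == pytest.approx(above, abs=1e-9)

    def test_single_line_flags_no_breakpoint(self):
        conc = np.logspace(-0.5, 1.5, 10)
        series = TitrationSeries(conc, 1.8 - 0.3 * np.log10(conc))
        fit = fit_cac_segmented(series, n_bootstrap=0)
        assert fit.flag == "no_breakpoint"
        assert fit.cac_uM is None

    def test_scale_equivariance(self):
        series = generate_titration(TitrationSimSpec(noise_sd=0.02, seed=11))
        k = 7.5
        scaled = TitrationSeries(k * series.concentrations_uM, series.ratios)
        f1 = fit_cac_segmented(series, n_bootstrap=0)
        f2 = fit_cac_segmented(scaled, n_bootstrap=0)
        assert f2.cac_uM == pytest.approx(k * f1.cac_uM, rel=1e-9)

    @given(st.floats(min_value=-1.0, max_value=1.0))
    @settings(max_examples=25, derandomize=True)
    def test_ratio_offset_invariance(self, offset):
        series = generate_titration(TitrationSimSpec(noise_sd=0.02, seed=5))
        shifted = TitrationSeries(series.concentrations_uM, series.ratios + offset)
        f1 = fit_cac_segmented(series, n_bootstrap=0)
        f2 = fit_cac_segmented(shifted, n_bootstrap=0)
        assert f2.cac_uM == pytest.approx(f1.cac_uM, rel=1e-9)

    def test_manual_regions(self):
        series = generate_titration(TitrationSimSpec(breakpoint_uM=4.3))
        n_below = int(np.sum(series.concentrations_uM < 4.3))
        fit = fit_cac_segmented(series, method="manual_regions",
                                regions=(range(n_below), range(n_below, len(series))))
        assert fit.cac_uM == pytest.approx(4.3, rel=1e-9)

    def test_bootstrap_ci_brackets_truth_on_noisy_data(self):
        series = generate_titration(TitrationSimSpec(noise_sd=0.02, seed=2))
        fit = fit_cac_segmented(series, n_bootstrap=300, seed=42)
        lo, hi = fit.bootstrap_ci_uM
        assert lo < 4.3 < hi
        assert lo < fit.cac_uM < hi

    def test_bootstrap_ci_coverage(self):
        """Percentile bootstrap CI covers the true breakpoint in >=90% of
        noisy replicates."""
        covered = 0
        for seed in range(100):
            series = generate_titration(
                TitrationSimSpec(noise_sd=0.02, seed=seed))
            fit = fit_cac_segmented(series, n_bootstrap=250, seed=seed + 10_000)
            if fit.flag == "ok" and fit.bootstrap_ci_uM is not None:
                lo, hi = fit.bootstrap_ci_uM
                covered += lo <= 4.3 <= hi
        assert covered >= 90

    def test_determinism(self):
        series = generate_titration(TitrationSimSpec(noise_sd=0.02, seed=9))
        f1 = fit_cac_segmented(series, n_bootstrap=100, seed=1)
        f2 = fit_cac_segmented(series, n_bootstrap=100, seed=1)
        assert f1 == f2


class TestSeriesValidation:
    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="6"):
            TitrationSeries([1, 2, 3, 4, 5], [1] * 5)

    def test_points_sorted_on_construction(self):
        series = TitrationSeries([5, 1, 3, 2, 4, 6], [5, 1, 3, 2, 4, 6])
        assert np.all(np.diff(series.concentrations_uM) > 0)
        np.testing.assert_array_equal(series.ratios, series.concentrations_uM)


class TestTextIO:
    def test_ratio_table_round_trip(self, tmp_path):
        series = generate_titration(TitrationSimSpec(noise_sd=0.02, seed=4))
        path = tmp_path / "titration.tsv"
        np.savetxt(path, np.column_stack([series.concentrations_uM, series.ratios]),
                   header="concentration_uM\tratio")
        back = read_ratio_table(path)
        np.testing.assert_allclose(back.ratios, series.ratios, rtol=1e-6)

    def test_three_column_table_forms_ratio(self, tmp_path):
        path = tmp_path / "i1i3.tsv"
        conc = np.logspace(-0.5, 1.3, 8)
        i1 = np.full(8, 178.0)
        i3 = np.full(8, 100.0)
        np.savetxt(path, np.column_stack([conc, i1, i3]),
                   header="concentration_uM\tI1\tI3")
        back = read_ratio_table(path)
        np.testing.assert_allclose(back.ratios, 1.78)

    def test_spectra_directory(self, tmp_path):
        # spectra whose I1/I3 falls with concentration; labels in headers
        for conc, h1 in [(0.5, 180.0), (1.0, 178.0), (2.0, 176.0),
                         (5.0, 160.0), (10.0, 140.0), (20.0, 120.0)]:
            spec = two_gaussian_spectrum(h1=h1)
            path = tmp_path / f"pyrene_{conc}uM.tsv"
            data = np.column_stack([spec.wavelengths_nm, spec.intensities])
            np.savetxt(path, data,
                       header=f" concentration_uM = {conc}", comments="#")
        series = read_spectra_dir(tmp_path)
        assert len(series) == 6
        assert np.all(np.diff(series.ratios) < 0)
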