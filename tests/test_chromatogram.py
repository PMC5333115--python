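"""Chromatogram I/O, peak detection and trapezoid integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chirokit import (
    Chromatogram,
    PeakFindingParams,
    detect_peaks,
    integrate_window,
    read_chromatogram,
    write_chromatogram,
)
from chirokit.exceptions import FormatError, RangeError, ValidationError


class TestIO:
    def test_minimal_csv_roundtrip_of_three_rows(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("time,uv,ecd\n0,0,0\n1,5,1\n2,0,0\n")
        chrom = read_chromatogram(path)
        assert chrom.n == 3
        assert chrom.uv[1] == 5.0
        assert chrom.wavelength == 250.0

    def test_missing_ecd_column_is_a_format_error(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("time,uv\n0,0\n1,5\n2,0\n")
        with pytest.raises(FormatError, match="missing column: ecd"):
            read_chromatogram(path)

    def test_non_monotone_time_is_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("time,uv,ecd\n0,0,0\n2,5,1\n1,0,0\n")
        with pytest.raises(ValidationError):
            read_chromatogram(path)

    def test_write_read_roundtrip_preserves_traces_and_metadata(self, tmp_path):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 5.0, 0.01)
        chrom = Chromatogram(
            time=t,
            uv=rng.normal(10.0, 2.0, len(t)),
            ecd=rng.normal(0.0, 1.0, len(t)),
            wavelength=254.0,
            meta={"column": "achiral", "sample_id": "run1"},
        )
        path = tmp_path / "c.csv"
        write_chromatogram(chrom, path)
        back = read_chromatogram(path)
        np.testing.assert_allclose(back.uv, chrom.uv, rtol=1e-9)
        np.testing.assert_allclose(back.ecd, chrom.ecd, rtol=1e-9)
        np.testing.assert_allclose(back.time, chrom.time, rtol=1e-9)
        assert back.wavelength == 254.0
        assert back.meta == {"column": "achiral", "sample_id": "run1"}


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"time": [0.0], "uv": [1.0], "ecd": [0.0]},  # too short
            {"time": [0, 1, 2], "uv": [1, 2], "ecd": [0, 0, 0]},  # length mismatch
            {"time": [0, 1, 1.5], "uv": [0, 0, 0], "ecd": [0, 0, 0]},  # non-uniform
            {"time": [0, 1, 2], "uv": [0, 0, 0], "ecd": [0, 0, 0], "wavelength": -1},
        ],
    )
    def test_invariant_violations_raise(self, kwargs):
        with pytest.raises(ValidationError):
            Chromatogram(**{"wavelength": 250.0, **kwargs})

    @pytest.mark.parametrize("window", [1.0, 0.0])
    def test_peak_params_require_positive_thresholds(self, window):
        with pytest.raises(ValidationError):
            PeakFindingParams(min_height=window - 1.0, min_prominence=1.0)


class TestDetection:
    def test_flat_trace_yields_no_peaks(self):
        t = np.arange(0.0, 10.0, 0.01)
        chrom = Chromatogram(time=t, uv=np.zeros_like(t), ecd=np.zeros_like(t))
        assert detect_peaks(chrom, PeakFindingParams()) == []

    @pytest.mark.parametrize("sigma", [0.05, 0.1, 0.2])
    def test_gaussian_area_matches_closed_form(self, gaussian_chromatogram, sigma):
        # trapezoid area vs amplitude*sigma*sqrt(2*pi) at a step of sigma/20
        amplitude = 100.0
        chrom = gaussian_chromatogram(amplitude=amplitude, rt=5.0, sigma=sigma)
        peaks = detect_peaks(chrom, PeakFindingParams(min_height=10, min_prominence=10))
        assert len(peaks) == 1
        expected = amplitude * sigma * math.sqrt(2.0 * math.pi)
        assert peaks[0].uv_area == pytest.approx(expected, rel=0.005)
        assert abs(peaks[0].rt - 5.0) <= chrom.dt

    def test_two_resolved_gaussians_give_two_peaks_at_true_apexes(self):
        t = np.arange(0.0, 12.0, 0.005)
        uv = 100.0 * np.exp(-0.5 * ((t - 3.0) / 0.1) ** 2) + 60.0 * np.exp(
            -0.5 * ((t - 8.0) / 0.1) ** 2
        )
        chrom = Chromatogram(time=t, uv=uv, ecd=np.zeros_like(t))
        peaks = detect_peaks(chrom, PeakFindingParams(min_height=10, min_prominence=10))
        assert len(peaks) == 2
        assert abs(peaks[0].rt - 3.0) <= chrom.dt
        assert abs(peaks[1].rt - 8.0) <= chrom.dt
        assert peaks[0].t_end < peaks[1].t_start

    def test_ecd_integrated_over_uv_bounds_keeps_sign(self, gaussian_chromatogram):
        chrom = gaussian_chromatogram(amplitude=50.0, ecd_scale=-0.2)
        (peak,) = detect_peaks(chrom, PeakFindingParams(min_height=5, min_prominence=5))
        assert peak.ecd_area == pytest.approx(-0.2 * peak.uv_area, rel=1e-9)

    def test_peak_on_linear_drift_with_rolling_minimum_baseline(self):
        t = np.arange(0.0, 10.0, 0.005)
        drift = 2.0 * t
        uv = drift + 100.0 * np.exp(-0.5 * ((t - 5.0) / 0.1) ** 2)
        chrom = Chromatogram(time=t, uv=uv, ecd=np.zeros_like(t))
        params = PeakFindingParams(
            min_height=10, min_prominence=10, baseline_mode="rolling-minimum"
        )
        peaks = detect_peaks(chrom, params)
        assert len(peaks) == 1
        expected = 100.0 * 0.1 * math.sqrt(2.0 * math.pi)
        assert peaks[0].uv_area == pytest.approx(expected, rel=0.10)


class TestIntegration:
    def test_zero_traces_integrate_to_zero(self):
        t = np.arange(0.0, 5.0, 0.01)
        chrom = Chromatogram(time=t, uv=np.zeros_like(t), ecd=np.zeros_like(t))
        assert integrate_window(chrom, 1.0, 4.0) == (0.0, 0.0)

    def test_rectangle_pulse_has_hand_computed_area(self):
        # half-open pulse [1, 3) of height 10 on a 0.01 min grid -> exactly 20 mAU*min
        t = np.arange(0.0, 5.0, 0.01)
        uv = np.where((t >= 1.0 - 1e-12) & (t < 3.0 - 1e-12), 10.0, 0.0)
        chrom = Chromatogram(time=t, uv=uv, ecd=np.zeros_like(t))
        uv_area, _ = integrate_window(chrom, 0.5, 4.5)
        assert uv_area == pytest.approx(20.0, abs=1e-9)

    def test_ecd_equal_to_negated_uv_gives_negated_area(self, gaussian_chromatogram):
        chrom = gaussian_chromatogram(amplitude=80.0, ecd_scale=-1.0)
        uv_area, ecd_area = integrate_window(chrom, 3.0, 7.0)
        assert ecd_area == pytest.approx(-uv_area, rel=1e-12)

    def test_window_outside_grid_raises(self, gaussian_chromatogram):
        chrom = gaussian_chromatogram()
        with pytest.raises(RangeError):
            integrate_window(chrom, -1.0, 5.0)
        with pytest.raises(RangeError):
            integrate_window(chrom, 5.0, 99.0)
        with pytest.raises(RangeError):
            integrate_window(chrom, 5.0, 4.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-100, 100, allow_nan=False),
                st.floats(-100, 100, allow_nan=False),
            ),
            min_size=10,
            max_size=40,
        ),
        alpha=st.floats(-5, 5, allow_nan=False),
        beta=st.floats(-5, 5, allow_nan=False),
    )
    def test_integration_is_linear_in_the_traces(self, data, alpha, beta):
        f = np.array([d[0] for d in data])
        g = np.array([d[1] for d in data])
        t = np.arange(len(f), dtype=float)
        zero = np.zeros_like(f)
        combo = Chromatogram(time=t, uv=alpha * f + beta * g, ecd=zero)
        cf = Chromatogram(time=t, uv=f, ecd=zero)
        cg = Chromatogram(time=t, uv=g, ecd=zero)
        lo, hi = 1.0, float(len(f) - 2)
        a_combo, _ = integrate_window(combo, lo, hi)
        a_f, _ = integrate_window(cf, lo, hi)
        a_g, _ = integrate_window(cg, lo, hi)
        assert a_combo == pytest.approx(alpha * a_f + beta * a_g, rel=1e-9, abs=1e-9)
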