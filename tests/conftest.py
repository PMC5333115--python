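import numpy as np
import pytest

from chirokit import (
    GFactor,
    PeakFindingParams,
    PeakShape,
    compute_g_factor,
    detect_peaks,
)


@pytest.fixture
def fast_achiral_shapes():
    """Compact achiral layout (substrate 3 min, product 7 min) for quick runs."""
    return {
        "substrate": PeakShape(rt=3.0, sigma_t=0.10),
        "product": PeakShape(rt=7.0, sigma_t=0.12),
    }


@pytest.fixture
def measure_product_g():
    """Measure the g-factor over the product peak of a chromatogram.

    Detects peaks on the UV channel and picks the largest-area peak inside
    the retention-time window, mirroring the CLI's species assignment.
    """

    def _measure(chrom, rt_window=(5.5, 8.5), min_signal=0.05) -> GFactor:
        peaks = detect_peaks(
            chrom, PeakFindingParams(min_height=min_signal, min_prominence=min_signal)
        )
        candidates = [p for p in peaks if rt_window[0] <= p.rt <= rt_window[1]]
        assert candidates, "no product peak found in window"
        peak = max(candidates, key=lambda p: p.uv_area)
        return compute_g_factor(peak.uv_area, peak.ecd_area, wavelength=chrom.wavelength)

    return _measure


@pytest.fixture
def gaussian_chromatogram():
    """Factory for single-channel-style Gaussian test traces."""

    def _make(amplitude=100.0, rt=5.0, sigma=0.1, duration=10.0, step=None, ecd_scale=0.0):
        from chirokit import Chromatogram

        step = sigma / 20 if step is None else step
        t = np.arange(0.0, duration + step / 2, step)
        uv = amplitude * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
        return Chromatogram(time=t, uv=uv, ecd=ecd_scale * uv)

    return _make
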