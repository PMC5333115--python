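"""Dual-channel chromatogram data model, CSV I/O, peak detection and integration.

A :class:`Chromatogram` holds the two time-aligned traces an HPLC-ECD
instrument produces at a single detection wavelength: ordinary UV absorbance
(mAU) and circular-dichroic ellipticity (mdeg).  Peaks are detected on the
UV channel; the ECD channel is always integrated over the *same* bounds,
because both detectors see the same eluate and the ECD trace of a
near-racemic sample may cross zero inside a perfectly good peak.

Areas are trapezoid-rule integrals on the raw time grid (minutes), after
subtraction of a baseline.  Two baseline models are offered:

``linear-endpoints``
    a straight line through the first and last point of the integration
    window (or of the whole trace, during detection) — the default, exact
    for flat or linearly drifting baselines;
``rolling-minimum``
    a running minimum filter, for baselines that drift non-linearly.

Units: time in minutes, UV in mAU, ECD in mdeg, areas in signal·min.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d
from scipy.signal import find_peaks

from .exceptions import FormatError, RangeError, ValidationError

__all__ = [
    "Chromatogram",
    "Peak",
    "PeakFindingParams",
    "read_chromatogram",
    "write_chromatogram",
    "detect_peaks",
    "integrate_window",
]

_REQUIRED_COLUMNS = ("time", "uv", "ecd")
_BASELINE_MODES = ("linear-endpoints", "rolling-minimum")


@dataclass(frozen=True)
class Chromatogram:
    """A dual-channel (UV + ECD) chromatogram on a uniform time grid.

    Parameters
    ----------
    time : array-like
        Strictly increasing, uniformly spaced retention times in minutes.
    uv : array-like
        UV absorbance trace in mAU, same length as ``time``.
    ecd : array-like
        Ellipticity trace in mdeg, same length as ``time``.
    wavelength : float
        Detection wavelength in nm (both channels share it). Default 250.
    meta : dict
        Free-form metadata (column type, sample id, ...).
    """

    time: np.ndarray
    uv: np.ndarray
    ecd: np.ndarray
    wavelength: float = 250.0
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        uv = np.asarray(self.uv, dtype=float)
        ecd = np.asarray(self.ecd, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "uv", uv)
        object.__setattr__(self, "ecd", ecd)
        object.__setattr__(self, "meta", dict(self.meta))
        if time.ndim != 1 or len(time) < 2:
            raise ValidationError("time grid must be 1-D with at least 2 points")
        if len(uv) != len(time) or len(ecd) != len(time):
            raise ValidationError("time, uv and ecd must have equal length")
        steps = np.diff(time)
        if np.any(steps <= 0):
            raise ValidationError("time must be strictly increasing")
        mean_step = steps.mean()
        if np.max(np.abs(steps - mean_step)) > 1e-6 * mean_step:
            raise ValidationError("time grid must be uniform (non-uniform step detected)")
        if not self.wavelength > 0:
            raise ValidationError("wavelength must be positive")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        """Mean grid step in minutes."""
        return float((self.time[-1] - self.time[0]) / (self.n - 1))


@dataclass(frozen=True)
class Peak:
    """An integrated chromatographic feature.

    ``uv_area`` is the baseline-corrected UV area (mAU·min, non-negative);
    ``ecd_area`` keeps its sign (mdeg·min) and is integrated over the same
    bounds as the UV channel.
    """

    rt: float
    t_start: float
    t_end: float
    uv_area: float
    ecd_area: float
    uv_height: float

    def __post_init__(self) -> None:
        if not (self.t_start < self.rt < self.t_end):
            raise ValidationError(
                f"peak bounds must bracket the apex: {self.t_start} < {self.rt} < {self.t_end} fails"
            )
        if self.uv_area < 0:
            if self.uv_area > -1e-12:
                object.__setattr__(self, "uv_area", 0.0)
            else:
                raise ValidationError("baseline-corrected UV area of a peak must be >= 0")


@dataclass(frozen=True)
class PeakFindingParams:
    """Detection thresholds and baseline handling for :func:`detect_peaks`.

    ``bound_threshold_rel`` sets where the integration bounds are placed:
    the nearest points, walking out from the apex, where the corrected UV
    signal falls below that fraction of the apex height (or the prominence
    base, whichever comes first).
    """

    min_height: float = 1.0
    min_prominence: float = 1.0
    baseline_mode: str = "linear-endpoints"
    smoothing_window: int = 1
    bound_threshold_rel: float = 1e-3
    rolling_points: int | None = None

    def __post_init__(self) -> None:
        if not self.min_height > 0:
            raise ValidationError("min_height must be > 0")
        if not self.min_prominence > 0:
            raise ValidationError("min_prominence must be > 0")
        if self.baseline_mode not in _BASELINE_MODES:
            raise ValidationError(f"baseline_mode must be one of {_BASELINE_MODES}")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValidationError("smoothing_window must be an odd integer >= 1")


# ---------------------------------------------------------------------------
# I/O — CSV dialect: leading '#key=value' metadata lines, then time,uv,ecd


def read_chromatogram(path, format: str = "csv") -> Chromatogram:
    """Read a chromatogram from a CSV file.

    The dialect is UTF-8 text: optional leading metadata lines of the form
    ``#key=value``, then a header row ``time,uv,ecd`` and numeric rows.
    A ``wavelength`` metadata key is promoted to the typed field.
    """
    if format != "csv":
        raise FormatError(f"unsupported format: {format!r}")
    meta: dict[str, str] = {}
    body_lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, value = stripped.partition("=")
                    meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    df = pd.read_csv(io.StringIO("".join(body_lines)))
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing column: {col}")
    wavelength = float(meta.pop("wavelength", 250.0))
    return Chromatogram(
        time=df["time"].to_numpy(float),
        uv=df["uv"].to_numpy(float),
        ecd=df["ecd"].to_numpy(float),
        wavelength=wavelength,
        meta=meta,
    )


def write_chromatogram(chrom: Chromatogram, path) -> None:
    """Write a chromatogram in the CSV dialect of :func:`read_chromatogram`.

    Values are emitted as shortest exact decimal representations (at least
    9 significant digits where needed), so a write/read cycle reproduces
    the traces bit-for-bit.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#wavelength={chrom.wavelength!r}\n")
        for key, value in chrom.meta.items():
            fh.write(f"#{key}={value}\n")
        fh.write("time,uv,ecd\n")
        for t, u, e in zip(chrom.time, chrom.uv, chrom.ecd):
            fh.write(f"{float(t)!r},{float(u)!r},{float(e)!r}\n")


# ---------------------------------------------------------------------------
# Baselines and integration


def _full_trace_baseline(t: np.ndarray, y: np.ndarray, mode: str, rolling_points: int | None) -> np.ndarray:
    if mode == "linear-endpoints":
        return y[0] + (y[-1] - y[0]) * (t - t[0]) / (t[-1] - t[0])
    if mode == "rolling-minimum":
        size = rolling_points if rolling_points else max(3, len(y) // 20) | 1
        return minimum_filter1d(y, size=size, mode="nearest")
    raise ValidationError(f"baseline_mode must be one of {_BASELINE_MODES}")


def integrate_window(
    chrom: Chromatogram,
    t_start: float,
    t_end: float,
    baseline_mode: str = "linear-endpoints",
    rolling_points: int | None = None,
) -> tuple[float, float]:
    """Trapezoid-rule areas of both channels over ``[t_start, t_end]``.

    Each channel is corrected by its own baseline before integration
    (``linear-endpoints``: a chord through the window's own endpoints;
    ``rolling-minimum``: a running-minimum baseline of the full trace).
    The ECD area keeps its sign.

    Returns
    -------
    (uv_area, ecd_area) : tuple of float
        Areas in mAU·min and mdeg·min.
    """
    if not t_start < t_end:
        raise RangeError("t_start must be < t_end")
    if t_start < chrom.time[0] - 1e-12 or t_end > chrom.time[-1] + 1e-12:
        raise RangeError(
            f"window [{t_start}, {t_end}] outside time grid "
            f"[{chrom.time[0]}, {chrom.time[-1]}]"
        )
    i0 = int(np.searchsorted(chrom.time, t_start, side="left"))
    i1 = int(np.searchsorted(chrom.time, t_end, side="right")) - 1
    if i1 - i0 < 1:
        raise RangeError("integration window must span at least two grid points")
    tseg = chrom.time[i0 : i1 + 1]
    areas = []
    for y in (chrom.uv, chrom.ecd):
        if baseline_mode == "linear-endpoints":
            seg = y[i0 : i1 + 1]
            base = seg[0] + (seg[-1] - seg[0]) * (tseg - tseg[0]) / (tseg[-1] - tseg[0])
        else:
            base = _full_trace_baseline(chrom.time, y, baseline_mode, rolling_points)[i0 : i1 + 1]
            seg = y[i0 : i1 + 1]
        areas.append(float(np.trapezoid(seg - base, tseg)))
    return areas[0], areas[1]


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    return np.convolve(y, kernel, mode="same")


def detect_peaks(chrom: Chromatogram, params: PeakFindingParams | None = None) -> list[Peak]:
    """Detect and integrate UV peaks; returns peaks sorted by retention time.

    Apexes are found on the (optionally smoothed) baseline-corrected UV
    trace with SciPy's prominence-based peak finder.  Integration bounds
    walk outward from each apex to the nearest point where the corrected
    signal drops below ``bound_threshold_rel`` of the apex height, capped
    at the prominence bases (which sit in the valleys between neighbouring
    peaks).  Areas are then computed on the *unsmoothed* data with
    :func:`integrate_window`, so the ECD channel shares the UV bounds.
    """
    if params is None:
        params = PeakFindingParams()
    baseline = _full_trace_baseline(chrom.time, chrom.uv, params.baseline_mode, params.rolling_points)
    corrected = chrom.uv - baseline
    search = _smooth(corrected, params.smoothing_window)
    apexes, props = find_peaks(search, height=params.min_height, prominence=params.min_prominence)
    peaks: list[Peak] = []
    for k, i in enumerate(apexes):
        height = corrected[i] if corrected[i] > 0 else search[i]
        thr = params.bound_threshold_rel * height
        left_cap = int(props["left_bases"][k])
        right_cap = int(props["right_bases"][k])
        j = i - 1
        while j > left_cap and corrected[j] > thr:
            j -= 1
        m = i + 1
        while m < right_cap and corrected[m] > thr:
            m += 1
        t_start, t_end = float(chrom.time[j]), float(chrom.time[m])
        uv_area, ecd_area = integrate_window(
            chrom, t_start, t_end, params.baseline_mode, params.rolling_points
        )
        peaks.append(
            Peak(
                rt=float(chrom.time[i]),
                t_start=t_start,
                t_end=t_end,
                uv_area=max(uv_area, 0.0),
                ecd_area=ecd_area,
                uv_height=float(height),
            )
        )
    peaks.sort(key=lambda p: p.rt)
    return peaks
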