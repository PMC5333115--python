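"""Kuhn g-factor statistics: enantiomeric excess, conversion ratio, calibration.

The analytical core of the online method.  On an achiral column the two
enantiomers of the product co-elute as a single peak, so UV absorbance
measures total product (c_R + c_S) while the ECD signal measures the signed
difference (c_R − c_S).  Their ratio — Kuhn's dissymmetry factor,

    g = ΔA / A,

— is therefore independent of concentration and path length, and scales
linearly with enantiomeric excess:

    g_mix = ee · g_pure,   ee = (c_R − c_S) / (c_R + c_S) ∈ [−1, +1].

A single injection of a reaction mixture then yields both the conversion
ratio (from UV peak areas of substrate and product) and the signed ee (from
the g-factor), without chiral separation.

Unit conventions: the ECD detector reports ellipticity θ in millidegrees,
related to the differential absorbance by θ[mdeg] ≈ 32980·ΔA, and UV in
mAU (1000 mAU = 1 AU).  Both constants are configurable; they cancel in
every ee estimate, so only the sign convention matters there.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    InconsistentReferenceError,
    UndefinedCVError,
    ValidationError,
)

__all__ = [
    "GFactor",
    "EEEstimate",
    "ConversionResult",
    "CalibrationFit",
    "LinearityReport",
    "InvarianceReport",
    "compute_g_factor",
    "estimate_ee",
    "conversion_ratio",
    "fit_calibration",
    "check_linearity",
    "g_concentration_invariance",
    "ELLIPTICITY_TO_DA",
    "MAU_TO_A",
]

#: mdeg of ellipticity per unit of differential absorbance ΔA (standard CD relation).
ELLIPTICITY_TO_DA = 32980.0
#: mAU per absorbance unit.
MAU_TO_A = 1000.0


@dataclass(frozen=True)
class GFactor:
    """A dissymmetry factor g = ΔA/A measured at one wavelength."""

    value: float
    wavelength: float
    uv_area_used: float
    ecd_area_used: float

    def __post_init__(self) -> None:
        if not self.uv_area_used > 0:
            raise ValidationError("uv_area_used must be > 0")
        if not math.isfinite(self.value):
            raise ValidationError("g value must be finite")

    @classmethod
    def from_value(cls, value: float, wavelength: float = 250.0) -> "GFactor":
        """Wrap a bare g value (e.g. a tabulated reference) with unit areas."""
        return cls(value=value, wavelength=wavelength, uv_area_used=1.0, ecd_area_used=value)


@dataclass(frozen=True)
class EEEstimate:
    """Signed enantiomeric excess with a dominant-configuration call.

    ``ee`` is a signed fraction in [−1, +1]; positive means an excess of the
    reference enantiomer.  ``dominant`` is ``"racemic"`` when |ee| is below
    the racemic floor (the detection limit below which no call is made).
    """

    ee: float
    ee_percent: float
    dominant: str
    g_mix: float
    g_pure_ref: float


@dataclass(frozen=True)
class ConversionResult:
    """Conversion ratio in percent, from substrate and product UV areas."""

    cr: float
    substrate_area: float
    product_area: float
    response_factor: float = 1.0


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary-least-squares line through calibration points.

    ``r_squared_defined`` is False when the responses have zero variance
    (SS_tot = 0); ``r_squared`` is then NaN rather than 0 or 1.
    ``x_span`` and ``y_mean`` are carried so linearity checks need no
    access to the raw points.
    """

    slope: float
    intercept: float
    r_squared: float
    n: int
    residual_sd: float
    x_span: float
    y_mean: float
    r_squared_defined: bool = True


@dataclass(frozen=True)
class LinearityReport:
    passed: bool
    mode: str
    metric: float
    threshold: float
    detail: str


@dataclass(frozen=True)
class InvarianceReport:
    """Coefficient of variation of g across a concentration series."""

    cv: float
    passed: bool
    n: int
    mean_g: float
    sd_g: float


def compute_g_factor(
    uv_area: float,
    ecd_area: float,
    ellipticity_to_dA: float = ELLIPTICITY_TO_DA,
    mau_to_A: float = MAU_TO_A,
    wavelength: float = 250.0,
) -> GFactor:
    """Kuhn dissymmetry factor from co-eluting UV and ECD peak areas.

    g = (ecd_area / ellipticity_to_dA) / (uv_area / mau_to_A), i.e. both
    areas are first converted to absorbance-unit scales.  Because UV and
    ECD areas are integrated over the same bounds of the same eluate, the
    concentration and injection volume cancel.

    Raises
    ------
    DegenerateInputError
        If ``uv_area`` is not positive (no analyte under the peak).
    """
    if not uv_area > 0:
        raise DegenerateInputError("uv_area must be > 0 to form a g-factor (no analyte)")
    value = (ecd_area / ellipticity_to_dA) / (uv_area / mau_to_A)
    return GFactor(value=value, wavelength=wavelength, uv_area_used=uv_area, ecd_area_used=ecd_area)


def _opposite(config: str) -> str:
    return "S" if config == "R" else "R"


def estimate_ee(
    g_mix: GFactor,
    g_pure_ref: GFactor,
    ref_config: str = "R",
    racemic_floor: float = 0.005,
) -> EEEstimate:
    """Enantiomeric excess from the mixture's and the pure reference's g.

    The linear mixing model gives ee = g_mix / g_pure: ECD is proportional
    to c_R − c_S and UV to c_R + c_S, so total concentration cancels.  A
    ratio slightly above 1 (up to 1.05) is clipped with a warning; beyond
    that the reference is declared inconsistent.

    Raises
    ------
    ValidationError
        If the two g-factors were measured at different wavelengths, or the
        reference g is zero.
    InconsistentReferenceError
        If |g_mix/g_pure| > 1.05.
    """
    if ref_config not in ("R", "S"):
        raise ValidationError("ref_config must be 'R' or 'S'")
    if abs(g_mix.wavelength - g_pure_ref.wavelength) > 1e-9:
        raise ValidationError(
            f"wavelength mismatch: g_mix at {g_mix.wavelength} nm, "
            f"reference at {g_pure_ref.wavelength} nm"
        )
    if g_pure_ref.value == 0:
        raise ValidationError("reference g must be nonzero")
    ee = g_mix.value / g_pure_ref.value
    if abs(ee) > 1.05:
        raise InconsistentReferenceError(
            f"|ee| = {abs(ee):.3f} > 1.05: the pure-enantiomer reference g is inconsistent"
        )
    if abs(ee) > 1.0:
        warnings.warn(f"|ee| = {abs(ee):.4f} slightly above 1; clipping to ±1", stacklevel=2)
        ee = math.copysign(1.0, ee)
    if ee > racemic_floor:
        dominant = ref_config
    elif ee < -racemic_floor:
        dominant = _opposite(ref_config)
    else:
        dominant = "racemic"
    return EEEstimate(
        ee=ee,
        ee_percent=min(100.0, 100.0 * abs(ee)),
        dominant=dominant,
        g_mix=g_mix.value,
        g_pure_ref=g_pure_ref.value,
    )


def conversion_ratio(
    substrate_area: float,
    product_area: float,
    response_factor: float = 1.0,
) -> ConversionResult:
    """Conversion ratio (%) by area-percent at one detection wavelength.

    ``response_factor`` is the product-to-substrate UV response ratio; the
    product area is divided by it before forming the percentage, so the
    default of 1 treats equal areas as equal amounts.
    """
    if substrate_area < 0 or product_area < 0:
        raise ValidationError("areas must be non-negative")
    if substrate_area == 0 and product_area == 0:
        raise DegenerateInputError("both areas are zero: no analyte")
    if not response_factor > 0:
        raise ValidationError("response_factor must be > 0")
    corrected = product_area / response_factor
    cr = 100.0 * corrected / (corrected + substrate_area)
    return ConversionResult(
        cr=cr,
        substrate_area=substrate_area,
        product_area=product_area,
        response_factor=response_factor,
    )


def fit_calibration(x, y) -> CalibrationFit:
    """OLS standard curve through (content, response) calibration points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValidationError("calibration needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValidationError("x values are all equal: cannot fit a line")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return CalibrationFit(
            slope=0.0,
            intercept=float(y.mean()),
            r_squared=float("nan"),
            n=n,
            residual_sd=0.0,
            x_span=float(np.ptp(x)),
            y_mean=float(y.mean()),
            r_squared_defined=False,
        )
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    ss_res = float(np.sum(resid**2))
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=1.0 - ss_res / ss_tot,
        n=n,
        residual_sd=math.sqrt(ss_res / (n - 2)),
        x_span=float(np.ptp(x)),
        y_mean=float(y.mean()),
    )


def check_linearity(
    fit: CalibrationFit,
    mode: str,
    slope_tolerance: float = 0.05,
    r2_threshold: float = 0.99,
) -> LinearityReport:
    """Validate a calibration against the method's two linearity requirements.

    ``uv-constant``: across the composition range the UV response must not
    change — passes when |slope|·span(x) < slope_tolerance·|mean(y)|.
    ``ecd-linear``: the summed ECD response must be linear in reference-
    enantiomer content — passes when R² ≥ ``r2_threshold``.
    """
    if mode == "uv-constant":
        if fit.y_mean == 0:
            passed = fit.slope == 0
            metric = math.inf if fit.slope else 0.0
        else:
            metric = abs(fit.slope) * fit.x_span / abs(fit.y_mean)
            passed = metric < slope_tolerance
        detail = f"relative UV change over range = {metric:.4g} (tolerance {slope_tolerance})"
        return LinearityReport(passed, mode, metric, slope_tolerance, detail)
    if mode == "ecd-linear":
        passed = fit.r_squared_defined and fit.r_squared >= r2_threshold
        metric = fit.r_squared
        detail = f"R^2 = {metric:.5f} (threshold {r2_threshold})"
        return LinearityReport(passed, mode, metric, r2_threshold, detail)
    raise ValidationError("mode must be 'uv-constant' or 'ecd-linear'")


def g_concentration_invariance(
    samples,
    threshold: float = 0.05,
    mean_floor: float = 1e-12,
) -> InvarianceReport:
    """Coefficient of variation of g over a pure-enantiomer dilution series.

    Concentration independence is the property that licenses ee estimation
    from a single injection; a small CV (default threshold 5%) across the
    linear range confirms it.  ``samples`` is a sequence of
    ``(concentration, GFactor-or-float)`` pairs; the population standard
    deviation is used.

    Raises
    ------
    UndefinedCVError
        If the mean g is (near) zero — a racemic series has no defined CV.
    """
    values = np.array(
        [g.value if isinstance(g, GFactor) else float(g) for _, g in samples], dtype=float
    )
    if len(values) < 3:
        raise ValidationError("need at least 3 samples for a CV")
    mean = float(values.mean())
    sd = float(values.std(ddof=0))
    if abs(mean) < mean_floor:
        raise UndefinedCVError("mean g is ~0 (racemic series): CV undefined")
    cv = sd / abs(mean)
    return InvarianceReport(cv=cv, passed=cv < threshold, n=len(values), mean_g=mean, sd_g=sd)
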