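"""Synthetic data with known ground truth for every pipeline stage.

Three generators cover the three kinds of input the method consumes:

* dual-channel chromatograms of enantiomer mixtures, on an achiral column
  (enantiomers co-elute as one product peak; ee is only accessible through
  the g-factor) or a chiral column (two resolved enantiomer peaks);
* per-conformer electronic-transition tables for a pseudo-molecule, plus
  its mirror image by strength negation;
* L9 response tables from an additive factor-effect model.

The detector model is deliberately simple: UV response proportional to
total concentration, ECD response proportional to the signed enantiomer
concentration difference scaled by the pure-enantiomer dissymmetry g_pure,
optional linear baseline drift, and multiplicative Gaussian noise per point
and channel.  With noise off, the analysis pipeline recovers the generator's
ground truth (g, ee, conversion ratio) exactly up to integration error —
the round trip the validation tests rely on.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import exponnorm

from .chromatogram import Chromatogram
from .doe import OrthogonalDesign, ResponseTable
from .ecdsim import ConformerRecord, Transition, mirror_conformers
from .exceptions import ValidationError

__all__ = [
    "MixtureSpec",
    "DetectorModel",
    "PeakShape",
    "GroundTruth",
    "EffectModel",
    "gen_chromatogram",
    "gen_transition_table",
    "gen_oa_responses",
    "ACHIRAL_SPECIES",
    "CHIRAL_SPECIES",
]

ACHIRAL_SPECIES = ("substrate", "product")
CHIRAL_SPECIES = ("substrate", "product_R", "product_S")


@dataclass(frozen=True)
class MixtureSpec:
    """Composition of an injected sample in arbitrary concentration units.

    ``f_R`` is the fraction of the reference (R) enantiomer within the
    product, so the true enantiomeric excess is ee = 2·f_R − 1.
    """

    total_conc: float
    f_R: float
    substrate_conc: float = 0.0

    def __post_init__(self) -> None:
        if not self.total_conc > 0:
            raise ValidationError("total_conc must be > 0")
        if not 0.0 <= self.f_R <= 1.0:
            raise ValidationError("f_R must lie in [0, 1]")
        if self.substrate_conc < 0:
            raise ValidationError("substrate_conc must be >= 0")

    @property
    def ee_true(self) -> float:
        return 2.0 * self.f_R - 1.0

    @property
    def c_R(self) -> float:
        return self.f_R * self.total_conc

    @property
    def c_S(self) -> float:
        return (1.0 - self.f_R) * self.total_conc


@dataclass(frozen=True)
class DetectorModel:
    """Response and noise model of the dual-channel detector.

    ``uv_response`` is an area response: mAU·min of UV peak area per
    concentration unit (peak profiles are unit-area densities, so species
    area = concentration · uv_response regardless of peak shape).
    ``g_pure`` is the dissymmetry factor of the pure reference enantiomer at
    the detection wavelength; the ECD trace of a product species is its UV
    trace times g_pure·ee·(ellipticity_to_dA/mau_to_A), so the analysis
    recovers g_pure·ee exactly in the noise-free limit.  Noise is
    multiplicative and independent per point and channel; drift is a linear
    baseline added to the UV channel.
    """

    uv_response: float = 100.0
    g_pure: float = 5.0e-3
    noise_sd_rel: float = 0.0
    baseline_drift: float = 0.0
    seed: int = 0
    ellipticity_to_dA: float = 32980.0
    mau_to_A: float = 1000.0

    def __post_init__(self) -> None:
        if not self.uv_response > 0:
            raise ValidationError("uv_response must be > 0")
        if self.noise_sd_rel < 0:
            raise ValidationError("noise_sd_rel must be >= 0")


@dataclass(frozen=True)
class PeakShape:
    """Chromatographic peak profile: Gaussian, optionally with exponential tail.

    ``rt`` is the Gaussian centre (minutes); when ``tau`` > 0 the profile is
    an exponentially modified Gaussian with tail constant ``tau`` and the
    apex shifts slightly later than ``rt``.
    """

    rt: float
    sigma_t: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma_t > 0:
            raise ValidationError("sigma_t must be > 0")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")

    def density(self, t: np.ndarray) -> np.ndarray:
        """Unit-area profile evaluated on the time grid."""
        if self.tau > 0:
            return exponnorm.pdf(t, K=self.tau / self.sigma_t, loc=self.rt, scale=self.sigma_t)
        z = (t - self.rt) / self.sigma_t
        return np.exp(-0.5 * z * z) / (self.sigma_t * math.sqrt(2.0 * math.pi))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into a chromatogram."""

    column: str
    f_R: float
    ee_true: float
    g_product: float
    cr_true: float | None
    uv_areas: Mapping[str, float]
    rts: Mapping[str, float]
    seed: int

    def to_json(self, path) -> None:
        record = {
            "column": self.column,
            "f_R": self.f_R,
            "ee_true": self.ee_true,
            "g_product": self.g_product,
            "cr_true": self.cr_true,
            "uv_areas": dict(self.uv_areas),
            "rts": dict(self.rts),
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(record, fh, indent=2, sort_keys=True)
            fh.write("\n")


#: Default peak layouts, loosely mirroring the real separations (product
#: enantiomers near 24/29 min on the chiral column) without claiming to
#: simulate the physical columns.
DEFAULT_ACHIRAL_SHAPES: dict[str, PeakShape] = {
    "substrate": PeakShape(rt=6.5, sigma_t=0.12),
    "product": PeakShape(rt=10.0, sigma_t=0.15),
}
DEFAULT_CHIRAL_SHAPES: dict[str, PeakShape] = {
    "substrate": PeakShape(rt=12.0, sigma_t=0.15),
    "product_R": PeakShape(rt=23.78, sigma_t=0.25),
    "product_S": PeakShape(rt=28.71, sigma_t=0.30),
}


def gen_chromatogram(
    mix: MixtureSpec,
    column: str = "achiral",
    shapes: Mapping[str, PeakShape] | None = None,
    detector: DetectorModel | None = None,
    duration: float = 35.0,
    step: float = 0.01,
    wavelength: float = 250.0,
    sample_id: str | None = None,
) -> tuple[Chromatogram, GroundTruth]:
    """Simulate one dual-channel injection with known ground truth.

    On the achiral column both enantiomers elute under one ``product``
    peak, so the ECD under that peak scales with c_R − c_S; on the chiral
    column ``product_R`` and ``product_S`` are resolved and carry mirror
    ECD signs.  The achiral substrate is ECD-silent.  Returns the
    chromatogram and a :class:`GroundTruth` record of what went in.
    """
    if column not in ("achiral", "chiral"):
        raise ValidationError("column must be 'achiral' or 'chiral'")
    if detector is None:
        detector = DetectorModel()
    if shapes is None:
        shapes = DEFAULT_ACHIRAL_SHAPES if column == "achiral" else DEFAULT_CHIRAL_SHAPES
    required = ACHIRAL_SPECIES if column == "achiral" else CHIRAL_SPECIES
    for species in required:
        if species not in shapes:
            raise ValidationError(f"missing peak shape for species: {species}")
    if not step > 0:
        raise ValidationError("step must be > 0")

    time = np.arange(0.0, duration + step / 2, step)
    uv = np.zeros_like(time)
    ecd = np.zeros_like(time)
    ecd_scale = detector.ellipticity_to_dA / detector.mau_to_A

    # (species, uv concentration, signed chiral concentration for ECD)
    if column == "achiral":
        plan = [
            ("substrate", mix.substrate_conc, 0.0),
            ("product", mix.total_conc, mix.c_R - mix.c_S),
        ]
    else:
        plan = [
            ("substrate", mix.substrate_conc, 0.0),
            ("product_R", mix.c_R, mix.c_R),
            ("product_S", mix.c_S, -mix.c_S),
        ]

    uv_areas: dict[str, float] = {}
    rts: dict[str, float] = {}
    for species, conc, signed_conc in plan:
        shape = shapes[species]
        rts[species] = shape.rt
        uv_areas[species] = conc * detector.uv_response
        if shape.rt - 4 * shape.sigma_t < 0 or shape.rt + 4 * shape.sigma_t > duration:
            warnings.warn(
                f"peak '{species}' at {shape.rt} min extends beyond the {duration} min run",
                stacklevel=2,
            )
        if conc == 0 and signed_conc == 0:
            continue
        profile = shape.density(time)
        uv += conc * detector.uv_response * profile
        ecd += signed_conc * detector.uv_response * detector.g_pure * ecd_scale * profile

    if detector.baseline_drift:
        uv = uv + detector.baseline_drift * time
    if detector.noise_sd_rel > 0:
        rng = np.random.default_rng(detector.seed)
        uv = uv * (1.0 + rng.normal(0.0, detector.noise_sd_rel, len(time)))
        ecd = ecd * (1.0 + rng.normal(0.0, detector.noise_sd_rel, len(time)))

    denom = mix.total_conc + mix.substrate_conc
    cr_true = 100.0 * mix.total_conc / denom if denom > 0 else None
    meta = {"column": column, "f_R": f"{mix.f_R:.9g}"}
    if sample_id is not None:
        meta["sample_id"] = sample_id
    chrom = Chromatogram(time=time, uv=uv, ecd=ecd, wavelength=wavelength, meta=meta)
    truth = GroundTruth(
        column=column,
        f_R=mix.f_R,
        ee_true=mix.ee_true,
        g_product=detector.g_pure * mix.ee_true,
        cr_true=cr_true,
        uv_areas=uv_areas,
        rts=rts,
        seed=detector.seed,
    )
    return chrom, truth


def gen_transition_table(
    n_conformers: int = 5,
    n_transitions: int = 30,
    energy_range: tuple[float, float] = (2.5, 6.5),
    strength_scale: float = 20.0,
    seed: int = 0,
    energy_spread_kcal: float = 2.0,
) -> list[ConformerRecord]:
    """Random transition tables for a pseudo-R species.

    Relative conformer energies are uniform on [0, ``energy_spread_kcal``]
    with the minimum shifted to zero; transition energies are sorted uniform
    draws over ``energy_range`` (eV) and rotational strengths are centred
    Gaussian with scale ``strength_scale`` (10⁻⁴⁰ cgs).  Feed the result to
    :func:`chirokit.ecdsim.mirror_conformers` for the pseudo-S enantiomer.
    """
    if n_conformers < 1 or n_transitions < 1:
        raise ValidationError("need at least one conformer and one transition")
    rng = np.random.default_rng(seed)
    rel = rng.uniform(0.0, energy_spread_kcal, n_conformers)
    rel = rel - rel.min()
    records = []
    for i in range(n_conformers):
        energies = np.sort(rng.uniform(energy_range[0], energy_range[1], n_transitions))
        strengths = rng.normal(0.0, strength_scale, n_transitions)
        oscillators = np.abs(rng.normal(0.0, 0.1, n_transitions))
        transitions = tuple(
            Transition(float(e), float(r), float(f))
            for e, r, f in zip(energies, strengths, oscillators)
        )
        records.append(ConformerRecord(f"conf_{i:02d}", float(rel[i]), transitions))
    return records


@dataclass(frozen=True)
class EffectModel:
    """Additive response model over an orthogonal array.

    response(run) = grand_mean + Σ_f effects[f][level(run, f) − 1] + noise,
    noise ~ N(0, noise_sd²) i.i.d. per run.
    """

    grand_mean: float
    effects: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", {k: tuple(v) for k, v in self.effects.items()})
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for f, e in self.effects.items():
            if len(e) != 3:
                raise ValidationError(f"factor {f}: exactly 3 level effects required")


def gen_oa_responses(
    design: OrthogonalDesign,
    models: Mapping[str, EffectModel],
    seed: int = 0,
) -> ResponseTable:
    """Response table from additive effect models (one per response name).

    With ``noise_sd`` = 0, range analysis recovers each factor's effect span
    and argmax level exactly — the recovery oracle for the DoE stage.
    """
    for name, model in models.items():
        for f in model.effects:
            if f not in design.factor_names:
                raise ValidationError(f"response {name}: unknown factor {f}")
    rng = np.random.default_rng(seed)
    data: dict[str, Sequence] = {"run": np.arange(1, design.n_runs + 1)}
    for f in design.factor_names:
        data[f] = design.levels_for(f)
    df = pd.DataFrame(data)
    for name, model in models.items():
        y = np.full(design.n_runs, model.grand_mean, dtype=float)
        for f, effect in model.effects.items():
            levels = design.levels_for(f)
            y += np.asarray(effect, dtype=float)[levels - 1]
        if model.noise_sd > 0:
            y = y + rng.normal(0.0, model.noise_sd, design.n_runs)
        df[name] = y
    return ResponseTable(df, tuple(design.factor_names))
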