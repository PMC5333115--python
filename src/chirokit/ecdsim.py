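"""Simulated ECD spectra from electronic-transition tables; configuration calls.

Quantum-chemistry programs emit, per conformer, a list of electronic
transitions (excitation energy E_i in eV, rotational strength R_i in
10⁻⁴⁰ cgs) plus a relative conformer energy.  This module post-processes
those tables into a Δε(λ) spectrum by the standard Gaussian band-shape
convolution,

    Δε(E) = 1 / (2.297×10⁻³⁹ · √π · σ) · Σ_i E_i · R_i · exp(−((E − E_i)/σ)²),

with σ the Gaussian band width in eV (default 0.35 eV), evaluated on a
wavelength grid via E = 1239.842/λ, and Boltzmann-averages the conformer
spectra at a chosen temperature.  The prefactor yields Δε in
L·mol⁻¹·cm⁻¹ when R_i is in cgs units; since an enantiomer's rotational
strengths are the exact negation of its mirror image's, the simulated
spectrum of the S species is −1 times that of the R species.

Absolute configuration is assigned by comparing the *sign* of the
experimental Cotton effect at one wavelength with the sign of the simulated
spectrum of the reference (R) configuration at that wavelength — a call
that is independent of the prefactor convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import IndeterminateAssignmentError, RangeError, ValidationError

__all__ = [
    "Transition",
    "ConformerRecord",
    "BandShapeParams",
    "SimulatedSpectrum",
    "ConfigurationCall",
    "boltzmann_weights",
    "simulate_ecd",
    "assign_configuration",
    "mirror_conformers",
    "read_transition_tables",
    "write_transition_tables",
    "read_spectrum",
    "write_spectrum",
    "KB_KCAL_MOL_K",
    "EV_NM",
    "CGS_PREFACTOR",
]

#: Boltzmann constant in kcal·mol⁻¹·K⁻¹.
KB_KCAL_MOL_K = 0.0019872
#: Planck·c conversion, eV·nm.
EV_NM = 1239.842
#: cgs prefactor of the Δε band shape, in (10⁻⁴⁰-free) cgs units.
CGS_PREFACTOR = 2.297e-39


@dataclass(frozen=True)
class Transition:
    """One electronic transition: energy (eV) and rotational strength (10⁻⁴⁰ cgs)."""

    energy: float
    rotational_strength: float
    oscillator_strength: float | None = None

    def __post_init__(self) -> None:
        if not self.energy > 0:
            raise ValidationError("transition energy must be > 0 eV")
        if self.oscillator_strength is not None and self.oscillator_strength < 0:
            raise ValidationError("oscillator strength must be >= 0")


@dataclass(frozen=True)
class ConformerRecord:
    """A conformer's relative energy (kcal/mol) and its transitions."""

    conformer_id: str
    relative_energy: float
    transitions: tuple[Transition, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "transitions", tuple(self.transitions))
        if len(self.transitions) == 0:
            raise ValidationError(f"conformer {self.conformer_id}: at least one transition required")
        if self.relative_energy < 0:
            raise ValidationError("relative conformer energy must be >= 0 (minimum conformer = 0)")


@dataclass(frozen=True)
class BandShapeParams:
    """Gaussian band width, wavelength grid and averaging temperature.

    ``sigma`` is the Gaussian σ in exp(−((E−E_i)/σ)²) — not a FWHM.
    """

    sigma: float = 0.35
    grid_min: float = 180.0
    grid_max: float = 400.0
    grid_step: float = 0.5
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValidationError("sigma must be > 0 eV")
        if not self.grid_min < self.grid_max:
            raise ValidationError("grid_min must be < grid_max")
        if not self.grid_step > 0:
            raise ValidationError("grid_step must be > 0")
        if not self.temperature > 0:
            raise ValidationError("temperature must be > 0 K")
        if self.grid_min <= 0:
            raise ValidationError("wavelength grid must be positive (nm)")


@dataclass(frozen=True)
class SimulatedSpectrum:
    """Δε (L·mol⁻¹·cm⁻¹) on a strictly increasing wavelength grid (nm)."""

    wavelength: np.ndarray
    delta_epsilon: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        de = np.asarray(self.delta_epsilon, dtype=float)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "delta_epsilon", de)
        if wl.shape != de.shape or wl.ndim != 1:
            raise ValidationError("wavelength and delta_epsilon must be 1-D of equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelength grid must be strictly increasing")

    def value_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated Δε at one wavelength (must lie inside the grid)."""
        if not self.wavelength[0] <= wavelength_nm <= self.wavelength[-1]:
            raise RangeError(
                f"{wavelength_nm} nm outside simulated grid "
                f"[{self.wavelength[0]}, {self.wavelength[-1]}]"
            )
        return float(np.interp(wavelength_nm, self.wavelength, self.delta_epsilon))

    def __neg__(self) -> "SimulatedSpectrum":
        return SimulatedSpectrum(self.wavelength.copy(), -self.delta_epsilon)


@dataclass(frozen=True)
class ConfigurationCall:
    """Result of a sign comparison at one wavelength."""

    configuration: str
    wavelength: float
    delta_epsilon_sim: float
    note: str


def boltzmann_weights(relative_energies: Sequence[float], temperature: float = 298.15) -> np.ndarray:
    """Normalized Boltzmann population weights from relative energies (kcal/mol).

    w_i = exp(−ΔE_i/kT) / Σ_j exp(−ΔE_j/kT), with kT = 0.0019872·T kcal/mol.
    Energies are shifted by their minimum before exponentiation, which leaves
    the weights unchanged but avoids underflow.
    """
    energies = np.asarray(relative_energies, dtype=float)
    if energies.size == 0:
        raise ValidationError("at least one energy required")
    if not temperature > 0:
        raise ValidationError("temperature must be > 0 K")
    kt = KB_KCAL_MOL_K * temperature
    shifted = energies - energies.min()
    w = np.exp(-shifted / kt)
    return w / w.sum()


def simulate_ecd(conformers: Sequence[ConformerRecord], params: BandShapeParams) -> SimulatedSpectrum:
    """Boltzmann-weighted Gaussian band convolution of conformer transition tables.

    Each transition contributes a Gaussian centred at its excitation energy,
    weighted by E_i·R_i; conformer spectra are combined with Boltzmann
    weights from their relative energies at ``params.temperature``.  The
    formula is evaluated pointwise on the wavelength grid (no discretization
    beyond the grid itself), so refining the grid never changes values at
    shared points.
    """
    if len(conformers) == 0:
        raise ValidationError("at least one conformer required")
    wl = np.arange(params.grid_min, params.grid_max + params.grid_step / 2, params.grid_step)
    energy_grid = EV_NM / wl
    weights = boltzmann_weights([c.relative_energy for c in conformers], params.temperature)
    prefactor = 1.0 / (CGS_PREFACTOR * math.sqrt(math.pi) * params.sigma)
    total = np.zeros_like(wl)
    for weight, conf in zip(weights, conformers):
        spec = np.zeros_like(wl)
        for tr in conf.transitions:
            spec += (
                tr.energy
                * (tr.rotational_strength * 1e-40)
                * np.exp(-(((energy_grid - tr.energy) / params.sigma) ** 2))
            )
        total += weight * prefactor * spec
    return SimulatedSpectrum(wavelength=wl, delta_epsilon=total)


def assign_configuration(
    experimental_sign: str,
    at_wavelength: float,
    simulated_R: SimulatedSpectrum,
    floor_abs: float = 0.0,
    floor_rel: float = 0.01,
) -> ConfigurationCall:
    """Call R or S from the Cotton-effect sign at one wavelength.

    Returns R when the experimental sign matches the sign of the simulated
    spectrum of the R configuration at ``at_wavelength``, S otherwise.  The
    simulated amplitude there must exceed a significance floor
    (``max(floor_abs, floor_rel · max|Δε|)``); a Cotton effect this weak
    cannot support a call and a different wavelength should be chosen.
    """
    if experimental_sign not in ("positive", "negative"):
        raise ValidationError("experimental_sign must be 'positive' or 'negative'")
    value = simulated_R.value_at(at_wavelength)
    scale = float(np.max(np.abs(simulated_R.delta_epsilon)))
    floor = max(floor_abs, floor_rel * scale)
    if scale == 0 or abs(value) < floor or value == 0:
        raise IndeterminateAssignmentError(
            f"simulated |delta-epsilon| = {abs(value):.3g} at {at_wavelength} nm is below the "
            f"significance floor {floor:.3g}; choose a wavelength with a stronger Cotton effect"
        )
    sim_sign = "positive" if value > 0 else "negative"
    configuration = "R" if sim_sign == experimental_sign else "S"
    note = (
        f"simulated-R delta-epsilon at {at_wavelength} nm = {value:.4g} L/(mol cm) "
        f"({sim_sign}); experimental Cotton effect {experimental_sign} -> {configuration}"
    )
    return ConfigurationCall(
        configuration=configuration,
        wavelength=at_wavelength,
        delta_epsilon_sim=value,
        note=note,
    )


def mirror_conformers(conformers: Sequence[ConformerRecord]) -> list[ConformerRecord]:
    """The enantiomer's transition tables: every rotational strength negated."""
    return [
        ConformerRecord(
            conformer_id=c.conformer_id,
            relative_energy=c.relative_energy,
            transitions=tuple(
                Transition(t.energy, -t.rotational_strength, t.oscillator_strength)
                for t in c.transitions
            ),
        )
        for c in conformers
    ]


# ---------------------------------------------------------------------------
# CSV dialects

_TT_COLUMNS = [
    "conformer_id",
    "relative_energy_kcal",
    "energy_ev",
    "rotational_strength_1e40cgs",
    "oscillator_strength",
]


def write_transition_tables(conformers: Sequence[ConformerRecord], path) -> None:
    rows = []
    for c in conformers:
        for t in c.transitions:
            rows.append(
                {
                    "conformer_id": c.conformer_id,
                    "relative_energy_kcal": c.relative_energy,
                    "energy_ev": t.energy,
                    "rotational_strength_1e40cgs": t.rotational_strength,
                    "oscillator_strength": "" if t.oscillator_strength is None else t.oscillator_strength,
                }
            )
    pd.DataFrame(rows, columns=_TT_COLUMNS).to_csv(path, index=False)


def read_transition_tables(path) -> list[ConformerRecord]:
    df = pd.read_csv(path)
    for col in _TT_COLUMNS[:4]:
        if col not in df.columns:
            raise ValidationError(f"transition table missing column: {col}")
    records = []
    for cid, grp in df.groupby("conformer_id", sort=False):
        rel = float(grp["relative_energy_kcal"].iloc[0])
        transitions = []
        for _, row in grp.iterrows():
            osc = row.get("oscillator_strength")
            osc = None if osc is None or (isinstance(osc, float) and math.isnan(osc)) else float(osc)
            transitions.append(
                Transition(
                    energy=float(row["energy_ev"]),
                    rotational_strength=float(row["rotational_strength_1e40cgs"]),
                    oscillator_strength=osc,
                )
            )
        records.append(ConformerRecord(str(cid), rel, tuple(transitions)))
    return records


def write_spectrum(spectrum: SimulatedSpectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelength, "delta_epsilon": spectrum.delta_epsilon}
    ).to_csv(path, index=False, float_format="%.9g")


def read_spectrum(path) -> SimulatedSpectrum:
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "delta_epsilon"):
        if col not in df.columns:
            raise ValidationError(f"spectrum file missing column: {col}")
    return SimulatedSpectrum(
        wavelength=df["wavelength_nm"].to_numpy(float),
        delta_epsilon=df["delta_epsilon"].to_numpy(float),
    )
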