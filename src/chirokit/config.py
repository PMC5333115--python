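"""Declarative pipeline configuration (YAML) for the command-line workflow.

A single file collects every tunable the `analyze` / `simulate-ecd`
subcommands need: detection wavelength, unit constants, peak-finding
thresholds, retention-time windows that assign peaks to species, the
pure-enantiomer reference g, and band-shape parameters.  All defaults are
embedded here and can be dumped with ``chirokit config init``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .chromatogram import PeakFindingParams
from .ecdsim import BandShapeParams
from .exceptions import ValidationError

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class PipelineConfig:
    """Everything the CLI pipeline needs, with bench-sensible defaults.

    ``windows`` maps species names to [start, end] retention-time windows
    in minutes; a detected peak is assigned to the species whose window
    contains its apex (nearest apex wins if several qualify).
    ``reference_g`` is the dissymmetry factor of the pure reference
    enantiomer; ``reference_config`` names which configuration it is.
    """

    wavelength: float = 250.0
    ellipticity_to_da: float = 32980.0
    mau_to_a: float = 1000.0
    racemic_floor: float = 0.005
    response_factor: float = 1.0
    reference_g: float | None = None
    reference_config: str = "R"
    min_height: float = 1.0
    min_prominence: float = 1.0
    baseline_mode: str = "linear-endpoints"
    smoothing_window: int = 1
    # defaults match the synthetic achiral layout (substrate 6.5 min, product 10 min)
    windows: dict = field(
        default_factory=lambda: {"substrate": [4.0, 8.5], "product": [8.5, 13.0]}
    )
    sigma: float = 0.35
    grid_min: float = 180.0
    grid_max: float = 400.0
    grid_step: float = 0.5
    temperature: float = 298.15

    def peak_params(self) -> PeakFindingParams:
        return PeakFindingParams(
            min_height=self.min_height,
            min_prominence=self.min_prominence,
            baseline_mode=self.baseline_mode,
            smoothing_window=self.smoothing_window,
        )

    def band_params(self) -> BandShapeParams:
        return BandShapeParams(
            sigma=self.sigma,
            grid_min=self.grid_min,
            grid_max=self.grid_max,
            grid_step=self.grid_step,
            temperature=self.temperature,
        )

    def validate(self) -> None:
        self.peak_params()
        self.band_params()
        if self.reference_config not in ("R", "S"):
            raise ValidationError("reference_config must be 'R' or 'S'")
        for name, window in self.windows.items():
            if len(window) != 2 or not window[0] < window[1]:
                raise ValidationError(f"window for {name} must be [start, end] with start < end")


def load_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True, default_flow_style=False)
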