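"""Per-injection analysis records and their JSON / CSV export.

One record per analyzed injection carries everything the online method
yields from a single run: conversion ratio, ee% with the dominant
configuration, and the underlying g-factors.  The writers are
deterministic (sorted keys, fixed column order, no timestamps) so repeated
runs on identical inputs produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import pandas as pd

__all__ = ["InjectionReport", "write_reports_json", "write_reports_csv", "read_reports_json"]

_CSV_COLUMNS = ["sample_id", "cr", "ee_percent", "dominant", "g_mix", "g_pure_ref", "wavelength"]


@dataclass(frozen=True)
class InjectionReport:
    """Analysis outcome of one injection; ee fields are None when no
    pure-enantiomer reference g was available."""

    sample_id: str
    cr: float | None
    ee_percent: float | None
    dominant: str | None
    g_mix: float | None
    g_pure_ref: float | None
    wavelength: float


def write_reports_json(reports, path) -> None:
    records = [asdict(r) for r in reports]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_reports_json(path) -> list[InjectionReport]:
    with open(path, "r", encoding="utf-8") as fh:
        return [InjectionReport(**rec) for rec in json.load(fh)]


def write_reports_csv(reports, path) -> None:
    df = pd.DataFrame([asdict(r) for r in reports], columns=_CSV_COLUMNS)
    df.to_csv(path, index=False)
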