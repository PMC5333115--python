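"""L9(3⁴) orthogonal-array construction and Taguchi range analysis.

A screening design for reaction optimization: nine runs accommodate up to
four three-level factors such that, for any pair of columns, every ordered
pair of levels occurs exactly once.  Here three factors are used — catalyst
loading (A), temperature (B) and reaction time (C) — and the fourth column
is retained internally as an (unreported) error column.

Range analysis summarizes each response (conversion ratio CR %, optical
purity OP %) per factor and level:

    M[f][l] = mean response over the three runs with factor f at level l
    R[f]    = max_l M[f][l] − min_l M[f][l]

Factors are ranked by descending R; the optimal combination takes, for each
factor, the level with the largest M ("higher is better" for both CR and
OP).  All arithmetic is done at full precision; rounding (half-up, two
decimals) is applied only for display, and R is always computed from the
unrounded level means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "OrthogonalDesign",
    "ResponseTable",
    "RangeAnalysisResult",
    "OptimalConditions",
    "build_L9",
    "range_analysis",
    "predict_optimal_conditions",
    "load_example_responses",
    "round_half_up",
    "L9_ARRAY",
]

#: The standard L9(3⁴) array (rows = runs, columns = factors, levels 1..3).
L9_ARRAY = np.array(
    [
        [1, 1, 1, 1],
        [1, 2, 2, 2],
        [1, 3, 3, 3],
        [2, 1, 2, 3],
        [2, 2, 3, 1],
        [2, 3, 1, 2],
        [3, 1, 3, 2],
        [3, 2, 1, 3],
        [3, 3, 2, 1],
    ],
    dtype=int,
)

#: Physical settings of the hydrosilylation screen: catalyst loading (mol %),
#: temperature (°C) and reaction time (h) at levels 1..3.
DEFAULT_LEVEL_VALUES: dict[str, tuple[float, float, float]] = {
    "A": (5.0, 10.0, 20.0),
    "B": (-10.0, 0.0, 10.0),
    "C": (8.0, 16.0, 24.0),
}

DEFAULT_FACTOR_UNITS: dict[str, str] = {"A": "mol %", "B": "degC", "C": "h"}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OrthogonalDesign:
    """An L9(3⁴) array with named factors on its leading columns.

    ``array`` is the full 9×4 level matrix; only the columns named in
    ``factor_names`` are analysed and reported, the remainder acting as
    error columns.
    """

    array: np.ndarray
    factor_names: tuple[str, ...] = ("A", "B", "C")
    level_values: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_VALUES)
    )
    factor_units: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_FACTOR_UNITS))

    def __post_init__(self) -> None:
        arr = np.asarray(self.array, dtype=int)
        object.__setattr__(self, "array", arr)
        object.__setattr__(self, "factor_names", tuple(self.factor_names))
        object.__setattr__(self, "level_values", dict(self.level_values))
        object.__setattr__(self, "factor_units", dict(self.factor_units))
        if arr.shape != (9, 4):
            raise ValidationError("L9 array must be 9x4")
        if len(self.factor_names) > 4:
            raise ValidationError("at most 4 factors on an L9 array")
        for j in range(arr.shape[1]):
            counts = np.bincount(arr[:, j], minlength=4)[1:4]
            if not np.all(counts == 3):
                raise ValidationError(f"column {j}: each level must appear exactly 3 times")
        for j in range(arr.shape[1]):
            for k in range(j + 1, arr.shape[1]):
                pairs = {(a, b) for a, b in zip(arr[:, j], arr[:, k])}
                if len(pairs) != 9:
                    raise ValidationError(
                        f"columns {j},{k}: orthogonality violated (pair coverage incomplete)"
                    )

    @property
    def n_runs(self) -> int:
        return self.array.shape[0]

    def levels_for(self, factor: str) -> np.ndarray:
        """Level column (values 1..3) for a named factor."""
        try:
            j = self.factor_names.index(factor)
        except ValueError:
            raise ValidationError(f"unknown factor: {factor}") from None
        return self.array[:, j]


def build_L9(
    factor_names: Sequence[str] = ("A", "B", "C"),
    level_values: Mapping[str, tuple[float, float, float]] | None = None,
    factor_units: Mapping[str, str] | None = None,
) -> OrthogonalDesign:
    """The standard L9(3⁴) design with the hydrosilylation factor settings.

    The default level values are catalyst 5/10/20 mol %, temperature
    −10/0/10 °C and time 8/16/24 h on factors A, B, C; the fourth column is
    kept as an error column and excluded from reporting.
    """
    return OrthogonalDesign(
        array=L9_ARRAY.copy(),
        factor_names=tuple(factor_names),
        level_values=dict(level_values) if level_values is not None else dict(DEFAULT_LEVEL_VALUES),
        factor_units=dict(factor_units) if factor_units is not None else dict(DEFAULT_FACTOR_UNITS),
    )


@dataclass(frozen=True)
class ResponseTable:
    """Nine measured responses aligned row-wise with an L9 design.

    Wraps a DataFrame with columns ``run``, one level column per factor
    (A, B, C) and one column per response (e.g. ``cr``, ``op``).
    """

    df: pd.DataFrame
    factor_names: tuple[str, ...] = ("A", "B", "C")

    def __post_init__(self) -> None:
        object.__setattr__(self, "factor_names", tuple(self.factor_names))
        df = self.df.reset_index(drop=True)
        object.__setattr__(self, "df", df)
        required = ["run", *self.factor_names]
        for col in required:
            if col not in df.columns:
                raise ValidationError(f"response table missing column: {col}")
        if len(df) != 9:
            raise ValidationError(f"L9 response table must have 9 rows, got {len(df)}")
        if not np.all(np.isfinite(df[self.response_names].to_numpy(float))):
            raise ValidationError("responses must be finite")

    @property
    def response_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("run", *self.factor_names)]

    @classmethod
    def from_csv(cls, path, factor_names: Sequence[str] = ("A", "B", "C")) -> "ResponseTable":
        return cls(pd.read_csv(path), tuple(factor_names))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def response(self, name: str) -> np.ndarray:
        if name not in self.response_names:
            raise ValidationError(f"unknown response: {name}")
        return self.df[name].to_numpy(float)


@dataclass(frozen=True)
class RangeAnalysisResult:
    """Level means M, ranges R and the derived ordering for one response.

    ``M[factor]`` is the length-3 array of level means (levels 1..3) at
    full precision; ``R[factor]`` = max(M) − min(M).  ``tie_in_R`` /
    ``tie_in_M`` flag ties resolved by the deterministic tie-breaks
    (declaration order for R, lowest level for M).
    """

    response_name: str
    factor_names: tuple[str, ...]
    M: Mapping[str, np.ndarray]
    R: Mapping[str, float]
    factor_order: tuple[str, ...]
    optimal_level: Mapping[str, int]
    optimal_combination: str
    grand_mean: float
    tie_in_R: bool
    tie_in_M: Mapping[str, bool]

    def to_dict(self, ndigits: int | None = None) -> dict:
        """JSON-ready dict; pass ``ndigits`` to apply display rounding."""

        def fmt(x: float) -> float:
            return round_half_up(x, ndigits) if ndigits is not None else float(x)

        return {
            "response": self.response_name,
            "M": {f: [fmt(v) for v in self.M[f]] for f in self.factor_names},
            "R": {f: fmt(self.R[f]) for f in self.factor_names},
            "factor_order": list(self.factor_order),
            "optimal_level": dict(self.optimal_level),
            "optimal_combination": self.optimal_combination,
            "grand_mean": fmt(self.grand_mean),
            "tie_in_R": self.tie_in_R,
            "tie_in_M": dict(self.tie_in_M),
        }

    def to_json(self, path, ndigits: int | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(ndigits), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def summary(self) -> str:
        """Human-readable range-analysis table (two-decimal display rounding)."""
        lines = [f"Range analysis of response '{self.response_name}'"]
        header = "        " + "".join(f"{f:>10}" for f in self.factor_names)
        lines.append(header)
        for lvl in (1, 2, 3):
            row = f"M{lvl}      " + "".join(
                f"{round_half_up(self.M[f][lvl - 1]):>10.2f}" for f in self.factor_names
            )
            lines.append(row)
        lines.append(
            "R       " + "".join(f"{round_half_up(self.R[f]):>10.2f}" for f in self.factor_names)
        )
        lines.append("Factor order: " + " > ".join(self.factor_order))
        lines.append(
            "Optimal level: "
            + "  ".join(f"{f}{self.optimal_level[f]}" for f in self.factor_names)
        )
        lines.append(f"Optimal combination: {self.optimal_combination}")
        if self.tie_in_R or any(self.tie_in_M.values()):
            lines.append("(ties resolved deterministically; see tie flags)")
        return "\n".join(lines)


def range_analysis(
    design: OrthogonalDesign,
    responses: ResponseTable,
    response_name: str,
) -> RangeAnalysisResult:
    """Taguchi range analysis of one response over an L9 design.

    Raises :class:`ValidationError` when the response table's level columns
    do not match the design row-for-row.
    """
    if tuple(responses.factor_names) != tuple(design.factor_names):
        raise ValidationError("factor names of design and response table differ")
    resp_rows = sorted(
        map(tuple, responses.df[list(design.factor_names)].to_numpy(int))
    )
    cols = [design.factor_names.index(f) for f in design.factor_names]
    design_rows = sorted(map(tuple, design.array[:, cols]))
    if resp_rows != design_rows:
        raise ValidationError("response-table levels do not match the design runs")
    y = responses.response(response_name)
    M: dict[str, np.ndarray] = {}
    R: dict[str, float] = {}
    optimal_level: dict[str, int] = {}
    tie_in_M: dict[str, bool] = {}
    for f in design.factor_names:
        levels = responses.df[f].to_numpy(int)
        means = np.array([y[levels == lvl].mean() for lvl in (1, 2, 3)])
        M[f] = means
        R[f] = float(means.max() - means.min())
        best = int(np.argmax(means)) + 1  # argmax returns the lowest level on ties
        optimal_level[f] = best
        others = np.delete(means, best - 1)
        tie_in_M[f] = bool(np.any(np.isclose(others, means[best - 1], rtol=1e-12, atol=1e-12)))
    # stable sort by descending R preserves declaration order on ties
    factor_order = tuple(sorted(design.factor_names, key=lambda f: -R[f]))
    r_values = np.array([R[f] for f in design.factor_names])
    tie_in_R = bool(
        len(r_values) > 1
        and np.any(np.isclose(np.diff(np.sort(r_values)), 0.0, rtol=1e-12, atol=1e-12))
    )
    combination = "".join(f"{f}{optimal_level[f]}" for f in design.factor_names)
    return RangeAnalysisResult(
        response_name=response_name,
        factor_names=tuple(design.factor_names),
        M=M,
        R=R,
        factor_order=factor_order,
        optimal_level=optimal_level,
        optimal_combination=combination,
        grand_mean=float(y.mean()),
        tie_in_R=tie_in_R,
        tie_in_M=tie_in_M,
    )


@dataclass(frozen=True)
class OptimalConditions:
    """Physical settings for the optimal combination, with run-coverage flag."""

    combination: str
    settings: Mapping[str, float]
    units: Mapping[str, str]
    present_in_runs: bool
    matching_run: int | None

    def describe(self) -> str:
        parts = [
            f"{f} = {self.settings[f]:g} {self.units.get(f, '')}".strip()
            for f in self.settings
        ]
        where = (
            f"appears in the executed runs (run {self.matching_run})"
            if self.present_in_runs
            else "did not appear among the executed runs"
        )
        return f"{self.combination}: " + ", ".join(parts) + f" — {where}"


def predict_optimal_conditions(
    result: RangeAnalysisResult, design: OrthogonalDesign
) -> OptimalConditions:
    """Map optimal levels to physical settings and flag run coverage.

    The best combination identified by range analysis need not be one of
    the nine executed runs; the flag records whether it was.
    """
    settings = {}
    for f in result.factor_names:
        lvl = result.optimal_level[f]
        values = design.level_values.get(f)
        settings[f] = float(values[lvl - 1]) if values is not None else float(lvl)
    target = np.array([result.optimal_level[f] for f in result.factor_names])
    cols = [design.factor_names.index(f) for f in result.factor_names]
    matching_run = None
    for i in range(design.n_runs):
        if np.array_equal(design.array[i, cols], target):
            matching_run = i + 1
            break
    return OptimalConditions(
        combination=result.optimal_combination,
        settings=settings,
        units=dict(design.factor_units),
        present_in_runs=matching_run is not None,
        matching_run=matching_run,
    )


def load_example_responses() -> ResponseTable:
    """The packaged 9-run hydrosilylation response table (CR % and OP %).

    Conversion ratio and optical purity measured online for the nine runs of
    the L9 catalyst/temperature/time screen; the values are instrument data
    shipped as a fixture, not quantities the package can recompute.
    """
    path = resources.files("chirokit").joinpath("data/l9_hydrosilylation.csv")
    with resources.as_file(path) as p:
        return ResponseTable.from_csv(p)
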