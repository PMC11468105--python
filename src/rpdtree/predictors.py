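"""Typed predictor tables and ten-year change coding.

Predictors are ordinal, nominal or continuous, each with a direction
(whether higher values are better).  For variables measured at two
waves, the change between waves is coded in two interchangeable
representations:

* three-level ordinal: worsened (-1) < unchanged (0) < improved (+1),
  the sign of (wave2 - wave1) mapped through the variable's direction;
* raw difference: wave2 - wave1 as a numeric column.

Short ordinal scales default to the three-level coding, wide score
scales to the raw difference (so a tree can cut inside the score
range).  A change value is missing whenever either wave is missing —
notably for every subject who died before the second wave.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ContractError, SchemaError, ValidationError

__all__ = [
    "VariableSpec",
    "PredictorTable",
    "code_change",
    "build_feature_table",
    "read_variable_specs",
    "write_variable_specs",
    "WORSENED",
    "UNCHANGED",
    "IMPROVED",
]

KINDS = ("ordinal", "nominal", "continuous")
DIRECTIONS = ("higher_is_better", "higher_is_worse", "undirected")
WAVES = ("baseline_only", "both_waves")
CHANGE_REPRESENTATIONS = ("auto", "three_level", "difference")

# ordered three-level change coding: worsened < unchanged < improved
WORSENED, UNCHANGED, IMPROVED = -1.0, 0.0, 1.0

#: ordinal scales with at most this many levels get the three-level
#: change coding under representation="auto"; wider scales get the raw
#: difference
AUTO_THREE_LEVEL_MAX_LEVELS = 5


@dataclass(frozen=True)
class VariableSpec:
    """Type, direction and wave availability of one predictor."""

    name: str
    kind: str
    direction: str = "undirected"
    waves: str = "baseline_only"
    minimum: float | None = None
    maximum: float | None = None
    levels: tuple = ()  # nominal category labels, if enumerated

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValidationError(f"{self.name}: unknown kind {self.kind!r}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"{self.name}: unknown direction {self.direction!r}")
        if self.waves not in WAVES:
            raise ValidationError(f"{self.name}: unknown waves {self.waves!r}")
        if self.waves == "both_waves" and self.kind == "nominal":
            raise ValidationError(f"{self.name}: nominal variables are never change-coded")
        if self.waves == "both_waves" and self.direction == "undirected":
            raise ValidationError(
                f"{self.name}: change coding requires a direction (higher_is_better/worse)"
            )

    @property
    def n_levels(self) -> float:
        if self.minimum is None or self.maximum is None:
            return float("inf")
        return self.maximum - self.minimum + 1


@dataclass
class PredictorTable:
    """Subjects x variables matrix with per-column specs.

    ``data`` holds numeric columns (float, NaN = missing) for ordinal
    and continuous variables and object/string columns (NaN/None =
    missing) for nominal ones.
    """

    data: pd.DataFrame
    specs: dict[str, VariableSpec] = field(default_factory=dict)

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate predictor column names")
        unknown = [c for c in self.data.columns if c not in self.specs]
        if unknown:
            raise ValidationError(f"columns without a VariableSpec: {unknown}")
        for name, spec in self.specs.items():
            if name not in self.data.columns:
                raise ValidationError(f"spec for absent column {name!r}")
            col = self.data[name]
            if spec.kind == "nominal":
                continue
            vals = pd.to_numeric(col, errors="coerce")
            if (vals.isna() & col.notna()).any():
                raise ValidationError(f"{name}: non-numeric value in a {spec.kind} column")
            if spec.minimum is not None and (vals < spec.minimum).any():
                raise ValidationError(f"{name}: value below declared minimum {spec.minimum}")
            if spec.maximum is not None and (vals > spec.maximum).any():
                raise ValidationError(f"{name}: value above declared maximum {spec.maximum}")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def kinds(self) -> dict[str, str]:
        return {c: self.specs[c].kind for c in self.columns}


def code_change(spec: VariableSpec, wave1, wave2) -> float:
    """Three-level change for one subject: -1 worsened, 0 unchanged, +1 improved.

    Missing (NaN) whenever either wave is missing.  The sign of
    (wave2 - wave1) is mapped through the variable's direction, so an
    increase in a higher-is-worse score counts as worsening.
    """
    if spec.kind == "nominal":
        raise ContractError(f"{spec.name}: nominal variables cannot be change-coded")
    if spec.direction == "undirected":
        raise ContractError(f"{spec.name}: change coding requires a direction")
    if spec.waves != "both_waves":
        raise ContractError(f"{spec.name}: variable is not measured at both waves")
    if pd.isna(wave1) or pd.isna(wave2):
        return float("nan")
    diff = float(wave2) - float(wave1)
    if diff == 0:
        return UNCHANGED
    improved = diff > 0 if spec.direction == "higher_is_better" else diff < 0
    return IMPROVED if improved else WORSENED


def _change_spec(spec: VariableSpec, three_level: bool) -> VariableSpec:
    if three_level:
        return VariableSpec(
            name=f"{spec.name}_change",
            kind="ordinal",
            direction="higher_is_better",
            minimum=WORSENED,
            maximum=IMPROVED,
        )
    lo = hi = None
    if spec.minimum is not None and spec.maximum is not None:
        lo, hi = spec.minimum - spec.maximum, spec.maximum - spec.minimum
    return VariableSpec(
        name=f"{spec.name}_change",
        kind="continuous",
        direction=spec.direction,
        minimum=lo,
        maximum=hi,
    )


def build_feature_table(
    wave1: PredictorTable,
    mode: str,
    wave2: pd.DataFrame | None = None,
    representation: str = "auto",
) -> PredictorTable:
    """Assemble the analysis feature matrix.

    ``mode="baseline_only"`` returns the baseline columns verbatim.
    ``mode="baseline_plus_changes"`` appends one change column per
    change-eligible (both-waves, directed, non-nominal) variable; all
    baseline subjects are retained, with missing change values for
    anyone lacking a wave-2 measurement.  ``representation`` selects
    three-level vs raw-difference change coding ("auto" picks
    three-level for ordinal scales with at most
    ``AUTO_THREE_LEVEL_MAX_LEVELS`` levels).
    """
    if mode not in ("baseline_only", "baseline_plus_changes"):
        raise ContractError(f"unknown mode {mode!r}")
    if representation not in CHANGE_REPRESENTATIONS:
        raise ContractError(f"unknown change representation {representation!r}")
    if mode == "baseline_only":
        return PredictorTable(wave1.data.copy(), dict(wave1.specs))

    eligible = [s for s in wave1.specs.values() if s.waves == "both_waves"]
    if eligible and wave2 is None:
        raise ContractError("baseline_plus_changes requires wave-2 measurements")
    data = wave1.data.copy()
    specs = dict(wave1.specs)
    for spec in eligible:
        if spec.name not in (wave2.columns if wave2 is not None else []):
            raise ContractError(f"wave-2 column missing for {spec.name!r}")
        w1 = wave1.data[spec.name]
        w2 = wave2[spec.name].reindex(wave1.data.index)
        if representation == "three_level":
            three = True
        elif representation == "difference":
            three = False
        else:
            three = spec.kind == "ordinal" and spec.n_levels <= AUTO_THREE_LEVEL_MAX_LEVELS
        if three:
            vals = [code_change(spec, a, b) for a, b in zip(w1, w2)]
            col = pd.Series(vals, index=wave1.data.index, dtype=float)
        else:
            col = pd.to_numeric(w2, errors="coerce") - pd.to_numeric(w1, errors="coerce")
        cs = _change_spec(spec, three)
        data[cs.name] = col
        specs[cs.name] = cs
    return PredictorTable(data, specs)


# -- spec sheet IO --------------------------------------------------------

_SPEC_COLS = ("name", "kind", "direction", "waves", "min", "max")


def read_variable_specs(path, delimiter: str | None = None) -> dict[str, VariableSpec]:
    """Read the variable-specification sheet (CSV: name, kind, direction, waves, min, max)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"variable spec sheet not found: {path}")
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    missing = [c for c in ("name", "kind") if c not in df.columns]
    if missing:
        raise SchemaError(f"spec sheet lacks columns: {missing}")
    specs = {}
    for _, row in df.iterrows():
        name = str(row["name"])
        specs[name] = VariableSpec(
            name=name,
            kind=str(row["kind"]),
            direction=str(row.get("direction", "undirected") or "undirected"),
            waves=str(row.get("waves", "baseline_only") or "baseline_only"),
            minimum=None if pd.isna(row.get("min")) else float(row["min"]),
            maximum=None if pd.isna(row.get("max")) else float(row["max"]),
        )
    return specs


def write_variable_specs(specs: dict[str, VariableSpec], path) -> None:
    pd.DataFrame(
        [
            {
                "name": s.name,
                "kind": s.kind,
                "direction": s.direction,
                "waves": s.waves,
                "min": s.minimum,
                "max": s.maximum,
            }
            for s in specs.values()
        ]
    ).to_csv(path, index=False)
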