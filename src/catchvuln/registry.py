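"""Canonical variable registry and catchment-table I/O.

Every other module takes its variable names, roles, scoring directions and
zero rules from :func:`default_registry`.  A catchment table is a plain
:class:`pandas.DataFrame` with one row per HUC12 catchment, a ``huc12_id``
column, a ``play`` column, optionally ``area_km2``, and one column per
registered variable.  Well-proximity variables are undefined in catchments
without wells and are stored as NaN (empty field in CSV).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SENSITIVITY = "sensitivity"
EXPOSURE = "exposure"

HIGHER_IS_WORSE = "higher_is_worse"
LOWER_IS_WORSE = "lower_is_worse"

QUARTILE = "quartile"
FIXED_BREAKPOINTS = "fixed_breakpoints"

ZERO_SCORES_ZERO = "zero_scores_zero"
UNDEFINED_WHEN_ABSENT = "undefined_when_absent"

ID_COLUMNS = ("huc12_id", "play")

#: percentage-valued variables, bounded to [0, 100]
PERCENT_VARIABLES = frozenset(
    {
        "pct_forest_grassland",
        "pct_wetlands",
        "pct_unconsolidated",
        "pct_crops",
        "pct_impervious",
        "pct_pasture",
    }
)

#: (proximity variable, matching well-density variable)
PROXIMITY_PAIRS = (
    ("vertical_well_proximity", "vertical_well_density"),
    ("nonvertical_well_proximity", "nonvertical_well_density"),
)


@dataclasses.dataclass(frozen=True)
class VariableSpec:
    """Scoring contract for one catchment variable.

    Parameters
    ----------
    name
        Canonical column name.
    role
        ``"sensitivity"`` (natural characteristic) or ``"exposure"``
        (anthropogenic stressor).
    direction
        ``"higher_is_worse"`` maps larger values to larger scores;
        ``"lower_is_worse"`` mirrors the mapping (used for precipitation and
        well-to-flowline proximity, where small values mean more stress).
    method
        ``"quartile"`` scores against pooled empirical quartiles;
        ``"fixed_breakpoints"`` scores against literature-style fixed bins.
    zero_rule
        ``"zero_scores_zero"``: a value of exactly zero scores 0 and zeros
        stay in the quartile pool.  ``"undefined_when_absent"``: the value may
        be absent (NaN); absent entries score 0 and are dropped from the pool.
    breakpoints
        Ascending 4-tuple ``(b0, b1, b2, b3)`` for ``fixed_breakpoints``:
        score 0 for v <= b0, then 1 for (b0, b1], 2 for (b1, b2],
        3 for (b2, b3], 4 above b3.
    """

    name: str
    role: str
    direction: str = HIGHER_IS_WORSE
    method: str = QUARTILE
    zero_rule: str = ZERO_SCORES_ZERO
    breakpoints: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.role not in (SENSITIVITY, EXPOSURE):
            raise ValueError(f"unknown role {self.role!r}")
        if self.direction not in (HIGHER_IS_WORSE, LOWER_IS_WORSE):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.method not in (QUARTILE, FIXED_BREAKPOINTS):
            raise ValueError(f"unknown method {self.method!r}")
        if self.zero_rule not in (ZERO_SCORES_ZERO, UNDEFINED_WHEN_ABSENT):
            raise ValueError(f"unknown zero_rule {self.zero_rule!r}")
        if (self.breakpoints is not None) != (self.method == FIXED_BREAKPOINTS):
            raise ValueError("breakpoints present iff method is fixed_breakpoints")
        if self.breakpoints is not None:
            bp = tuple(float(b) for b in self.breakpoints)
            if len(bp) != 4 or any(a >= b for a, b in zip(bp, bp[1:])):
                raise ValueError("breakpoints must be a strictly ascending 4-tuple")
            object.__setattr__(self, "breakpoints", bp)


def default_registry() -> dict[str, VariableSpec]:
    """The 7 sensitivity + 10 exposure variable specs used throughout.

    Precipitation and both well-proximity variables are inverted
    (``lower_is_worse``); impervious, crop and pasture cover use fixed
    breakpoints (implementation defaults, overridable in config — the
    literature values behind the original index are not published with it);
    proximity variables are undefined where the matching well density is
    zero.  All other variables use pooled quartiles with zero scoring zero.
    """
    specs = [
        # --- natural sensitivity -------------------------------------------
        VariableSpec("precipitation", SENSITIVITY, direction=LOWER_IS_WORSE),
        VariableSpec("pct_forest_grassland", SENSITIVITY),
        VariableSpec("pct_wetlands", SENSITIVITY),
        VariableSpec("stream_density", SENSITIVITY),
        VariableSpec("mean_slope", SENSITIVITY),
        VariableSpec("soil_erodibility", SENSITIVITY),
        VariableSpec("pct_unconsolidated", SENSITIVITY),
        # --- anthropogenic exposure ----------------------------------------
        VariableSpec("vertical_well_density", EXPOSURE),
        VariableSpec(
            "vertical_well_proximity",
            EXPOSURE,
            direction=LOWER_IS_WORSE,
            zero_rule=UNDEFINED_WHEN_ABSENT,
        ),
        VariableSpec("nonvertical_well_density", EXPOSURE),
        VariableSpec(
            "nonvertical_well_proximity",
            EXPOSURE,
            direction=LOWER_IS_WORSE,
            zero_rule=UNDEFINED_WHEN_ABSENT,
        ),
        VariableSpec("road_density", EXPOSURE),
        VariableSpec("mine_density", EXPOSURE),
        VariableSpec("dam_density", EXPOSURE),
        VariableSpec(
            "pct_crops",
            EXPOSURE,
            method=FIXED_BREAKPOINTS,
            breakpoints=(0.0, 25.0, 50.0, 75.0),
        ),
        VariableSpec(
            "pct_impervious",
            EXPOSURE,
            method=FIXED_BREAKPOINTS,
            breakpoints=(0.0, 1.0, 5.0, 10.0),
        ),
        VariableSpec(
            "pct_pasture",
            EXPOSURE,
            method=FIXED_BREAKPOINTS,
            breakpoints=(0.0, 25.0, 50.0, 75.0),
        ),
    ]
    return {s.name: s for s in specs}


def variable_names(
    registry: dict[str, VariableSpec] | None = None, role: str | None = None
) -> list[str]:
    """Registered variable names, optionally filtered by role, in canonical order."""
    registry = registry if registry is not None else default_registry()
    return [n for n, s in registry.items() if role is None or s.role == role]


@dataclasses.dataclass(frozen=True)
class Diagnostic:
    """One row-level validation failure: which row, which field, what's wrong."""

    row: int | str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}, field {self.field}: {self.message}"


def validate_table(
    table: pd.DataFrame, registry: dict[str, VariableSpec] | None = None
) -> list[Diagnostic]:
    """Check a catchment table against the structural invariants.

    Returns one :class:`Diagnostic` per violating (row, field); an empty
    list means the table is valid.  Checked: required columns present,
    densities/distances non-negative, percentages within [0, 100],
    precipitation strictly positive, and proximity defined exactly where the
    matching well density is non-zero.
    """
    registry = registry if registry is not None else default_registry()
    diags: list[Diagnostic] = []

    required = list(ID_COLUMNS) + list(registry)
    missing = [c for c in required if c not in table.columns]
    for col in missing:
        diags.append(Diagnostic("<table>", col, "missing column"))
    if missing:
        return diags

    def _flag(mask: pd.Series, field: str, message: str) -> None:
        for idx in table.index[mask.fillna(False)]:
            diags.append(Diagnostic(idx, field, message))

    for name, spec in registry.items():
        col = pd.to_numeric(table[name], errors="coerce")
        if spec.zero_rule != UNDEFINED_WHEN_ABSENT:
            _flag(table[name].isna(), name, "value missing")
        _flag(col < 0, name, "negative value")
        if name in PERCENT_VARIABLES:
            _flag(col > 100, name, "percentage above 100")
    if "precipitation" in registry:
        precip = pd.to_numeric(table["precipitation"], errors="coerce")
        _flag(precip <= 0, "precipitation", "must be strictly positive")
    if "area_km2" in table.columns:
        _flag(pd.to_numeric(table["area_km2"], errors="coerce") <= 0, "area_km2",
              "area must be positive")

    for prox, dens in PROXIMITY_PAIRS:
        if prox in registry and dens in registry:
            d = pd.to_numeric(table[dens], errors="coerce")
            p = table[prox]
            _flag(p.notna() & (d == 0), prox, "proximity present with zero well density")
            _flag(p.isna() & (d > 0), prox, "proximity absent with non-zero well density")

    dup = table["huc12_id"].duplicated()
    _flag(dup, "huc12_id", "duplicate identifier")
    return diags


def read_catchment_table(
    path: str | Path,
    registry: dict[str, VariableSpec] | None = None,
    on_invalid: str = "raise",
) -> pd.DataFrame:
    """Read and validate a catchment CSV.

    ``on_invalid="raise"`` raises :class:`ValueError` listing every
    diagnostic; ``"drop"`` silently drops violating rows and returns the
    rest (the diagnostics are attached as ``df.attrs["diagnostics"]``).
    Lines starting with ``#`` (run metadata headers) are ignored.
    """
    if on_invalid not in ("raise", "drop"):
        raise ValueError("on_invalid must be 'raise' or 'drop'")
    registry = registry if registry is not None else default_registry()
    table = pd.read_csv(path, comment="#", dtype={"huc12_id": str, "play": str})
    diags = validate_table(table, registry)
    if diags and on_invalid == "raise":
        listing = "\n".join(str(d) for d in diags[:50])
        raise ValueError(f"{len(diags)} invalid entries in {path}:\n{listing}")
    if diags:
        bad_rows = {d.row for d in diags if not isinstance(d.row, str)}
        table = table.drop(index=sorted(bad_rows))
    table.attrs["diagnostics"] = diags
    return table.reset_index(drop=True)


def write_catchment_table(
    table: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    """Write a catchment table as CSV, with optional ``# key=value`` header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        table.to_csv(fh, index=False)
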