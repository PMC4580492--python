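"""Quartile-based 0-4 scoring, totals S / E / V, and collinearity screening.

Each variable is scored 0-4 against the 25th/50th/75th percentiles of its
pooled values across *all* catchments in the table (all plays together).
For ``higher_is_worse`` variables with the ``zero_scores_zero`` rule, an
exact zero scores 0, values up to the 25th percentile score 1, and so on up
to 4 above the 75th percentile; bin edges are upper-inclusive.  Inverted
(``lower_is_worse``) variables mirror the mapping so the smallest present
values score 4; score 0 is reserved for absent entries (a catchment with no
wells contributes 0 to exposure through the proximity variables).

Totals: sensitivity S is the sum of the seven sensitivity scores (0-28),
exposure E the sum of the ten exposure scores (0-40), and vulnerability
V = S * E (0-1120).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .registry import (
    EXPOSURE,
    FIXED_BREAKPOINTS,
    HIGHER_IS_WORSE,
    LOWER_IS_WORSE,
    SENSITIVITY,
    UNDEFINED_WHEN_ABSENT,
    ZERO_SCORES_ZERO,
    VariableSpec,
    default_registry,
    variable_names,
)

SCORE_COLUMNS = ("S", "E", "V")


@dataclasses.dataclass(frozen=True)
class Breakpoints:
    """Empirical quartile breaks of one variable's pooled distribution."""

    q25: float
    q50: float
    q75: float

    def __post_init__(self) -> None:
        if not self.q25 <= self.q50 <= self.q75:
            raise ValueError("quartiles must be non-decreasing")


def compute_breakpoints(values, zero_rule: str = ZERO_SCORES_ZERO) -> Breakpoints:
    """25/50/75th percentiles (sorted linear interpolation) of the pooled values.

    ``zero_scores_zero`` keeps zeros in the pool; ``undefined_when_absent``
    drops missing (NaN) entries before pooling.  Requires at least four
    usable values.
    """
    pool = np.asarray(values, dtype=float)
    if zero_rule == UNDEFINED_WHEN_ABSENT:
        pool = pool[~np.isnan(pool)]
    elif np.isnan(pool).any():
        raise ValueError("missing value under zero_scores_zero")
    if pool.size < 4:
        raise ValueError(f"need at least 4 usable values, got {pool.size}")
    q25, q50, q75 = np.percentile(pool, [25.0, 50.0, 75.0])
    return Breakpoints(float(q25), float(q50), float(q75))


def score_variable(
    values, spec: VariableSpec, breaks: Breakpoints | None = None
) -> np.ndarray:
    """Integer 0-4 scores for one variable.

    For ``method="quartile"``, ``breaks`` must be supplied; for
    ``method="fixed_breakpoints"`` the spec's own breakpoints are used.
    """
    v = np.asarray(values, dtype=float)
    absent = np.isnan(v)
    if spec.zero_rule == ZERO_SCORES_ZERO and absent.any():
        raise ValueError(f"{spec.name}: absent value under zero_scores_zero")
    if np.nanmin(v, initial=0.0) < 0:
        raise ValueError(f"{spec.name}: negative value")

    if spec.method == FIXED_BREAKPOINTS:
        b0, b1, b2, b3 = spec.breakpoints
        edges = np.array([b0, b1, b2, b3])
        filled = np.where(absent, 0.0, v)
        # upper-inclusive bins: v <= b0 -> 0, (b0,b1] -> 1, ..., > b3 -> 4
        scores = _count_edges_exceeded(filled, edges)
    else:
        if breaks is None:
            raise ValueError(f"{spec.name}: quartile scoring needs breakpoints")
        edges = np.array([breaks.q25, breaks.q50, breaks.q75])
        filled = np.where(absent, 0.0, v)
        if spec.direction == HIGHER_IS_WORSE:
            # 0 -> 0; (0, q25] -> 1; (q25, q50] -> 2; (q50, q75] -> 3; > q75 -> 4
            scores = 1 + _count_edges_exceeded(filled, edges)
            scores = np.where(filled == 0.0, 0, scores)
        else:
            # mirrored: smallest present values -> 4, values above q75 -> 1
            scores = 4 - _count_edges_exceeded(filled, edges)
    scores = np.where(absent, 0, scores)
    return scores.astype(np.int64)


def _count_edges_exceeded(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Per value: how many (ascending) edges it strictly exceeds.

    Upper-inclusive binning: a value exactly at an edge does not exceed it
    and takes the lower bin.
    """
    return (values[:, None] > edges[None, :]).sum(axis=1)


def breakpoints_for_table(
    table: pd.DataFrame, registry: dict[str, VariableSpec] | None = None
) -> dict[str, Breakpoints]:
    """Pooled quartile breaks per quartile-scored variable of a catchment table."""
    registry = registry if registry is not None else default_registry()
    return {
        name: compute_breakpoints(table[name].to_numpy(dtype=float), spec.zero_rule)
        for name, spec in registry.items()
        if spec.method != FIXED_BREAKPOINTS
    }


def score_table(
    table: pd.DataFrame,
    registry: dict[str, VariableSpec] | None = None,
    breakpoints: dict[str, Breakpoints] | None = None,
) -> pd.DataFrame:
    """Score every registered variable for every catchment and total S, E, V.

    Returns a frame with ``huc12_id``, ``play``, one 0-4 score column per
    variable, and ``S``, ``E``, ``V``.  Pass ``breakpoints`` to score a table
    against breaks computed elsewhere (e.g. a partial rerun); by default they
    are computed from this table's pooled values.
    """
    registry = registry if registry is not None else default_registry()
    if breakpoints is None:
        breakpoints = breakpoints_for_table(table, registry)
    missing = [n for n in registry if n not in table.columns]
    if missing:
        raise ValueError(f"missing variable columns: {missing}")

    out = table[["huc12_id", "play"]].copy()
    for name, spec in registry.items():
        out[name] = score_variable(
            table[name].to_numpy(dtype=float), spec, breakpoints.get(name)
        )
    return total_scores(out, registry)


def total_scores(
    scores: pd.DataFrame, registry: dict[str, VariableSpec] | None = None
) -> pd.DataFrame:
    """Fill S (sensitivity sum), E (exposure sum) and V = S * E from per-variable scores."""
    registry = registry if registry is not None else default_registry()
    missing = [n for n in registry if n not in scores.columns]
    if missing:
        raise ValueError(f"missing score columns: {missing}")
    out = scores.copy()
    sens = variable_names(registry, SENSITIVITY)
    expo = variable_names(registry, EXPOSURE)
    out["S"] = out[sens].sum(axis=1)
    out["E"] = out[expo].sum(axis=1)
    out["V"] = out["S"] * out["E"]
    return out


@dataclasses.dataclass(frozen=True)
class CorrelationFlag:
    """One flagged variable pair: |Spearman rho| above the screening threshold."""

    var_a: str
    var_b: str
    rho: float
    n: int


def screen_correlations(
    table: pd.DataFrame,
    threshold: float = 0.6,
    registry: dict[str, VariableSpec] | None = None,
) -> list[CorrelationFlag]:
    """Flag variable pairs with |Spearman rho| > threshold (reporting only).

    Rows where either variable is missing are dropped pairwise; pairs with
    fewer than 3 complete rows or a constant variable (rho undefined) are
    skipped.  Dropping a flagged variable is a configuration action, not done
    here.
    """
    registry = registry if registry is not None else default_registry()
    names = [n for n in variable_names(registry) if n in table.columns]
    flags: list[CorrelationFlag] = []
    for a, b in itertools.combinations(names, 2):
        pair = table[[a, b]].dropna()
        if len(pair) < 3:
            continue
        xa, xb = pair[a].to_numpy(float), pair[b].to_numpy(float)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            continue  # constant variable: rho undefined
        rho = stats.spearmanr(xa, xb).statistic
        if abs(rho) > threshold:
            flags.append(CorrelationFlag(a, b, float(rho), len(pair)))
    return flags
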