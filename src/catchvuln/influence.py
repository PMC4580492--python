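"""Variable-removal influence analysis and the UOG-only variant.

How much does any one variable drive a catchment's sensitivity or exposure
total?  Removing a variable can only subtract its non-negative score, so the
per-catchment effect is the percent change of the role total:

    pct_change = (original - modified) / original * 100

computed against S for sensitivity removals and against E for exposure
removals, then summarised per play as mean and standard deviation.
Catchments whose original role total is 0 are excluded (the change is
undefined there) and counted.

The UOG-only variant restricts exposure to the two unconventional-well
variables (non-vertical well density and proximity — non-vertical wells
proxy unconventional development) and recomputes vulnerability against the
unchanged sensitivity score.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .registry import SENSITIVITY, VariableSpec, default_registry, variable_names

#: the four well-related exposure variables removed together as "all UOG metrics"
UOG_VARIABLES = (
    "vertical_well_density",
    "vertical_well_proximity",
    "nonvertical_well_density",
    "nonvertical_well_proximity",
)

#: exposure variables defining the UOG-only exposure score
UOG_ONLY_VARIABLES = ("nonvertical_well_density", "nonvertical_well_proximity")

WELL_DENSITY_VARIABLES = ("vertical_well_density", "nonvertical_well_density")


def removal_effect(
    scores: pd.DataFrame,
    variables: str | Sequence[str],
    registry: dict[str, VariableSpec] | None = None,
) -> pd.DataFrame:
    """Per-play mean and SD of percent change when variable(s) are removed.

    ``variables`` may be one name or several of the *same role* (several are
    removed simultaneously, e.g. all four well metrics).  Returns a frame
    keyed by play with columns ``variable, role, mean_pct_change,
    sd_pct_change, n_included, n_excluded`` plus an ``All`` row pooling every
    catchment.
    """
    registry = registry if registry is not None else default_registry()
    if isinstance(variables, str):
        variables = [variables]
    variables = list(variables)
    unknown = [v for v in variables if v not in registry]
    if unknown:
        raise KeyError(f"unknown variable(s): {unknown}")
    roles = {registry[v].role for v in variables}
    if len(roles) != 1:
        raise ValueError("variables removed together must share a role")
    role = roles.pop()
    total_col = "S" if role == SENSITIVITY else "E"

    original = scores[total_col].to_numpy(dtype=float)
    removed = scores[variables].sum(axis=1).to_numpy(dtype=float)
    included = original > 0
    pct = np.full(len(scores), np.nan)
    pct[included] = (removed[included] / original[included]) * 100.0

    label = "+".join(variables)
    rows = []
    groups = [("All", np.ones(len(scores), dtype=bool))]
    groups += [(p, (scores["play"] == p).to_numpy()) for p in
               sorted(scores["play"].unique())]
    for play, in_play in groups:
        use = in_play & included
        rows.append(
            {
                "play": play,
                "variable": label,
                "role": role,
                "mean_pct_change": float(np.mean(pct[use])) if use.any() else np.nan,
                "sd_pct_change": float(np.std(pct[use], ddof=1)) if use.sum() > 1 else np.nan,
                "n_included": int(use.sum()),
                "n_excluded": int((in_play & ~included).sum()),
            }
        )
    return pd.DataFrame(rows)


def influence_table(
    scores: pd.DataFrame,
    registry: dict[str, VariableSpec] | None = None,
    include_all_uog: bool = True,
) -> pd.DataFrame:
    """Removal effect of every registered variable (plus the joint UOG removal)."""
    registry = registry if registry is not None else default_registry()
    parts = []
    if include_all_uog and all(v in registry for v in UOG_VARIABLES):
        parts.append(removal_effect(scores, list(UOG_VARIABLES), registry))
    for name in variable_names(registry):
        parts.append(removal_effect(scores, name, registry))
    return pd.concat(parts, ignore_index=True)


def uog_only_scores(
    scores: pd.DataFrame, registry: dict[str, VariableSpec] | None = None
) -> pd.DataFrame:
    """UOG-only exposure and vulnerability per catchment.

    ``E_uog`` is the sum of the non-vertical well density and proximity
    scores (max 8); ``V_uog = S * E_uog``.
    """
    registry = registry if registry is not None else default_registry()
    out = scores[["huc12_id", "play"]].copy()
    out["E_uog"] = scores[list(UOG_ONLY_VARIABLES)].sum(axis=1)
    out["V_uog"] = scores["S"] * out["E_uog"]
    return out


def drop_no_well_variant(
    table: pd.DataFrame,
    scores: pd.DataFrame,
    variables: str | Sequence[str],
    registry: dict[str, VariableSpec] | None = None,
) -> pd.DataFrame:
    """Removal analysis restricted to catchments that contain any well.

    ``table`` supplies the raw well densities used to build the subset mask;
    ``scores`` the already-computed score table (aligned on ``huc12_id``).
    Raises if no catchment has a well.
    """
    dens = table.set_index("huc12_id")[list(WELL_DENSITY_VARIABLES)]
    has_well = dens.sum(axis=1) > 0
    keep_ids = set(dens.index[has_well])
    subset = scores[scores["huc12_id"].isin(keep_ids)]
    if subset.empty:
        raise ValueError("no catchments with wells in table")
    return removal_effect(subset.reset_index(drop=True), variables, registry)
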