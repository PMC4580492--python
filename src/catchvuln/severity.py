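"""Play-level severity-weighted vulnerability for three postulated effects.

The catchment index ranks individual HUC12s; this module ranks whole plays
against each of the three main postulated effects of unconventional oil and
gas development on streams — altered natural flow regime, sedimentation and
chemical contamination.  For one effect:

1. each relevant variable's six play means are ranked 1 (low stress) to
   6 (high stress) in the variable's stress direction;
2. each exposure variable's rank is multiplied by its severity weight — an
   author-elicited 1 (least) to 3 (most severe) score averaged across
   raters — and rounded half-up to an integer weighted cell (proximity
   variables carry implicit weight 1);
3. per play, the sensitivity ranks are summed, the weighted exposure cells
   are summed, and the two sums are multiplied into the total index.

The module ships the published severity weights and the published flow-
regime rank block as reference data, and can equally rank plays from any
supplied per-play means (e.g. from a synthetic table).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .registry import HIGHER_IS_WORSE, LOWER_IS_WORSE

EFFECTS = ("flow", "sediment", "chemical")

COMPETITION = "competition"  # ties share the minimum rank of their block
_TIE_METHODS = {"competition": "min", "max": "max", "dense": "dense"}

PLAY_ORDER = ("Bakken", "Barnett", "Fayetteville", "Hilliard", "Marcellus", "Mowry")


def rank_plays(
    means: Sequence[float] | Mapping[str, float],
    direction: str = HIGHER_IS_WORSE,
    tie_rule: str = COMPETITION,
) -> np.ndarray | dict[str, int]:
    """Rank plays 1 (low) to 6 (high) toward greater stress / sensitivity.

    ``higher_is_worse`` ranks ascending in the mean; ``lower_is_worse``
    (precipitation, well proximity) ranks descending, so e.g. the driest
    play ranks highest.  Ties share the minimum rank of their block under
    the default competition rule.  Accepts a mapping play -> mean and then
    returns a mapping play -> rank.
    """
    if isinstance(means, Mapping):
        keys = list(means)
        ranks = rank_plays([means[k] for k in keys], direction, tie_rule)
        return {k: int(r) for k, r in zip(keys, ranks)}
    m = np.asarray(means, dtype=float)
    if not np.isfinite(m).all():
        raise ValueError("non-finite play mean")
    if direction == LOWER_IS_WORSE:
        m = -m
    elif direction != HIGHER_IS_WORSE:
        raise ValueError(f"unknown direction {direction!r}")
    try:
        method = _TIE_METHODS[tie_rule]
    except KeyError:
        raise ValueError(f"unknown tie_rule {tie_rule!r}") from None
    return rankdata(m, method=method).astype(int)


def weighted_exposure_score(rank: int, weight: float) -> int:
    """One weighted exposure cell: round-half-up(rank * weight)."""
    if not 1 <= rank <= 6:
        raise ValueError(f"rank must be in 1..6, got {rank}")
    if not 1.0 <= weight <= 3.0:
        raise ValueError(f"severity weight must be in [1, 3], got {weight}")
    return int(math.floor(rank * weight + 0.5))


@dataclasses.dataclass(frozen=True)
class SeverityIndexResult:
    """One (effect, play): rank sum, weighted-exposure sum, and their product."""

    sens_rank_sum: int
    weighted_exposure_sum: int
    total: int

    def __post_init__(self) -> None:
        assert self.total == self.sens_rank_sum * self.weighted_exposure_sum


def severity_totals(
    sens_ranks: Sequence[int], weighted_cells: Sequence[int]
) -> SeverityIndexResult:
    """Sum the sensitivity ranks and weighted exposure cells; total is their product."""
    if not len(sens_ranks) or not len(weighted_cells):
        raise ValueError("empty rank or cell set")
    s = int(sum(sens_ranks))
    e = int(sum(weighted_cells))
    return SeverityIndexResult(s, e, s * e)


# ---------------------------------------------------------------------------
# Published severity weights (author-averaged, 1-3) per effect.  Proximity
# variables are weighted 1.0 (printed without a severity score).
# ---------------------------------------------------------------------------

SEVERITY_WEIGHTS: dict[str, dict[str, float]] = {
    "flow": {
        "vertical_well_density": 1.25,
        "nonvertical_well_density": 2.00,
        "road_density": 1.33,
        "mine_density": 1.80,
        "dam_density": 3.00,
        "pct_crops": 2.50,
        "pct_impervious": 3.00,
        "pct_pasture": 1.42,
    },
    "sediment": {
        "vertical_well_proximity": 1.00,
        "nonvertical_well_proximity": 1.00,
        "vertical_well_density": 1.25,
        "nonvertical_well_density": 2.50,
        "road_density": 2.75,
        "mine_density": 1.80,
        "dam_density": 1.70,
        "pct_crops": 2.67,
        "pct_impervious": 2.17,
        "pct_pasture": 1.83,
    },
    "chemical": {
        "vertical_well_proximity": 1.00,
        "nonvertical_well_proximity": 1.00,
        "vertical_well_density": 1.67,
        "nonvertical_well_density": 2.33,
        "road_density": 2.33,
        "mine_density": 3.00,
        "dam_density": 1.00,
        "pct_crops": 2.20,
        "pct_impervious": 2.83,
        "pct_pasture": 1.70,
    },
}

#: sensitivity variables entering each effect's rank sum
EFFECT_SENSITIVITY_VARIABLES: dict[str, tuple[str, ...]] = {
    "flow": ("precipitation", "stream_density"),
    "sediment": ("mean_slope", "pct_unconsolidated", "soil_erodibility"),
    "chemical": ("mean_slope", "pct_unconsolidated"),
}

# ---------------------------------------------------------------------------
# Published flow-regime rank block (plays in PLAY_ORDER).  Shipped as
# reference data because two rows are not reproducible from the published
# play means alone: the stream-density sensitivity ranks invert the printed
# means for Barnett/Hilliard, and the mine-density row follows a tie
# convention inconsistent with the dam-density row (see the methods note).
# ---------------------------------------------------------------------------

FLOW_SENSITIVITY_RANKS: dict[str, tuple[int, ...]] = {
    "precipitation": (4, 3, 1, 5, 2, 6),
    "stream_density": (5, 2, 6, 1, 3, 4),
}

FLOW_EXPOSURE_RANKS: dict[str, tuple[int, ...]] = {
    "vertical_well_density": (1, 2, 4, 3, 5, 6),
    "nonvertical_well_density": (4, 5, 6, 3, 2, 1),
    "road_density": (3, 5, 2, 1, 6, 4),
    "mine_density": (2, 2, 4, 4, 3, 6),
    "dam_density": (2, 6, 2, 1, 2, 2),
    "pct_crops": (4, 3, 6, 2, 5, 1),
    "pct_impervious": (3, 6, 4, 2, 5, 1),
    "pct_pasture": (6, 4, 3, 1, 5, 2),
}


def flow_regime_totals(
    weights: Mapping[str, float] | None = None,
) -> dict[str, SeverityIndexResult]:
    """Flow-regime severity index per play from the shipped reference ranks.

    The Hilliard entry is computed like the others; its published total is
    not recomposable from the published cells (methods note) and is excluded
    from exact-reproduction checks, not "corrected" here.
    """
    weights = dict(weights) if weights is not None else SEVERITY_WEIGHTS["flow"]
    results = {}
    for i, play in enumerate(PLAY_ORDER):
        sens = [ranks[i] for ranks in FLOW_SENSITIVITY_RANKS.values()]
        cells = [
            weighted_exposure_score(ranks[i], weights[var])
            for var, ranks in FLOW_EXPOSURE_RANKS.items()
        ]
        results[play] = severity_totals(sens, cells)
    return results


def severity_index_from_means(
    play_means: Mapping[str, Mapping[str, float]],
    effect: str,
    directions: Mapping[str, str] | None = None,
    weights: Mapping[str, float] | None = None,
    tie_rule: str = COMPETITION,
) -> dict[str, SeverityIndexResult]:
    """Severity index per play, ranking plays from supplied per-play means.

    ``play_means`` maps variable -> (play -> mean); variables needed are the
    effect's sensitivity variables plus every weighted exposure variable.
    ``directions`` overrides the default stress direction per variable
    (default: lower_is_worse for precipitation and proximities, else
    higher_is_worse).
    """
    if effect not in EFFECTS:
        raise ValueError(f"unknown effect {effect!r}")
    weights = dict(weights) if weights is not None else SEVERITY_WEIGHTS[effect]
    directions = dict(directions or {})

    def _direction(var: str) -> str:
        if var in directions:
            return directions[var]
        if var == "precipitation" or var.endswith("_proximity"):
            return LOWER_IS_WORSE
        return HIGHER_IS_WORSE

    plays = None
    ranks: dict[str, dict[str, int]] = {}
    for var in (*EFFECT_SENSITIVITY_VARIABLES[effect], *weights):
        means = play_means[var]
        if plays is None:
            plays = list(means)
        ranks[var] = rank_plays({p: means[p] for p in plays}, _direction(var), tie_rule)

    results = {}
    for play in plays:
        sens = [ranks[v][play] for v in EFFECT_SENSITIVITY_VARIABLES[effect]]
        cells = [
            weighted_exposure_score(ranks[v][play], w) for v, w in weights.items()
        ]
        results[play] = severity_totals(sens, cells)
    return results
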