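"""Play-level comparison of S, E and V: ANOVA, Tukey HSD, compact letters.

Catchments are treated as replicates within plays.  Mean scores are compared
with one-way analysis of variance followed by Tukey's studentized-range
post-hoc pairwise comparisons.  Because three metrics (S, E, V) are tested,
the default significance level is Bonferroni-style alpha = 0.016
(0.05 / 3).  Plays that share a compact-display letter are not
significantly different at that level.

The parametric path is used throughout; :func:`diagnostics` reports
normality (Shapiro on residuals, subsampled) and variance-homogeneity
(Levene) checks as warnings without switching tests.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.016  # 0.05 / 3 compared metrics


def oneway_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value across named groups."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


@dataclasses.dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    p_adjusted: float
    significant: bool


def tukey_hsd(
    groups: Mapping[str, Sequence[float]], alpha: float = DEFAULT_ALPHA
) -> tuple[list[PairwiseComparison], dict[str, str]]:
    """Tukey HSD pairwise comparisons and a compact letter display.

    Returns the pairwise table (studentized-range adjusted p per unordered
    pair) and a mapping group -> letters; groups sharing any letter are not
    significantly different at ``alpha``.
    """
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    res = stats.tukey_hsd(*arrays)
    pairs = []
    nonsig: set[frozenset[str]] = set()
    for i, j in itertools.combinations(range(len(names)), 2):
        p = float(res.pvalue[i, j])
        sig = p <= alpha
        pairs.append(PairwiseComparison(names[i], names[j], p, sig))
        if not sig:
            nonsig.add(frozenset((names[i], names[j])))
    letters = compact_letter_display(names, nonsig, groups)
    return pairs, letters


def compact_letter_display(
    names: Sequence[str],
    nonsignificant: set[frozenset[str]],
    groups: Mapping[str, Sequence[float]] | None = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Each letter marks a maximal set of mutually non-different groups.
    Groups are processed in order of decreasing mean (ties broken by name)
    so letter 'a' lands on the highest-scoring block, the usual convention.
    """
    if groups is not None:
        order = sorted(names, key=lambda g: (-float(np.mean(groups[g])), g))
    else:
        order = sorted(names)

    significant = [
        (a, b)
        for a, b in itertools.combinations(order, 2)
        if frozenset((a, b)) not in nonsignificant
    ]

    def absorb(blocks: list[set[str]]) -> list[set[str]]:
        return [
            b for i, b in enumerate(blocks)
            if b and not any(
                (b < o) or (b == o and i > j) for j, o in enumerate(blocks) if i != j
            )
        ]

    blocks: list[set[str]] = [set(order)]
    for a, b in significant:
        for block in [x for x in blocks if a in x and b in x]:
            blocks.remove(block)
            blocks.extend([block - {a}, block - {b}])
        blocks = absorb(blocks)
    blocks.sort(key=lambda b: min(order.index(g) for g in b))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in names}
    for letter, block in zip(alphabet, blocks):
        for g in order:
            if g in block:
                letters[g] += letter
    return letters


def diagnostics(groups: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Optional distribution/variance checks; warns, never switches tests."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    resid = np.concatenate([a - a.mean() for a in arrays])
    if len(resid) > 4500:  # Shapiro is defined for n <= 5000
        rng = np.random.default_rng(0)
        resid = rng.choice(resid, size=4500, replace=False)
    out = {}
    if np.ptp(resid) > 0:
        out["shapiro_p"] = float(stats.shapiro(resid).pvalue)
        out["levene_p"] = float(stats.levene(*arrays).pvalue)
        if out["shapiro_p"] < 0.05:
            warnings.warn("residuals look non-normal; parametric path retained")
        if out["levene_p"] < 0.05:
            warnings.warn("group variances look unequal; parametric path retained")
    return out


def compare_plays(
    scores: pd.DataFrame,
    metrics: Sequence[str] = ("S", "E", "V"),
    alpha: float = DEFAULT_ALPHA,
    run_diagnostics: bool = True,
) -> pd.DataFrame:
    """ANOVA + Tukey + letters for each score metric across plays.

    Returns a long frame: one ANOVA row per metric (``play`` empty) plus one
    row per play with its letters, and one row per pair with adjusted p.
    """
    rows = []
    for metric in metrics:
        groups = {
            p: g[metric].to_numpy(dtype=float)
            for p, g in scores.groupby("play", sort=True)
        }
        F, p = oneway_anova(groups)
        if run_diagnostics:
            diagnostics(groups)
        pairs, letters = tukey_hsd(groups, alpha=alpha)
        rows.append({"metric": metric, "kind": "anova", "F": F, "p": p})
        for play, lets in letters.items():
            rows.append(
                {"metric": metric, "kind": "letters", "play": play,
                 "letters": lets, "mean": float(np.mean(groups[play]))}
            )
        for pc in pairs:
            rows.append(
                {"metric": metric, "kind": "pairwise", "play": pc.group_a,
                 "play_b": pc.group_b, "p": pc.p_adjusted,
                 "significant": pc.significant}
            )
    return pd.DataFrame(rows)
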