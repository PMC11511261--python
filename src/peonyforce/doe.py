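"""Taguchi L9 range analysis: level means K, range R, factor ranking.

Given a per-group response (here the group mean flowering index) over
the nine L9 treatment groups, each factor's effect is summarized by the
level means K[f][l] (mean response of the three groups with factor f at
its l-th level) and the range R[f] = max K - min K.  Factors are ranked
by descending R, and the optimal combination picks the best level of
each factor independently (legitimate under the no-interaction
assumption of the orthogonal design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .design import FACTORS, GroupDesign
from .errors import DesignError, DomainError

LEVEL_LABELS = ("K1", "K2", "K3")


@dataclass(frozen=True)
class RangeAnalysisResult:
    factors: tuple[str, ...]
    K: pd.DataFrame          # index K1..K3 (ascending level rank), columns = factors
    levels: pd.DataFrame     # same shape: the physical level values
    R: pd.Series             # per-factor range
    order: tuple[str, ...]   # factors by descending R
    optimal: str             # e.g. "A1B3C3"
    objective: str
    grand_mean: float


def level_means(
    design: GroupDesign,
    response: Mapping[str, float],
) -> pd.DataFrame:
    """K matrix: mean response per (factor, level rank) over the L9 groups.

    *response* maps group id -> response value; it must cover exactly
    the nine non-control groups (a control entry, if present, is
    ignored).
    """
    groups = design.non_control
    missing = [g.group_id for g in groups if g.group_id not in response]
    if missing:
        raise DesignError(f"response missing for groups: {missing}")
    K = pd.DataFrame(
        index=list(LEVEL_LABELS), columns=list(FACTORS), dtype=float
    )
    for f in FACTORS:
        for rank, lev in enumerate(design.levels(f), start=1):
            members = [g.group_id for g in groups if g.level(f) == lev]
            if len(members) != 3:
                raise DesignError(
                    f"factor {f} level {lev} covered by {len(members)} groups, expected 3"
                )
            K.loc[f"K{rank}", f] = float(
                np.mean([float(response[m]) for m in members])
            )
    return K


def range_R(k_row) -> float:
    """Range of one factor's level means: max - min."""
    vals = np.asarray(list(k_row), dtype=float)
    if vals.size == 0:
        raise DomainError("empty level-mean row")
    if vals.size < 2:
        raise DomainError("range requires at least two levels")
    return float(vals.max() - vals.min())


def rank_factors(R: Mapping[str, float]) -> tuple[str, ...]:
    """Factors sorted by descending range; ties keep input order (warned)."""
    items = list(R.items())
    values = [v for _, v in items]
    if len(set(values)) < len(values):
        warnings.warn(
            "tied ranges: factor order among ties follows input order",
            stacklevel=2,
        )
    order = sorted(range(len(items)), key=lambda i: (-items[i][1], i))
    return tuple(items[i][0] for i in order)


def optimal_combination(K: pd.DataFrame, objective: str = "maximize") -> str:
    """Best level of each factor, coded as e.g. ``A1B3C3``.

    A within-factor tie is an error: the design cannot distinguish the
    tied levels and a silent choice would be arbitrary.
    """
    if objective not in ("maximize", "minimize"):
        raise DomainError(f"unknown objective {objective!r}")
    parts = []
    for f in K.columns:
        col = K[f].to_numpy(dtype=float)
        best = col.max() if objective == "maximize" else col.min()
        ranks = [i + 1 for i, v in enumerate(col) if v == best]
        if len(ranks) > 1:
            raise DomainError(
                f"factor {f}: levels {ranks} are tied at K={best}; "
                "no unique optimum"
            )
        parts.append(f"{f}{ranks[0]}")
    return "".join(parts)


def range_analysis(
    design: GroupDesign,
    response: Mapping[str, float],
    objective: str = "maximize",
) -> RangeAnalysisResult:
    """Full range analysis of a per-group response over the L9 array."""
    K = level_means(design, response)
    R = pd.Series({f: range_R(K[f]) for f in K.columns}, dtype=float)
    order = rank_factors(R.to_dict())
    optimal = optimal_combination(K, objective)
    levels = pd.DataFrame(
        {f: list(design.levels(f)) for f in FACTORS},
        index=list(LEVEL_LABELS),
        dtype=float,
    )
    grand = float(
        np.mean([float(response[g.group_id]) for g in design.non_control])
    )
    return RangeAnalysisResult(
        factors=tuple(K.columns),
        K=K,
        levels=levels,
        R=R,
        order=order,
        optimal=optimal,
        objective=objective,
        grand_mean=grand,
    )


def render_range_table(result: RangeAnalysisResult, decimals: int = 2) -> str:
    """Plain-text table in the conventional K1/K2/K3/R layout."""
    lines = ["\t".join(["", *result.factors])]
    for label in result.K.index:
        row = [label] + [
            f"{result.K.loc[label, f]:.{decimals}f}" for f in result.factors
        ]
        lines.append("\t".join(row))
    lines.append(
        "\t".join(["R", *[f"{result.R[f]:.{decimals}f}" for f in result.factors]])
    )
    lines.append("Order\t" + " > ".join(result.order))
    lines.append("Optimal combination\t" + result.optimal)
    return "\n".join(lines) + "\n"
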