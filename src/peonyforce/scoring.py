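"""Ordinal rubric scoring of ornamental traits and the flowering index.

Six ornamental characteristics of a forced potted bloom — petal redness
a*, flower diameter FD (mm), flowers per plant FNP, leaf SPAD, branch
number BN and crown index CI (= 100 x CWI) — are each binned into five
ordered quality levels, and the flowering index is their unweighted sum:

    FI = level(a*) + level(FD) + level(FNP) + level(SPAD) + level(BN) + level(CI)

so 6 <= FI <= 30.  Bins follow a left-closed/right-open convention: a
printed boundary value belongs to the upper bin ("21-25" means
[21, 25)).  The published criteria contain two evident misprints in the
CI row ("123" for 120 and "40" for 140) which are repaired to the
gap-free monotone grid (-inf,120) | [120,130) | [130,140) | [140,150) |
[150,inf); the count rows are completed monotonically (BN of exactly 5
scores 5; FNP of 0 scores 1).

FI is computed per plant and then averaged within a group, which is how
fractional group means arise from integer plant scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .errors import DomainError, ValidationError
from .table import TraitTable

FI_TRAITS = ("a*", "FD", "FNP", "SPAD", "BN", "CI")
N_LEVELS = 5
FI_MIN = N_LEVELS + 1  # six traits at level 1
FI_MAX = 6 * N_LEVELS


@dataclass(frozen=True)
class RubricTrait:
    """Five ordered bins for one trait, encoded by their upper bounds.

    ``upper_bounds`` are the right-open bin edges; the last must be
    +inf.  A value scores level i+1 where i is the first index with
    value < upper_bounds[i].  Strictly increasing bounds guarantee the
    bins are non-overlapping, exhaustive and monotone.
    """

    code: str
    upper_bounds: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.upper_bounds) != N_LEVELS:
            raise ValidationError(
                f"rubric trait {self.code!r} needs exactly {N_LEVELS} bins"
            )
        if not math.isinf(self.upper_bounds[-1]):
            raise ValidationError(
                f"rubric trait {self.code!r}: last upper bound must be +inf"
            )
        if any(
            a >= b for a, b in zip(self.upper_bounds, self.upper_bounds[1:])
        ):
            raise ValidationError(
                f"rubric trait {self.code!r}: upper bounds must strictly increase"
            )

    def level(self, value: float) -> int:
        if not math.isfinite(value):
            raise DomainError(f"non-finite value for rubric trait {self.code!r}")
        for i, ub in enumerate(self.upper_bounds):
            if value < ub:
                return i + 1
        raise AssertionError("unreachable: last bound is +inf")


@dataclass(frozen=True)
class Rubric:
    traits: tuple[RubricTrait, ...]

    def __post_init__(self) -> None:
        codes = [t.code for t in self.traits]
        if len(set(codes)) != len(codes):
            raise ValidationError("duplicate rubric traits")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(t.code for t in self.traits)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __getitem__(self, code: str) -> RubricTrait:
        for t in self.traits:
            if t.code == code:
                return t
        raise KeyError(code)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "traits": [
                {
                    "code": t.code,
                    "upper_bounds": [
                        None if math.isinf(b) else b for b in t.upper_bounds
                    ],
                }
                for t in self.traits
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rubric":
        return cls(
            traits=tuple(
                RubricTrait(
                    code=str(t["code"]),
                    upper_bounds=tuple(
                        math.inf if b is None else float(b)
                        for b in t["upper_bounds"]
                    ),
                )
                for t in d["traits"]
            )
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Rubric":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


#: National-standard-derived scoring grid for the six ornamental traits.
DEFAULT_RUBRIC = Rubric(
    traits=(
        RubricTrait("a*", (21, 25, 29, 33, math.inf)),
        RubricTrait("FD", (155, 170, 185, 200, math.inf)),
        RubricTrait("FNP", (2, 3, 4, 5, math.inf)),
        RubricTrait("SPAD", (30, 32, 34, 36, math.inf)),
        RubricTrait("BN", (2, 3, 4, 5, math.inf)),
        RubricTrait("CI", (120, 130, 140, 150, math.inf)),
    )
)


@dataclass(frozen=True)
class FlowerScore:
    """Per-plant rubric levels and their sum, the flowering index."""

    plant_id: str
    group_id: str
    levels: Mapping[str, int]
    fi: int


def score_trait(trait_code: str, value: float, rubric: Rubric = DEFAULT_RUBRIC) -> int:
    """Quality level (1-5) of one trait value under the rubric."""
    if trait_code not in rubric:
        raise ValidationError(f"trait {trait_code!r} is not in the rubric")
    return rubric[trait_code].level(value)


def flowering_index(levels: Mapping[str, int]) -> int:
    """Unweighted sum of the six rubric levels."""
    missing = [c for c in FI_TRAITS if c not in levels]
    if missing:
        raise ValidationError(f"missing rubric levels for: {missing}")
    extra = sorted(set(levels) - set(FI_TRAITS))
    if extra:
        raise ValidationError(f"unexpected rubric traits: {extra}")
    for code, lev in levels.items():
        if not 1 <= int(lev) <= N_LEVELS or int(lev) != lev:
            raise DomainError(f"level for {code!r} must be an integer in 1..{N_LEVELS}")
    return int(sum(int(levels[c]) for c in FI_TRAITS))


def score_table(
    table: TraitTable,
    rubric: Rubric = DEFAULT_RUBRIC,
) -> list[FlowerScore]:
    """Score every plant of the flowering stage.

    Each plant must carry all six rubric traits; CI is derived on the
    fly as 100 x CWI when absent.
    """
    wide = table.wide("flowering")
    if wide.empty:
        return []
    if "CI" not in wide.columns and "CWI" in wide.columns:
        wide = wide.assign(CI=100.0 * wide["CWI"])
    scores: list[FlowerScore] = []
    for _, row in wide.iterrows():
        missing = [
            c for c in FI_TRAITS if c not in wide.columns or pd.isna(row.get(c))
        ]
        if missing:
            raise ValidationError(
                f"plant {row['plant_id']!r} is missing rubric traits: {missing}"
            )
        levels = {c: score_trait(c, float(row[c]), rubric) for c in FI_TRAITS}
        scores.append(
            FlowerScore(
                plant_id=str(row["plant_id"]),
                group_id=str(row["group_id"]),
                levels=levels,
                fi=flowering_index(levels),
            )
        )
    return scores


def scores_frame(scores: list[FlowerScore]) -> pd.DataFrame:
    """Tabular view: one row per plant with levels and FI."""
    return pd.DataFrame(
        [
            {
                "plant_id": s.plant_id,
                "group_id": s.group_id,
                **{f"level_{c}": s.levels[c] for c in FI_TRAITS},
                "FI": s.fi,
            }
            for s in scores
        ]
    )


def group_fi(scores: list[FlowerScore]) -> pd.Series:
    """Group mean flowering index from per-plant integer scores."""
    df = scores_frame(scores)
    if df.empty:
        return pd.Series(dtype=float)
    return df.groupby("group_id")["FI"].mean()
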