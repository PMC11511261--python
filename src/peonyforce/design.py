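"""Group/factor metadata and the L9(3^4) orthogonal design.

Ten treatment groups: a control T0 (no intervention) plus nine groups
T1-T9 forming a Taguchi L9 array over three 3-level factors:

* ``A`` — root pruning intensity (% of total coarse-root length removed):
  25, 33, 50;
* ``B`` — rooting-agent concentration (mg/L): 250, 500, 750;
* ``C`` — *Metarhizium anisopliae* suspension (million U/mL): 10, 15, 20.

The fourth column of the L9(3^4) table is unused (only three factors
are assigned).  The L9 validator checks the two defining balance
properties: each (factor, level) occurs in exactly three groups and each
ordered level pair of any two factors occurs exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import yaml

from .errors import DesignError

FACTORS = ("A", "B", "C")

FACTOR_NAMES = {
    "A": "root pruning (%)",
    "B": "rooting agent (mg/L)",
    "C": "Metarhizium (million U/mL)",
}


@dataclass(frozen=True)
class Group:
    group_id: str
    level_A: float
    level_B: float
    level_C: float
    is_control: bool = False

    def level(self, factor: str) -> float:
        return getattr(self, f"level_{factor}")


@dataclass(frozen=True)
class GroupDesign:
    groups: tuple[Group, ...]

    def __post_init__(self) -> None:
        ids = [g.group_id for g in self.groups]
        if len(set(ids)) != len(ids):
            raise DesignError("group ids are not unique")
        controls = [g for g in self.groups if g.is_control]
        if len(controls) > 1:
            raise DesignError("at most one control group is permitted")
        for g in controls:
            if (g.level_A, g.level_B, g.level_C) != (0, 0, 0):
                raise DesignError(
                    f"control group {g.group_id!r} must have all factor levels 0"
                )
        self._validate_l9()

    # -- structure ---------------------------------------------------------
    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(g.group_id for g in self.groups)

    @property
    def non_control(self) -> tuple[Group, ...]:
        return tuple(g for g in self.groups if not g.is_control)

    @property
    def control(self) -> Group | None:
        for g in self.groups:
            if g.is_control:
                return g
        return None

    def __getitem__(self, group_id: str) -> Group:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    def __contains__(self, group_id: str) -> bool:
        return any(g.group_id == group_id for g in self.groups)

    def levels(self, factor: str) -> tuple[float, ...]:
        """Ascending distinct levels of *factor* over the L9 groups."""
        return tuple(sorted({g.level(factor) for g in self.non_control}))

    def level_rank(self, factor: str, value: float) -> int:
        """1-based rank of a level value within its factor (A1, A2, ...)."""
        return self.levels(factor).index(value) + 1

    # -- validation --------------------------------------------------------
    def _validate_l9(self) -> None:
        arr = self.non_control
        if len(arr) != 9:
            raise DesignError(
                f"an L9 design needs exactly 9 non-control groups, got {len(arr)}"
            )
        for f in FACTORS:
            levels = [g.level(f) for g in arr]
            distinct = sorted(set(levels))
            if len(distinct) != 3:
                raise DesignError(f"factor {f} must take exactly 3 levels")
            for lev in distinct:
                if levels.count(lev) != 3:
                    raise DesignError(
                        f"factor {f} level {lev} occurs {levels.count(lev)} times, expected 3"
                    )
        for f1, f2 in combinations(FACTORS, 2):
            pairs = [(g.level(f1), g.level(f2)) for g in arr]
            if len(set(pairs)) != 9:
                raise DesignError(
                    f"factors {f1} and {f2} are not orthogonal: "
                    "each ordered level pair must occur exactly once"
                )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "groups": [
                {
                    "group_id": g.group_id,
                    "A": g.level_A,
                    "B": g.level_B,
                    "C": g.level_C,
                    "is_control": g.is_control,
                }
                for g in self.groups
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupDesign":
        return cls(
            groups=tuple(
                Group(
                    group_id=str(g["group_id"]),
                    level_A=float(g["A"]),
                    level_B=float(g["B"]),
                    level_C=float(g["C"]),
                    is_control=bool(g.get("is_control", False)),
                )
                for g in d["groups"]
            )
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroupDesign":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


#: The study's assignment: control plus the standard L9 array.
DEFAULT_DESIGN = GroupDesign(
    groups=(
        Group("T0", 0, 0, 0, is_control=True),
        Group("T1", 25, 250, 10),
        Group("T2", 25, 500, 15),
        Group("T3", 25, 750, 20),
        Group("T4", 33, 250, 15),
        Group("T5", 33, 500, 20),
        Group("T6", 33, 750, 10),
        Group("T7", 50, 250, 20),
        Group("T8", 50, 500, 10),
        Group("T9", 50, 750, 15),
    )
)
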