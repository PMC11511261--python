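"""Per-plant trait tables: long-form container, CSV readers and writers.

The canonical in-memory representation is long form — one row per
(plant, stage, trait) — because different traits are measured on
different plants at different stages (the defoliation harvest is
destructive).  Wide CSV input (one column per trait) is accepted for
convenience and melted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import COUNT, CONTINUOUS_POSITIVE, DEFAULT_CATALOG, STAGES, TraitCatalog
from .design import GroupDesign
from .errors import ValidationError

COLUMNS = ("plant_id", "group_id", "stage", "trait_code", "value")
_KEY = ["plant_id", "stage", "trait_code"]


@dataclass
class TraitTable:
    """Validated long-form trait table.

    ``data`` has exactly the columns ``plant_id, group_id, stage,
    trait_code, value``; the key (plant_id, stage, trait_code) is unique.
    """

    data: pd.DataFrame
    catalog: TraitCatalog = field(default=DEFAULT_CATALOG, repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"trait table is missing columns: {missing}")
        df = df.loc[:, list(COLUMNS)].reset_index(drop=True)
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        self.data = df
        self.validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records,
        catalog: TraitCatalog = DEFAULT_CATALOG,
    ) -> "TraitTable":
        """Build from an iterable of (plant_id, group_id, stage, trait_code, value)."""
        df = pd.DataFrame(list(records), columns=list(COLUMNS))
        return cls(data=df, catalog=catalog)

    # -- validation --------------------------------------------------------
    def validate(self, design: GroupDesign | None = None) -> None:
        df = self.data
        bad_stage = sorted(set(df["stage"]) - set(STAGES))
        if bad_stage:
            raise ValidationError(f"unknown stages: {bad_stage}")
        unknown = sorted(set(df["trait_code"]) - set(self.catalog.codes))
        if unknown:
            raise ValidationError(f"unknown trait codes: {unknown}")
        dup = df.duplicated(subset=_KEY, keep=False)
        if dup.any():
            offenders = (
                df.loc[dup, _KEY].drop_duplicates().to_records(index=False).tolist()
            )
            raise ValidationError(
                f"duplicate (plant, stage, trait) entries: {offenders[:10]}"
            )
        if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
            raise ValidationError("non-finite trait values present")
        for code, sub in df.groupby("trait_code"):
            kind = self.catalog.kind(str(code))
            vals = sub["value"].to_numpy(dtype=float)
            if kind == CONTINUOUS_POSITIVE and not (vals > 0).all():
                raise ValidationError(
                    f"continuous trait {code!r} has non-positive values"
                )
            if kind == COUNT:
                if not ((vals >= 0) & (vals == np.round(vals))).all():
                    raise ValidationError(
                        f"count trait {code!r} has non-integer or negative values"
                    )
        if design is not None:
            orphan = sorted(set(df["group_id"]) - set(design.group_ids))
            if orphan:
                raise ValidationError(
                    f"groups absent from the design: {orphan}"
                )

    # -- convenience -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    def stage(self, stage: str) -> pd.DataFrame:
        return self.data[self.data["stage"] == stage]

    def wide(self, stage: str | None = None) -> pd.DataFrame:
        """Pivot to one row per (plant, stage), one column per trait."""
        df = self.data if stage is None else self.stage(stage)
        return df.pivot_table(
            index=["group_id", "plant_id", "stage"],
            columns="trait_code",
            values="value",
            aggfunc="first",
        ).reset_index()

    def concat(self, other: "TraitTable") -> "TraitTable":
        return TraitTable(
            data=pd.concat([self.data, other.data], ignore_index=True),
            catalog=self.catalog,
        )

    def equals(self, other: "TraitTable") -> bool:
        a = self.data.sort_values(list(COLUMNS)).reset_index(drop=True)
        b = other.data.sort_values(list(COLUMNS)).reset_index(drop=True)
        return a.equals(b)


def read_trait_table(
    path: str | Path,
    catalog: TraitCatalog = DEFAULT_CATALOG,
) -> TraitTable:
    """Read a CSV trait table, long or wide.

    A long file has columns ``plant_id, group_id, stage, trait_code,
    value``; a wide file has ``plant_id, group_id, stage`` followed by
    one column per trait (empty cells allowed for unmeasured traits).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, skip_blank_lines=True, float_precision="round_trip")
    except ValueError as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    required = ("plant_id", "group_id", "stage")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing key columns {missing}")
    for c in required:
        df[c] = df[c].astype(str).str.strip()

    if "trait_code" in df.columns and "value" in df.columns:
        long = df.loc[:, list(COLUMNS)]
    else:
        trait_cols = [c for c in df.columns if c not in required]
        unknown = sorted(set(trait_cols) - set(catalog.codes))
        if unknown:
            raise ValidationError(
                f"{path}: columns not in the trait catalog: {unknown}"
            )
        long = df.melt(
            id_vars=list(required),
            value_vars=trait_cols,
            var_name="trait_code",
            value_name="value",
        ).dropna(subset=["value"])

    values = pd.to_numeric(long["value"], errors="coerce")
    bad = long[values.isna() & long["value"].notna()]
    if len(bad):
        first = bad.iloc[0]
        raise ValidationError(
            f"{path}: non-numeric value {first['value']!r} for trait "
            f"{first['trait_code']!r} (plant {first['plant_id']!r})"
        )
    long = long.assign(value=values).dropna(subset=["value"])
    return TraitTable(data=long.reset_index(drop=True), catalog=catalog)


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    """Write long-form CSV with a deterministic row and column order."""
    df = (
        table.data.sort_values(["group_id", "plant_id", "stage", "trait_code"])
        .reset_index(drop=True)
        .loc[:, list(COLUMNS)]
    )
    # repr round-trips float64 exactly; pandas' default float formatting
    # may drop the last bits
    df = df.assign(value=[repr(float(v)) for v in df["value"]])
    df.to_csv(path, index=False)
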