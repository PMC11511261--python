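"""Closed-form derived plant indices and group summaries.

All indices are computed per plant and then averaged within a group
(the index-then-average convention): group values printed for SI, CWI,
WUE and NSCAT in the source tables are consistent with averaging
per-plant indices, not with applying the formula to group means.  The
formula-on-means variant remains available simply by passing group
means to the same functions.

Formulas
--------
* water-use efficiency      ``WUE = Pn / Tr``
* seedling index            ``SI  = SD / SL * WPB``
* crown-width index         ``CWI = CW / PH``
* NSC accumulation          ``NSCA = content * biomass`` (per organ)
* whole-plant accumulation  ``NSCAT = sum of NSCA over organs``
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .design import GroupDesign
from .errors import DomainError
from .table import TraitTable

ORGANS = ("stem", "old_root", "woody_new_root", "fine_root", "root")
ROOT_ORGANS = ("old_root", "woody_new_root", "fine_root")


@dataclass(frozen=True)
class OrganNSC:
    """NSC concentration and dry biomass of one organ.

    ``nsc_content`` is g NSC per g dry biomass (a mass fraction in
    [0, 1]); ``biomass`` is g per plant.  The three root organs may be
    pooled as ``"root"``.
    """

    organ: str
    nsc_content: float
    biomass: float

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise DomainError(f"unknown organ {self.organ!r}; expected one of {ORGANS}")
        if not 0.0 <= self.nsc_content <= 1.0:
            raise DomainError("nsc_content must lie in [0, 1]")
        if self.biomass < 0:
            raise DomainError("biomass must be non-negative")


def water_use_efficiency(pn: float, tr: float) -> float:
    """Net photosynthesis per unit transpiration, Pn/Tr."""
    pn, tr = np.asarray(pn, dtype=float), np.asarray(tr, dtype=float)
    if np.any(tr <= 0):
        raise DomainError("transpiration rate must be > 0")
    return pn / tr


def seedling_index(sd: float, sl: float, wpb: float) -> float:
    """Compactness-weighted vigor score, SD/SL x WPB."""
    sd = np.asarray(sd, dtype=float)
    sl = np.asarray(sl, dtype=float)
    wpb = np.asarray(wpb, dtype=float)
    if np.any(sl <= 0):
        raise DomainError("stem length must be > 0")
    if np.any(sd < 0) or np.any(wpb < 0):
        raise DomainError("stem diameter and biomass must be >= 0")
    return sd / sl * wpb


def crown_width_index(cw: float, ph: float) -> float:
    """Crown width over plant height, CW/PH."""
    cw, ph = np.asarray(cw, dtype=float), np.asarray(ph, dtype=float)
    if np.any(ph <= 0):
        raise DomainError("plant height must be > 0")
    return cw / ph


def nsc_accumulation(organ: OrganNSC) -> float:
    """NSC pool size of one organ: content x biomass (g per plant)."""
    return organ.nsc_content * organ.biomass


def total_nsc(accumulations: Iterable[float]) -> float:
    """Whole-plant NSC accumulation: sum of per-organ pools."""
    acc = np.asarray(list(accumulations), dtype=float)
    if acc.size and np.any(acc < 0):
        raise DomainError("organ NSC accumulations must be non-negative")
    return float(acc.sum())


def organ_fraction(part: float, total: float) -> float:
    """Share (%) of the whole-plant NSC pool held by one organ."""
    if total <= 0:
        raise DomainError("total must be > 0")
    if not 0 <= part <= total:
        raise DomainError("part must lie in [0, total]")
    return 100.0 * part / total


def percent_change(reference: float, value: float) -> float:
    """Relative change (%) of *value* from *reference*; negative = reduction."""
    if reference == 0:
        raise DomainError("reference must be nonzero")
    return 100.0 * (value - reference) / reference


def summarize_group(
    table: TraitTable,
    design: GroupDesign | None = None,
) -> pd.DataFrame:
    """Per (group, stage, trait) mean, standard error and replicate count.

    SE is the sample standard deviation (ddof=1) over the plants of the
    group divided by sqrt(n).  With a single replicate the SE is
    undefined and reported as NaN with a warning.
    """
    if design is not None:
        table.validate(design)
    rows = []
    for (gid, stage, code), sub in table.data.groupby(
        ["group_id", "stage", "trait_code"], sort=True
    ):
        vals = sub["value"].to_numpy(dtype=float)
        n = vals.size
        if n < 2:
            warnings.warn(
                f"group {gid} trait {code} at {stage} has n={n}; SE undefined",
                stacklevel=2,
            )
            se = np.nan
        else:
            se = float(np.std(vals, ddof=1) / np.sqrt(n))
        rows.append(
            {
                "group_id": gid,
                "stage": stage,
                "trait_code": code,
                "mean": float(np.mean(vals)),
                "se": se,
                "n": int(n),
            }
        )
    return pd.DataFrame(rows, columns=["group_id", "stage", "trait_code", "mean", "se", "n"])


def derive_plant_indices(table: TraitTable) -> TraitTable:
    """Add per-plant derived traits that are absent from the table.

    WUE from Pn and Tr, SI from SD/SL/WPB, CWI from CW/PH, NSCAT from
    NSCAS + NSCAR, and CI = 100 x CWI.  Traits already present are left
    untouched; a derived trait is added only for plants carrying all of
    its inputs at the relevant stage.
    """
    recipes = [
        ("WUE", "vigorous_growth", ("Pn", "Tr"), lambda d: water_use_efficiency(d["Pn"], d["Tr"])),
        ("SI", "defoliation", ("SD", "SL", "WPB"), lambda d: seedling_index(d["SD"], d["SL"], d["WPB"])),
        ("NSCAT", "defoliation", ("NSCAS", "NSCAR"), lambda d: d["NSCAS"] + d["NSCAR"]),
        ("CWI", "flowering", ("CW", "PH"), lambda d: crown_width_index(d["CW"], d["PH"])),
        ("CI", "flowering", ("CWI",), lambda d: 100.0 * d["CWI"]),
    ]
    out = table
    for code, stage, needs, fn in recipes:
        present = set(out.stage(stage)["trait_code"])
        if code in present or not set(needs) <= present:
            continue
        wide = out.wide(stage).dropna(subset=list(needs))
        if wide.empty:
            continue
        new = pd.DataFrame(
            {
                "plant_id": wide["plant_id"],
                "group_id": wide["group_id"],
                "stage": stage,
                "trait_code": code,
                "value": fn(wide),
            }
        )
        out = TraitTable(
            data=pd.concat([out.data, new], ignore_index=True),
            catalog=out.catalog,
        )
    return out
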