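"""Seeded per-plant replicate generator and the built-in study fixture.

The study published only group summaries (mean +/- SE, n = 4 per group,
n = 5 for the leaf gas-exchange campaign), not the underlying plants.
This module embeds those summaries verbatim and generates synthetic
replicate plants that reproduce them in distribution:

* continuous traits: Normal(mean, sd) with sd = SE * sqrt(n), truncated
  at zero by redraw for strictly positive traits (redraw, not clipping,
  to avoid a point mass at zero);
* count traits (BN, FNP): a small-integer distribution on {0..8}
  obtained by rounding a normal draw, with the location parameter
  calibrated so the discretized distribution's mean matches the printed
  mean to within 0.05;
* traits are drawn independently of one another (the tables carry no
  covariance information); a *planted effect* mechanism regenerates one
  response trait as an explicit linear function of a predictor trait
  plus noise, providing controlled dependence for regression tests.

Generation is fully deterministic given the seed: each (group, stage,
trait) stream is derived from the seed through a numpy SeedSequence
keyed on the spec's position, so tables are reproducible byte for byte
and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from .catalog import (
    CONTINUOUS_POSITIVE,
    COUNT,
    DEFAULT_CATALOG,
    STAGES,
    TraitCatalog,
)
from .design import DEFAULT_DESIGN, GroupDesign
from .errors import DomainError, ValidationError
from .table import COLUMNS, TraitTable

COUNT_SUPPORT_MAX = 8
_COUNT_MEAN_TOL = 0.05


@dataclass(frozen=True)
class GroupSpec:
    """Printed summary of one group at one stage: trait -> (mean, se, n)."""

    group_id: str
    stage: str
    traits: Mapping[str, tuple[float, float, int]]

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        for code, (mean, se, n) in self.traits.items():
            if se < 0:
                raise ValidationError(f"{self.group_id}/{code}: SE must be >= 0")
            if n < 2:
                raise ValidationError(f"{self.group_id}/{code}: n must be >= 2")


@dataclass(frozen=True)
class PlantedEffect:
    """Linear link regenerating *response* from *predictor* plus noise."""

    response: str
    predictor: str
    slope: float
    noise_sd: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValidationError("planted slope must be finite")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_override: int | None = None
    effect: PlantedEffect | None = None


# ---------------------------------------------------------------------------
# built-in fixture: the published group summaries
# ---------------------------------------------------------------------------

_GROUPS = ("T0", "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9")

# gas-exchange campaign used five plants per group; everything else four
_N_BY_TRAIT = {"Pn": 5, "Gs": 5, "Ci": 5, "Tr": 5, "WUE": 5}
_DEFAULT_N = 4

# stage -> trait -> per-group (mean, se) in T0..T9 order
_SUMMARIES: dict[str, dict[str, list[tuple[float, float]]]] = {
    "vigorous_growth": {
        "Pn": [(10.21, 1.51), (9.75, 2.23), (10.81, 1.79), (11.01, 1.65), (11.41, 1.08),
               (10.60, 2.44), (10.52, 1.05), (10.63, 1.06), (10.69, 1.56), (10.64, 1.49)],
        "Gs": [(0.09, 0.01), (0.09, 0.04), (0.10, 0.02), (0.10, 0.02), (0.10, 0.02),
               (0.12, 0.03), (0.11, 0.02), (0.11, 0.02), (0.10, 0.02), (0.11, 0.02)],
        "Ci": [(200.8, 18.0), (194.4, 29.1), (195.7, 28.5), (198.1, 17.7), (196.2, 17.9),
               (225.0, 13.9), (222.9, 14.9), (210.7, 11.3), (189.4, 18.8), (220.0, 24.3)],
        "Tr": [(2.89, 0.34), (2.81, 0.97), (3.08, 0.59), (3.27, 0.62), (3.36, 0.46),
               (3.78, 0.85), (4.02, 0.47), (3.84, 0.47), (3.53, 0.67), (3.65, 0.49)],
        "WUE": [(3.54, 0.35), (3.58, 0.45), (3.57, 0.58), (3.40, 0.25), (3.42, 0.26),
                (2.82, 0.23), (2.63, 0.28), (2.78, 0.15), (3.06, 0.26), (2.94, 0.43)],
        "LA": [(1725.6, 263.5), (1554.1, 77.6), (1345.4, 81.4), (1792.3, 209.7), (1269.2, 244.1),
               (1237.0, 40.5), (1434.7, 203.5), (1028.6, 112.3), (1097.5, 157.0), (1219.2, 209.9)],
        "POD": [(41.4, 13.6), (62.5, 11.0), (63.7, 15.1), (82.7, 14.2), (19.8, 2.6),
                (27.9, 8.8), (33.5, 11.0), (26.4, 6.2), (15.7, 10.2), (19.8, 4.6)],
        "MDA": [(9.79, 0.29), (10.07, 0.57), (8.54, 0.37), (8.14, 0.37), (9.10, 0.33),
                (9.28, 0.38), (8.02, 0.39), (10.36, 0.40), (7.94, 0.35), (7.55, 0.13)],
    },
    "defoliation": {
        "SL": [(111.6, 11.9), (102.0, 9.0), (88.2, 4.0), (91.4, 7.6), (93.4, 14.7),
               (87.2, 12.0), (99.1, 12.4), (82.8, 5.8), (78.7, 9.7), (92.7, 4.6)],
        "SD": [(6.2, 0.1), (6.3, 0.3), (5.4, 0.1), (6.4, 0.3), (5.8, 0.7),
               (5.3, 0.2), (6.1, 0.4), (4.7, 0.2), (4.9, 0.4), (5.9, 0.3)],
        "WPB": [(344.8, 39.2), (332.9, 17.3), (345.4, 39.2), (370.7, 15.1), (321.6, 32.9),
                (333.3, 24.9), (362.6, 24.2), (288.0, 41.1), (287.7, 39.4), (292.5, 27.9)],
        "NSCAS": [(1.42, 0.06), (2.46, 0.03), (2.92, 0.12), (2.01, 0.06), (1.93, 0.08),
                  (1.84, 0.07), (2.33, 0.16), (1.79, 0.03), (1.65, 0.05), (1.28, 0.04)],
        "NSCAR": [(81.3, 4.3), (79.1, 2.8), (80.3, 6.2), (89.0, 0.5), (71.4, 3.0),
                  (69.9, 1.1), (81.3, 2.8), (54.0, 2.2), (57.4, 3.1), (58.1, 2.1)],
        "NSCAT": [(82.7, 4.2), (81.6, 2.8), (83.2, 6.3), (91.0, 0.5), (73.4, 3.0),
                  (71.7, 1.2), (83.6, 2.7), (55.7, 2.2), (59.0, 3.1), (59.4, 2.1)],
        "SI": [(19.2, 1.7), (20.8, 2.4), (21.2, 2.5), (26.2, 2.9), (20.2, 2.3),
               (20.3, 1.5), (22.4, 0.9), (16.4, 2.6), (18.0, 2.1), (18.7, 1.7)],
    },
    "flowering": {
        "PH": [(47.8, 5.4), (44.2, 6.2), (42.0, 2.7), (41.5, 4.7), (43.8, 3.3),
               (45.3, 7.1), (41.8, 7.3), (35.0, 4.1), (34.0, 3.7), (43.3, 2.1)],
        "CW": [(57.1, 4.6), (56.5, 11.2), (52.3, 5.4), (55.8, 4.3), (57.1, 9.1),
               (59.1, 6.0), (60.3, 8.0), (48.0, 4.0), (44.8, 3.7), (56.5, 4.3)],
        "BN": [(1.8, 0.5), (2.3, 0.5), (3.0, 1.1), (3.0, 0.0), (3.5, 0.6),
               (3.8, 1.0), (3.5, 0.6), (3.3, 0.5), (3.5, 0.6), (2.5, 0.6)],
        "SPAD": [(38.3, 3.5), (33.4, 2.5), (35.5, 1.4), (35.3, 1.1), (34.0, 2.6),
                 (34.5, 2.2), (35.5, 3.8), (28.8, 4.6), (30.1, 2.3), (32.5, 3.1)],
        "BD": [(8.45, 1.54), (7.82, 0.59), (7.60, 0.64), (8.00, 0.60), (8.05, 0.56),
               (8.09, 0.56), (7.61, 0.57), (7.21, 0.96), (7.58, 0.85), (8.54, 0.47)],
        "LL": [(35.5, 4.2), (32.8, 2.6), (31.6, 2.1), (33.3, 3.1), (34.1, 3.5),
               (36.5, 3.8), (32.1, 2.2), (29.0, 3.3), (28.3, 2.3), (34.5, 2.7)],
        "LT": [(0.17, 0.01), (0.17, 0.01), (0.16, 0.01), (0.16, 0.01), (0.17, 0.01),
               (0.15, 0.01), (0.16, 0.01), (0.17, 0.01), (0.17, 0.01), (0.17, 0.01)],
        "CWI": [(1.20, 0.05), (1.27, 0.10), (1.24, 0.08), (1.35, 0.06), (1.30, 0.12),
                (1.32, 0.09), (1.45, 0.07), (1.38, 0.09), (1.32, 0.04), (1.31, 0.07)],
        "FNP": [(1.8, 0.5), (1.3, 0.5), (1.8, 0.5), (2.3, 0.5), (2.0, 0.8),
                (3.0, 0.1), (2.3, 1.0), (1.0, 0.1), (1.8, 1.0), (1.5, 0.6)],
        "FD": [(189.2, 4.4), (198.7, 2.8), (191.4, 12.0), (181.7, 16.2), (175.2, 20.1),
               (188.5, 17.8), (175.7, 21.6), (150.6, 10.5), (156.7, 29.5), (189.7, 15.4)],
        "L*": [(49.6, 5.3), (50.3, 1.8), (41.1, 3.3), (45.7, 5.7), (48.8, 6.9),
               (52.8, 5.9), (52.4, 8.2), (58.9, 1.9), (52.8, 5.7), (58.1, 3.0)],
        "a*": [(25.2, 3.7), (27.8, 0.6), (32.1, 2.5), (32.1, 1.2), (26.2, 5.0),
               (21.8, 7.0), (24.2, 7.9), (19.4, 5.9), (19.7, 6.6), (17.4, 2.8)],
        "PAC": [(24.7, 0.7), (29.3, 0.9), (40.6, 1.5), (34.2, 1.9), (28.9, 1.2),
                (21.5, 0.9), (34.0, 1.6), (19.4, 0.2), (19.5, 0.7), (16.3, 0.4)],
        "PFC": [(26.9, 1.5), (28.4, 0.7), (32.0, 0.8), (34.9, 2.6), (30.5, 1.3),
                (29.3, 0.5), (34.9, 2.1), (26.7, 1.0), (27.0, 0.9), (27.8, 1.9)],
        "PSSC": [(36.3, 2.7), (36.7, 2.4), (33.2, 1.2), (32.8, 1.3), (37.4, 3.0),
                 (32.1, 4.8), (34.6, 2.6), (32.8, 1.2), (32.6, 5.4), (28.6, 4.4)],
        "FI": [(16.0, 1.4), (16.8, 1.5), (18.3, 2.5), (19.8, 2.1), (17.0, 2.2),
               (18.5, 0.6), (19.0, 2.0), (11.5, 1.9), (13.5, 2.7), (14.0, 1.4)],
    },
}


def builtin_fixture() -> list[GroupSpec]:
    """All published group summaries: 10 groups x 3 stages."""
    specs = []
    for stage in STAGES:
        traits_by_group: dict[str, dict[str, tuple[float, float, int]]] = {
            g: {} for g in _GROUPS
        }
        for code, rows in _SUMMARIES[stage].items():
            n = _N_BY_TRAIT.get(code, _DEFAULT_N)
            for gid, (mean, se) in zip(_GROUPS, rows):
                traits_by_group[gid][code] = (mean, se, n)
        for gid in _GROUPS:
            specs.append(GroupSpec(gid, stage, traits_by_group[gid]))
    return specs


def fixture_summary(stage: str | None = None) -> pd.DataFrame:
    """Fixture as a tidy frame: group_id, stage, trait_code, mean, se, n."""
    rows = [
        {
            "group_id": s.group_id,
            "stage": s.stage,
            "trait_code": code,
            "mean": mean,
            "se": se,
            "n": n,
        }
        for s in builtin_fixture()
        for code, (mean, se, n) in s.traits.items()
        if stage is None or s.stage == stage
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# replicate generation
# ---------------------------------------------------------------------------

def _count_pmf(mean: float, sd: float) -> tuple[np.ndarray, np.ndarray]:
    """Distribution on {0..COUNT_SUPPORT_MAX} from rounding N(mu, sd),
    with mu calibrated so the discretized mean matches *mean* within
    0.05 (exactly, via root finding)."""
    support = np.arange(COUNT_SUPPORT_MAX + 1)

    def pmf_for(mu: float) -> np.ndarray:
        upper = np.where(support == COUNT_SUPPORT_MAX, np.inf, support + 0.5)
        lower = np.where(support == 0, -np.inf, support - 0.5)
        probs = sps.norm.cdf(upper, mu, sd) - sps.norm.cdf(lower, mu, sd)
        return probs / probs.sum()

    def mean_err(mu: float) -> float:
        return float(pmf_for(mu) @ support) - mean

    lo, hi = mean - 6 * sd - 1, mean + 6 * sd + 1
    try:
        mu = brentq(mean_err, lo, hi, xtol=1e-10)
    except ValueError as exc:
        raise DomainError(
            f"cannot match count mean {mean} on support 0..{COUNT_SUPPORT_MAX}"
        ) from exc
    pmf = pmf_for(mu)
    assert abs(pmf @ support - mean) <= _COUNT_MEAN_TOL
    return support, pmf


def _draw_trait(
    rng: np.random.Generator, kind: str, mean: float, sd: float, n: int
) -> np.ndarray:
    if sd == 0.0:
        if kind == COUNT:
            if abs(mean - round(mean)) > _COUNT_MEAN_TOL:
                raise DomainError(
                    f"degenerate count trait mean {mean} is not an integer"
                )
            return np.full(n, float(round(mean)))
        if kind == CONTINUOUS_POSITIVE and mean <= 0:
            raise DomainError("positive trait with mean <= 0")
        return np.full(n, float(mean))
    if kind == COUNT:
        support, pmf = _count_pmf(mean, sd)
        return rng.choice(support, size=n, p=pmf).astype(float)
    if kind == CONTINUOUS_POSITIVE:
        if mean <= 0:
            raise DomainError(
                f"cannot generate strictly positive trait with mean {mean}"
            )
        out = rng.normal(mean, sd, size=n)
        # redraw non-positive values; preserves the distribution shape
        # far better than clipping for the ~sd-away-from-zero means here
        for _ in range(1000):
            bad = out <= 0
            if not bad.any():
                return out
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        raise DomainError(
            f"truncation failed: mean {mean} too close to zero for sd {sd}"
        )
    return rng.normal(mean, sd, size=n)


_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}


def _trait_rng(seed: int, group_id: str, stage: str, trait_code: str) -> np.random.Generator:
    # stable per-(group, stage, trait) stream regardless of generation order
    key = [
        int(seed),
        _STAGE_INDEX[stage],
        *[ord(c) for c in group_id],
        0,
        *[ord(c) for c in trait_code],
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def generate_plants(
    spec: GroupSpec,
    config: SimulationConfig,
    catalog: TraitCatalog = DEFAULT_CATALOG,
) -> pd.DataFrame:
    """Synthetic replicate rows for one (group, stage) summary.

    Returns a long-form frame (TraitTable columns).  Plant ids are
    ``<group>-<stage initial><replicate>``; replicate i of two traits
    with equal n refers to the same synthetic plant.
    """
    prefix = f"{spec.group_id}-{spec.stage[0]}"
    frames = []
    for code in sorted(spec.traits):
        mean, se, n = spec.traits[code]
        n = config.n_override or n
        sd = se * np.sqrt(spec.traits[code][2])  # replicate SD from printed SE
        rng = _trait_rng(config.seed, spec.group_id, spec.stage, code)
        values = _draw_trait(rng, catalog.kind(code), mean, sd, n)
        frames.append(
            pd.DataFrame(
                {
                    "plant_id": [f"{prefix}{i + 1}" for i in range(n)],
                    "group_id": spec.group_id,
                    "stage": spec.stage,
                    "trait_code": code,
                    "value": values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[list(COLUMNS)]


def generate_study(
    specs: Sequence[GroupSpec] | None = None,
    config: SimulationConfig | None = None,
    design: GroupDesign = DEFAULT_DESIGN,
    catalog: TraitCatalog = DEFAULT_CATALOG,
) -> tuple[TraitTable, GroupDesign]:
    """Full synthetic study table (all groups, all stages).

    With a planted effect configured, the response trait is regenerated
    per replicate as intercept + slope * predictor + Normal(0, sd),
    matching predictor and response replicates by (group, index) across
    stages.
    """
    if specs is None:
        specs = builtin_fixture()
    if config is None:
        raise ValidationError("a SimulationConfig with a seed is required")
    frames = [generate_plants(s, config, catalog) for s in specs]
    data = pd.concat(frames, ignore_index=True)

    if config.effect is not None:
        data = _apply_effect(data, config, catalog)

    table = TraitTable(data=data, catalog=catalog)
    table.validate(design)
    return table, design


def _replicate_index(plant_id: pd.Series) -> pd.Series:
    return plant_id.str.extract(r"(\d+)$")[0].astype(int)


def _apply_effect(
    data: pd.DataFrame, config: SimulationConfig, catalog: TraitCatalog
) -> pd.DataFrame:
    eff = config.effect
    pred = data[data["trait_code"] == eff.predictor].copy()
    resp_mask = data["trait_code"] == eff.response
    if pred.empty or not resp_mask.any():
        raise ValidationError(
            f"planted effect needs traits {eff.predictor!r} and {eff.response!r}"
        )
    pred["rep"] = _replicate_index(pred["plant_id"])
    lookup = pred.set_index(["group_id", "rep"])["value"]
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 999_983])
    )
    resp = data.loc[resp_mask].copy()
    reps = _replicate_index(resp["plant_id"])
    keys = list(zip(resp["group_id"], reps))
    missing = [k for k in keys if k not in lookup.index]
    if missing:
        raise ValidationError(
            f"planted effect: no predictor replicate for {missing[:5]}"
        )
    x = lookup.loc[keys].to_numpy(dtype=float)
    noise = rng.normal(0.0, eff.noise_sd, size=len(x))
    data = data.copy()
    data.loc[resp_mask, "value"] = eff.intercept + eff.slope * x + noise
    return data
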