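"""Trait catalog: codes, descriptions, units and measurement kinds.

Every trait handled by the pipeline is registered here.  The *kind* of a
trait controls validation (strict positivity for continuous traits,
integrality for counts) and how the synthetic generator draws replicates:

``continuous_positive``
    strictly positive continuous measurement (lengths, rates, biomass,
    pigment contents, derived ratios);
``count``
    small non-negative integer per plant (branch number, flowers per
    plant);
``score``
    continuous or integer index without a positivity constraint enforced
    at the per-plant level (SPAD reading, composite flowering index);
``color``
    CIELAB coordinate, may take any real value (L*, a*).

Three measurement campaigns (growth stages) are distinguished:
``vigorous_growth`` (leaf gas exchange and antioxidant assays in May),
``defoliation`` (destructive morphology and carbohydrate harvest in
October) and ``flowering`` (ornamental traits at forced peak bloom).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

STAGES = ("vigorous_growth", "defoliation", "flowering")

CONTINUOUS_POSITIVE = "continuous_positive"
COUNT = "count"
SCORE = "score"
COLOR = "color"
KINDS = frozenset({CONTINUOUS_POSITIVE, COUNT, SCORE, COLOR})


@dataclass(frozen=True)
class Trait:
    """One catalog entry.

    ``stage`` records the campaign in which the trait is measured; it is
    informational (a trait value row carries its own stage).
    """

    code: str
    description: str
    units: str
    kind: str
    stage: str | None = None

    def __post_init__(self) -> None:
        if not self.code:
            raise ValidationError("trait code must be non-empty")
        if self.kind not in KINDS:
            raise ValidationError(
                f"unknown trait kind {self.kind!r} for {self.code!r}"
            )
        if self.stage is not None and self.stage not in STAGES:
            raise ValidationError(
                f"unknown stage {self.stage!r} for trait {self.code!r}"
            )


@dataclass(frozen=True)
class TraitCatalog:
    entries: tuple[Trait, ...]

    def __post_init__(self) -> None:
        codes = [t.code for t in self.entries]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValidationError(f"duplicate trait codes: {dupes}")

    def __contains__(self, code: str) -> bool:
        return any(t.code == code for t in self.entries)

    def __getitem__(self, code: str) -> Trait:
        for t in self.entries:
            if t.code == code:
                return t
        raise KeyError(code)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(t.code for t in self.entries)

    def kind(self, code: str) -> str:
        return self[code].kind


_VG = "vigorous_growth"
_DF = "defoliation"
_FL = "flowering"

#: All traits of the study, in table order.
DEFAULT_CATALOG = TraitCatalog(
    entries=(
        Trait("Pn", "net photosynthetic rate", "umol CO2 m-2 s-1", CONTINUOUS_POSITIVE, _VG),
        Trait("Gs", "stomatal conductance", "mmol H2O m-2 s-1", CONTINUOUS_POSITIVE, _VG),
        Trait("Ci", "intercellular CO2 concentration", "umol mol-1", CONTINUOUS_POSITIVE, _VG),
        Trait("Tr", "transpiration rate", "mmol H2O m-2 s-1", CONTINUOUS_POSITIVE, _VG),
        Trait("WUE", "water use efficiency (Pn/Tr)", "umol CO2 mmol-1 H2O", CONTINUOUS_POSITIVE, _VG),
        Trait("LA", "leaf area per plant", "cm2 plant-1", CONTINUOUS_POSITIVE, _VG),
        Trait("POD", "peroxidase activity", "U g-1 h-1", CONTINUOUS_POSITIVE, _VG),
        Trait("MDA", "malondialdehyde content", "umol g-1", CONTINUOUS_POSITIVE, _VG),
        Trait("SL", "stem length", "mm", CONTINUOUS_POSITIVE, _DF),
        Trait("SD", "stem diameter", "mm", CONTINUOUS_POSITIVE, _DF),
        Trait("WPB", "whole plant biomass", "g plant-1", CONTINUOUS_POSITIVE, _DF),
        Trait("NSCAS", "NSC accumulation in stem", "g plant-1", CONTINUOUS_POSITIVE, _DF),
        Trait("NSCAR", "NSC accumulation in root", "g plant-1", CONTINUOUS_POSITIVE, _DF),
        Trait("NSCAT", "NSC accumulation in total plant", "g plant-1", CONTINUOUS_POSITIVE, _DF),
        Trait("SI", "seedling index (SD/SL x WPB)", "g", CONTINUOUS_POSITIVE, _DF),
        Trait("PH", "plant height", "cm", CONTINUOUS_POSITIVE, _FL),
        Trait("CW", "crown width", "cm", CONTINUOUS_POSITIVE, _FL),
        Trait("BN", "branch number", "count", COUNT, _FL),
        Trait("SPAD", "leaf SPAD chlorophyll reading", "SPAD units", SCORE, _FL),
        Trait("BD", "branch diameter", "mm", CONTINUOUS_POSITIVE, _FL),
        Trait("LL", "leaf length", "cm", CONTINUOUS_POSITIVE, _FL),
        Trait("LT", "leaf thickness", "mm", CONTINUOUS_POSITIVE, _FL),
        Trait("CWI", "crown width index (CW/PH)", "ratio", CONTINUOUS_POSITIVE, _FL),
        Trait("FNP", "flower number per plant", "count", COUNT, _FL),
        Trait("FD", "flower diameter", "mm", CONTINUOUS_POSITIVE, _FL),
        Trait("L*", "petal CIELAB lightness", "CIELAB", COLOR, _FL),
        Trait("a*", "petal CIELAB red-green coordinate", "CIELAB", COLOR, _FL),
        Trait("PAC", "petal anthocyanin content", "U g-1", CONTINUOUS_POSITIVE, _FL),
        Trait("PFC", "petal flavonoid content", "mg g-1", CONTINUOUS_POSITIVE, _FL),
        Trait("PSSC", "petal soluble sugars content", "mg g-1", CONTINUOUS_POSITIVE, _FL),
        Trait("FI", "flowering index (sum of six rubric levels)", "score", SCORE, _FL),
        Trait("CI", "crown index (100 x CWI)", "score", SCORE, _FL),
    )
)
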