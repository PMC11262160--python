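"""Fixed nutritional reference constants.

Houses the estimated average requirements (EAR), tolerable upper intake
levels (UL), and externally imputed within:between-person variance ratios
used throughout the pipeline, together with the Ethiopian multiple-fortified
salt (MFS) reference design: per-group discretionary salt intakes derived
from the 2015 WHO STEPS urinary-sodium survey and the fortificant addition
rates adopted for the two salt scenarios.

EAR/UL values are loaded from a packaged CSV (``data/ear_ul.csv``) and can
be overridden with a user file of the same schema.  For folate the UL column
holds the *folic-acid* (fortificant) UL, following the IOM convention that
the UL applies to synthetic folic acid rather than total dietary folate;
the excess-intake check in :mod:`saltfort.adequacy` therefore compares
fortificant-delivered micrograms against it, while zinc excess is checked on
total usual intake.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

NUTRIENTS = ("zinc", "folate")
LIFE_STAGES = ("child_1_3y", "woman_15_49y", "man_19_45y")
STATUSES = ("none", "pregnant", "lactating")
REGIONS = ("AddisAbaba", "Somali")

#: Aliases accepted anywhere a nutrient name is taken.  "folic_acid" refers
#: to the fortificant; its references live on the folate rows.
_NUTRIENT_ALIASES = {"folic_acid": "folate", "zn": "zinc"}

#: Sodium-chloride equivalence used by the source surveys: 2000 mg Na ~ 5 g salt.
SODIUM_TO_SALT_FACTOR = 2.5 / 1000.0

#: Mean total salt intake of Ethiopian adults (g/d), WHO STEPS 2015.
ADULT_TOTAL_SALT_G_D = 8.3

#: Fraction of total salt assumed discretionary (cooking/table + processed food).
DISCRETIONARY_FRACTION = 0.9

#: WHO recommended maximum adult salt intake (g/d).
RECOMMENDED_ADULT_SALT_G_D = 5.0

#: Fortificant addition rates per gram of salt for the two scenarios:
#: "calculated" pairs with urinary-sodium-derived discretionary salt,
#: "recommended" with the WHO 5 g/d scenario.
FORTIFICANT_RATES = {
    "calculated": {"zinc_mg_per_g": 0.6, "folic_acid_ug_per_g": 22.0},
    "recommended": {"zinc_mg_per_g": 0.8, "folic_acid_ug_per_g": 30.0},
}

#: Reference discretionary salt intakes (g/d) by region and demographic group
#: entering the MFS design arithmetic: "calculated" from urinary sodium,
#: "recommended" from the WHO limit (children scaled by energy intake).
REFERENCE_SALT_G_D = pd.DataFrame(
    [
        ("AddisAbaba", "child_1_3y", 3.0, 2.3),
        ("AddisAbaba", "woman_15_49y", 6.7, 5.0),
        ("AddisAbaba", "man_19_45y", 8.5, 5.0),
        ("Somali", "child_1_3y", 2.4, 2.3),
        ("Somali", "woman_15_49y", 5.3, 5.0),
        ("Somali", "man_19_45y", 6.8, 5.0),
    ],
    columns=["region", "life_stage", "calculated", "recommended"],
)


class ReferenceLookupError(KeyError):
    """Unknown nutrient, demographic group, or age class in a reference table."""


def canonical_nutrient(nutrient: str) -> str:
    name = nutrient.lower()
    name = _NUTRIENT_ALIASES.get(name, name)
    if name not in NUTRIENTS:
        raise ReferenceLookupError(f"unknown nutrient {nutrient!r}")
    return name


@dataclass(frozen=True)
class DemographicGroup:
    """A survey demographic stratum: life stage plus physiological status.

    ``status`` other than ``"none"`` is only meaningful for women of
    reproductive age (pregnant / lactating).
    """

    life_stage: str
    status: str = "none"

    def __post_init__(self) -> None:
        if self.life_stage not in LIFE_STAGES:
            raise ValueError(f"unknown life stage {self.life_stage!r}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown physiological status {self.status!r}")
        if self.status != "none" and self.life_stage != "woman_15_49y":
            raise ValueError(
                f"status {self.status!r} is only valid for woman_15_49y, "
                f"got {self.life_stage!r}"
            )

    @property
    def age_class(self) -> str:
        """"child" or "adult" — the key into the variance-ratio table."""
        return "child" if self.life_stage == "child_1_3y" else "adult"


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("saltfort.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


class NutrientReferences:
    """EAR/UL and variance-ratio lookups with explicit failure on misses."""

    def __init__(self, ear_ul: pd.DataFrame, variance_ratios: pd.DataFrame):
        required = {"nutrient", "life_stage", "status", "ear", "ul"}
        if missing := required - set(ear_ul.columns):
            raise ValueError(f"ear_ul table missing columns: {sorted(missing)}")
        required = {"nutrient", "age_class", "ratio"}
        if missing := required - set(variance_ratios.columns):
            raise ValueError(
                f"variance_ratios table missing columns: {sorted(missing)}"
            )
        if (ear_ul["ear"] <= 0).any():
            raise ValueError("all EAR values must be > 0")
        if (ear_ul["ul"] <= ear_ul["ear"]).any():
            bad = ear_ul[ear_ul["ul"] <= ear_ul["ear"]]
            raise ValueError(f"UL must exceed EAR; offending rows:\n{bad}")
        if (variance_ratios["ratio"] <= 0).any():
            raise ValueError("all variance ratios must be > 0")
        self._ear_ul = ear_ul.set_index(["nutrient", "life_stage", "status"])
        self._ratios = variance_ratios.set_index(["nutrient", "age_class"])["ratio"]

    # -- constructors -----------------------------------------------------

    @classmethod
    def default(cls) -> "NutrientReferences":
        """References from the packaged CSV files."""
        return cls(_read_packaged("ear_ul.csv"), _read_packaged("variance_ratios.csv"))

    @classmethod
    def from_files(cls, ear_ul_path=None, variance_path=None) -> "NutrientReferences":
        """Packaged defaults, with either table overridable by a user CSV."""
        ear_ul = (
            pd.read_csv(ear_ul_path) if ear_ul_path else _read_packaged("ear_ul.csv")
        )
        ratios = (
            pd.read_csv(variance_path)
            if variance_path
            else _read_packaged("variance_ratios.csv")
        )
        return cls(ear_ul, ratios)

    # -- lookups ----------------------------------------------------------

    def _row(self, nutrient: str, group: DemographicGroup) -> pd.Series:
        key = (canonical_nutrient(nutrient), group.life_stage, group.status)
        try:
            return self._ear_ul.loc[key]
        except KeyError:
            raise ReferenceLookupError(
                f"no EAR/UL entry for nutrient={key[0]!r}, "
                f"life_stage={key[1]!r}, status={key[2]!r}"
            ) from None

    def ear(self, nutrient: str, group: DemographicGroup) -> float:
        """Estimated average requirement (amount/day) for a demographic group."""
        return float(self._row(nutrient, group)["ear"])

    def ul(self, nutrient: str, group: DemographicGroup) -> float:
        """Tolerable upper intake level (amount/day); for folate this is the
        folic-acid (fortificant) UL."""
        return float(self._row(nutrient, group)["ul"])

    def variance_ratio(self, nutrient: str, age_class: str) -> float:
        """Within:between-person variance ratio on the transformed scale."""
        key = (canonical_nutrient(nutrient), age_class)
        try:
            return float(self._ratios.loc[key])
        except KeyError:
            raise ReferenceLookupError(
                f"no variance ratio for nutrient={key[0]!r}, age_class={key[1]!r}"
            ) from None

    # -- persistence ------------------------------------------------------

    def write(self, ear_ul_path, variance_path) -> None:
        """Write both tables back out (round-trips with :meth:`from_files`)."""
        self._ear_ul.reset_index().to_csv(ear_ul_path, index=False)
        self._ratios.reset_index().to_csv(variance_path, index=False)


def lookup_ear(nutrient: str, group: DemographicGroup) -> float:
    return NutrientReferences.default().ear(nutrient, group)


def lookup_ul(nutrient: str, group: DemographicGroup) -> float:
    return NutrientReferences.default().ul(nutrient, group)


def variance_ratio(nutrient: str, age_class: str) -> float:
    return NutrientReferences.default().variance_ratio(nutrient, age_class)
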