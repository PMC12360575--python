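"""Feature catalog: the variable taxonomy driving every downstream subset.

The catalog declares, for each raw variable, its category (early-life
factor, sociodemographic, blood assay, ...), its type and categorical
levels, whether it is a laboratory measurement, and whether it belongs to
the seven "core" predictors used by the published CVD and diabetes scores.
Subsets such as "ELF", "core-7" or "non-laboratory" are always *computed*
from these declarations, never hard-coded elsewhere.

The default catalog describes a synthetic UK-Biobank-like variable panel:
64 raw variables (8 of them early-life factors) that one-hot encode into
83 feature columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

CATEGORIES = (
    "ELF",
    "sociodemographic",
    "blood_assay",
    "physical",
    "lifestyle",
    "psychosocial",
    "family_history",
    "medical_history",
    "mental_health",
)
DTYPES = ("binary", "categorical", "continuous")
TASKS = ("CVD", "diabetes")


@dataclass(frozen=True)
class VariableDef:
    """Declaration of one raw variable."""

    name: str
    category: str
    dtype: str
    levels: tuple[str, ...] = ()
    is_lab: bool = False
    core7_for: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.name}")
        if self.dtype not in DTYPES:
            raise ValueError(f"unknown dtype {self.dtype!r} for {self.name}")
        if self.dtype == "categorical" and len(self.levels) < 2:
            raise ValueError(f"categorical {self.name} needs >=2 levels")
        if self.dtype != "categorical" and self.levels:
            raise ValueError(f"{self.name}: levels only allowed for categoricals")
        if not self.core7_for <= set(TASKS):
            raise ValueError(f"{self.name}: core7_for must be a subset of {TASKS}")

    @property
    def encoded_columns(self) -> list[str]:
        """Encoded column names this variable expands to (full one-hot)."""
        if self.dtype == "categorical":
            return [f"{self.name}_{lv}" for lv in self.levels]
        return [self.name]


@dataclass
class FeatureCatalog:
    """Ordered collection of :class:`VariableDef` with subset accessors."""

    entries: list[VariableDef] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("variable names must be unique")

    # -- lookups -------------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> VariableDef:
        return self._by_name[name]

    @property
    def _by_name(self) -> dict[str, VariableDef]:
        return {e.name: e for e in self.entries}

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def encoded_names(self) -> list[str]:
        return [c for e in self.entries for c in e.encoded_columns]

    @property
    def n_encoded(self) -> int:
        return len(self.encoded_names)

    def encoded_map(self) -> dict[str, list[str]]:
        """Raw variable name -> its encoded column names."""
        return {e.name: e.encoded_columns for e in self.entries}

    def by_category(self, category: str) -> list[str]:
        return [e.name for e in self.entries if e.category == category]

    @property
    def elf_names(self) -> list[str]:
        return self.by_category("ELF")

    def core7(self, task: str) -> list[str]:
        if task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        return [e.name for e in self.entries if task in e.core7_for]

    def lab_names(self) -> list[str]:
        return [e.name for e in self.entries if e.is_lab]

    def nonlab_names(self) -> list[str]:
        return [e.name for e in self.entries if not e.is_lab]

    def continuous_names(self) -> list[str]:
        return [e.name for e in self.entries if e.dtype == "continuous"]

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "name": e.name,
                "category": e.category,
                "dtype": e.dtype,
                "levels": list(e.levels),
                "is_lab": e.is_lab,
                "core7_for": sorted(e.core7_for),
            }
            for e in self.entries
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureCatalog":
        payload = json.loads(Path(path).read_text())
        entries = [
            VariableDef(
                name=d["name"],
                category=d["category"],
                dtype=d["dtype"],
                levels=tuple(d.get("levels", ())),
                is_lab=bool(d.get("is_lab", False)),
                core7_for=frozenset(d.get("core7_for", ())),
            )
            for d in payload
        ]
        return cls(entries)


def _v(
    name: str,
    category: str,
    dtype: str = "continuous",
    levels: Iterable[str] = (),
    is_lab: bool = False,
    core7: Iterable[str] = (),
) -> VariableDef:
    return VariableDef(name, category, dtype, tuple(levels), is_lab, frozenset(core7))


def default_catalog() -> FeatureCatalog:
    """The default 64-variable panel (83 encoded columns, 8 ELFs).

    Variable names follow UK-Biobank-style phenotype labels. Exactly seven
    variables are flagged as core for each prediction task, mirroring the
    inputs of the Framingham (CVD) and Leicester/DiabetesUK (diabetes)
    scores.
    """
    e: list[VariableDef] = []
    # sociodemographic (7)
    e += [
        _v("Age", "sociodemographic", core7=("CVD", "diabetes")),
        _v("Sex", "sociodemographic", "binary", core7=("CVD", "diabetes")),
        _v("Ethnicity", "sociodemographic", "categorical",
           ("White", "Asian", "Black", "Other"), core7=("diabetes",)),
        _v("AvgHouseholdIncome", "sociodemographic"),
        _v("Qualifications", "sociodemographic", "categorical",
           ("UnivDegree", "ALevels", "GCSE", "ProfQual", "NoneAbove")),
        _v("CurrentEmploymentStatus", "sociodemographic", "categorical",
           ("PaidOrSelfEmployed", "Retired", "SickOrDisabled", "Unemployed", "Other")),
        _v("TownsendDeprivationIndex", "sociodemographic"),
    ]
    # blood assays (9, laboratory)
    e += [
        _v("HbA1c", "blood_assay", is_lab=True),
        _v("Glucose", "blood_assay", is_lab=True),
        _v("Cholesterol", "blood_assay", is_lab=True, core7=("CVD",)),
        _v("HDLCholesterol", "blood_assay", is_lab=True, core7=("CVD",)),
        _v("LDLDirect", "blood_assay", is_lab=True),
        _v("Triglycerides", "blood_assay", is_lab=True),
        _v("ApolipoproteinA", "blood_assay", is_lab=True),
        _v("ApolipoproteinB", "blood_assay", is_lab=True),
        _v("CReactiveProtein", "blood_assay", is_lab=True),
    ]
    # physical measures (10)
    e += [
        _v("BMI", "physical", core7=("diabetes",)),
        _v("Height", "physical"),
        _v("Weight", "physical"),
        _v("WaistCircumference", "physical", core7=("diabetes",)),
        _v("HipCircumference", "physical"),
        _v("BodyFatPercentage", "physical"),
        _v("SystolicBloodPressure", "physical", core7=("CVD",)),
        _v("DiastolicBloodPressure", "physical"),
        _v("PulseRate", "physical"),
        _v("HandGripStrength", "physical"),
    ]
    # lifestyle (13)
    e += [
        _v("SmokingStatus", "lifestyle", "binary", core7=("CVD",)),
        _v("AlcoholIntakeFrequency", "lifestyle"),
        _v("PhysicalActivity", "lifestyle"),
        _v("SleepDuration", "lifestyle"),
        _v("FreshFruitIntake", "lifestyle"),
        _v("CookedVegetableIntake", "lifestyle"),
        _v("RawVegetableIntake", "lifestyle"),
        _v("ProcessedMeatIntake", "lifestyle"),
        _v("PorkIntake", "lifestyle"),
        _v("PoultryIntake", "lifestyle"),
        _v("CerealIntake", "lifestyle"),
        _v("WaterIntake", "lifestyle"),
        _v("SaltAddedToFood", "lifestyle", "binary"),
    ]
    # psychosocial (7)
    e += [
        _v("MoodSwings", "psychosocial", "binary"),
        _v("Loneliness", "psychosocial", "binary"),
        _v("Irritability", "psychosocial", "binary"),
        _v("FrequencyOfTirednessLethargy", "psychosocial"),
        _v("LeisureSocialActivities", "psychosocial", "binary"),
        _v("OverallHealthRating", "psychosocial"),
        _v("AbleToConfideInSomeone", "psychosocial", "binary"),
    ]
    # family history (3)
    e += [
        _v("IllnessesOfMother", "family_history", "categorical",
           ("None", "CVD", "Diabetes", "Other"), core7=("diabetes",)),
        _v("IllnessesOfFather", "family_history", "categorical",
           ("None", "CVD", "Diabetes", "Other")),
        _v("IllnessesOfSiblings", "family_history", "categorical",
           ("None", "CVD", "Diabetes")),
    ]
    # medical history (5)
    e += [
        _v("Hypertension", "medical_history", "binary", core7=("CVD", "diabetes")),
        _v("Diabetes", "medical_history", "binary"),
        _v("CVD", "medical_history", "binary"),
        _v("HighCholesterol", "medical_history", "binary"),
        _v("LongstandingIllness", "medical_history", "binary"),
    ]
    # mental health (2)
    e += [
        _v("Depression", "mental_health", "binary"),
        _v("Anxiety", "mental_health", "binary"),
    ]
    # early-life factors (8)
    e += [
        _v("BreastfedAsABaby", "ELF", "binary"),
        _v("MaternalSmokingAroundBirth", "ELF", "binary"),
        _v("FeltLovedAsAChild", "ELF", "binary"),
        _v("FeltHatedByFamilyMemberAsAChild", "ELF", "binary"),
        _v("PhysicallyAbusedByFamilyAsAChild", "ELF", "binary"),
        _v("SexuallyMolestedAsAChild", "ELF", "binary"),
        _v("SomeoneToTakeToDoctorWhenNeededAsAChild", "ELF", "binary"),
        _v("PartOfMultipleBirth", "ELF", "binary"),
    ]
    return FeatureCatalog(e)
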