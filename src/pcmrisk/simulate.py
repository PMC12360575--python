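"""Synthetic UK-Biobank-like cohort generator.

The generator produces cohorts with the statistical structure the
downstream analyses assume, so the whole pipeline is testable without any
restricted data access. The latent chain is:

    early-life factors (independent Bernoulli)
        -> adversity score -> mental-health flags (depression, anxiety)
    metabolic latent factor -> anthropometry and blood assays
    mental health + metabolic factor -> complementary baseline condition
    comorbid := (depression | anxiety) & complementary condition
    outcome  ~ logistic(proximal effects + ELF main effect
                        + ELF x comorbid interaction
                        + piecewise marker coupling) with subgroup-specific
                        label-flip noise

Design features mirroring the target analyses:

* ELFs are weakly predictive alone but carry an extra comorbid-only
  interaction, so their single-variable AUC and importance rankings are
  higher in the comorbid subgroup.
* Label noise is higher in the comorbid subgroup, so k-NN Bayes-error
  bounds come out higher there.
* The designated "HbA1c-like" marker couples to the outcome only above
  its population mean (flat below, linear above), so marker-stratified
  post-hoc comparisons show the marker carrying signal only in the
  high-normal stratum.

Intercepts for the outcome and the complementary condition are calibrated
by bisection so the realized prevalence and comorbid fraction hit their
targets by construction. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .catalog import CATEGORIES, FeatureCatalog, default_catalog
from .cohort import COMPLEMENTARY_FLAG, Cohort, assign_subgroups, encode_features
from .exceptions import DegenerateConfig

#: the designated continuous lab marker with piecewise outcome coupling
MARKER = "HbA1c"

#: ELF adversity signs: +1 adverse exposure, -1 protective exposure
_ELF_SIGNS = {
    "BreastfedAsABaby": -1.0,
    "MaternalSmokingAroundBirth": 1.0,
    "FeltLovedAsAChild": -1.0,
    "FeltHatedByFamilyMemberAsAChild": 1.0,
    "PhysicallyAbusedByFamilyAsAChild": 1.0,
    "SexuallyMolestedAsAChild": 1.0,
    "SomeoneToTakeToDoctorWhenNeededAsAChild": -1.0,
    "PartOfMultipleBirth": 0.5,
}
_ELF_PREVALENCE = {
    "BreastfedAsABaby": 0.70,
    "MaternalSmokingAroundBirth": 0.30,
    "FeltLovedAsAChild": 0.80,
    "FeltHatedByFamilyMemberAsAChild": 0.15,
    "PhysicallyAbusedByFamilyAsAChild": 0.10,
    "SexuallyMolestedAsAChild": 0.05,
    "SomeoneToTakeToDoctorWhenNeededAsAChild": 0.85,
    "PartOfMultipleBirth": 0.03,
}

#: per-encoded-column base log-odds weights (on standardized features)
_TASK_WEIGHTS: dict[str, dict[str, float]] = {
    "diabetes": {
        "Glucose": 0.50, "WaistCircumference": 0.50, "BMI": 0.35,
        "Triglycerides": 0.30, "HDLCholesterol": -0.30, "Age": 0.40,
        "Sex": 0.25, "Hypertension": 0.35, "OverallHealthRating": 0.30,
        "IllnessesOfMother_Diabetes": 0.40, "IllnessesOfSiblings_Diabetes": 0.30,
        "Depression": 0.20, "BodyFatPercentage": 0.25, "SleepDuration": -0.15,
        "ProcessedMeatIntake": 0.15,
    },
    "CVD": {
        "Age": 0.80, "SystolicBloodPressure": 0.50, "Cholesterol": 0.40,
        "HDLCholesterol": -0.40, "SmokingStatus": 0.40, "Glucose": 0.30,
        "WaistCircumference": 0.30, "Sex": 0.30, "Hypertension": 0.30,
        "OverallHealthRating": 0.30, "IllnessesOfMother_CVD": 0.35,
        "Depression": 0.25, "DiastolicBloodPressure": 0.25,
        "CReactiveProtein": 0.20, "AlcoholIntakeFrequency": 0.15,
    },
}


def _default_proximal() -> dict[str, float]:
    return {c: 1.0 for c in CATEGORIES}


def _default_missing() -> dict[str, float]:
    return {c: 0.0 for c in CATEGORIES}


@dataclass
class GeneratorConfig:
    """Cohort-generation parameters; defaults are the study conditions."""

    n_samples: int = 20_000
    seed: int = 0
    task: str = "diabetes"
    prevalence: float = 0.10
    comorbid_fraction: float = 0.15
    elf_main_effect: float = 0.0
    elf_comorbid_interaction: float = 2.0
    proximal_effects: dict[str, float] = field(default_factory=_default_proximal)
    marker_coupling: float = 0.8
    noise_rate_comorbid: float = 0.15
    noise_rate_noncomorbid: float = 0.03
    missing_rates: dict[str, float] = field(default_factory=_default_missing)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0.0 <= self.comorbid_fraction < 1.0:
            raise ValueError("comorbid_fraction must be in [0, 1)")
        for r in (self.noise_rate_comorbid, self.noise_rate_noncomorbid):
            if not 0.0 <= r < 0.5:
                raise ValueError("noise rates must be in [0, 0.5)")
        for cat, r in self.missing_rates.items():
            if not 0.0 <= r <= 0.25:
                raise ValueError(f"missing rate for {cat} must be in [0, 0.25]")

    @classmethod
    def from_mapping(cls, d: Mapping) -> "GeneratorConfig":
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        for name in ("proximal_effects", "missing_rates"):
            if name in d:
                base = getattr(cls(), name)
                base.update(d[name])
                setattr(cfg, name, base)
        return cfg


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(eta: np.ndarray, target: float, tol: float = 1e-3,
                         max_iter: int = 50) -> float:
    """Bisect b so that mean(sigmoid(b + eta)) = target (0.1 pp tolerance)."""
    lo, hi = -20.0, 20.0
    if _sigmoid(lo + eta).mean() > target or _sigmoid(hi + eta).mean() < target:
        raise DegenerateConfig(
            f"target rate {target} unreachable given effect scales")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + eta).mean() < target:
            lo = mid
        else:
            hi = mid
        if abs(_sigmoid(0.5 * (lo + hi) + eta).mean() - target) < tol:
            break
    return 0.5 * (lo + hi)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_cohort(config: GeneratorConfig,
                    catalog: FeatureCatalog | None = None,
                    return_truth: bool = False):
    """Draw one cohort; deterministic given ``config.seed``.

    With ``return_truth=True`` also returns a dict holding the encoded
    coefficient vector, adversity score, linear predictor and noiseless
    outcome probabilities, for recovery tests.
    """
    if catalog is None:
        catalog = default_catalog()
    if config.n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    n = config.n_samples
    rng = np.random.default_rng(config.seed)
    task = config.task
    cols: dict[str, np.ndarray | list] = {}

    # --- early-life factors and adversity ---------------------------------
    adversity = np.zeros(n)
    for name in catalog.elf_names:
        p = _ELF_PREVALENCE.get(name, 0.2)
        x = (rng.random(n) < p).astype(float)
        cols[name] = x
        adversity += _ELF_SIGNS.get(name, 1.0) * x
    adversity -= adversity.mean()

    # --- latent factors ----------------------------------------------------
    metabolic = 0.8 * rng.normal(size=n) + 0.10 * adversity
    deprivation = rng.normal(size=n)

    # --- sociodemographic --------------------------------------------------
    age = rng.uniform(40, 70, size=n)
    cols["Age"] = np.round(age, 1)
    cols["Sex"] = (rng.random(n) < 0.46).astype(float)
    cols["Ethnicity"] = rng.choice(
        ["White", "Asian", "Black", "Other"], size=n, p=[0.88, 0.05, 0.04, 0.03])
    cols["AvgHouseholdIncome"] = np.round(
        np.exp(10.5 - 0.25 * deprivation + 0.3 * rng.normal(size=n)), 0)
    cols["Qualifications"] = rng.choice(
        ["UnivDegree", "ALevels", "GCSE", "ProfQual", "NoneAbove"],
        size=n, p=[0.33, 0.12, 0.25, 0.12, 0.18])
    cols["CurrentEmploymentStatus"] = rng.choice(
        ["PaidOrSelfEmployed", "Retired", "SickOrDisabled", "Unemployed", "Other"],
        size=n, p=[0.55, 0.30, 0.05, 0.04, 0.06])
    cols["TownsendDeprivationIndex"] = np.round(deprivation * 3.0 - 1.3, 2)

    # --- physical measures -------------------------------------------------
    bmi = 27.0 + 4.2 * (0.65 * metabolic + 0.76 * rng.normal(size=n))
    height = 168.0 + 9.0 * rng.normal(size=n) + 6.0 * cols["Sex"]
    weight = bmi * (height / 100.0) ** 2
    cols["BMI"] = np.round(bmi, 2)
    cols["Height"] = np.round(height, 1)
    cols["Weight"] = np.round(weight, 1)
    cols["WaistCircumference"] = np.round(
        90.0 + 11.0 * (0.7 * metabolic + 0.71 * rng.normal(size=n)), 1)
    cols["HipCircumference"] = np.round(
        103.0 + 9.0 * (0.5 * metabolic + 0.87 * rng.normal(size=n)), 1)
    cols["BodyFatPercentage"] = np.round(
        30.0 + 7.0 * (0.55 * metabolic + 0.83 * rng.normal(size=n)), 1)
    cols["SystolicBloodPressure"] = np.round(
        138.0 + 17.0 * (0.35 * metabolic + 0.02 * (age - 55)
                        + 0.9 * rng.normal(size=n)), 0)
    cols["DiastolicBloodPressure"] = np.round(
        82.0 + 10.0 * (0.3 * metabolic + 0.95 * rng.normal(size=n)), 0)
    cols["PulseRate"] = np.round(69.0 + 11.0 * rng.normal(size=n), 0)
    cols["HandGripStrength"] = np.round(
        30.0 + 9.0 * rng.normal(size=n) + 8.0 * cols["Sex"], 1)

    # --- blood assays ------------------------------------------------------
    cols[MARKER] = np.round(
        5.34 + 0.55 * (0.5 * metabolic + 0.87 * rng.normal(size=n)), 3)
    cols["Glucose"] = np.round(
        5.1 + 1.1 * (0.55 * metabolic + 0.83 * rng.normal(size=n)), 3)
    cols["Cholesterol"] = np.round(5.7 + 1.1 * rng.normal(size=n), 3)
    cols["HDLCholesterol"] = np.round(
        1.45 + 0.38 * (-0.4 * metabolic + 0.92 * rng.normal(size=n)), 3)
    cols["LDLDirect"] = np.round(
        3.56 + 0.87 * (0.65 * _zscore(cols["Cholesterol"])
                       + 0.76 * rng.normal(size=n)), 3)
    cols["Triglycerides"] = np.round(np.exp(
        0.43 + 0.5 * (0.5 * metabolic + 0.87 * rng.normal(size=n))), 3)
    cols["ApolipoproteinA"] = np.round(
        1.54 + 0.27 * (0.6 * _zscore(cols["HDLCholesterol"])
                       + 0.8 * rng.normal(size=n)), 3)
    cols["ApolipoproteinB"] = np.round(
        1.03 + 0.24 * (0.6 * _zscore(cols["LDLDirect"])
                       + 0.8 * rng.normal(size=n)), 3)
    cols["CReactiveProtein"] = np.round(np.exp(
        0.3 + 1.0 * (0.3 * metabolic + 0.95 * rng.normal(size=n))), 3)

    # --- lifestyle ---------------------------------------------------------
    cols["SmokingStatus"] = (rng.random(n) < _sigmoid(
        -1.4 + 0.25 * deprivation + 0.15 * adversity)).astype(float)
    cols["AlcoholIntakeFrequency"] = np.round(rng.uniform(0, 6, size=n), 0)
    cols["PhysicalActivity"] = np.round(
        np.exp(3.0 + 0.8 * rng.normal(size=n) - 0.1 * metabolic), 0)
    cols["SleepDuration"] = np.round(7.1 + 1.1 * rng.normal(size=n), 1)
    for nm, mean in [("FreshFruitIntake", 2.1), ("CookedVegetableIntake", 2.7),
                     ("RawVegetableIntake", 2.0), ("ProcessedMeatIntake", 1.8),
                     ("PorkIntake", 1.1), ("PoultryIntake", 1.9),
                     ("CerealIntake", 4.4), ("WaterIntake", 2.6)]:
        cols[nm] = np.round(np.clip(mean + 1.2 * rng.normal(size=n), 0, None), 1)
    cols["SaltAddedToFood"] = (rng.random(n) < 0.45).astype(float)

    # --- psychosocial ------------------------------------------------------
    cols["MoodSwings"] = (rng.random(n) < _sigmoid(
        -0.7 + 0.3 * adversity)).astype(float)
    cols["Loneliness"] = (rng.random(n) < _sigmoid(
        -1.6 + 0.35 * adversity)).astype(float)
    cols["Irritability"] = (rng.random(n) < _sigmoid(
        -1.0 + 0.25 * adversity)).astype(float)
    cols["FrequencyOfTirednessLethargy"] = np.round(np.clip(
        1.6 + 0.25 * adversity + 0.15 * metabolic + 0.9 * rng.normal(size=n),
        1, 4), 1)
    cols["LeisureSocialActivities"] = (rng.random(n) < 0.62).astype(float)
    cols["OverallHealthRating"] = np.round(np.clip(
        2.1 + 0.25 * metabolic + 0.12 * adversity + 0.7 * rng.normal(size=n),
        1, 4), 1)
    cols["AbleToConfideInSomeone"] = (rng.random(n) < _sigmoid(
        1.3 - 0.25 * adversity)).astype(float)

    # --- family history ----------------------------------------------------
    cols["IllnessesOfMother"] = rng.choice(
        ["None", "CVD", "Diabetes", "Other"], size=n, p=[0.45, 0.25, 0.12, 0.18])
    cols["IllnessesOfFather"] = rng.choice(
        ["None", "CVD", "Diabetes", "Other"], size=n, p=[0.40, 0.30, 0.10, 0.20])
    cols["IllnessesOfSiblings"] = rng.choice(
        ["None", "CVD", "Diabetes"], size=n, p=[0.75, 0.15, 0.10])

    # --- medical and mental-health history --------------------------------
    cols["Hypertension"] = (rng.random(n) < _sigmoid(
        -1.2 + 0.5 * metabolic + 0.03 * (age - 55))).astype(float)
    cols["HighCholesterol"] = (rng.random(n) < _sigmoid(
        -1.8 + 0.6 * _zscore(cols["Cholesterol"]))).astype(float)
    cols["LongstandingIllness"] = (rng.random(n) < _sigmoid(
        -1.1 + 0.3 * metabolic + 0.2 * adversity)).astype(float)

    eta_dep = 0.55 * adversity + 0.25 * rng.normal(size=n)
    dep = (rng.random(n) < _sigmoid(
        _calibrate_intercept(eta_dep, 0.15) + eta_dep)).astype(float)
    eta_anx = 0.45 * adversity + 0.8 * dep + 0.25 * rng.normal(size=n)
    anx = (rng.random(n) < _sigmoid(
        _calibrate_intercept(eta_anx, 0.13) + eta_anx)).astype(float)
    cols["Depression"], cols["Anxiety"] = dep, anx
    mental = (dep + anx) > 0

    # complementary baseline condition, calibrated to the comorbid fraction
    comp_name = COMPLEMENTARY_FLAG[task]
    eta_comp = 0.7 * metabolic + 0.02 * (age - 55) + 0.5 * mental
    if config.comorbid_fraction == 0:
        comp = np.zeros(n)
    else:
        upper = (mental & True).mean()
        if config.comorbid_fraction >= upper:
            raise DegenerateConfig(
                f"comorbid_fraction {config.comorbid_fraction} exceeds the "
                f"mental-disorder rate {upper:.3f}")
        lo, hi = -20.0, 20.0
        u = rng.random(n)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            frac = ((u < _sigmoid(mid + eta_comp)) & mental).mean()
            if frac < config.comorbid_fraction:
                lo = mid
            else:
                hi = mid
        comp = (u < _sigmoid(0.5 * (lo + hi) + eta_comp)).astype(float)
    cols[comp_name] = comp
    # predicted condition is absent at baseline (prevalent cases excluded)
    cols[{"CVD": "CVD", "diabetes": "Diabetes"}[task]] = np.zeros(n)

    # --- assemble cohort ---------------------------------------------------
    raw = pd.DataFrame({name: cols[name] for name in catalog.names},
                       index=[f"S{i:06d}" for i in range(n)])
    mask = pd.DataFrame(False, index=raw.index, columns=raw.columns)
    cohort = Cohort(raw=raw, catalog=catalog, missing_mask=mask)
    cohort = assign_subgroups(cohort, task)
    comorbid = cohort.comorbid

    # --- outcome model -----------------------------------------------------
    enc = encode_features(cohort).encoded
    weights = _TASK_WEIGHTS[task]
    var_of = {c: v for v, cs in catalog.encoded_map().items() for c in cs}
    coef = {}
    eta = np.zeros(n)
    for col, w in weights.items():
        scale = config.proximal_effects.get(catalog[var_of[col]].category, 1.0)
        coef[col] = w * scale
        eta += coef[col] * _zscore(enc[col].to_numpy())
    marker_z = _zscore(enc[MARKER].to_numpy())
    eta += config.marker_coupling * np.maximum(marker_z, 0.0)
    eta += config.elf_main_effect * adversity
    eta += config.elf_comorbid_interaction * adversity * comorbid

    # calibrate the intercept on the post-noise prevalence:
    # E[y] = p (1 - r) + (1 - p) r with subgroup-specific flip rate r
    flip_rate = np.where(comorbid, config.noise_rate_comorbid,
                         config.noise_rate_noncomorbid)
    lo, hi = -20.0, 20.0
    def _noisy_rate(b: float) -> float:
        p = _sigmoid(b + eta)
        return float((p * (1 - flip_rate) + (1 - p) * flip_rate).mean())
    if _noisy_rate(lo) > config.prevalence or _noisy_rate(hi) < config.prevalence:
        raise DegenerateConfig(
            f"target prevalence {config.prevalence} unreachable given noise rates")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _noisy_rate(mid) < config.prevalence:
            lo = mid
        else:
            hi = mid
    b0 = 0.5 * (lo + hi)
    p_true = _sigmoid(b0 + eta)
    y = (rng.random(n) < p_true).astype(int)
    flips = rng.random(n) < flip_rate
    y = np.where(flips, 1 - y, y)
    cohort.outcomes[task] = y

    if any(r > 0 for r in config.missing_rates.values()):
        cohort = inject_missingness(cohort, config)

    if return_truth:
        truth = {"coef": coef, "intercept": b0, "adversity": adversity,
                 "eta": eta, "p": p_true,
                 "marker_coupling": config.marker_coupling}
        return cohort, truth
    return cohort


_PROTECTED = {"Depression", "Anxiety", "CVD", "Diabetes"}


def inject_missingness(cohort: Cohort, config: GeneratorConfig) -> Cohort:
    """Blank cells missing-at-random at per-category rates.

    The baseline diagnosis flags needed for subgroup assignment are never
    blanked. Within positive-outcome rows the realized per-variable rate
    is capped at 25% (excess blanks are restored), mirroring the
    missingness screen applied to the real cohort.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    out = cohort.copy()
    mask = out.missing_mask
    y = out.outcomes.get(config.task)
    pos = None if y is None else np.flatnonzero(y == 1)
    for var in cohort.catalog.entries:
        rate = config.missing_rates.get(var.category, 0.0)
        if rate <= 0 or var.name in _PROTECTED:
            continue
        hit = rng.random(cohort.n_samples) < rate
        if pos is not None and len(pos):
            cap = int(0.25 * len(pos))
            hit_pos = np.flatnonzero(hit[pos])
            if len(hit_pos) > cap:
                drop = rng.choice(hit_pos, size=len(hit_pos) - cap, replace=False)
                hit[pos[drop]] = False
        mask.loc[hit, var.name] = True
    vals = out.raw.to_numpy(object)
    m = mask.to_numpy()
    vals[m] = np.nan
    raw = pd.DataFrame(vals, index=out.raw.index, columns=out.raw.columns)
    out.raw = _retype(raw, cohort)
    out.encoded = None
    return out


def _retype(raw: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    for var in cohort.catalog.entries:
        if var.dtype != "categorical":
            raw[var.name] = raw[var.name].astype(float)
    return raw
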