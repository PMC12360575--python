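"""Cohort container, tabular I/O, encoding, imputation and subgroups.

A :class:`Cohort` holds the raw variable table (samples x raw variables),
a boolean missingness mask, the one-hot encoded feature matrix once
built, per-task outcome labels, and — after subgroup assignment — the
comorbidity flag that every downstream evaluation stratifies on.

Comorbidity is defined at baseline as a mental disorder (depression or
anxiety) co-occurring with the condition complementary to the prediction
task: diabetes when predicting CVD, CVD when predicting diabetes.

Conventions: samples are rows, features are columns; fold indices are
0-based; in delimited files an empty string denotes a missing cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.model_selection import StratifiedKFold

from .catalog import FeatureCatalog, TASKS
from .exceptions import (
    ExcessMissingness,
    LevelMismatch,
    MissingFlag,
    MissingValues,
    UnknownVariable,
)

#: reserved (non-catalog) outcome columns accepted in cohort tables
OUTCOME_COLUMNS = {f"outcome_{t}": t for t in TASKS}

#: complementary baseline condition defining comorbidity for each task
COMPLEMENTARY_FLAG = {"CVD": "Diabetes", "diabetes": "CVD"}
MENTAL_FLAGS = ("Depression", "Anxiety")


@dataclass
class Cohort:
    raw: pd.DataFrame
    catalog: FeatureCatalog
    missing_mask: pd.DataFrame
    outcomes: dict[str, np.ndarray] = field(default_factory=dict)
    encoded: pd.DataFrame | None = None
    task: str | None = None
    comorbid: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.raw)

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.raw.index]

    @property
    def outcome(self) -> np.ndarray:
        if self.task is None:
            raise MissingFlag("no task assigned; call assign_subgroups first")
        return self.outcomes[self.task]

    def copy(self) -> "Cohort":
        return Cohort(
            raw=self.raw.copy(),
            catalog=self.catalog,
            missing_mask=self.missing_mask.copy(),
            outcomes={k: v.copy() for k, v in self.outcomes.items()},
            encoded=None if self.encoded is None else self.encoded.copy(),
            task=self.task,
            comorbid=None if self.comorbid is None else self.comorbid.copy(),
        )

    def subset(self, rows: np.ndarray) -> "Cohort":
        """New cohort restricted to the given row positions."""
        rows = np.asarray(rows)
        return Cohort(
            raw=self.raw.iloc[rows].copy(),
            catalog=self.catalog,
            missing_mask=self.missing_mask.iloc[rows].copy(),
            outcomes={k: v[rows] for k, v in self.outcomes.items()},
            encoded=None if self.encoded is None else
            self.encoded.iloc[rows].copy(),
            task=self.task,
            comorbid=None if self.comorbid is None else self.comorbid[rows],
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the raw table (plus outcome columns) as UTF-8 CSV."""
        out = self.raw.copy()
        mask = self.missing_mask.to_numpy()
        out = out.astype(object)
        out.values[mask] = ""
        for task, y in self.outcomes.items():
            out[f"outcome_{task}"] = y
        out.to_csv(path, index_label="sample_id")


@dataclass
class FoldScheme:
    """Stratified cross-validation assignment (one fold index per sample)."""

    n_folds: int
    assignment: np.ndarray
    stratify_on: np.ndarray

    def train_test(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignment == fold)
        train = np.flatnonzero(self.assignment != fold)
        return train, test


def make_folds(y: np.ndarray, n_folds: int = 5, seed: int = 0) -> FoldScheme:
    """Stratified folds; per-fold positive counts within 1 of proportionality."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for k, (_, test) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test] = k
    return FoldScheme(n_folds=n_folds, assignment=assignment, stratify_on=np.asarray(y))


# ---------------------------------------------------------------------------
# loading and validation
# ---------------------------------------------------------------------------

def load_cohort(table_path: str | Path, catalog: FeatureCatalog | str | Path,
                sep: str | None = None) -> Cohort:
    """Parse a delimited cohort table against a feature catalog.

    Missing cells (empty strings) are recorded in the mask; no encoding or
    imputation is performed. Reserved columns ``outcome_CVD`` and
    ``outcome_diabetes`` are read as task labels, and a ``sample_id``
    column becomes the index.
    """
    if not isinstance(catalog, FeatureCatalog):
        catalog = FeatureCatalog.from_json(catalog)
    if sep is None:
        sep = "\t" if str(table_path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(table_path, sep=sep, dtype=str,
                        keep_default_na=False, na_values=[])
    if "sample_id" in table.columns:
        table = table.set_index("sample_id")

    outcomes: dict[str, np.ndarray] = {}
    for col, task in OUTCOME_COLUMNS.items():
        if col in table.columns:
            outcomes[task] = table.pop(col).astype(int).to_numpy()

    unknown = [c for c in table.columns if c not in catalog]
    if unknown:
        raise UnknownVariable(f"columns not in catalog: {unknown}")
    absent = [n for n in catalog.names if n not in table.columns]
    if absent:
        raise UnknownVariable(f"catalog variables absent from table: {absent}")

    table = table[catalog.names]
    mask = table.eq("").to_frame() if isinstance(table, pd.Series) else table.eq("")
    raw = _typed_raw(table, mask, catalog)
    return Cohort(raw=raw, catalog=catalog, missing_mask=mask, outcomes=outcomes)


def _typed_raw(table: pd.DataFrame, mask: pd.DataFrame,
               catalog: FeatureCatalog) -> pd.DataFrame:
    cols = {}
    for var in catalog.entries:
        s = table[var.name].copy()
        miss = mask[var.name]
        if var.dtype == "categorical":
            bad = ~s[~miss].isin(var.levels)
            if bad.any():
                values = sorted(s[~miss][bad].unique())
                raise LevelMismatch(
                    f"{var.name}: values {values} outside declared levels {var.levels}")
            s[miss] = None
            cols[var.name] = s.astype(object)
        else:
            num = pd.to_numeric(s.where(~miss), errors="coerce")
            if var.dtype == "binary":
                ok = num[~miss].isin([0, 1]) | num[~miss].isna()
                if not ok.all():
                    raise LevelMismatch(f"{var.name}: binary values must be 0/1")
            cols[var.name] = num.astype(float)
    return pd.DataFrame(cols, index=table.index)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def encode_features(cohort: Cohort) -> Cohort:
    """One-hot encode the raw table into the feature matrix.

    Binary and continuous variables map to one column each; a k-level
    categorical maps to k indicator columns named ``<var>_<level>`` (full
    encoding, no reference level dropped). Requires complete data.
    """
    if cohort.missing_mask.to_numpy().any():
        raise MissingValues("cohort has missing cells; impute before encoding")
    blocks = []
    for var in cohort.catalog.entries:
        s = cohort.raw[var.name]
        if var.dtype == "categorical":
            arr = np.zeros((len(s), len(var.levels)))
            codes = pd.Categorical(s, categories=var.levels).codes
            arr[np.arange(len(s)), codes] = 1.0
            blocks.append(pd.DataFrame(arr, index=s.index, columns=var.encoded_columns))
        else:
            blocks.append(s.astype(float).rename(var.name))
    encoded = pd.concat(blocks, axis=1)
    out = replace(cohort)
    out.encoded = encoded
    return out


def decode_features(encoded: pd.DataFrame, catalog: FeatureCatalog) -> pd.DataFrame:
    """Inverse of :func:`encode_features` on complete data."""
    cols = {}
    for var in catalog.entries:
        if var.dtype == "categorical":
            block = encoded[var.encoded_columns].to_numpy()
            cols[var.name] = pd.Series(
                [var.levels[i] for i in block.argmax(axis=1)], index=encoded.index,
                dtype=object)
        else:
            cols[var.name] = encoded[var.name].astype(float)
    return pd.DataFrame(cols, index=encoded.index)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing(cohort: Cohort, method: str = "iterative", seed: int = 0,
                   ceiling: float = 0.25,
                   fit_rows: np.ndarray | None = None) -> Cohort:
    """Fill missing cells and clear the mask.

    Continuous variables use iterative chained-equation imputation
    (``method="iterative"``) or column means (``method="mean"``); binary
    and categorical variables use the mode. Statistics are learned on
    ``fit_rows`` only (all rows by default), supporting leakage-safe
    per-fold use. Imputed continuous values are clipped to the observed
    [min, max] of each variable. Deterministic given ``seed``.

    Raises :class:`ExcessMissingness` when any variable's missing
    fraction exceeds ``ceiling`` — the screen used to drop over-sparse
    variables.
    """
    if method not in ("iterative", "mean"):
        raise ValueError("method must be 'iterative' or 'mean'")
    mask = cohort.missing_mask
    frac = mask.mean(axis=0)
    over = frac[frac > ceiling]
    if len(over):
        worst = {k: round(v, 3) for k, v in over.items()}
        raise ExcessMissingness(
            f"variables above the {ceiling:.0%} missingness ceiling: {worst}")
    out = cohort.copy()
    if not mask.to_numpy().any():
        return out
    if fit_rows is None:
        fit_rows = np.arange(cohort.n_samples)

    raw = out.raw
    cont = [n for n in cohort.catalog.continuous_names() if mask[n].any()]
    cont_all = cohort.catalog.continuous_names()
    if cont:
        block = raw[cont_all].to_numpy(float)
        if method == "iterative":
            imputer = IterativeImputer(max_iter=5, random_state=seed,
                                       sample_posterior=False)
            imputer.fit(block[fit_rows])
            filled = imputer.transform(block)
        else:
            means = np.nanmean(block[fit_rows], axis=0)
            filled = np.where(np.isnan(block), means, block)
        # clip to the observed range of each variable (fit rows)
        lo = np.nanmin(block[fit_rows], axis=0)
        hi = np.nanmax(block[fit_rows], axis=0)
        filled = np.clip(filled, lo, hi)
        raw.loc[:, cont_all] = filled
    for var in cohort.catalog.entries:
        if var.dtype == "continuous" or not mask[var.name].any():
            continue
        observed = raw[var.name].iloc[fit_rows].dropna()
        mode = observed.mode().iloc[0]
        miss = mask[var.name].to_numpy()
        raw.loc[miss, var.name] = mode
    out.missing_mask = pd.DataFrame(False, index=mask.index, columns=mask.columns)
    return out


# ---------------------------------------------------------------------------
# subgroups
# ---------------------------------------------------------------------------

def assign_subgroups(cohort: Cohort, task: str) -> Cohort:
    """Attach the comorbidity flag for one prediction task.

    comorbid := (depression OR anxiety) AND complementary condition at
    baseline (diabetes for the CVD task, CVD for the diabetes task).
    The partition {comorbid, non-comorbid} is exhaustive and disjoint.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    needed = list(MENTAL_FLAGS) + [COMPLEMENTARY_FLAG[task]]
    for flag in needed:
        if flag not in cohort.catalog or flag not in cohort.raw.columns:
            raise MissingFlag(f"baseline diagnosis variable {flag!r} absent")
        if cohort.missing_mask[flag].any():
            raise MissingFlag(f"baseline diagnosis variable {flag!r} has missing cells")
    dep = cohort.raw["Depression"].to_numpy(float) == 1
    anx = cohort.raw["Anxiety"].to_numpy(float) == 1
    comp = cohort.raw[COMPLEMENTARY_FLAG[task]].to_numpy(float) == 1
    out = replace(cohort)
    out.task = task
    out.comorbid = (dep | anx) & comp
    return out
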