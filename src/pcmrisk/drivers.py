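"""Performance-driver and prediction-driver analyses.

Performance drivers are variables whose perturbation degrades the
model's measured performance: single-variable AUC models (see
:func:`pcmrisk.models.single_variable_models`) and permutation feature
importance (PFI). Prediction drivers are variables that shape the
model's output regardless of correctness: mean-absolute Shapley
attribution and the dual-group risk effect size (Cohen's D between
predicted high-risk and low-risk patients).

Sign convention for PFI: importance = loss(shuffled) - loss(original),
so predictive features score positive. One-hot blocks belonging to one
raw variable are always shuffled (and attributed) as a unit, so rankings
are reported at the raw-variable level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .attribution import shap_values
from .evaluate import SUBGROUPS, rank_auc
from .exceptions import DegenerateGroups

_EPS = 1e-12


def _log_loss(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(np.asarray(p, float), _EPS, 1 - _EPS)
    y = np.asarray(y, float)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _one_minus_auc(y: np.ndarray, p: np.ndarray) -> float:
    return 1.0 - rank_auc(y, p)


_LOSSES = {"log_loss": _log_loss, "one_minus_auc": _one_minus_auc}


@dataclass
class DriverTable:
    """Per-feature scores and dense 1..p ranks for one driver metric."""

    metric: str
    tables: dict[str, pd.DataFrame]   # subgroup -> (name, category, score, rank)
    n: int
    seed: int | None = None
    repeats: int | None = None

    def table(self, subgroup: str) -> pd.DataFrame:
        return self.tables[subgroup]

    def top(self, subgroup: str, k: int = 30) -> list[str]:
        return list(self.tables[subgroup].nsmallest(k, "rank")["name"])

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for sg, t in self.tables.items():
            t = t.copy()
            t.insert(0, "subgroup", sg)
            t.insert(0, "metric", self.metric)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def _ranked(rows: pd.DataFrame) -> pd.DataFrame:
    rows = rows.sort_values("score", ascending=False, na_position="last",
                            ignore_index=True)
    rows["rank"] = np.arange(1, len(rows) + 1)
    return rows


# ---------------------------------------------------------------------------
# permutation feature importance
# ---------------------------------------------------------------------------

def permutation_importance(results, repeats: int = 10, loss: str = "log_loss",
                           seed: int = 0) -> DriverTable:
    """PFI per raw variable, per subgroup, averaged over test folds.

    For each test fold and subgroup, each raw variable's encoded block is
    shuffled jointly across the subgroup's rows ``repeats`` times and the
    mean loss increase recorded. The table carries the across-repeat
    standard error in an ``se`` column for null-calibration checks.
    """
    from .models import derive_seed

    loss_fn = _LOSSES[loss]
    cohort = results.cohort
    y = cohort.outcome
    emap = cohort.catalog.encoded_map()
    acc: dict[str, dict[str, list[float]]] = {
        sg: {v: [] for v in cohort.catalog.names} for sg in SUBGROUPS}
    for fold, model in enumerate(results.fold_models):
        enc = results.fold_encoded(fold)
        _, test = results.folds.train_test(fold)
        col_idx = {c: i for i, c in enumerate(model.feature_names)}
        for sg in SUBGROUPS:
            member = cohort.comorbid if sg == "comorbid" else ~cohort.comorbid
            rows = test[member[test]]
            if len(rows) < 2 or (loss == "one_minus_auc"
                                 and len(np.unique(y[rows])) < 2):
                continue
            X = enc.iloc[rows][model.feature_names].to_numpy(float)
            base = loss_fn(y[rows], model.predict_proba(X))
            rng = np.random.default_rng(derive_seed(seed, fold, hash(sg) % 997))
            for var in cohort.catalog.names:
                cols = [col_idx[c] for c in emap[var] if c in col_idx]
                if not cols:
                    continue
                deltas = []
                for _ in range(repeats):
                    perm = rng.permutation(len(rows))
                    Xp = X.copy()
                    Xp[:, cols] = X[np.ix_(perm, cols)]
                    deltas.append(loss_fn(y[rows], model.predict_proba(Xp))
                                  - base)
                acc[sg][var].extend(deltas)
    tables = {}
    for sg in SUBGROUPS:
        names = [v for v in cohort.catalog.names if acc[sg][v]]
        scores = [float(np.mean(acc[sg][v])) for v in names]
        ses = [float(np.std(acc[sg][v], ddof=1) / np.sqrt(len(acc[sg][v])))
               if len(acc[sg][v]) > 1 else 0.0 for v in names]
        rows = pd.DataFrame({
            "name": names,
            "category": [cohort.catalog[v].category for v in names],
            "score": scores, "se": ses})
        tables[sg] = _ranked(rows)
    return DriverTable(metric="pfi", tables=tables, n=cohort.n_samples,
                       seed=seed, repeats=repeats)


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    correlations: pd.DataFrame
    fully_correlated: list[tuple[str, str]] = field(default_factory=list)

    @property
    def max_abs(self) -> float:
        c = self.correlations.to_numpy(float).copy()
        np.fill_diagonal(c, 0.0)
        return float(np.nanmax(np.abs(c)))


def spearman_screen(X: pd.DataFrame) -> CorrelationReport:
    """Pairwise Spearman rank correlations on training data.

    Pairs at |rho| = 1 are flagged as fully correlated — a warning that
    PFI may split importance between them, never an automatic drop.
    """
    if len(X) < 3:
        raise ValueError("need at least 3 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # constant columns yield NaN rho
        rho = spearmanr(X.to_numpy(float), axis=0).statistic
    if np.ndim(rho) == 0:   # scipy collapses the two-column case
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    corr = pd.DataFrame(rho, index=X.columns, columns=X.columns)
    pairs = []
    cols = list(X.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if np.isclose(abs(rho[i, j]), 1.0, atol=1e-12):
                pairs.append((cols[i], cols[j]))
    return CorrelationReport(correlations=corr, fully_correlated=pairs)


# ---------------------------------------------------------------------------
# SHAP importance
# ---------------------------------------------------------------------------

def shap_importance(results, method: str = "fast") -> DriverTable:
    """Mean absolute Shapley attribution per raw variable, per subgroup.

    Attributions are computed on each fold's test rows (margin scale);
    encoded columns of one raw variable are summed per instance before
    taking the absolute value, then averaged within the subgroup and
    across folds.
    """
    cohort = results.cohort
    emap = cohort.catalog.encoded_map()
    acc: dict[str, dict[str, list[float]]] = {
        sg: {v: [] for v in cohort.catalog.names} for sg in SUBGROUPS}
    for fold, model in enumerate(results.fold_models):
        enc = results.fold_encoded(fold)
        _, test = results.folds.train_test(fold)
        X = enc.iloc[test][model.feature_names].to_numpy(float)
        phi, _ = shap_values(model, X, method=method)
        col_idx = {c: i for i, c in enumerate(model.feature_names)}
        for sg in SUBGROUPS:
            member = cohort.comorbid if sg == "comorbid" else ~cohort.comorbid
            m = member[test]
            if m.sum() == 0:
                continue
            for var in cohort.catalog.names:
                cols = [col_idx[c] for c in emap[var] if c in col_idx]
                if not cols:
                    continue
                agg = phi[np.ix_(m.nonzero()[0], cols)].sum(axis=1)
                acc[sg][var].append(float(np.mean(np.abs(agg))))
    tables = {}
    for sg in SUBGROUPS:
        names = [v for v in cohort.catalog.names if acc[sg][v]]
        rows = pd.DataFrame({
            "name": names,
            "category": [cohort.catalog[v].category for v in names],
            "score": [float(np.mean(acc[sg][v])) for v in names]})
        tables[sg] = _ranked(rows)
    return DriverTable(metric="shap_importance", tables=tables,
                       n=cohort.n_samples)


# ---------------------------------------------------------------------------
# dual-group risk effect size
# ---------------------------------------------------------------------------

@dataclass
class RiskGroups:
    """Predicted high/low risk partition at threshold t."""

    high: np.ndarray
    low: np.ndarray
    excluded: np.ndarray
    t: float


def risk_groups(probabilities: np.ndarray, t: float = 0.5) -> RiskGroups:
    p = np.asarray(probabilities, float)
    high = np.flatnonzero(p > t)
    low = np.flatnonzero(p <= 1.0 - t)
    middle = np.flatnonzero((p <= t) & (p > 1.0 - t))
    return RiskGroups(high=high, low=low, excluded=middle, t=t)


def cohens_d(high: np.ndarray, low: np.ndarray) -> float:
    """|mean difference| / pooled sd with (n-1)-weighted sample variances.

    Returns NaN (undefined) when the pooled variance is zero.
    """
    nh, nl = len(high), len(low)
    if nh < 2 or nl < 2:
        raise DegenerateGroups("both groups need >= 2 samples")
    s2h = float(np.var(high, ddof=1))
    s2l = float(np.var(low, ddof=1))
    pooled = ((nh - 1) * s2h + (nl - 1) * s2l) / (nh + nl - 2)
    if pooled == 0.0:
        return float("nan")
    return abs(float(np.mean(high)) - float(np.mean(low))) / np.sqrt(pooled)


def effect_size_table(probabilities: np.ndarray, X: pd.DataFrame,
                      t: float = 0.5,
                      categories: dict[str, str] | None = None) -> pd.DataFrame:
    """Cohen's D per feature column between predicted risk groups."""
    groups = risk_groups(probabilities, t)
    if len(groups.high) < 2 or len(groups.low) < 2:
        raise DegenerateGroups(
            f"high/low groups too small at t={t}: "
            f"{len(groups.high)}/{len(groups.low)}")
    scores = {}
    for col in X.columns:
        x = X[col].to_numpy(float)
        scores[col] = cohens_d(x[groups.high], x[groups.low])
    rows = pd.DataFrame({
        "name": list(scores),
        "category": [(categories or {}).get(c, "") for c in scores],
        "score": list(scores.values())})
    return _ranked(rows)


def dual_group_effect_size(results, t: float = 0.5) -> DriverTable:
    """Dual-group risk effect sizes per subgroup from out-of-fold risks.

    Within each subgroup, samples with predicted risk > t form the
    high-risk group and those with risk <= 1-t the low-risk group
    (at t=0.5 the split is exhaustive); each encoded feature's Cohen's D
    between the groups is reported, sorted descending.
    """
    cohort = results.cohort
    enc = results.fold_encoded(0)[results.fold_models[0].feature_names]
    var_of = {c: v for v, cs in cohort.catalog.encoded_map().items()
              for c in cs}
    cats = {c: cohort.catalog[var_of[c]].category for c in enc.columns}
    proba = results.oof_proba
    tables = {}
    for sg in SUBGROUPS:
        member = cohort.comorbid if sg == "comorbid" else ~cohort.comorbid
        tables[sg] = effect_size_table(proba[member], enc[member],
                                       t=t, categories=cats)
    return DriverTable(metric="cohens_d", tables=tables, n=cohort.n_samples)


# ---------------------------------------------------------------------------
# cross-subgroup summary
# ---------------------------------------------------------------------------

@dataclass
class DriverSummary:
    metric: str
    top_k: int
    top: dict[str, list[str]]
    overlap_fraction: float
    shared: list[str]
    elf_counts: dict[str, int]


def driver_summary(table: DriverTable, top_k: int = 30,
                   elf_names: list[str] | None = None) -> DriverSummary:
    """Compare the two subgroups' top-k rankings for one driver metric.

    Reports the per-subgroup top-k lists, their overlap fraction, the
    shared variables (the dagger convention of the printed rankings),
    and how many early-life factors each list contains.
    """
    tops = {sg: table.top(sg, top_k) for sg in table.tables}
    sgs = list(tops)
    shared = [v for v in tops[sgs[0]] if v in set(tops[sgs[1]])] \
        if len(sgs) == 2 else []
    overlap = len(shared) / max(1, min(len(tops[sg]) for sg in sgs))
    elf_counts = {}
    for sg in sgs:
        sub = table.tables[sg]
        in_top = sub.nsmallest(top_k, "rank")
        if elf_names is not None:
            elf_counts[sg] = sum(1 for nm in in_top["name"]
                                 if nm in set(elf_names))
        else:
            elf_counts[sg] = int((in_top["category"] == "ELF").sum())
    return DriverSummary(metric=table.metric, top_k=top_k, top=tops,
                         overlap_fraction=float(overlap), shared=shared,
                         elf_counts=elf_counts)
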