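"""Gradient-boosted risk models under stratified cross-validation.

The central objects follow the Model/Results idiom: build a
:class:`SubgroupRiskModel` from a cohort and a feature set, call
``fit()``, and receive a :class:`SubgroupRiskResults` carrying the
per-fold boosters, out-of-fold risk predictions, subgroup-stratified
metrics and a ``summary()`` table. Driver analyses (permutation
importance, Shapley attribution, effect sizes) and decision curves hang
off the Results object.

A single unified model is always trained on the full training split of
each fold; comorbid and non-comorbid subgroups are only separated at
evaluation time, so predictor contributions are directly comparable
across subgroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .catalog import FeatureCatalog
from .cohort import Cohort, FoldScheme, encode_features, impute_missing, make_folds
from .exceptions import (
    FeatureMismatch,
    MissingScoreVariable,
    SingleClassFold,
)
from .simulate import MARKER

#: hyperparameter search space (random search)
SEARCH_SPACE = {
    "max_depth": (2, 8),
    "learning_rate": (0.01, 0.3),   # log-uniform
    "n_estimators": (50, 500),
    "subsample": (0.5, 1.0),
}
#: trial-0 configuration, used as-is when the tuning budget is 1
DEFAULT_PARAMS = {
    "max_depth": 4,
    "learning_rate": 0.1,
    "n_estimators": 150,
    "subsample": 0.9,
}


def derive_seed(master: int, *parts: int) -> int:
    """Stable per-fold / per-trial seed derivation."""
    s = master * 1_000_003
    for i, p in enumerate(parts):
        s = s * 31 + (p + 1) * (1009 + i)
    return s % (2**31 - 1)


@dataclass
class FeatureSet:
    """A named subset of encoded feature columns."""

    name: str
    columns: list[str]

    def __post_init__(self) -> None:
        if len(self.columns) == 0:
            raise ValueError(f"feature set {self.name!r} has no columns")


def resolve_feature_set(name: str, catalog: FeatureCatalog, task: str,
                        k: int | None = None,
                        order: list[str] | None = None,
                        columns: list[str] | None = None) -> FeatureSet:
    """Build a :class:`FeatureSet` from a catalog-defined subset name.

    ``top_k`` requires an ``order`` of raw variable names (e.g. a PFI
    ranking) and ``k``; ``custom`` requires explicit ``columns``.
    """
    emap = catalog.encoded_map()
    if name == "all":
        cols = catalog.encoded_names
    elif name == "core7":
        cols = [c for v in catalog.core7(task) for c in emap[v]]
    elif name == "hba1c_only":
        cols = list(emap[MARKER])
    elif name == "all_minus_hba1c":
        cols = [c for c in catalog.encoded_names if c not in emap[MARKER]]
    elif name == "nonlab":
        cols = [c for v in catalog.nonlab_names() for c in emap[v]]
    elif name == "top_k":
        if order is None or k is None:
            raise ValueError("top_k needs an ordering of raw variables and k")
        cols = [c for v in order[:k] for c in emap[v]]
    elif name == "custom":
        if columns is None:
            raise ValueError("custom needs explicit columns")
        cols = list(columns)
    else:
        raise ValueError(f"unknown feature set {name!r}")
    return FeatureSet(name=name, columns=cols)


@dataclass
class RiskModel:
    """One fitted booster with its feature ordering and provenance."""

    booster: xgb.XGBClassifier
    feature_names: list[str]
    hyperparams: dict
    train_fold: int
    seed: int

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise FeatureMismatch(f"missing feature columns: {missing}")
            X = X[self.feature_names].to_numpy(float)
        elif X.shape[1] != len(self.feature_names):
            raise FeatureMismatch(
                f"expected {len(self.feature_names)} columns, got {X.shape[1]}")
        if len(X) == 0:
            return np.empty(0)
        return self.booster.predict_proba(X)[:, 1]


def predict_risk(model: RiskModel, cohort: Cohort,
                 rows: np.ndarray | None = None) -> np.ndarray:
    """Risk probabilities for the given cohort rows (all rows by default)."""
    enc = cohort.encoded if cohort.encoded is not None \
        else encode_features(cohort).encoded
    if rows is not None:
        enc = enc.iloc[rows]
    return model.predict_proba(enc)


def _new_classifier(params: dict, seed: int) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        **params, tree_method="hist", n_jobs=1, random_state=seed,
        eval_metric="logloss", base_score=0.5)


def _sample_params(rng: np.random.Generator) -> dict:
    lo, hi = SEARCH_SPACE["learning_rate"]
    return {
        "max_depth": int(rng.integers(*SEARCH_SPACE["max_depth"], endpoint=True)),
        "learning_rate": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
        "n_estimators": int(rng.integers(*SEARCH_SPACE["n_estimators"],
                                         endpoint=True)),
        "subsample": float(rng.uniform(*SEARCH_SPACE["subsample"])),
    }


def _fold_encoded(cohort: Cohort, train: np.ndarray, seed: int,
                  impute_method: str = "iterative") -> pd.DataFrame:
    """Encoded matrix for one fold; imputation fitted on training rows only."""
    if cohort.missing_mask.to_numpy().any():
        cohort = impute_missing(cohort, method=impute_method, seed=seed,
                                fit_rows=train)
    if cohort.encoded is None:
        cohort = encode_features(cohort)
    return cohort.encoded


def fit_unified_model(cohort: Cohort, fset: FeatureSet, folds: FoldScheme,
                      budget: int = 25, seed: int = 0,
                      impute_method: str = "iterative") -> list[RiskModel]:
    """Train one gradient-boosted model per fold on its training split.

    Imputation (when needed) and hyperparameter selection happen strictly
    inside each training split. The search draws ``budget`` candidate
    configurations (trial 0 is the fixed default) and keeps the one with
    the best AUC-ROC on an inner 20% validation split; with ``budget=1``
    the default configuration is fitted directly.
    """
    y = cohort.outcome
    wanted = list(fset.columns)   # validated against the encoding per fold
    models: list[RiskModel] = []
    complete = not cohort.missing_mask.to_numpy().any()
    enc_all = _fold_encoded(cohort, np.arange(cohort.n_samples), seed) \
        if complete else None
    for fold in range(folds.n_folds):
        train, _ = folds.train_test(fold)
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise SingleClassFold(f"training split of fold {fold} is single-class")
        enc = enc_all if enc_all is not None else _fold_encoded(
            cohort, train, derive_seed(seed, fold), impute_method)
        bad = [c for c in wanted if c not in enc.columns]
        if bad:
            raise FeatureMismatch(f"feature set columns not in cohort: {bad}")
        X_tr = enc.iloc[train][fset.columns].to_numpy(float)

        best_params, best_score = dict(DEFAULT_PARAMS), -np.inf
        if budget > 1:
            idx_fit, idx_val = train_test_split(
                np.arange(len(train)), test_size=0.2, stratify=y_tr,
                random_state=derive_seed(seed, fold, 777))
            rng = np.random.default_rng(derive_seed(seed, fold, 999))
            for trial in range(budget):
                params = dict(DEFAULT_PARAMS) if trial == 0 else _sample_params(rng)
                clf = _new_classifier(params, derive_seed(seed, fold, trial))
                clf.fit(X_tr[idx_fit], y_tr[idx_fit])
                score = roc_auc_score(
                    y_tr[idx_val], clf.predict_proba(X_tr[idx_val])[:, 1])
                if score > best_score:
                    best_params, best_score = params, score
        fold_seed = derive_seed(seed, fold)
        clf = _new_classifier(best_params, fold_seed)
        clf.fit(X_tr, y_tr)
        models.append(RiskModel(booster=clf, feature_names=list(fset.columns),
                                hyperparams=best_params, train_fold=fold,
                                seed=fold_seed))
    return models


def single_variable_models(cohort: Cohort, folds: FoldScheme, seed: int = 0,
                           params: dict | None = None):
    """Per-variable AUC-ROC: one small booster per raw variable.

    Each model uses only the variable's encoded column(s); AUCs are
    evaluated separately on comorbid and non-comorbid test rows and
    averaged over folds. Constant variables score 0.5 with a warning.
    Returns a :class:`~pcmrisk.drivers.DriverTable`.
    """
    from .drivers import DriverTable  # local import to avoid a cycle

    params = params or {"max_depth": 3, "learning_rate": 0.1,
                        "n_estimators": 100, "subsample": 1.0}
    y = cohort.outcome
    comorbid = cohort.comorbid
    enc = cohort.encoded if cohort.encoded is not None \
        else encode_features(cohort).encoded
    emap = cohort.catalog.encoded_map()
    scores: dict[str, dict[str, list[float]]] = {
        "comorbid": {}, "non_comorbid": {}}
    for name in cohort.catalog.names:
        X = enc[emap[name]].to_numpy(float)
        if np.allclose(X.std(axis=0), 0):
            warnings.warn(f"{name} is constant; AUC set to 0.5")
            for sg in scores:
                scores[sg][name] = [0.5]
            continue
        per_sg: dict[str, list[float]] = {"comorbid": [], "non_comorbid": []}
        for fold in range(folds.n_folds):
            train, test = folds.train_test(fold)
            clf = _new_classifier(params, derive_seed(seed, fold))
            clf.fit(X[train], y[train])
            p = clf.predict_proba(X[test])[:, 1]
            for sg, m in (("comorbid", comorbid[test]),
                          ("non_comorbid", ~comorbid[test])):
                yt = y[test][m]
                if len(np.unique(yt)) < 2:
                    continue
                per_sg[sg].append(roc_auc_score(yt, p[m]))
        for sg in per_sg:
            scores[sg][name] = per_sg[sg] or [0.5]
    frames = {}
    for sg, d in scores.items():
        rows = pd.DataFrame({
            "name": list(d),
            "category": [cohort.catalog[n].category for n in d],
            "score": [float(np.mean(v)) for v in d.values()],
        })
        rows = rows.sort_values("score", ascending=False, ignore_index=True)
        rows["rank"] = np.arange(1, len(rows) + 1)
        frames[sg] = rows
    return DriverTable(metric="single_var_auc", tables=frames,
                       n=cohort.n_samples, seed=seed)


# ---------------------------------------------------------------------------
# external (published-score style) benchmarks
# ---------------------------------------------------------------------------

@dataclass
class ScoreSpec:
    """Pluggable linear score: named coefficients, intercept and link."""

    coefficients: dict[str, float]
    intercept: float = 0.0
    link: str = "logistic"
    name: str = "external"


def external_score(cohort: Cohort, score_spec: ScoreSpec) -> np.ndarray:
    """Per-sample risk from a published-score style coefficient table."""
    enc = cohort.encoded if cohort.encoded is not None \
        else encode_features(cohort).encoded
    eta = np.full(cohort.n_samples, score_spec.intercept, dtype=float)
    for var, coef in score_spec.coefficients.items():
        if var not in enc.columns:
            raise MissingScoreVariable(f"score variable {var!r} not in cohort")
        eta += coef * enc[var].to_numpy(float)
    if score_spec.link == "logistic":
        return 1.0 / (1.0 + np.exp(-eta))
    if score_spec.link == "identity":
        return eta
    raise ValueError(f"unknown link {score_spec.link!r}")


def stand_in_benchmark(cohort: Cohort, seed: int = 0,
                       fit_rows: np.ndarray | None = None) -> ScoreSpec:
    """Synthetic stand-in for a published core-7 risk score.

    Fits a plain logistic regression on the task's seven core variables
    (standardized encoded columns) and packages it as a :class:`ScoreSpec`.
    The published Framingham / DiabetesUK coefficient tables are
    deliberately not reproduced; supply them via :class:`ScoreSpec` when
    available.
    """
    fset = resolve_feature_set("core7", cohort.catalog, cohort.task)
    enc = cohort.encoded if cohort.encoded is not None \
        else encode_features(cohort).encoded
    rows = np.arange(cohort.n_samples) if fit_rows is None else fit_rows
    X = enc.iloc[rows][fset.columns].to_numpy(float)
    y = cohort.outcome[rows]
    lr = LogisticRegression(max_iter=1000, random_state=seed)
    lr.fit(X, y)
    coefs = dict(zip(fset.columns, lr.coef_[0]))
    return ScoreSpec(coefficients=coefs, intercept=float(lr.intercept_[0]),
                     link="logistic", name="stand_in_core7")


# ---------------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------------

class SubgroupRiskModel:
    """Unified risk model specification for one prediction task.

    Parameters
    ----------
    cohort : Cohort
        Cohort with subgroups assigned (see
        :func:`pcmrisk.cohort.assign_subgroups`).
    feature_set : str or FeatureSet
        Named subset (``all``, ``core7``, ``hba1c_only``,
        ``all_minus_hba1c``, ``nonlab``) or an explicit
        :class:`FeatureSet`.
    """

    def __init__(self, cohort: Cohort, feature_set: str | FeatureSet = "all",
                 **fset_kwargs):
        if cohort.task is None or cohort.comorbid is None:
            raise ValueError("cohort needs assign_subgroups(...) first")
        self.cohort = cohort
        if isinstance(feature_set, str):
            feature_set = resolve_feature_set(
                feature_set, cohort.catalog, cohort.task, **fset_kwargs)
        self.feature_set = feature_set

    def fit(self, n_folds: int = 5, budget: int = 1, seed: int = 0,
            impute_method: str = "iterative") -> "SubgroupRiskResults":
        folds = make_folds(self.cohort.outcome, n_folds=n_folds, seed=seed)
        models = fit_unified_model(self.cohort, self.feature_set, folds,
                                   budget=budget, seed=seed,
                                   impute_method=impute_method)
        return SubgroupRiskResults(self, models, folds, seed,
                                   impute_method=impute_method)


@dataclass
class SubgroupRiskResults:
    """Fitted per-fold models plus subgroup-stratified diagnostics."""

    model: SubgroupRiskModel
    fold_models: list[RiskModel]
    folds: FoldScheme
    seed: int
    impute_method: str = "iterative"
    _oof: np.ndarray | None = field(default=None, repr=False)
    _enc: dict = field(default_factory=dict, repr=False)

    @property
    def cohort(self) -> Cohort:
        return self.model.cohort

    def fold_encoded(self, fold: int) -> pd.DataFrame:
        """Encoded matrix under fold-specific (training-rows) imputation."""
        if fold not in self._enc:
            train, _ = self.folds.train_test(fold)
            self._enc[fold] = _fold_encoded(
                self.cohort, train, derive_seed(self.seed, fold),
                self.impute_method)
        return self._enc[fold]

    @property
    def oof_proba(self) -> np.ndarray:
        """Out-of-fold risk predictions (one per sample)."""
        if self._oof is None:
            p = np.empty(self.cohort.n_samples)
            for fold, m in enumerate(self.fold_models):
                _, test = self.folds.train_test(fold)
                enc = self.fold_encoded(fold)
                p[test] = m.predict_proba(enc.iloc[test])
            self._oof = p
        return self._oof

    # -- diagnostics (delegate to the evaluation / driver modules) --------
    def subgroup_metrics(self, model_name: str | None = None):
        from .evaluate import evaluate_subgroups
        name = model_name or f"XGB ({self.model.feature_set.name})"
        return evaluate_subgroups(self, model_name=name)

    def decision_curve(self, subgroup: str = "comorbid", t_grid=None,
                       extra_scores: dict[str, np.ndarray] | None = None):
        from .evaluate import decision_curve
        name = f"XGB ({self.model.feature_set.name})"
        scores = {name: self.oof_proba}
        if extra_scores:
            scores.update(extra_scores)
        return decision_curve(self.cohort, scores, t_grid=t_grid,
                              subgroup=subgroup)

    def permutation_importance(self, repeats: int = 10, loss: str = "log_loss",
                               seed: int | None = None):
        from .drivers import permutation_importance
        return permutation_importance(
            self, repeats=repeats, loss=loss,
            seed=self.seed if seed is None else seed)

    def shap_importance(self, method: str = "fast"):
        from .drivers import shap_importance
        return shap_importance(self, method=method)

    def effect_sizes(self, t: float = 0.5):
        from .drivers import dual_group_effect_size
        return dual_group_effect_size(self, t=t)

    def summary(self) -> str:
        """Human-readable per-subgroup performance table."""
        metrics = self.subgroup_metrics()
        lines = [
            f"SubgroupRiskModel: task={self.cohort.task} "
            f"features={self.model.feature_set.name} "
            f"(p={len(self.model.feature_set.columns)})",
            f"n={self.cohort.n_samples}  folds={self.folds.n_folds}  "
            f"seed={self.seed}",
            f"{'subgroup':<14}{'n':>7}{'AUC-ROC':>16}{'Brier':>16}",
        ]
        for m in metrics:
            lines.append(
                f"{m.subgroup:<14}{m.n:>7}"
                f"{m.auc_mean:>10.3f} ± {m.auc_sd:.3f}"
                f"{m.brier_mean:>10.3f} ± {m.brier_sd:.3f}")
        return "\n".join(lines)
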