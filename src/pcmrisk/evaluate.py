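"""Subgroup-stratified performance metrics and decision-curve analysis.

Metrics are always computed on test folds restricted to one subgroup
(comorbid or non-comorbid), then summarized as mean ± sd across folds.
AUC-ROC uses the rank (Mann-Whitney) formulation with midrank tie
handling; the Brier score is the mean squared difference between the
predicted probability and the binary outcome.

The clinical net benefit of thresholding a risk score at t is

    b(t) = TP/n - (FP/n) * t / (1 - t)

with a prediction counted positive iff probability > t (ties at t are
negative). Reference strategies: 'none' (never intervene) has b == 0;
'all' (always intervene) has b(t) = pi - (1 - pi) * t / (1 - t) with
prevalence pi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import Cohort, FoldScheme
from .exceptions import InvalidThreshold

SUBGROUPS = ("comorbid", "non_comorbid")


def rank_auc(y: np.ndarray, score: np.ndarray) -> float:
    """AUC-ROC via the Mann-Whitney statistic with midranks."""
    y = np.asarray(y)
    score = np.asarray(score, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(score)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def brier_score(y: np.ndarray, p: np.ndarray) -> float:
    return float(np.mean((np.asarray(p, float) - np.asarray(y, float)) ** 2))


@dataclass
class SubgroupMetrics:
    """Mean ± sd of AUC-ROC and Brier over folds for one subgroup."""

    task: str
    model_name: str
    subgroup: str
    auc_mean: float
    auc_sd: float
    brier_mean: float
    brier_sd: float
    n_folds: int
    n: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def subgroup_metrics_from_proba(cohort: Cohort, proba: np.ndarray,
                                folds: FoldScheme,
                                model_name: str) -> list[SubgroupMetrics]:
    """Fold-stratified subgroup metrics for any full-cohort risk vector.

    A fold whose test subgroup has fewer than two samples or a single
    outcome class is skipped for that subgroup (reported as missing with
    a warning, reducing ``n_folds``).
    """
    y = cohort.outcome
    out = []
    for sg in SUBGROUPS:
        member = cohort.comorbid if sg == "comorbid" else ~cohort.comorbid
        aucs, briers = [], []
        for fold in range(folds.n_folds):
            _, test = folds.train_test(fold)
            rows = test[member[test]]
            if len(rows) < 2 or len(np.unique(y[rows])) < 2:
                warnings.warn(
                    f"{model_name}: fold {fold} {sg} subgroup degenerate; skipped")
                continue
            aucs.append(rank_auc(y[rows], proba[rows]))
            briers.append(brier_score(y[rows], proba[rows]))
        out.append(SubgroupMetrics(
            task=cohort.task, model_name=model_name, subgroup=sg,
            auc_mean=float(np.mean(aucs)) if aucs else float("nan"),
            auc_sd=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
            brier_mean=float(np.mean(briers)) if briers else float("nan"),
            brier_sd=float(np.std(briers, ddof=1)) if len(briers) > 1 else 0.0,
            n_folds=len(aucs), n=int(member.sum())))
    return out


def evaluate_subgroups(results, model_name: str = "XGB") -> list[SubgroupMetrics]:
    """Subgroup metrics from a fitted :class:`SubgroupRiskResults`."""
    return subgroup_metrics_from_proba(
        results.cohort, results.oof_proba, results.folds, model_name)


# ---------------------------------------------------------------------------
# decision curves
# ---------------------------------------------------------------------------

def net_benefit(labels: np.ndarray, probabilities: np.ndarray,
                t: float) -> float:
    """Net benefit of intervening when predicted probability exceeds t."""
    if not 0.0 < t < 1.0:
        raise InvalidThreshold(f"threshold must be in (0, 1), got {t}")
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    n = len(y)
    pos = p > t
    tp = int((pos & (y == 1)).sum())
    fp = int((pos & (y == 0)).sum())
    return tp / n - (fp / n) * (t / (1.0 - t))


def default_threshold_grid() -> np.ndarray:
    return np.round(np.arange(0.01, 1.0, 0.01), 2)


@dataclass
class NetBenefitCurve:
    """Net benefit over a threshold grid for several strategies."""

    thresholds: np.ndarray
    values: dict[str, np.ndarray]
    subgroup: str
    n: int
    prevalence: float

    def to_frame(self) -> pd.DataFrame:
        """Tidy layout: one row per model x threshold."""
        rows = [
            {"model": name, "threshold": t, "net_benefit": v,
             "subgroup": self.subgroup}
            for name, vals in self.values.items()
            for t, v in zip(self.thresholds, vals)
        ]
        return pd.DataFrame(rows)


def decision_curve(cohort: Cohort, scores: dict[str, np.ndarray],
                   t_grid: np.ndarray | None = None,
                   subgroup: str = "comorbid",
                   rows: np.ndarray | None = None) -> NetBenefitCurve:
    """Decision curves for the given risk scores plus 'all'/'none'.

    Scores are full-cohort probability vectors (e.g. out-of-fold model
    predictions or an external published score); evaluation is restricted
    to the requested subgroup, the comorbid test population by default.
    """
    if t_grid is None:
        t_grid = default_threshold_grid()
    member = np.ones(cohort.n_samples, bool) if subgroup == "both" else (
        cohort.comorbid if subgroup == "comorbid" else ~cohort.comorbid)
    idx = np.flatnonzero(member) if rows is None else rows[member[rows]]
    y = cohort.outcome[idx]
    pi = float(np.mean(y))
    values: dict[str, np.ndarray] = {}
    for name, p in scores.items():
        values[name] = np.array([net_benefit(y, p[idx], t) for t in t_grid])
    values["all"] = pi - (1.0 - pi) * t_grid / (1.0 - t_grid)
    values["none"] = np.zeros_like(t_grid)
    return NetBenefitCurve(thresholds=np.asarray(t_grid, float), values=values,
                           subgroup=subgroup, n=len(idx), prevalence=pi)
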