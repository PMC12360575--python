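"""Group-specific Bayes-error lower/upper bound estimation.

The Bayes error is the smallest expected misclassification rate any
classifier can achieve on a task; comparing bound intervals between the
comorbid and non-comorbid subgroups indicates whether one population is
intrinsically harder to predict, independent of model choice.

Three classical estimators are implemented:

* Mahalanobis — upper bound only:
  ``E_up = 2 p1 p2 / (1 + p1 p2 * Delta)`` with ``Delta`` the squared
  Mahalanobis distance between class means under the pooled covariance.
* Bhattacharyya — Gaussian class models with per-class mean/covariance;
  with ``B`` the Bhattacharyya distance and ``rho = exp(-B)``:
  ``E_up = sqrt(p1 p2) * rho`` and
  ``E_low = (1 - sqrt(1 - 4 p1 p2 rho^2)) / 2``.
* k-NN — the cross-validated k-nearest-neighbour error ``eps`` gives
  ``E_up = eps`` and, by the two-class Cover-Hart inversion,
  ``E_low = (1 - sqrt(1 - 2 eps)) / 2`` (``eps`` clipped to [0, 1/2]).

Covariance singularity is detected via a condition-number threshold of
1e12 and reported as a status rather than an exception escape — with
full one-hot encoded feature sets the class covariances are rank
deficient by construction, reproducing the known failure mode of the
parametric estimators on all-variable sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier

from .cohort import Cohort, make_folds
from .evaluate import SUBGROUPS
from .exceptions import TooFewSamples
from .models import resolve_feature_set
from .cohort import encode_features

COND_THRESHOLD = 1e12


@dataclass
class ErrorBoundEstimate:
    method: str
    subgroup: str | None
    variable_set: str | None
    E_low: float | None
    E_up: float | None
    k: int | None = None
    n_folds: int | None = None
    status: str = "ok"

    def interval(self) -> tuple[float | None, float | None]:
        return (self.E_low, self.E_up)


def _priors(y: np.ndarray) -> tuple[float, float]:
    y = np.asarray(y)
    p1 = float(np.mean(y == np.unique(y)[0]))
    return p1, 1.0 - p1


def _class_split(X: np.ndarray, y: np.ndarray):
    labels = np.unique(y)
    if len(labels) != 2:
        raise ValueError("two classes required")
    return X[y == labels[0]], X[y == labels[1]]


def _singular(cov: np.ndarray) -> bool:
    return not np.isfinite(cov).all() or np.linalg.cond(cov) > COND_THRESHOLD


def mahalanobis_bound(X: np.ndarray, y: np.ndarray, subgroup: str | None = None,
                      variable_set: str | None = None) -> ErrorBoundEstimate:
    """Upper bound from the Mahalanobis distance between class means."""
    X = np.asarray(X, float)
    X0, X1 = _class_split(X, y)
    p1, p2 = _priors(y)
    n0, n1 = len(X0), len(X1)
    pooled = ((n0 - 1) * np.cov(X0, rowvar=False, ddof=1)
              + (n1 - 1) * np.cov(X1, rowvar=False, ddof=1)) / (n0 + n1 - 2)
    pooled = np.atleast_2d(pooled)
    if _singular(pooled):
        return ErrorBoundEstimate("mahalanobis", subgroup, variable_set,
                                  None, None, status="singular_covariance")
    d = X0.mean(axis=0) - X1.mean(axis=0)
    delta = float(d @ np.linalg.solve(pooled, d))
    e_up = 2.0 * p1 * p2 / (1.0 + p1 * p2 * delta)
    return ErrorBoundEstimate("mahalanobis", subgroup, variable_set,
                              None, float(np.clip(e_up, 0.0, 0.5)))


def bhattacharyya_bounds(X: np.ndarray, y: np.ndarray,
                         subgroup: str | None = None,
                         variable_set: str | None = None) -> ErrorBoundEstimate:
    """Bound pair from the Bhattacharyya distance under Gaussian models."""
    X = np.asarray(X, float)
    X0, X1 = _class_split(X, y)
    p1, p2 = _priors(y)
    S0 = np.atleast_2d(np.cov(X0, rowvar=False, ddof=1))
    S1 = np.atleast_2d(np.cov(X1, rowvar=False, ddof=1))
    Sbar = 0.5 * (S0 + S1)
    if _singular(S0) or _singular(S1) or _singular(Sbar):
        return ErrorBoundEstimate("bhattacharyya", subgroup, variable_set,
                                  None, None, status="singular_covariance")
    d = X0.mean(axis=0) - X1.mean(axis=0)
    term1 = 0.125 * float(d @ np.linalg.solve(Sbar, d))
    sign, logdet_bar = np.linalg.slogdet(Sbar)
    _, logdet0 = np.linalg.slogdet(S0)
    _, logdet1 = np.linalg.slogdet(S1)
    if sign <= 0:
        return ErrorBoundEstimate("bhattacharyya", subgroup, variable_set,
                                  None, None, status="singular_covariance")
    B = term1 + 0.5 * (logdet_bar - 0.5 * (logdet0 + logdet1))
    rho = float(np.exp(-B))
    e_up = float(np.sqrt(p1 * p2) * rho)
    e_low = 0.5 * (1.0 - np.sqrt(max(0.0, 1.0 - 4.0 * p1 * p2 * rho**2)))
    return ErrorBoundEstimate("bhattacharyya", subgroup, variable_set,
                              float(e_low), float(np.clip(e_up, 0.0, 0.5)))


def knn_bounds(X: np.ndarray, y: np.ndarray, k: int = 5, folds: int = 5,
               seed: int = 0, subgroup: str | None = None,
               variable_set: str | None = None) -> ErrorBoundEstimate:
    """Bound pair from the cross-validated k-NN error (Cover-Hart).

    Features are standardized with training-fold statistics (Euclidean
    metric); the pooled misclassification rate over the stated folds is
    clipped to [0, 1/2] before inversion.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    counts = np.unique(y, return_counts=True)[1]
    if len(counts) < 2 or counts.min() < 10 * k:
        raise TooFewSamples(f"need >= {10 * k} samples per class")
    scheme = make_folds(y, n_folds=folds, seed=seed)
    errors = 0
    for fold in range(folds):
        train, test = scheme.train_test(fold)
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        clf = KNeighborsClassifier(n_neighbors=k)
        clf.fit((X[train] - mu) / sd, y[train])
        errors += int((clf.predict((X[test] - mu) / sd) != y[test]).sum())
    eps = float(np.clip(errors / len(y), 0.0, 0.5))
    e_low = 0.5 * (1.0 - np.sqrt(max(0.0, 1.0 - 2.0 * eps)))
    return ErrorBoundEstimate("knn", subgroup, variable_set, float(e_low),
                              eps, k=k, n_folds=folds)


@dataclass
class BoundsReport:
    estimates: list[ErrorBoundEstimate]
    knn_nonoverlap: dict[str, bool]

    def to_frame(self) -> pd.DataFrame:
        """Tidy grid: method x variable set x subgroup with statuses."""
        rows = []
        for e in self.estimates:
            rows.append({
                "method": e.method, "variable_set": e.variable_set,
                "subgroup": e.subgroup,
                "E_low": np.nan if e.E_low is None else e.E_low,
                "E_up": np.nan if e.E_up is None else e.E_up,
                "status": e.status})
        return pd.DataFrame(rows)


def _full_rank_reduce(X: np.ndarray) -> np.ndarray:
    """Drop constant columns and one column per exact linear tie.

    One-hot blocks carry an exact sum-to-one constraint; removing one
    indicator per block (and any constant column) is an information-
    preserving reparameterization that lets the moment-based estimators
    operate on encoded panels.
    """
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    # greedy QR-based removal of exactly dependent columns
    _, R = np.linalg.qr(X - X.mean(axis=0))
    diag = np.abs(np.diag(R))
    independent = diag > 1e-9 * max(1.0, diag.max())
    return X[:, independent]


def bounds_report(cohort: Cohort, feature_sets=("core7", "all"),
                  methods=("mahalanobis", "bhattacharyya", "knn"),
                  k: int = 5, folds: int = 5, seed: int = 0,
                  drop_redundant: bool = False) -> BoundsReport:
    """Bound grid: methods x variable sets x subgroups.

    Each estimate uses the subgroup's rows only. Singular-covariance
    failures are recorded in the status column — with full one-hot
    encoding the parametric estimators are expected to fail; pass
    ``drop_redundant=True`` to reduce each feature matrix to full rank
    (constant columns and redundant indicators removed) before the
    Mahalanobis/Bhattacharyya estimators. Non-overlap of the two
    subgroups' k-NN intervals is flagged per variable set.
    """
    enc = cohort.encoded if cohort.encoded is not None \
        else encode_features(cohort).encoded
    y = cohort.outcome
    estimates: list[ErrorBoundEstimate] = []
    nonoverlap: dict[str, bool] = {}
    for fs_name in feature_sets:
        fset = resolve_feature_set(fs_name, cohort.catalog, cohort.task)
        Xall = enc[fset.columns].to_numpy(float)
        per_sg: dict[str, ErrorBoundEstimate] = {}
        for sg in SUBGROUPS:
            member = cohort.comorbid if sg == "comorbid" else ~cohort.comorbid
            X, ysg = Xall[member], y[member]
            Xp = _full_rank_reduce(X) if drop_redundant else X
            for method in methods:
                if method == "mahalanobis":
                    est = mahalanobis_bound(Xp, ysg, sg, fs_name)
                elif method == "bhattacharyya":
                    est = bhattacharyya_bounds(Xp, ysg, sg, fs_name)
                elif method == "knn":
                    try:
                        est = knn_bounds(X, ysg, k=k, folds=folds, seed=seed,
                                         subgroup=sg, variable_set=fs_name)
                        per_sg[sg] = est
                    except TooFewSamples:
                        est = ErrorBoundEstimate(
                            "knn", sg, fs_name, None, None, k=k,
                            n_folds=folds, status="too_few_samples")
                else:
                    raise ValueError(f"unknown method {method!r}")
                estimates.append(est)
        if len(per_sg) == 2:
            a, b = per_sg["comorbid"], per_sg["non_comorbid"]
            nonoverlap[fs_name] = bool(a.E_low > b.E_up or b.E_low > a.E_up)
    return BoundsReport(estimates=estimates, knn_nonoverlap=nonoverlap)
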