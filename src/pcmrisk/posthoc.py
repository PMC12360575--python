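"""Post-hoc analyses and end-to-end report assembly.

Covers the marker-stratified model comparison (splitting the cohort at
the population mean of a dominant continuous marker such as HbA1c), the
incremental PFI-ordered feature curve with plateau detection, the ELF
contribution-share accounting across model variants, and the
``run_full_analysis`` driver that writes every table family plus a run
manifest.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bayes_error import bounds_report
from .cohort import Cohort, encode_features
from .drivers import DriverTable, driver_summary
from .evaluate import SUBGROUPS, rank_auc, subgroup_metrics_from_proba
from .exceptions import ConstantMarker, ZeroTotal
from .models import (
    SubgroupRiskModel,
    external_score,
    resolve_feature_set,
    single_variable_models,
    stand_in_benchmark,
)
from .simulate import MARKER, GeneratorConfig, generate_cohort


# ---------------------------------------------------------------------------
# marker stratification
# ---------------------------------------------------------------------------

def stratify_by_marker(cohort: Cohort, marker: str = MARKER
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Split rows at the whole-cohort mean of a continuous marker.

    Returns (low_rows, high_rows): strictly-below-mean vs at-or-above
    (values exactly at the mean fall in the high stratum). The strata
    partition the cohort.
    """
    if cohort.missing_mask[marker].any():
        raise ValueError(f"marker {marker!r} has missing values")
    x = cohort.raw[marker].to_numpy(float)
    if np.ptp(x) == 0:
        raise ConstantMarker(f"marker {marker!r} is constant")
    mean = float(x.mean())
    return np.flatnonzero(x < mean), np.flatnonzero(x >= mean)


#: model variants of the marker-stratified comparison
STRATIFIED_VARIANTS = ("core7", "hba1c_only", "all_minus_hba1c", "all")


def stratified_model_comparison(cohort: Cohort,
                                variants=STRATIFIED_VARIANTS,
                                marker: str = MARKER, n_folds: int = 5,
                                budget: int = 1, seed: int = 0,
                                include_benchmark: bool = True) -> pd.DataFrame:
    """AUC (mean ± sd over folds) per model variant x marker stratum.

    Models are unified (trained on all training rows); evaluation is
    restricted to comorbid test rows inside each stratum, the population
    the comparison is designed for. ``include_benchmark`` adds a
    stand-in core-7 logistic score fitted per training fold.
    """
    low, high = stratify_by_marker(cohort, marker)
    strata = {"low": np.zeros(cohort.n_samples, bool),
              "high": np.zeros(cohort.n_samples, bool)}
    strata["low"][low] = True
    strata["high"][high] = True
    y = cohort.outcome
    rows = []
    scores: dict[str, np.ndarray] = {}
    folds = None
    for variant in variants:
        res = SubgroupRiskModel(cohort, variant).fit(
            n_folds=n_folds, budget=budget, seed=seed)
        folds = res.folds
        scores[f"XGB ({variant})"] = res.oof_proba
    if include_benchmark and folds is not None:
        p = np.empty(cohort.n_samples)
        for fold in range(folds.n_folds):
            train, test = folds.train_test(fold)
            spec = stand_in_benchmark(cohort, seed=seed, fit_rows=train)
            p[test] = external_score(cohort, spec)[test]
        scores["benchmark (stand-in core7 logistic)"] = p
    for name, proba in scores.items():
        for stratum, member in strata.items():
            aucs = []
            for fold in range(folds.n_folds):
                _, test = folds.train_test(fold)
                sel = test[member[test] & cohort.comorbid[test]]
                if len(sel) < 2 or len(np.unique(y[sel])) < 2:
                    continue
                aucs.append(rank_auc(y[sel], proba[sel]))
            rows.append({
                "model": name, "stratum": stratum,
                "auc_mean": float(np.mean(aucs)) if aucs else np.nan,
                "auc_sd": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                "n_folds": len(aucs)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# incremental feature curve
# ---------------------------------------------------------------------------

@dataclass
class IncrementalCurve:
    steps: pd.DataFrame
    plateau_step: int | None
    epsilon: float

    def auc_sequence(self, subgroup: str = "comorbid") -> np.ndarray:
        return self.steps[f"auc_{subgroup}"].to_numpy()


def incremental_feature_curve(cohort: Cohort, base_vars: list[str],
                              order: DriverTable | list[str],
                              order_subgroup: str = "comorbid",
                              n_folds: int = 5, seed: int = 0,
                              epsilon: float = 0.002,
                              plateau_run: int = 3,
                              max_steps: int | None = None,
                              eval_subgroup: str = "comorbid"
                              ) -> IncrementalCurve:
    """AUC after each PFI-ordered feature addition, with plateau point.

    Starts from ``base_vars`` (raw variable names, e.g. the seven core
    variables plus all ELFs) and adds remaining raw variables by
    descending driver score. The plateau is the first step where
    ``plateau_run`` consecutive marginal gains on the evaluated subgroup
    all fall below ``epsilon``.
    """
    if isinstance(order, DriverTable):
        ranked = list(order.table(order_subgroup)["name"])
    else:
        ranked = list(order)
    queue = [v for v in ranked if v not in set(base_vars)]
    if max_steps is not None:
        queue = queue[:max_steps]
    current = list(base_vars)
    records = []
    gains: list[float] = []
    prev = None
    plateau = None
    emap = cohort.catalog.encoded_map()
    for step, added in enumerate([None] + queue):
        if added is not None:
            current.append(added)
        cols = [c for v in current for c in emap[v]]
        fset = resolve_feature_set("custom", cohort.catalog, cohort.task,
                                   columns=cols)
        res = SubgroupRiskModel(cohort, fset).fit(
            n_folds=n_folds, budget=1, seed=seed)
        metrics = {m.subgroup: m for m in res.subgroup_metrics()}
        rec = {"step": step, "added": added or "", "n_vars": len(current)}
        for sg in SUBGROUPS:
            rec[f"auc_{sg}"] = metrics[sg].auc_mean
        records.append(rec)
        auc = rec[f"auc_{eval_subgroup}"]
        if prev is not None:
            gains.append(auc - prev)
            if (plateau is None and len(gains) >= plateau_run
                    and all(g < epsilon for g in gains[-plateau_run:])):
                plateau = step
        prev = auc
    return IncrementalCurve(steps=pd.DataFrame(records),
                            plateau_step=plateau, epsilon=epsilon)


# ---------------------------------------------------------------------------
# contribution shares
# ---------------------------------------------------------------------------

def category_shares(table: pd.DataFrame) -> pd.Series:
    """Percentage share of summed scores per category (PFI clipped at 0)."""
    s = table.copy()
    s["score"] = s["score"].clip(lower=0).fillna(0.0)
    total = s["score"].sum()
    if total == 0:
        raise ZeroTotal("all scores are zero")
    return 100.0 * s.groupby("category")["score"].sum() / total


def elf_contribution_shares(tables: dict[str, dict[str, DriverTable]],
                            subgroup: str = "comorbid",
                            baseline: str = "all_vars") -> pd.DataFrame:
    """ELF contribution shares per model variant and driver metric.

    ``tables[variant][metric]`` holds the driver table of that variant
    computed on the comorbid subgroup. Shares are
    ``100 * sum(ELF scores) / sum(all scores)`` with negative PFI values
    clipped to zero; gains are reported against the all-variables
    baseline in percentage points and in percent of the baseline.
    """
    rows = []
    for variant, metrics in tables.items():
        for metric, table in metrics.items():
            shares = category_shares(table.table(subgroup))
            rows.append({"variant": variant, "metric": metric,
                         "elf_share": float(shares.get("ELF", 0.0))})
    df = pd.DataFrame(rows)
    base = df[df["variant"] == baseline].set_index("metric")["elf_share"]
    df["gain_abs"] = df.apply(
        lambda r: r["elf_share"] - base.get(r["metric"], np.nan), axis=1)
    df["gain_rel"] = df.apply(
        lambda r: 100.0 * r["gain_abs"] / base.get(r["metric"], np.nan)
        if base.get(r["metric"], 0) else np.nan, axis=1)
    return df


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Configuration of one end-to-end run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_folds: int = 5
    budget: int = 1
    seed: int = 0
    top_k: int = 25
    pfi_repeats: int = 10
    do_bounds: bool = True
    do_single_variable: bool = False
    do_posthoc: bool = True
    do_incremental: bool = False
    incremental_max_steps: int | None = None
    shap_method: str = "fast"

    @classmethod
    def from_mapping(cls, d: dict) -> "AnalysisConfig":
        gen = GeneratorConfig.from_mapping(d.get("generator", {}))
        rest = {k: v for k, v in d.items()
                if k in cls.__dataclass_fields__ and k != "generator"}
        return cls(generator=gen, **rest)


def run_full_analysis(config: AnalysisConfig,
                      out_dir: str | Path | None = None) -> dict:
    """Generate a cohort and run every enabled analysis stage.

    Returns a dict of result tables; with ``out_dir`` also writes them as
    CSV plus a ``manifest.json`` recording seeds and versions. Outputs
    are deterministic for a fixed config.
    """
    import sklearn
    import xgboost

    cohort = generate_cohort(config.generator)
    cohort = encode_features(cohort)
    results: dict = {}

    fitted = {}
    for variant in ("all", "core7"):
        fitted[variant] = SubgroupRiskModel(cohort, variant).fit(
            n_folds=config.n_folds, budget=config.budget, seed=config.seed)
    metrics = []
    for variant, res in fitted.items():
        metrics += [m.as_dict() for m in res.subgroup_metrics(
            model_name=f"XGB ({variant})")]
    bench = np.empty(cohort.n_samples)
    folds = fitted["all"].folds
    for fold in range(folds.n_folds):
        train, test = folds.train_test(fold)
        spec = stand_in_benchmark(cohort, seed=config.seed, fit_rows=train)
        bench[test] = external_score(cohort, spec)[test]
    metrics += [m.as_dict() for m in subgroup_metrics_from_proba(
        cohort, bench, folds, "benchmark (stand-in core7 logistic)")]
    results["metrics"] = pd.DataFrame(metrics)

    curves = fitted["all"].decision_curve(
        subgroup="comorbid",
        extra_scores={"XGB (core7)": fitted["core7"].oof_proba,
                      "benchmark (stand-in core7 logistic)": bench})
    results["decision_curves"] = curves.to_frame()

    if config.do_bounds:
        results["bounds"] = bounds_report(
            cohort, seed=config.seed).to_frame()

    pfi = fitted["all"].permutation_importance(
        repeats=config.pfi_repeats, seed=config.seed)
    shap_t = fitted["all"].shap_importance(method=config.shap_method)
    effect = fitted["all"].effect_sizes()
    results["drivers_pfi"] = pfi.to_frame()
    results["drivers_shap"] = shap_t.to_frame()
    results["drivers_effectsize"] = effect.to_frame()
    results["driver_summary"] = pd.DataFrame([
        {"metric": t.metric, "overlap_fraction":
         driver_summary(t).overlap_fraction,
         "elf_top30_comorbid": driver_summary(t).elf_counts.get("comorbid"),
         "elf_top30_non_comorbid":
         driver_summary(t).elf_counts.get("non_comorbid")}
        for t in (pfi, shap_t)])

    if config.do_single_variable:
        results["drivers_singlevar"] = single_variable_models(
            cohort, folds, seed=config.seed).to_frame()

    if config.do_posthoc:
        results["posthoc_stratified"] = stratified_model_comparison(
            cohort, n_folds=config.n_folds, budget=config.budget,
            seed=config.seed)
        order = list(pfi.table("comorbid")["name"])
        variant_tables: dict[str, dict[str, DriverTable]] = {}
        specs = {"all_vars": ("all", {}),
                 "top_k": ("top_k", {"k": config.top_k, "order": order}),
                 "nonlab": ("nonlab", {})}
        for vname, (fs, kw) in specs.items():
            if vname == "all_vars":
                res = fitted["all"]
            else:
                res = SubgroupRiskModel(cohort, fs, **kw).fit(
                    n_folds=config.n_folds, budget=config.budget,
                    seed=config.seed)
            variant_tables[vname] = {
                "pfi": res.permutation_importance(
                    repeats=config.pfi_repeats, seed=config.seed)
                if vname != "all_vars" else pfi,
                "shap": res.shap_importance(method=config.shap_method)
                if vname != "all_vars" else shap_t,
                "effect_size": res.effect_sizes()
                if vname != "all_vars" else effect,
            }
        results["elf_shares"] = elf_contribution_shares(variant_tables)

    if config.do_incremental:
        base_vars = (cohort.catalog.core7(cohort.task)
                     + cohort.catalog.elf_names)
        results["incremental_curve"] = incremental_feature_curve(
            cohort, base_vars, pfi, n_folds=config.n_folds,
            seed=config.seed,
            max_steps=config.incremental_max_steps).steps

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "seed": config.seed,
            "generator": {k: v for k, v in vars(config.generator).items()},
            "n_folds": config.n_folds, "budget": config.budget,
            "python": platform.python_version(),
            "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                         "scikit-learn": sklearn.__version__,
                         "xgboost": xgboost.__version__},
            "tables": sorted(results),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=str))
    return results
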