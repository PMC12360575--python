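# pcmrisk

Subgroup-aware evaluation of machine-learning risk prediction for
psycho-cardio-metabolic multimorbidity.

Clinical risk scores for cardiovascular disease (CVD) and diabetes are
validated on general populations but degrade in exactly the patients who
need them most: people whose mental disorder (depression or anxiety)
co-occurs with the complementary cardiometabolic condition. `pcmrisk`
is a pipeline for quantifying that gap and explaining it. It trains a
single unified gradient-boosted (XGBoost) risk model under stratified
5-fold cross-validation and then evaluates it *separately* in the
comorbid and non-comorbid subgroups:

* **Performance** — AUC-ROC and Brier score per subgroup (mean ± sd over
  folds) and decision-curve analysis with the net benefit
  b(t) = TP/n − (FP/n)·t/(1−t) against 'all' and 'none' reference
  strategies.
* **Intrinsic difficulty** — group-specific Bayes-error bounds by three
  estimators: the Mahalanobis upper bound E_up = 2p₁p₂/(1+p₁p₂Δ), the
  Gaussian Bhattacharyya pair (E_up = √(p₁p₂)·e^(−B),
  E_low = ½(1−√(1−4p₁p₂e^(−2B)))), and the Cover–Hart inversion of the
  cross-validated 5-NN error.
* **Drivers** — single-variable AUCs, permutation feature importance
  PFI_j = L(shuffled j) − L(original), mean-absolute Shapley attribution
  I_j = mean|φ_j| (with an exact float64 tree-conditional backend), and
  the dual-group risk effect size: Cohen's D of each feature between
  model-predicted high-risk (p > t) and low-risk (p ≤ 1−t) patients.
* **Post-hoc** — marker-stratified model comparisons (split at the
  population mean of HbA1c), incremental PFI-ordered feature curves with
  plateau detection, and early-life-factor (ELF) contribution shares
  across model variants.

Because real psycho-cardio-metabolic cohorts are access-restricted, the
package ships a first-class synthetic cohort generator (64 raw
variables one-hot encoding to 83 features, 8 ELFs, two tasks) whose
latent structure designs in the patterns the pipeline is meant to
detect — ELF×comorbidity interactions, subgroup-specific label noise,
and a piecewise marker coupling — so every stage is testable against
known ground truth.

## Worked example

```python
import pcmrisk as pm

cfg = pm.GeneratorConfig(n_samples=20_000, seed=0)        # diabetes task
cohort = pm.encode_features(pm.generate_cohort(cfg))

res = pm.SubgroupRiskModel(cohort, "all").fit(n_folds=5, budget=1, seed=0)
print(res.summary())
```

```
SubgroupRiskModel: task=diabetes features=all (p=83)
n=20000  folds=5  seed=0
subgroup            n         AUC-ROC           Brier
comorbid         3000     0.687 ± 0.027     0.189 ± 0.010
non_comorbid    17000     0.703 ± 0.023     0.055 ± 0.003
```

The restricted seven-core-variable model loses far more in the comorbid
subgroup (AUC 0.593 ± 0.024 there vs 0.669 ± 0.016 non-comorbid), i.e.
the extra variables buy +0.094 AUC for comorbid patients but only
+0.034 for everyone else. The k-NN Bayes-error bounds explain part of
this as irreducible noise:

```python
print(pm.bounds_report(cohort, methods=("knn",), seed=0).to_frame())
```

```
method variable_set     subgroup    E_low     E_up status
   knn        core7     comorbid 0.214810 0.337333     ok
   knn        core7 non_comorbid 0.035369 0.068235     ok
   knn          all     comorbid 0.195862 0.315000     ok
   knn          all non_comorbid 0.034199 0.066059     ok
```

The comorbid interval sits far above the non-comorbid one — that
subgroup is intrinsically harder, no model can close the gap entirely.
Driver analyses show who carries the extra signal:

```python
pfi = res.permutation_importance(repeats=5, seed=0)
print(pfi.table("comorbid").head(4))
s = pm.driver_summary(pfi, top_k=30)
print("top-30 overlap:", s.overlap_fraction, "ELFs in top-30:", s.elf_counts)
```

```
                           name      category    score       se  rank
                     Depression mental_health 0.037958 0.002670     1
                        Anxiety mental_health 0.027161 0.001862     2
     MaternalSmokingAroundBirth           ELF 0.011735 0.000679     3
FeltHatedByFamilyMemberAsAChild           ELF 0.006248 0.000676     4
top-30 overlap: 0.67 ELFs in top-30: {'comorbid': 7, 'non_comorbid': 1}
```

Seven of the top 30 comorbid performance drivers are early-life factors
versus one in the non-comorbid ranking — the generator's designed-in
ELF×comorbidity interaction, recovered end to end.

The whole pipeline (metrics, decision curves, bounds, driver tables,
post-hoc stratification, ELF shares, manifest) runs in one call or from
the shell:

```sh
pcmrisk report --seed 1 --out results/run1
pcmrisk generate --seed 1 --n-samples 5000 --out cohort.csv
pcmrisk bounds --table cohort.csv --catalog catalog.json \
    --task diabetes --out bounds.csv
```

See `docs/methods.md` for the model, estimator formulas, generator
assumptions and numerical conventions.

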