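import json

import numpy as np
import pandas as pd
import pytest

import pcmrisk as pm
from pcmrisk.drivers import DriverTable
from pcmrisk.exceptions import ConstantMarker, ZeroTotal
from pcmrisk.posthoc import (
    AnalysisConfig,
    category_shares,
    elf_contribution_shares,
    incremental_feature_curve,
    run_full_analysis,
    stratified_model_comparison,
    stratify_by_marker,
)
from pcmrisk.simulate import GeneratorConfig

from conftest import cohort_from_arrays


class TestStratify:
    def _marker_cohort(self, values):
        n = len(values)
        return cohort_from_arrays({"HbA1c": np.asarray(values, float)},
                                  np.zeros(n, int))

    def test_mean_split_hand_example(self):
        cohort = self._marker_cohort([1, 2, 3, 4])
        low, high = stratify_by_marker(cohort, "HbA1c")
        assert list(low) == [0, 1]
        assert list(high) == [2, 3]

    def test_value_at_mean_goes_high(self):
        cohort = self._marker_cohort([1.0, 2.0, 3.0])   # mean exactly 2
        low, high = stratify_by_marker(cohort, "HbA1c")
        assert 1 in high

    def test_partition_covers_cohort(self, sim_cohort):
        low, high = stratify_by_marker(sim_cohort)
        assert len(low) + len(high) == sim_cohort.n_samples
        assert not set(low) & set(high)

    def test_constant_marker_rejected(self):
        with pytest.raises(ConstantMarker):
            stratify_by_marker(self._marker_cohort([2, 2, 2]), "HbA1c")


@pytest.fixture(scope="module")
def comparison(sim_cohort):
    return stratified_model_comparison(sim_cohort, n_folds=3, budget=1, seed=7)


class TestStratifiedComparison:
    def test_marker_only_model_recovers_piecewise_coupling(self, comparison):
        t = comparison.set_index(["model", "stratum"])
        lo = t.loc[("XGB (hba1c_only)", "low"), "auc_mean"]
        hi = t.loc[("XGB (hba1c_only)", "high"), "auc_mean"]
        # below the population mean the marker is uncoupled by design
        assert abs(lo - 0.5) < 0.08
        assert hi > lo + 0.05

    def test_all_variables_strongest_in_high_stratum(self, comparison):
        t = comparison.set_index(["model", "stratum"])
        assert t.loc[("XGB (all)", "high"), "auc_mean"] \
            >= t.loc[("XGB (hba1c_only)", "high"), "auc_mean"] - 0.02

    def test_every_variant_and_stratum_reported(self, comparison):
        assert set(comparison["stratum"]) == {"low", "high"}
        assert len(comparison) == 5 * 2   # 4 XGB variants + benchmark


class TestIncrementalCurve:
    def _scenario(self, seed=0, n=2500):
        rng = np.random.default_rng(seed)
        data = {f"s{i}": rng.normal(size=n) for i in range(3)}
        data.update({f"n{i}": rng.normal(size=n) for i in range(7)})
        eta = data["s0"] + 0.8 * data["s1"] + 0.6 * data["s2"]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return cohort_from_arrays(data, y)

    def test_informative_then_null_additions(self):
        cohort = self._scenario()
        order = ["s1", "s2"] + [f"n{i}" for i in range(7)]
        curve = incremental_feature_curve(
            cohort, base_vars=["s0"], order=order, n_folds=3, seed=0,
            eval_subgroup="non_comorbid")
        aucs = curve.auc_sequence("non_comorbid")
        # informative additions help; every null addition moves AUC < 0.01
        assert aucs[2] > aucs[0]
        null_deltas = np.abs(np.diff(aucs[2:]))
        assert (null_deltas < 0.01).all()
        # endpoint uses the full universe: matches the all-variables model
        full = pm.SubgroupRiskModel(cohort, "custom",
                                    columns=list(cohort.encoded.columns)).fit(
            n_folds=3, budget=1, seed=0)
        full_auc = [m for m in full.subgroup_metrics()
                    if m.subgroup == "non_comorbid"][0].auc_mean
        assert abs(aucs[-1] - full_auc) < 0.01

    def test_plateau_detected_after_informative_features(self):
        cohort = self._scenario(seed=1)
        order = ["s1", "s2"] + [f"n{i}" for i in range(7)]
        curve = incremental_feature_curve(
            cohort, base_vars=["s0"], order=order, n_folds=3, seed=1,
            eval_subgroup="non_comorbid")
        assert curve.plateau_step is not None
        assert curve.plateau_step <= 2 + 3   # informative run + plateau_run


class TestContributionShares:
    def _table(self, scores, categories):
        rows = pd.DataFrame({
            "name": [f"v{i}" for i in range(len(scores))],
            "category": categories, "score": scores,
            "rank": np.arange(1, len(scores) + 1)})
        return DriverTable(metric="pfi", tables={"comorbid": rows}, n=10)

    def test_equal_scores_give_proportional_share(self):
        t = self._table([1.0] * 10, ["ELF"] * 2 + ["physical"] * 8)
        shares = category_shares(t.table("comorbid"))
        assert shares["ELF"] == pytest.approx(20.0)
        assert shares.sum() == pytest.approx(100.0, abs=1e-9)

    def test_negative_scores_clipped_before_normalization(self):
        t = self._table([2.0, -1.0, 2.0], ["ELF", "ELF", "physical"])
        shares = category_shares(t.table("comorbid"))
        assert shares["ELF"] == pytest.approx(50.0)

    def test_zero_total_rejected(self):
        t = self._table([0.0, 0.0], ["ELF", "physical"])
        with pytest.raises(ZeroTotal):
            category_shares(t.table("comorbid"))

    def test_gains_against_baseline(self):
        tables = {
            "all_vars": {"pfi": self._table([1, 1, 1, 1],
                                            ["ELF", "physical", "physical",
                                             "physical"])},
            "top_k": {"pfi": self._table([1, 1], ["ELF", "physical"])},
        }
        df = elf_contribution_shares(tables)
        row = df[(df.variant == "top_k")].iloc[0]
        assert row["elf_share"] == pytest.approx(50.0)
        assert row["gain_abs"] == pytest.approx(25.0)
        assert row["gain_rel"] == pytest.approx(100.0)
        base_row = df[(df.variant == "all_vars")].iloc[0]
        assert base_row["gain_abs"] == pytest.approx(0.0)


class TestFullAnalysis:
    def _config(self, seed=3, **kw):
        gen = GeneratorConfig(n_samples=1_500, seed=seed)
        defaults = dict(generator=gen, n_folds=3, budget=1, seed=seed,
                        pfi_repeats=2, do_bounds=False, do_posthoc=False)
        defaults.update(kw)
        return AnalysisConfig(**defaults)

    def test_deterministic_outputs(self, tmp_path):
        a = run_full_analysis(self._config(), out_dir=tmp_path / "a")
        b = run_full_analysis(self._config(), out_dir=tmp_path / "b")
        for name in a:
            pd.testing.assert_frame_equal(a[name], b[name])
        ma = json.loads((tmp_path / "a" / "manifest.json").read_text())
        mb = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert ma == mb

    def test_all_table_families_emitted(self, tmp_path):
        cfg = self._config(do_bounds=True, do_posthoc=True)
        out = run_full_analysis(cfg, out_dir=tmp_path)
        for family in ("metrics", "bounds", "drivers_pfi", "drivers_shap",
                       "drivers_effectsize", "decision_curves",
                       "posthoc_stratified", "elf_shares"):
            assert family in out, family
            assert (tmp_path / f"{family}.csv").exists()

    def test_disabling_bounds_removes_only_that_family(self):
        with_bounds = run_full_analysis(self._config(do_bounds=True))
        without = run_full_analysis(self._config(do_bounds=False))
        assert "bounds" in with_bounds and "bounds" not in without
        pd.testing.assert_frame_equal(with_bounds["metrics"],
                                      without["metrics"])
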