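import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pcmrisk as pm
from pcmrisk.catalog import FeatureCatalog, VariableDef
from pcmrisk.cohort import Cohort, decode_features, make_folds
from pcmrisk.exceptions import (
    ExcessMissingness,
    LevelMismatch,
    MissingFlag,
    MissingValues,
    UnknownVariable,
)


def small_catalog() -> FeatureCatalog:
    return FeatureCatalog([
        VariableDef("Age", "sociodemographic", "continuous"),
        VariableDef("Smoker", "lifestyle", "binary"),
        VariableDef("Colour", "psychosocial", "categorical",
                    ("red", "green", "blue")),
    ])


def write_table(tmp_path, rows, header="sample_id,Age,Smoker,Colour"):
    path = tmp_path / "t.csv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestLoad:
    def test_complete_table_has_empty_mask(self, tmp_path):
        path = write_table(tmp_path, ["a,50,1,red", "b,61,0,green",
                                      "c,44.5,1,blue"])
        cohort = pm.load_cohort(path, small_catalog())
        assert cohort.n_samples == 3
        assert not cohort.missing_mask.to_numpy().any()
        assert cohort.raw.loc["c", "Age"] == 44.5

    def test_empty_cell_masked_exactly_there(self, tmp_path):
        path = write_table(tmp_path, ["a,50,1,red", "b,,0,green"])
        cohort = pm.load_cohort(path, small_catalog())
        mask = cohort.missing_mask
        assert mask.loc["b", "Age"]
        assert mask.to_numpy().sum() == 1

    def test_unknown_column_rejected(self, tmp_path):
        path = write_table(tmp_path, ["a,50,1,red,9"],
                           header="sample_id,Age,Smoker,Colour,Bogus")
        with pytest.raises(UnknownVariable, match="Bogus"):
            pm.load_cohort(path, small_catalog())

    def test_undeclared_level_rejected(self, tmp_path):
        path = write_table(tmp_path, ["a,50,1,purple"])
        with pytest.raises(LevelMismatch, match="purple"):
            pm.load_cohort(path, small_catalog())

    def test_outcome_columns_read(self, tmp_path):
        path = write_table(
            tmp_path, ["a,50,1,red,1", "b,60,0,blue,0"],
            header="sample_id,Age,Smoker,Colour,outcome_diabetes")
        cohort = pm.load_cohort(path, small_catalog())
        assert list(cohort.outcomes["diabetes"]) == [1, 0]


class TestEncode:
    def test_default_catalog_gives_83_columns(self, sim_cohort):
        assert sim_cohort.encoded.shape[1] == 83

    def test_binary_maps_to_single_01_column(self, tmp_path):
        path = write_table(tmp_path, ["a,50,1,red", "b,60,0,blue"])
        enc = pm.encode_features(pm.load_cohort(path, small_catalog())).encoded
        assert set(enc["Smoker"]) <= {0.0, 1.0}

    def test_one_hot_indicators_sum_to_one(self, tmp_path):
        path = write_table(tmp_path, ["a,50,1,red", "b,60,0,blue",
                                      "c,55,1,green"])
        enc = pm.encode_features(pm.load_cohort(path, small_catalog())).encoded
        block = enc[["Colour_red", "Colour_green", "Colour_blue"]]
        assert (block.sum(axis=1) == 1.0).all()

    def test_missing_values_block_encoding(self, tmp_path):
        path = write_table(tmp_path, ["a,,1,red"])
        with pytest.raises(MissingValues):
            pm.encode_features(pm.load_cohort(path, small_catalog()))

    def test_encode_decode_round_trip(self, sim_cohort):
        decoded = decode_features(sim_cohort.encoded, sim_cohort.catalog)
        pd.testing.assert_frame_equal(decoded, sim_cohort.raw,
                                      check_dtype=False)


class TestImpute:
    def _mcar_cohort(self, seed, rho=0.9, rate=0.10, n=400):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        raw = pd.DataFrame({"X": x, "Y": y})
        catalog = FeatureCatalog([VariableDef("X", "physical", "continuous"),
                                  VariableDef("Y", "physical", "continuous")])
        mask = pd.DataFrame(False, index=raw.index, columns=raw.columns)
        hit = rng.random(n) < rate
        truth = raw["Y"].to_numpy().copy()
        mask.loc[hit, "Y"] = True
        raw.loc[hit, "Y"] = np.nan
        return Cohort(raw=raw, catalog=catalog, missing_mask=mask), truth, hit

    def test_no_missing_is_identity(self, sim_cohort):
        out = pm.impute_missing(sim_cohort, seed=0)
        pd.testing.assert_frame_equal(out.raw, sim_cohort.raw)

    def test_ceiling_enforced(self):
        cohort, _, _ = self._mcar_cohort(0, rate=0.30)
        with pytest.raises(ExcessMissingness, match="Y"):
            pm.impute_missing(cohort, ceiling=0.25)

    def test_chained_imputation_beats_mean_on_correlated_data(self):
        # oracle: mean imputation RMSE, averaged over 20 seeds
        worse = 0
        for seed in range(20):
            cohort, truth, hit = self._mcar_cohort(seed)
            it = pm.impute_missing(cohort, method="iterative", seed=seed)
            mn = pm.impute_missing(cohort, method="mean", seed=seed)
            rmse_it = np.sqrt(np.mean(
                (it.raw["Y"].to_numpy()[hit] - truth[hit]) ** 2))
            rmse_mn = np.sqrt(np.mean(
                (mn.raw["Y"].to_numpy()[hit] - truth[hit]) ** 2))
            worse += rmse_it > rmse_mn
        assert worse == 0

    def test_imputed_values_within_observed_range(self):
        cohort, _, hit = self._mcar_cohort(3)
        observed = cohort.raw["Y"].dropna()
        out = pm.impute_missing(cohort, seed=3)
        filled = out.raw["Y"].to_numpy()[hit]
        assert filled.min() >= observed.min() - 1e-12
        assert filled.max() <= observed.max() + 1e-12

    def test_deterministic_given_seed(self):
        cohort, _, _ = self._mcar_cohort(5)
        a = pm.impute_missing(cohort, seed=11).raw
        b = pm.impute_missing(cohort, seed=11).raw
        pd.testing.assert_frame_equal(a, b)


class TestSubgroups:
    def _flag_cohort(self, dep, anx, diab, cvd):
        n = len(dep)
        names = ["Depression", "Anxiety", "Diabetes", "CVD"]
        cats = ["mental_health", "mental_health", "medical_history",
                "medical_history"]
        catalog = FeatureCatalog([
            VariableDef(nm, c, "binary") for nm, c in zip(names, cats)])
        raw = pd.DataFrame({"Depression": dep, "Anxiety": anx,
                            "Diabetes": diab, "CVD": cvd}, dtype=float)
        mask = pd.DataFrame(False, index=raw.index, columns=raw.columns)
        return Cohort(raw=raw, catalog=catalog, missing_mask=mask,
                      outcomes={"CVD": np.zeros(n, int),
                                "diabetes": np.zeros(n, int)})

    def test_definition_for_cvd_task(self):
        cohort = self._flag_cohort([1, 0, 0], [0, 1, 0], [1, 0, 1], [0, 0, 0])
        out = pm.assign_subgroups(cohort, "CVD")
        # dep&diab -> comorbid; anx without diabetes -> not; diab alone -> not
        assert list(out.comorbid) == [True, False, False]

    def test_definition_for_diabetes_task(self):
        cohort = self._flag_cohort([1, 1], [0, 0], [0, 0], [1, 0])
        out = pm.assign_subgroups(cohort, "diabetes")
        assert list(out.comorbid) == [True, False]

    def test_partition_is_exhaustive(self, sim_cohort):
        c = sim_cohort.comorbid
        assert c.sum() + (~c).sum() == sim_cohort.n_samples

    def test_missing_flag_detected(self):
        catalog = FeatureCatalog([VariableDef("Depression", "mental_health",
                                              "binary")])
        raw = pd.DataFrame({"Depression": [1.0, 0.0]})
        mask = pd.DataFrame(False, index=raw.index, columns=raw.columns)
        cohort = Cohort(raw=raw, catalog=catalog, missing_mask=mask)
        with pytest.raises(MissingFlag):
            pm.assign_subgroups(cohort, "CVD")


class TestFolds:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(n=st.integers(60, 400), prev=st.floats(0.1, 0.5),
           seed=st.integers(0, 10))
    def test_fold_prevalence_within_tolerance(self, n, prev, seed):
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < prev).astype(int)
        if y.sum() < 5 or y.sum() > n - 5:
            return
        folds = make_folds(y, n_folds=5, seed=seed)
        global_prev = y.mean()
        for k in range(5):
            test = folds.assignment == k
            assert abs(y[test].mean() - global_prev) <= 1.0 / test.sum()

    def test_positive_counts_near_proportional(self):
        rng = np.random.default_rng(0)
        y = (rng.random(1000) < 0.2).astype(int)
        folds = make_folds(y, n_folds=5, seed=1)
        counts = [y[folds.assignment == k].sum() for k in range(5)]
        assert max(counts) - min(counts) <= 1
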