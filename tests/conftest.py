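from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pcmrisk as pm
from pcmrisk.catalog import FeatureCatalog, VariableDef
from pcmrisk.cohort import Cohort


def cohort_from_arrays(data: dict[str, np.ndarray], y: np.ndarray,
                       task: str = "diabetes",
                       comorbid: np.ndarray | None = None,
                       categories: dict[str, str] | None = None) -> Cohort:
    """Build a minimal encoded cohort straight from numpy arrays.

    Variable dtypes are inferred (binary iff values within {0,1});
    categories default to 'physical'. Used to construct hand-designed
    scenarios that the default catalog would obscure.
    """
    n = len(y)
    entries, cols = [], {}
    for name, arr in data.items():
        arr = np.asarray(arr, float)
        dtype = "binary" if set(np.unique(arr)) <= {0.0, 1.0} else "continuous"
        cat = (categories or {}).get(name, "physical")
        entries.append(VariableDef(name, cat, dtype))
        cols[name] = arr
    catalog = FeatureCatalog(entries)
    raw = pd.DataFrame(cols, index=[f"S{i}" for i in range(n)])
    mask = pd.DataFrame(False, index=raw.index, columns=raw.columns)
    cohort = Cohort(raw=raw, catalog=catalog, missing_mask=mask,
                    outcomes={task: np.asarray(y, int)}, task=task)
    cohort.comorbid = (np.zeros(n, bool) if comorbid is None
                       else np.asarray(comorbid, bool))
    return pm.encode_features(cohort)


@pytest.fixture(scope="session")
def sim_cohort() -> Cohort:
    """Moderate default-condition synthetic cohort, encoded."""
    cohort = pm.generate_cohort(pm.GeneratorConfig(n_samples=12_000, seed=7))
    return pm.encode_features(cohort)


@pytest.fixture(scope="session")
def sim_results_all(sim_cohort):
    """All-variables model fitted on the session cohort (5 folds)."""
    return pm.SubgroupRiskModel(sim_cohort, "all").fit(
        n_folds=5, budget=1, seed=7)
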