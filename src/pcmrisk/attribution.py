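"""Per-instance additive attributions for gradient-boosted tree models.

Attributions are Shapley values of the tree-conditional value function:
for a coalition S, a tree is evaluated by following the split when the
split feature is in S and taking the cover-weighted average of both
children otherwise; the forest value is the sum over trees (margin /
log-odds scale). Two backends are provided:

``exact``
    Per-tree coalition enumeration in float64, vectorized over
    instances. Because features absent from a tree are null players and
    Shapley values are additive across trees, enumerating the 2^m
    coalitions of each tree's m *used* features reproduces the full
    2^|F| definition exactly. Practical for models whose individual
    trees use at most ~16 distinct features.

``fast``
    xgboost's built-in path-dependent TreeSHAP (``pred_contribs``).
    Fast enough for the full pipeline, but computed in float32 and known
    to deviate from the exact conditional Shapley value when a feature
    appears more than once along a root-leaf path.

Local accuracy holds for the exact backend by construction:
``base_value + sum_j phi_j`` equals the float64 margin prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import xgboost as xgb

from .exceptions import NonTreeModel


@dataclass
class _Tree:
    feature: np.ndarray        # split feature index, -1 at leaves
    threshold: np.ndarray
    yes: np.ndarray            # child node index when x[f] < threshold
    no: np.ndarray
    cover: np.ndarray
    value: np.ndarray          # leaf value, 0 elsewhere
    used: list[int]            # distinct feature indices in this tree


def _booster_of(model) -> xgb.Booster:
    if isinstance(model, xgb.Booster):
        return model
    if hasattr(model, "get_booster"):           # sklearn wrapper
        return model.get_booster()
    if isinstance(getattr(model, "booster", None), (xgb.Booster,
                                                    xgb.XGBClassifier)):
        return _booster_of(model.booster)       # pcmrisk RiskModel
    raise NonTreeModel(f"not a gradient-boosted tree model: {type(model)!r}")


def base_margin(model) -> float:
    """The ensemble's intercept on the margin (log-odds) scale."""
    import json
    cfg = json.loads(_booster_of(model).save_config())
    b = float(cfg["learner"]["learner_model_param"]["base_score"])
    obj = cfg["learner"]["objective"]["name"]
    if "logistic" in obj:
        return float(np.log(b / (1.0 - b)))
    return b


def parse_trees(model) -> list[_Tree]:
    import json
    booster = _booster_of(model)
    trees = []
    for dump in booster.get_dump(dump_format="json", with_stats=True):
        nodes: dict[int, dict] = {}

        def walk(nd):
            nodes[nd["nodeid"]] = nd
            for c in nd.get("children", ()):
                walk(c)

        walk(json.loads(dump))
        size = max(nodes) + 1
        t = _Tree(
            feature=np.full(size, -1, dtype=int),
            threshold=np.zeros(size),
            yes=np.zeros(size, dtype=int),
            no=np.zeros(size, dtype=int),
            cover=np.zeros(size),
            value=np.zeros(size),
            used=[],
        )
        for i, nd in nodes.items():
            t.cover[i] = nd.get("cover", 0.0)
            if "leaf" in nd:
                t.value[i] = nd["leaf"]
            else:
                f = nd["split"]
                t.feature[i] = int(f[1:]) if f.startswith("f") else int(f)
                # thresholds live in float32 inside the booster
                t.threshold[i] = np.float32(nd["split_condition"])
                t.yes[i] = nd["yes"]
                t.no[i] = nd["no"]
        t.used = sorted({int(f) for f in t.feature[t.feature >= 0]})
        trees.append(t)
    return trees


def _tree_value(t: _Tree, X: np.ndarray, in_coalition: np.ndarray,
                node: int = 0) -> np.ndarray:
    """Conditional-expectation tree value for every row of X (float64)."""
    f = t.feature[node]
    if f < 0:
        return np.full(len(X), t.value[node])
    vy = _tree_value(t, X, in_coalition, t.yes[node])
    vn = _tree_value(t, X, in_coalition, t.no[node])
    if in_coalition[f]:
        return np.where(X[:, f] < t.threshold[node], vy, vn)
    cy, cn = t.cover[t.yes[node]], t.cover[t.no[node]]
    return (cy * vy + cn * vn) / (cy + cn)


def _as_f32_grid(X: np.ndarray) -> np.ndarray:
    # xgboost routes splits on float32 values; quantize so threshold
    # comparisons agree with the booster, then keep float64 arithmetic
    return np.asarray(X, np.float32).astype(np.float64)


def predict_margin(model, X: np.ndarray) -> np.ndarray:
    """Float64 margin prediction reproduced from the tree structures."""
    X = _as_f32_grid(X)
    full = np.ones(X.shape[1] if X.ndim == 2 else 1, dtype=bool)
    out = np.full(len(X), base_margin(model))
    for t in parse_trees(model):
        out += _tree_value(t, X, full)
    return out


def shap_values(model, X, method: str = "exact",
                max_enum_features: int = 16) -> tuple[np.ndarray, float]:
    """Per-instance attributions ``(phi, base_value)`` on the margin scale.

    ``phi`` has one column per model feature; ``base_value`` is the
    coalition-free expected margin, so
    ``base_value + phi.sum(axis=1) == margin prediction`` (exactly for
    the exact backend, to float32 precision for the fast one).
    """
    booster = _booster_of(model)
    X = np.asarray(X, float)
    if method == "fast":
        contribs = booster.predict(xgb.DMatrix(X), pred_contribs=True)
        return contribs[:, :-1].astype(float), float(contribs[0, -1])
    if method != "exact":
        raise ValueError("method must be 'exact' or 'fast'")
    phi, tree_base = exact_shap_from_trees(parse_trees(model), X,
                                           max_enum_features)
    return phi, tree_base + base_margin(model)


def exact_shap_from_trees(trees: list[_Tree], X: np.ndarray,
                          max_enum_features: int = 16
                          ) -> tuple[np.ndarray, float]:
    """Exact conditional Shapley values for a list of parsed trees."""
    X = _as_f32_grid(X)
    n, p = X.shape
    phi = np.zeros((n, p))
    base = 0.0
    for t in trees:
        m = len(t.used)
        if m > max_enum_features:
            raise ValueError(
                f"tree uses {m} distinct features; exact enumeration capped "
                f"at {max_enum_features} (use method='fast')")
        if m == 0:
            base += float(t.value[0])
            continue
        pos = {f: i for i, f in enumerate(t.used)}
        # value of every coalition of the used features, keyed by bitmask
        values = {}
        coalition = np.zeros(p, dtype=bool)
        for mask in range(1 << m):
            coalition[:] = False
            for f, i in pos.items():
                if mask >> i & 1:
                    coalition[f] = True
            values[mask] = _tree_value(t, X, coalition)
        base += float(values[0][0]) if n else 0.0
        fact = [factorial(i) for i in range(m + 1)]
        for f, i in pos.items():
            bit = 1 << i
            others = [j for j in range(m) if j != i]
            for r in range(m):
                w = fact[r] * fact[m - r - 1] / fact[m]
                for sub in combinations(others, r):
                    mask = sum(1 << j for j in sub)
                    phi[:, f] += w * (values[mask | bit] - values[mask])
    return phi, base
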