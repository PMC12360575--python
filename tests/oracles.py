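"""Independent oracles used by the test suite.

These deliberately re-derive quantities from first principles, separate
from the package's implementation paths:

* a brute-force Shapley oracle that enumerates all 2^|F| coalitions of
  the *whole* forest value function (conditional-expectation semantics),
  parsing the booster dump with its own code;
* numeric overlap integrals for the Bayes error of Gaussian
  class-conditional problems in one and two dimensions.
"""

from __future__ import annotations

import json
from itertools import combinations
from math import factorial

import numpy as np
from scipy import integrate
from scipy.stats import multivariate_normal, norm


# ---------------------------------------------------------------------------
# exhaustive Shapley oracle
# ---------------------------------------------------------------------------

def _dump_trees(booster):
    trees = []
    for dump in booster.get_dump(dump_format="json", with_stats=True):
        nodes = {}

        def walk(nd):
            nodes[nd["nodeid"]] = nd
            for c in nd.get("children", ()):
                walk(c)

        walk(json.loads(dump))
        trees.append(nodes)
    return trees


def _expvalue(nodes, X, S, nodeid=0):
    """Conditional-expectation value of one tree for all rows of X."""
    nd = nodes[nodeid]
    if "leaf" in nd:
        return np.full(len(X), nd["leaf"])
    f = int(nd["split"].lstrip("f"))
    vy = _expvalue(nodes, X, S, nd["yes"])
    vn = _expvalue(nodes, X, S, nd["no"])
    if f in S:
        # thresholds are float32 inside the booster
        return np.where(X[:, f] < np.float64(np.float32(nd["split_condition"])),
                        vy, vn)
    cy = nodes[nd["yes"]]["cover"]
    cn = nodes[nd["no"]]["cover"]
    return (cy * vy + cn * vn) / (cy + cn)


def brute_force_shap(booster, X, base_margin: float = 0.0):
    """Shapley values over *all* features by full coalition enumeration.

    Returns ``(phi, base)`` where ``base = E[f] = v(empty) + base_margin``
    and ``base + phi.sum(axis=1)`` equals the margin prediction.
    """
    # match the booster's float32 split routing, keep float64 arithmetic
    X = np.asarray(X, np.float32).astype(np.float64)
    n, p = X.shape
    trees = _dump_trees(booster)
    # forest value of every coalition (vectorized over instances)
    values = {}
    feats = list(range(p))
    for r in range(p + 1):
        for S in combinations(feats, r):
            v = np.zeros(n)
            for nodes in trees:
                v += _expvalue(nodes, X, set(S))
            values[frozenset(S)] = v
    phi = np.zeros((n, p))
    for j in feats:
        rest = [f for f in feats if f != j]
        for r in range(p):
            w = factorial(r) * factorial(p - r - 1) / factorial(p)
            for S in combinations(rest, r):
                phi[:, j] += w * (values[frozenset(S) | {j}]
                                  - values[frozenset(S)])
    base = float(values[frozenset()][0]) + base_margin
    return phi, base


# ---------------------------------------------------------------------------
# Gaussian Bayes-error oracles
# ---------------------------------------------------------------------------

def bayes_error_gaussian_1d(mu0, s0, mu1, s1, p0=0.5) -> float:
    """Numeric overlap integral of min(p0 f0, p1 f1) on the real line."""
    lo = min(mu0 - 10 * s0, mu1 - 10 * s1)
    hi = max(mu0 + 10 * s0, mu1 + 10 * s1)

    def f(x):
        return np.minimum(p0 * norm.pdf(x, mu0, s0),
                          (1 - p0) * norm.pdf(x, mu1, s1))

    val, _ = integrate.quad(f, lo, hi, limit=200)
    return float(val)


def bayes_error_gaussian_2d(mu0, cov0, mu1, cov1, p0=0.5,
                            grid: int = 400, span: float = 8.0) -> float:
    """Numeric overlap integral on a 2-D grid (trapezoidal)."""
    mu0, mu1 = np.asarray(mu0, float), np.asarray(mu1, float)
    center = 0.5 * (mu0 + mu1)
    xs = np.linspace(center[0] - span, center[0] + span, grid)
    ys = np.linspace(center[1] - span, center[1] + span, grid)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([XX.ravel(), YY.ravel()], axis=1)
    f0 = multivariate_normal(mu0, cov0).pdf(pts).reshape(grid, grid)
    f1 = multivariate_normal(mu1, cov1).pdf(pts).reshape(grid, grid)
    integrand = np.minimum(p0 * f0, (1 - p0) * f1)
    return float(np.trapezoid(np.trapezoid(integrand, ys, axis=1), xs))
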