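"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: exhaustive path
enumeration instead of Dijkstra, O(n^2) rescans instead of the fast
non-dominated sort, grid search instead of the scalar optimizer, and a
step-by-step LOOCV loop assembled from primitives.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from sklearn.svm import SVC


def enumerate_shortest_distance(graph: nx.Graph, source: str, target: str) -> float:
    """Minimum total edge weight over all simple paths (inf if none)."""
    if source == target:
        return 0.0
    if source not in graph or target not in graph:
        return float("inf")
    best = float("inf")
    for path in nx.all_simple_paths(graph, source, target):
        w = sum(graph[a][b]["weight"] for a, b in zip(path, path[1:]))
        best = min(best, w)
    return best


def brute_force_fronts(objectives) -> list[list[int]]:
    """Pareto front partition by repeated O(n^2) dominance scans."""
    objs = [tuple(map(float, o)) for o in objectives]

    def dom(a, b):
        return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))

    remaining = list(range(len(objs)))
    fronts = []
    while remaining:
        front = [i for i in remaining
                 if not any(dom(objs[j], objs[i]) for j in remaining if j != i)]
        fronts.append(front)
        remaining = [i for i in remaining if i not in front]
    return fronts


def grid_sigmoid_A(f, c, lo=-50.0, hi=50.0, step=1e-3) -> float:
    """Regularized-likelihood sigmoid slope by dense grid search (B = 0)."""
    f = np.asarray(f, dtype=float)
    c = np.asarray(c, dtype=int)
    n_res = int((c == -1).sum())
    n_sen = int((c == 1).sum())
    t = np.where(c == -1, (n_res + 1.0) / (n_res + 2.0), 1.0 / (n_sen + 2.0))
    grid = np.arange(lo, hi + step, step)
    z = grid[:, None] * f[None, :]
    nll = (np.logaddexp(0.0, z) * t[None, :]
           + np.logaddexp(0.0, -z) * (1.0 - t)[None, :]).sum(axis=1)
    return float(grid[int(np.argmin(nll))])


def loocv_separation_oracle(X, y, C=1.0, grid_step=1e-3) -> float:
    """Hand-assembled LOOCV separation: SVM + grid-search sigmoid per fold.

    X is a complete (no missing) samples x features design; y is +1/-1 with
    sensitive = +1. Returns -min_i(c_i(0.5 - p_i) + 0.5).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    margins = []
    for i in range(n):
        tr = [j for j in range(n) if j != i]
        svm = SVC(kernel="linear", C=C)
        svm.fit(X[tr], y[tr])
        f_tr = svm.decision_function(X[tr])
        A = grid_sigmoid_A(f_tr, y[tr], step=grid_step)
        f_i = float(svm.decision_function(X[i:i + 1])[0])
        p_i = 1.0 / (1.0 + np.exp(A * f_i))
        margins.append(y[i] * (0.5 - p_i) + 0.5)
    return -min(margins)
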