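"""The three minimized objectives: signature size, separation, relevance.

A candidate signature is a binary chromosome over a fixed candidate site list.
Its objective vector is

* **size** — the number of selected phosphosites (smaller signatures are
  easier to translate into targeted assays),
* **separation** — the negative minimal per-sample posterior-probability
  margin, ``-min_i(c_i(1/2 - p_i) + 1/2)``, estimated by an inner
  leave-one-out cross-validation of a linear soft-margin SVM (C = 1) whose
  decision values are calibrated to posterior probabilities by a sigmoid
  with the offset fixed at 0 (so the hyperplane maps to p = 0.5); always
  in [-1, 0], lower is better,
* **relevance** — the mean penalty-weighted shortest-path distance from each
  distinct signature protein to the drug-target protein in a
  confidence-filtered PPI network.

Edge confidences s in (0.9, 1) become Dijkstra penalties via
``rho = 1 / (-log10(1 - s))``, which maps s = 0.9 -> 1 and s = 0.999 -> 1/3,
amplifying differences between high and very high confidences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit
from sklearn.svm import SVC

from .phospho_io import RESISTANT, SENSITIVE, PhosphoMatrix, PPIEdgeList, SampleLabels


class ObjectiveVector(NamedTuple):
    size: int
    separation: float
    relevance: float


# ---------------------------------------------------------------------------
# penalty transform and network
# ---------------------------------------------------------------------------

def confidence_to_penalty(s, *, threshold: float = 0.9, form: str = "reciprocal"):
    """Map an interaction confidence in (threshold, 1) to an edge penalty.

    ``form="reciprocal"`` (default): rho = 1 / (-log10(1 - s)), strictly
    decreasing, with rho(0.9) = 1 and rho(0.999) = 1/3.
    ``form="literal"``: rho = 1 - log10(1 - s), an alternative increasing
    transform kept behind this switch.

    The domain is inclusive at the threshold (confidences range from 0.9 to
    0.999, mapping to penalties 1 down to 1/3); the network itself only keeps
    edges strictly above the threshold.
    """
    arr = np.asarray(s, dtype=float)
    if np.any(arr >= 1.0) or np.any(arr < threshold):
        raise ValueError(
            f"confidence must lie in [{threshold}, 1), got {s!r}"
        )
    if form == "reciprocal":
        out = 1.0 / (-np.log10(1.0 - arr))
    elif form == "literal":
        out = 1.0 - np.log10(1.0 - arr)
    else:
        raise ValueError(f"unknown penalty form {form!r}")
    return float(out) if np.ndim(s) == 0 else out


class PPINetwork:
    """Confidence-filtered PPI graph with penalty-weighted distances to a target.

    Only edges with confidence strictly greater than ``confidence_threshold``
    are retained. Distances from every node to ``target`` are computed once
    with Dijkstra on the penalty weights. Proteins absent from the network or
    disconnected from the target get a finite ``fallback`` distance, by
    default (max finite node-to-target distance) + 1.
    """

    def __init__(
        self,
        edges: PPIEdgeList,
        target: str,
        *,
        confidence_threshold: float = 0.9,
        penalty_form: str = "reciprocal",
        fallback: float | None = None,
    ):
        self.target = target
        self.confidence_threshold = confidence_threshold
        self.penalty_form = penalty_form
        g = nx.Graph()
        for a, b, s in edges.edges:
            if s > confidence_threshold:
                w = confidence_to_penalty(s, threshold=confidence_threshold,
                                          form=penalty_form)
                if g.has_edge(a, b):
                    w = min(w, g[a][b]["weight"])
                g.add_edge(a, b, weight=w)
        self.graph = g
        if target in g:
            self._dist = nx.single_source_dijkstra_path_length(g, target, weight="weight")
        else:
            self._dist = {target: 0.0}
        finite_max = max(self._dist.values(), default=0.0)
        self.fallback = float(fallback) if fallback is not None else finite_max + 1.0

    def distance(self, protein: str) -> float:
        """Penalty-weighted shortest distance to the target (0 for the target itself)."""
        return float(self._dist.get(protein, self.fallback))

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def shortest_distance(network: PPINetwork, protein: str) -> float:
    return network.distance(protein)


# ---------------------------------------------------------------------------
# sigmoid posterior calibration (offset fixed at 0)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SigmoidModel:
    """p(resistant | f) = 1 / (1 + exp(A f + B)), with B fixed to 0."""

    A: float
    B: float = 0.0

    def proba_resistant(self, f):
        return expit(-(self.A * np.asarray(f, dtype=float) + self.B))


def fit_sigmoid(f, c) -> SigmoidModel:
    """Fit the slope A of the posterior sigmoid by regularized maximum likelihood.

    ``f`` are SVM decision values, ``c`` the classes (+1 sensitive,
    -1 resistant). Targets follow the standard regularized scheme:
    resistant samples get t = (N_r + 1)/(N_r + 2), sensitive samples
    t = 1/(N_s + 2), which keeps the likelihood bounded for separable data.
    The offset stays at 0 so a point on the hyperplane always gets p = 0.5.
    The problem is one-dimensional and convex; a bounded scalar minimizer
    makes the fit deterministic.
    """
    f = np.asarray(f, dtype=float)
    c = np.asarray(c, dtype=int)
    n_res = int((c == RESISTANT).sum())
    n_sen = int((c == SENSITIVE).sum())
    if n_res == 0 or n_sen == 0:
        raise ValueError("both classes must be present to fit the sigmoid")
    if np.all(f == f[0]):
        warnings.warn("decision values are constant; sigmoid slope is weakly determined",
                      stacklevel=2)
    t = np.where(c == RESISTANT, (n_res + 1.0) / (n_res + 2.0), 1.0 / (n_sen + 2.0))

    def nll(a: float) -> float:
        z = a * f
        # -log p = log(1+e^z); -log(1-p) = log(1+e^-z)
        return float(t @ np.logaddexp(0.0, z) + (1.0 - t) @ np.logaddexp(0.0, -z))

    res = minimize_scalar(nll, bounds=(-500.0, 500.0), method="bounded",
                          options={"xatol": 1e-9})
    return SigmoidModel(A=float(res.x))


# ---------------------------------------------------------------------------
# evaluator
# ---------------------------------------------------------------------------

def impute_by_class_means(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column imputation value: mean of the two class means.

    Columns where one class has no observed value fall back to the overall
    column mean; columns with no observed value at all fall back to 0.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice means
        m_s = np.nanmean(X[y == SENSITIVE], axis=0)
        m_r = np.nanmean(X[y == RESISTANT], axis=0)
        overall = np.nanmean(X, axis=0)
    imp = (m_s + m_r) / 2.0
    imp = np.where(np.isnan(imp), overall, imp)
    return np.where(np.isnan(imp), 0.0, imp)


class ObjectiveEvaluator:
    """Evaluates chromosomes against a fixed training context.

    The context is a candidate site list, the training matrix restricted to
    those sites, the sample labels and a :class:`PPINetwork`. Results are
    cached by bit pattern, so re-encountered individuals cost nothing.

    Missing training values are imputed per leave-one-out fold by the mean of
    the two class means computed from that fold's training samples only (the
    same scheme used later for validation imputation), so the held-out sample
    never leaks into the imputation.
    """

    def __init__(
        self,
        candidates,
        train: PhosphoMatrix,
        labels: SampleLabels,
        network: PPINetwork,
        *,
        svm_c: float = 1.0,
    ):
        self.candidates = candidates
        self.network = network
        self.svm_c = float(svm_c)

        index = train.site_index
        rows = [index[s.site_id] for s in candidates.sites]
        self.X = train.values[rows].T.copy()  # (n_samples, K)
        self.y = labels.aligned(train.samples)
        self.k = self.X.shape[1]
        n = self.X.shape[0]
        if min((self.y == SENSITIVE).sum(), (self.y == RESISTANT).sum()) < 2:
            raise ValueError("separation objective needs at least 2 samples per class")

        self.proteins = [s.protein_id for s in candidates.sites]
        self._protein_dist = {p: network.distance(p) for p in set(self.proteins)}

        # fold-specific fully imputed design matrices (fold i holds out sample i)
        self._fold_X: list[np.ndarray] = []
        idx = np.arange(n)
        for i in range(n):
            tr = idx != i
            imp = impute_by_class_means(self.X[tr], self.y[tr])
            self._fold_X.append(np.where(np.isnan(self.X), imp[None, :], self.X))

        self._cache: dict[bytes, ObjectiveVector] = {}
        self.n_separation_evals = 0  # bookkeeping for the memoization contract

    # -- individual objectives ------------------------------------------------

    @staticmethod
    def size(bits: np.ndarray) -> int:
        return int(np.count_nonzero(bits))

    def relevance(self, bits: np.ndarray) -> float:
        sel = np.flatnonzero(bits)
        if sel.size == 0:
            return self.network.fallback
        prots = {self.proteins[i] for i in sel}
        return float(np.mean([self._protein_dist[p] for p in prots]))

    def separation(self, bits: np.ndarray) -> float:
        """-min_i margin_i over a leave-one-out CV; always in [-1, 0]."""
        sel = np.flatnonzero(bits)
        if sel.size == 0:
            raise ValueError("separation of an empty signature is undefined")
        self.n_separation_evals += 1
        n = self.X.shape[0]
        margins = np.empty(n)
        for i in range(n):
            Xi = self._fold_X[i][:, sel]
            tr = np.arange(n) != i
            y_tr = self.y[tr]
            if SENSITIVE not in y_tr or RESISTANT not in y_tr:
                margins[i] = 0.0  # degenerate fold: worst margin
                continue
            svm = SVC(kernel="linear", C=self.svm_c)
            svm.fit(Xi[tr], y_tr)
            f_tr = svm.decision_function(Xi[tr])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sigmoid = fit_sigmoid(f_tr, y_tr)
            p_i = float(sigmoid.proba_resistant(svm.decision_function(Xi[i:i + 1]))[0])
            margins[i] = self.y[i] * (0.5 - p_i) + 0.5
        return float(-margins.min())

    # -- combined -------------------------------------------------------------

    def evaluate(self, bits: np.ndarray) -> ObjectiveVector:
        bits = np.asarray(bits, dtype=np.uint8)
        key = bits.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if not bits.any():
            # degenerate chromosome: never run through the SVM; worst-case
            # separation (0) and fallback relevance keep it dominated
            out = ObjectiveVector(0, 0.0, self.network.fallback)
        else:
            out = ObjectiveVector(self.size(bits), self.separation(bits),
                                  self.relevance(bits))
        self._cache[key] = out
        return out

    def __call__(self, bits: np.ndarray) -> ObjectiveVector:
        return self.evaluate(bits)
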