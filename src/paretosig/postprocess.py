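"""From Pareto front to representative signatures, final predictors and validation.

After the optimizer terminates, the accepted first-front solutions are

1. filtered for sufficiently good separation (scores >= the cutoff, default
   -0.6, are removed — the front also carries very small, biologically
   relevant solutions that separate poorly),
2. hierarchically clustered (Ward linkage) on their binary feature vectors,
3. reduced to one representative per cluster — the member closest (Euclidean)
   to the cluster centroid, ties broken by better separation, then by index.

Each representative signature is turned into a final predictor: a linear SVM
(C = 1) trained on the full training set, calibrated with the zero-offset
sigmoid. Validation samples are imputed by the mean of the training class
means and scored with the prediction accuracy and the average probability
distance (1/N) sum_i (0.5 - p_i) c_i, a signed confidence-weighted score in
[-0.5, 0.5] (larger is better).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from sklearn.svm import SVC

from . import nsga2
from .objectives import (
    ObjectiveEvaluator,
    ObjectiveVector,
    PPINetwork,
    fit_sigmoid,
    impute_by_class_means,
)
from .phospho_io import (
    RESISTANT,
    SENSITIVE,
    PhosphoMatrix,
    PPIEdgeList,
    SampleLabels,
    join_failure_report,
)
from .prefilter import build_candidate_set

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


@dataclass(eq=False)
class FrontSolution:
    """One Pareto-front solution decoded against the candidate set."""

    bits: np.ndarray
    objectives: tuple        # (size, separation, relevance)
    sites: list              # selected PhosphoSite objects, candidate order
    cluster_id: int | None = None
    is_representative: bool = False

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def separation(self) -> float:
        return float(self.objectives[1])


@dataclass(eq=False)
class PredictionResult:
    samples: list[str]
    p_resistant: np.ndarray
    predicted: np.ndarray    # +1 / -1
    true: np.ndarray         # +1 / -1
    accuracy: float
    avg_prob_distance: float

    def to_frame(self) -> pd.DataFrame:
        names = {SENSITIVE: "sensitive", RESISTANT: "resistant"}
        return pd.DataFrame(
            {
                "sample_id": self.samples,
                "p_resistant": self.p_resistant,
                "predicted": [names[int(v)] for v in self.predicted],
                "true": [names[int(v)] for v in self.true],
                "correct": self.predicted == self.true,
            }
        )


# ---------------------------------------------------------------------------
# front filtering / clustering / representatives
# ---------------------------------------------------------------------------

def filter_front(front: list[FrontSolution],
                 separation_cutoff: float = -0.6) -> list[FrontSolution]:
    """Keep solutions with separation strictly below the cutoff."""
    kept = [s for s in front if s.separation < separation_cutoff]
    if not kept:
        raise ValueError(
            f"no front solution has separation < {separation_cutoff}; "
            "relax the cutoff (separation_cutoff) or inspect the data"
        )
    return kept


def cluster_solutions(solutions: list[FrontSolution], n_clusters: int = 4) -> np.ndarray:
    """Ward-linkage clustering of binary solution vectors, cut into n_clusters.

    Cluster ids are relabeled 1..n_clusters in dendrogram leaf order so that
    labels are stable across reruns.
    """
    if len(solutions) < n_clusters:
        raise ValueError(
            f"{len(solutions)} solution(s) cannot form {n_clusters} clusters"
        )
    X = np.array([s.bits for s in solutions], dtype=float)
    if len(solutions) == n_clusters:
        raw = np.arange(1, n_clusters + 1)
        leaf_order = np.arange(len(solutions))
    else:
        Z = linkage(X, method="ward")
        raw = fcluster(Z, t=n_clusters, criterion="maxclust")
        leaf_order = leaves_list(Z)
    relabel: dict[int, int] = {}
    for i in leaf_order:
        relabel.setdefault(int(raw[i]), len(relabel) + 1)
    labels = np.array([relabel[int(r)] for r in raw])
    for sol, lab in zip(solutions, labels):
        sol.cluster_id = int(lab)
    return labels


def select_representatives(solutions: list[FrontSolution],
                           assignment: np.ndarray) -> list[FrontSolution]:
    """Per cluster: the member closest to the centroid of the binary vectors.

    Exact distance ties are broken by better (smaller) separation, remaining
    ties by solution index.
    """
    assignment = np.asarray(assignment)
    reps = []
    for cid in sorted(set(int(c) for c in assignment)):
        members = [i for i in range(len(solutions)) if assignment[i] == cid]
        X = np.array([solutions[i].bits for i in members], dtype=float)
        centroid = X.mean(axis=0)
        d = np.linalg.norm(X - centroid[None, :], axis=1)
        best = min(range(len(members)),
                   key=lambda j: (d[j], solutions[members[j]].separation, members[j]))
        rep = solutions[members[best]]
        rep.is_representative = True
        rep.cluster_id = cid
        reps.append(rep)
    return reps


# ---------------------------------------------------------------------------
# final predictors and validation
# ---------------------------------------------------------------------------

@dataclass
class Predictor:
    """Serializable final predictor: linear SVM weights plus sigmoid slope.

    ``impute`` holds the per-site imputation value (mean of the training
    class means) used both to complete training data and to fill missing or
    absent validation values.
    """

    site_ids: list[str]
    protein_ids: list[str]
    w: np.ndarray
    b: float
    A: float
    impute: np.ndarray

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b

    def proba_resistant(self, X: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit(-self.A * self.decision(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.proba_resistant(X) > 0.5, RESISTANT, SENSITIVE)

    def to_dict(self) -> dict:
        return {
            "site_ids": list(self.site_ids),
            "protein_ids": list(self.protein_ids),
            "w": [float(v) for v in self.w],
            "b": float(self.b),
            "A": float(self.A),
            "impute": [float(v) for v in self.impute],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Predictor":
        return cls(
            site_ids=list(d["site_ids"]),
            protein_ids=list(d["protein_ids"]),
            w=np.asarray(d["w"], dtype=float),
            b=float(d["b"]),
            A=float(d["A"]),
            impute=np.asarray(d["impute"], dtype=float),
        )


def train_final_predictor(signature_sites, train: PhosphoMatrix,
                          labels: SampleLabels, *, svm_c: float = 1.0) -> Predictor:
    """Linear SVM (C = 1) on the full training set restricted to the signature.

    Training missingness is imputed by the mean of the training class means;
    the posterior sigmoid (offset 0) is fitted on the training decision
    values, so a sample on the hyperplane gets p = 0.5.
    """
    sites = list(signature_sites)
    if not sites:
        raise ValueError("signature is empty")
    index = train.site_index
    rows = [index[s.site_id] for s in sites]
    X = train.values[rows].T.copy()
    y = labels.aligned(train.samples)
    imp = impute_by_class_means(X, y)
    X = np.where(np.isnan(X), imp[None, :], X)
    svm = SVC(kernel="linear", C=svm_c)
    svm.fit(X, y)
    w = svm.coef_[0].copy()
    b = float(svm.intercept_[0])
    sigmoid = fit_sigmoid(X @ w + b, y)
    return Predictor(
        site_ids=[s.site_id for s in sites],
        protein_ids=[s.protein_id for s in sites],
        w=w,
        b=b,
        A=sigmoid.A,
        impute=imp,
    )


def impute_validation(validation: PhosphoMatrix, train: PhosphoMatrix,
                      labels: SampleLabels, signature_sites) -> np.ndarray:
    """Validation design matrix for a signature, missing values imputed.

    Each missing value for site s becomes (mean of training sensitive values
    + mean of training resistant values) / 2. Signature sites entirely absent
    from the validation matrix are treated as all-missing (with a warning).
    Returns an array of shape (n_validation_samples, len(signature)).
    """
    sites = list(signature_sites)
    t_index = train.site_index
    rows = [t_index[s.site_id] for s in sites]
    y = labels.aligned(train.samples)
    imp = impute_by_class_means(train.values[rows].T, y)

    v_index = validation.site_index
    n_val = len(validation.samples)
    X = np.empty((n_val, len(sites)))
    for j, site in enumerate(sites):
        if site.site_id in v_index:
            col = validation.values[v_index[site.site_id]]
        else:
            logger.warning("signature site %s absent from validation matrix; "
                           "treated as all-missing", site.site_id)
            col = np.full(n_val, np.nan)
        X[:, j] = np.where(np.isnan(col), imp[j], col)
    return X


def predict_and_score(predictor: Predictor, X_val: np.ndarray,
                      validation_labels: SampleLabels,
                      sample_order: list[str] | None = None) -> PredictionResult:
    """Score validation predictions.

    A sensitive sample is correct iff p < 0.5, a resistant one iff p > 0.5
    (p = 0.5 exactly counts as incorrect). The average probability distance
    is (1/N) sum_i (0.5 - p_i) c_i.
    """
    samples = sample_order if sample_order is not None else validation_labels.samples
    c = validation_labels.aligned(samples)
    p = predictor.proba_resistant(X_val)
    predicted = predictor.predict(X_val)
    correct = ((c == SENSITIVE) & (p < 0.5)) | ((c == RESISTANT) & (p > 0.5))
    return PredictionResult(
        samples=list(samples),
        p_resistant=p,
        predicted=predicted,
        true=c,
        accuracy=float(correct.mean()),
        avg_prob_distance=float(np.mean((0.5 - p) * c)),
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class ParetoResult:
    config: object                      # RunConfig
    candidates: object                  # CandidateSet
    network: PPINetwork
    ga: nsga2.GARunResult
    front: list[FrontSolution]          # all unique first-front solutions
    accepted: list[FrontSolution]       # after the separation cutoff
    cluster_labels: np.ndarray
    representatives: list[FrontSolution]
    representative_names: list[str]
    predictors: list[Predictor]
    predictions: list[PredictionResult] | None
    join_failures: list[str]

    @property
    def history(self):
        return self.ga.history

    @property
    def generations(self) -> int:
        return self.ga.generations


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(train: PhosphoMatrix, labels: SampleLabels, ppi: PPIEdgeList,
                 target: str, validation: PhosphoMatrix | None = None,
                 validation_labels: SampleLabels | None = None,
                 config=None) -> ParetoResult:
    """Run prefilter -> NSGA-II -> front filter -> cluster -> representatives
    -> final predictors (-> validation, when a validation set is supplied)."""
    from .config import RunConfig

    if config is None:
        config = RunConfig()
    if (validation is None) != (validation_labels is None):
        raise ValueError("validation matrix and labels must be supplied together")

    with _stage("prefilter"):
        candidates = build_candidate_set(
            train, labels,
            min_presence=config.min_presence,
            min_fold=config.min_fold,
            k=config.top_k,
            stats_panel=config.rank_stats,
        )
        logger.info("candidate set: %d sites", candidates.k)

    with _stage("network"):
        network = PPINetwork(
            ppi, target,
            confidence_threshold=config.confidence_threshold,
            penalty_form=config.penalty_form,
            fallback=config.fallback_distance,
        )
        join_failures = join_failure_report(train.subset(
            [train.site_index[s] for s in candidates.site_ids]), ppi)

    with _stage("optimize"):
        evaluator = ObjectiveEvaluator(candidates, train, labels, network,
                                       svm_c=config.svm_c)
        ga = nsga2.evolve(evaluator, candidates.k, config.ga_config())
        logger.info("GA terminated after %d generations (%s); front size %d",
                    ga.generations, ga.terminated_by, len(ga.front))

    def decode(ind: nsga2.Individual) -> FrontSolution:
        sel = np.flatnonzero(ind.bits)
        return FrontSolution(
            bits=ind.bits.copy(),
            objectives=tuple(ind.objectives),
            sites=[candidates.sites[i] for i in sel],
        )

    with _stage("filter_front"):
        front = [decode(ind) for ind in ga.front]
        accepted = filter_front(front, config.separation_cutoff)
        logger.info("front filtering: %d / %d solutions kept", len(accepted), len(front))

    with _stage("cluster"):
        n_clusters = config.n_clusters
        if len(accepted) < n_clusters:
            logger.warning("only %d accepted solution(s); reducing n_clusters from %d",
                           len(accepted), n_clusters)
            n_clusters = len(accepted)
        cluster_labels = cluster_solutions(accepted, n_clusters)
        representatives = select_representatives(accepted, cluster_labels)
        names = [f"Pareto{i + 1}" for i in range(len(representatives))]

    with _stage("train_predictors"):
        predictors = [
            train_final_predictor(rep.sites, train, labels, svm_c=config.svm_c)
            for rep in representatives
        ]

    predictions = None
    if validation is not None:
        with _stage("validate"):
            predictions = []
            for rep, predictor in zip(representatives, predictors):
                X_val = impute_validation(validation, train, labels, rep.sites)
                predictions.append(
                    predict_and_score(predictor, X_val, validation_labels,
                                      sample_order=validation.samples)
                )

    return ParetoResult(
        config=config,
        candidates=candidates,
        network=network,
        ga=ga,
        front=front,
        accepted=accepted,
        cluster_labels=cluster_labels,
        representatives=representatives,
        representative_names=names,
        predictors=predictors,
        predictions=predictions,
        join_failures=join_failures,
    )
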