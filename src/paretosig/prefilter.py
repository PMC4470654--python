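"""Candidate-set construction: presence filter, ranking, fold-change filter, top-k.

The optimizer searches over a fixed, ordered candidate list, built as

1. keep sites quantified in at least ``min_presence`` (default 2/3) of the
   samples of *each* class,
2. keep sites whose class-mean difference on the log10 scale is at least
   log10(``min_fold``) (default 4-fold),
3. rank the survivors by a MeanRank-style combination of two-sample
   statistics (mean of the per-statistic ranks; lower is better),
4. walk the ranking, keeping at most one site per protein, stopping at
   ``k`` (default 100) sites.

The resulting order defines the chromosome positions of the optimizer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phospho_io import RESISTANT, SENSITIVE, PhosphoMatrix, SampleLabels

logger = logging.getLogger(__name__)

DEFAULT_RANK_STATS = ("mean_diff", "welch_t", "rank_sum")


@dataclass(eq=False)
class CandidateSet:
    """Ordered candidate sites plus their filter/rank provenance table."""

    sites: list
    table: pd.DataFrame  # indexed by site_id: protein_id, rank, mean_rank, per-stat ranks

    @property
    def k(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def _class_masks(matrix: PhosphoMatrix, labels: SampleLabels):
    y = labels.aligned(matrix.samples)
    return y == SENSITIVE, y == RESISTANT


def presence_filter(matrix: PhosphoMatrix, labels: SampleLabels,
                    min_fraction: float = 2.0 / 3.0) -> np.ndarray:
    """Boolean mask of sites quantified in >= min_fraction of each class."""
    sens, res = _class_masks(matrix, labels)
    present = matrix.present
    frac_s = present[:, sens].sum(axis=1) / sens.sum()
    frac_r = present[:, res].sum(axis=1) / res.sum()
    return (frac_s >= min_fraction) & (frac_r >= min_fraction)


def class_mean_difference(matrix: PhosphoMatrix, labels: SampleLabels) -> np.ndarray:
    """Signed difference of per-class means (sensitive - resistant), pairwise-complete."""
    sens, res = _class_masks(matrix, labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m_s = np.nanmean(matrix.values[:, sens], axis=1)
        m_r = np.nanmean(matrix.values[:, res], axis=1)
    return m_s - m_r


def fold_change_filter(matrix: PhosphoMatrix, labels: SampleLabels,
                       min_fold: float = 4.0) -> np.ndarray:
    """Mask of sites with |class-mean difference| >= log10(min_fold).

    Values are log10 ratios, so an x-fold ratio difference is additive:
    log10(x).
    """
    diff = np.abs(class_mean_difference(matrix, labels))
    threshold = np.log10(min_fold)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(diff, nan=0.0) >= threshold


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _site_statistics(matrix: PhosphoMatrix, labels: SampleLabels,
                     stats_panel) -> pd.DataFrame:
    """Per-site discrimination statistics (larger = more discriminative)."""
    sens, res = _class_masks(matrix, labels)
    values = matrix.values
    out = pd.DataFrame(index=pd.Index(matrix.site_ids, name="site_id"))

    if "mean_diff" in stats_panel:
        out["mean_diff"] = np.abs(class_mean_difference(matrix, labels))

    if "welch_t" in stats_panel:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m_s = np.nanmean(values[:, sens], axis=1)
            m_r = np.nanmean(values[:, res], axis=1)
            v_s = np.nanvar(values[:, sens], axis=1, ddof=1)
            v_r = np.nanvar(values[:, res], axis=1, ddof=1)
        n_s = matrix.present[:, sens].sum(axis=1)
        n_r = matrix.present[:, res].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(v_s / n_s + v_r / n_r)
            t = np.abs(m_s - m_r) / se
        # zero pooled variance: infinitely significant if means differ, else null
        t = np.where(se == 0, np.where(np.abs(m_s - m_r) > 0, np.inf, 0.0), t)
        out["welch_t"] = t

    if "rank_sum" in stats_panel:
        dist = np.empty(len(matrix.sites))
        for i in range(len(matrix.sites)):
            xs = values[i, sens]
            xr = values[i, res]
            xs = xs[~np.isnan(xs)]
            xr = xr[~np.isnan(xr)]
            if len(xs) < 1 or len(xr) < 1:
                dist[i] = np.nan
                continue
            u = stats.mannwhitneyu(xs, xr, alternative="two-sided").statistic
            dist[i] = abs(u - len(xs) * len(xr) / 2.0)  # distance from null mean
        out["rank_sum"] = dist

    return out


def rank_sites(matrix: PhosphoMatrix, labels: SampleLabels,
               stats_panel=DEFAULT_RANK_STATS) -> pd.DataFrame:
    """MeanRank-style ranking: mean of per-statistic ranks, 1 = best.

    Each statistic ranks sites separately (larger statistic = better rank);
    the final score is the mean of the ranks. Final total order breaks mean-
    rank ties by site id. Sites with fewer than two observed values in a
    class are excluded (with a warning) since the dispersion statistics are
    undefined for them.
    """
    sens, res = _class_masks(matrix, labels)
    n_s = matrix.present[:, sens].sum(axis=1)
    n_r = matrix.present[:, res].sum(axis=1)
    eligible = (n_s >= 2) & (n_r >= 2)
    if not eligible.all():
        dropped = [matrix.site_ids[i] for i in np.flatnonzero(~eligible)]
        logger.warning("excluding %d site(s) with <2 observed values in a class: %s",
                       len(dropped), ", ".join(dropped[:10]))

    table = _site_statistics(matrix.subset(eligible), labels, stats_panel)
    stat_cols = list(table.columns)
    for col in stat_cols:
        # rank descending: larger statistic -> better (smaller) rank
        table[f"rank_{col}"] = stats.rankdata(-table[col].to_numpy(), method="average")
    rank_cols = [f"rank_{c}" for c in stat_cols]
    table["mean_rank"] = table[rank_cols].mean(axis=1)
    table = table.sort_values(["mean_rank", "site_id"], kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return table


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

def select_candidates(matrix: PhosphoMatrix, labels: SampleLabels, *,
                      k: int = 100,
                      stats_panel=DEFAULT_RANK_STATS) -> CandidateSet:
    """Top-k ranked sites with at most one site per protein.

    Assumes the presence and fold-change filters were already applied to
    ``matrix``; walks sites in rank order, keeping a site only if its protein
    has not been kept yet, stopping at ``k`` sites or exhaustion.
    """
    ranking = rank_sites(matrix, labels, stats_panel)
    index = matrix.site_index
    kept_proteins: set[str] = set()
    kept_sites = []
    kept_rows = []
    for site_id in ranking.index:
        site = matrix.sites[index[site_id]]
        if site.protein_id in kept_proteins:
            continue
        kept_proteins.add(site.protein_id)
        kept_sites.append(site)
        kept_rows.append(site_id)
        if len(kept_sites) >= k:
            break
    # a deliberate k=1 request is honored; otherwise the optimizer needs a
    # non-trivial search space
    if len(kept_sites) < min(2, k):
        raise ValueError(
            f"only {len(kept_sites)} candidate site(s) survive filtering; "
            "the optimizer needs at least 2"
        )
    if len(kept_sites) < 2:
        logger.warning("candidate set has a single site (k=%d); "
                       "the optimizer needs at least 2", k)
    table = ranking.loc[kept_rows].copy()
    table.insert(0, "protein_id", [s.protein_id for s in kept_sites])
    return CandidateSet(sites=kept_sites, table=table)


def build_candidate_set(matrix: PhosphoMatrix, labels: SampleLabels, *,
                        min_presence: float = 2.0 / 3.0,
                        min_fold: float = 4.0,
                        k: int = 100,
                        stats_panel=DEFAULT_RANK_STATS) -> CandidateSet:
    """Full prefilter pipeline: presence -> fold-change -> rank -> dedup/top-k."""
    mask = presence_filter(matrix, labels, min_presence)
    logger.info("presence filter: %d / %d sites retained", mask.sum(), len(matrix.sites))
    filtered = matrix.subset(mask)
    fold_mask = fold_change_filter(filtered, labels, min_fold)
    logger.info("fold-change filter: %d / %d sites retained",
                fold_mask.sum(), len(filtered.sites))
    return select_candidates(filtered.subset(fold_mask), labels,
                             k=k, stats_panel=stats_panel)
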