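"""Readers, writers and core containers for phosphoproteomic signature discovery.

The external formats are deliberately plain:

* phospho matrix — delimited text, one row per phosphosite, a site-id column,
  a protein-id column, optionally a residue column, and one column per sample
  holding log10-transformed quantitative ratios. Empty cells and the sentinels
  ``NA`` / ``NaN`` (case-insensitive) mean "not quantified".
* labels — two columns: sample id, class (``sensitive``/``resistant`` or ``1``/``-1``).
* PPI edge list — three columns: protein A, protein B, interaction confidence;
  the STRING ``protein.links`` dialect (integer scores 0–999) is supported via
  ``score_scale="string_0_999"``.

No identifier mapping is performed: protein ids in the matrix and the edge
list must already share a namespace (see :func:`join_failure_report`).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: class coding used throughout: sensitive = +1, resistant = -1
SENSITIVE = 1
RESISTANT = -1

#: cell contents treated as missing (compared case-insensitively, stripped)
MISSING_SENTINELS = frozenset({"", "na", "nan"})

_LABEL_ALIASES = {
    "sensitive": SENSITIVE,
    "1": SENSITIVE,
    "+1": SENSITIVE,
    "resistant": RESISTANT,
    "-1": RESISTANT,
    "−1": RESISTANT,  # unicode minus
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhosphoSite:
    """A quantified phosphorylation site.

    ``site_id`` must be unique within a matrix; ``protein_id`` is the
    network-joinable identifier (gene name or accession — whatever namespace
    the PPI edge list uses); ``residue`` is free text such as ``"S1448"``.
    """

    site_id: str
    protein_id: str
    residue: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError(f"site {self.site_id!r} has an empty protein id")


@dataclass(eq=False)
class PhosphoMatrix:
    """Sites x samples table of log10 ratios; missing entries are NaN."""

    sites: list[PhosphoSite]
    samples: list[str]
    values: np.ndarray  # shape (n_sites, n_samples), float, NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"value block shape {self.values.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate site id(s): {', '.join(dup)}")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if np.isinf(self.values).any():
            raise ValueError("matrix contains non-finite (inf) values")

    @property
    def present(self) -> np.ndarray:
        """Boolean mask, True where a value was quantified."""
        return ~np.isnan(self.values)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def protein_ids(self) -> list[str]:
        return [s.protein_id for s in self.sites]

    @property
    def site_index(self) -> dict[str, int]:
        return {s.site_id: i for i, s in enumerate(self.sites)}

    def subset(self, rows) -> "PhosphoMatrix":
        """New matrix restricted to the given site rows (mask or indices)."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return PhosphoMatrix(
            sites=[self.sites[i] for i in rows],
            samples=list(self.samples),
            values=self.values[rows].copy(),
        )

    def equals(self, other: "PhosphoMatrix") -> bool:
        return (
            self.sites == other.sites
            and self.samples == other.samples
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass(eq=False)
class SampleLabels:
    """Per-sample binary response: sensitive = +1, resistant = -1."""

    samples: list[str]
    y: np.ndarray  # +1 / -1, aligned with `samples`

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.samples) != len(self.y):
            raise ValueError("label vector length does not match sample list")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in labels")
        bad = set(np.unique(self.y)) - {SENSITIVE, RESISTANT}
        if bad:
            raise ValueError(f"labels must be +1/-1, got {sorted(bad)}")
        if SENSITIVE not in self.y or RESISTANT not in self.y:
            raise ValueError("both classes (sensitive and resistant) must be present")

    def aligned(self, sample_order: list[str]) -> np.ndarray:
        """Label vector reordered to ``sample_order``; every sample must be labeled."""
        lut = dict(zip(self.samples, self.y))
        missing = [s for s in sample_order if s not in lut]
        if missing:
            raise ValueError(f"samples without labels: {', '.join(missing)}")
        return np.array([lut[s] for s in sample_order], dtype=int)

    def equals(self, other: "SampleLabels") -> bool:
        return self.samples == other.samples and np.array_equal(self.y, other.y)


@dataclass(eq=False)
class PPIEdgeList:
    """Undirected protein-protein interaction edges with confidences in [0, 1]."""

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        for a, b, s in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"confidence {s} for ({a},{b}) outside [0,1]")

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for a, b, _ in self.edges:
            out.add(a)
            out.add(b)
        return out

    def equals(self, other: "PPIEdgeList") -> bool:
        def norm(edges):
            return sorted((min(a, b), max(a, b), s) for a, b, s in edges)

        return norm(self.edges) == norm(other.edges)


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _infer_sep(path, sep):
    if sep is not None:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


def _is_missing(cell: str) -> bool:
    return cell.strip().lower() in MISSING_SENTINELS


def _parse_value_columns(df: pd.DataFrame, cols: list[str], site_ids: list[str]) -> np.ndarray:
    """Parse string cells to floats; sentinels become NaN, anything else must be numeric."""
    values = np.full((len(df), len(cols)), np.nan)
    for j, col in enumerate(cols):
        raw = df[col].astype(str).str.strip()
        sentinel = raw.str.lower().isin(MISSING_SENTINELS).to_numpy()
        present_idx = np.flatnonzero(~sentinel)
        cells = raw.to_numpy()[present_idx]
        try:
            # numpy's parser is correctly rounded, so written values
            # round-trip bit-exactly
            parsed = cells.astype(float)
        except ValueError:
            for i, cell in zip(present_idx, cells):
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric value {cell!r} in column {col!r}, "
                        f"row for site {site_ids[int(i)]!r}"
                    ) from None
            raise
        bad = np.isinf(parsed) | np.isnan(parsed)
        if bad.any():
            i = int(present_idx[np.flatnonzero(bad)[0]])
            raise ValueError(
                f"non-finite value {raw.iloc[i]!r} in column {col!r}, "
                f"row for site {site_ids[i]!r}"
            )
        values[present_idx, j] = parsed
    return values


# ---------------------------------------------------------------------------
# phospho matrix I/O
# ---------------------------------------------------------------------------

def read_phospho_matrix(
    path,
    *,
    site_col: str = "site_id",
    protein_col: str = "protein_id",
    residue_col: str | None = "residue",
    sample_cols: list[str] | None = None,
    sep: str | None = None,
) -> PhosphoMatrix:
    """Read a sites-as-rows delimited matrix.

    ``sample_cols`` defaults to every column that is not the site, protein or
    residue column. Raises on duplicate site ids and on any cell that is
    neither numeric nor a missing-value sentinel.
    """
    sep = _infer_sep(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (site_col, protein_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if residue_col is not None and residue_col not in df.columns:
        residue_col = None

    site_ids = [s.strip() for s in df[site_col]]
    dup = sorted({s for s in site_ids if site_ids.count(s) > 1})
    if dup:
        raise ValueError(f"duplicate site id(s) in {path}: {', '.join(dup)}")

    reserved = {site_col, protein_col} | ({residue_col} if residue_col else set())
    if sample_cols is None:
        sample_cols = [c for c in df.columns if c not in reserved]
    values = _parse_value_columns(df, sample_cols, site_ids)

    residues = df[residue_col].astype(str).str.strip() if residue_col else [""] * len(df)
    sites = [
        PhosphoSite(site_id=sid, protein_id=prot.strip(), residue=res)
        for sid, prot, res in zip(site_ids, df[protein_col], residues)
    ]
    return PhosphoMatrix(sites=sites, samples=list(sample_cols), values=values)


def write_phospho_matrix(matrix: PhosphoMatrix, path, *, sep: str | None = None,
                         missing: str = "NA") -> None:
    sep = _infer_sep(path, sep)
    df = pd.DataFrame(
        {
            "site_id": matrix.site_ids,
            "protein_id": matrix.protein_ids,
            "residue": [s.residue for s in matrix.sites],
        }
    )
    block = pd.DataFrame(matrix.values, columns=matrix.samples)
    df = pd.concat([df, block], axis=1)
    df.to_csv(path, sep=sep, index=False, na_rep=missing)


# ---------------------------------------------------------------------------
# labels I/O
# ---------------------------------------------------------------------------

def _parse_label(cell: str) -> int:
    key = cell.strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(
            f"unrecognized class label {cell!r} "
            "(expected sensitive/resistant or 1/-1)"
        )
    return _LABEL_ALIASES[key]


def read_labels(path, *, sep: str | None = None) -> SampleLabels:
    """Read a two-column (sample id, class) file; a header row is auto-detected."""
    sep = _infer_sep(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, header=None)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns")
    try:
        _parse_label(df.iloc[0, 1])
    except ValueError:
        df = df.iloc[1:].reset_index(drop=True)  # first row was a header
    samples = [s.strip() for s in df.iloc[:, 0]]
    y = np.array([_parse_label(c) for c in df.iloc[:, 1]], dtype=int)
    return SampleLabels(samples=samples, y=y)


def write_labels(labels: SampleLabels, path, *, sep: str | None = None) -> None:
    sep = _infer_sep(path, sep)
    names = {SENSITIVE: "sensitive", RESISTANT: "resistant"}
    df = pd.DataFrame({"sample_id": labels.samples,
                       "label": [names[int(v)] for v in labels.y]})
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# PPI edge list I/O
# ---------------------------------------------------------------------------

def read_ppi_edges(path, *, score_scale: str = "unit", sep: str | None = None) -> PPIEdgeList:
    """Read a three-column edge list.

    ``score_scale="unit"`` expects confidences in [0, 1];
    ``score_scale="string_0_999"`` expects STRING-style integer scores in
    [0, 999], which are divided by 1000. Self-loops are dropped; duplicate
    undirected edges collapse to the maximum confidence.
    """
    if score_scale not in ("unit", "string_0_999"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    sep = _infer_sep(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, header=None)
    if df.shape[1] < 3:
        raise ValueError(f"edge list {path} needs three columns")
    try:
        float(df.iloc[0, 2])
    except ValueError:
        df = df.iloc[1:].reset_index(drop=True)

    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for a, b, raw in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
        a, b = a.strip(), b.strip()
        try:
            score = float(raw)
        except ValueError as exc:
            raise ValueError(f"non-numeric confidence {raw!r} for edge ({a},{b})") from exc
        if score_scale == "string_0_999":
            if not (0 <= score <= 999):
                raise ValueError(f"score {raw} for ({a},{b}) outside STRING 0-999 scale")
            conf = score / 1000.0
        else:
            if not (0.0 <= score <= 1.0):
                raise ValueError(f"confidence {raw} for ({a},{b}) outside [0,1]")
            conf = score
        if a == b:
            logger.debug("dropping self-loop on %s", a)
            continue
        key = (a, b) if a <= b else (b, a)
        if key not in best:
            order.append(key)
            best[key] = conf
        else:
            best[key] = max(best[key], conf)
    return PPIEdgeList(edges=[(a, b, best[(a, b)]) for a, b in order])


def write_ppi_edges(edges: PPIEdgeList, path, *, score_scale: str = "unit",
                    sep: str | None = None) -> None:
    sep = _infer_sep(path, sep)
    rows = []
    for a, b, s in edges.edges:
        if score_scale == "string_0_999":
            rows.append((a, b, int(round(s * 1000))))
        else:
            rows.append((a, b, s))
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"]).to_csv(
        path, sep=sep, index=False
    )


def join_failure_report(matrix: PhosphoMatrix, edges: PPIEdgeList) -> list[str]:
    """Matrix proteins that do not appear in the edge list (no mapping is attempted)."""
    nodes = edges.proteins
    return sorted({p for p in matrix.protein_ids if p not in nodes})


# ---------------------------------------------------------------------------
# result report
# ---------------------------------------------------------------------------

def write_signature_report(result, outdir) -> Path:
    """Write the end-of-run report for a pipeline result.

    Emits, under ``outdir``:

    * ``solutions.tsv`` — one row per accepted front solution (id, members,
      three objective scores, cluster, representative flag),
    * ``representatives.tsv`` — one row per site of each representative
      signature (accession-style columns plus objective scores),
    * ``predictions_<name>.tsv`` — per-representative validation predictions,
      when a validation set was supplied,
    * ``generations.tsv`` — the optimizer's per-generation front statistics,
    * ``report.json`` — the machine-readable summary (config, objectives,
      serialized final predictors).

    ``result`` is a :class:`paretosig.postprocess.ParetoResult`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    accepted = list(result.accepted)
    if not accepted:
        logger.warning("empty Pareto front after filtering: report has zero solution rows")

    rep_keys = {sol.bits.tobytes(): name
                for name, sol in zip(result.representative_names, result.representatives)}
    rows = []
    for i, sol in enumerate(accepted):
        size, sep_, rel = sol.objectives
        rows.append(
            {
                "solution_id": f"S{i + 1:03d}",
                "cluster": int(sol.cluster_id) if sol.cluster_id is not None else "",
                "representative": rep_keys.get(sol.bits.tobytes(), ""),
                "size": int(size),
                "separation": sep_,
                "relevance": rel,
                "site_ids": ";".join(sol.site_ids),
            }
        )
    pd.DataFrame(
        rows,
        columns=["solution_id", "cluster", "representative", "size",
                 "separation", "relevance", "site_ids"],
    ).to_csv(outdir / "solutions.tsv", sep="\t", index=False)

    rep_rows = []
    for name, sol in zip(result.representative_names, result.representatives):
        size, sep_, rel = sol.objectives
        for site in sol.sites:
            rep_rows.append(
                {
                    "signature": name,
                    "site_id": site.site_id,
                    "protein_id": site.protein_id,
                    "residue": site.residue,
                    "size": int(size),
                    "separation": sep_,
                    "relevance": rel,
                }
            )
    pd.DataFrame(
        rep_rows,
        columns=["signature", "site_id", "protein_id", "residue",
                 "size", "separation", "relevance"],
    ).to_csv(outdir / "representatives.tsv", sep="\t", index=False)

    if result.predictions is not None:
        for name, pred in zip(result.representative_names, result.predictions):
            pred.to_frame().to_csv(outdir / f"predictions_{name}.tsv", sep="\t", index=False)

    if result.history is not None:
        pd.DataFrame([dataclasses.asdict(h) for h in result.history]).to_csv(
            outdir / "generations.tsv", sep="\t", index=False
        )

    payload = {
        "config": dataclasses.asdict(result.config) if result.config is not None else None,
        "n_front": len(result.front),
        "n_accepted": len(accepted),
        "generations": result.generations,
        "join_failures": result.join_failures,
        "representatives": [
            {
                "name": name,
                "site_ids": sol.site_ids,
                "protein_ids": [s.protein_id for s in sol.sites],
                "objectives": {
                    "size": int(sol.objectives[0]),
                    "separation": sol.objectives[1],
                    "relevance": sol.objectives[2],
                },
                "cluster": int(sol.cluster_id) if sol.cluster_id is not None else None,
                "predictor": predictor.to_dict(),
                "validation": (
                    {
                        "accuracy": pred.accuracy,
                        "avg_prob_distance": pred.avg_prob_distance,
                    }
                    if pred is not None
                    else None
                ),
            }
            for name, sol, predictor, pred in zip(
                result.representative_names,
                result.representatives,
                result.predictors,
                result.predictions or [None] * len(result.representatives),
            )
        ],
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return outdir
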