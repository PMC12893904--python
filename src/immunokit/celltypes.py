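"""QC filtering, normalisation, and hierarchical marker-based cell typing.

Quality control removes cells with fewer than two total reads or fewer than
two expressed genes. Normalisation follows the standard single-cell recipe
(per-cell totals rescaled to the cohort median, log1p, per-gene z-scaling),
delegated to scanpy. Typing is a hierarchical k-means scheme: level-1
clustering of a marker panel (defaults: 19 genes into 24 clusters), each
cluster mapped to the level-1 type whose signature score is maximal in the
cluster centroid; each level-1 type is then re-clustered with its own panel
and k for level-2 (and, for CD4/CD8 T cells, a level-3 refinement over a
15-marker panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse
from sklearn.cluster import KMeans

__all__ = [
    "LevelSpec",
    "TypingHierarchy",
    "TypedCells",
    "default_hierarchy",
    "qc_filter",
    "preprocess",
    "hierarchical_classify",
    "CellTypeModel",
    "TypingResults",
]

LEVEL1_TYPES = ("T cell", "B cell", "macrophage", "dendritic cell")


@dataclass
class LevelSpec:
    """One level of the typing hierarchy.

    ``signatures`` maps each candidate type at this level to its designated
    marker genes; a cluster is assigned the type whose signature (mean of the
    type's markers in the cluster centroid) is maximal, or "unassigned" when
    no signature is positive.
    """

    panel: Sequence[str]
    k: int
    signatures: Mapping[str, Sequence[str]]

    def validate(self, genes: pd.Index) -> None:
        missing = [g for g in self.panel if g not in genes]
        if missing:
            raise ValueError(f"panel genes absent from matrix: {missing}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for t, markers in self.signatures.items():
            bad = [g for g in markers if g not in self.panel]
            if bad:
                raise ValueError(f"signature markers for {t!r} outside panel: {bad}")


@dataclass
class TypingHierarchy:
    """Level-1 spec plus optional per-type level-2 and level-3 specs.

    ``level2`` maps a level-1 type to its LevelSpec; ``level3`` maps a level-2
    type (e.g. "CD4 T cell") to its refinement spec.
    """

    level1: LevelSpec
    level2: Mapping[str, LevelSpec] = field(default_factory=dict)
    level3: Mapping[str, LevelSpec] = field(default_factory=dict)


@dataclass
class TypedCells:
    assignments: pd.DataFrame  # index cell id; level1/level2/level3 columns
    dropped: pd.DataFrame  # index cell id; dropped_reason column

    @property
    def n_typed(self) -> int:
        return len(self.assignments)


def default_hierarchy(
    genes: Sequence[str],
    types: Sequence[str] = LEVEL1_TYPES,
    k_level1: int = 24,
    k_level2: int = 2,
) -> TypingHierarchy:
    """Generic hierarchy over a 19-gene level-1 panel split into per-type
    marker blocks, with a two-way level-2 split under each level-1 type and a
    15-marker level-3 refinement of T cells.

    Marker blocks are assigned in order: with the default 19-gene panel and
    four types, each type's signature is a contiguous block of the panel
    (the last block absorbs the remainder). Intended for the synthetic
    fixtures; real panels are supplied by the user.
    """
    genes = list(genes)
    panel1 = genes[:19] if len(genes) >= 19 else genes
    n_types = len(types)
    block = max(1, len(panel1) // n_types)
    signatures = {}
    for i, t in enumerate(types):
        lo = i * block
        hi = len(panel1) if i == n_types - 1 else (i + 1) * block
        signatures[t] = panel1[lo:hi]
    level1 = LevelSpec(panel=panel1, k=k_level1, signatures=signatures)
    level2 = {
        t: LevelSpec(
            panel=signatures[t],
            k=k_level2,
            signatures={
                f"{t} subset 0": signatures[t],
                f"{t} subset 1": signatures[t][:1],
            },
        )
        for t in types
    }
    # Level-3 refinement of T cells over a 15-marker panel.
    panel3 = genes[:15] if len(genes) >= 15 else genes
    level3 = {
        f"{types[0]} subset 1": LevelSpec(
            panel=panel3, k=k_level2, signatures={"T refined": panel3}
        )
    }
    return TypingHierarchy(level1=level1, level2=level2, level3=level3)


def _counts_matrix(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense() if sparse.issparse(X) else X, dtype=float)


def qc_filter(
    adata: ad.AnnData, min_reads: int = 2, min_genes: int = 2
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove low-quality cells from a raw count matrix.

    A cell is excluded when it has fewer than ``min_reads`` total reads OR
    expresses fewer than ``min_genes`` genes. Returns the filtered matrix and
    a per-cell report of removal reasons.
    """
    X = _counts_matrix(adata)
    totals = X.sum(axis=1)
    n_genes = (X > 0).sum(axis=1)
    low_reads = totals < min_reads
    low_genes = n_genes < min_genes
    drop = low_reads | low_genes
    reasons = np.where(
        low_reads & low_genes,
        "low_reads,low_genes",
        np.where(low_reads, "low_reads", np.where(low_genes, "low_genes", "")),
    )
    report = pd.DataFrame(
        {"dropped_reason": reasons[drop]}, index=adata.obs_names[drop]
    )
    kept = adata[~drop].copy()
    if kept.n_obs == 0:
        raise ValueError("no cells remain after QC filtering")
    return kept, report


def preprocess(adata: ad.AnnData) -> ad.AnnData:
    """Median-total normalisation, log1p, per-gene z-scaling (scanpy recipe).

    Raw counts are kept in ``layers["counts"]``; zero-total cells (which QC
    should already have removed) raise.
    """
    X = _counts_matrix(adata)
    if np.any(X.sum(axis=1) == 0):
        raise ValueError("zero-total cell encountered; run qc_filter first")
    out = adata.copy()
    out.layers["counts"] = X.copy()
    sc.pp.normalize_total(out)  # target_sum=None -> cohort median total
    out.layers["norm_total"] = np.asarray(out.X, dtype=float).copy()
    sc.pp.log1p(out)
    sc.pp.scale(out)
    return out


def _kmeans_assign(
    X: np.ndarray, spec: LevelSpec, genes: pd.Index, seed: int
) -> tuple[np.ndarray, dict[int, str]]:
    """Cluster the panel submatrix and map clusters to types by max signature."""
    cols = [genes.get_loc(g) for g in spec.panel]
    sub = X[:, cols]
    k = min(spec.k, len(sub))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(sub)
    centroids = km.cluster_centers_
    panel_idx = {g: i for i, g in enumerate(spec.panel)}
    mapping: dict[int, str] = {}
    for c in range(k):
        best_type, best_score = "unassigned", 0.0
        for t, markers in spec.signatures.items():
            score = float(np.mean([centroids[c, panel_idx[g]] for g in markers]))
            if score > best_score:
                best_type, best_score = t, score
        mapping[c] = best_type
    return km.labels_, mapping


def hierarchical_classify(
    adata: ad.AnnData, hierarchy: TypingHierarchy, seed: int = 0
) -> TypedCells:
    """Three-level marker-based typing of a preprocessed matrix.

    Cells with zero raw expression across the level-1 panel are removed with
    a recorded reason. Level-2 labels always nest under their level-1 parent
    (and level-3 under level-2) by construction.
    """
    hierarchy.level1.validate(adata.var_names)
    X = np.asarray(adata.X, dtype=float)
    counts = adata.layers.get("counts")
    if counts is None:
        counts = X
    counts = np.asarray(
        counts.todense() if sparse.issparse(counts) else counts, dtype=float
    )

    panel_cols = [adata.var_names.get_loc(g) for g in hierarchy.level1.panel]
    no_marker = counts[:, panel_cols].sum(axis=1) == 0
    dropped = pd.DataFrame(
        {"dropped_reason": "no_level1_marker_expression"},
        index=adata.obs_names[no_marker],
    )
    keep = ~no_marker
    Xk = X[keep]
    ids = adata.obs_names[keep]
    if len(ids) == 0:
        raise ValueError("no cells express any level-1 marker")

    labels1_raw, map1 = _kmeans_assign(Xk, hierarchy.level1, adata.var_names, seed)
    level1 = pd.Series([map1[c] for c in labels1_raw], index=ids)

    level2 = pd.Series(pd.NA, index=ids, dtype=object)
    level3 = pd.Series(pd.NA, index=ids, dtype=object)
    for parent, spec in hierarchy.level2.items():
        spec.validate(adata.var_names)
        mask = (level1 == parent).to_numpy()
        if mask.sum() == 0:
            continue
        labs, mapping = _kmeans_assign(
            Xk[mask], spec, adata.var_names, seed + 1
        )
        level2.loc[mask] = [mapping[c] for c in labs]
    for parent, spec in hierarchy.level3.items():
        spec.validate(adata.var_names)
        mask = (level2 == parent).to_numpy()
        if mask.sum() == 0:
            continue
        labs, mapping = _kmeans_assign(
            Xk[mask], spec, adata.var_names, seed + 2
        )
        level3.loc[mask] = [mapping[c] for c in labs]

    assignments = pd.DataFrame(
        {"level1": level1, "level2": level2, "level3": level3}, index=ids
    )
    return TypedCells(assignments=assignments, dropped=dropped)


class CellTypeModel:
    """QC + normalisation + hierarchical typing as one fit.

    Takes raw counts (AnnData); ``fit`` runs qc_filter, preprocess, and
    hierarchical_classify, and returns a TypingResults carrying the labels
    and the per-cell QC/dropout bookkeeping (conserving the input cells).
    """

    def __init__(self, adata: ad.AnnData, hierarchy: TypingHierarchy):
        self.adata = adata
        self.hierarchy = hierarchy

    def fit(self, seed: int = 0) -> "TypingResults":
        filtered, qc_report = qc_filter(self.adata)
        prepped = preprocess(filtered)
        typed = hierarchical_classify(prepped, self.hierarchy, seed=seed)
        return TypingResults(self, qc_report, typed)


class TypingResults:
    def __init__(self, model: CellTypeModel, qc_report: pd.DataFrame, typed: TypedCells):
        self.model = model
        self.qc_report = qc_report
        self.typed = typed

    @property
    def assignments(self) -> pd.DataFrame:
        return self.typed.assignments

    def accounting(self) -> pd.DataFrame:
        """One row per input cell: qc_pass, dropped_reason, labels."""
        idx = self.model.adata.obs_names
        out = pd.DataFrame(index=idx)
        out["qc_pass"] = ~idx.isin(self.qc_report.index)
        reasons = pd.concat([self.qc_report, self.typed.dropped])["dropped_reason"]
        out["dropped_reason"] = reasons.reindex(idx).fillna("")
        for col in ("level1", "level2", "level3"):
            out[col] = self.typed.assignments[col].reindex(idx)
        return out

    def summary(self) -> str:
        acc = self.accounting()
        counts = acc["level1"].value_counts(dropna=True)
        lines = [
            f"Cell typing: {len(acc)} input cells, "
            f"{int((~acc['qc_pass']).sum())} failed QC, "
            f"{len(self.typed.dropped)} lacked level-1 markers, "
            f"{len(self.typed.assignments)} typed",
            "level-1 composition: "
            + ", ".join(f"{t}: {n}" for t, n in counts.items()),
        ]
        return "\n".join(lines)
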