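"""Clonotype calling, Shannon diversity, CLR tag normalisation, tetramer gating.

Clones are defined by the CDR3 amino-acid junction: cells sharing the same
per-chain junction set (TRA|TRB when both chains are annotated, the single
chain otherwise) share a clone. Diversity is Shannon entropy of clone
frequencies (natural log by default), optionally averaged over bootstrap
downsamples to a common depth so groups of unequal size are comparable.
Antibody-derived tag (ADT) counts are normalised per tag with a centred
log-ratio (log1p minus its mean across cells); tetramer-positive cells are
gated at CLR strictly greater than 1.7.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GateConfig",
    "DiversityResult",
    "call_clones",
    "shannon_diversity",
    "clr_normalize",
    "tetramer_gate",
    "downsample_equal",
    "RepertoireModel",
    "RepertoireResults",
]


@dataclass
class GateConfig:
    threshold: float = 1.7
    tag: str = "tetramer"

    def validate(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("gate threshold must be finite")


@dataclass
class DiversityResult:
    group: str
    H: float
    n_cells: int
    n_clones: int
    downsample_n: int | None = None
    n_boot: int | None = None
    seed: int | None = None


def call_clones(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign clone ids from CDR3 amino-acid junctions.

    ``table`` is long-form (cell_id, chain, junction_aa, run_id, ...). The
    clone key concatenates per-chain junctions (sorted by chain name), so
    paired-chain cells match only paired-chain cells with both junctions
    identical, while orphan single chains remain usable. Cells whose
    junctions are all empty are excluded with a reason.

    Returns (per-cell assignment table with clone_id and exclusion reason,
    per-run clone table with sizes and proportions summing to 1).
    """
    if table.empty:
        raise ValueError("empty clonotype table")
    t = table.copy()
    t["junction_aa"] = t["junction_aa"].fillna("").astype(str)
    t = t[t["junction_aa"] != ""]

    all_cells = table["cell_id"].unique()
    keys = (
        t.sort_values(["cell_id", "chain"])
        .groupby("cell_id")
        .apply(
            lambda g: ";".join(f"{c}:{j}" for c, j in zip(g["chain"], g["junction_aa"])),
            include_groups=False,
        )
    )
    run_of = table.drop_duplicates("cell_id").set_index("cell_id")["run_id"]

    clone_ids = {k: f"clone{i}" for i, k in enumerate(pd.unique(keys.values))}
    assign = pd.DataFrame(index=pd.Index(all_cells, name="cell_id"))
    assign["clone_key"] = keys.reindex(all_cells)
    assign["clone_id"] = assign["clone_key"].map(clone_ids)
    assign["excluded_reason"] = np.where(
        assign["clone_key"].isna(), "empty_junction", ""
    )
    assign["run_id"] = run_of.reindex(all_cells)

    retained = assign[assign["excluded_reason"] == ""]
    clones = (
        retained.groupby(["run_id", "clone_id"], observed=True)
        .size()
        .rename("size")
        .reset_index()
    )
    clones["proportion"] = clones["size"] / clones.groupby("run_id")["size"].transform(
        "sum"
    )
    return assign, clones


def shannon_diversity(
    clone_sizes: Sequence[int] | np.ndarray,
    downsample_n: int | None = None,
    n_boot: int = 100,
    seed: int = 0,
    group: str = "all",
    base: float = np.e,
) -> DiversityResult:
    """Shannon diversity H = -sum p_i log p_i of clone frequencies.

    With ``downsample_n`` set, cells are bootstrap-downsampled without
    replacement to that depth ``n_boot`` times and H is the mean over draws,
    making repertoires of different sizes comparable at equal depth.
    """
    sizes = np.asarray(clone_sizes, dtype=np.int64)
    sizes = sizes[sizes > 0]
    if sizes.size == 0:
        raise ValueError("need at least one clone")
    n_cells = int(sizes.sum())

    def entropy(s: np.ndarray) -> float:
        p = s[s > 0] / s.sum()
        return float(-(p * np.log(p)).sum() / np.log(base))

    if downsample_n is None:
        return DiversityResult(
            group=group, H=entropy(sizes), n_cells=n_cells, n_clones=int(sizes.size)
        )
    if downsample_n > n_cells:
        raise ValueError("downsample_n exceeds the number of cells")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(sizes.size), sizes)
    hs = np.empty(n_boot)
    for b in range(n_boot):
        take = rng.choice(labels, size=downsample_n, replace=False)
        hs[b] = entropy(np.bincount(take, minlength=sizes.size))
    return DiversityResult(
        group=group,
        H=float(hs.mean()),
        n_cells=n_cells,
        n_clones=int(sizes.size),
        downsample_n=downsample_n,
        n_boot=n_boot,
        seed=seed,
    )


def clr_normalize(adt: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio per tag: log1p(count) minus its mean over cells.

    Each tag's CLR column has mean 0 by construction. Negative counts raise.
    """
    X = adt.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("ADT counts must be non-negative")
    logged = np.log1p(X)
    clr = logged - logged.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=adt.index, columns=adt.columns)


def tetramer_gate(clr: pd.DataFrame, config: GateConfig | None = None) -> pd.Series:
    """Tet+/Tet- flags: positive iff CLR strictly exceeds the threshold."""
    config = config or GateConfig()
    config.validate()
    if config.tag not in clr.columns:
        raise ValueError(f"tag {config.tag!r} absent from CLR matrix")
    return (clr[config.tag] > config.threshold).rename("tet_positive")


def downsample_equal(
    groups: Mapping[str, Sequence[str]], seed: int = 0
) -> dict[str, list[str]]:
    """Sample every group without replacement to the smallest group's size."""
    if not groups:
        raise ValueError("no groups given")
    sizes = {g: len(ids) for g, ids in groups.items()}
    if min(sizes.values()) == 0:
        empty = [g for g, n in sizes.items() if n == 0]
        raise ValueError(f"empty group(s): {empty}")
    n = min(sizes.values())
    rng = np.random.default_rng(seed)
    out = {}
    for g, ids in groups.items():
        ids = np.asarray(list(ids))
        out[g] = sorted(rng.choice(ids, size=n, replace=False).tolist())
    return out


class RepertoireModel:
    """Clonotype + tetramer repertoire analysis.

    Parameters
    ----------
    clonotypes : long AIRR-style table (cell_id, chain, junction_aa, run_id,
        treatment).
    adt : optional cells x tags count table (index = cell_id) for CLR
        normalisation and tetramer gating.
    """

    def __init__(
        self,
        clonotypes: pd.DataFrame,
        adt: pd.DataFrame | None = None,
        gate: GateConfig | None = None,
    ):
        self.clonotypes = clonotypes
        self.adt = adt
        self.gate = gate or GateConfig()

    def fit(
        self,
        downsample_n: int | None = None,
        n_boot: int = 100,
        seed: int = 0,
        group_by: str = "treatment",
    ) -> "RepertoireResults":
        assign, clones = call_clones(self.clonotypes)
        meta = self.clonotypes.drop_duplicates("cell_id").set_index("cell_id")
        groups = meta[group_by] if group_by in meta else pd.Series("all", index=meta.index)

        clr = flags = None
        if self.adt is not None:
            clr = clr_normalize(self.adt)
            flags = tetramer_gate(clr, self.gate)

        diversity = []
        retained = assign[assign["excluded_reason"] == ""]
        for g, sub in retained.groupby(groups.reindex(retained.index)):
            sizes = sub["clone_id"].value_counts().to_numpy()
            diversity.append(
                shannon_diversity(
                    sizes, downsample_n=downsample_n, n_boot=n_boot, seed=seed,
                    group=str(g),
                )
            )
        return RepertoireResults(self, assign, clones, diversity, clr, flags)


class RepertoireResults:
    def __init__(self, model, assignments, clones, diversity, clr, tet_flags):
        self.model = model
        self.assignments = assignments
        self.clones = clones
        self.diversity = diversity
        self.clr = clr
        self.tet_flags = tet_flags

    def diversity_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(d) for d in self.diversity])

    def summary(self) -> str:
        n_cells = int((self.assignments["excluded_reason"] == "").sum())
        lines = [
            f"Repertoire: {n_cells} cells with junctions, "
            f"{self.assignments['clone_id'].nunique()} clones",
        ]
        for d in self.diversity:
            lines.append(
                f"  group {d.group}: H = {d.H:.4f} nats over {d.n_clones} clones "
                f"({d.n_cells} cells)"
            )
        if self.tet_flags is not None:
            lines.append(
                f"  tetramer gate (> {self.model.gate.threshold} CLR): "
                f"{int(self.tet_flags.sum())} Tet+ / "
                f"{int((~self.tet_flags).sum())} Tet-"
            )
        return "\n".join(lines)
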