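"""Ligand-receptor interaction scoring with a permutation null and age trends.

An interaction (ligand gene in a sender cell type, receptor gene in a receiver
cell type) at one age is scored as the arithmetic mean of the two
subpopulation means on log-normalised expression - the convention of standard
cell-cell communication frameworks. Significance at one age comes from
permuting cell-type labels within that age group (so the null preserves age
composition), with the add-one permutation p-value p = (1 + #{perm >= obs}) /
(n_perm + 1). Trajectories of the mean score across ages are tested with
Spearman rank correlation (exact enumeration p for <= 9 ages, t-approximation
otherwise) and Bonferroni correction over the tested interactions, and
categorised as increasing/decreasing/flat.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse, stats

__all__ = [
    "LRPair",
    "LRScore",
    "LRTrend",
    "log_normalize",
    "lr_mean_score",
    "lr_permutation_test",
    "lr_age_trend",
    "exact_spearman",
    "LigandReceptorModel",
    "LRResults",
]


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str
    sender: str
    receiver: str

    def __post_init__(self):
        if not all((self.ligand, self.receptor, self.sender, self.receiver)):
            raise ValueError("all four LRPair identifiers must be non-empty")


@dataclass
class LRScore:
    pair: LRPair
    age: float
    mean_value: float
    p_perm: float | None = None


@dataclass
class LRTrend:
    pair: LRPair
    spearman_r: float
    p: float
    p_bonferroni: float
    category: str  # increasing | decreasing | flat
    n_ages: int


def log_normalize(adata: ad.AnnData) -> ad.AnnData:
    """Median-total normalisation + log1p (counts in, log-normal values out)."""
    out = adata.copy()
    sc.pp.normalize_total(out)
    sc.pp.log1p(out)
    return out


def _gene_vector(adata: ad.AnnData, gene: str) -> np.ndarray:
    if gene not in adata.var_names:
        raise ValueError(f"gene {gene!r} absent from matrix")
    col = adata[:, gene].X
    col = col.toarray() if sparse.issparse(col) else np.asarray(col)
    return np.asarray(col, dtype=float).ravel()


def lr_mean_score(adata: ad.AnnData, pair: LRPair) -> float:
    """Mean interaction score on log-normalised expression.

    0.5 * (mean ligand over sender cells + mean receptor over receiver cells).
    The matrix passed in should already be restricted to one age group.
    """
    types = adata.obs["cell_type"]
    send = (types == pair.sender).to_numpy()
    recv = (types == pair.receiver).to_numpy()
    if not send.any():
        raise ValueError(f"sender type {pair.sender!r} absent")
    if not recv.any():
        raise ValueError(f"receiver type {pair.receiver!r} absent")
    lig = _gene_vector(adata, pair.ligand)
    rec = _gene_vector(adata, pair.receptor)
    return float(0.5 * (lig[send].mean() + rec[recv].mean()))


def lr_permutation_test(
    adata: ad.AnnData, pair: LRPair, n_perm: int = 999, seed: int = 0
) -> LRScore:
    """Label-permutation test of the mean score within one age group.

    Cell-type labels are shuffled across the cells of this age group; the
    permutation p-value is (1 + #{permuted >= observed}) / (n_perm + 1), so it
    is never zero and has resolution 1/(n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    types = adata.obs["cell_type"].to_numpy()
    send = types == pair.sender
    recv = types == pair.receiver
    if send.sum() < 2 or recv.sum() < 2:
        raise ValueError("need >= 2 cells in both sender and receiver types")
    lig = _gene_vector(adata, pair.ligand)
    rec = _gene_vector(adata, pair.receptor)
    observed = 0.5 * (lig[send].mean() + rec[recv].mean())

    rng = np.random.default_rng(seed)
    n = len(types)
    n_send, n_recv = int(send.sum()), int(recv.sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ps = perm[:n_send]
        pr = perm[n_send : n_send + n_recv] if pair.sender != pair.receiver else ps
        score = 0.5 * (lig[ps].mean() + rec[pr].mean())
        if score >= observed - 1e-12:
            count += 1
    age = float(adata.obs["age"].iloc[0]) if "age" in adata.obs else float("nan")
    p = (1 + count) / (n_perm + 1)
    return LRScore(pair=pair, age=age, mean_value=float(observed), p_perm=float(p))


@lru_cache(maxsize=8)
def _spearman_null(n: int) -> np.ndarray:
    """Sorted |rho| values over all n! permutations (tie-free null)."""
    base = np.arange(1, n + 1)
    rhos = []
    denom = n * (n * n - 1)
    for perm in permutations(base):
        d2 = int(np.sum((np.asarray(perm) - base) ** 2))
        rhos.append(abs(1 - 6 * d2 / denom))
    return np.sort(np.asarray(rhos))


def exact_spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with midranks; exact two-sided enumeration p for n <= 9
    when both variables are tie-free, t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= 9 and not ties:
        null = _spearman_null(n)
        p = float(np.mean(null >= abs(rho) - 1e-12))
    else:
        p = float(res.pvalue)
    return rho, p


def lr_age_trend(scores: Sequence[LRScore], m: int) -> LRTrend:
    """Spearman age trend of a pair's mean scores with Bonferroni over m tests.

    Category is increasing/decreasing when the Bonferroni-corrected p is below
    0.05 with the matching sign, flat otherwise.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    ages = np.asarray([s.age for s in scores], dtype=float)
    vals = np.asarray([s.mean_value for s in scores], dtype=float)
    if len(ages) < 3:
        raise ValueError("need scores at >= 3 ages")
    if len(np.unique(vals)) == 1 or len(np.unique(ages)) == 1:
        raise ValueError("undefined correlation: constant mean_value or age")
    rho, p = exact_spearman(ages, vals)
    p_bonf = min(1.0, m * p)
    if p_bonf < 0.05 and rho > 0:
        category = "increasing"
    elif p_bonf < 0.05 and rho < 0:
        category = "decreasing"
    else:
        category = "flat"
    return LRTrend(
        pair=scores[0].pair,
        spearman_r=rho,
        p=p,
        p_bonferroni=p_bonf,
        category=category,
        n_ages=len(ages),
    )


class LigandReceptorModel:
    """Ligand-receptor scoring across age groups.

    Parameters
    ----------
    adata : AnnData of raw counts with obs columns cell_type and age; the
        model log-normalises internally (pass ``normalized=True`` to skip).
    pairs : the LRPair interactions to score.
    """

    def __init__(
        self,
        adata: ad.AnnData,
        pairs: Sequence[LRPair],
        normalized: bool = False,
    ):
        self.adata = adata if normalized else log_normalize(adata)
        self.pairs = list(pairs)

    def fit(self, n_perm: int | None = 999, seed: int = 0) -> "LRResults":
        """Score every pair at every age; permutation p-values when
        ``n_perm`` is set (None scores means only)."""
        scores: list[LRScore] = []
        ages = np.sort(self.adata.obs["age"].unique())
        for age in ages:
            sub = self.adata[self.adata.obs["age"] == age]
            for pair in self.pairs:
                if n_perm is None:
                    scores.append(
                        LRScore(pair=pair, age=float(age),
                                mean_value=lr_mean_score(sub, pair))
                    )
                else:
                    scores.append(lr_permutation_test(sub, pair, n_perm, seed))
        return LRResults(self, scores)


class LRResults:
    def __init__(self, model: LigandReceptorModel, scores: list[LRScore]):
        self.model = model
        self.scores = scores

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand": [s.pair.ligand for s in self.scores],
                "receptor": [s.pair.receptor for s in self.scores],
                "sender": [s.pair.sender for s in self.scores],
                "receiver": [s.pair.receiver for s in self.scores],
                "age": [s.age for s in self.scores],
                "mean_value": [s.mean_value for s in self.scores],
                "p_perm": [s.p_perm for s in self.scores],
            }
        )

    def age_trends(self, m: int | None = None) -> list[LRTrend]:
        pairs = {s.pair for s in self.scores}
        m = m if m is not None else len(pairs)
        out = []
        for pair in self.model.pairs:
            series = sorted(
                (s for s in self.scores if s.pair == pair), key=lambda s: s.age
            )
            out.append(lr_age_trend(series, m=m))
        return out

    def summary(self) -> str:
        trends = self.age_trends()
        lines = ["Ligand-receptor age trends (Spearman, Bonferroni-corrected)"]
        for t in trends:
            lines.append(
                f"  {t.pair.ligand}->{t.pair.receptor} "
                f"({t.pair.sender}->{t.pair.receiver}): R={t.spearman_r:+.3f}, "
                f"p_bonf={t.p_bonferroni:.4g}, {t.category}"
            )
        return "\n".join(lines)
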