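"""Synthetic data generators for every stage of the analysis pipeline.

Each generator is deterministic given its config and seed, and returns ground
truth separately from the observed table so downstream estimators can be
scored against it without the truth ever leaking into the observations.

The tissue generator uses a Neyman-Scott-style parenting scheme: "attracted"
cells are Gaussian offspring of uniformly chosen parent cells of another type,
giving a single parameter (the attraction probability alpha) with a monotone
effect on the spatial interaction Z statistic. With alpha = 0 every type is an
independent binomial (fixed-n) point process, i.e. complete spatial
randomness, which calibrates the null of the Z statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "TissueSimConfig",
    "CohortSimConfig",
    "GroupProgram",
    "gen_spatial_tissue",
    "gen_aging_series",
    "gen_expression",
    "default_programs",
    "gen_age_response_cohort",
    "gen_repertoire",
    "gen_adt",
    "gen_assay",
]

# Amino-acid alphabet for synthetic CDR3 junctions.
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class TissueSimConfig:
    """Configuration for a simulated 2-D tissue array.

    The default 8,000 x 8,000 um domain keeps the 150 um null neighbourhood
    small relative to the array, so boundary effects on the interaction
    statistic (which uses no edge correction) are negligible at the default
    cell numbers.
    """

    n_cells_per_type: Mapping[str, int]
    domain_width: float = 8000.0
    domain_height: float = 8000.0
    attraction: Mapping[tuple[str, str], float] = field(default_factory=dict)
    cluster_sd: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.domain_width <= 0 or self.domain_height <= 0:
            raise ValueError("tissue domain must have positive area")
        if not self.n_cells_per_type:
            raise ValueError("n_cells_per_type must not be empty")
        for t, n in self.n_cells_per_type.items():
            if n <= 0:
                raise ValueError(f"cell count for type {t!r} must be > 0")
        if self.cluster_sd <= 0:
            raise ValueError("cluster_sd must be > 0")
        offspring_seen: set[str] = set()
        for (a, b), alpha in self.attraction.items():
            for t in (a, b):
                if t not in self.n_cells_per_type:
                    raise ValueError(f"unknown type {t!r} in attraction map")
            if not 0.0 <= alpha <= 1.0:
                raise ValueError(f"attraction alpha for {(a, b)} must be in [0, 1]")
            if b in offspring_seen:
                raise ValueError(f"type {b!r} has more than one parent type")
            offspring_seen.add(b)


@dataclass
class CohortSimConfig:
    """Configuration for a quadratic age-response calibration cohort.

    ``coeffs`` are (a, b, c) of mean response = a + b*age + c*age^2 with age
    in weeks; responses (e.g. antigen-specific T cell frequencies, %) are
    clipped at zero.
    """

    ages: Sequence[float] = (8.0, 16.0, 24.0, 32.0, 40.0, 52.0, 64.0, 76.0)
    n_per_age: int = 4
    coeffs: tuple[float, float, float] = (15.0, -0.3, 0.0016)
    noise_sd: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.ages)) < 3:
            raise ValueError("need >= 3 distinct ages for an identifiable quadratic")
        if self.n_per_age <= 0:
            raise ValueError("n_per_age must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _uniform_points(rng: np.random.Generator, n: int, w: float, h: float) -> np.ndarray:
    return rng.uniform((0.0, 0.0), (w, h), size=(n, 2))


def gen_spatial_tissue(
    config: TissueSimConfig,
    *,
    age: float = 0.0,
    array_id: str = "array0",
) -> pd.DataFrame:
    """Simulate one spatial cell map.

    Parent types are placed uniformly on the domain. For each attracted pair
    (A, B) with probability alpha, a B cell is displaced from a uniformly
    chosen A cell by an isotropic Gaussian of sd ``cluster_sd``; out-of-domain
    draws are resampled (not clipped) to avoid boundary pile-up. Remaining B
    cells are uniform.

    Returns a tidy table with columns cell_id, x, y, cell_type, age, array_id.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w, h = config.domain_width, config.domain_height

    parent_of = {b: (a, alpha) for (a, b), alpha in config.attraction.items()}

    frames: dict[str, np.ndarray] = {}
    # Parents first (insertion order of n_cells_per_type, parents before
    # offspring regardless of declaration order).
    order = sorted(config.n_cells_per_type, key=lambda t: t in parent_of)
    for ctype in order:
        n = config.n_cells_per_type[ctype]
        if ctype not in parent_of:
            frames[ctype] = _uniform_points(rng, n, w, h)
            continue
        parent_type, alpha = parent_of[ctype]
        parents = frames[parent_type]
        attracted = rng.random(n) < alpha
        pts = _uniform_points(rng, n, w, h)
        idx = np.flatnonzero(attracted)
        for i in idx:
            centre = parents[rng.integers(len(parents))]
            while True:
                p = centre + rng.normal(0.0, config.cluster_sd, size=2)
                if 0.0 <= p[0] <= w and 0.0 <= p[1] <= h:
                    break
            pts[i] = p
        frames[ctype] = pts

    rows = []
    for ctype in config.n_cells_per_type:
        pts = frames[ctype]
        rows.append(
            pd.DataFrame(
                {
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                    "cell_type": ctype,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "cell_id", [f"{array_id}_c{i}" for i in range(len(out))])
    out["age"] = float(age)
    out["array_id"] = array_id
    return out


def _age_seed(seed: int, age: float) -> int:
    """Stable per-age child seed; adding an age never perturbs other ages."""
    ss = np.random.SeedSequence([int(seed), int(round(float(age) * 1000))])
    return int(ss.generate_state(1)[0] % (2**31))


def gen_aging_series(
    config: TissueSimConfig,
    ages: Sequence[float],
    attraction_schedule: Mapping[float, float],
) -> list[pd.DataFrame]:
    """One tissue array per age with the scheduled cross-type attraction.

    The schedule maps age -> alpha applied to every attracted pair in the
    config. Per-age seeds are derived deterministically from (seed, age).
    """
    config.validate()
    missing = [a for a in ages if a not in attraction_schedule]
    if missing:
        raise ValueError(f"attraction schedule missing ages: {missing}")
    maps = []
    for age in ages:
        alpha = attraction_schedule[age]
        cfg = TissueSimConfig(
            n_cells_per_type=dict(config.n_cells_per_type),
            domain_width=config.domain_width,
            domain_height=config.domain_height,
            attraction={pair: alpha for pair in config.attraction},
            cluster_sd=config.cluster_sd,
            seed=_age_seed(config.seed, age),
        )
        maps.append(gen_spatial_tissue(cfg, age=age, array_id=f"array_age{age:g}"))
    return maps


@dataclass
class GroupProgram:
    """Per-group expression program: mean multiplier per gene.

    ``multipliers`` has shape (n_groups, n_genes); entry (g, j) scales the
    baseline negative-binomial mean of gene j in group g.
    """

    names: Sequence[str]
    multipliers: np.ndarray

    def validate(self, n_genes: int) -> None:
        m = np.asarray(self.multipliers, dtype=float)
        if m.shape != (len(self.names), n_genes):
            raise ValueError("multiplier matrix shape must be (n_groups, n_genes)")
        if np.any(m < 0):
            raise ValueError("multipliers must be non-negative")


def default_programs(n_groups: int, n_genes: int, effect: float = 3.0) -> GroupProgram:
    """Block-marker layout: gene panel split evenly, each block elevated
    ``effect``-fold in its own group."""
    mult = np.ones((n_groups, n_genes))
    block = max(1, n_genes // n_groups)
    for g in range(n_groups):
        lo = g * block
        hi = n_genes if g == n_groups - 1 else (g + 1) * block
        mult[g, lo:hi] = effect
    names = [f"group{g}" for g in range(n_groups)]
    return GroupProgram(names=names, multipliers=mult)


def gen_expression(
    mode: str,
    layout: GroupProgram,
    nb_mean: float = 2.0,
    nb_dispersion: float = 2.0,
    n_genes: int | None = None,
    n_cells: int = 900,
    seed: int = 0,
    poisson: bool = False,
    domain: tuple[float, float] = (900.0, 300.0),
) -> tuple[ad.AnnData, pd.Series]:
    """Negative-binomial cell x gene counts with group-specific programs.

    mode "regions": cells get uniform 2-D coordinates and group labels from
    contiguous vertical bands of the domain (the smoothing fixture).
    mode "types": cells are assigned to groups uniformly at random with no
    coordinates (the typing fixture).

    Counts for cell i, gene j are NB with mean nb_mean * multiplier and
    dispersion ``nb_dispersion`` (variance mu + mu^2/dispersion); with
    ``poisson=True`` the Poisson limit is sampled instead.

    Returns (AnnData of observed counts, ground-truth group labels). Truth is
    never placed in ``adata.obs``.
    """
    if mode not in ("regions", "types"):
        raise ValueError(f"unknown mode {mode!r}")
    if nb_mean <= 0 or nb_dispersion <= 0:
        raise ValueError("nb_mean and nb_dispersion must be > 0")
    mult = np.asarray(layout.multipliers, dtype=float)
    if n_genes is None:
        n_genes = mult.shape[1]
    layout.validate(n_genes)
    n_groups = len(layout.names)
    rng = np.random.default_rng(seed)

    obs = pd.DataFrame(index=[f"cell{i}" for i in range(n_cells)])
    if mode == "regions":
        w, h = domain
        xy = rng.uniform((0.0, 0.0), (w, h), size=(n_cells, 2))
        group_idx = np.minimum((xy[:, 0] / w * n_groups).astype(int), n_groups - 1)
        obs["x"] = xy[:, 0]
        obs["y"] = xy[:, 1]
    else:
        group_idx = rng.integers(n_groups, size=n_cells)

    mu = nb_mean * mult[group_idx]  # (n_cells, n_genes)
    if poisson:
        X = rng.poisson(mu)
    else:
        # Gamma-Poisson mixture: shape = dispersion, scale = mu / dispersion.
        lam = rng.gamma(nb_dispersion, mu / nb_dispersion)
        X = rng.poisson(lam)

    adata = ad.AnnData(
        X=X.astype(np.float64),
        obs=obs,
        var=pd.DataFrame(index=[f"gene{j}" for j in range(n_genes)]),
    )
    truth = pd.Series(
        [layout.names[g] for g in group_idx], index=adata.obs_names, name="truth_group"
    )
    return adata, truth


def gen_age_response_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Cohort table (animal_id, age, response) on a quadratic mean curve.

    response = a + b*age + c*age^2 + N(0, noise_sd^2), clipped at 0 with the
    clip event flagged in the ``clipped`` column.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    a, b, c = config.coeffs
    rows = []
    k = 0
    for age in config.ages:
        mean = a + b * age + c * age * age
        for _ in range(config.n_per_age):
            resp = mean + rng.normal(0.0, config.noise_sd)
            clipped = resp < 0
            rows.append((f"animal{k}", float(age), max(resp, 0.0), bool(clipped)))
            k += 1
    return pd.DataFrame(rows, columns=["animal_id", "age", "response", "clipped"])


def _clone_weights(k: int, clone_distribution: str, params: Mapping) -> np.ndarray:
    if clone_distribution == "uniform":
        w = np.ones(k)
    elif clone_distribution == "geometric":
        q = float(params.get("q", 0.5))
        if not 0 < q < 1:
            raise ValueError("geometric q must be in (0, 1)")
        w = (1 - q) ** np.arange(k)
    elif clone_distribution == "powerlaw":
        s = float(params.get("exponent", 1.5))
        w = np.arange(1, k + 1, dtype=float) ** (-s)
    else:
        raise ValueError(f"unknown clone distribution {clone_distribution!r}")
    return w / w.sum()


def gen_repertoire(
    n_cells: int,
    clone_distribution: str = "uniform",
    params: Mapping | None = None,
    seed: int = 0,
    run_id: str = "run0",
    treatment: str = "none",
    paired_fraction: float = 0.8,
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic AIRR-style clonotype table.

    Each clone has a distinct TRB CDR3 amino-acid junction (and, for a
    ``paired_fraction`` of cells, a clone-matched TRA junction). Clone sizes
    follow the named distribution over ``n_clones`` clones.

    Returns (long table with cell_id/chain/junction_aa/run_id/treatment,
    ground-truth clone index per cell).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    params = dict(params or {})
    k = int(params.get("n_clones", 8))
    if clone_distribution == "uniform" and n_cells % k == 0 and "exact" not in params:
        # Equal sizes exactly realisable: deterministic assignment.
        assign = np.repeat(np.arange(k), n_cells // k)
    else:
        rng0 = np.random.default_rng(seed)
        assign = rng0.choice(k, size=n_cells, p=_clone_weights(k, clone_distribution, params))
    rng = np.random.default_rng(seed + 1)

    def junction(prefix: str, clone: int) -> str:
        r = np.random.default_rng((seed, hash(prefix) % (2**31), clone))
        core = "".join(r.choice(_AA, size=9))
        return f"CA{core}F" if prefix == "TRA" else f"CASS{core}F"

    trb = {c: junction("TRB", c) for c in range(k)}
    tra = {c: junction("TRA", c) for c in range(k)}
    rows = []
    for i, clone in enumerate(assign):
        cid = f"{run_id}_cell{i}"
        rows.append((cid, "TRB", trb[clone], run_id, treatment))
        if rng.random() < paired_fraction:
            rows.append((cid, "TRA", tra[clone], run_id, treatment))
    table = pd.DataFrame(
        rows, columns=["cell_id", "chain", "junction_aa", "run_id", "treatment"]
    )
    truth = pd.Series(
        assign, index=[f"{run_id}_cell{i}" for i in range(n_cells)], name="truth_clone"
    )
    return table, truth


def gen_adt(
    n_cells: int,
    pos_fraction: float = 0.3,
    neg_logmean: float = 0.7,
    pos_logmean: float = 5.5,
    log_sd: float = 0.4,
    seed: int = 0,
    tag: str = "tetramer",
) -> tuple[pd.DataFrame, pd.Series]:
    """Bimodal antibody-derived-tag counts (log-normal mixture, integerised).

    Emulates tetramer/dextramer staining: a ``pos_fraction`` of cells draw
    counts around exp(pos_logmean), the rest around exp(neg_logmean).
    Returns (counts table cells x 1 tag, ground-truth positivity flags).
    """
    if not 0.0 <= pos_fraction <= 1.0:
        raise ValueError("pos_fraction must be in [0, 1]")
    if pos_logmean <= neg_logmean:
        raise ValueError("pos_logmean must exceed neg_logmean")
    rng = np.random.default_rng(seed)
    is_pos = rng.random(n_cells) < pos_fraction
    logmean = np.where(is_pos, pos_logmean, neg_logmean)
    counts = np.rint(np.exp(rng.normal(logmean, log_sd))).astype(int)
    idx = [f"cell{i}" for i in range(n_cells)]
    table = pd.DataFrame({tag: counts}, index=idx)
    truth = pd.Series(is_pos, index=idx, name="truth_positive")
    return table, truth


def gen_assay(
    mode: str,
    params: Mapping | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Small assay fixtures.

    mode "pk": exponential-decay concentration time series with multiplicative
    log-normal noise; columns time_h, value. Values are never negative.
    mode "qpcr": paired technical-duplicate Ct values for a target and a
    reference amplicon with additive Gaussian noise; columns sample_id,
    target, replicate, ct.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if mode == "pk":
        times = np.asarray(params.get("times", [0, 3, 6, 12, 24, 48]), dtype=float)
        if times.size == 0:
            raise ValueError("pk time grid must not be empty")
        c0 = float(params.get("c0", 100.0))
        k = float(params.get("k", 0.1))
        noise = float(params.get("noise_cv", 0.0))
        values = c0 * np.exp(-k * times)
        if noise > 0:
            values = values * np.exp(rng.normal(0.0, noise, size=times.size))
        return pd.DataFrame({"time_h": times, "value": np.maximum(values, 0.0)})
    if mode == "qpcr":
        n = int(params.get("n_samples", 4))
        ct_ref = float(params.get("ct_ref", 25.0))
        delta_ct = float(params.get("delta_ct", 5.0))
        noise = float(params.get("noise_sd", 0.0))
        rows = []
        for i in range(n):
            for rep in (1, 2):
                rows.append((f"s{i}", "TREC", rep, ct_ref + delta_ct + rng.normal(0, noise)))
                rows.append((f"s{i}", "TCRA", rep, ct_ref + rng.normal(0, noise)))
        return pd.DataFrame(rows, columns=["sample_id", "target", "replicate", "ct"])
    raise ValueError(f"unknown assay mode {mode!r}")
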