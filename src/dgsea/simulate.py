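"""Synthetic two-cohort RNA-Seq count data with known embedded truth.

Counts are drawn from a negative-binomial model (variance = mu + alpha*mu^2,
alpha the gene-wise dispersion) via its gamma-Poisson construction:

    count_gj ~ Poisson(Gamma(1/alpha_g, scale=alpha_g * m_gj)),
    m_gj = s_j * mu_g * 2^(beta_g * x_j + gamma_g * TMS_j)

with library factor s_j (log-normal, mean-centred in log space so
size-factor estimation is identifiable), baseline mean mu_g (log-normal),
case indicator x_j, per-gene log2 fold change beta_g and severity slope
gamma_g.  The defaults emulate two whole-blood case-control cohorts
(112 carriers + 22 controls, and 74 + 27 for the second cohort) with a
motor-severity score (TMS) for carriers drawn as a rounded positive
half-normal, zero for controls.

Every embedded effect is recorded in a :class:`SyntheticTruth` so the
differential-expression, enrichment, concordance and module stages can all
be tested against known ground truth.  All draws go through a single
`numpy.random.Generator` in a fixed documented order, so identical
configuration + seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSetCollection, ModuleDefinition

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_gene_sets",
    "generate_cohort",
    "generate_module_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the count generator; defaults are the study conditions.

    Log-scale parameters are natural logs.  ``dispersion_shape`` /
    ``dispersion_rate`` are Gamma hyperparameters for the gene-wise NB
    dispersion alpha (defaults give mean 0.2, typical for bulk RNA-Seq);
    ``tms_sd`` is the half-normal sigma for carrier motor scores (17 gives
    a mean score of about 14, the first cohort's mean).
    """

    n_genes: int = 2000
    n_cases: int = 112
    n_controls: int = 22
    baseline_mean_log_mu: float = 4.0
    baseline_mean_log_sd: float = 1.2
    dispersion_shape: float = 2.0
    dispersion_rate: float = 10.0
    libsize_log_sd: float = 0.25
    effect_log2fc: float = 1.0
    frac_sets_up: float = 0.05
    frac_sets_down: float = 0.05
    severity_slope: float = 0.0
    tms_sd: float = 17.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cases, self.n_controls) < 1:
            raise ValueError("n_genes, n_cases, n_controls must all be >= 1")
        if min(
            self.baseline_mean_log_sd,
            self.dispersion_shape,
            self.dispersion_rate,
        ) <= 0:
            raise ValueError("sd/shape/rate parameters must be positive")
        if self.libsize_log_sd < 0 or self.tms_sd < 0:
            raise ValueError("libsize_log_sd and tms_sd must be nonnegative")
        for frac in (self.frac_sets_up, self.frac_sets_down):
            if not 0 <= frac <= 1:
                raise ValueError("set fractions must lie in [0, 1]")
        if self.frac_sets_up + self.frac_sets_down > 1:
            raise ValueError("frac_sets_up + frac_sets_down must be <= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: what was embedded where.

    ``set_direction`` labels every set up/down/null; ``gene_log2fc`` and
    ``gene_severity_slope`` give each gene's true effect (0 for null
    genes).  When a gene belongs to sets with conflicting directions the
    first-assigned set wins and the conflict is recorded in ``conflicts``
    as (gene, losing set, losing direction).
    """

    set_direction: dict[str, str]
    gene_log2fc: pd.Series
    gene_severity_slope: pd.Series
    conflicts: list[tuple[str, str, str]]
    config: SimulationConfig
    seed: int


def gene_ids(n_genes: int) -> list[str]:
    """Zero-padded synthetic identifiers ("G000001"): lexicographic order
    equals numeric order, so ranking tie-breaks are deterministic."""
    width = max(6, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def generate_gene_sets(
    universe,
    n_sets: int,
    size_min: int = 3,
    size_max: int = 500,
    overlap_frac: float = 0.0,
    seed: int = 0,
) -> GeneSetCollection:
    """Random gene sets over ``universe`` with controlled pairwise sharing.

    Each set's size is uniform on [size_min, size_max].  A fraction
    ``overlap_frac`` of each set's members is drawn from genes already used
    by earlier sets (when available); the rest from unused genes, so
    overlap_frac = 0 with a large enough universe yields pairwise-disjoint
    sets.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty universe")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not (1 <= size_min <= size_max <= len(universe)):
        raise ValueError("need 1 <= size_min <= size_max <= |universe|")
    if not 0 <= overlap_frac <= 1:
        raise ValueError("overlap_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    unused = list(universe)
    used: list[str] = []
    sets: dict[str, list[str]] = {}
    width = len(str(n_sets))
    for i in range(n_sets):
        size = int(rng.integers(size_min, size_max + 1))
        n_shared = min(int(round(overlap_frac * size)), len(used))
        members = []
        if n_shared:
            members.extend(rng.choice(used, size=n_shared, replace=False))
        n_new = size - len(members)
        if n_new > len(unused):  # universe exhausted: fall back to reuse
            extra = rng.choice(
                [g for g in used if g not in members],
                size=n_new - len(unused),
                replace=False,
            )
            members.extend(extra)
            n_new = len(unused)
        if n_new:
            picked = rng.choice(len(unused), size=n_new, replace=False)
            fresh = [unused[k] for k in sorted(picked)]
            members.extend(fresh)
            fresh_set = set(fresh)
            used.extend(fresh)
            unused = [g for g in unused if g not in fresh_set]
        sets[f"S{i + 1:0{width}d}"] = members
    return GeneSetCollection(sets, "simulated")


def _assign_truth(
    config: SimulationConfig,
    collection: GeneSetCollection,
    genes: list[str],
    rng: np.random.Generator,
) -> SyntheticTruth:
    names = list(collection)
    n_up = int(round(config.frac_sets_up * len(names)))
    n_down = int(round(config.frac_sets_down * len(names)))
    chosen = rng.choice(len(names), size=n_up + n_down, replace=False)
    direction = {name: "null" for name in names}
    for k in chosen[:n_up]:
        direction[names[k]] = "up"
    for k in chosen[n_up:]:
        direction[names[k]] = "down"
    log2fc = pd.Series(0.0, index=pd.Index(genes, name="gene"))
    slope = pd.Series(0.0, index=log2fc.index)
    owner: dict[str, str] = {}
    conflicts: list[tuple[str, str, str]] = []
    # first-assigned set wins; iterate up sets then down sets in chosen order
    for k in chosen:
        name = names[k]
        sign = 1.0 if direction[name] == "up" else -1.0
        for g in collection[name]:
            if g in owner:
                if direction[owner[g]] != direction[name]:
                    conflicts.append((g, name, direction[name]))
                continue
            owner[g] = name
            log2fc[g] = sign * config.effect_log2fc
            slope[g] = sign * config.severity_slope
    return SyntheticTruth(direction, log2fc, slope, conflicts, config, config.seed)


def generate_cohort(
    config: SimulationConfig,
    collection: GeneSetCollection,
    truth_assignment: SyntheticTruth | None = None,
    cohort: str = "cohortA",
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one cohort of NB counts with the collection's embedded effects.

    If ``truth_assignment`` is given its per-set directions and per-gene
    effects are reused (two cohorts sharing biology); baseline means,
    dispersions, library sizes and covariates are still drawn fresh from
    this config's seed.
    """
    genes = gene_ids(config.n_genes)
    missing = set().union(*(collection[n] for n in collection)) - set(genes)
    if missing:
        raise ValueError(f"collection genes outside simulated universe: {sorted(missing)[:5]}")
    rng = np.random.default_rng(config.seed)
    if truth_assignment is None:
        truth = _assign_truth(config, collection, genes, rng)
    else:
        if list(truth_assignment.gene_log2fc.index) != genes:
            raise ValueError("truth_assignment universe does not match config")
        truth = SyntheticTruth(
            truth_assignment.set_direction,
            truth_assignment.gene_log2fc.copy(),
            truth_assignment.gene_severity_slope.copy(),
            list(truth_assignment.conflicts),
            config,
            config.seed,
        )
        # keep the draw order identical whether or not truth is reused
        _assign_truth(config, collection, genes, rng)

    n = config.n_cases + config.n_controls
    mu = np.exp(rng.normal(config.baseline_mean_log_mu, config.baseline_mean_log_sd, config.n_genes))
    alpha = rng.gamma(config.dispersion_shape, 1.0 / config.dispersion_rate, config.n_genes)
    log_s = rng.normal(0.0, config.libsize_log_sd, n)
    s = np.exp(log_s - log_s.mean())
    age = np.clip(np.round(rng.normal(47.0, 10.0, n)), 18, 80).astype(int)
    gender = np.where(rng.random(n) < 0.5, "F", "M")
    case = np.concatenate([np.ones(config.n_cases), np.zeros(config.n_controls)])
    tms = np.where(
        case == 1, np.round(np.abs(rng.normal(0.0, config.tms_sd, n))), 0.0
    )
    beta = truth.gene_log2fc.to_numpy()
    gamma = truth.gene_severity_slope.to_numpy()
    log2_mean = (
        np.log2(mu)[:, None]
        + beta[:, None] * case[None, :]
        + gamma[:, None] * tms[None, :]
    )
    mean = s[None, :] * np.exp2(log2_mean)
    # gamma-Poisson draw; alpha -> 0 collapses to Poisson
    shape = 1.0 / np.maximum(alpha, 1e-12)
    lam = rng.gamma(shape[:, None], mean / shape[:, None])
    counts = rng.poisson(lam).astype(np.int64)

    samples = [f"{cohort}_{'HD' if c else 'CTRL'}_{i + 1:03d}" for i, c in enumerate(case)]
    group = np.where(
        case == 0, "control", np.where(tms <= 5, "premanifest", "manifest")
    )
    meta = pd.DataFrame(
        {
            "cohort": cohort,
            "group": group,
            "age": age,
            "gender": gender,
            "tms": np.where(case == 1, tms, np.nan),
        },
        index=pd.Index(samples, name="sample"),
    )
    cm = CountMatrix(pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples), meta)
    return cm, truth


def generate_module_fixture(
    n_genes: int,
    n_samples: int,
    latent_cor: float | None = None,
    seed: int = 0,
    loadings=None,
) -> tuple[pd.DataFrame, ModuleDefinition, pd.Series]:
    """Latent-factor expression fixture for eigengene / kME analysis.

    Gene i = loading_i * z + sqrt(1 - loading_i^2) * noise with a shared
    latent factor z, so each gene's expected correlation with z (its
    theoretical kME) equals its loading.  ``latent_cor`` sets a common
    loading for all genes; pass ``loadings`` for per-gene values.  Returns
    (expression genes x samples, module definition carrying the true
    loadings as reference kME, the latent factor as a Series).
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    if loadings is None:
        if latent_cor is None:
            raise ValueError("give latent_cor or loadings")
        loadings = np.full(n_genes, float(latent_cor))
    loadings = np.asarray(loadings, dtype=float)
    if loadings.shape != (n_genes,):
        raise ValueError("loadings must have length n_genes")
    if np.any((loadings < 0) | (loadings > 1)):
        raise ValueError("loadings must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n_samples)
    noise = rng.normal(size=(n_genes, n_samples))
    expr = loadings[:, None] * z[None, :] + np.sqrt(1.0 - loadings**2)[:, None] * noise
    genes = gene_ids(n_genes)
    samples = [f"S{j + 1:03d}" for j in range(n_samples)]
    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)
    module = ModuleDefinition(
        "M1", tuple(genes), kme=pd.Series(loadings, index=genes), annotation="latent-factor fixture"
    )
    return expr_df, module, pd.Series(z, index=samples, name="latent")


def truth_to_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Per-gene truth table for writing to TSV."""
    return pd.DataFrame(
        {
            "true_log2fc": truth.gene_log2fc,
            "true_severity_slope": truth.gene_severity_slope,
        }
    )
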