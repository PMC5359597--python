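"""Eigengene and module-membership (kME) analysis for co-expression modules.

A module's eigengene is the first principal component of its standardised
(per-gene mean 0, sd 1) expression submatrix — one value per sample,
summarising the whole module's profile.  A gene's module membership, kME,
is the Pearson correlation of its expression with the eigengene; highly
connected "hub" genes have high kME.  Module discovery itself (network
construction, soft thresholding, tree cutting) is out of scope — modules
arrive as definitions, mirroring the use of published module sets.

The kME-dysregulation test asks whether hub genes are more dysregulated:
it correlates kME with -log10 of the per-gene one-sided p-value in the
direction of interest and assesses the correlation with a seeded label
permutation test (the p-values are bounded and non-normal, so the
t-approximation is avoided).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GeneSetCollection, ModuleDefinition, validate_stats
from .enrichment import DirectionalGSEA, GSEAResults

__all__ = [
    "eigengene",
    "kme",
    "kme_dysregulation_correlation",
    "module_gsea",
]


def eigengene(expr: pd.DataFrame, module: ModuleDefinition) -> pd.Series:
    """First principal component of the module's standardised submatrix.

    Returned as a unit-norm per-sample Series, sign-oriented so the mean
    correlation with member genes is nonnegative.  Constant-expression
    genes are dropped with a warning; fewer than two usable genes or three
    samples is an error.
    """
    present = [g for g in module.genes if g in expr.index]
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    X = expr.loc[present].to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(
            f"module {module.module_id!r}: dropping {int((~keep).sum())} "
            "constant-expression gene(s)",
            stacklevel=2,
        )
    X = X[keep]
    if X.shape[0] < 2:
        raise ValueError(
            f"module {module.module_id!r}: fewer than 2 usable genes in expression"
        )
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    if u[:, 0].mean() < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns, name=f"ME_{module.module_id}")


def kme(expr: pd.DataFrame, eig: pd.Series, genes=None) -> pd.Series:
    """Pearson correlation of each gene's expression with the eigengene.

    Constant genes get NaN.  ``genes`` defaults to every gene in ``expr``.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    genes = list(expr.index) if genes is None else [g for g in genes if g in expr.index]
    X = expr.loc[genes, eig.index].to_numpy(dtype=float)
    e = eig.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    ec = e - e.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (ec**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xc @ ec) / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.Series(np.clip(r, -1.0, 1.0), index=genes, name="kME")


def kme_dysregulation_correlation(
    kme_values: pd.Series,
    p_directional: pd.Series,
    method: str = "spearman",
    transform: bool = True,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Correlation between module membership and dysregulation evidence.

    Pairs kME with -log10 one-sided p (``transform=True``) or raw p over
    the shared, non-missing genes and returns (rho, permutation p) with a
    one-sided p for positive correlation: rho > 0 means hub genes are more
    dysregulated in the direction of interest.
    """
    common = kme_values.dropna().index.intersection(p_directional.dropna().index)
    if len(common) < 5:
        raise ValueError("need at least 5 paired non-missing values")
    x = kme_values.loc[common].to_numpy(dtype=float)
    y = p_directional.loc[common].to_numpy(dtype=float)
    y = -np.log10(np.clip(y, 1e-300, None)) if transform else y
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("all-tied input: correlation undefined")

    if method == "spearman":
        xr, yr = sps.rankdata(x), sps.rankdata(y)
    elif method == "pearson":
        xr, yr = x, y
    else:
        raise ValueError(f"method must be spearman or pearson, got {method!r}")
    # correlation as a dot product of centred vectors; the denominator is
    # permutation-invariant, so the permutation test compares dot products
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = float(np.sqrt((xc**2).sum() * (yc**2).sum()))
    rho = float(xc @ yc) / denom
    rng = np.random.default_rng(seed)
    obs_dot = xc @ yc
    hits = 0
    for _ in range(n_perm):
        if xc @ yc[rng.permutation(len(yc))] >= obs_dot - 1e-12:
            hits += 1
    return rho, (hits + 1.0) / (n_perm + 1.0)


def module_gsea(
    stats: pd.DataFrame,
    modules: list[ModuleDefinition],
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    size_min: int = 3,
    size_max: int | None = None,
    **kwargs,
) -> GSEAResults:
    """Directional GSEA over co-expression modules, with replication flags.

    A thin adapter: modules become a GeneSetCollection and run through the
    enrichment engine (by default without the 500-gene ceiling — published
    modules are often larger).  When a module carries a reference
    disease-status correlation (``hd_cor``), each result row is flagged
    ``same-direction`` or ``opposite-direction`` by comparing the tested
    direction's sign with the reference sign; modules without a reference
    are flagged ``unoriented``.
    """
    validate_stats(stats)
    collection = GeneSetCollection(
        {m.module_id: m.genes for m in modules}, "module"
    )
    model = DirectionalGSEA(
        stats, collection, n_perm=n_perm, size_min=size_min, size_max=size_max, **kwargs
    )
    results = model.fit(seed)
    ref = {m.module_id: m.hd_cor for m in modules}

    def flag(row) -> str:
        cor = ref.get(row["set"])
        if cor is None or (isinstance(cor, float) and np.isnan(cor)):
            return "unoriented"
        return (
            "same-direction"
            if (row["direction"] == "up") == (cor > 0)
            else "opposite-direction"
        )

    table = results.table.copy()
    table["replication"] = table.apply(flag, axis=1)
    results.table = table
    return results
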