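"""Directional gene-set enrichment with a gene-label permutation null.

The engine ranks every gene in the universe by a nonnegative weight — the
1-df chi-square equivalent of its one-sided (up- or down-regulation)
p-value — and computes a weighted Kolmogorov-Smirnov-style running sum for
each gene set: hits add their weight (normalised by the set's total weight),
misses subtract 1/(N - |S|).  The enrichment score (ES) is the signed
maximum deviation of that running sum, so ES is always in [-1, 1].

Significance comes from permuting the gene-wide statistics among gene
labels: one shared stream of label permutations is used for every set in
the collection, which preserves the correlation induced by overlapping
memberships and is what makes the downstream overlap-excess test valid.
Multiple testing across sets is handled by Storey q-values with a fixed
lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GeneSetCollection, validate_stats

__all__ = [
    "chisq_from_p",
    "enrichment_score",
    "permutation_test",
    "qvalues",
    "run_gsea",
    "DirectionalGSEA",
    "GSEAResults",
]


def chisq_from_p(p):
    """Convert one-sided p-values to 1-df chi-square statistics.

    Returns the value x whose upper-tail probability under a chi-square
    distribution with one degree of freedom equals ``p``; strictly
    decreasing in p, with p = 1 mapping to 0.  p must lie in (0, 1] —
    zeros must be floored upstream (the stats builders floor at 1e-300).
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p must lie in (0, 1]; floor zeros upstream")
    out = sps.chi2.isf(arr, df=1)
    return float(out) if np.isscalar(p) else out


# ---------------------------------------------------------------------------
# running-sum machinery
# ---------------------------------------------------------------------------


class _SetBatch:
    """Pre-indexed gene sets for vectorised ES computation.

    Stores all member indices in one flat array with segment boundaries so
    that a single label permutation yields every set's ES in O(M log M),
    M = total membership.
    """

    def __init__(self, collection: GeneSetCollection, gene_index: pd.Index):
        self.names = list(collection)
        pos = {g: i for i, g in enumerate(gene_index)}
        idx_lists = []
        for name in self.names:
            members = collection[name]
            try:
                idx_lists.append(np.array([pos[g] for g in members], dtype=np.int64))
            except KeyError as exc:  # pragma: no cover - restrict() prevents this
                raise ValueError(f"set {name!r} member {exc} not in universe") from exc
        self.sizes = np.array([len(a) for a in idx_lists], dtype=np.int64)
        if np.any(self.sizes == 0):
            raise ValueError("empty set after intersection with universe")
        self.n_genes = len(gene_index)
        if np.any(self.sizes >= self.n_genes):
            raise ValueError("a set equal to the whole universe has no misses")
        self.flat = (
            np.concatenate(idx_lists) if idx_lists else np.empty(0, dtype=np.int64)
        )
        self.starts = np.concatenate([[0], np.cumsum(self.sizes)[:-1]])
        self.seg_start_rep = np.repeat(self.starts, self.sizes)
        self.j = np.arange(len(self.flat)) - self.seg_start_rep + 1  # 1-based hit count
        self.miss_den_rep = np.repeat(self.n_genes - self.sizes, self.sizes).astype(float)
        self.ends = self.starts + self.sizes - 1

    def es_all(self, ranks: np.ndarray, wexp_sorted: np.ndarray) -> np.ndarray:
        """ES for every set given gene -> rank-slot assignment ``ranks``."""
        pos = ranks[self.flat]
        # sort member positions within each segment
        key = self.seg_start_rep * np.int64(self.n_genes) + pos
        order = np.argsort(key, kind="stable")
        pos = pos[order]
        w = wexp_sorted[pos]
        cw = np.cumsum(w)
        offset = np.concatenate([[0.0], cw])[self.starts]
        cw = cw - np.repeat(offset, self.sizes)
        total = cw[self.ends]
        inv_total = np.where(total > 0, 1.0 / np.where(total > 0, total, 1.0), 0.0)
        inv_rep = np.repeat(inv_total, self.sizes)
        after = cw * inv_rep - (pos + 1 - self.j) / self.miss_den_rep
        before = (cw - w) * inv_rep - (pos - (self.j - 1)) / self.miss_den_rep
        max_after = np.maximum.reduceat(after, self.starts)
        min_before = np.minimum(np.minimum.reduceat(before, self.starts), 0.0)
        return np.where(max_after >= -min_before, max_after, min_before)


def _ranked_weights(weights: pd.Series, exponent: float):
    """Deterministic ranking: weight descending, gene id ascending on ties.

    Returns (gene_index_sorted_by_id, rank_of_gene, wexp_sorted) where
    ``rank_of_gene[i]`` is the rank slot (0 = top) of the i-th gene in the
    id-sorted universe and ``wexp_sorted`` the exponentiated weights laid
    out in rank order.
    """
    weights = weights.sort_index()
    w = weights.to_numpy(dtype=float)
    if np.any(w < 0) or np.any(~np.isfinite(w)):
        raise ValueError("weights must be finite and nonnegative")
    order = np.argsort(-w, kind="stable")  # ties resolved by ascending gene id
    rank_of_gene = np.empty_like(order)
    rank_of_gene[order] = np.arange(len(order))
    ws = w[order]
    wexp = np.where(ws > 0, np.power(np.where(ws > 0, ws, 1.0), exponent), 0.0)
    return weights.index, rank_of_gene, wexp


def enrichment_score(
    weights: pd.Series,
    gene_set,
    exponent: float = 1.0,
):
    """Weighted running-sum enrichment score for one gene set.

    ``weights`` maps every universe gene to a nonnegative statistic.  Genes
    are ranked by weight descending (ties broken by gene id ascending); the
    running sum gains w_i^exponent / sum_hits(w^exponent) at member genes
    and loses 1/(N - |S|) at non-members.  Returns ``(ES, leading_edge)``
    where ES is the signed maximum deviation and the leading edge holds the
    members at or before the maximum (ES >= 0) or at or after the minimum
    (ES < 0).
    """
    members = [g for g in set(gene_set) if g in weights.index]
    if not members:
        raise ValueError("gene set does not intersect the universe")
    if len(members) >= len(weights):
        raise ValueError("gene set equals the universe; no misses to score")
    if not np.any(weights.loc[members].to_numpy(dtype=float) > 0):
        raise ValueError("gene set has zero total weight")
    gene_index, rank_of_gene, wexp_sorted = _ranked_weights(weights, exponent)
    member_idx = np.array([gene_index.get_loc(g) for g in sorted(members)])
    pos = np.sort(rank_of_gene[member_idx])
    k, n = len(pos), len(gene_index)
    w = wexp_sorted[pos]
    cw = np.cumsum(w)
    total = cw[-1]
    j = np.arange(1, k + 1)
    after = cw / total - (pos + 1 - j) / (n - k)
    before = (cw - w) / total - (pos - (j - 1)) / (n - k)
    max_after = after.max()
    min_before = min(before.min(), 0.0)
    es = max_after if max_after >= -min_before else min_before
    genes_by_rank = gene_index[np.argsort(rank_of_gene)]
    if es >= 0:
        cut = pos[int(np.argmax(after))]
        leading = [g for g in genes_by_rank[: cut + 1] if g in set(members)]
    else:
        cut = pos[int(np.argmin(before))]
        leading = [g for g in genes_by_rank[cut:] if g in set(members)]
    return float(es), leading


# ---------------------------------------------------------------------------
# permutation null and q-values
# ---------------------------------------------------------------------------


def _null_es(
    weights: pd.Series,
    collection: GeneSetCollection,
    n_perm: int,
    rng: np.random.Generator,
    exponent: float = 1.0,
):
    """Observed ES plus the shared-stream permuted ES pool.

    Returns ``(names, es_obs, es_null)`` with ``es_null`` of shape
    (n_sets, n_perm).  One label permutation per replicate is shared by all
    sets, preserving between-set correlation from overlapping members.
    """
    gene_index, rank_of_gene, wexp_sorted = _ranked_weights(weights, exponent)
    batch = _SetBatch(collection, gene_index)
    es_obs = batch.es_all(rank_of_gene, wexp_sorted)
    es_null = np.empty((len(batch.names), n_perm))
    for r in range(n_perm):
        es_null[:, r] = batch.es_all(rng.permutation(batch.n_genes), wexp_sorted)
    return batch.names, es_obs, es_null


def permutation_test(
    stats: pd.DataFrame,
    collection: GeneSetCollection,
    direction: str,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    exponent: float = 1.0,
    size_min: int = 3,
    size_max: int | None = 500,
) -> pd.DataFrame:
    """Gene-label permutation enrichment test for one direction.

    Weights are the per-gene ``chi2_up`` (direction="up") or ``chi2_down``
    (direction="down") statistics; ``chi2_two`` from the two-sided p is used
    for direction="nondirectional".  p = (#{permuted ES >= observed} + 1) /
    (n_perm + 1), so the smallest attainable p is 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    validate_stats(stats)
    weights = _direction_weights(stats, direction)
    filtered, dropped = collection.restrict(stats.index, size_min, size_max)
    if len(filtered) == 0:
        raise ValueError(
            f"no gene sets left after size filtering "
            f"(too_small={dropped['too_small']}, too_large={dropped['too_large']})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names, es_obs, es_null = _null_es(weights, filtered, n_perm, rng, exponent)
    pvals = ((es_null >= es_obs[:, None]).sum(axis=1) + 1.0) / (n_perm + 1.0)
    leading = []
    for name, es in zip(names, es_obs):
        members = filtered[name]
        try:
            _, le = enrichment_score(weights, members, exponent)
        except ValueError:  # zero total weight: no leading edge to report
            le = []
        leading.append(",".join(le))
    return pd.DataFrame(
        {
            "set": names,
            "direction": direction,
            "size": [len(filtered[n]) for n in names],
            "es": es_obs,
            "p": pvals,
            "leading_edge": leading,
        }
    )


def _direction_weights(stats: pd.DataFrame, direction: str) -> pd.Series:
    if direction == "up":
        return stats["chi2_up"]
    if direction == "down":
        return stats["chi2_down"]
    if direction == "nondirectional":
        return pd.Series(
            chisq_from_p(np.clip(stats["p_two"].to_numpy(), 1e-300, 1.0)),
            index=stats.index,
        )
    raise ValueError(f"direction must be up/down/nondirectional, got {direction!r}")


def qvalues(pvals, lam: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """Storey q-values at a fixed lambda.

    pi0 = min(1, max(#{p > lam} / ((1 - lam) m), 1/m)) unless given
    explicitly; q is the pi0-scaled Benjamini-Hochberg step-up with a
    cumulative minimum, so q is nondecreasing in p and pi0 = 1 reproduces
    plain BH.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = min(1.0, max((p > lam).sum() / ((1.0 - lam) * m), 1.0 / m))
    elif not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


@dataclass
class GSEAResults:
    """Both-direction enrichment results.

    ``table`` is tidy (one row per set per direction) with columns set,
    direction, size, es, p, q, leading_edge, sorted by q then p.  q-values
    are computed within each direction separately.
    """

    table: pd.DataFrame
    n_perm: int
    exponent: float
    qvalue_lambda: float
    seed: int | None = None
    dropped: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05, by: str = "q") -> pd.DataFrame:
        return self.table[self.table[by] < alpha]

    def direction(self, direction: str) -> pd.DataFrame:
        return self.table[self.table["direction"] == direction]

    def summary(self, top: int = 10) -> str:
        lines = [
            "Directional GSEA (gene-label permutation null)",
            f"  sets tested : {self.table['set'].nunique()}"
            f"  (dropped: {self.dropped})",
            f"  permutations: {self.n_perm}   exponent: {self.exponent}"
            f"   lambda: {self.qvalue_lambda}   seed: {self.seed}",
            f"  q < 0.05    : "
            f"{(self.direction('up')['q'] < 0.05).sum()} up, "
            f"{(self.direction('down')['q'] < 0.05).sum()} down",
            "",
            self.table.drop(columns="leading_edge").head(top).to_string(index=False),
        ]
        return "\n".join(lines)

    def plot(self, top: int = 10, ax=None):
        """Minimal summary figure: -log10 q for the top sets per direction."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * top + 1))
        sub = self.table.head(top).iloc[::-1]
        colors = sub["direction"].map({"up": "tab:red", "down": "tab:blue"})
        ax.barh(sub["set"] + " (" + sub["direction"] + ")",
                -np.log10(sub["q"].clip(lower=1e-300)), color=colors)
        ax.set_xlabel("-log10 q")
        return ax


class DirectionalGSEA:
    """Model object: per-gene statistics + a gene-set collection.

    ``fit(seed)`` runs the up- and down-direction permutation tests with
    independent child streams of the given seed and returns
    :class:`GSEAResults`.
    """

    def __init__(
        self,
        stats: pd.DataFrame,
        collection: GeneSetCollection,
        n_perm: int = 10_000,
        exponent: float = 1.0,
        size_min: int = 3,
        size_max: int | None = 500,
        qvalue_lambda: float = 0.5,
    ) -> None:
        self.stats = validate_stats(stats)
        self.collection = collection
        self.n_perm = n_perm
        self.exponent = exponent
        self.size_min = size_min
        self.size_max = size_max
        self.qvalue_lambda = qvalue_lambda

    def fit(self, seed: int = 0) -> GSEAResults:
        ss = np.random.SeedSequence(seed)
        streams = [np.random.default_rng(s) for s in ss.spawn(2)]
        _, dropped = self.collection.restrict(
            self.stats.index, self.size_min, self.size_max
        )
        frames = []
        for direction, rng in zip(("up", "down"), streams):
            res = permutation_test(
                self.stats,
                self.collection,
                direction,
                n_perm=self.n_perm,
                seed=rng,
                exponent=self.exponent,
                size_min=self.size_min,
                size_max=self.size_max,
            )
            res["q"] = qvalues(res["p"].to_numpy(), lam=self.qvalue_lambda)
            frames.append(res)
        table = (
            pd.concat(frames, ignore_index=True)
            .sort_values(["q", "p", "set"], kind="stable")
            .reset_index(drop=True)
        )
        cols = ["set", "direction", "size", "es", "p", "q", "leading_edge"]
        return GSEAResults(
            table[cols], self.n_perm, self.exponent, self.qvalue_lambda, seed, dropped
        )


def run_gsea(
    stats: pd.DataFrame,
    collection: GeneSetCollection,
    n_perm: int = 10_000,
    seed: int = 0,
    **kwargs,
) -> GSEAResults:
    """Functional wrapper: both-direction GSEA with per-direction q-values."""
    return DirectionalGSEA(stats, collection, n_perm=n_perm, **kwargs).fit(seed)
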