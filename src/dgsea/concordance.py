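"""Cross-dataset concordance and replication statistics.

Three tests for whether two transcriptome analyses see the same biology:

* sign concordance of per-gene fold changes against an exact binomial null
  whose success probability comes from the two datasets' direction
  marginals (a gene is "up" iff its fold change exceeds 1);
* a replication-count test — how many of a fixed external gene list reach
  nominal significance, against Binomial(m, alpha);
* an overlap-excess permutation test — how many gene sets are enriched
  (p < alpha, same direction) in both of two enrichment analyses, against
  a null that permutes the comparison dataset's gene-wide statistics among
  genes while preserving the collection's overlap structure.

All binomial tail probabilities are computed by exact summation in log
space; at n in the tens of thousands the interesting tails are far beyond
normal-approximation territory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .containers import GeneSetCollection, validate_stats
from .enrichment import _direction_weights, _null_es

__all__ = [
    "concordance_probability",
    "binomial_upper_tail",
    "concordance_test",
    "replication_count_test",
    "overlap_excess",
    "ConcordanceTest",
    "ConcordanceResult",
    "OverlapExcess",
    "OverlapResult",
    "ReplicationResult",
]


def truncate(x: float, decimals: int = 4) -> float:
    """Truncate (not round) toward zero at the given decimal place."""
    scale = 10**decimals
    return math.trunc(x * scale) / scale


def concordance_probability(a_up: int, b_up: int, n: int) -> float:
    """Null probability that one gene's fold-change direction agrees.

    With ``a_up`` of ``n`` genes direction-positive in dataset A and
    ``b_up`` in dataset B, independence gives
    p0 = (a/n)(b/n) + ((n-a)/n)((n-b)/n).  Equivalently
    p0 - 1/2 = 2(a/n - 1/2)(b/n - 1/2), so p0 = 1/2 exactly whenever either
    marginal is balanced.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= a_up <= n and 0 <= b_up <= n):
        raise ValueError("counts must lie in [0, n]")
    a, b = a_up / n, b_up / n
    return a * b + (1.0 - a) * (1.0 - b)


def binomial_upper_tail(n_obs: int, n: int, p0: float) -> float:
    """P(X >= n_obs) for X ~ Binomial(n, p0), by exact log-space summation."""
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must lie in [0, 1]")
    if n_obs <= 0:
        return 1.0
    if n_obs > n:
        return 0.0
    if p0 == 0.0:
        return 0.0
    if p0 == 1.0:
        return 1.0
    k = np.arange(n_obs, n + 1)
    logpmf = (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        + k * math.log(p0)
        + (n - k) * math.log1p(-p0)
    )
    return float(np.exp(special.logsumexp(logpmf)))


@dataclass
class ConcordanceResult:
    """Fold-change direction concordance between two datasets."""

    n_common: int
    a_up: int
    b_up: int
    n_concordant: int
    n_boundary_a: int
    n_boundary_b: int
    p0: float
    expected: float
    p: float

    @property
    def p0_truncated(self) -> float:
        """p0 truncated to 4 decimals (printed-table convention)."""
        return truncate(self.p0, 4)

    @property
    def expected_truncated(self) -> int:
        """Expected concordant count under truncate-then-multiply."""
        return math.trunc(self.p0_truncated * self.n_common)

    def summary(self) -> str:
        return (
            f"Fold-change concordance: {self.n_concordant}/{self.n_common} genes "
            f"agree in direction\n"
            f"  up in A: {self.a_up}  up in B: {self.b_up}  "
            f"(boundary log2FC==0: {self.n_boundary_a}, {self.n_boundary_b})\n"
            f"  null p0 = {self.p0:.6f} (truncated {self.p0_truncated}), "
            f"expected = {self.expected:.1f}\n"
            f"  exact binomial upper-tail p = {self.p:.3g}"
        )


class ConcordanceTest:
    """Sign concordance of per-gene fold changes across two datasets.

    Inputs are per-gene fold-change Series (ratios > 0) or log fold
    changes (``log=True``).  Gene ids are upper-cased and intersected; a
    gene counts as upregulated iff its fold change is strictly > 1 (log
    fold change > 0), so exact-boundary genes count as not upregulated
    (their number is reported separately).
    """

    def __init__(self, fc_a: pd.Series, fc_b: pd.Series, log: bool = False) -> None:
        a = fc_a.copy()
        b = fc_b.copy()
        a.index = a.index.astype(str).str.upper()
        b.index = b.index.astype(str).str.upper()
        common = a.index.intersection(b.index)
        if len(common) == 0:
            raise ValueError("no genes shared between the two datasets")
        a, b = a.loc[common].astype(float), b.loc[common].astype(float)
        if not log:
            if (a <= 0).any() or (b <= 0).any():
                raise ValueError("fold changes must be positive ratios (or pass log=True)")
            a, b = np.log2(a), np.log2(b)
        self.log_a, self.log_b = a, b
        self.n_dropped = len(fc_a) - len(common), len(fc_b) - len(common)

    def fit(self) -> ConcordanceResult:
        a_up = int((self.log_a > 0).sum())
        b_up = int((self.log_b > 0).sum())
        n = len(self.log_a)
        concordant = int(((self.log_a > 0) == (self.log_b > 0)).sum())
        p0 = concordance_probability(a_up, b_up, n)
        return ConcordanceResult(
            n_common=n,
            a_up=a_up,
            b_up=b_up,
            n_concordant=concordant,
            n_boundary_a=int((self.log_a == 0).sum()),
            n_boundary_b=int((self.log_b == 0).sum()),
            p0=p0,
            expected=p0 * n,
            p=binomial_upper_tail(concordant, n, p0),
        )


def concordance_test(fc_a: pd.Series, fc_b: pd.Series, log: bool = False) -> ConcordanceResult:
    """Functional wrapper around :class:`ConcordanceTest`."""
    return ConcordanceTest(fc_a, fc_b, log=log).fit()


@dataclass
class ReplicationResult:
    n_observed: int
    n_total: int
    alpha: float
    expected: float
    p: float

    def summary(self) -> str:
        return (
            f"Replication count: {self.n_observed}/{self.n_total} at p < {self.alpha} "
            f"(expected {self.expected:.2f}); exact binomial p = {self.p:.3g}"
        )


def replication_count_test(pvals, alpha: float = 0.05) -> ReplicationResult:
    """Excess of nominally significant p-values over the chance rate.

    Counts p < alpha among ``m`` p-values and compares against
    Binomial(m, alpha) with an exact upper tail.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n_obs = int((p < alpha).sum())
    return ReplicationResult(
        n_observed=n_obs,
        n_total=p.size,
        alpha=alpha,
        expected=alpha * p.size,
        p=binomial_upper_tail(n_obs, p.size, alpha),
    )


# ---------------------------------------------------------------------------
# overlap excess
# ---------------------------------------------------------------------------


@dataclass
class OverlapResult:
    """Excess of gene sets enriched in both of two analyses."""

    n_sets: int
    n_sig_a: int
    n_sig_b: int
    n_overlap: int
    p: float
    direction: str
    alpha: float
    n_perm: int
    null_mean: float

    def summary(self) -> str:
        return (
            f"Overlap excess ({self.direction}): {self.n_overlap} of {self.n_sets} sets "
            f"enriched (p < {self.alpha}) in both analyses\n"
            f"  significant: A {self.n_sig_a}, B {self.n_sig_b}; "
            f"null mean {self.null_mean:.2f}\n"
            f"  permutation p = {self.p:.4g} ({self.n_perm} label permutations of B)"
        )


class OverlapExcess:
    """Permutation test for shared gene-set enrichment across datasets.

    Dataset A's significant sets (enrichment p < alpha in ``results_a``
    for the chosen direction) are held fixed.  Dataset B's gene-wide
    statistics are permuted among gene labels with one shared stream for
    the whole collection; each permutation's per-set enrichment p-value is
    its ES's rank within the permuted ES pool, and the overlap with A's
    significant sets is recounted.  p = (#{null overlap >= observed} + 1) /
    (n_perm + 1).
    """

    def __init__(
        self,
        results_a: pd.DataFrame,
        stats_b: pd.DataFrame,
        collection: GeneSetCollection,
        direction: str = "up",
        alpha: float = 0.05,
        n_perm: int = 1000,
        exponent: float = 1.0,
        size_min: int = 3,
        size_max: int | None = 500,
    ) -> None:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        self.direction = direction
        self.alpha = alpha
        self.n_perm = n_perm
        self.exponent = exponent
        self.stats_b = validate_stats(stats_b)
        self.collection, _ = collection.restrict(stats_b.index, size_min, size_max)
        if len(self.collection) == 0:
            raise ValueError("no gene sets left after size filtering")
        sub = results_a[results_a["direction"] == direction] if "direction" in results_a else results_a
        p_a = sub.set_index("set")["p"]
        missing = [s for s in self.collection if s not in p_a.index]
        if missing:
            raise ValueError(f"results_a lacks sets analysed in B: {missing[:5]}")
        self.p_a = p_a.loc[list(self.collection)]

    def fit(self, seed: int = 0) -> OverlapResult:
        rng = np.random.default_rng(seed)
        weights = _direction_weights(self.stats_b, self.direction)
        names, es_obs, es_null = _null_es(
            weights, self.collection, self.n_perm, rng, self.exponent
        )
        r = self.n_perm
        p_obs_b = ((es_null >= es_obs[:, None]).sum(axis=1) + 1.0) / (r + 1.0)
        # alpha >= 1 is the degenerate threshold: everything is significant
        # (permutation p-values can equal 1 exactly, so strict < would not do)
        if self.alpha >= 1.0:
            a_sig = np.ones(len(self.p_a), dtype=bool)
            b_sig = np.ones_like(a_sig)
        else:
            a_sig = self.p_a.to_numpy() < self.alpha
            b_sig = p_obs_b < self.alpha
        observed = int(np.sum(a_sig & b_sig))
        # per-replicate pseudo p: rank of each permuted ES within its set's
        # pool (ties counted as >=)
        sorted_desc = -np.sort(-es_null, axis=1)
        ge_counts = np.empty_like(es_null, dtype=float)
        for i in range(es_null.shape[0]):
            # number of pool values >= value, tie-inclusive
            ge_counts[i] = sorted_desc.shape[1] - np.searchsorted(
                sorted_desc[i][::-1], es_null[i], side="left"
            )
        p_null = ge_counts / r
        if self.alpha >= 1.0:
            null_overlap = np.full(r, int(a_sig.sum()))
        else:
            null_overlap = (p_null[a_sig] < self.alpha).sum(axis=0)
        p = (float(np.sum(null_overlap >= observed)) + 1.0) / (r + 1.0)
        return OverlapResult(
            n_sets=len(names),
            n_sig_a=int(a_sig.sum()),
            n_sig_b=int(b_sig.sum()),
            n_overlap=observed,
            p=p,
            direction=self.direction,
            alpha=self.alpha,
            n_perm=r,
            null_mean=float(null_overlap.mean()),
        )


def overlap_excess(
    results_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    collection: GeneSetCollection,
    direction: str = "up",
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    **kwargs,
) -> OverlapResult:
    """Functional wrapper around :class:`OverlapExcess`."""
    return OverlapExcess(
        results_a, stats_b, collection, direction, alpha, n_perm, **kwargs
    ).fit(seed)
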