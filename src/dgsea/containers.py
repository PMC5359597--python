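"""Core in-memory containers shared across the pipeline.

A :class:`CountMatrix` couples an integer gene-by-sample count table with
per-sample clinical metadata (cohort, disease group, age, gender and a
motor-severity score).  A :class:`GeneSetCollection` is an ordered mapping
from set names to gene-identifier tuples with a provenance label per set
(pathway, co-expression module, or custom list).  Per-gene statistics travel
as plain :class:`pandas.DataFrame` objects indexed by gene id with the
columns listed in :data:`STATS_COLUMNS`.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Required columns of a per-gene statistics table ("GeneStatsTable").
#: ``log2fc`` holds the case/control log2 fold change or, for severity
#: regressions, the per-unit-severity slope; ``stat`` the Wald statistic;
#: ``p_up``/``p_down`` the one-sided tail probabilities for up- and
#: down-regulation; ``chi2_up``/``chi2_down`` their 1-df chi-square
#: equivalents used as enrichment weights.
STATS_COLUMNS = (
    "log2fc",
    "stat",
    "p_two",
    "p_up",
    "p_down",
    "chi2_up",
    "chi2_down",
    "mean_norm_count",
)

METADATA_COLUMNS = ("cohort", "group", "age", "gender", "tms")
VALID_GROUPS = frozenset({"control", "premanifest", "manifest"})


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus aligned sample metadata.

    ``counts``: DataFrame, genes in rows (unique ids), samples in columns.
    ``metadata``: DataFrame indexed by sample id with columns ``cohort``,
    ``group`` (control/premanifest/manifest), ``age`` (years), ``gender``
    and ``tms`` (total motor score; NaN allowed for controls).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            frac, _ = np.modf(values)
            if np.any(frac != 0) or np.any(~np.isfinite(values)):
                g, s = np.argwhere((frac != 0) | ~np.isfinite(values))[0]
                raise ValueError(
                    f"non-integer count for gene {self.counts.index[g]!r} "
                    f"in sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValueError("negative counts are not allowed")
        missing = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata missing column {col!r}")
        self.metadata = self.metadata.loc[self.counts.columns]
        bad = set(self.metadata["group"]) - VALID_GROUPS
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(self.counts[samples], self.metadata.loc[samples])


class GeneSetCollection(Mapping):
    """Named gene-identifier sets with a provenance label per set.

    Member lists are deduplicated and stored sorted so downstream ranking
    tie-breaks are platform independent.
    """

    def __init__(
        self,
        sets: Mapping[str, Sequence[str]],
        provenance: str | Mapping[str, str] = "custom",
    ) -> None:
        self._sets: dict[str, tuple[str, ...]] = {}
        for name, members in sets.items():
            if name in self._sets:
                raise ValueError(f"duplicate set name: {name!r}")
            self._sets[name] = tuple(sorted(set(members)))
        if isinstance(provenance, str):
            self.provenance = {name: provenance for name in self._sets}
        else:
            self.provenance = dict(provenance)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets and self.provenance == other.provenance

    def restrict(
        self,
        universe: Sequence[str],
        size_min: int = 3,
        size_max: int | None = 500,
    ) -> tuple["GeneSetCollection", dict[str, int]]:
        """Intersect every set with ``universe`` and apply size bounds.

        Returns the filtered collection and counts of sets dropped for
        being too small / too large after intersection.
        """
        uni = set(universe)
        kept: dict[str, tuple[str, ...]] = {}
        dropped = {"too_small": 0, "too_large": 0}
        for name, members in self._sets.items():
            inter = tuple(g for g in members if g in uni)
            if len(inter) < size_min:
                dropped["too_small"] += 1
            elif size_max is not None and len(inter) > size_max:
                dropped["too_large"] += 1
            else:
                kept[name] = inter
        return (
            GeneSetCollection(kept, {n: self.provenance.get(n, "custom") for n in kept}),
            dropped,
        )


@dataclass
class ModuleDefinition:
    """A co-expression module: members plus optional reference annotations.

    ``hd_cor`` is the reference correlation between the module eigengene and
    disease status in the tissue the module was derived from (positive means
    upregulated in disease there); it orients replication calls.
    """

    module_id: str
    genes: tuple[str, ...]
    kme: pd.Series | None = None
    annotation: str | None = None
    region: str | None = None
    hd_cor: float | None = None

    def __post_init__(self) -> None:
        self.genes = tuple(sorted(set(self.genes)))
        if len(self.genes) < 1:
            raise ValueError(f"module {self.module_id!r} has no members")
        if self.kme is not None:
            vals = np.asarray(self.kme, dtype=float)
            if np.any((vals < -1 - 1e-9) | (vals > 1 + 1e-9)):
                raise ValueError(f"module {self.module_id!r}: kME outside [-1, 1]")


def validate_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Check a per-gene statistics table for required columns and sanity."""
    missing = [c for c in STATS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"stats table missing columns: {missing}")
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"duplicate gene id in stats table: {dup!r}")
    for col in ("p_two", "p_up", "p_down"):
        vals = table[col].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1 + 1e-12)):
            raise ValueError(f"column {col!r} outside [0, 1]")
    return table


def stats_from_z(
    genes: Sequence[str],
    log2fc: np.ndarray,
    z: np.ndarray,
    mean_norm_count: np.ndarray,
    tail: str = "normal",
    df: float | None = None,
) -> pd.DataFrame:
    """Assemble a GeneStatsTable from effects and Wald statistics.

    Directional p-values come from the continuous upper/lower tails of the
    standard normal (``tail="normal"``) or a t distribution with ``df``
    degrees of freedom (``tail="t"``); they are floored at 1e-300 before the
    1-df chi-square conversion so weights stay finite.
    """
    from scipy import stats as sps

    from .enrichment import chisq_from_p

    z = np.asarray(z, dtype=float)
    if tail == "normal":
        p_up = sps.norm.sf(z)
        p_down = sps.norm.cdf(z)
    elif tail == "t":
        if df is None:
            raise ValueError("df required for t tails")
        p_up = sps.t.sf(z, df)
        p_down = sps.t.cdf(z, df)
    else:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown tail {tail!r}")
    p_up = np.clip(p_up, 1e-300, 1.0)
    p_down = np.clip(p_down, 1e-300, 1.0)
    p_two = np.clip(2.0 * np.minimum(p_up, p_down), 1e-300, 1.0)
    table = pd.DataFrame(
        {
            "log2fc": np.asarray(log2fc, dtype=float),
            "stat": z,
            "p_two": p_two,
            "p_up": p_up,
            "p_down": p_down,
            "chi2_up": chisq_from_p(p_up),
            "chi2_down": chisq_from_p(p_down),
            "mean_norm_count": np.asarray(mean_norm_count, dtype=float),
        },
        index=pd.Index(genes, name="gene"),
    )
    return validate_stats(table)


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
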