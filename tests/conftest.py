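import numpy as np
import pandas as pd
import pytest

from dgsea import CountMatrix, GeneSetCollection, SimulationConfig, generate_cohort
from dgsea.containers import stats_from_z
from dgsea.simulate import gene_ids, generate_gene_sets


def make_stats(z, genes=None, log2fc=None, seed=None):
    """GeneStatsTable from a vector of Wald z statistics."""
    z = np.asarray(z, dtype=float)
    if genes is None:
        genes = gene_ids(len(z))
    if log2fc is None:
        log2fc = z / 4.0
    return stats_from_z(genes, log2fc, z, np.full(len(z), 100.0))


def random_null_stats(n_genes, seed):
    """Null stats table: z ~ N(0, 1)."""
    rng = np.random.default_rng(seed)
    return make_stats(rng.normal(size=n_genes))


@pytest.fixture(scope="session")
def null_cohort():
    """One synthetic cohort with no embedded effects (40 + 40 samples)."""
    cfg = SimulationConfig(
        n_genes=120, n_cases=40, n_controls=40, seed=11,
        frac_sets_up=0.0, frac_sets_down=0.0, effect_log2fc=0.0,
    )
    coll = generate_gene_sets(gene_ids(120), 6, 5, 10, seed=11)
    cm, truth = generate_cohort(cfg, coll)
    return cm, truth, coll


@pytest.fixture(scope="session")
def effect_cohort():
    """Cohort with two up and two down sets embedded at log2FC 1.5."""
    cfg = SimulationConfig(
        n_genes=300, n_cases=40, n_controls=40, seed=7,
        frac_sets_up=0.1, frac_sets_down=0.1, effect_log2fc=1.5,
    )
    coll = generate_gene_sets(gene_ids(300), 20, 8, 15, seed=7)
    cm, truth = generate_cohort(cfg, coll)
    return cm, truth, coll


@pytest.fixture(scope="session")
def tiny_counts():
    counts = pd.DataFrame(
        {"s1": [10, 20, 5], "s2": [12, 18, 6], "s3": [8, 25, 4], "s4": [11, 22, 5]},
        index=["G1", "G2", "G3"],
    )
    meta = pd.DataFrame(
        {
            "cohort": "c",
            "group": ["control", "control", "manifest", "manifest"],
            "age": [40, 45, 50, 55],
            "gender": ["M", "F", "M", "F"],
            "tms": [np.nan, np.nan, 20.0, 30.0],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    return CountMatrix(counts, meta)
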