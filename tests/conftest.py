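import numpy as np
import pandas as pd
import pytest

from dpbm.io_formats import SurvivalData
from dpbm.synthetic_data import SimulationDesign, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_survival():
    """Ten subjects with a mix of events, censorings and tied times."""
    time = np.array([2.0, 3.0, 3.0, 5.0, 7.0, 8.0, 8.0, 10.0, 12.0, 15.0])
    event = np.array([1, 1, 0, 1, 0, 1, 1, 0, 1, 0])
    ids = tuple(f"s{i}" for i in range(10))
    return SurvivalData(ids, time, event)


@pytest.fixture
def small_cohort():
    """A small planted cohort: 120 samples, 60 genes, 2 signal genes."""
    design = SimulationDesign(
        n_samples=120,
        n_genes=60,
        n_signal_genes=2,
        effect_size=1.0,
        censoring_rate=0.5,
        n_pathways=8,
        pathway_size_range=(6, 12),
        n_enriched_pathways=1,
        enrichment_overlap=2,
        seed=77,
    )
    expr, survival, truth = simulate_cohort(design)
    return design, expr, survival, truth


def make_expr(values, genes=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
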