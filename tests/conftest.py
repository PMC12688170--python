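import numpy as np
import pandas as pd
import pytest

import leukotype as lt


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across read-only tests."""
    cohort, truth = lt.simulate_cohort(lt.SimConfig(seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def small_expression():
    """Tiny deterministic expression matrix (6 genes × 4 samples)."""
    rng = np.random.default_rng(5)
    values = pd.DataFrame(
        rng.uniform(0, 50, size=(6, 4)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(4)],
    )
    gene_class = pd.Series(
        ["mRNA", "mRNA", "mRNA", "lncRNA", "lncRNA", "other"], index=values.index
    )
    return lt.ExpressionMatrix(values, gene_class)


@pytest.fixture()
def feature_matrix_factory():
    """Feature matrices from simulated cohorts (expression + mutations)."""

    def make(seed: int, n_per_class: int = 300, **sim_kwargs):
        cfg = lt.SimConfig(seed=seed, **sim_kwargs)
        cohort, truth = lt.simulate_cohort(cfg)
        fs = lt.select_top_mad(cohort.expression, n_per_class=n_per_class)
        mfs = lt.filter_mutation_prevalence(cohort.mutations, cohort.sample_ids)
        fm = lt.build_feature_matrix(cohort.expression, fs, mfs)
        return fm, truth, cohort

    return make
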