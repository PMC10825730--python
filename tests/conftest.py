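import numpy as np
import pandas as pd
import pytest

import methylpanel as mp
from methylpanel import collapse, preprocess
from methylpanel.pipeline import _row_batch


@pytest.fixture(scope="session")
def small_cohort():
    return mp.generate_cohort(seed=11)


@pytest.fixture(scope="session")
def dup_cohort():
    return mp.generate_cohort(n_duplicates=6, seed=11)


@pytest.fixture(scope="session")
def small_truth_params():
    return mp.TruthParams(n_genes=200, n_modules=3, module_size=25)


@pytest.fixture(scope="session")
def small_dataset(dup_cohort, small_truth_params):
    """(matrix, truth, annotation) for the small duplicate-bearing cohort."""
    return mp.generate_methylation(dup_cohort, small_truth_params, seed=12)


@pytest.fixture(scope="session")
def small_gene_matrix(small_cohort):
    """Residualized, collapsed gene matrix with a planted disease module."""
    # module size must clear the default min module size of 20
    params = mp.TruthParams(n_genes=120, n_modules=3, module_size=22)
    matrix, truth, ann = mp.generate_methylation(small_cohort, params, seed=13)
    residual = preprocess.batch_residualize(matrix, _row_batch(small_cohort, 12))
    gm = collapse.collapse_max_mean(residual, ann)
    return gm, truth, small_cohort
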