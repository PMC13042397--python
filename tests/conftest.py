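import numpy as np
import pandas as pd
import pytest

from dnbpipe.io import (
    ExpressionMatrix,
    build_stage_design,
    filter_by_completeness,
    median_normalize,
)
from dnbpipe.simulate import SyntheticConfig, generate_staged_dataset

#: Group sizes of the emulated cohort, duplicated here so fixture construction
#: does not depend on the generator's own constant.
COHORT_SIZES = {
    ("ESO", "L"): 10, ("MID", "L"): 19, ("MOD", "L"): 11,
    ("SED", "L"): 14, ("ESCC", "L"): 10,
    ("ESO", "N"): 8, ("MID", "N"): 17, ("MOD", "N"): 8,
    ("SED", "N"): 10, ("ESCC", "N"): 5,
}

SMALL_SYNTH = dict(
    n_proteins=300, n_trend_proteins=20, seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort (300 proteins, full group sizes)."""
    cfg = SyntheticConfig(**SMALL_SYNTH)
    matrix, annotations, truth = generate_staged_dataset(cfg)
    design = build_stage_design(annotations)
    return matrix, design, truth, cfg


@pytest.fixture(scope="session")
def normalized_cohort(small_cohort):
    matrix, design, truth, cfg = small_cohort
    norm = filter_by_completeness(median_normalize(matrix), design, 0.5)
    return norm, design, truth, cfg


@pytest.fixture()
def tiny_matrix():
    """3 proteins x 4 samples with one missing cell."""
    vals = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, np.nan, 6.0, 8.0], [5.0, 5.0, 5.0, 5.0]],
        index=["p1", "p2", "p3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(vals, "log2")
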