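import numpy as np
import pandas as pd
import pytest

from immunomod.datatypes import ClinicalTable, ExpressionMatrix
from immunomod.modules import build_all_modules
from immunomod.synthdata import generate_reference_panel, generate_tumor_cohort


@pytest.fixture(scope="session")
def ref_panel():
    """Small reference panel: 3 planted blocks of 100 genes + 400 background."""
    return generate_reference_panel(
        n_blocks=3, genes_per_block=100, n_background_genes=400,
        n_samples=120, within_block_corr=0.7, noise_sd=1.0, seed=101)


@pytest.fixture(scope="session")
def module_collection(ref_panel):
    expr, markers, _ = ref_panel
    return build_all_modules(expr, markers, module_size=100)


@pytest.fixture(scope="session")
def tumor_cohort(ref_panel):
    """Cohort with a protective high-infiltrate effect (beta = -1)."""
    _, _, truth = ref_panel
    return generate_tumor_cohort(n_samples=300, reference_truth=truth,
                                 beta=-1.0, seed=202)


@pytest.fixture(scope="session")
def null_cohort(ref_panel):
    """Cohort with no expression-survival association (beta = 0)."""
    _, _, truth = ref_panel
    return generate_tumor_cohort(n_samples=200, reference_truth=truth,
                                 beta=0.0, seed=303)


@pytest.fixture
def toy_expr():
    return ExpressionMatrix(pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [2.0, 4.0, 6.0, 8.0],
         [5.0, 1.0, 4.0, 2.0],
         [3.0, 3.0, 2.0, 1.0],
         [0.0, 2.0, 1.0, 5.0]],
        index=["G1", "G2", "G3", "G4", "G5"],
        columns=["S1", "S2", "S3", "S4"]))


@pytest.fixture
def toy_clinical():
    """6 samples, mixed events and censoring, distinct times."""
    return ClinicalTable(pd.DataFrame(
        {"time": [10.0, 25.0, 40.0, 55.0, 70.0, 85.0],
         "event": [1, 0, 1, 1, 0, 1]},
        index=[f"S{i}" for i in range(1, 7)]))


def clinical_from_arrays(times, events, prefix="S"):
    index = [f"{prefix}{i}" for i in range(1, len(times) + 1)]
    return ClinicalTable(pd.DataFrame(
        {"time": np.asarray(times, dtype=float),
         "event": np.asarray(events, dtype=int)}, index=index))
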