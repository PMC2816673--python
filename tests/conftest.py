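import numpy as np
import pandas as pd
import pytest

from moduledisease.expression import CONTROL, DISEASE, ExpressionStudy
from moduledisease.modules import ModuleCatalog


def make_study(
    values: np.ndarray,
    n_disease: int,
    study_id: str = "s0",
    disease_id: str = "dX",
    gene_ids=None,
) -> ExpressionStudy:
    """Build an ExpressionStudy from a raw genes x samples array.

    The first ``n_disease`` columns are disease samples, the rest controls.
    """
    values = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"{study_id}_smp{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    labels = pd.Series(
        [DISEASE] * n_disease + [CONTROL] * (values.shape[1] - n_disease),
        index=df.columns,
    )
    return ExpressionStudy(study_id, disease_id, df, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_catalog():
    return ModuleCatalog(
        {
            "m1": ["g0", "g1", "g2"],
            "m2": ["g2", "g3"],
            "m3": ["g4", "g5", "g6", "g7"],
        }
    )


@pytest.fixture
def random_study(rng):
    return make_study(rng.normal(size=(30, 8)), n_disease=4, study_id="rand")
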