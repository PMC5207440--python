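import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from claudinlow.data_io import ExpressionMatrix

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """30 genes x 12 samples, two labeled subtypes, two batches."""
    genes = [f"G{i:02d}" for i in range(30)]
    samples = [f"S{i:02d}" for i in range(12)]
    values = pd.DataFrame(rng.normal(7, 1, (30, 12)), index=genes, columns=samples)
    return ExpressionMatrix(
        values=values,
        batch_labels=pd.Series(["b1"] * 6 + ["b2"] * 6, index=samples),
        subtype_labels=pd.Series(["luminal A"] * 6 + ["basal-like"] * 6, index=samples),
    )
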