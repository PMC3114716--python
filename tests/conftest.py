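import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from trailkit.preprocess import ExpressionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(values: np.ndarray, genes=None, design_rows=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a plain array.

    ``design_rows``: list of (sample, tissue, genotype, treatment, replicate);
    defaults to single-tissue WT/+Fe samples, one replicate index per column.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if genes is None:
        genes = [f"g{i}" for i in range(n_genes)]
    if design_rows is None:
        design_rows = [
            (f"s{j}", "root", "WT", "+Fe", j + 1) for j in range(n_samples)
        ]
    samples = [r[0] for r in design_rows]
    design = pd.DataFrame(
        [dict(zip(("sample", "tissue", "genotype", "treatment", "replicate"), r))
         for r in design_rows]
    ).set_index("sample")
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    return ExpressionMatrix(values=frame, design=design)


@pytest.fixture
def two_condition_matrix() -> ExpressionMatrix:
    """4 genes x 6 samples: two conditions (WT +Fe / WT -Fe), 3 replicates each."""
    rows = [
        ("a1", "root", "WT", "+Fe", 1), ("a2", "root", "WT", "+Fe", 2),
        ("a3", "root", "WT", "+Fe", 3),
        ("b1", "root", "WT", "-Fe", 1), ("b2", "root", "WT", "-Fe", 2),
        ("b3", "root", "WT", "-Fe", 3),
    ]
    values = np.array(
        [
            [5.0, 5.0, 5.0, 5.0, 5.0, 5.0],   # unchanged
            [3.0, 5.0, 100.0, 8.0, 8.0, 8.0],  # median 5 -> 8
            [2.0, 2.0, 2.0, 8.0, 8.0, 8.0],    # 4-fold up
            [8.0, 8.0, 8.0, 2.0, 2.0, 2.0],    # 4-fold down
        ]
    )
    return make_matrix(values, genes=["flat", "noisy", "up", "down"], design_rows=rows)
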