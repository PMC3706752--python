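import numpy as np
import pandas as pd
import pytest

from isosig.matrix import AnnotationMap, ExpressionMatrix
from isosig.simulate import SyntheticSpec, simulate_dataset


@pytest.fixture(scope="session")
def tiny_spec() -> SyntheticSpec:
    return SyntheticSpec(
        n_genes=80,
        n_samples_per_class=10,
        n_tissues=2,
        noise_sd=0.6,
        tissue_sd=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    """(matrix, annotation, metadata, truth) for a small seeded study."""
    return simulate_dataset(tiny_spec)


@pytest.fixture()
def two_gene_matrix() -> tuple[ExpressionMatrix, AnnotationMap]:
    """Two genes: G1 with isoforms (1,2)/(3,4), G2 single-isoform."""
    data = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["G1.T1", "G1.T2", "G2.T1"],
        columns=["s1", "s2"],
    )
    ann = AnnotationMap(
        pd.Series(["G1", "G1", "G2"], index=["G1.T1", "G1.T2", "G2.T1"])
    )
    return ExpressionMatrix(data, level="isoform", scale="linear"), ann


def log2_matrix(values, features=None, samples=None, level="isoform") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples), level=level, scale="log2"
    )
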