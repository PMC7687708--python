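import numpy as np
import pandas as pd
import pytest

from cpgdeconv import BetaMatrix


@pytest.fixture
def tiny_matrix() -> BetaMatrix:
    """4 CpGs x 4 samples with easy hand-checkable values."""
    data = pd.DataFrame(
        {
            "s1": [0.0, 1.0, 0.25, 0.5],
            "s2": [1.0, 0.0, 0.75, 0.5],
            "s3": [0.1, 0.9, 0.2, 0.5],
            "s4": [0.9, 0.1, 0.8, 0.5],
        },
        index=pd.Index(["cg01", "cg02", "cg03", "cg04"], name="cpg_id"),
    )
    return BetaMatrix(data)


@pytest.fixture
def tiny_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "cell_type": ["fibroblast", "leukocyte", "fibroblast", "leukocyte"],
        }
    )


def random_beta_matrix(rng: np.random.Generator, n_cpgs: int, n_samples: int) -> BetaMatrix:
    data = pd.DataFrame(
        rng.uniform(0, 1, size=(n_cpgs, n_samples)),
        index=pd.Index([f"cg{i:05d}" for i in range(n_cpgs)], name="cpg_id"),
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )
    return BetaMatrix(data)
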