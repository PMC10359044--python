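import numpy as np
import pandas as pd
import pytest

from hervscope import CountMatrix, SampleDesign, synthetic


@pytest.fixture(scope="session")
def toy_annotation():
    """20 loci / 50 genes on 3 toy chromosomes, fixed seed."""
    return synthetic.make_toy_annotation(
        20, 50, n_chromosomes=3,
        family_weights={"HML2": 5.0, "MER101": 3.0, "HERVL": 1.0},
        frac_intragenic=0.3, seed=11,
    )


@pytest.fixture(scope="session")
def balanced_design():
    return synthetic.make_design(10, 10)


@pytest.fixture(scope="session")
def batch_design():
    return synthetic.make_design(10, 10, batches=("b1", "b2"))


def small_matrix(values, conditions, batches=None):
    """Build a CountMatrix from a plain nested list (features x samples)."""
    arr = np.asarray(values)
    batches = batches or ["b1"] * arr.shape[1]
    samples = [
        SampleDesign(f"s{i + 1}", c, b)
        for i, (c, b) in enumerate(zip(conditions, batches))
    ]
    counts = pd.DataFrame(
        arr,
        index=[f"f{i + 1}" for i in range(arr.shape[0])],
        columns=[s.sample_id for s in samples],
    )
    return CountMatrix(counts, samples)
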