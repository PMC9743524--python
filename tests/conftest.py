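import numpy as np
import pytest

from crrpred.regions import class_count_fixture, dataset_summary
from crrpred.synthetic import generate_dataset, benchmark_spec


@pytest.fixture(scope="session")
def hg19_summary():
    return dataset_summary(class_count_fixture("hg19"), "hg19")


@pytest.fixture(scope="session")
def hg38_summary():
    return dataset_summary(class_count_fixture("hg38"), "hg38")


@pytest.fixture(scope="session")
def benchmark_features():
    """A benchmark synthetic feature task: n=2000, 20:1 imbalance, effect 1."""
    spec = benchmark_spec(seed=11)
    _, _, features, y = generate_dataset(spec)
    return features.to_numpy(np.float32), y
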