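import numpy as np
import pytest

from fedlung.cohort import (
    Cohort,
    GeneratorParams,
    LabeledCase,
    SliceImage,
    generate_cohort,
)
from fedlung.evaluation import prepare_federation


@pytest.fixture(scope="session")
def gen_params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def cohort300():
    """Default study cohort: 300 cases, equal class mix, fixed seed."""
    return generate_cohort(300, seed=42)


@pytest.fixture(scope="session")
def cohort60():
    """Small cohort for fast federation tests."""
    return generate_cohort(60, seed=11)


@pytest.fixture(scope="session")
def setup5(cohort300):
    """Standard 5-client federation setup on the 300-case cohort."""
    return prepare_federation(cohort300, n_clients=5, split_seed=1, partition_seed=2)


def make_flat_cohort(n: int, seed: int) -> Cohort:
    """Cheap cohort of featureless cases (zero images) for structural tests."""
    rng = np.random.default_rng(seed)
    labels = ["normal", "benign", "malignant"]
    cases = []
    counts = {lab: 0 for lab in labels}
    # guarantee >= 2 per class so stratified splitting is possible
    seq = labels * 2 + [labels[rng.integers(3)] for _ in range(max(0, n - 6))]
    for i, lab in enumerate(seq[:n]):
        counts[lab] += 1
        img = SliceImage(np.zeros((16, 16)), case_id=f"f{seed}_{i}")
        cases.append(LabeledCase(image=img, label=lab, features=np.zeros(8)))
    return Cohort(cases=tuple(cases), seed=seed)


def edge_perimeter(mask: np.ndarray) -> int:
    """Independent brute-force boundary length: count of exposed pixel edges."""
    pad = np.pad(mask.astype(bool), 1)
    return int(
        np.sum(pad[1:, :] != pad[:-1, :]) + np.sum(pad[:, 1:] != pad[:, :-1])
    )
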