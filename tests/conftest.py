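import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from allerknn import (
    LabeledInstance,
    STANDARD_AMINO_ACIDS,
    SyntheticSpec,
    generate_synthetic,
    load_zscale,
)


@pytest.fixture(scope="session")
def ztable():
    return load_zscale()


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_AMINO_ACIDS), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20130417)


@pytest.fixture(scope="session")
def small_dataset():
    """200 synthetic proteins (100 per class) with the default class bias."""
    return generate_synthetic(SyntheticSpec(n_per_class=100, seed=11))


def random_instances(rng: np.random.Generator, n: int, dim: int = 45):
    """Labelled instances with random vectors, both classes present."""
    instances = []
    for i in range(n):
        label = "allergen" if rng.random() < 0.5 or i == 0 else "non-allergen"
        if i == 1:
            label = "non-allergen"
        routes = frozenset()
        if label == "allergen":
            routes = frozenset(
                rng.choice(["food", "inhalant", "toxin"],
                           size=rng.integers(1, 3), replace=False).tolist()
            )
        instances.append(
            LabeledInstance(id=f"inst{i}", vector=rng.normal(size=dim),
                            label=label, routes=routes)
        )
    return instances
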