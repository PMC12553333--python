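import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from protbench import TaskSpec


@pytest.fixture
def regression_task():
    return TaskSpec(name="reg", objective="regression")


@pytest.fixture
def binary_task():
    return TaskSpec(name="bin", objective="binary")


@pytest.fixture
def pair_regression_task():
    return TaskSpec(name="pairreg", arity="pair", objective="regression")


@pytest.fixture
def pair_binary_task():
    return TaskSpec(name="pairbin", arity="pair", objective="binary")


@pytest.fixture
def residue_task():
    return TaskSpec(name="res", level="residue", objective="binary")


@pytest.fixture
def multiclass_task():
    return TaskSpec(name="multi", objective="multiclass", num_classes=3)
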