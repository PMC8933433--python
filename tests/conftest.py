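import numpy as np
import pytest

from stdpmem import ModelParams, run_image_task, run_semantic_task


@pytest.fixture(scope="session")
def image_task_exact():
    """Full store+retrieve of 5 synthetic 16x16 images, exact cue."""
    return run_image_task(cue_mode="exact", seed=1)


@pytest.fixture(scope="session")
def image_task_irrelevant():
    """Same stored group, cued with an image the system never saw."""
    return run_image_task(cue_mode="irrelevant", seed=1)


@pytest.fixture(scope="session")
def semantic_mary_s():
    return run_semantic_task([("Mary", "S")])


@pytest.fixture(scope="session")
def semantic_john_s():
    return run_semantic_task([("John", "S")])


@pytest.fixture(scope="session")
def semantic_john_s_mary_o():
    return run_semantic_task([("John", "S"), ("Mary", "O")])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
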