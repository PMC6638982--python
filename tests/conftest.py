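import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from probtrack import TaskConfig


@pytest.fixture(scope="session")
def config():
    """Default task configuration (d' = 1.5, states 0.2..0.8)."""
    return TaskConfig()


@pytest.fixture(scope="session")
def labels_800():
    """A fixed 800-trial label stream with realistic serial structure."""
    rng = np.random.default_rng(2024)
    from probtrack import sample_probability_path

    cfg = TaskConfig(seed=2024)
    pi, _ = sample_probability_path(cfg, 2024)
    return (rng.random(800) < pi).astype(int)
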