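import numpy as np
import pytest

import gutlink as gl


@pytest.fixture
def small_counts():
    """3 taxa x 2 samples toy table."""
    return gl.CountTable(["ta", "tb", "tc"], ["s1", "s2"],
                         np.array([[2, 0], [2, 3], [4, 1]]))


@pytest.fixture
def random_counts():
    rng = np.random.default_rng(1234)
    return gl.CountTable(
        [f"t{i:02d}" for i in range(12)],
        [f"s{j:02d}" for j in range(8)],
        rng.integers(0, 50, size=(12, 8)),
    )


@pytest.fixture(scope="session")
def study():
    """One seeded synthetic study shared by read-only tests."""
    cfg = gl.study_preset(7)
    counts, meta, behav, truth = gl.generate_study(cfg)
    return cfg, counts, meta, behav, truth
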