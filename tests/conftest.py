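import numpy as np
import pytest

from lungseg import LogisticTypeDist, MixtureParams

# Two-component pixel-intensity model fitted to real lung CT (8-bit scale):
# lung interior vs surrounding tissue, equal weights, shape fixed at 4.
TABLE_LOCS = (60.54, 121.98)
TABLE_SCALES2 = (94.2568, 128.784)


@pytest.fixture
def table_truth() -> MixtureParams:
    comps = tuple(
        LogisticTypeDist(m, np.sqrt(s2), 4.0)
        for m, s2 in zip(TABLE_LOCS, TABLE_SCALES2)
    )
    return MixtureParams(comps, (0.5, 0.5))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def draw_mixture(params: MixtureParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Ancestral sampling from a mixture (independent oracle for tests)."""
    counts = rng.multinomial(n, params.weights)
    parts = [c.rvs(int(k), rng) for c, k in zip(params.components, counts) if k > 0]
    x = np.concatenate(parts)
    rng.shuffle(x)
    return x


def all_partitions(n: int):
    """Every set partition of range(n) as a label vector (restricted growth)."""
    out = []

    def rec(labels, next_label):
        i = len(labels)
        if i == n:
            out.append(tuple(labels))
            return
        for lab in range(next_label + 1):
            rec(labels + [lab], max(next_label, lab + 1))

    rec([], 0)
    return out
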