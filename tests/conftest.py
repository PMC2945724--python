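import numpy as np
import pytest

from colorseed import builtin_family
from colorseed.seeds import PositionedSeed, SeedFamily, SpacedSeed


@pytest.fixture(scope="session")
def lossless_family():
    """The shipped 3-seed weight-10 position-restricted family (m=34)."""
    return builtin_family("3-lossless-10-24p", read_length=34)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_positioned_family(
    rng,
    n_members=1,
    w_range=(3, 8),
    max_gaps=4,
    m_range=(8, 20),
    n_pos_range=(1, 4),
):
    """Sample a random valid positioned family (test helper)."""
    m = int(rng.integers(*m_range))
    members = []
    for _ in range(n_members):
        while True:
            w = int(rng.integers(w_range[0], w_range[1] + 1))
            g = int(rng.integers(0, max_gaps + 1)) if w >= 2 else 0
            s = w + g
            if s <= m:
                break
        pat = ["#"] * s
        if g:
            for i in rng.choice(s - 2, g, replace=False) + 1:
                pat[i] = "-"
        hi = min(n_pos_range[1], m - s + 1)
        lo = min(n_pos_range[0], hi)
        n_pos = int(rng.integers(lo, hi + 1))
        pos = tuple(int(p) for p in sorted(rng.choice(m - s + 1, n_pos, replace=False)))
        members.append(PositionedSeed(SpacedSeed("".join(pat)), pos))
    return SeedFamily(tuple(members), m)
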