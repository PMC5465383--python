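import numpy as np
import pytest

from cogbattery import build_schedule


@pytest.fixture
def schedule():
    return build_schedule()


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------


def nback_oracle(n_level: int, letters) -> list[bool]:
    """Position-by-position re-scan of the n-back rule."""
    flags = []
    for i, ch in enumerate(letters):
        if n_level == 0:
            flags.append(ch == "X")
        elif i < n_level:
            flags.append(False)
        else:
            flags.append(ch == letters[i - n_level])
    return flags


def midrank_oracle(values) -> list[float]:
    """O(n^2) mid-ranks: 1 + #smaller + (#equal - 1)/2."""
    ranks = []
    for v in values:
        smaller = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(1.0 + smaller + (equal - 1) / 2.0)
    return ranks


def spearman_oracle(x, y) -> float:
    """Pearson correlation of mid-ranks, computed from first principles."""
    rx, ry = midrank_oracle(x), midrank_oracle(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
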