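import numpy as np
import pytest

from msatselect.seqio import Read


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_read(rng, rid="r", min_len=60, max_len=200, qual_low=2, qual_high=41):
    n = int(rng.integers(min_len, max_len + 1))
    bases = "".join(rng.choice(list("ACGT"), n))
    quals = rng.integers(qual_low, qual_high, n)
    return Read(rid, bases, tuple(int(q) for q in quals))


@pytest.fixture
def make_random_read():
    return random_read


def decay_read(rng, rid="r", min_len=60, max_len=200, q_start=40.0, q_end=18.0,
               jitter=2.0):
    """Read with a pyrosequencing-like 3' quality decline."""
    import numpy as np

    n = int(rng.integers(min_len, max_len + 1))
    bases = "".join(rng.choice(list("ACGT"), n))
    q = q_start + (q_end - q_start) * np.arange(n) / max(n - 1, 1)
    q = np.clip(np.rint(q + rng.normal(0.0, jitter, n)), 2, 40)
    return Read(rid, bases, tuple(int(x) for x in q))
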