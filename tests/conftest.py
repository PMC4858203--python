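import numpy as np
import pytest

from riplet import Cassette, DnaSegment, HomologyPattern, generate_test, homology_mask


def random_segment(length: int, seed: int, name: str = "ref") -> DnaSegment:
    rng = np.random.default_rng(seed)
    return DnaSegment(name, "".join(rng.choice(list("ACGT"), size=length)))


def random_cassette(length: int, seed: int, density: float = 0.5) -> Cassette:
    """A cassette with an arbitrary (non-periodic) homology mask."""
    rng = np.random.default_rng(seed)
    ref = random_segment(length, seed)
    mask = rng.random(length) < density
    seq = list(ref.seq)
    for i in np.flatnonzero(~mask):
        alternatives = [b for b in "ACGT" if b != seq[i]]
        seq[i] = alternatives[rng.integers(3)]
    return Cassette(ref, DnaSegment("test", "".join(seq)), mask)


@pytest.fixture
def reference_550() -> DnaSegment:
    return random_segment(550, seed=2024)


@pytest.fixture
def reference_500() -> DnaSegment:
    return random_segment(500, seed=1959)


@pytest.fixture
def cassette_4h7n(reference_550) -> Cassette:
    pattern = HomologyPattern(4, 7, 1, 550)
    return generate_test(reference_550, pattern, seed=11)


def brute_force_positions(x, y, z, length, end_policy="truncate", extend_by=0):
    """Independent enumeration of homologous positions from the defining set
    { Z + k*P + j : k >= 0, 0 <= j < X } intersected with [1, L]."""
    if x == 0 or z > length:
        return []
    p = x + y
    positions = set()
    k = 0
    while z + k * p <= length:
        for j in range(x):
            pos = z + k * p + j
            if pos <= length:
                positions.add(pos)
        k += 1
    if end_policy == "extend" and extend_by and positions:
        last_start = z + (k - 1) * p
        for j in range(x, x + extend_by):
            pos = last_start + j
            if pos <= length:
                positions.add(pos)
    return sorted(positions)
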