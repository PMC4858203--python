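"""Canonical triplet census of homologous units.

Forward and reverse-complement instances of each 3-mer are pooled into one
canonical class (the lexicographically smaller of the pair).  No 3-mer is
its own reverse complement — the middle base would have to pair with itself
— so there are exactly 32 canonical classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .cassette import Cassette, mask_runs
from .patterns import DNA_ALPHABET, reverse_complement


def canonical_triplet(t: str) -> str:
    """The lexicographically smaller of a 3-mer and its reverse complement."""
    if len(t) != 3 or any(b not in DNA_ALPHABET for b in t):
        raise ValueError(f"not an ACGT triplet: {t!r}")
    rc = reverse_complement(t)
    return t if t <= rc else rc


CANONICAL_TRIPLETS: tuple[str, ...] = tuple(
    sorted(
        {
            canonical_triplet(a + b + c)
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
        }
    )
)
assert len(CANONICAL_TRIPLETS) == 32


@dataclass
class TripletCensus:
    """Counts of canonical triplets contained in homologous units."""

    counts: Counter = field(default_factory=Counter)
    unit_count: int = 0  # number of homologous runs of length >= 3

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, triplet: str) -> int:
        return self.counts.get(canonical_triplet(triplet), 0)

    def to_frame(self) -> pd.DataFrame:
        """Tabular census: one row per canonical class, sorted by count desc
        then name; zero classes included."""
        rows = [
            {"triplet": t, "count": self.counts.get(t, 0)}
            for t in CANONICAL_TRIPLETS
        ]
        df = pd.DataFrame(rows)
        return df.sort_values(
            ["count", "triplet"], ascending=[False, True], ignore_index=True
        )


def enumerate_unit_triplets(cassette: Cassette) -> TripletCensus:
    """Census all triplets contained in the cassette's homologous units.

    Every maximal homologous run of length l >= 3 contributes its l - 2
    overlapping 3-windows, read from the reference copy and counted under
    their canonical names; shorter runs contribute nothing.
    """
    ref = cassette.reference_copy.seq
    census = TripletCensus()
    for start0, length in mask_runs(cassette.homology_mask):
        if length < 3:
            continue
        census.unit_count += 1
        for i in range(start0, start0 + length - 2):
            census.counts[canonical_triplet(ref[i : i + 3])] += 1
    return census
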