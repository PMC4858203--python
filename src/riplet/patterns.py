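"""Interspersed-homology patterns and plain DNA segments.

An interspersed homology is written ``XH-YN_Z``: homologous units of X bp
separated by Y bp of non-homology, with the first unit starting at 1-based
sequence position Z of the reference region.  The periodicity of the pattern
is P = X + Y; e.g. ``4H-7N_1`` places 4-bp units at positions 1, 12, 23, ...
of a region of length L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

_log = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def complement(base: str) -> str:
    """Watson-Crick complement of a single base."""
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DnaSegment:
    """A named DNA sequence over {A,C,G,T}; coordinates are 1-based inclusive."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"segment {self.id!r}: empty sequence")
        for i, b in enumerate(self.seq, start=1):
            if b not in DNA_ALPHABET:
                raise ValueError(
                    f"segment {self.id!r}: non-ACGT base {b!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, new_id: str | None = None) -> "DnaSegment":
        return DnaSegment(new_id or f"{self.id}_rc", reverse_complement(self.seq))


@dataclass(frozen=True)
class HomologyPattern:
    """The (X, Y, Z, L) parameterization of an interspersed homology.

    Parameters
    ----------
    unit_len : int
        X, length of each homologous unit in bp (X >= 0).
    spacer_len : int
        Y, length of the non-homologous spacer between units in bp (Y >= 0).
    start : int
        Z, 1-based position of the first homologous unit (Z >= 1).  No unit,
        not even a partial one, is placed before Z.
    region_len : int
        L, length of the region the pattern spans.
    end_policy : {"truncate", "extend"}
        How the last unit interacts with the region end.  With "truncate"
        (default) units crossing L are clipped at L.  With "extend" the final
        unit is lengthened by ``extend_by`` positions (still clipped at L);
        this exists to reproduce construct variants whose last unit was
        accidentally lengthened during synthesis.
    extend_by : int
        Extra bp appended to the final unit under ``end_policy="extend"``.
    """

    unit_len: int
    spacer_len: int
    start: int
    region_len: int
    end_policy: str = "truncate"
    extend_by: int = 0

    def __post_init__(self) -> None:
        if self.unit_len < 0 or self.spacer_len < 0:
            raise ValueError("unit_len and spacer_len must be non-negative")
        if self.unit_len + self.spacer_len < 1:
            raise ValueError("period X+Y must be at least 1")
        if self.start < 1:
            raise ValueError("start (Z) must be >= 1")
        if self.region_len < 1:
            raise ValueError("region_len (L) must be >= 1")
        if self.end_policy not in ("truncate", "extend"):
            raise ValueError(f"unknown end_policy {self.end_policy!r}")
        if self.end_policy == "extend" and self.extend_by < 0:
            raise ValueError("extend_by must be >= 0")

    @property
    def period(self) -> int:
        """P = X + Y, the pattern periodicity in bp."""
        return self.unit_len + self.spacer_len

    @property
    def name(self) -> str:
        """Canonical pattern name, e.g. '4H-7N_1'."""
        return f"{self.unit_len}H-{self.spacer_len}N_{self.start}"

    def per_period_identity(self) -> float:
        """Fraction of identical positions per full period, X / (X + Y)."""
        return self.unit_len / self.period

    def shifted(self, delta_z: int) -> "HomologyPattern":
        """Same pattern with Z moved by ``delta_z`` (Z stays >= 1)."""
        return HomologyPattern(
            self.unit_len,
            self.spacer_len,
            self.start + delta_z,
            self.region_len,
            self.end_policy,
            self.extend_by,
        )


def homologous_positions(pattern: HomologyPattern) -> list[int]:
    """All 1-based positions belonging to a homologous unit, in order.

    The set is { Z + k*P + j : k >= 0, 0 <= j < X } intersected with [1, L];
    under ``end_policy="extend"`` the final unit is lengthened by
    ``extend_by`` positions before clipping at L.  Z > L yields an empty
    list (with a warning), as does X = 0.
    """
    x, p, z, length = pattern.unit_len, pattern.period, pattern.start, pattern.region_len
    if z > length:
        _log.warning(
            "pattern %s: start Z=%d beyond region length L=%d; no homologous positions",
            pattern.name, z, length,
        )
        return []
    if x == 0:
        return []
    positions: list[int] = []
    unit_starts = list(range(z, length + 1, p))
    for k, s in enumerate(unit_starts):
        end = s + x - 1
        if pattern.end_policy == "extend" and k == len(unit_starts) - 1:
            end += pattern.extend_by
        positions.extend(range(s, min(end, length) + 1))
    return positions


def homology_mask(pattern: HomologyPattern):
    """Boolean mask of length L; True at homologous positions."""
    import numpy as np

    mask = np.zeros(pattern.region_len, dtype=bool)
    pos = homologous_positions(pattern)
    if pos:
        mask[np.asarray(pos) - 1] = True
    return mask
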