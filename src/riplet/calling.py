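"""RIP mutation calling and summarization.

RIP (repeat-induced point mutation) introduces C-to-T transitions on one
strand of a duplicated region, observed in sequenced spore contigs as C→T
or G→A substitutions relative to the expected cassette sequence.  This
module compares spore contigs to their expected sequence, classifies every
mismatch, and summarizes calls as per-spore counts (mean ± SEM) and
per-site incidence profiles.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .patterns import DnaSegment

_log = logging.getLogger(__name__)

_ID_RE = re.compile(r"^(?P<repeat_id>[A-Za-z]+)(?P<cross>\d+)_(?P<spore>\d+)$")


@dataclass
class SporeRecord:
    """One sequenced spore contig.

    Ids follow the convention ``{RepeatID}{cross index}_{spore index}``,
    e.g. ``XIF1_1``.  ``recorded_ct``/``recorded_ga`` hold externally
    supplied mutation totals (from an archived dataset), kept separate
    from any counts this package recomputes.
    """

    id: str
    seq: str
    construct: str = ""
    recorded_ct: Optional[int] = None
    recorded_ga: Optional[int] = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if not self.construct:
            m = _ID_RE.match(self.id)
            if m:
                self.construct = m.group("repeat_id")

    def id_parts(self) -> tuple[str, int, int]:
        """(RepeatID, cross index, spore index) parsed from the id."""
        m = _ID_RE.match(self.id)
        if not m:
            raise ValueError(f"unparseable spore id: {self.id!r}")
        return m.group("repeat_id"), int(m.group("cross")), int(m.group("spore"))


@dataclass
class MutationCallSet:
    """Called substitutions for one spore, in expected-sequence coordinates.

    ``positions`` is a list of (1-based position, class) with class one of
    "CT" (expected C observed T), "GA" (expected G observed A) or "other"
    (any remaining mismatch).  Non-RIP mismatches are reported but excluded
    from all RIP statistics.
    """

    spore_id: str
    positions: list[tuple[int, str]] = field(default_factory=list)
    gap_columns: int = 0

    @property
    def n_ct(self) -> int:
        return sum(1 for _, c in self.positions if c == "CT")

    @property
    def n_ga(self) -> int:
        return sum(1 for _, c in self.positions if c == "GA")

    @property
    def n_other(self) -> int:
        return sum(1 for _, c in self.positions if c == "other")

    @property
    def total(self) -> int:
        """RIP mutations only (CT + GA)."""
        return self.n_ct + self.n_ga

    def rip_positions(self, region: Optional[tuple[int, int]] = None) -> list[int]:
        pos = [p for p, c in self.positions if c in ("CT", "GA")]
        if region is not None:
            lo, hi = region
            pos = [p for p in pos if lo <= p <= hi]
        return pos


@dataclass
class SiteProfile:
    """Per-position mutated-spore counts across all spores of one construct."""

    construct: str
    site_counts: np.ndarray
    n_spores: int

    @property
    def length(self) -> int:
        return len(self.site_counts)

    @property
    def percent(self) -> np.ndarray:
        """Mutation incidence per site as percent of all spores sequenced."""
        return 100.0 * self.site_counts / self.n_spores

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, self.length + 1),
                "count": self.site_counts,
                "percent": np.round(self.percent, 4),
            }
        )


def _classify(exp_base: str, obs_base: str) -> Optional[str]:
    if exp_base == obs_base:
        return None
    if exp_base == "C" and obs_base == "T":
        return "CT"
    if exp_base == "G" and obs_base == "A":
        return "GA"
    return "other"


def call_mutations(
    expected: DnaSegment,
    spore: SporeRecord,
    mode: str = "positional",
    max_gap_fraction: float = 0.2,
) -> MutationCallSet:
    """Call substitutions in a spore contig against its expected sequence.

    ``positional`` mode (default) compares site by site and requires equal
    lengths — appropriate because RIP introduces substitutions only.
    ``gapped`` mode first computes a global pairwise alignment (match +1,
    mismatch -2, gap open -6, gap extend -1) to tolerate indel artifacts in
    real contigs; gap columns are excluded from counts and tallied, and an
    alignment with more than ``max_gap_fraction`` gap columns is rejected
    as a likely wrong construct assignment.
    """
    if mode == "positional":
        if len(expected) != len(spore.seq):
            raise ValueError(
                f"positional mode needs equal lengths: expected {len(expected)}, "
                f"spore {spore.id!r} has {len(spore.seq)}"
            )
        calls = MutationCallSet(spore.id)
        for i, (e, o) in enumerate(zip(expected.seq, spore.seq), start=1):
            cls = _classify(e, o)
            if cls is not None:
                calls.positions.append((i, cls))
        return calls
    if mode != "gapped":
        raise ValueError(f"unknown mode {mode!r}")

    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    alignment = aligner.align(expected.seq, spore.seq)[0]
    exp_aln, obs_aln = str(alignment[0]), str(alignment[1])

    calls = MutationCallSet(spore.id)
    exp_pos = 0
    n_gap = 0
    for e, o in zip(exp_aln, obs_aln):
        if e != "-":
            exp_pos += 1
        if e == "-" or o == "-":
            n_gap += 1
            continue
        cls = _classify(e, o)
        if cls is not None:
            calls.positions.append((exp_pos, cls))
    calls.gap_columns = n_gap
    if n_gap > max_gap_fraction * len(exp_aln):
        raise ValueError(
            f"spore {spore.id!r}: {n_gap}/{len(exp_aln)} gap columns "
            f"(> {max_gap_fraction:.0%}); likely wrong construct assignment"
        )
    if n_gap:
        _log.info("spore %s: %d gap columns excluded from counts", spore.id, n_gap)
    return calls


def mean_mutations(
    calls: Sequence[MutationCallSet],
    region: Optional[tuple[int, int]] = None,
) -> tuple[float, float, int]:
    """Mean RIP mutations per spore with its standard error.

    Per-spore totals are n_CT + n_GA, restricted to the 1-based inclusive
    ``region`` when given.  SEM uses the sample standard deviation (n-1
    denominator) divided by sqrt(n), and is reported as 0 when n = 1.
    """
    if not calls:
        raise ValueError("empty call list")
    totals = np.array([len(c.rip_positions(region)) for c in calls], dtype=float)
    n = len(totals)
    mean = float(totals.mean())
    sem = float(totals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return mean, sem, n


def site_profile(
    calls: Sequence[MutationCallSet],
    length: int,
    construct: str = "",
) -> SiteProfile:
    """Per-site count of spores carrying a RIP call at each position."""
    counts = np.zeros(length, dtype=int)
    for c in calls:
        for p in c.rip_positions():
            if p > length:
                raise ValueError(
                    f"spore {c.spore_id!r}: call at position {p} beyond length {length}"
                )
            counts[p - 1] += 1
    return SiteProfile(construct, counts, n_spores=len(calls))


def calls_to_frame(calls: Iterable[MutationCallSet]) -> pd.DataFrame:
    """Per-spore call table: spore_id, n_CT, n_GA, n_other."""
    return pd.DataFrame(
        [
            {"spore_id": c.spore_id, "n_CT": c.n_ct, "n_GA": c.n_ga, "n_other": c.n_other}
            for c in calls
        ]
    )
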