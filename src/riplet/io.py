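"""Readers and writers for the pipeline's file formats.

FASTA and ClustalW go through Biopython.  The contig CSV dialect has four
fields per row — id, C/T mutation total, G/A mutation total, sequence —
optionally gzip-compressed.  Homology masks are exported as BED (0-based
half-open); all tabular outputs and logs use 1-based inclusive coordinates.
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import SporeRecord
from .cassette import Cassette, mask_runs
from .patterns import DNA_ALPHABET, DnaSegment, HomologyPattern

_log = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA

def read_fasta(path: PathLike) -> list[DnaSegment]:
    with _open_text(path) as fh:
        return [DnaSegment(r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, "fasta")]


def write_fasta(segments: Iterable[DnaSegment], path: PathLike, wrap: int = 70) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in segments]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


# ------------------------------------------------------------- ClustalW

def write_clustal_pair(cassette: Cassette, path: PathLike) -> None:
    """One reference/test pairwise alignment per construct, Clustal format."""
    aln = MultipleSeqAlignment(
        [
            SeqRecord(Seq(cassette.reference_copy.seq), id=cassette.reference_copy.id),
            SeqRecord(Seq(cassette.test_copy.seq), id=cassette.test_copy.id),
        ]
    )
    AlignIO.write(aln, str(path), "clustal")


@dataclass
class ClustalPair:
    reference: DnaSegment
    test: DnaSegment
    mask: np.ndarray  # over alignment columns excluding gap columns
    gap_columns: int


def read_clustalw_pair(path: PathLike) -> ClustalPair:
    """Read a two-sequence Clustal alignment and derive the homology mask.

    The mask covers gap-free columns only (column-wise equality of the two
    sequences); gap columns are excluded and their count reported.
    """
    aln = AlignIO.read(str(path), "clustal")
    if len(aln) != 2:
        raise ValueError(f"{path}: expected exactly 2 sequences, found {len(aln)}")
    a, b = (str(r.seq).upper() for r in aln)
    mask, ref_chars, test_chars, n_gap = [], [], [], 0
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            n_gap += 1
            continue
        ref_chars.append(ca)
        test_chars.append(cb)
        mask.append(ca == cb)
    if n_gap:
        _log.info("%s: %d gap columns excluded from mask", path, n_gap)
    return ClustalPair(
        DnaSegment(aln[0].id, "".join(ref_chars)),
        DnaSegment(aln[1].id, "".join(test_chars)),
        np.asarray(mask, dtype=bool),
        n_gap,
    )


# ------------------------------------------------------------ contig CSV

def read_contig_csv(path: PathLike) -> list[SporeRecord]:
    """Read a 4-field contig CSV: id, C/T total, G/A total, sequence.

    Recorded totals are retained on the record, separate from anything the
    caller recomputes.  Malformed rows raise with their line number;
    non-ACGT sequences are flagged with a warning, not rejected.
    """
    records: list[SporeRecord] = []
    with _open_text(path) as fh:
        reader = csv.reader(fh)
        n_rows = 0
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            n_rows += 1
            if len(row) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 fields, found {len(row)}"
                )
            sid, ct, ga, seq = (f.strip() for f in row)
            try:
                ct_n, ga_n = int(ct), int(ga)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count") from exc
            seq = seq.upper()
            flagged = any(b not in DNA_ALPHABET for b in seq)
            if flagged:
                _log.warning("%s:%d: spore %s has non-ACGT characters", path, lineno, sid)
            records.append(
                SporeRecord(sid, seq, recorded_ct=ct_n, recorded_ga=ga_n, flagged=flagged)
            )
    if n_rows == 0:
        _log.warning("%s: empty contig CSV", path)
    return records


def write_contig_csv(records: Iterable[SporeRecord], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        for r in records:
            writer.writerow([r.id, r.recorded_ct or 0, r.recorded_ga or 0, r.seq])


# ------------------------------------------------------------------ BED

def mask_to_bed(mask: np.ndarray, name: str, path: PathLike) -> None:
    """Export homologous runs as BED intervals (0-based, half-open)."""
    with open(path, "w") as fh:
        for start0, length in mask_runs(mask):
            fh.write(f"{name}\t{start0}\t{start0 + length}\n")


def bed_to_mask(path: PathLike, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            _, start, end = line.split("\t")[:3]
            mask[int(start) : int(end)] = True
    return mask


def to_bed_interval(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> BED 0-based half-open."""
    return start1 - 1, end1


def from_bed_interval(start0: int, end0: int) -> tuple[int, int]:
    """BED 0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


# -------------------------------------------------------------- manifest

@dataclass
class ConstructManifest:
    """Maps each RepeatID to its description and expected cassette FASTA."""

    table: pd.DataFrame  # repeat_id, description, fasta_path, n_crosses, n_spores

    def __post_init__(self) -> None:
        ids = self.table["repeat_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate RepeatID in manifest: {dup!r}")

    def expected_for(self, repeat_id: str, root: Optional[PathLike] = None) -> DnaSegment:
        row = self.table.loc[self.table["repeat_id"] == repeat_id]
        if row.empty:
            raise KeyError(f"RepeatID {repeat_id!r} not in manifest")
        p = Path(row["fasta_path"].iloc[0])
        if root is not None:
            p = Path(root) / p
        return read_fasta(p)[0]


def read_manifest(path: PathLike) -> ConstructManifest:
    return ConstructManifest(pd.read_csv(path, sep="\t"))


def write_manifest(manifest: ConstructManifest, path: PathLike) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------- pattern config

def read_pattern_config(path: PathLike) -> dict:
    """Plain config: keys X, Y, Z, L, end_policy, extend_by, block_len,
    block_side, junction_insert_len, interruption, seed."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def pattern_from_config(cfg: dict) -> HomologyPattern:
    return HomologyPattern(
        unit_len=int(cfg["X"]),
        spacer_len=int(cfg["Y"]),
        start=int(cfg.get("Z", 1)),
        region_len=int(cfg["L"]),
        end_policy=cfg.get("end_policy", "truncate"),
        extend_by=int(cfg.get("extend_by", 0)),
    )
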