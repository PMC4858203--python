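"""Repeat-cassette construction: test-sequence generation, composition, editing.

A cassette is a pair of aligned, equal-length sequences — the fixed
"reference" copy and the designed "test" copy — plus a homology mask that is
True exactly where the two copies agree.  Test sequences realizing a given
interspersed-homology pattern are produced by keeping the reference base at
every homologous position and substituting every other position with one of
the three alternative bases, chosen uniformly and independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .patterns import (
    DNA_ALPHABET,
    DnaSegment,
    HomologyPattern,
    complement,
    homology_mask,
)

_log = logging.getLogger(__name__)

PERFECT = "perfect"
PatternOrPerfect = Union[HomologyPattern, str]

# fixed per-component RNG stream keys so that adding a block or insert to a
# composed cassette never perturbs the 500-bp region's sequence
_STREAM_REGION = 0
_STREAM_BLOCK_REF = 1
_STREAM_BLOCK_SUBS = 2
_STREAM_JUNCTION = 3
_STREAM_INTERRUPTION = 4

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


def _component_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class CassetteSpec:
    """Composition of a full repeat construct.

    The 500-bp (or generally L-bp) partially homologous region described by
    ``pattern`` is optionally flanked by a block of ``block_len`` bp of
    perfect (or patterned) homology on ``block_side``, with an optional
    random junction insert between block and region, and an optional
    interruption replacing part of the block with non-matching bases.
    Interruption coordinates are 1-based within the block.
    """

    reference: DnaSegment
    pattern: PatternOrPerfect
    block_len: int = 0
    block_side: str = "none"  # left | right | none
    block_pattern: PatternOrPerfect = PERFECT
    junction_insert_len: int = 0
    interruption: Optional[tuple[int, int]] = None  # (start, len), block-relative

    def __post_init__(self) -> None:
        if self.block_side not in ("left", "right", "none"):
            raise ValueError(f"unknown block_side {self.block_side!r}")
        if (self.block_len == 0) != (self.block_side == "none"):
            raise ValueError("block_len == 0 exactly when block_side == 'none'")
        if self.block_len < 0 or self.junction_insert_len < 0:
            raise ValueError("lengths must be non-negative")
        if self.block_len == 0 and self.junction_insert_len > 0:
            raise ValueError("junction insert requires a block")
        if self.interruption is not None:
            start, length = self.interruption
            if start < 1 or length < 1 or start + length - 1 > self.block_len:
                raise ValueError(
                    f"interruption ({start}, {length}) outside the {self.block_len}-bp block"
                )
        if isinstance(self.pattern, str) and self.pattern != PERFECT:
            raise ValueError(f"pattern must be a HomologyPattern or {PERFECT!r}")
        if isinstance(self.block_pattern, str) and self.block_pattern != PERFECT:
            raise ValueError(f"block_pattern must be a HomologyPattern or {PERFECT!r}")


@dataclass(frozen=True)
class Cassette:
    """A realized reference/test repeat pair with its homology mask.

    Invariant: ``homology_mask[i]`` is True iff the test base at position
    i+1 equals the aligned reference base.
    """

    reference_copy: DnaSegment
    test_copy: DnaSegment
    homology_mask: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.reference_copy) != len(self.test_copy):
            raise ValueError("reference and test copies must have equal length")
        if len(self.homology_mask) != len(self.reference_copy):
            raise ValueError("mask length must match sequence length")

    def __len__(self) -> int:
        return len(self.reference_copy)

    def validate(self) -> None:
        """Check the mask/sequence consistency invariant; raise on violation."""
        ref = np.frombuffer(self.reference_copy.seq.encode(), dtype="S1")
        test = np.frombuffer(self.test_copy.seq.encode(), dtype="S1")
        equal = ref == test
        if not np.array_equal(equal, self.homology_mask.astype(bool)):
            bad = int(np.flatnonzero(equal != self.homology_mask)[0]) + 1
            raise ValueError(f"mask/sequence mismatch first at position {bad}")

    def reverse_complement(self) -> "Cassette":
        return Cassette(
            self.reference_copy.reverse_complement(),
            self.test_copy.reverse_complement(),
            self.homology_mask[::-1].copy(),
            dict(self.provenance, reverse_complemented=True),
        )


def percent_identity(a: DnaSegment, b: DnaSegment) -> float:
    """Fraction of identical positions between two equal-length segments."""
    if len(a) != len(b):
        raise ValueError(
            f"length mismatch: {a.id!r} has {len(a)} bp, {b.id!r} has {len(b)} bp"
        )
    return sum(x == y for x, y in zip(a.seq, b.seq)) / len(a)


def _substitute(ref_arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace ``positions`` (0-based) with a uniformly chosen different base."""
    out = ref_arr.copy()
    for i in positions:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[rng.integers(3)]
    return out


def generate_test(
    reference: DnaSegment,
    pattern: PatternOrPerfect,
    seed: int,
    *,
    _rng: np.random.Generator | None = None,
) -> Cassette:
    """Generate the test copy realizing ``pattern`` against ``reference``.

    Homologous positions keep the reference base; every non-homologous
    position receives one of the three alternative bases, drawn uniformly
    and independently from a generator seeded by ``seed``.  Identical
    (reference, pattern, seed) triples reproduce byte-identical output.
    """
    if isinstance(pattern, str):  # "perfect"
        mask = np.ones(len(reference), dtype=bool)
        test = DnaSegment(f"{reference.id}_test", reference.seq)
        return Cassette(reference, test, mask, {"pattern": PERFECT, "seed": seed})
    if len(reference) != pattern.region_len:
        raise ValueError(
            f"reference length {len(reference)} != pattern region_len {pattern.region_len}"
        )
    mask = homology_mask(pattern)
    rng = _rng if _rng is not None else _component_rng(seed, _STREAM_REGION)
    ref_arr = np.array(list(reference.seq), dtype="U1")
    test_arr = _substitute(ref_arr, np.flatnonzero(~mask), rng)
    test = DnaSegment(f"{reference.id}_{pattern.name}", "".join(test_arr))
    return Cassette(reference, test, mask, {"pattern": pattern.name, "seed": seed})


def mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask as (start0, length) pairs."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def delete_unit_triplet(
    cassette: Cassette,
    triplet: str,
    occurrences: int | str = "all",
) -> Cassette:
    """Destroy occurrences of ``triplet`` within homologous units by
    single-base complement substitutions in the test copy.

    Occurrences are located exactly as the triplet census counts them: both
    the forward triplet and its reverse complement, read from the reference
    copy, fully inside a maximal homologous run.  Each targeted occurrence
    is destroyed by substituting exactly one base with its complement — the
    base of the triplet that belongs to no other overlapping triplet of the
    run (for a 4-bp unit: the first base if the triplet occupies unit
    positions 1-3, the last if it occupies 2-4).  The edited position
    becomes non-homologous in the mask.

    ``occurrences`` is ``"all"`` or an integer n (edit the first n, left to
    right).
    """
    from .triplets import canonical_triplet  # local import, avoids cycle

    target = canonical_triplet(triplet)
    ref = cassette.reference_copy.seq
    runs = mask_runs(cassette.homology_mask)

    # (edit_pos0, window_start0) per targeted occurrence, in sequence order
    hits: list[tuple[int, int]] = []
    for start0, length in runs:
        if length < 3:
            continue
        n_windows = length - 2
        for s in range(n_windows):  # run-relative window index, 0-based
            w0 = start0 + s
            if canonical_triplet(ref[w0 : w0 + 3]) != target:
                continue
            if s == 0:
                edit = w0  # first base: exclusive to this window
            elif s == n_windows - 1:
                edit = w0 + 2  # last base: exclusive to this window
            else:
                edit = w0 + 1  # interior window: no exclusive base exists
                _log.warning(
                    "triplet %s at position %d lies in the interior of a "
                    "%d-bp homologous run; the edit also alters neighboring triplets",
                    target, w0 + 1, length,
                )
            hits.append((edit, w0))

    if occurrences != "all":
        hits = hits[: int(occurrences)]
    if not hits:
        return cassette

    # warn when one edit falls inside another targeted occurrence's window
    windows = {w for _, w in hits}
    for edit, w in hits:
        for other in windows - {w}:
            if other <= edit <= other + 2:
                _log.warning(
                    "edit at position %d also destroys the %s occurrence at %d",
                    edit + 1, target, other + 1,
                )

    test_arr = np.array(list(cassette.test_copy.seq), dtype="U1")
    mask = cassette.homology_mask.copy()
    for edit, _ in hits:
        test_arr[edit] = complement(str(test_arr[edit]))
        mask[edit] = False
    test = DnaSegment(cassette.test_copy.id, "".join(test_arr))
    prov = dict(cassette.provenance)
    prov.setdefault("edits", []).append((f"delta_{target}", len(hits)))
    return Cassette(cassette.reference_copy, test, mask, prov)


def _random_bases(n: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(4, size=n)]


def _nonmatching_bases(ref_arr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return _substitute(ref_arr, np.arange(len(ref_arr)), rng)


def compose_cassette(spec: CassetteSpec, seed: int) -> Cassette:
    """Assemble a full repeat cassette from a composition spec.

    Layout (per ``block_side``): block + junction insert + region for
    "left"; region + junction insert + block for "right".  The junction
    insert and any block interruption are random and non-homologous by
    construction (every inserted test base differs from its aligned
    reference base).  Total length = L + block_len + junction_insert_len.

    Each component draws from its own deterministic child stream of
    ``seed``, so the region's sequence is identical whether or not a block
    or insert is present.
    """
    region = generate_test(
        spec.reference, spec.pattern, seed,
        _rng=_component_rng(seed, _STREAM_REGION),
    )
    parts_ref: list[np.ndarray] = []
    parts_test: list[np.ndarray] = []
    parts_mask: list[np.ndarray] = []

    region_ref = np.array(list(region.reference_copy.seq), dtype="U1")
    region_test = np.array(list(region.test_copy.seq), dtype="U1")

    block_ref = block_test = block_mask = None
    if spec.block_len > 0:
        rng_ref = _component_rng(seed, _STREAM_BLOCK_REF)
        block_ref = _random_bases(spec.block_len, rng_ref)
        if isinstance(spec.block_pattern, str):  # perfect
            block_test = block_ref.copy()
            block_mask = np.ones(spec.block_len, dtype=bool)
        else:
            if spec.block_pattern.region_len != spec.block_len:
                raise ValueError(
                    f"block_pattern region_len {spec.block_pattern.region_len} "
                    f"!= block_len {spec.block_len}"
                )
            block_mask = homology_mask(spec.block_pattern)
            block_test = _substitute(
                block_ref, np.flatnonzero(~block_mask),
                _component_rng(seed, _STREAM_BLOCK_SUBS),
            )
        if spec.interruption is not None:
            start, length = spec.interruption
            sl = slice(start - 1, start - 1 + length)
            block_test[sl] = _nonmatching_bases(
                block_ref[sl], _component_rng(seed, _STREAM_INTERRUPTION)
            )
            block_mask[sl] = False

    junction_ref = junction_test = None
    if spec.junction_insert_len > 0:
        rng_j = _component_rng(seed, _STREAM_JUNCTION)
        junction_ref = _random_bases(spec.junction_insert_len, rng_j)
        junction_test = _nonmatching_bases(junction_ref, rng_j)

    def _append(ref, test, mask):
        parts_ref.append(ref)
        parts_test.append(test)
        parts_mask.append(mask)

    junction_mask = np.zeros(spec.junction_insert_len, dtype=bool)
    region_mask = region.homology_mask
    if spec.block_side == "left":
        _append(block_ref, block_test, block_mask)
        if junction_ref is not None:
            _append(junction_ref, junction_test, junction_mask)
        _append(region_ref, region_test, region_mask)
    elif spec.block_side == "right":
        _append(region_ref, region_test, region_mask)
        if junction_ref is not None:
            _append(junction_ref, junction_test, junction_mask)
        _append(block_ref, block_test, block_mask)
    else:
        _append(region_ref, region_test, region_mask)

    full_ref = "".join("".join(p) for p in parts_ref)
    full_test = "".join("".join(p) for p in parts_test)
    full_mask = np.concatenate(parts_mask)
    pat_name = spec.pattern if isinstance(spec.pattern, str) else spec.pattern.name
    name = f"{spec.reference.id}_{pat_name}"
    if spec.block_len:
        name += f"_b{spec.block_len}{spec.block_side[0].upper()}"
    return Cassette(
        DnaSegment(f"{name}_ref", full_ref),
        DnaSegment(f"{name}_test", full_test),
        full_mask,
        {"spec": spec, "seed": seed},
    )
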