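"""Synthetic spore-contig generator with RIP-like mutation structure.

The simulator is phenomenological: it reproduces the observable statistics
of RIP'd spore contigs — C→T and G→A substitutions only, heavy
spore-to-spore variability including complete escapes, and a mutation
density concentrated symmetrically around the cassette center — without
modelling how homology features set mutation intensity.  Each simulated
spore carries its planted ground-truth call set, so the caller, profiler
and statistics can be validated by exact round-trip recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .calling import MutationCallSet, SporeRecord
from .cassette import Cassette
from .patterns import DnaSegment

_log = logging.getLogger(__name__)


def triangular_profile(length: int) -> np.ndarray:
    """Symmetric triangular weight vector peaking at the sequence center.

    Strictly positive everywhere (the edge weight is 2/(L+1) of the peak),
    so every mutable site remains reachable.
    """
    p = np.arange(1, length + 1, dtype=float)
    w = 1.0 - np.abs(2.0 * p - (length + 1)) / (length + 1)
    return w / w.sum()


@dataclass
class RipSimModel:
    """Parameters of the RIP mutagenesis model.

    lambda_mean : float
        Expected mutations per non-escaping spore (Poisson mean).  The
        default 12.5, thinned by the default escape fraction, yields an
        observed mean of 10 mutations per spore — the level of a strongly
        RIP'd 500-bp construct — with a per-spore spread well above
        Poisson, as real crosses show.
    escape_prob : float
        Fraction of spores with no RIP at all (default 0.2).
    spatial_profile : array or None
        Per-position placement weights over the cassette; None selects the
        default center-peaked triangle.
    ct_ga_ratio : float
        Fraction of mutations assigned to the C→T class (the rest are
        G→A); default 0.5.
    indel_rate : float
        Per-position deletion probability emulating sequencing artifacts;
        default 0 (RIP itself makes no indels).
    seed : int
        Base seed for the generator's random stream.
    """

    lambda_mean: float = 12.5
    escape_prob: float = 0.2
    spatial_profile: Optional[np.ndarray] = None
    ct_ga_ratio: float = 0.5
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.escape_prob <= 1.0:
            raise ValueError("escape_prob must be in [0, 1]")
        if not 0.0 <= self.ct_ga_ratio <= 1.0:
            raise ValueError("ct_ga_ratio must be in [0, 1]")
        if self.lambda_mean < 0 or self.indel_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.spatial_profile is not None:
            w = np.asarray(self.spatial_profile, dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("spatial_profile weights must be >= 0 with positive sum")
            self.spatial_profile = w / w.sum()


def _expected_sequence(cassette: Union[Cassette, DnaSegment]) -> DnaSegment:
    return cassette.test_copy if isinstance(cassette, Cassette) else cassette


def _draw_sites(
    rng: np.random.Generator,
    sites: np.ndarray,
    weights: np.ndarray,
    k: int,
    spore_id: str,
    klass: str,
) -> np.ndarray:
    if k > sites.size:
        _log.warning(
            "spore %s: requested %d %s mutations but only %d mutable sites; truncating",
            spore_id, k, klass, sites.size,
        )
        k = sites.size
    if k == 0 or sites.size == 0:
        return np.empty(0, dtype=int)
    p = weights / weights.sum()
    return rng.choice(sites, size=k, replace=False, p=p)


def simulate_spores(
    cassette: Union[Cassette, DnaSegment],
    model: RipSimModel,
    n_spores: int,
    construct_id: str = "SIM",
    cross: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[SporeRecord], list[MutationCallSet]]:
    """Simulate spore contigs of a cassette and their ground-truth calls.

    Each spore independently escapes RIP with probability ``escape_prob``;
    otherwise its mutation count is Poisson(lambda_mean), split between the
    C→T and G→A classes by ``ct_ga_ratio``, and placed without replacement
    among that class's mutable sites (C positions for C→T, G positions for
    G→A) with probabilities proportional to the spatial profile.  Spore ids
    are ``{construct_id}{cross}_{i}``.  Deterministic under the model seed.
    """
    expected = _expected_sequence(cassette)
    length = len(expected)
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(model.seed, spawn_key=(cross,))
        )
    weights = (
        triangular_profile(length)
        if model.spatial_profile is None
        else np.asarray(model.spatial_profile, dtype=float)
    )
    if weights.size != length:
        raise ValueError(
            f"spatial_profile length {weights.size} != cassette length {length}"
        )
    seq_arr = np.array(list(expected.seq), dtype="U1")
    c_sites = np.flatnonzero(seq_arr == "C")  # 0-based
    g_sites = np.flatnonzero(seq_arr == "G")

    spores: list[SporeRecord] = []
    truths: list[MutationCallSet] = []
    for i in range(1, n_spores + 1):
        spore_id = f"{construct_id}{cross}_{i}"
        truth = MutationCallSet(spore_id)
        out = seq_arr.copy()
        if rng.random() >= model.escape_prob:
            k = int(rng.poisson(model.lambda_mean))
            k_ct = int(rng.binomial(k, model.ct_ga_ratio))
            ct_hits = _draw_sites(rng, c_sites, weights[c_sites], k_ct, spore_id, "CT")
            ga_hits = _draw_sites(
                rng, g_sites, weights[g_sites], k - k_ct, spore_id, "GA"
            )
            out[ct_hits] = "T"
            out[ga_hits] = "A"
            truth.positions = sorted(
                [(int(p) + 1, "CT") for p in ct_hits]
                + [(int(p) + 1, "GA") for p in ga_hits]
            )
        if model.indel_rate > 0:
            keep = rng.random(length) >= model.indel_rate
            out_seq = "".join(out[keep])
        else:
            out_seq = "".join(out)
        spores.append(SporeRecord(spore_id, out_seq, construct=construct_id))
        truths.append(truth)
    return spores, truths


@dataclass
class StudyData:
    """An emulated study dataset: contigs, expected sequences, ground truth."""

    contigs: pd.DataFrame  # columns: id, n_CT, n_GA, seq
    constructs: pd.DataFrame  # columns: repeat_id, n_crosses, n_spores, lambda_mean
    expected: dict = field(default_factory=dict)  # repeat_id -> DnaSegment
    truths: dict = field(default_factory=dict)  # spore id -> MutationCallSet

    def write(self, outdir: Union[str, Path]) -> dict:
        """Write the archive-shaped files: contig CSV, per-construct FASTA,
        construct table TSV and planted-call TSV.  Returns the paths."""
        from .io import write_fasta, write_contig_csv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "contigs": outdir / "contigs.csv",
            "constructs": outdir / "constructs.tsv",
            "truth": outdir / "planted_calls.tsv",
        }
        records = [
            SporeRecord(r.id, r.seq, recorded_ct=int(r.n_CT), recorded_ga=int(r.n_GA))
            for r in self.contigs.itertuples()
        ]
        write_contig_csv(records, paths["contigs"])
        self.constructs.to_csv(paths["constructs"], sep="\t", index=False)
        truth_rows = []
        for sid, t in self.truths.items():
            for pos, cls in t.positions:
                truth_rows.append({"spore_id": sid, "position": pos, "class": cls})
        pd.DataFrame(
            truth_rows, columns=["spore_id", "position", "class"]
        ).to_csv(paths["truth"], sep="\t", index=False)
        for rid, seg in self.expected.items():
            p = outdir / f"{rid}_expected.fasta"
            write_fasta([seg], p)
            paths[f"fasta:{rid}"] = p
        return paths


def emulate_study(
    cassettes: dict,
    lambda_table: Optional[dict] = None,
    n_crosses: int = 2,
    n_spores_per_cross: int = 30,
    seed: int = 0,
    model: Optional[RipSimModel] = None,
) -> StudyData:
    """Emulate a whole RIP study over a manifest of constructs.

    ``cassettes`` maps RepeatID -> Cassette (or DnaSegment).  Each
    construct is crossed ``n_crosses`` times with ``n_spores_per_cross``
    spores per cross (the study design: 1-3 replica crosses, >= 30 spores
    each); ``lambda_table`` overrides the model's per-construct mutation
    intensity.  Output has the archive file shapes (4-field contig CSV,
    per-construct expected FASTA, construct table) so the whole pipeline
    can be rehearsed end to end.  Byte-identical under equal seeds.
    """
    base = model or RipSimModel()
    rows, truths, expected, construct_rows = [], {}, {}, []
    for ci, (rid, cassette) in enumerate(sorted(cassettes.items())):
        lam = (lambda_table or {}).get(rid, base.lambda_mean)
        expected[rid] = _expected_sequence(cassette)
        for cross in range(1, n_crosses + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(ci, cross))
            )
            m = RipSimModel(
                lambda_mean=lam,
                escape_prob=base.escape_prob,
                spatial_profile=base.spatial_profile,
                ct_ga_ratio=base.ct_ga_ratio,
                indel_rate=base.indel_rate,
                seed=seed,
            )
            spores, cross_truths = simulate_spores(
                cassette, m, n_spores_per_cross,
                construct_id=rid, cross=cross, rng=rng,
            )
            for s, t in zip(spores, cross_truths):
                rows.append(
                    {"id": s.id, "n_CT": t.n_ct, "n_GA": t.n_ga, "seq": s.seq}
                )
                truths[s.id] = t
        construct_rows.append(
            {
                "repeat_id": rid,
                "n_crosses": n_crosses,
                "n_spores": n_crosses * n_spores_per_cross,
                "lambda_mean": lam,
            }
        )
    return StudyData(
        contigs=pd.DataFrame(rows, columns=["id", "n_CT", "n_GA", "seq"]),
        constructs=pd.DataFrame(construct_rows),
        expected=expected,
        truths=truths,
    )
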