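"""The temperature predictor: pooled IVYWREL fraction and the linear calibration.

The fraction of the residues Ile, Val, Tyr, Trp, Arg, Glu, Leu among all
standard residues of a proteome (F_IVYWREL) is strongly correlated with
prokaryotic optimal growth temperature (OGT), and OGT is predicted by the
linear relation

    OGT [degC] = 937 * F_IVYWREL - 335

Applied to the pooled coding fragments of a whole metagenomic sample,
the same relation yields the metagenomic predicted temperature (MPT):
communities dominated by thermophiles carry a higher pooled IVYWREL
fraction and hence a higher MPT.

Residue counts are pooled across all proteins (length-weighted), not
averaged per protein; non-standard symbols (X, B, Z, U, *, gaps) are
excluded from both numerator and denominator.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.SeqIO.FastaIO import SimpleFastaParser

from . import orf_finder, seqio
from .seqio import FilterStats, SequenceRecord

__all__ = [
    "SLOPE",
    "INTERCEPT",
    "IVYWREL",
    "STANDARD_AA",
    "CompositionSummary",
    "ThermometerReport",
    "InsufficientCodingSignal",
    "pool_composition",
    "mpt_from_f",
    "predict_mpt",
    "predict_ogt_proteome",
    "read_protein_fasta",
]

SLOPE = 937.0  # degC per unit of F_IVYWREL
INTERCEPT = -335.0  # degC at F_IVYWREL = 0

IVYWREL = frozenset("IVYWREL")
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

# Outside this band the linear calibration is extrapolating far beyond
# any observed growth temperature; a warning (never a clamp) is issued.
_CALIBRATION_RANGE = (0.0, 110.0)


class InsufficientCodingSignal(ValueError):
    """Raised when a sample yields no countable residues (no temperature)."""


@dataclass(frozen=True)
class CompositionSummary:
    """Pooled residue counts over the 20 standard amino acids."""

    counts: dict[str, int]
    total: int
    f_ivywrel: float

    @property
    def ivywrel_count(self) -> int:
        return sum(self.counts[a] for a in IVYWREL)


@dataclass(frozen=True)
class ThermometerReport:
    """Per-sample prediction with stage tallies for auditability.

    ``mpt_celsius`` is ``None`` (status ``insufficient coding signal``)
    when the sample produced no countable residues; a temperature is never
    fabricated from an empty composition.
    """

    n_reads_in: int
    n_reads_pass: int
    n_orfs: int
    composition: CompositionSummary
    mpt_celsius: float | None
    status: str = "ok"
    filter_stats: FilterStats | None = None

    def as_dict(self) -> dict:
        return {
            "n_reads_in": self.n_reads_in,
            "n_reads_pass": self.n_reads_pass,
            "n_orfs": self.n_orfs,
            "n_residues": self.composition.total,
            "f_ivywrel": self.composition.f_ivywrel if self.composition.total else None,
            "mpt_celsius": self.mpt_celsius,
            "status": self.status,
        }


def pool_composition(proteins: Iterable[str]) -> CompositionSummary:
    """Pool residue counts across all proteins and compute F_IVYWREL.

    Pooling is length-weighted: ``["IV", "GGGGGG"]`` gives f = 2/8, not
    the per-protein mean (1.0 + 0.0)/2. Symbols outside the 20 standard
    residues ('X', '*', 'B', 'Z', 'U', gaps, ...) are ignored entirely.
    An empty stream yields total = 0 and f_ivywrel = 0.0.
    """
    raw: Counter[str] = Counter()
    for protein in proteins:
        raw.update(protein.upper())
    counts = {aa: raw.get(aa, 0) for aa in sorted(STANDARD_AA)}
    total = sum(counts.values())
    if total:
        f = sum(counts[a] for a in IVYWREL) / total
    else:
        f = 0.0
    return CompositionSummary(counts=counts, total=total, f_ivywrel=f)


def mpt_from_f(f: float) -> float:
    """Apply the linear OGT/MPT calibration: 937 * f - 335 degC."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"F_IVYWREL must lie in [0, 1], got {f}")
    return SLOPE * f + INTERCEPT


def _finish(
    composition: CompositionSummary,
    n_in: int,
    n_pass: int,
    n_orfs: int,
    stats: FilterStats | None,
) -> ThermometerReport:
    if composition.total == 0:
        return ThermometerReport(
            n_reads_in=n_in,
            n_reads_pass=n_pass,
            n_orfs=n_orfs,
            composition=composition,
            mpt_celsius=None,
            status="insufficient coding signal",
            filter_stats=stats,
        )
    mpt = mpt_from_f(composition.f_ivywrel)
    if not _CALIBRATION_RANGE[0] <= mpt <= _CALIBRATION_RANGE[1]:
        warnings.warn(
            f"MPT {mpt:.2f} degC is outside the calibration regime "
            f"{_CALIBRATION_RANGE}; the linear relation is extrapolating",
            stacklevel=3,
        )
    return ThermometerReport(
        n_reads_in=n_in,
        n_reads_pass=n_pass,
        n_orfs=n_orfs,
        composition=composition,
        mpt_celsius=mpt,
        filter_stats=stats,
    )


def predict_mpt(
    reads: Iterable[SequenceRecord],
    min_len: int = 50,
    max_n: int = 1,
    min_aa: int = 20,
    orf_mode: str = "fragment",
    frame_policy: str = "unique",
    exclude_ids: frozenset[str] | set[str] | None = None,
) -> ThermometerReport:
    """End-to-end metagenomic predicted temperature for one read stream.

    Pipeline: optional id-based exclusion -> quality filter (length,
    N count) -> six-frame ORF extraction -> pooled composition -> linear
    calibration. Zero countable residues is a result, not an error: the
    report carries status ``insufficient coding signal`` and no
    temperature.

    ``frame_policy`` controls which of a read's six frames contribute
    residues. The default ``'unique'`` keeps a read only when exactly one
    frame contains no stop codon and pools that frame's fragments;
    ambiguous reads (zero or several stop-free frames) contribute
    nothing. ``'all'`` pools every fragment from every frame. The
    ``'all'`` policy systematically drags the pooled IVYWREL fraction
    toward the near-constant composition of shuffled coding frames
    (several tens of degC of bias on warm communities), because
    out-of-frame fragments are not a uniform background; ``'unique'``
    removes that bias at the cost of discarding frame-ambiguous reads.
    """
    if frame_policy not in {"unique", "all"}:
        raise ValueError(f"frame_policy must be 'unique' or 'all', got {frame_policy!r}")
    stream: Iterable[SequenceRecord] = reads
    if exclude_ids:
        stream = seqio.exclude_by_id(stream, exclude_ids)
    passed, stats = seqio.quality_filter(stream, min_len=min_len, max_n=max_n)
    raw: Counter[str] = Counter()
    n_orfs = 0
    for rec in passed:
        calls = orf_finder.find_orfs(rec, min_aa=min_aa, mode=orf_mode)
        if frame_policy == "unique":
            frames = orf_finder.stop_free_frames(rec.seq)
            if len(frames) != 1:
                continue
            calls = [c for c in calls if (c.strand, c.frame) == frames[0]]
        for call in calls:
            n_orfs += 1
            raw.update(call.protein)
    counts = {aa: raw.get(aa, 0) for aa in sorted(STANDARD_AA)}
    total = sum(counts.values())
    f = sum(counts[a] for a in IVYWREL) / total if total else 0.0
    composition = CompositionSummary(counts=counts, total=total, f_ivywrel=f)
    return _finish(composition, stats.n_in, stats.n_pass, n_orfs, stats)


def predict_proteins(proteins: Iterable[str]) -> ThermometerReport:
    """Temperature prediction for a pre-translated protein stream (QC/ORF skipped)."""
    proteins = list(proteins)
    composition = pool_composition(proteins)
    return _finish(composition, 0, 0, len(proteins), None)


def read_protein_fasta(path: str | Path) -> list[str]:
    """Read an amino-acid FASTA (gzip transparent) into a list of sequences."""
    with seqio._open_text(path) as handle:
        return [seq.upper().replace("*", "") for _, seq in SimpleFastaParser(handle)]


def predict_ogt_proteome(proteins: Iterable[str] | str | Path) -> float:
    """Predicted optimal growth temperature for one species' proteome.

    Accepts a path to a coding-sequence amino-acid FASTA or an iterable of
    protein strings; pools composition over all coding sequences and
    applies the linear calibration. An empty proteome is an error — a
    genome-level prediction from zero residues is meaningless.
    """
    if isinstance(proteins, (str, Path)):
        proteins = read_protein_fasta(proteins)
    composition = pool_composition(proteins)
    if composition.total == 0:
        raise InsufficientCodingSignal("proteome contains no countable residues")
    return mpt_from_f(composition.f_ivywrel)
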