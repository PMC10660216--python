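"""Synthetic proteomes, coding sequences and shotgun reads with known truth.

Generates communities whose pooled IVYWREL fraction (equivalently, whose
predicted temperature) is prescribed, so every pipeline stage can be
tested against a known answer without downloading sequence data:

1. :func:`make_proteome` draws proteins whose pooled residue composition
   hits the target fraction to the nearest achievable count;
2. :func:`reverse_translate` maps each protein to a coding sequence under
   the bacterial genetic code with uniform synonymous-codon choice;
3. :func:`shred_to_reads` samples fixed-length substrings at a target
   coverage, optionally injecting ambiguous bases (N) at a per-base rate.

Defaults emulate the study conditions the pipeline targets: 181 bp reads
(the average read length of the hot-water-canal shotgun data), 200 genes
of 150 aa, 5x coverage, no N injection. All randomness derives from the
spec seed; runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from . import thermometer
from .orf_finder import translate
from .seqio import SequenceRecord

__all__ = [
    "CommunitySpec",
    "SyntheticCommunity",
    "make_proteome",
    "reverse_translate",
    "shred_to_reads",
    "make_community",
]

# Table-11 synonymous codons per residue, stop codons excluded by
# construction so no in-frame internal stop can arise.
_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(unambiguous_dna_by_id[11].forward_table.items()):
    _CODONS[_aa] = _CODONS.get(_aa, ()) + (_codon,)

_IVYWREL = tuple(sorted(thermometer.IVYWREL))
_OTHER13 = tuple(sorted(thermometer.STANDARD_AA - thermometer.IVYWREL))


@dataclass(frozen=True)
class CommunitySpec:
    """Recipe for one synthetic community.

    Exactly one of ``target_temp`` (degC) or ``target_f`` may be given;
    they are interconvertible through the linear calibration
    f = (T + 335)/937, so the implied temperature range is [-335, 602].
    """

    target_temp: float | None = None
    target_f: float | None = None
    n_genes: int = 200
    gene_len_aa: int = 150
    read_len: int = 181
    coverage: float = 5.0
    n_rate: float = 0.0
    seed: int = 0
    allow_short_reads: bool = False

    def __post_init__(self) -> None:
        if (self.target_temp is None) == (self.target_f is None):
            raise ValueError("give exactly one of target_temp or target_f")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(
                f"target fraction {self.f:.4f} outside [0, 1] "
                "(temperature outside [-335, 602] degC)"
            )
        if self.n_genes < 1 or self.gene_len_aa < 1:
            raise ValueError("n_genes and gene_len_aa must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.n_rate <= 1.0:
            raise ValueError("n_rate must lie in [0, 1]")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")

    @property
    def f(self) -> float:
        """Target pooled IVYWREL fraction."""
        if self.target_f is not None:
            return self.target_f
        return (self.target_temp - thermometer.INTERCEPT) / thermometer.SLOPE

    @property
    def temp(self) -> float:
        """Target temperature in degC."""
        if self.target_temp is not None:
            return self.target_temp
        return thermometer.mpt_from_f(self.target_f)


@dataclass(frozen=True)
class SyntheticCommunity:
    """Generated community plus ground truth for assertions."""

    spec: CommunitySpec
    proteins: tuple[str, ...]
    cds: tuple[str, ...]
    achieved_f: float

    @property
    def achieved_temp(self) -> float:
        return thermometer.mpt_from_f(self.achieved_f)

    def manifest(self) -> dict:
        return {
            "target_temp": self.spec.temp,
            "target_f": self.spec.f,
            "achieved_f": self.achieved_f,
            "achieved_temp": self.achieved_temp,
            "n_genes": self.spec.n_genes,
            "gene_len_aa": self.spec.gene_len_aa,
            "read_len": self.spec.read_len,
            "coverage": self.spec.coverage,
            "n_rate": self.spec.n_rate,
            "seed": self.spec.seed,
        }


def _rng(spec: CommunitySpec, stage: int) -> np.random.Generator:
    # Independent streams per stage, all derived from the spec seed.
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stage]))


def make_proteome(spec: CommunitySpec) -> tuple[list[str], float]:
    """Draw ``n_genes`` proteins of ``gene_len_aa`` residues each.

    The pooled IVYWREL count is ``round(target_f * total)``, so the pooled
    fraction equals the target exactly whenever ``target_f * total`` is an
    integer and is otherwise off by at most ``1/(2*total)``. IVYWREL
    positions draw uniformly among the 7 residues, the rest uniformly
    among the other 13. Returns (proteins, achieved pooled fraction).
    """
    rng = _rng(spec, 0)
    total = spec.n_genes * spec.gene_len_aa
    k = int(round(spec.f * total))
    residues = np.concatenate([
        rng.choice(_IVYWREL, size=k),
        rng.choice(_OTHER13, size=total - k),
    ])
    rng.shuffle(residues)
    flat = "".join(residues)
    proteins = [
        flat[i * spec.gene_len_aa : (i + 1) * spec.gene_len_aa]
        for i in range(spec.n_genes)
    ]
    return proteins, k / total


def reverse_translate(protein: str, seed: int) -> str:
    """Back-translate a protein to a table-11 CDS with uniform codon choice.

    Each residue maps to a uniformly chosen synonymous codon; a terminal
    TAA stop is appended. Stop codons never occur mid-frame because only
    sense codons are drawn. ``translate(result)`` equals ``protein + '*'``
    with the stop, i.e. the coding part round-trips exactly.
    """
    rng = np.random.default_rng(seed)
    codons = []
    for residue in protein:
        try:
            options = _CODONS[residue]
        except KeyError:
            raise ValueError(f"invalid residue {residue!r}") from None
        codons.append(options[rng.integers(len(options))])
    codons.append("TAA")
    cds = "".join(codons)
    assert translate(cds)[:-1] == protein
    return cds


def shred_to_reads(
    cds_list: list[str] | tuple[str, ...], spec: CommunitySpec
) -> Iterator[SequenceRecord]:
    """Sample shotgun-style reads from coding sequences.

    Per CDS the read count is Poisson with mean coverage*L/read_len (so
    expected sampled bases per position equal the coverage), positions are
    uniform, and each base is independently replaced by N with probability
    ``n_rate``. Read ids encode source gene and offset for traceability.
    CDS shorter than the read length are skipped unless
    ``allow_short_reads`` is set, in which case the whole CDS is emitted.
    """
    rng = _rng(spec, 2)
    for gene_idx, cds in enumerate(cds_list):
        length = len(cds)
        if length < spec.read_len and not spec.allow_short_reads:
            continue
        read_len = min(spec.read_len, length)
        n_reads = rng.poisson(spec.coverage * length / read_len)
        if n_reads == 0:
            continue
        positions = rng.integers(0, length - read_len + 1, size=n_reads)
        for read_idx, pos in enumerate(positions):
            fragment = cds[pos : pos + read_len]
            if spec.n_rate > 0:
                mask = rng.random(read_len) < spec.n_rate
                if mask.any():
                    chars = np.frombuffer(fragment.encode(), dtype="S1").copy()
                    chars[mask] = b"N"
                    fragment = chars.tobytes().decode()
            yield SequenceRecord(
                id=f"g{gene_idx}_r{read_idx}_pos{pos}", seq=fragment
            )


def make_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Full truth-carrying community: proteome, CDS set, achieved fraction."""
    proteins, achieved_f = make_proteome(spec)
    cds_rng = _rng(spec, 1)
    cds = tuple(
        reverse_translate(p, int(cds_rng.integers(2**31))) for p in proteins
    )
    return SyntheticCommunity(
        spec=spec, proteins=tuple(proteins), cds=cds, achieved_f=achieved_f
    )
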