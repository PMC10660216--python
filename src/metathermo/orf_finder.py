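"""Six-frame extraction of candidate coding fragments from short reads.

Shotgun metagenomic reads (~181 bp on average) rarely span a complete
gene, so the default *fragment* mode emits every maximal in-frame stretch
between stop codons (or read edges) of at least ``min_aa`` residues,
recording whether the stretch happens to begin at a start codon or end at
a stop. *Complete* mode keeps only stretches that both begin at a start
codon and end at a stop codon. This is a deliberately simple,
deterministic stand-in for a trained metagenomic gene predictor: it has
no coding-potential model, so it also emits spurious stretches from
non-coding frames; downstream composition pooling absorbs these and the
effect is quantified in the package docs.

Translation uses the bacterial/archaeal genetic code (NCBI table 11);
codons containing ambiguous bases translate to ``X``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .seqio import SequenceRecord

__all__ = ["OrfCall", "translate", "find_orfs", "revcomp", "orf_fasta_header"]

_TABLE11 = unambiguous_dna_by_id[11]
_CODON_TO_AA: dict[str, str] = dict(_TABLE11.forward_table)
_CODON_TO_AA.update({c: "*" for c in _TABLE11.stop_codons})
STOP_CODONS = frozenset(_TABLE11.stop_codons)  # {TAA, TAG, TGA}
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class OrfCall:
    """One predicted coding fragment on a read.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    FORWARD strand of the read regardless of ``strand``; when ``has_stop``
    is set the coordinates include the stop codon but the stop is not
    translated. ``frame`` is the offset (0..2) on the scanned strand.
    """

    parent_id: str
    strand: str  # '+' or '-'
    frame: int
    start: int
    end: int
    protein: str
    has_start: bool
    has_stop: bool

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a multiple of 3")
        if "*" in self.protein:
            raise ValueError("translated ORF must not contain internal stops")
        expected = (self.end - self.start) // 3 - (1 if self.has_stop else 0)
        if len(self.protein) != expected:
            raise ValueError(
                f"protein length {len(self.protein)} inconsistent with span "
                f"{self.start}-{self.end} (has_stop={self.has_stop})"
            )


def translate(codons: str, table: int = 11) -> str:
    """Translate an in-frame nucleotide string.

    Sense codons follow the requested genetic code (default: bacterial
    table 11); stop codons yield ``*`` (callers split/strip); any codon
    containing an ambiguous base yields ``X``. No start-codon remapping is
    done here — :func:`find_orfs` rewrites the initial residue to M only
    for stretches that begin at a start codon.
    """
    if len(codons) % 3 != 0:
        raise ValueError(f"length {len(codons)} is not a multiple of 3")
    if table == 11:
        lookup = _CODON_TO_AA
    else:
        tbl = unambiguous_dna_by_id[table]
        lookup = dict(tbl.forward_table)
        lookup.update({c: "*" for c in tbl.stop_codons})
    return "".join(
        lookup.get(codons[i : i + 3], "X") for i in range(0, len(codons), 3)
    )


def find_orfs(
    record: SequenceRecord,
    min_aa: int = 20,
    mode: str = "fragment",
    starts: frozenset[str] | set[str] = DEFAULT_START_CODONS,
) -> list[OrfCall]:
    """Scan all six frames of a read for coding stretches.

    In ``fragment`` mode every maximal in-frame stretch between stop codons
    (or read edges) with at least ``min_aa`` translated residues is
    emitted; ``complete`` mode restricts to stretches that begin at a start
    codon and end at a stop codon. The initial codon of a has_start stretch
    translates to M (bacterial alternative starts GTG/TTG included).
    Output is sorted by (start, strand, frame).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if mode not in {"fragment", "complete"}:
        raise ValueError(f"mode must be 'fragment' or 'complete', got {mode!r}")
    starts = frozenset(starts)
    seq = record.seq
    length = len(seq)
    calls: list[OrfCall] = []
    for strand in "+-":
        scanned = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            n_codons = (length - frame) // 3
            begin = 0  # codon index of current stretch start
            for idx in range(n_codons + 1):
                at_edge = idx == n_codons
                codon = None if at_edge else scanned[frame + 3 * idx : frame + 3 * idx + 3]
                if at_edge or codon in STOP_CODONS:
                    call = _emit(
                        record.id, scanned, length, strand, frame,
                        begin, idx, has_stop=not at_edge,
                        min_aa=min_aa, starts=starts,
                    )
                    if call is not None and (
                        mode == "fragment" or (call.has_start and call.has_stop)
                    ):
                        calls.append(call)
                    begin = idx + 1
    calls.sort(key=lambda c: (c.start, c.strand, c.frame))
    return calls


def _emit(
    parent_id: str,
    scanned: str,
    length: int,
    strand: str,
    frame: int,
    begin: int,
    end_codon: int,
    has_stop: bool,
    min_aa: int,
    starts: frozenset[str],
) -> OrfCall | None:
    n_aa = end_codon - begin
    if n_aa < min_aa:
        return None
    nt_start = frame + 3 * begin
    nt_end = frame + 3 * end_codon + (3 if has_stop else 0)
    stretch = scanned[nt_start : frame + 3 * end_codon]
    first_codon = stretch[:3]
    has_start = first_codon in starts
    protein = translate(stretch)
    if has_start:
        protein = "M" + protein[1:]
    if strand == "-":
        fwd_start, fwd_end = length - nt_end, length - nt_start
    else:
        fwd_start, fwd_end = nt_start, nt_end
    return OrfCall(
        parent_id=parent_id,
        strand=strand,
        frame=frame,
        start=fwd_start,
        end=fwd_end,
        protein=protein,
        has_start=has_start,
        has_stop=has_stop,
    )


def stop_free_frames(seq: str) -> list[tuple[str, int]]:
    """(strand, frame) pairs with no in-frame stop codon anywhere in the read.

    A read lying wholly inside a protein-coding gene is stop-free in its
    true frame, and a read spanning a gene end sees the terminal stop as
    the frame's *last* codon — so a stop codon in final position does not
    disqualify a frame. Shuffled frames of coding sequence instead
    accumulate internal stops at roughly one per ~20 codons. A read whose
    plausible frame is *unique* can therefore be assigned a coding frame
    with high confidence, which is the basis of the default
    frame-disambiguation policy of ``predict_mpt``
    (see ``frame_policy='unique'`` there).
    """
    frames: list[tuple[str, int]] = []
    length = len(seq)
    for strand in "+-":
        scanned = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            last = frame + 3 * ((length - frame) // 3 - 1)
            internal_stop = any(
                scanned[i : i + 3] in STOP_CODONS
                for i in range(frame, last, 3)
            )
            if not internal_stop and length - frame >= 3:
                frames.append((strand, frame))
    return frames


def orf_fasta_header(call: OrfCall) -> str:
    """FASTA header for a translated ORF: parent|strand|frame|start-end|flags."""
    flags = ("S" if call.has_start else "-") + ("E" if call.has_stop else "-")
    return f"{call.parent_id}|{call.strand}|{call.frame}|{call.start}-{call.end}|{flags}"


def write_orf_fasta(calls: Iterable[OrfCall], path) -> int:
    """Write translated ORFs as an amino-acid FASTA; returns the count."""
    n = 0
    with open(path, "w") as out:
        for call in calls:
            out.write(f">{orf_fasta_header(call)}\n{call.protein}\n")
            n += 1
    return n


def orfs_to_proteins(
    records: Iterable[SequenceRecord],
    min_aa: int = 20,
    mode: str = "fragment",
) -> Iterator[tuple[OrfCall, str]]:
    """Yield (call, protein) over all ORFs of a record stream."""
    for rec in records:
        for call in find_orfs(rec, min_aa=min_aa, mode=mode):
            yield call, call.protein
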