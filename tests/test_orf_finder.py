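"""Six-frame coding-fragment extraction, checked against a brute-force oracle.

The oracle enumerates every in-frame codon window on both strands and
keeps exactly the maximal stop-free windows of sufficient length,
translating each codon independently through Biopython's ``Seq`` — a
separate route from the implementation's stretch-splitting scan.
"""

import random

import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from metathermo.orf_finder import (
    DEFAULT_START_CODONS,
    OrfCall,
    find_orfs,
    revcomp,
    stop_free_frames,
    translate,
)
from metathermo.seqio import SequenceRecord

STOPS = {"TAA", "TAG", "TGA"}


def _oracle_translate_codon(codon):
    if set(codon) - set("ACGT"):
        return "X"
    return str(Seq(codon).translate(table=11))


def oracle_orfs(seq, min_aa=20, mode="fragment", starts=DEFAULT_START_CODONS):
    """All maximal stop-free in-frame windows, by direct enumeration."""
    length = len(seq)
    found = set()
    for strand, scanned in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            codons = [
                scanned[i : i + 3] for i in range(frame, length - 2, 3)
            ]
            n = len(codons)
            for begin in range(n):
                if begin > 0 and codons[begin - 1] not in STOPS:
                    continue  # not left-maximal
                end = begin
                while end < n and codons[end] not in STOPS:
                    end += 1
                # window [begin, end) is stop-free and right-maximal
                n_aa = end - begin
                if n_aa < max(min_aa, 1) or n_aa == 0:
                    continue
                has_stop = end < n
                has_start = codons[begin] in starts
                protein = "".join(_oracle_translate_codon(c) for c in codons[begin:end])
                if has_start:
                    protein = "M" + protein[1:]
                nt_start = frame + 3 * begin
                nt_end = frame + 3 * end + (3 if has_stop else 0)
                if strand == "-":
                    nt_start, nt_end = length - nt_end, length - nt_start
                if mode == "complete" and not (has_start and has_stop):
                    continue
                found.add(
                    (strand, frame, nt_start, nt_end, protein, has_start, has_stop)
                )
    return found


def _as_set(calls):
    return {
        (c.strand, c.frame, c.start, c.end, c.protein, c.has_start, c.has_stop)
        for c in calls
    }


class TestTranslate:
    @pytest.mark.parametrize(
        "codons,expected",
        [
            ("ATGAAA", "MK"),
            ("ATGNNNAAA", "MXK"),
            ("GTGAAA", "VK"),  # GTG is V mid-frame; M only at an ORF start
            ("TAATAGTGA", "***"),
        ],
    )
    def test_table11_and_ambiguity(self, codons, expected):
        assert translate(codons) == expected

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            translate("ACGTA")


class TestFindOrfs:
    COMPLETE = "ATG" + "GCT" * 60 + "TAA"

    def test_complete_gene_forward(self):
        rec = SequenceRecord(id="r", seq=self.COMPLETE)
        calls = find_orfs(rec, min_aa=20, mode="complete")
        assert len(calls) == 1
        (call,) = calls
        assert call.protein == "M" + "A" * 60
        assert (call.start, call.end) == (0, 186)
        assert call.has_start and call.has_stop and call.strand == "+"

    def test_complete_gene_on_reverse_strand_maps_to_forward_coords(self):
        rec = SequenceRecord(id="r", seq=revcomp(self.COMPLETE))
        calls = find_orfs(rec, min_aa=20, mode="complete")
        assert len(calls) == 1
        (call,) = calls
        assert call.strand == "-"
        assert call.protein == "M" + "A" * 60
        assert (call.start, call.end) == (0, 186)

    def test_gtg_start_translates_to_m_only_with_has_start(self):
        rec = SequenceRecord(id="r", seq="GTG" + "AAA" * 25 + "TAA")
        (call,) = find_orfs(rec, min_aa=20, mode="complete")
        assert call.has_start and call.protein.startswith("M")

    def test_edge_truncated_fragment_flags(self, rng):
        # stop-free frame-0 sequence: fragment mode emits it without start/stop
        seq = "".join(rng.choice(["GCT", "GAA", "CTT", "ATT"]) for _ in range(33))
        calls = [
            c for c in find_orfs(SequenceRecord(id="r", seq=seq), min_aa=20)
            if c.strand == "+" and c.frame == 0
        ]
        assert any(not c.has_start and not c.has_stop and c.start == 0 for c in calls)

    def test_invalid_params_rejected(self):
        rec = SequenceRecord(id="r", seq="ACGT")
        with pytest.raises(ValueError):
            find_orfs(rec, min_aa=0)
        with pytest.raises(ValueError):
            find_orfs(rec, mode="prodigal")

    def test_sorted_by_start_then_strand_then_frame(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        calls = find_orfs(SequenceRecord(id="r", seq=seq), min_aa=5)
        keys = [(c.start, c.strand, c.frame) for c in calls]
        assert keys == sorted(keys)


@st.composite
def dna(draw, max_len=300):
    return draw(
        st.text(alphabet="ACGTN", min_size=1, max_size=max_len)
    )


class TestOracleEquivalence:
    @given(dna(), st.sampled_from([1, 5, 20]), st.sampled_from(["fragment", "complete"]))
    def test_matches_bruteforce_enumeration(self, seq, min_aa, mode):
        rec = SequenceRecord(id="r", seq=seq)
        assert _as_set(find_orfs(rec, min_aa=min_aa, mode=mode)) == oracle_orfs(
            seq, min_aa=min_aa, mode=mode
        )

    @given(dna())
    def test_strand_symmetry(self, seq):
        rec_f = SequenceRecord(id="r", seq=seq)
        rec_r = SequenceRecord(id="r", seq=revcomp(seq))
        flipped = {
            (("-" if s == "+" else "+"), f, len(seq) - e, len(seq) - b, p, st_, sp)
            for s, f, b, e, p, st_, sp in _as_set(find_orfs(rec_f, min_aa=5))
        }
        # frames renumber under reverse complement; compare frame-insensitively
        strip = lambda items: {(s, b, e, p, st_, sp) for s, f, b, e, p, st_, sp in items}
        assert strip(flipped) == strip(_as_set(find_orfs(rec_r, min_aa=5)))

    @given(dna(), st.sampled_from([5, 20]))
    def test_complete_subset_of_fragment_and_no_stops(self, seq, min_aa):
        rec = SequenceRecord(id="r", seq=seq)
        fragment = _as_set(find_orfs(rec, min_aa=min_aa, mode="fragment"))
        complete = _as_set(find_orfs(rec, min_aa=min_aa, mode="complete"))
        assert complete <= fragment
        for call in find_orfs(rec, min_aa=min_aa):
            assert len(call.protein) >= min_aa
            assert "*" not in call.protein


class TestStopFreeFrames:
    def test_coding_read_has_its_frame(self):
        seq = ("ATG" + "GCTGAAATTCTT" * 10)[:100]
        assert ("+", 0) in stop_free_frames(seq)

    def test_all_stop_frame_absent(self):
        seq = "TAA" * 30
        assert ("+", 0) not in stop_free_frames(seq)


class TestOrfCallInvariants:
    def test_span_protein_consistency_enforced(self):
        with pytest.raises(ValueError):
            OrfCall(
                parent_id="r", strand="+", frame=0, start=0, end=9,
                protein="MK", has_start=True, has_stop=False,
            )

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            OrfCall(
                parent_id="r", strand="+", frame=0, start=0, end=9,
                protein="M*K", has_start=True, has_stop=False,
            )


def test_orf_fasta_output_headers_carry_provenance(tmp_path):
    from metathermo.orf_finder import write_orf_fasta

    rec = SequenceRecord(id="read1", seq="ATG" + "GCT" * 60 + "TAA")
    calls = find_orfs(rec, min_aa=20, mode="complete")
    path = tmp_path / "orfs.faa"
    assert write_orf_fasta(calls, path) == 1
    header, protein = path.read_text().strip().splitlines()
    assert header == ">read1|+|0|0-186|SE"
    assert protein == "M" + "A" * 60
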