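"""IsomiR decomposition: lenient mapping, selection, tail calling, thresholds."""

import pandas as pd
import pytest

from mirtail.isomir import (
    ReferenceIndex,
    apply_count_threshold,
    call_isomir,
    call_sample,
    classify_tail,
    reconstruct_read,
    select_alignment,
)
from mirtail.preprocess import preprocess_sample
from mirtail.refio import CollapsedRead, HairpinRecord, MatureAnnotation
from mirtail.simulate import TRUSEQ_ADAPTER

from conftest import records_of

MAT = "ATGCCGTAGCATGCGATCGGTC"  # 22 nt


def hairpin_with_downstream(downstream, hairpin_id="hp-1", mirna_id="mir-x"):
    """Mature at [20, 42) followed by ``downstream``, padded to >= 40 nt."""
    seq = "GGGGCCCCGGGGCCCCGGGG" + MAT + downstream + "GGCCGGCCGGCCGGCCGGCC"
    return HairpinRecord(
        hairpin_id, seq, [MatureAnnotation(mirna_id, "5p", 20, 42, MAT)]
    ).validate()


def call_read(read, index):
    aln = select_alignment(index.map_lenient(read), index)
    return call_isomir(read, aln, index) if aln is not None else None


class TestMapLenient:
    def test_exact_read_aligns_without_mismatches(self):
        index = ReferenceIndex([hairpin_with_downstream("CAG")])
        (aln,) = [a for a in index.map_lenient(MAT) if a.start == 20]
        assert (aln.t5, aln.t3, aln.n_interior) == (0, 0, 0)

    def test_terminal_tt_reported_as_trailing_mismatches(self):
        index = ReferenceIndex([hairpin_with_downstream("CAG")])
        hits = [a for a in index.map_lenient(MAT + "TT") if a.start == 20]
        assert hits and hits[0].t3 == 2 and hits[0].n_interior == 0

    def test_three_scattered_mismatches_rejected(self):
        index = ReferenceIndex([hairpin_with_downstream("CAG")])
        read = list(MAT)
        for pos in (5, 10, 15):
            read[pos] = "A" if read[pos] != "A" else "C"
        assert [a for a in index.map_lenient("".join(read)) if a.start == 20] == []

    def test_overhang_beyond_hairpin_end_is_candidate_tail(self):
        hp = hairpin_with_downstream("CAG")
        # read runs to the very end of the hairpin and 3 nt beyond
        read = hp.sequence[-15:] + "TTT"
        index = ReferenceIndex([hp])
        hits = [a for a in index.map_lenient(read) if a.start == len(hp.sequence) - 15]
        assert hits and hits[0].t3 == 3


class TestSelectAlignment:
    def test_fewest_mismatches_preferred(self):
        hp1 = hairpin_with_downstream("CAG", "hp-1", "mir-1")
        # second hairpin shares the mature with 2 substitutions
        mutated = MAT[:5] + "A" + MAT[6:15] + "C" + MAT[16:]
        assert mutated != MAT
        hp2 = HairpinRecord(
            "hp-2",
            "GGGGCCCCGGGGCCCCGGGG" + mutated + "CAGGGCCGGCCGGCCGGCCGGCC",
            [MatureAnnotation("mir-2", "5p", 20, 42, mutated)],
        ).validate()
        index = ReferenceIndex([hp1, hp2])
        best = select_alignment(index.map_lenient(MAT), index)
        assert best.hairpin_id == "hp-1" and best.n_interior == 0

    def test_no_alignments_returns_none(self):
        index = ReferenceIndex([hairpin_with_downstream("CAG")])
        assert select_alignment([], index) is None


class TestCallIsomir:
    @pytest.mark.parametrize(
        "read,downstream,expected",
        [
            # pure nontemplated tail
            (MAT + "TTT", "CAG", (0, "TTT", "U")),
            # maximal-templated rule: first tail base matches template C
            (MAT + "CTT", "CAG", (1, "TT", "U")),
            # greedy tie-break toward the template: downstream AG, tail AA
            (MAT + "AA", "AGG", (1, "A", "A")),
            # 3' trimming, no tail
            (MAT[:-2], "CAG", (-2, "", "none")),
            # templated extension only
            (MAT + "CA", "CAG", (2, "", "none")),
            # mixed tail
            (MAT + "TA", "CCG", (0, "TA", "mixed")),
        ],
    )
    def test_three_prime_decomposition(self, read, downstream, expected):
        index = ReferenceIndex([hairpin_with_downstream(downstream)])
        call = call_read(read, index)
        assert (call.three_templated_offset, call.nta3, call.tail_class) == expected
        assert call.five_offset == 0

    def test_five_prime_trim_and_addition(self):
        index = ReferenceIndex([hairpin_with_downstream("CAG")])
        call = call_read(MAT[3:], index)
        assert call.five_offset == 3 and call.nta5 == ""
        # leading nontemplated base (template has G at position 19)
        call = call_read("T" + MAT, index)
        assert call.five_offset == 0 and call.nta5 == "T"

    def test_interior_mismatch_far_from_ends_discards_read(self):
        index = ReferenceIndex([hairpin_with_downstream("CAG")])
        read = MAT[:10] + ("A" if MAT[10] != "A" else "C") + MAT[11:]
        assert call_read(read, index) is None

    def test_reconstruction_identity_on_simulated_reads(self, sim_reference, sim_study):
        samples, _ = sim_study
        index = ReferenceIndex(sim_reference)
        matures = {m.mirna_id: (hp, m) for hp in sim_reference for m in hp.matures}
        reads, _ = preprocess_sample(
            records_of(samples[0]), TRUSEQ_ADAPTER, sample_id=samples[0].sample_id
        )
        n_checked = 0
        for read in reads[:400]:
            aln = select_alignment(index.map_lenient(read.sequence), index)
            if aln is None:
                continue
            call = call_isomir(read.sequence, aln, index)
            if call is None:
                continue
            hp, m = matures[call.mirna_id]
            assert reconstruct_read(call, hp, m) == read.sequence
            n_checked += 1
        assert n_checked > 100

    def test_confusion_with_ground_truth_is_diagonal(self, sim_reference, sim_study):
        """Called isoform classes match the simulator's provenance exactly
        when no sequencing errors are injected."""
        samples, truth = sim_study
        sample = samples[0]
        index = ReferenceIndex(sim_reference)
        for seq, count, meta in sample.records:
            if meta["is_fragment"]:
                continue
            insert = seq[: -len(TRUSEQ_ADAPTER)]
            call = call_read(insert, index)
            assert call is not None, insert
            assert call.mirna_id == meta["mirna_id"]
            assert call.three_templated_offset == meta["three_offset"]
            assert call.tail_class == meta["tail_class"]
            assert len(call.nta3) == meta["tail_len"]


class TestCountThreshold:
    def frame(self, rows):
        cols = [
            "mirna_id",
            "arm",
            "five_offset",
            "three_templated_offset",
            "nta5",
            "nta3",
            "tail_class",
            "read_len",
            "count",
        ]
        rows = [(*r[:-1], 22, r[-1]) for r in rows]
        return pd.DataFrame(rows, columns=cols)

    def test_threshold_boundary(self):
        calls = self.frame(
            [
                ("m1", "5p", 0, 0, "", "T", "U", 1),  # dropped: total 1
                ("m2", "5p", 0, 0, "", "TT", "U", 2),  # kept: exactly 2
            ]
        )
        out = apply_count_threshold(calls, 2)
        assert list(out["mirna_id"]) == ["m2"]

    def test_signatures_sum_before_thresholding(self):
        calls = self.frame(
            [
                ("m1", "5p", 0, 0, "", "T", "U", 1),
                ("m1", "5p", 0, 0, "", "T", "U", 1),
            ]
        )
        out = apply_count_threshold(calls, 2)
        assert len(out) == 1 and out.loc[0, "count"] == 2


def test_classify_tail():
    assert classify_tail("") == "none"
    assert classify_tail("TTT") == "U"
    assert classify_tail("AA") == "A"
    assert classify_tail("TAT") == "mixed"
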