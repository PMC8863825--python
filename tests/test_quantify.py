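"""Read processing: trimming, collapsing, precursor-space mapping with
best-stratum 1/N weighting, arm assignment and fractional counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirnapipe import (
    Alignment,
    CollapsedRead,
    SimDesign,
    assign_arm,
    collapse,
    count,
    generate_reference,
    map_reads,
    simulate_counts,
    trim_and_filter,
    write_fastq,
)
from mirnapipe.quantify import PrecursorIndex, quantify_samples
from mirnapipe.reference import MatureArm, Precursor, PrecursorSet
from oracles import bruteforce_best_stratum

ADAPTER = "AACTGTAGGCACCATCAAT"


class TestTrimAndFilter:
    def test_exact_adapter_is_removed(self):
        insert = "ACGTACGTACGTACGTACGTAC"  # 22 nt
        assert trim_and_filter(insert + ADAPTER, ADAPTER) == insert

    def test_short_insert_is_discarded(self):
        insert = "ACGTACGTACGTAC"  # 14 nt
        assert trim_and_filter(insert + ADAPTER, ADAPTER) is None

    def test_read_without_adapter_kept_full_length(self):
        read = "ACGT" * 10
        assert trim_and_filter(read, ADAPTER) == read

    def test_adapter_with_one_substitution_still_found(self):
        insert = "ACGTACGTACGTACGTACGTAC"
        mutated = "AACTGTAGGCACCATCTAT"  # one substitution, within 10%
        assert trim_and_filter(insert + mutated, ADAPTER) == insert

    def test_partial_adapter_at_read_end(self):
        insert = "ACGTACGTACGTACGTACGTAC"
        read = (insert + ADAPTER)[: len(insert) + 9]  # 9-base adapter stub
        assert trim_and_filter(read, ADAPTER) == insert

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_and_filter("ACGT" * 5, "")


class TestCollapse:
    def test_multiplicities(self):
        seqs = ["A" * 20, "A" * 20, "C" * 20]
        out = {r.sequence: r.multiplicity for r in collapse(seqs)}
        assert out == {"A" * 20: 2, "C" * 20: 1}

    def test_empty_input(self):
        assert collapse([]) == []

    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=15, max_size=25), max_size=60
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_conservation(self, seqs):
        out = collapse(seqs)
        assert sum(r.multiplicity for r in out) == len(seqs)
        assert len({r.sequence for r in out}) == len(out)


def _two_precursor_ref(shared: str) -> PrecursorSet:
    ref = PrecursorSet()
    loop = "GGGGGGGGGGGG"
    other = "TTGCAATTGCAATTGCAATTGC"
    ref.add_precursor(Precursor("p1", shared + loop + other))
    ref.add_precursor(Precursor("p2", shared + loop + other[::-1]))
    for pid in ("p1", "p2"):
        L = len(ref.precursors[pid])
        ref.add_mature(MatureArm(f"{pid}-5p", pid, 0, len(shared), "5p"))
        ref.add_mature(MatureArm(f"{pid}-3p", pid, L - len(other), L, "3p"))
    return ref


class TestMapReads:
    def test_unique_read_single_alignment(self, small_reference):
        mid = small_reference.mature_ids()[0]
        seq = small_reference.mature_sequence(mid)
        alns = map_reads([CollapsedRead(seq, 1)], small_reference)
        assert len(alns) == 1 and alns[0].n_loci == 1

    def test_planted_multimapper_gets_half_weight(self):
        shared = "ACGTTGCATCGATCGGATCGAT"
        ref = _two_precursor_ref(shared)
        alns = map_reads([CollapsedRead(shared, 1)], ref)
        assert len(alns) == 2
        assert all(a.n_loci == 2 and a.weight == 0.5 for a in alns)

    def test_two_substitutions_unmapped_at_max_one(self, small_reference):
        seq = list(small_reference.mature_sequence(small_reference.mature_ids()[0]))
        for pos in (2, 10):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        assert map_reads([CollapsedRead("".join(seq), 1)], small_reference) == []

    def test_high_n_content_unmapped(self, small_reference):
        seq = small_reference.mature_sequence(small_reference.mature_ids()[0])
        noisy = "NNN" + seq[3:]
        assert map_reads([CollapsedRead(noisy, 1)], small_reference) == []

    def test_best_stratum_excludes_worse_hits(self):
        # same read hits p1 exactly and p2 with one mismatch: N must be 1
        shared = "ACGTTGCATCGATCGGATCGAT"
        near = shared[:-1] + ("A" if shared[-1] != "A" else "C")
        ref = PrecursorSet()
        loop = "GGGGGGGGGGGG"
        tail = "TTGCAATTGCAATTGCAATTGC"
        ref.add_precursor(Precursor("p1", shared + loop + tail))
        ref.add_precursor(Precursor("p2", near + loop + tail))
        alns = map_reads([CollapsedRead(shared, 1)], ref)
        assert [(a.precursor_id, a.mismatches) for a in alns] == [("p1", 0)]
        assert alns[0].n_loci == 1

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_mapper_equals_bruteforce_hamming_scan(self, max_mm):
        """Oracle equivalence: the seeded mapper returns exactly the
        best-stratum alignment set of an all-offsets Hamming scan."""
        rng = np.random.default_rng(5)
        design = SimDesign(
            n_mirna=100, group_sizes=(2, 2, 2), lib_size_range=(1e3, 2e3), seed=5
        )
        ref = generate_reference(design)  # 50 precursors
        seqs = {pid: p.sequence for pid, p in ref.precursors.items()}
        bases = np.array(list("ACGT"))
        reads = []
        for k in range(200):
            if k % 2 == 0:  # mutated mature sequence
                mid = ref.mature_ids()[int(rng.integers(len(ref.matures)))]
                seq = list(ref.mature_sequence(mid))
                for _ in range(int(rng.integers(0, 3))):
                    seq[int(rng.integers(len(seq)))] = str(rng.choice(bases))
                reads.append("".join(seq))
            else:  # random read
                reads.append("".join(rng.choice(bases, size=int(rng.integers(15, 31)))))
        collapsed = collapse(reads)
        alns = map_reads(collapsed, ref, max_mismatches=max_mm)
        by_seq: dict[str, set] = {r.sequence: set() for r in collapsed}
        for a in alns:
            by_seq[a.sequence].add((a.precursor_id, a.start, a.mismatches))
        for r in collapsed:
            expected = bruteforce_best_stratum(r.sequence, seqs, max_mm)
            assert by_seq[r.sequence] == expected


class TestAssignArm:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (4, 26, "5p"),  # midpoint 14.5, first half
            (36, 58, "3p"),  # midpoint 46.5, second half
            (19, 41, "5p"),  # midpoint 29.5 < 30, still first half
        ],
    )
    def test_midpoint_rule_on_60nt_precursor(self, start, end, expected):
        ref = PrecursorSet()
        ref.add_precursor(Precursor("p", "A" * 60))
        aln = Alignment("X" * (end - start), "p", start, end, 0, 1)
        assert assign_arm(aln, ref) == expected

    def test_exact_tie_goes_to_5p(self):
        ref = PrecursorSet()
        ref.add_precursor(Precursor("p", "A" * 60))
        # midpoint exactly 30.0: offsets 20..41 (inclusive end 40)
        aln = Alignment("X" * 21, "p", 20, 41, 0, 1)
        assert (aln.start + aln.end - 1) / 2 == 30.0
        assert assign_arm(aln, ref) == "5p"


class TestCount:
    def test_multimapper_splits_multiplicity(self):
        shared = "ACGTTGCATCGATCGGATCGAT"
        ref = _two_precursor_ref(shared)
        reads = [CollapsedRead(shared, 10)]
        alns = map_reads(reads, ref)
        col = count(alns, reads, ref, "s1")
        assert col["p1-5p"] == 5.0 and col["p2-5p"] == 5.0
        assert col.sum() == 10.0

    def test_unique_read_counts_once(self, small_reference):
        mid = small_reference.mature_ids()[0]
        reads = [CollapsedRead(small_reference.mature_sequence(mid), 1)]
        alns = map_reads(reads, small_reference)
        col = count(alns, reads, small_reference, "s1")
        assert col[mid] == 1.0 and col.sum() == 1.0

    def test_unknown_precursor_aborts(self, small_reference):
        reads = [CollapsedRead("A" * 20, 1)]
        aln = Alignment("A" * 20, "no-such-precursor", 0, 20, 0, 1)
        with pytest.raises(ValueError):
            count([aln], reads, small_reference, "s1")

    def test_column_sum_conserves_mapped_multiplicity(self, small_reference):
        rng = np.random.default_rng(2)
        reads = []
        for mid in small_reference.mature_ids():
            reads.append(
                CollapsedRead(
                    small_reference.mature_sequence(mid), int(rng.integers(1, 50))
                )
            )
        alns = map_reads(reads, small_reference)
        col = count(alns, reads, small_reference, "s1")
        assert col.sum() == pytest.approx(sum(r.multiplicity for r in reads), abs=1e-9)

    def test_read_order_does_not_change_counts(self, small_reference):
        rng = np.random.default_rng(3)
        reads = [
            CollapsedRead(small_reference.mature_sequence(m), int(rng.integers(1, 9)))
            for m in small_reference.mature_ids()
        ]
        col_a = count(map_reads(reads, small_reference), reads, small_reference, "s")
        rev = reads[::-1]
        col_b = count(map_reads(rev, small_reference), rev, small_reference, "s")
        assert (col_a == col_b).all()


class TestRoundTrip:
    def test_error_free_pipeline_recovers_truth_exactly(
        self, small_design, small_reference, small_truth, tmp_path
    ):
        truth, _ = small_truth
        paths = write_fastq(truth, small_reference, small_design, tmp_path)
        counts, qcs = quantify_samples(paths, small_reference, small_design.adapter)
        assert (counts.to_numpy() == truth.true_counts.to_numpy()).all()
        for qc in qcs:
            assert qc["reads_mapped"] == qc["reads_in"]
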