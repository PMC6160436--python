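import numpy as np
import pysam
import pytest

from tmodscan import (ModificationProfile, ReferenceSet, SimulationConfig,
                      TRNAReference, align_library, align_read, length_filter,
                      polyA_remap, read_sam, simulate_reads, trim_adapter,
                      write_sam)
from helpers import brute_force_align, revcomp


def test_length_filter_boundary():
    reads = [("a", "A" * 14), ("b", "A" * 15), ("c", "A" * 40)]
    kept, removed = length_filter(reads)
    assert [r[0] for r in kept] == ["b", "c"]
    assert removed == 1
    assert length_filter([]) == ([], 0)


class TestTrimAdapter:
    ADAPTER = "AGATCGGAAGAGCACACGTC"

    def test_full_adapter_removed(self):
        read = "ACGTACGTACGTACGTACGT" + self.ADAPTER
        assert trim_adapter(read, self.ADAPTER) == "ACGTACGTACGTACGTACGT"

    def test_partial_suffix_overlap_removed(self):
        read = "CCCCGGGGCCCCGGGG" + self.ADAPTER[:8]
        assert trim_adapter(read, self.ADAPTER) == "CCCCGGGGCCCCGGGG"

    def test_below_min_overlap_untouched(self):
        read = "CCCCGGGGCCCCGGGG" + self.ADAPTER[:3]
        assert trim_adapter(read, self.ADAPTER) == read

    def test_pure_adapter_composes_with_length_filter(self):
        trimmed = trim_adapter(self.ADAPTER, self.ADAPTER)
        assert trimmed == ""
        kept, removed = length_filter([("r", trimmed)])
        assert kept == [] and removed == 1

    def test_homopolymer_tail_preserved(self):
        read = "ACGTACGTACGTACGT" + "A" * 12
        assert trim_adapter(read, self.ADAPTER) == read


def test_exact_read_unique(refset, mt_tk):
    read = mt_tk.mature_seq[10:40]
    records = align_read(read, refset)
    assert len(records) == 1
    rec = records[0]
    assert (rec.ref_name, rec.start, rec.end) == ("MT-TK", 11, 40)
    assert rec.n_mismatch == 0 and rec.unique and rec.orientation == "sense"


def test_antisense_read_aligns(refset, mt_tk):
    records = align_read(revcomp(mt_tk.mature_seq[5:35]), refset)
    assert len(records) == 1
    assert records[0].orientation == "antisense"
    assert (records[0].start, records[0].end) == (6, 35)


def test_mismatch_cap(refset, mt_tk):
    read = list(mt_tk.mature_seq[10:40])
    for i in (2, 8, 14, 20):  # 4 mismatches > -v 3
        read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
    assert align_read("".join(read), refset) == []
    read[20] = mt_tk.mature_seq[30]  # back to 3 mismatches
    records = align_read("".join(read), refset)
    assert len(records) == 1 and records[0].n_mismatch == 3


def _shared_kmer_refset():
    """Two references sharing a verbatim 20-mer."""
    rng = np.random.default_rng(99)
    shared = "".join(rng.choice(list("ACGT"), 20))
    a = "".join(rng.choice(list("ACGT"), 20)) + shared + "".join(rng.choice(list("ACGT"), 20))
    b = "".join(rng.choice(list("ACGT"), 25)) + shared + "".join(rng.choice(list("ACGT"), 15))
    return ReferenceSet(references={
        "A": TRNAReference(name="A", gene_seq=a),
        "B": TRNAReference(name="B", gene_seq=b),
    }), shared


def test_shared_kmer_multimaps():
    refs, shared = _shared_kmer_refset()
    records = align_read(shared, refs)
    assert len(records) == 2
    assert all(not r.unique for r in records)
    assert {r.ref_name for r in records} == {"A", "B"}


def test_best_stratum_prefers_fewer_mismatches():
    refs, shared = _shared_kmer_refset()
    # one mismatch against A's copy only: B's exact copy forms the best stratum
    read = list(shared)
    read[0] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[0]]
    mutated = "".join(read)
    brute_status, stratum = brute_force_align(
        mutated, {"A": refs["A"].mature_seq, "B": refs["B"].mature_seq})
    records = align_read(mutated, refs)
    assert brute_status == "aligned"
    assert len(records) == len(stratum)
    got = sorted((r.n_mismatch, r.ref_name, r.start, r.orientation) for r in records)
    assert got == stratum


def test_max_hits_suppression():
    refs, shared = _shared_kmer_refset()
    assert align_read(shared, refs, max_hits=1) == []


def test_polyA_remap_soft_tail(refset, mt_tk):
    read = mt_tk.mature_seq[-25:] + "AAAAAA"
    assert align_read(read, refset) == []  # 31 nt do not fit the mature ref
    records = polyA_remap([("r1", read)], refset)
    assert len(records) == 1
    rec = records[0]
    assert rec.pass_ == "polyA_remap" and rec.ref_variant == "with_cca"
    assert rec.soft_tail == "AAAAAA" and rec.end == mt_tk.mature_len


def test_polyA_remap_cca_less_variant(refset, mt_tk):
    read = mt_tk.gene_seq[-25:] + "AAAA"
    records = polyA_remap([("r1", read)], refset)
    assert len(records) == 1
    rec = records[0]
    assert rec.ref_variant == "no_cca"
    assert rec.end == mt_tk.gene_len and rec.soft_tail == "AAAA"
    assert rec.n_mismatch == 0


def test_unalignable_read_stays_unaligned(refset):
    rng = np.random.default_rng(123)
    read = "".join(rng.choice(list("ACGT"), 40))
    assert align_read(read, refset) == []
    assert polyA_remap([("r", read)], refset) == []


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_aligner_matches_brute_force_on_random_instances(seed):
    """Exhaustive check against the independent pure-Python enumerator."""
    rng = np.random.default_rng(seed)
    refs = {}
    for i in range(5):
        refs[f"R{i}"] = TRNAReference(name=f"R{i}",
                                      gene_seq="".join(rng.choice(list("ACGT"), 60)))
    refset = ReferenceSet(references=refs)
    mature = {name: r.mature_seq for name, r in refs.items()}
    for _ in range(60):
        src = refs[f"R{int(rng.integers(5))}"].mature_seq
        k = int(rng.integers(15, 40))
        off = int(rng.integers(0, len(src) - k + 1))
        read = list(src[off:off + k])
        for _m in range(int(rng.integers(0, 5))):  # 0..4 mutations
            j = int(rng.integers(k))
            read[j] = "ACGT"[int(rng.integers(4))]
        read = "".join(read)
        if rng.random() < 0.5:
            read = revcomp(read)
        status, stratum = brute_force_align(read, mature)
        records = align_read(read, refset)
        if status != "aligned":
            assert records == []
        else:
            got = sorted((r.n_mismatch, r.ref_name, r.start, r.orientation)
                         for r in records)
            assert got == stratum
            assert all(r.unique == (len(stratum) == 1) for r in records)


def test_align_library_summary_and_order(refset):
    cfg = SimulationConfig(reference_set=refset,
                           reads_per_ref={"MT-TK": 60, "MT-TF": 40},
                           seq_error_rate=0.0, rng_seed=5,
                           profiles=[ModificationProfile("MT-TK", 40, 0.5, 0.5, 0.5)])
    reads, _ = simulate_reads(cfg)
    records, summary, unplaced = align_library(reads, refset)
    assert summary["total"] == 100
    assert summary["aligned_unique"] + summary["multimapped"] + \
        summary["suppressed"] + summary["unaligned"] == 100 - summary["short_removed"]
    ids = [(r.read_id, r.ref_name, r.start) for r in records]
    assert ids == sorted(ids)


def test_sam_roundtrip(refset, tmp_path):
    cfg = SimulationConfig(reference_set=refset,
                           reads_per_ref={"MT-TK": 40}, seq_error_rate=0.005,
                           cca_absent_fraction=0.4, oligoA_mean_cca_absent=3.0,
                           rng_seed=8)
    reads, _ = simulate_reads(cfg)
    records, _, unplaced = align_library(reads, refset)
    sam = tmp_path / "out.sam"
    write_sam(records, refset, sam, unplaced)
    back, unaligned_ids = read_sam(sam, refset)
    assert back == records
    assert len(unaligned_ids) == len(unplaced)


def test_sam_flags_and_tags(refset, mt_tk, tmp_path):
    sense_read = mt_tk.mature_seq[10:40]
    cdna_read = revcomp(sense_read)
    records = align_read(("r1", cdna_read), refset)
    sam = tmp_path / "flags.sam"
    write_sam(records, refset, sam, unplaced=[("r2", "T" * 20)])
    with pysam.AlignmentFile(sam, "r") as fh:
        rows = list(fh)
    mapped = [r for r in rows if not r.is_unmapped]
    assert len(mapped) == 1
    # antisense placement: FLAG 16 and SEQ stored reverse-complemented
    assert mapped[0].flag == 16
    assert mapped[0].query_sequence == sense_read
    assert mapped[0].get_tag("NM") == 0
    unmapped = [r for r in rows if r.is_unmapped]
    assert len(unmapped) == 1 and unmapped[0].flag == 4
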