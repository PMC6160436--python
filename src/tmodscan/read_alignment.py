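"""Ungapped best-stratum alignment of tRNA-seq reads.

The mapping policy mirrors Bowtie-1 ``-v 3 -m 10 --best --strata`` run
against a tRNA reference set: end-to-end, ungapped placement of every read
at every offset of every reference in both orientations, keep placements
with Hamming distance <= ``max_mismatch``, retain only the minimum-distance
stratum, and suppress the read entirely if that stratum holds more than
``max_hits`` placements.  A read is *unique* iff exactly one best-stratum
placement exists; only unique records feed quantitation downstream.

Reads that fail the primary pass are remapped against poly-A(30)-appended
references so oligoadenylated molecules can place end-to-end.  The remap
targets include both the mature (gene+CCA) and the gene-only variant of
each reference: adenylated molecules *lacking* the CCA could not otherwise
align end-to-end.  Read bases landing in the appended tract are reported
as ``soft_tail`` (and soft-clipped in SAM output).

At this scale (tens of references x ~75 nt) exhaustive enumeration with
numpy sliding windows is exact and fast; no index structure is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .reference_model import ReferenceSet
from .synthetic_reads import reverse_complement

__all__ = [
    "AlignmentRecord",
    "length_filter",
    "trim_adapter",
    "align_read",
    "polyA_remap",
    "align_library",
    "write_sam",
    "read_sam",
    "aligned_sequence",
]

SENSE = "sense"
ANTISENSE = "antisense"

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class AlignmentRecord:
    """One read placed on one reference, in 1-based mature coordinates.

    ``start``/``end`` cover templated positions only; ``soft_tail`` holds
    read bases beyond the templated 3' end (poly-A remap pass).
    ``ref_variant`` records which remap target matched: ``"mature"``
    (primary pass), ``"with_cca"`` or ``"no_cca"``.  ``n_mismatch`` is the
    full end-to-end Hamming distance (tract bases included); the
    ``mismatch_list`` triples ``(position, ref_base, read_base)`` cover
    templated positions only, with read bases in reference sense.
    """

    read_id: str
    ref_name: str
    start: int
    end: int
    n_mismatch: int
    mismatch_list: tuple[tuple[int, str, str], ...]
    orientation: str
    unique: bool
    pass_: str = "primary"
    soft_tail: str = ""
    ref_variant: str = "mature"


def length_filter(reads: Iterable[tuple[str, str]], min_len: int = 15
                  ) -> tuple[list[tuple[str, str]], int]:
    """Drop reads shorter than ``min_len`` nt; returns (kept, n_removed)."""
    kept, removed = [], 0
    for read_id, seq in reads:
        if len(seq) >= min_len:
            kept.append((read_id, seq))
        else:
            removed += 1
    return kept, removed


def trim_adapter(read: str, adapter: str, min_overlap: int = 5) -> str:
    """Remove a 3' adapter trace by exact matching.

    If the full adapter occurs in the read, everything from its first
    occurrence on is removed; otherwise the longest read suffix equal to an
    adapter prefix (>= ``min_overlap`` nt) is removed.  No quality- or
    complexity-based trimming is done, so homopolymer (poly-A) stretches
    are preserved for the tail analysis.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    idx = read.find(adapter)
    if idx >= 0:
        return read[:idx]
    for k in range(min(len(read), len(adapter) - 1), min_overlap - 1, -1):
        if read.endswith(adapter[:k]):
            return read[:-k]
    return read


# ---------------------------------------------------------------------------
# Alignment core
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Target:
    ref_name: str
    variant: str        # "mature" | "with_cca" | "no_cca"
    seq: str
    templated_len: int  # positions beyond this are appended poly-A tract
    enc: np.ndarray


_CODE_TABLE = np.zeros(256, dtype=np.uint8)
for _b, _c in _ENC.items():
    _CODE_TABLE[ord(_b)] = _c
_CODE_TABLE[ord("N")] = 4


def _enc_ref(seq: str) -> np.ndarray:
    return _CODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _enc_read(seq: str) -> np.ndarray:
    enc = _CODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int16)
    enc[enc == 4] = 5  # read N matches nothing, including reference N
    return enc


def _build_targets(reference_set: ReferenceSet, mode: str) -> list[_Target]:
    targets = []
    for ref in reference_set:
        if mode == "mature":
            targets.append(_Target(ref.name, "mature", ref.mature_seq,
                                   ref.mature_len, _enc_ref(ref.mature_seq)))
        elif mode == "polyA":
            tract = "A" * reference_set.polyA_n
            with_cca = ref.mature_seq + tract
            no_cca = ref.gene_seq + tract
            targets.append(_Target(ref.name, "with_cca", with_cca,
                                   ref.mature_len, _enc_ref(with_cca)))
            targets.append(_Target(ref.name, "no_cca", no_cca,
                                   ref.gene_len, _enc_ref(no_cca)))
        else:
            raise ValueError(f"unknown target mode {mode!r}")
    return targets


def _placements(seq: str, targets: Sequence[_Target], max_mismatch: int
                ) -> list[tuple[int, _Target, int, str, str]]:
    """All placements with Hamming distance <= max_mismatch.

    Returns tuples (distance, target, offset0, orientation, oriented_seq),
    where oriented_seq matches the reference forward strand.
    """
    out = []
    oriented = {SENSE: seq, ANTISENSE: reverse_complement(seq)}
    enc = {o: _enc_read(s) for o, s in oriented.items()}
    k = len(seq)
    for target in targets:
        L = len(target.seq)
        if k > L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(target.enc, k)
        for orient in (SENSE, ANTISENSE):
            dists = (windows != enc[orient]).sum(axis=1)
            for off in np.flatnonzero(dists <= max_mismatch):
                out.append((int(dists[off]), target, int(off), orient, oriented[orient]))
    return out


def _make_record(read_id: str, placement, unique: bool, pass_: str) -> AlignmentRecord:
    dist, target, off, orient, oriented = placement
    k = len(oriented)
    start = off + 1
    raw_end = off + k
    end = min(raw_end, target.templated_len)
    soft_tail = oriented[target.templated_len - off:] if raw_end > target.templated_len else ""
    mismatches = []
    body = oriented[: end - start + 1]
    for i, base in enumerate(body):
        ref_base = target.seq[off + i]
        if base != ref_base:
            mismatches.append((start + i, ref_base, base))
    return AlignmentRecord(
        read_id=read_id,
        ref_name=target.ref_name,
        start=start,
        end=end,
        n_mismatch=dist,
        mismatch_list=tuple(mismatches),
        orientation=orient,
        unique=unique,
        pass_=pass_,
        soft_tail=soft_tail,
        ref_variant=target.variant,
    )


def _align_seq(seq: str, targets: Sequence[_Target], max_mismatch: int,
               max_hits: int, pass_: str) -> tuple[str, list[AlignmentRecord]]:
    """Align one sequence; returns (status, records).

    status is "aligned", "suppressed" (best stratum larger than max_hits)
    or "unaligned".  Records carry an empty read_id; callers fill it in.
    """
    placements = _placements(seq, targets, max_mismatch)
    if not placements:
        return "unaligned", []
    best = min(p[0] for p in placements)
    stratum = [p for p in placements if p[0] == best]
    if len(stratum) > max_hits:
        return "suppressed", []
    stratum.sort(key=lambda p: (p[1].ref_name, p[1].variant, p[2], p[3]))
    unique = len(stratum) == 1
    return "aligned", [_make_record("", p, unique, pass_) for p in stratum]


def align_read(read: str | tuple[str, str], reference_set: ReferenceSet,
               max_mismatch: int = 3, max_hits: int = 10) -> list[AlignmentRecord]:
    """Primary-pass alignment of one read against the mature references.

    Returns the best-stratum records (all ties reported, ``unique`` set on
    each); an empty list means the read was unaligned or suppressed.
    """
    read_id, seq = read if isinstance(read, tuple) else ("read", read)
    targets = _build_targets(reference_set, "mature")
    _, records = _align_seq(seq, targets, max_mismatch, max_hits, "primary")
    return [replace(r, read_id=read_id) for r in records]


def polyA_remap(reads: Iterable[tuple[str, str]], reference_set: ReferenceSet,
                max_mismatch: int = 3, max_hits: int = 10) -> list[AlignmentRecord]:
    """Remap primary-pass failures against poly-A-appended references."""
    targets = _build_targets(reference_set, "polyA")
    out: list[AlignmentRecord] = []
    for read_id, seq in reads:
        _, records = _align_seq(seq, targets, max_mismatch, max_hits, "polyA_remap")
        out.extend(replace(r, read_id=read_id) for r in records)
    return out


def align_library(reads: Iterable[tuple[str, str]], reference_set: ReferenceSet,
                  max_mismatch: int = 3, max_hits: int = 10, min_len: int = 15,
                  adapter: str | None = None, polyA: bool = True
                  ) -> tuple[list[AlignmentRecord], dict, list[tuple[str, str]]]:
    """Filter, align and (for failures) poly-A remap a whole library.

    Identical sequences are aligned once and the result shared.  Returns
    ``(records, summary, unplaced)`` with records sorted by
    (read_id, ref_name, start) and unplaced = [(read_id, seq)] of reads
    that stayed unaligned or suppressed (for unmapped SAM records).
    """
    reads = list(reads)
    if adapter:
        reads = [(rid, trim_adapter(seq, adapter)) for rid, seq in reads]
    kept, n_short = length_filter(reads, min_len)

    primary_targets = _build_targets(reference_set, "mature")
    remap_targets = _build_targets(reference_set, "polyA") if polyA else []

    by_seq: dict[str, list[str]] = {}
    for read_id, seq in kept:
        by_seq.setdefault(seq, []).append(read_id)

    cache: dict[str, tuple[str, list[AlignmentRecord]]] = {}
    for seq in by_seq:
        status, records = _align_seq(seq, primary_targets, max_mismatch, max_hits,
                                     "primary")
        if status == "unaligned" and remap_targets:
            status2, records2 = _align_seq(seq, remap_targets, max_mismatch, max_hits,
                                           "polyA_remap")
            if status2 != "unaligned":
                status, records = status2, records2
        cache[seq] = (status, records)

    records_out: list[AlignmentRecord] = []
    unplaced: list[tuple[str, str]] = []
    summary = {
        "total": len(reads),
        "short_removed": n_short,
        "aligned_unique": 0,
        "multimapped": 0,
        "suppressed": 0,
        "unaligned": 0,
        "polyA_remapped": 0,
    }
    for read_id, seq in kept:
        status, recs = cache[seq]
        if status == "aligned":
            if recs[0].unique:
                summary["aligned_unique"] += 1
            else:
                summary["multimapped"] += 1
            if recs[0].pass_ == "polyA_remap":
                summary["polyA_remapped"] += 1
            records_out.extend(replace(r, read_id=read_id) for r in recs)
        else:
            summary[status] += 1
            unplaced.append((read_id, seq))
    records_out.sort(key=lambda r: (r.read_id, r.ref_name, r.start))
    return records_out, summary, unplaced


# ---------------------------------------------------------------------------
# SAM I/O
# ---------------------------------------------------------------------------

def aligned_sequence(record: AlignmentRecord, ref) -> str:
    """Reconstruct the read bases over the templated span (reference sense)."""
    body = list(ref.mature_seq[record.start - 1: record.end])
    for pos, _ref_base, read_base in record.mismatch_list:
        body[pos - record.start] = read_base
    return "".join(body)


def _md_tag(record: AlignmentRecord, ref) -> str:
    md = []
    run = 0
    mism = {pos: rb for pos, rb, _ in record.mismatch_list}
    for pos in range(record.start, record.end + 1):
        if pos in mism:
            md.append(str(run))
            md.append(mism[pos])
            run = 0
        else:
            run += 1
    md.append(str(run))
    return "".join(md)


def write_sam(records: Sequence[AlignmentRecord], reference_set: ReferenceSet,
              path: str | Path, unplaced: Sequence[tuple[str, str]] = ()) -> None:
    """Write standard SAM: @SQ per mature reference, NM/MD tags, soft-clipped
    tails, FLAG 16 for antisense placements (read stored reverse-complemented),
    FLAG 4 records for unaligned/suppressed reads.

    Extra tags: XU:i unique flag, XP:Z pass, XV:Z reference variant,
    XN:i end-to-end mismatch count (tract included).
    """
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": ref.name, "LN": ref.mature_len} for ref in reference_set],
        "PG": [{"ID": "tmodscan", "PN": "tmodscan"}],
    })
    tid = {ref.name: i for i, ref in enumerate(reference_set)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            ref = reference_set[rec.ref_name]
            a = pysam.AlignedSegment(header)
            a.query_name = rec.read_id
            a.flag = 16 if rec.orientation == ANTISENSE else 0
            a.reference_id = tid[rec.ref_name]
            a.reference_start = rec.start - 1
            a.mapping_quality = 60 if rec.unique else 0
            body = aligned_sequence(rec, ref)
            cigar = f"{len(body)}M"
            if rec.soft_tail:
                cigar += f"{len(rec.soft_tail)}S"
            a.cigarstring = cigar
            a.query_sequence = body + rec.soft_tail
            a.query_qualities = pysam.qualitystring_to_array("I" * len(a.query_sequence))
            a.set_tags([
                ("NM", len(rec.mismatch_list), "i"),
                ("MD", _md_tag(rec, ref), "Z"),
                ("XU", int(rec.unique), "i"),
                ("XP", rec.pass_, "Z"),
                ("XV", rec.ref_variant, "Z"),
                ("XN", rec.n_mismatch, "i"),
            ])
            out.write(a)
        for read_id, seq in unplaced:
            a = pysam.AlignedSegment(header)
            a.query_name = read_id
            a.flag = 4
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(a)


def read_sam(path: str | Path, reference_set: ReferenceSet
             ) -> tuple[list[AlignmentRecord], list[str]]:
    """Read a SAM written by :func:`write_sam` back into records.

    Mismatch triples are recomputed against the reference set, so any
    SAM with M/S CIGARs over these references is acceptable input.
    Returns (records, unaligned read ids).
    """
    records: list[AlignmentRecord] = []
    unaligned: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                unaligned.append(a.query_name)
                continue
            ref = reference_set[a.reference_name]
            start = a.reference_start + 1
            cig = a.cigartuples or []
            body_len = sum(n for op, n in cig if op == 0)
            tail_len = sum(n for op, n in cig if op == 4)
            seq = a.query_sequence or ""
            body = seq[:body_len]
            soft_tail = seq[body_len: body_len + tail_len]
            end = start + body_len - 1
            mism = tuple(
                (start + i, ref.mature_seq[start - 1 + i], b)
                for i, b in enumerate(body)
                if b != ref.mature_seq[start - 1 + i]
            )
            records.append(AlignmentRecord(
                read_id=a.query_name,
                ref_name=a.reference_name,
                start=start,
                end=end,
                n_mismatch=int(a.get_tag("XN")) if a.has_tag("XN") else len(mism),
                mismatch_list=mism,
                orientation=ANTISENSE if a.is_reverse else SENSE,
                unique=bool(a.get_tag("XU")) if a.has_tag("XU")
                       else a.mapping_quality > 0,
                pass_=a.get_tag("XP") if a.has_tag("XP") else "primary",
                soft_tail=soft_tail,
                ref_variant=a.get_tag("XV") if a.has_tag("XV") else "mature",
            ))
    records.sort(key=lambda r: (r.read_id, r.ref_name, r.start))
    return records, unaligned
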