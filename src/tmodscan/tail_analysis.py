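"""3'-end classification: CCA presence and oligo(A) tails.

Reads are sorted into two pools by the presence or absence of the
post-transcriptionally added CCA, and the oligoadenylation length
distribution is tabulated per pool — the logic behind a 3'-position
sequencing plot of adenylation frequency.

CCA detection is strict: the read must cover all three CCA positions and
match ``CCA`` exactly, even though the aligner tolerates mismatches
elsewhere (a single mismatch in CCA is indistinguishable from absence at
this depth, so strictness is the conservative contract; a read ending
``...CC`` is never called CCA-present).  Reads whose alignment does not
reach the gene 3' end (internal RT stops) carry no evidence either way and
are excluded from tail statistics, not counted as CCA-absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .read_alignment import AlignmentRecord, aligned_sequence
from .reference_model import ReferenceSet, TRNAReference

__all__ = [
    "TailRecord",
    "classify_tail",
    "classify_tails",
    "adenylation_frequency",
]


@dataclass(frozen=True)
class TailRecord:
    """Per-read 3'-end classification.

    ``tail_seq`` holds the read bases 3' of the templated end (after the
    CCA when present); ``oligoA_len`` is the maximal *terminal* adenosine
    run within it — mixed tails are reported but only their terminal A-run
    counts as adenylation.
    """

    read_id: str
    ref_name: str
    cca_present: bool
    body_end: int          # last gene position covered
    tail_seq: str
    oligoA_len: int
    is_adenylated: bool


def _terminal_a_run(seq: str) -> int:
    n = 0
    for base in reversed(seq):
        if base != "A":
            break
        n += 1
    return n


def classify_tail(record: AlignmentRecord, ref: TRNAReference,
                  min_tail: int = 1) -> TailRecord | None:
    """Classify one uniquely aligned read's 3' end; None if unclassifiable.

    A read is classifiable when its alignment covers the last gene
    position.  ``cca_present`` requires full, exact coverage of the CCA;
    for CCA-absent reads the tail is every read base beyond the gene end
    (bases aligned over the reference CCA/tract positions plus any
    soft-clipped tail).
    """
    if record.end < ref.gene_len:
        return None
    body = aligned_sequence(record, ref)
    cca_present = (
        record.end >= ref.mature_len
        and body[ref.mature_len - record.start - 2: ref.mature_len - record.start + 1]
        == "CCA"
    )
    if cca_present:
        tail_seq = record.soft_tail
    else:
        beyond = body[ref.gene_len - record.start + 1:]
        tail_seq = beyond + record.soft_tail
    oligoA_len = _terminal_a_run(tail_seq)
    return TailRecord(
        read_id=record.read_id,
        ref_name=record.ref_name,
        cca_present=cca_present,
        body_end=min(record.end, ref.gene_len),
        tail_seq=tail_seq,
        oligoA_len=oligoA_len,
        is_adenylated=oligoA_len >= min_tail,
    )


def classify_tails(records: Iterable[AlignmentRecord], reference_set: ReferenceSet,
                   min_tail: int = 1) -> tuple[list[TailRecord], int]:
    """Classify all unique records; returns (tail records, n excluded)."""
    out: list[TailRecord] = []
    excluded = 0
    for rec in records:
        if not rec.unique:
            continue
        tr = classify_tail(rec, reference_set[rec.ref_name], min_tail)
        if tr is None:
            excluded += 1
        else:
            out.append(tr)
    return out, excluded


def adenylation_frequency(tail_records: Sequence[TailRecord],
                          min_pool: int = 20) -> pd.DataFrame:
    """Tail-length distribution per (reference, CCA pool).

    Columns: ref, pool ("CCA"/"noCCA"), oligoA_len, n, fraction, pool_n,
    low_confidence (pool smaller than ``min_pool``).  Fractions sum to 1
    within each non-empty (ref, pool).
    """
    rows = []
    pools: dict[tuple[str, str], dict[int, int]] = {}
    for tr in tail_records:
        pool = "CCA" if tr.cca_present else "noCCA"
        pools.setdefault((tr.ref_name, pool), {}).setdefault(tr.oligoA_len, 0)
        pools[(tr.ref_name, pool)][tr.oligoA_len] += 1
    for (ref_name, pool), lengths in sorted(pools.items()):
        pool_n = sum(lengths.values())
        for length, n in sorted(lengths.items()):
            rows.append({
                "ref": ref_name,
                "pool": pool,
                "oligoA_len": length,
                "n": n,
                "fraction": n / pool_n,
                "pool_n": pool_n,
                "low_confidence": pool_n < min_pool,
            })
    return pd.DataFrame(rows, columns=["ref", "pool", "oligoA_len", "n", "fraction",
                                       "pool_n", "low_confidence"])
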