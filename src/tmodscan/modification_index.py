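"""Per-position RT-stop/mutation pileup and the Modification Index.

A Watson-Crick-face modification leaves two signatures in TGIRT cDNA:
premature termination (RT stop) and read-through misincorporation.  The
Modification Index (MI) at a position is the sum of the stop fraction and
the mutation fraction, a value in [0, 1] that approximates the modified
fraction of the site.

Counting conventions (stop-before-copy, shared with the simulator):

* a read aligned to ``[start, end]`` copied every covered position; if
  ``start > 1`` the RT stopped at ``start - 1`` (the uncopied base);
* ``S(p)`` = reads stopping at ``p``; ``R(p)`` = reads covering ``p``
  (read-throughs); ``N(p) = S(p) + R(p)`` is the shared denominator for
  both fractions, which guarantees ``MI <= 1``.

Because every cDNA starts at the molecule 3' terminus, stop products at
positions close to the 3' end are too short to survive library
construction; at such positions the stop fraction collapses toward zero
and the MI reports (a conditioned version of) the mutation signature only
— a lower bound of the modification fraction.  Positions closer than
``lower_bound_threshold`` (~25 nt) to the 3' end are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .read_alignment import AlignmentRecord
from .reference_model import ReferenceSet, distance_to_3prime

__all__ = [
    "PositionTable",
    "build_position_table",
    "modification_index",
    "flag_lower_bound",
    "call_modifications",
    "estimate_modified_fraction",
]

_BASES = ("A", "C", "G", "T", "N")

CALL_METHYL = "demethylase_sensitive_methyl"
CALL_NON_METHYL = "non_methyl_signal"
CALL_UNMODIFIED = "unmodified"


@dataclass
class PositionTable:
    """Per-position counts and fractions for one reference.

    ``table`` columns: pos, conv_pos, N, S, R, X, base counts
    base_A..base_N (over read-throughs), stop_frac, mut_frac, MI,
    lower_bound, coverage_ok — the data behind a "position sequencing
    plot".
    """

    ref_name: str
    table: pd.DataFrame
    n_reads: int
    full_length_count: int
    min_coverage: int

    def row(self, pos: int) -> pd.Series:
        return self.table.loc[self.table["pos"] == pos].iloc[0]

    def mi(self, pos: int) -> float:
        return float(self.row(pos)["MI"])


def modification_index(stop_fraction: float, mutation_fraction: float) -> float:
    """MI = stop fraction + mutation fraction (shared denominator).

    A sum above 1 signals a denominator inconsistency upstream and is an
    error, never silently clipped.
    """
    for label, v in (("stop_fraction", stop_fraction),
                     ("mutation_fraction", mutation_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{label} must be in [0,1], got {v}")
    total = stop_fraction + mutation_fraction
    if total > 1.0 + 1e-9:
        raise ValueError(
            f"stop + mutation fraction = {total} > 1: the fractions do not share "
            "a denominator"
        )
    return min(total, 1.0)


def build_position_table(records: Sequence[AlignmentRecord],
                         reference_set: ReferenceSet,
                         min_coverage: int = 50,
                         lower_bound_threshold: int = 25,
                         ) -> dict[str, PositionTable]:
    """Merge uniquely aligned reads into per-reference position tables.

    Only ``unique`` records are counted.  Positions with ``N < min_coverage``
    are flagged ``coverage_ok=False`` and excluded from downstream calls.
    """
    by_ref: dict[str, list[AlignmentRecord]] = {name: [] for name in reference_set.names}
    for rec in records:
        if not rec.unique:
            continue
        if rec.ref_name not in by_ref:
            raise ValueError(f"record references {rec.ref_name!r}, absent from set")
        by_ref[rec.ref_name].append(rec)

    tables: dict[str, PositionTable] = {}
    for name, recs in by_ref.items():
        ref = reference_set[name]
        L = ref.mature_len
        S = np.zeros(L + 1, dtype=np.int64)       # index by position 1..L
        cov_diff = np.zeros(L + 2, dtype=np.int64)
        base_counts = {b: np.zeros(L + 1, dtype=np.int64) for b in _BASES}
        mism_at = np.zeros(L + 1, dtype=np.int64)
        full_length = 0
        for rec in recs:
            cov_diff[rec.start] += 1
            cov_diff[rec.end + 1] -= 1
            if rec.start > 1:
                S[rec.start - 1] += 1
            else:
                full_length += 1
            for pos, _ref_base, read_base in rec.mismatch_list:
                mism_at[pos] += 1
                base_counts[read_base][pos] += 1
        R = np.cumsum(cov_diff)[: L + 1]  # R[p] = reads covering p
        N = S + R
        # reference-base counts among read-throughs
        for p in range(1, L + 1):
            base_counts[ref.mature_seq[p - 1]][p] += R[p] - mism_at[p]
        X = mism_at

        with np.errstate(divide="ignore", invalid="ignore"):
            stop_frac = np.where(N > 0, S / np.maximum(N, 1), np.nan)
            mut_frac = np.where(N > 0, X / np.maximum(N, 1), np.nan)
        mi = stop_frac + mut_frac
        positions = np.arange(1, L + 1)
        conv = {idx: c for c, idx in ref.numbering_map.items()}
        dist = L - positions
        table = pd.DataFrame({
            "pos": positions,
            "conv_pos": [conv.get(p, pd.NA) for p in positions],
            "N": N[1:],
            "S": S[1:],
            "R": R[1:],
            "X": X[1:],
            **{f"base_{b}": base_counts[b][1:] for b in _BASES},
            "stop_frac": stop_frac[1:],
            "mut_frac": mut_frac[1:],
            "MI": mi[1:],
            "lower_bound": dist < lower_bound_threshold,
            "coverage_ok": N[1:] >= min_coverage,
        })
        tables[name] = PositionTable(
            ref_name=name,
            table=table,
            n_reads=len(recs),
            full_length_count=full_length,
            min_coverage=min_coverage,
        )
    return tables


def flag_lower_bound(table: PositionTable, reference_set: ReferenceSet,
                     threshold: int = 25) -> PositionTable:
    """Re-flag positions closer than ``threshold`` nt to the mature 3' end.

    At these positions the stop fraction cannot be mapped accurately (stop
    products are lost from the library) and the MI is a lower bound of the
    modification fraction.
    """
    ref = reference_set[table.ref_name]
    table.table["lower_bound"] = [
        distance_to_3prime(ref, int(p)) < threshold for p in table.table["pos"]
    ]
    return table


def call_modifications(tables_untreated: Mapping[str, PositionTable],
                       tables_treated: Mapping[str, PositionTable],
                       reference_set: ReferenceSet,
                       mi_min: float = 0.1,
                       treated_max: float = 0.05) -> pd.DataFrame:
    """Classify positions by comparing matched untreated/treated libraries.

    * ``demethylase_sensitive_methyl``: MI_untreated >= ``mi_min`` and
      MI_treated <= ``treated_max`` (the methyl signature is erased by
      AlkB treatment);
    * ``non_methyl_signal``: MI >= ``mi_min`` in both libraries (e.g. a
      2-thio wobble modification, or a heteroplasmic variant);
    * ``unmodified`` otherwise.

    Positions failing the coverage threshold in either library are
    skipped, as are the three CCA positions: the CCA is added
    post-transcriptionally, is not a modifiable gene position, and
    collects alignment mismatches from short oligo(A) tails.  Calls are
    signature classes, not chemical identifications.
    """
    if set(tables_untreated) != set(tables_treated):
        raise ValueError("untreated and treated tables cover different references")
    rows = []
    for name in tables_untreated:
        un = tables_untreated[name].table
        tr = tables_treated[name].table
        gene_len = reference_set[name].gene_len
        if len(un) != len(tr):
            raise ValueError(f"position tables for {name!r} have different lengths")
        for (_, u), (_, t) in zip(un.iterrows(), tr.iterrows()):
            if int(u["pos"]) > gene_len:
                continue
            if not (u["coverage_ok"] and t["coverage_ok"]):
                continue
            mi_u, mi_t = float(u["MI"]), float(t["MI"])
            if mi_u >= mi_min and mi_t <= treated_max:
                call = CALL_METHYL
            elif mi_u >= mi_min and mi_t >= mi_min:
                call = CALL_NON_METHYL
            else:
                call = CALL_UNMODIFIED
            rows.append({
                "ref": name,
                "pos": int(u["pos"]),
                "conv_pos": u["conv_pos"],
                "MI_untreated": mi_u,
                "MI_treated": mi_t,
                "delta": mi_u - mi_t,
                "call": call,
                "lower_bound": bool(u["lower_bound"]),
            })
    return pd.DataFrame(rows, columns=["ref", "pos", "conv_pos", "MI_untreated",
                                       "MI_treated", "delta", "call", "lower_bound"])


def estimate_modified_fraction(mutation_only_MI: float,
                               mutation_share: float = 0.5) -> float:
    """Scale a mutation-only MI up to an estimated modified fraction.

    At a 3'-proximal site the stop products are lost, so the MI carries
    only the mutation signature.  If mutations contribute a share
    ``mutation_share`` of the full signature at a context-matched site
    (0.5 for equal mutation/stop contributions; the empirical m1A16 split
    0.074/0.16 ~ 0.4625 is the alternative), the modified fraction is
    approximately ``MI / mutation_share``, capped at 1.
    """
    if not 0.0 <= mutation_only_MI <= 1.0:
        raise ValueError(f"mutation_only_MI must be in [0,1], got {mutation_only_MI}")
    if not 0.0 < mutation_share <= 1.0:
        raise ValueError(f"mutation_share must be in (0,1], got {mutation_share}")
    estimate = mutation_only_MI / mutation_share
    if estimate > 1.0:
        warnings.warn(
            f"estimated modified fraction {estimate:.3f} > 1; capping at 1.0",
            stacklevel=2,
        )
        return 1.0
    return estimate
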