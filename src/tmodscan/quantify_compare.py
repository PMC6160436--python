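"""Abundance, heteroplasmy, replicate correlation and paired comparisons.

Abundance is counted from uniquely aligned reads only, as a fraction of
the mitochondrial tRNA pool.  Heteroplasmy at a configured variant site is
the alternative-allele fraction among read-throughs (RT stops carry no
base call at the site and are uninformative about the substituted base).
Condition comparisons use the paired sample t test; a Benjamini-Hochberg
column is emitted alongside the raw p-values as a clearly labelled
extension (no correction is applied to the primary results).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .modification_index import PositionTable
from .read_alignment import AlignmentRecord
from .reference_model import ReferenceSet

__all__ = [
    "abundance",
    "HeteroplasmyResult",
    "heteroplasmy",
    "replicate_correlation",
    "ComparisonResult",
    "paired_t",
    "compare_abundance",
    "primer_extension_proportion",
]


def abundance(records: Sequence[AlignmentRecord], reference_set: ReferenceSet
              ) -> pd.DataFrame:
    """Unique-read counts and pool fractions per reference.

    References with zero reads appear with fraction 0; fractions sum to 1
    over the set.
    """
    counted_ids: set[str] = set()
    counts = {name: 0 for name in reference_set.names}
    for rec in records:
        if rec.unique and rec.read_id not in counted_ids:
            counted_ids.add(rec.read_id)
            counts[rec.ref_name] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no uniquely aligned reads: cannot compute abundance")
    return pd.DataFrame({
        "ref": list(counts),
        "unique_reads": list(counts.values()),
        "fraction": [c / total for c in counts.values()],
    })


@dataclass(frozen=True)
class HeteroplasmyResult:
    ref_name: str
    mature_index: int
    fraction: float | None      # None when coverage is insufficient
    ref_count: int
    alt_count: int
    other_count: int            # error mass: read-throughs with other bases
    coverage: int
    low_coverage: bool


def heteroplasmy(table: PositionTable, mature_index: int, ref_base: str,
                 alt_base: str, min_coverage: int = 50) -> HeteroplasmyResult:
    """Alt-allele fraction among read-throughs at a point-variant site."""
    row = table.row(mature_index)
    ref_count = int(row[f"base_{ref_base}"])
    alt_count = int(row[f"base_{alt_base}"])
    other = int(row["R"]) - ref_count - alt_count
    coverage = int(row["R"])
    if coverage < min_coverage:
        return HeteroplasmyResult(table.ref_name, mature_index, None, ref_count,
                                  alt_count, other, coverage, True)
    denom = ref_count + alt_count
    fraction = alt_count / denom if denom > 0 else 0.0
    return HeteroplasmyResult(table.ref_name, mature_index, fraction, ref_count,
                              alt_count, other, coverage, False)


def replicate_correlation(vectors: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise Pearson r matrix over matched item vectors.

    A zero-variance vector yields NaN against every partner (undefined r,
    reported as such).
    """
    names = list(vectors)
    arrays = [np.asarray(vectors[n], dtype=float) for n in names]
    n_items = {len(a) for a in arrays}
    if len(n_items) != 1:
        raise ValueError("vectors must have matched item sets (equal lengths)")
    mat = np.full((len(names), len(names)), np.nan)
    for i in range(len(names)):
        for j in range(len(names)):
            a, b = arrays[i], arrays[j]
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            mat[i, j] = float(np.corrcoef(a, b)[0, 1])
    return pd.DataFrame(mat, index=names, columns=names)


@dataclass(frozen=True)
class ComparisonResult:
    """One paired-comparison row: condition means/SDs and the paired t."""

    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float | None       # None when the differences have zero variance
    p: float | None
    df: int


def paired_t(condition_a: Sequence[float], condition_b: Sequence[float]
             ) -> ComparisonResult:
    """Paired sample t test: t = mean(d) / (sd(d)/sqrt(n)), two-sided p.

    Differences with zero variance leave t undefined (reported as None,
    p omitted) rather than infinite.
    """
    a = np.asarray(condition_a, dtype=float)
    b = np.asarray(condition_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("conditions must be equal-length 1-d vectors")
    n = len(a)
    if n < 2:
        raise ValueError("paired t requires n >= 2 pairs")
    d = a - b
    sd_d = float(np.std(d, ddof=1))
    mean = lambda x: float(np.mean(x))
    sd = lambda x: float(np.std(x, ddof=1))
    if sd_d == 0.0:
        return ComparisonResult(n, mean(a), sd(a), mean(b), sd(b), None, None, n - 1)
    t = float(np.mean(d) / (sd_d / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return ComparisonResult(n, mean(a), sd(a), mean(b), sd(b), t, p, n - 1)


def compare_abundance(tables_a: Sequence[pd.DataFrame],
                      tables_b: Sequence[pd.DataFrame],
                      label_a: str = "A", label_b: str = "B") -> pd.DataFrame:
    """Per-reference paired t over replicate abundance fractions.

    ``tables_*`` are :func:`abundance` outputs, paired by replicate order.
    The ``p_bh`` column is a Benjamini-Hochberg adjustment offered as an
    extension; the primary result is the raw paired-t p-value.
    """
    if len(tables_a) != len(tables_b):
        raise ValueError("conditions must have the same number of replicates")
    refs = list(tables_a[0]["ref"])
    rows = []
    for ref in refs:
        va = [float(t.loc[t["ref"] == ref, "fraction"].iloc[0]) for t in tables_a]
        vb = [float(t.loc[t["ref"] == ref, "fraction"].iloc[0]) for t in tables_b]
        res = paired_t(va, vb)
        rows.append({
            "ref": ref,
            f"mean_{label_a}": res.mean_a, f"sd_{label_a}": res.sd_a,
            f"mean_{label_b}": res.mean_b, f"sd_{label_b}": res.sd_b,
            "n_pairs": res.n, "t": res.t, "p": res.p,
        })
    out = pd.DataFrame(rows)
    defined = out["p"].notna()
    out["p_bh"] = np.nan
    if defined.any():
        out.loc[defined, "p_bh"] = stats.false_discovery_control(
            out.loc[defined, "p"].to_numpy()
        )
    return out


def primer_extension_proportion(intensity_modified: float,
                                intensity_stop: float) -> float:
    """Proportion of the modified species from primer-extension intensities.

    For two gel bands a (extension stopped at the modified base) and b
    (the upstream control stop), the modified proportion is a / (a + b).
    """
    if intensity_modified < 0 or intensity_stop < 0:
        raise ValueError("intensities must be >= 0")
    total = intensity_modified + intensity_stop
    if total == 0:
        raise ValueError("both intensities are zero: proportion undefined")
    return intensity_modified / total
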