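"""Shared test utilities: an independent alignment oracle and a pipeline runner.

The brute-force enumerator below is deliberately naive pure Python — it
re-derives placements, strata and uniqueness from first principles and
shares no code with the package's aligner, so it can serve as an oracle.
"""

from __future__ import annotations

from tmodscan import (SimulationConfig, align_library, build_position_table,
                      simulate_reads)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_force_align(read: str, mature_seqs: dict[str, str],
                      max_mismatch: int = 3, max_hits: int = 10):
    """Enumerate every ungapped end-to-end placement in both orientations.

    Returns (status, stratum) where stratum is a sorted list of
    (n_mismatch, ref_name, start_1based, orientation) for the
    minimum-distance stratum, or [] when unaligned/suppressed.
    """
    placements = []
    for name, seq in mature_seqs.items():
        for orient, r in (("sense", read), ("antisense", revcomp(read))):
            for off in range(len(seq) - len(r) + 1):
                window = seq[off:off + len(r)]
                d = sum(1 for a, b in zip(window, r) if a != b or a == "N")
                if d <= max_mismatch:
                    placements.append((d, name, off + 1, orient))
    if not placements:
        return "unaligned", []
    best = min(p[0] for p in placements)
    stratum = sorted(p for p in placements if p[0] == best)
    if len(stratum) > max_hits:
        return "suppressed", []
    return "aligned", stratum


def simulate_align_pileup(refset, **config_kwargs):
    """Simulate a library, align it and build position tables in one go."""
    config = SimulationConfig(reference_set=refset, **config_kwargs)
    reads, truths = simulate_reads(config)
    records, summary, unplaced = align_library(reads, refset)
    tables = build_position_table(records, refset)
    return {
        "reads": reads,
        "truths": truths,
        "records": records,
        "summary": summary,
        "unplaced": unplaced,
        "tables": tables,
    }
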