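"""Simulator for demethylase-treated tRNA sequencing (DM-tRNA-seq) reads.

DM-tRNA-seq libraries are built without fragmentation by a thermostable
group II intron RT (TGIRT), so every cDNA starts at the tRNA 3' terminus
(after the CCA and any oligo(A) extension) and extends 5'-ward.  At a
Watson-Crick-face modification such as m1A the RT either terminates
prematurely (an "RT stop") or reads through with a misincorporation; an
AlkB demethylase pre-treatment erases methyl marks, so a treated library
loses both signatures at methyl sites.

The simulator draws molecules with fully recorded ground truth:

1. heteroplasmic genomic variant applied with its fraction;
2. CCA present/absent at the 3' end;
3. oligo(A) tail drawn from the pool-specific length distribution
   (by default only CCA-lacking molecules are adenylated);
4. each profiled site carries its modification with probability ``f``;
5. reverse transcription from the molecule 3' terminus: at each modified
   template position the RT stops with probability ``s`` *before copying
   it* (the read then covers positions strictly 3' of the site), else
   reads through and misincorporates with probability ``m``;
6. uniform per-base sequencing error;
7. cDNAs shorter than ``min_insert_len`` are lost during library
   construction; they are counted and resampled so the library size stays
   exact — this loss is what turns 3'-proximal MI values into lower bounds.

Reads are written to FASTQ in cDNA orientation (reverse complement of tRNA
sense) with constant quality, the orientation a TGIRT library sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .reference_model import ReferenceSet, TRNAReference

__all__ = [
    "ModificationProfile",
    "HeteroplasmicVariant",
    "SimulationConfig",
    "TruthRecord",
    "simulate_molecule",
    "simulate_reads",
    "simulate_library",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ModificationProfile:
    """Ground-truth behaviour of one modified site.

    ``stop_prob`` and ``mut_prob`` describe the RT signature given a
    modified template: termination probability and, on read-through, the
    misincorporation probability.  ``demethylase_sensitive`` marks methyl
    modifications (m1A/m1G/m3C class) erased by AlkB treatment; a
    2-thio-containing wobble modification like tau-m5s2U is insensitive and
    produces read-through mutations only.
    """

    ref_name: str
    mature_index: int
    fraction: float
    stop_prob: float
    mut_prob: float
    mut_base: str = "random"  # substituted base, or "random" = uniform non-template
    demethylase_sensitive: bool = True

    def __post_init__(self) -> None:
        for label, v in (("fraction", self.fraction), ("stop_prob", self.stop_prob),
                         ("mut_prob", self.mut_prob)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{label} must be in [0,1], got {v}")
        if self.mut_base != "random" and self.mut_base not in _BASES:
            raise ValueError(f"mut_base must be one of {_BASES} or 'random'")


@dataclass(frozen=True)
class HeteroplasmicVariant:
    """A genomic point variant carried by a fraction of molecules (heteroplasmy)."""

    ref_name: str
    mature_index: int
    alt_base: str
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"heteroplasmy fraction must be in [0,1], got {self.fraction}")
        if self.alt_base not in _BASES:
            raise ValueError(f"alt_base must be one of {_BASES}")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated library.

    ``reads_per_ref`` gives exact counts; alternatively supply
    ``relative_abundance`` plus ``total_reads`` for multinomial allocation.
    ``oligoA_mean_*`` are means of geometric tail-length distributions
    (support 0, 1, 2, ...); by default only CCA-lacking molecules receive
    tails, mirroring the observation that oligoadenylation is widespread
    but confined to the pool lacking the CCA extension.
    """

    reference_set: ReferenceSet
    profiles: Sequence[ModificationProfile] = ()
    reads_per_ref: Mapping[str, int] | None = None
    relative_abundance: Mapping[str, float] | None = None
    total_reads: int | None = None
    variants: Sequence[HeteroplasmicVariant] = ()
    cca_absent_fraction: float | Mapping[str, float] = 0.0
    oligoA_mean_cca_absent: float = 0.0
    oligoA_mean_cca_present: float = 0.0
    seq_error_rate: float = 0.001
    min_insert_len: int = 15
    demethylase_treated: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        refs = self.reference_set
        for p in self.profiles:
            if p.ref_name not in refs:
                raise ValueError(f"profile references absent reference {p.ref_name!r}")
            if not 1 <= p.mature_index <= refs[p.ref_name].mature_len:
                raise ValueError(
                    f"profile index {p.mature_index} invalid for {p.ref_name!r}"
                )
        for v in self.variants:
            if v.ref_name not in refs:
                raise ValueError(f"variant references absent reference {v.ref_name!r}")
            if not 1 <= v.mature_index <= refs[v.ref_name].gene_len:
                raise ValueError(
                    f"variant index {v.mature_index} must fall in the gene body of "
                    f"{v.ref_name!r}"
                )
        if self.reads_per_ref is None and (
            self.relative_abundance is None or self.total_reads is None
        ):
            raise ValueError(
                "supply reads_per_ref, or relative_abundance together with total_reads"
            )
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must be in [0,1)")
        if self.min_insert_len < 1:
            raise ValueError("min_insert_len must be >= 1")
        if self.oligoA_mean_cca_absent < 0 or self.oligoA_mean_cca_present < 0:
            raise ValueError("oligo(A) means must be >= 0")

    def cca_absent(self, ref_name: str) -> float:
        if isinstance(self.cca_absent_fraction, Mapping):
            return float(self.cca_absent_fraction.get(ref_name, 0.0))
        return float(self.cca_absent_fraction)

    def counts(self, rng: np.random.Generator) -> dict[str, int]:
        """Per-reference read counts (exact, or multinomial from abundances)."""
        if self.reads_per_ref is not None:
            for name in self.reads_per_ref:
                if name not in self.reference_set:
                    raise ValueError(f"reads_per_ref names absent reference {name!r}")
            return {k: int(v) for k, v in self.reads_per_ref.items()}
        names = list(self.relative_abundance)
        for name in names:
            if name not in self.reference_set:
                raise ValueError(f"relative_abundance names absent reference {name!r}")
        weights = np.asarray([self.relative_abundance[n] for n in names], dtype=float)
        draw = rng.multinomial(int(self.total_reads), weights / weights.sum())
        return dict(zip(names, (int(c) for c in draw)))


@dataclass
class TruthRecord:
    """Everything the simulator decided for one read."""

    read_id: str
    ref_name: str
    stop_pos: int | None          # uncopied position; None = full-length cDNA
    modified_positions: tuple[int, ...]
    mutated_positions: tuple[int, ...]
    cca_present: bool
    tail_len: int
    variant_alleles: tuple[str, ...]   # "index:alt" for applied variants
    read_len: int
    n_resampled: int = 0          # short cDNAs lost before this read was kept


def _draw_tail(mean: float, rng: np.random.Generator) -> int:
    """Geometric tail length on {0,1,2,...} with the given mean."""
    if mean <= 0:
        return 0
    p = 1.0 / (mean + 1.0)
    return int(rng.geometric(p)) - 1


def simulate_molecule(ref: TRNAReference, config: SimulationConfig,
                      rng: np.random.Generator, read_id: str = "read") -> tuple[str, TruthRecord]:
    """Draw one sequenced molecule; returns (read in tRNA sense, truth).

    Short cDNAs (< ``min_insert_len``) are lost from the library and
    resampled; the number of losses is recorded on the returned truth.
    """
    profiles = [
        p for p in config.profiles
        if p.ref_name == ref.name
        and not (config.demethylase_treated and p.demethylase_sensitive)
    ]
    variants = [v for v in config.variants if v.ref_name == ref.name]
    err = config.seq_error_rate
    n_resampled = 0

    while True:
        body = list(ref.gene_seq)
        applied: list[str] = []
        for v in variants:
            if rng.random() < v.fraction:
                body[v.mature_index - 1] = v.alt_base
                applied.append(f"{v.mature_index}:{v.alt_base}")
        cca_present = rng.random() >= config.cca_absent(ref.name)
        if cca_present:
            body.extend("CCA")
        tail_mean = (config.oligoA_mean_cca_present if cca_present
                     else config.oligoA_mean_cca_absent)
        tail_len = _draw_tail(tail_mean, rng)
        molecule = body + ["A"] * tail_len
        body_len = len(body)

        modified = tuple(sorted(
            p.mature_index for p in profiles
            if p.mature_index <= body_len and rng.random() < p.fraction
        ))
        by_index = {p.mature_index: p for p in profiles}

        # RT walks 3'->5'; stop-before-copy: a stop at p leaves p uncopied.
        start = 1
        mutated: list[int] = []
        for pos in sorted(modified, reverse=True):
            prof = by_index[pos]
            if rng.random() < prof.stop_prob:
                start = pos + 1
                mutated = [q for q in mutated if q >= start]
                break
            if rng.random() < prof.mut_prob:
                template = molecule[pos - 1]
                if prof.mut_base != "random" and prof.mut_base != template:
                    molecule[pos - 1] = prof.mut_base
                else:
                    choices = [b for b in _BASES if b != template]
                    molecule[pos - 1] = choices[int(rng.integers(3))]
                mutated.append(pos)

        read = molecule[start - 1:]
        if err > 0.0 and read:
            hits = np.flatnonzero(rng.random(len(read)) < err)
            for i in hits:
                current = read[i]
                choices = [b for b in _BASES if b != current]
                read[i] = choices[int(rng.integers(3))]
        if len(read) < config.min_insert_len:
            n_resampled += 1
            continue
        truth = TruthRecord(
            read_id=read_id,
            ref_name=ref.name,
            stop_pos=start - 1 if start > 1 else None,
            modified_positions=modified,
            mutated_positions=tuple(sorted(mutated)),
            cca_present=cca_present,
            tail_len=tail_len,
            variant_alleles=tuple(applied),
            read_len=len(read),
            n_resampled=n_resampled,
        )
        return "".join(read), truth


def simulate_reads(config: SimulationConfig) -> tuple[list[tuple[str, str]], list[TruthRecord]]:
    """Simulate a library in memory.

    Returns ``(reads, truths)`` where reads are ``(read_id, sequence)`` in
    cDNA orientation (as they would appear in the FASTQ).
    """
    rng = np.random.default_rng(config.rng_seed)
    counts = config.counts(rng)
    reads: list[tuple[str, str]] = []
    truths: list[TruthRecord] = []
    serial = 0
    for name in counts:
        ref = config.reference_set[name]
        for _ in range(counts[name]):
            read_id = f"read{serial:07d}"
            serial += 1
            sense, truth = simulate_molecule(ref, config, rng, read_id)
            reads.append((read_id, reverse_complement(sense)))
            truths.append(truth)
    return reads, truths


def simulate_library(config: SimulationConfig, fastq_path: str | Path,
                     truth_path: str | Path) -> dict:
    """Simulate and write a FASTQ plus a per-read ground-truth TSV.

    Byte-identical output under a fixed ``rng_seed``.  Returns a summary
    dict (read counts, short-cDNA losses).
    """
    reads, truths = simulate_reads(config)
    with open(fastq_path, "w") as fq:
        for read_id, seq in reads:
            fq.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
    n_discarded = sum(t.n_resampled for t in truths)
    with open(truth_path, "w") as fh:
        fh.write(f"# discarded_short_cdna\t{n_discarded}\n")
        fh.write("read_id\tref\tstop_pos\tmodified\tmutated\tcca\ttail_len\t"
                 "variants\tread_len\n")
        for t in truths:
            fh.write(
                f"{t.read_id}\t{t.ref_name}\t"
                f"{'full' if t.stop_pos is None else t.stop_pos}\t"
                f"{','.join(map(str, t.modified_positions)) or '-'}\t"
                f"{','.join(map(str, t.mutated_positions)) or '-'}\t"
                f"{int(t.cca_present)}\t{t.tail_len}\t"
                f"{','.join(t.variant_alleles) or '-'}\t{t.read_len}\n"
            )
    return {
        "n_reads": len(reads),
        "n_discarded_short": n_discarded,
        "demethylase_treated": config.demethylase_treated,
    }
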