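"""Reference model for mature mitochondrial tRNAs.

A mitochondrial tRNA gene is transcribed and matured by addition of the
3'-terminal CCA (by TRNT1).  All downstream coordinates in this package are
1-based, inclusive, on the *mature* (CCA-appended) sequence, 5'->3' in tRNA
sense — the coordinate system of a per-position "sequencing plot".

Because human mitochondrial tRNAs lack classical D/T arms, conventional
tRNA numbering (e.g. position 58 in the T-loop) cannot be derived from the
sequence; it is supplied as metadata (``numbering_map``).  For mt-tRNA-Lys
the conventional position 58 sits at mature-sequence nucleotide 54
(genomic m.8348).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TRNAReference",
    "ReferenceSet",
    "load_references",
    "build_polyA_reference",
    "resolve_position",
    "distance_to_3prime",
    "synthetic_reference_set",
    "write_reference_fasta",
    "write_reference_metadata",
]

_VALID_BASES = frozenset("ACGTN")
#: sanity bounds on a (mito) tRNA gene length, nt
MIN_GENE_LEN = 55
MAX_GENE_LEN = 100


@dataclass(frozen=True)
class TRNAReference:
    """One mature tRNA reference: gene body plus the post-transcriptional CCA.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"MT-TK"`` (mitochondrially encoded tRNA-Lys).
    gene_seq:
        Genomic tRNA gene, 5'->3' in tRNA sense, without CCA.
    strand:
        Coding-strand label, ``"H"`` (heavy) or ``"L"`` (light); metadata only.
    genome_start:
        Optional 1-based genomic coordinate of the gene 5' end (for labels
        such as m.8344; no genome alignment is ever performed).
    numbering_map:
        Conventional tRNA position -> 1-based mature-sequence index.
    """

    name: str
    gene_seq: str
    strand: str = "H"
    genome_start: int | None = None
    numbering_map: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.gene_seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"reference {self.name!r}: invalid characters {sorted(bad)} "
                "(alphabet is A/C/G/T/N)"
            )
        if not MIN_GENE_LEN <= len(self.gene_seq) <= MAX_GENE_LEN:
            raise ValueError(
                f"reference {self.name!r}: gene length {len(self.gene_seq)} outside "
                f"[{MIN_GENE_LEN}, {MAX_GENE_LEN}]"
            )
        if self.strand not in ("H", "L"):
            raise ValueError(f"reference {self.name!r}: strand must be 'H' or 'L'")
        vals = list(self.numbering_map.values())
        if len(set(vals)) != len(vals):
            raise ValueError(f"reference {self.name!r}: numbering_map values not unique")
        for conv, idx in self.numbering_map.items():
            if not 1 <= idx <= len(self.gene_seq):
                raise ValueError(
                    f"reference {self.name!r}: numbering_map {conv}->{idx} outside "
                    f"[1, {len(self.gene_seq)}]"
                )

    @property
    def mature_seq(self) -> str:
        """Gene body with the 3' CCA appended."""
        return self.gene_seq + "CCA"

    @property
    def gene_len(self) -> int:
        return len(self.gene_seq)

    @property
    def mature_len(self) -> int:
        return len(self.gene_seq) + 3


@dataclass
class ReferenceSet:
    """A named collection of :class:`TRNAReference` plus remapping policy.

    ``polyA_n`` is the length of the adenosine tract appended for the
    remapping pass used to place oligoadenylated reads (default 30).
    """

    references: dict[str, TRNAReference]
    polyA_n: int = 30

    def __post_init__(self) -> None:
        if self.polyA_n < 1:
            raise ValueError("polyA_n must be >= 1")
        for name, ref in self.references.items():
            if name != ref.name:
                raise ValueError(f"key {name!r} does not match reference name {ref.name!r}")

    def __iter__(self) -> Iterator[TRNAReference]:
        return iter(self.references.values())

    def __len__(self) -> int:
        return len(self.references)

    def __contains__(self, name: str) -> bool:
        return name in self.references

    def __getitem__(self, name: str) -> TRNAReference:
        return self.references[name]

    @property
    def names(self) -> list[str]:
        return list(self.references)


def load_references(fasta_path: str | Path, metadata_path: str | Path | None = None,
                    polyA_n: int = 30) -> ReferenceSet:
    """Load a tRNA reference set from FASTA plus optional TSV metadata.

    The FASTA holds gene bodies (no CCA); the CCA is appended here to form
    mature sequences.  The metadata TSV has columns ``name``, ``strand``,
    ``genome_start`` and ``numbering`` (semicolon-separated ``conv:idx``
    pairs); records missing from the metadata default to strand "H" and an
    empty numbering map.

    Raises
    ------
    ValueError
        On duplicate record names or non-ACGTN characters.
    """
    meta: dict[str, dict] = {}
    if metadata_path is not None:
        with open(metadata_path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                entry: dict = {"strand": row.get("strand") or "H"}
                gs = row.get("genome_start")
                entry["genome_start"] = int(gs) if gs not in (None, "", "NA") else None
                numbering: dict[int, int] = {}
                for pair in (row.get("numbering") or "").split(";"):
                    pair = pair.strip()
                    if pair:
                        conv, idx = pair.split(":")
                        numbering[int(conv)] = int(idx)
                entry["numbering_map"] = numbering
                meta[row["name"]] = entry

    references: dict[str, TRNAReference] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        name = record.id
        if name in references:
            raise ValueError(f"duplicate reference name {name!r} in {fasta_path}")
        info = meta.get(name, {})
        references[name] = TRNAReference(
            name=name,
            gene_seq=str(record.seq).upper(),
            strand=info.get("strand", "H"),
            genome_start=info.get("genome_start"),
            numbering_map=info.get("numbering_map", {}),
        )
    return ReferenceSet(references=references, polyA_n=polyA_n)


def build_polyA_reference(ref: TRNAReference, n: int) -> str:
    """Mature sequence with ``n`` adenosines appended (remapping reference)."""
    if n < 1:
        raise ValueError(f"poly-A length must be >= 1, got {n}")
    return ref.mature_seq + "A" * n


def resolve_position(ref: TRNAReference, conventional_pos: int) -> int:
    """Map a conventional tRNA position to its 1-based mature-sequence index."""
    try:
        return ref.numbering_map[conventional_pos]
    except KeyError:
        raise LookupError(
            f"conventional position {conventional_pos} not mapped for {ref.name!r}; "
            f"available: {sorted(ref.numbering_map)}"
        ) from None


def distance_to_3prime(ref: TRNAReference, mature_index: int) -> int:
    """Number of nucleotides strictly 3' of ``mature_index`` on the mature sequence."""
    if not 1 <= mature_index <= ref.mature_len:
        raise ValueError(
            f"mature index {mature_index} outside [1, {ref.mature_len}] for {ref.name!r}"
        )
    return ref.mature_len - mature_index


# ---------------------------------------------------------------------------
# Synthetic reference fixtures
# ---------------------------------------------------------------------------

#: the 22 mitochondrially encoded tRNA gene names (human nomenclature)
MT_TRNA_NAMES = [
    "MT-TF", "MT-TV", "MT-TL1", "MT-TI", "MT-TQ", "MT-TM", "MT-TW", "MT-TA",
    "MT-TN", "MT-TC", "MT-TY", "MT-TS1", "MT-TD", "MT-TK", "MT-TG", "MT-TR",
    "MT-TH", "MT-TS2", "MT-TL2", "MT-TE", "MT-TT", "MT-TP",
]
_L_STRAND = {"MT-TQ", "MT-TA", "MT-TN", "MT-TC", "MT-TY", "MT-TS1", "MT-TE", "MT-TP"}


def synthetic_reference_set(seed: int = 8344, n_refs: int = 22, polyA_n: int = 30) -> ReferenceSet:
    """Generate a synthetic mt-tRNA-like reference set with known landmarks.

    The sequences are random tRNA-length DNA (not real human sequences) but
    the set mirrors the mitochondrial tRNA pool: 22 genes named after the
    human mt-tRNAs, and a "MT-TK" fixture with a 70-nt gene whose landmarks
    match the tRNA-Lys geometry used throughout: conventional position 58 at
    mature index 54 (an A, the m1A58 site, 19 nt from the mature 3' end),
    position 9 at index 9 (A), the anticodon wobble position 34 at index 34
    (T), and the m.8344-equivalent variant site at gene index 50 (A).
    All cross-reference 15-mers are unique so reads >= 15 nt place uniquely.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    names = MT_TRNA_NAMES[:n_refs]
    if len(names) < n_refs:
        names = names + [f"SYN-T{i}" for i in range(n_refs - len(names))]

    def _kmers(seq: str, k: int = 15) -> set[str]:
        rc = str(Seq(seq).reverse_complement())
        out = set()
        for s in (seq, rc):
            out.update(s[i:i + k] for i in range(len(s) - k + 1))
        return out

    seen_kmers: set[str] = set()
    references: dict[str, TRNAReference] = {}
    for name in names:
        gene_len = 70 if name == "MT-TK" else int(rng.integers(64, 75))
        for _attempt in range(100):
            seq = list(rng.choice(bases, size=gene_len))
            if name == "MT-TK":
                seq[8] = "A"    # conventional 9 (m1A9 site)
                seq[33] = "T"   # wobble U34 site
                seq[49] = "A"   # m.8344-equivalent variant site (gene index 50)
                seq[53] = "A"   # conventional 58 / m1A58 site (mature index 54)
            gene = "".join(seq)
            kmers = _kmers(gene + "CCA")
            if kmers.isdisjoint(seen_kmers):
                seen_kmers |= kmers
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not draw a divergent sequence for {name}")
        if name == "MT-TK":
            numbering: dict[int, int] = {9: 9, 34: 34, 58: 54}
            genome_start: int | None = 8295  # real MT-TK locus start, for labels
        else:
            numbering = {9: 9, 34: 34}
            genome_start = int(rng.integers(500, 16000))
        references[name] = TRNAReference(
            name=name,
            gene_seq=gene,
            strand="L" if name in _L_STRAND else "H",
            genome_start=genome_start,
            numbering_map=numbering,
        )
    return ReferenceSet(references=references, polyA_n=polyA_n)


def write_reference_fasta(refset: ReferenceSet, path: str | Path) -> None:
    """Write gene bodies (no CCA) as FASTA, the on-disk reference format."""
    records = [SeqRecord(Seq(ref.gene_seq), id=ref.name, description="") for ref in refset]
    SeqIO.write(records, str(path), "fasta")


def write_reference_metadata(refset: ReferenceSet, path: str | Path) -> None:
    """Write the TSV metadata side-car consumed by :func:`load_references`."""
    with open(path, "w") as fh:
        fh.write("name\tstrand\tgenome_start\tnumbering\n")
        for ref in refset:
            numbering = ";".join(f"{c}:{i}" for c, i in sorted(ref.numbering_map.items()))
            gs = "" if ref.genome_start is None else str(ref.genome_start)
            fh.write(f"{ref.name}\t{ref.strand}\t{gs}\t{numbering}\n")
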