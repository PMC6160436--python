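# Methods

`tmodscan` implements a desk-scale DM-tRNA-seq analysis: detection and
quantification of Watson–Crick-face modifications on mitochondrial tRNAs
from reverse-transcriptase stop and misincorporation signatures, together
with 3′-tail classification, abundance and heteroplasmy quantification.
This note describes the model behind each stage, the defaults and why
they were chosen, what the simulator does and does not emulate, and the
numerical conventions.

## Background and model

DM-tRNA-seq builds sequencing libraries from deacylated small RNA with a
thermostable group II intron RT (TGIRT), without fragmentation, so every
cDNA begins at the tRNA 3′ terminus — after the post-transcriptional CCA
and any oligo(A) extension — and extends 5′-ward. Two matched libraries
are prepared per sample: one untreated and one pre-treated with AlkB
demethylases, which erase methyl marks on the Watson–Crick face
(m¹A/m¹G/m³C class). At a methylated template position the RT either
terminates prematurely (an "RT stop") or reads through with a
misincorporation; after demethylase treatment both signatures vanish.
Modifications whose perturbation is not a methyl group — e.g. the 2-thio
of the anticodon-wobble τm⁵s²U — survive treatment and produce
read-through mutations only.

Per position *p* of the mature (CCA-appended) reference, with S(p) reads
stopping at *p*, R(p) reads covering (i.e. copying) *p*, X(p) of those
carrying a non-reference base, and N(p) = S(p) + R(p):

    stop fraction      = S(p) / N(p)
    mutation fraction  = X(p) / N(p)
    Modification Index = stop fraction + mutation fraction  ∈ [0, 1]

For a site modified in a fraction *f* of molecules, with stop probability
*s* and read-through misincorporation probability *m* given modification,
the expected MI is `f·(s + (1−s)·m)`; the MI therefore approximates, and
never exceeds, the modified fraction times the per-event detection
probability.

### Coordinate conventions

All coordinates are 1-based, inclusive, on the mature sequence, 5′→3′ in
tRNA sense. A stop "at p" means *p was not copied* — the read covers
p+1 … 3′ terminus; the simulator and the pileup share this single
convention, and it is why a template methyl at position *q* produces a
mutation peak at *q* with a raw cDNA 5′-terminus peak one position 3′ of
it. Human mitochondrial tRNAs lack classical D/T arms, so conventional
tRNA numbering is supplied as per-reference metadata rather than derived
from sequence: in tRNA-Lys, conventional position 58 is mature nucleotide
54 (genomic m.8348). Genomic coordinates are carried only for labelling;
no genome alignment is performed.

### 3′-proximal lower bound

Stop products from sites near the 3′ end are short; cDNAs below the
library minimum (default 15 nt, `min_insert_len`) are lost during library
construction. At such a site the measured stop fraction collapses toward
zero, and the MI is computed over the *surviving* molecules: its
expectation is `f·(1−s)·m / (1−f·s)` — bounded between the unconditioned
mutation signal `f·(1−s)·m` and the full-detection value
`f·(s+(1−s)·m)`, and always at most *f*. The MI there is a lower bound of
the modified fraction. Positions closer than `lower_bound_threshold`
(default 25 nt; stop mapping is unreliable roughly within this range, and
the value is deliberately configurable because the exact boundary depends
on library construction) to the 3′ end are flagged `lower_bound` in every
position table.

For a flagged site, `estimate_modified_fraction` scales the mutation-only
MI by the mutation share of the full signature at a context-matched site:
the default share 0.5 assumes equal mutation and stop contributions
(reproducing, e.g., 0.24 → 0.48 for an m¹ACA context); the empirical
split of a measured two-signature site (e.g. 0.074/0.16 ≈ 0.46) can be
supplied instead. Estimates above 1 are capped with a warning.

## Alignment policy

Reads are mapped with Bowtie-1-style semantics: ungapped, end-to-end
placement at every offset of every reference in both orientations,
Hamming distance ≤ `max_mismatch` (default 3), best stratum only, read
suppressed when the best stratum exceeds `max_hits` (default 10)
placements, and `unique` iff the stratum has exactly one placement. All
ties within the stratum are reported. Reads shorter than `min_len`
(default 15 nt) are removed first; an optional exact-match adapter trim
(full occurrence, or suffix/prefix overlap ≥ 5 nt) runs before the length
filter and never touches homopolymer stretches, preserving poly(A) tails.
At tRNA scale (≲ 50 references × ~75 nt) exhaustive enumeration with
numpy sliding windows is exact and fast, so no index structure or
heuristic is used; the implementation is validated against a brute-force
enumerator in the test suite.

Reads that fail the primary pass are remapped against references with a
30-adenosine tract appended (`polyA_n`). The remap targets include both
the mature (gene+CCA) and the gene-only variant of each reference:
oligoadenylated molecules *lacking* the CCA could not otherwise place
end-to-end. Bases aligned within the tract are reported as `soft_tail`
(soft-clipped in SAM). Tract mismatches count toward the end-to-end
distance used for strata, but mismatch lists and pileups use templated
positions only. Note that CCA-less reads with very short tails (1–3 A)
can still place in the primary pass with mismatches over the reference
CCA; the tail classifier recovers their tails from those bases, and
modification calling skips the three CCA positions entirely (the CCA is
post-transcriptional, not a modifiable gene position).

Only unique records feed position tables, tail statistics and abundance.
Abundance is preferentially computed from demethylase-treated libraries
(longer reads, better assignment); heteroplasmy at a configured variant
site uses read-through base calls only, because a stop carries no base
call, with non-ref/non-alt bases reported separately as error mass.

## Modification calling

Matched untreated/treated tables are compared per position (coverage
≥ `min_coverage`, default 50, in both — below this the fractions are too
unstable to call):

* `demethylase_sensitive_methyl` — MI_untreated ≥ `mi_min` (0.1) and
  MI_treated ≤ `treated_max` (0.05);
* `non_methyl_signal` — MI ≥ `mi_min` in both (2-thio-type modifications,
  and fixed differences such as heteroplasmic variants);
* `unmodified` otherwise.

The thresholds are this package's defaults — the underlying method
reports MI values without calling cutoffs — and are parameters
everywhere. Calls are signature classes, not chemical identities.

## Tail analysis

Uniquely aligned reads that cover the last gene position are sorted into
CCA-present and CCA-absent pools. CCA presence requires exact,
mismatch-free coverage of all three CCA positions (a read ending "…CC" is
never CCA-present); reads that stop before the gene end are excluded
rather than counted as CCA-absent — absence of evidence is not absence of
CCA. The tail is every read base 3′ of the templated end; its maximal
*terminal* A-run is the oligo(A) length, so mixed tails are reported but
only their terminal run counts as adenylation. Per-pool length
distributions are reported with pools smaller than `min_pool` (20)
flagged low-confidence.

## Statistics

Replicate agreement is the Pearson correlation of abundance fractions (or
MI vectors); zero-variance vectors give an undefined r, reported as NaN.
Condition comparisons use the paired sample t test,
`t = mean(d)/(sd(d)/√n)` with n−1 df and a two-sided p; zero-variance
differences leave t undefined rather than infinite. No multiple-testing
correction is applied to the primary results; a Benjamini–Hochberg column
is emitted alongside, labelled as an extension. The primer-extension
helper computes the modified proportion a/(a+b) from two band
intensities.

## The simulator

The generator draws each molecule in a fixed order: (1) heteroplasmic
variant with its fraction; (2) CCA present/absent; (3) oligo(A) tail from
a geometric distribution on {0, 1, 2, …} with the configured pool mean —
by default only CCA-less molecules are adenylated, matching the observed
confinement of oligoadenylation to the pool lacking the CCA, while tails
on CCA-bearing molecules can be enabled to emulate a deadenylase-deficient
scenario; (4) each profiled site modified with probability *f*; (5) RT
synthesis 3′→5′ with stop-before-copy at probability *s* and read-through
misincorporation at probability *m* per modified site (demethylase
treatment removes sensitive profiles entirely); (6) uniform per-base
sequencing error (default 0.001, a typical Illumina substitution rate);
(7) cDNAs shorter than `min_insert_len` are counted as lost and
resampled, keeping the library size exact while reproducing the
3′-proximal detection loss. Reads are written in cDNA orientation
(reverse complement of tRNA sense) with constant quality — no stage of
the analysis uses base quality.

Per-modification signature strengths are not measurable from first
principles; the defaults used in the bundled demo (m¹A-like: s = 0.45,
m = 0.45; τm⁵s²U-like: s = 0, m = 0.25) are calibration knobs chosen to
produce MI magnitudes in the range reported for real mt-tRNA sites, not
ground truth about RT chemistry.

The bundled synthetic reference set mirrors the mitochondrial pool in
shape — 22 genes with the human mt-tRNA names, tRNA-length (64–74 nt)
random sequences, strand labels, and a tRNA-Lys fixture with the real
landmark geometry (70-nt gene; A at mature index 54 = conventional 58,
19 nt from the 3′ end; wobble position 34; variant site at gene index 50,
the m.8344 equivalent; genomic start 8295) — but the sequences are random,
generated with all cross-reference 15-mers unique so that reads of the
minimum aligned length place uniquely. Real mt-tRNA references can be
supplied as FASTA + metadata TSV at any entry point.

What the simulator does *not* emulate: adapter read-through, PCR
duplicates and chimeras, quality-score structure, context-dependent RT
behaviour, correlated modifications on one molecule, nuclear-encoded
tRNAs and their sequence families, and the circularization artifacts of
real library construction. Passing tests therefore demonstrate that the
analysis recovers known signals under the stated noise model — not that
it is robust to every artifact of real libraries; in particular, real
multi-mapping structure among near-identical nuclear tRNA isodecoders is
absent here (mitochondrial tRNA sequences are unique and divergent, so
this matches the intended scope).

## Numerical and design choices

* Shared denominator N(p) = S(p) + R(p) for both fractions guarantees
  MI ∈ [0, 1] and the clean recovery formula; a stop+mutation sum above 1
  raises an error instead of being clipped, because it can only arise
  from a denominator inconsistency. The denominator is defined from S and
  R directly (rather than "reads covering p+1") so it remains correct at
  pool boundaries where CCA-less read bodies end at the gene end.
* Tie-breaking: alignment output is deterministically ordered by
  (read id, reference, start); within a stratum all placements are
  reported, none preferred.
* Per-sample simulation seeds are derived from the run seed with
  `numpy.random.SeedSequence`, making every library independent yet the
  whole run byte-reproducible.
* Degenerate inputs: empty pools give empty (flagged) distributions;
  zero-coverage positions have NaN fractions and `coverage_ok = False`;
  an all-adapter read trims to empty and is removed by the length filter.
* Problem sizes in the test suite (10⁴–5·10⁴ reads per check, 22
  references) were chosen so that binomial/multinomial error bands at 4
  SD are a few per mille to a few percent — small enough to detect real
  defects, while each check runs in seconds.

## Known limitations

* The aligner is exact but brute-force; it is not intended for
  genome-scale reference sets.
* MI cannot separate co-occurring signatures at one position (e.g. a
  variant plus a modification), and per-molecule co-occurrence of two
  sites is observable only for reads spanning both without stopping.
* The ~25-nt stop-accuracy threshold and the mutation-share scaling are
  heuristics inherited from the method; both are exposed as parameters
  rather than resolved.
* Modification calls on 3′-proximal (flagged) positions compare lower
  bounds, not modified fractions.
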