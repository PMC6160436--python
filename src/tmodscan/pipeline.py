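"""End-to-end orchestration: simulate -> align -> modcall -> tails -> quantify.

A run is driven by one TOML config (see :func:`write_demo` for a complete
example) holding the reference paths, per-stage parameters, the
modification/variant ground truth for simulated samples, and a sample
sheet of (id, condition, replicate, treated) entries.  Samples either name
a FASTQ or are simulated with a per-sample seed derived deterministically
from the run seed, so a fixed config+seed reproduces byte-identical
outputs.  All artifacts are plain text (FASTQ/SAM/TSV/JSON) so every stage
is independently inspectable.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .modification_index import (PositionTable, build_position_table,
                                 call_modifications)
from .quantify_compare import (abundance, compare_abundance, heteroplasmy,
                               replicate_correlation)
from .read_alignment import align_library, write_sam
from .reference_model import (ReferenceSet, load_references,
                              synthetic_reference_set, write_reference_fasta,
                              write_reference_metadata)
from .synthetic_reads import (HeteroplasmicVariant, ModificationProfile,
                              SimulationConfig, simulate_library)
from .tail_analysis import adenylation_frequency, classify_tails

__all__ = ["RunConfig", "Sample", "validate_config", "run_pipeline", "write_demo"]

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class Sample:
    id: str
    condition: str
    replicate: int
    treated: bool
    fastq: str = ""


@dataclass
class RunConfig:
    """Validated pipeline configuration (every parameter explicit)."""

    config_path: Path
    seed: int
    fasta: Path
    metadata: Path | None
    polyA_n: int
    align: dict[str, Any]
    modcall: dict[str, Any]
    tails: dict[str, Any]
    simulate: dict[str, Any]
    profiles: list[dict[str, Any]]
    variants: list[dict[str, Any]]
    samples: list[Sample]
    outdir: Path | None = None

    def reference_set(self) -> ReferenceSet:
        return load_references(self.fasta, self.metadata, polyA_n=self.polyA_n)


_ALIGN_DEFAULTS = {"max_mismatch": 3, "max_hits": 10, "min_len": 15, "adapter": ""}
_MODCALL_DEFAULTS = {"min_coverage": 50, "lower_bound_threshold": 25,
                     "mi_min": 0.1, "treated_max": 0.05}
_TAILS_DEFAULTS = {"min_pool": 20}
_SIM_DEFAULTS = {"total_reads": 2000, "seq_error_rate": 0.001, "min_insert_len": 15,
                 "cca_absent_fraction": 0.0, "oligoA_mean_cca_absent": 0.0,
                 "oligoA_mean_cca_present": 0.0, "relative_abundance": {}}


def validate_config(path: str | Path) -> tuple[RunConfig | None, list[str]]:
    """Parse and validate a run config; all errors are collected, not
    first-failure.  Returns (config, []) or (None, errors)."""
    path = Path(path)
    errors: list[str] = []
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except FileNotFoundError:
        return None, [f"config file not found: {path}"]
    except tomllib.TOMLDecodeError as exc:
        return None, [f"config parse error: {exc}"]

    run = raw.get("run", {})
    seed = run.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append("run.seed must be a non-negative integer")

    refs = raw.get("references", {})
    fasta = refs.get("fasta")
    if not fasta:
        errors.append("references.fasta is required")
        fasta_path = Path("")
    else:
        fasta_path = (path.parent / fasta).resolve()
        if not fasta_path.exists():
            errors.append(f"references.fasta does not exist: {fasta_path}")
    metadata = refs.get("metadata")
    metadata_path = None
    if metadata:
        metadata_path = (path.parent / metadata).resolve()
        if not metadata_path.exists():
            errors.append(f"references.metadata does not exist: {metadata_path}")
    polyA_n = refs.get("polyA", 30)
    if not isinstance(polyA_n, int) or polyA_n < 1:
        errors.append("references.polyA must be an integer >= 1")

    align = {**_ALIGN_DEFAULTS, **raw.get("align", {})}
    modcall = {**_MODCALL_DEFAULTS, **raw.get("modcall", {})}
    tails = {**_TAILS_DEFAULTS, **raw.get("tails", {})}
    simulate = {**_SIM_DEFAULTS, **raw.get("simulate", {})}
    for key in ("seq_error_rate", "cca_absent_fraction"):
        v = simulate.get(key)
        if not isinstance(v, (int, float)) or not 0 <= v < 1:
            errors.append(f"simulate.{key} must be in [0,1), got {v!r}")
    if simulate["min_insert_len"] < 1:
        errors.append("simulate.min_insert_len must be >= 1")

    profiles = raw.get("profiles", [])
    for i, p in enumerate(profiles):
        for key in ("ref", "index", "fraction", "stop_prob", "mut_prob"):
            if key not in p:
                errors.append(f"profiles[{i}] missing key {key!r}")
    variants = raw.get("variants", [])
    for i, v in enumerate(variants):
        for key in ("ref", "index", "alt", "fraction"):
            if key not in v:
                errors.append(f"variants[{i}] missing key {key!r}")

    samples: list[Sample] = []
    seen_ids: set[str] = set()
    for i, s in enumerate(raw.get("samples", [])):
        sid = s.get("id")
        if not sid:
            errors.append(f"samples[{i}] missing id")
            continue
        if sid in seen_ids:
            errors.append(f"duplicate sample id {sid!r}")
        seen_ids.add(sid)
        fastq = s.get("fastq", "")
        if fastq:
            fq = (path.parent / fastq).resolve()
            if not fq.exists():
                errors.append(f"samples[{i}] fastq does not exist: {fq}")
            fastq = str(fq)
        samples.append(Sample(
            id=sid,
            condition=s.get("condition", "default"),
            replicate=int(s.get("replicate", 1)),
            treated=bool(s.get("treated", False)),
            fastq=fastq,
        ))
    if not samples:
        errors.append("at least one [[samples]] entry is required")

    outdir = run.get("outdir")
    if errors:
        return None, errors
    return RunConfig(
        config_path=path, seed=seed, fasta=fasta_path, metadata=metadata_path,
        polyA_n=polyA_n, align=align, modcall=modcall, tails=tails,
        simulate=simulate, profiles=profiles, variants=variants, samples=samples,
        outdir=(path.parent / outdir).resolve() if outdir else None,
    ), []


def _sample_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


def _sim_config(cfg: RunConfig, refset: ReferenceSet, sample: Sample,
                seed: int) -> SimulationConfig:
    sim = cfg.simulate
    profiles = [
        ModificationProfile(
            ref_name=p["ref"], mature_index=int(p["index"]),
            fraction=float(p["fraction"]), stop_prob=float(p["stop_prob"]),
            mut_prob=float(p["mut_prob"]),
            mut_base=p.get("mut_base", "random"),
            demethylase_sensitive=bool(p.get("demethylase_sensitive", True)),
        )
        for p in cfg.profiles
        if sample.condition in p.get("conditions", [sample.condition])
    ]
    variants = [
        HeteroplasmicVariant(
            ref_name=v["ref"], mature_index=int(v["index"]),
            alt_base=v["alt"], fraction=float(v["fraction"]),
        )
        for v in cfg.variants
        if sample.condition in v.get("conditions", [sample.condition])
    ]
    weights = {name: 1.0 for name in refset.names}
    weights.update({k: float(v) for k, v in sim["relative_abundance"].items()})
    return SimulationConfig(
        reference_set=refset,
        profiles=profiles,
        relative_abundance=weights,
        total_reads=int(sim["total_reads"]),
        variants=variants,
        cca_absent_fraction=float(sim["cca_absent_fraction"]),
        oligoA_mean_cca_absent=float(sim["oligoA_mean_cca_absent"]),
        oligoA_mean_cca_present=float(sim["oligoA_mean_cca_present"]),
        seq_error_rate=float(sim["seq_error_rate"]),
        min_insert_len=int(sim["min_insert_len"]),
        demethylase_treated=sample.treated,
        rng_seed=seed,
    )


def _read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Execute all stages for every sample, then cross-sample comparisons.

    Writes per-sample FASTQ/truth (simulated samples), SAM, alignment
    summary, position table, tail tables and abundance, then per-condition
    modification calls, condition comparisons, the replicate correlation
    matrix, heteroplasmy at configured variant sites, a manifest and a
    plain-text report.  Any stage failure writes a FAILED marker naming
    the stage and sample, keeps partial outputs, and re-raises.
    """
    out = Path(outdir or config.outdir or "tmodscan_run")
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    sample_id = "-"
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    try:
        refset = config.reference_set()
        note(f"[references] loaded {len(refset)} references from {config.fasta.name}")

        tables: dict[str, dict[str, PositionTable]] = {}
        abundances: dict[str, pd.DataFrame] = {}
        summaries: dict[str, dict] = {}
        all_tail_freqs: list[pd.DataFrame] = []

        for idx, sample in enumerate(config.samples):
            sample_id = sample.id
            sdir = out / sample.id
            sdir.mkdir(exist_ok=True)

            stage = "simulate"
            if sample.fastq:
                reads = _read_fastq(sample.fastq)
                note(f"[{sample.id}] loaded {len(reads)} reads from FASTQ")
            else:
                seed = _sample_seed(config.seed, idx)
                sim_cfg = _sim_config(config, refset, sample, seed)
                stats = simulate_library(sim_cfg, sdir / "reads.fastq",
                                         sdir / "truth.tsv")
                reads = _read_fastq(sdir / "reads.fastq")
                note(f"[{sample.id}] simulated {stats['n_reads']} reads "
                     f"(seed {seed}, treated={sample.treated}, "
                     f"{stats['n_discarded_short']} short cDNAs lost)")

            stage = "align"
            records, summary, unplaced = align_library(
                reads, refset,
                max_mismatch=config.align["max_mismatch"],
                max_hits=config.align["max_hits"],
                min_len=config.align["min_len"],
                adapter=config.align["adapter"] or None,
            )
            write_sam(records, refset, sdir / "aligned.sam", unplaced)
            _write_tsv(pd.DataFrame([summary]), sdir / "alignment_summary.tsv")
            summaries[sample.id] = summary
            note(f"[{sample.id}] aligned: {summary['aligned_unique']} unique, "
                 f"{summary['multimapped']} multimapped, "
                 f"{summary['suppressed']} suppressed, "
                 f"{summary['unaligned']} unaligned, "
                 f"{summary['polyA_remapped']} polyA-remapped, "
                 f"{summary['short_removed']} removed (<{config.align['min_len']} nt)")

            stage = "modcall"
            sample_tables = build_position_table(
                records, refset,
                min_coverage=config.modcall["min_coverage"],
                lower_bound_threshold=config.modcall["lower_bound_threshold"],
            )
            tables[sample.id] = sample_tables
            pos_df = pd.concat(
                [t.table.assign(ref=name) for name, t in sample_tables.items()],
                ignore_index=True,
            )
            cols = ["ref"] + [c for c in pos_df.columns if c != "ref"]
            _write_tsv(pos_df[cols], sdir / "position_table.tsv")

            stage = "tails"
            tail_records, n_excluded = classify_tails(records, refset)
            freq = adenylation_frequency(tail_records,
                                         min_pool=config.tails["min_pool"])
            _write_tsv(freq, sdir / "adenylation.tsv")
            all_tail_freqs.append(freq.assign(sample=sample.id))
            note(f"[{sample.id}] tails: {len(tail_records)} classified, "
                 f"{n_excluded} excluded (no 3' evidence)")

            stage = "quantify"
            ab = abundance(records, refset)
            abundances[sample.id] = ab
            _write_tsv(ab, sdir / "abundance.tsv")

        sample_id = "-"
        stage = "modcall-compare"
        conditions = sorted({s.condition for s in config.samples})
        call_frames = []
        for cond in conditions:
            cond_samples = [s for s in config.samples if s.condition == cond]
            by_rep: dict[int, dict[bool, Sample]] = {}
            for s in cond_samples:
                by_rep.setdefault(s.replicate, {})[s.treated] = s
            for rep, pair in sorted(by_rep.items()):
                if True in pair and False in pair:
                    calls = call_modifications(
                        tables[pair[False].id], tables[pair[True].id], refset,
                        mi_min=config.modcall["mi_min"],
                        treated_max=config.modcall["treated_max"],
                    )
                    call_frames.append(calls.assign(condition=cond, replicate=rep))
        calls_df = (pd.concat(call_frames, ignore_index=True) if call_frames
                    else pd.DataFrame())
        if not calls_df.empty:
            _write_tsv(calls_df, out / "modification_calls.tsv")

        stage = "compare"
        comparisons = pd.DataFrame()
        if len(conditions) == 2:
            # abundance from demethylase-treated libraries when available
            def _cond_tables(cond: str) -> list[pd.DataFrame]:
                chosen = [s for s in config.samples
                          if s.condition == cond and s.treated]
                if not chosen:
                    chosen = [s for s in config.samples if s.condition == cond]
                return [abundances[s.id] for s in
                        sorted(chosen, key=lambda s: s.replicate)]

            ta, tb = _cond_tables(conditions[0]), _cond_tables(conditions[1])
            if len(ta) == len(tb) and len(ta) >= 2:
                comparisons = compare_abundance(ta, tb, conditions[0], conditions[1])
                _write_tsv(comparisons, out / "abundance_comparison.tsv")

        corr = replicate_correlation(
            {sid: list(ab["fraction"]) for sid, ab in abundances.items()}
        )
        corr.to_csv(out / "replicate_correlation.tsv", sep="\t",
                    float_format=_FLOAT_FMT)

        stage = "heteroplasmy"
        het_rows = []
        for v in config.variants:
            v_conds = v.get("conditions")
            for s in config.samples:
                if v_conds and s.condition not in v_conds:
                    continue
                ref = refset[v["ref"]]
                ref_base = ref.mature_seq[int(v["index"]) - 1]
                res = heteroplasmy(
                    tables[s.id][v["ref"]], int(v["index"]), ref_base, v["alt"],
                    min_coverage=config.modcall["min_coverage"],
                )
                het_rows.append({
                    "sample": s.id, "condition": s.condition, "ref": v["ref"],
                    "pos": v["index"], "ref_base": ref_base, "alt_base": v["alt"],
                    "fraction": res.fraction, "coverage": res.coverage,
                    "low_coverage": res.low_coverage,
                })
        if het_rows:
            _write_tsv(pd.DataFrame(het_rows), out / "heteroplasmy.tsv")

        stage = "report"
        manifest = {
            "tool": "tmodscan",
            "version": __version__,
            "seed": config.seed,
            "parameters": {
                "align": config.align, "modcall": config.modcall,
                "tails": config.tails, "simulate": config.simulate,
                "polyA_n": config.polyA_n,
            },
            "profiles": config.profiles,
            "variants": config.variants,
            "samples": [vars(s) for s in config.samples],
            "inputs": {
                "config": _sha256(config.config_path),
                "fasta": _sha256(config.fasta),
                "metadata": _sha256(config.metadata) if config.metadata else None,
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        _write_report(out, config, refset, abundances, calls_df, comparisons,
                      het_rows, pd.concat(all_tail_freqs, ignore_index=True)
                      if all_tail_freqs else pd.DataFrame(), log)
        return out
    except Exception as exc:
        (out / "FAILED").write_text(
            f"stage: {stage}\nsample: {sample_id}\nerror: {exc}\n"
        )
        raise


def _write_report(out: Path, config: RunConfig, refset: ReferenceSet,
                  abundances: dict[str, pd.DataFrame], calls: pd.DataFrame,
                  comparisons: pd.DataFrame, het_rows: list[dict],
                  tail_freq: pd.DataFrame, log: list[str]) -> None:
    lines = ["tmodscan run report", "=" * 60, ""]
    lines.extend(log)
    lines.append("")

    by_cond: dict[str, list[str]] = {}
    for s in config.samples:
        by_cond.setdefault(s.condition, []).append(s.id)
    lines.append("Mean mt-tRNA pool fraction per condition:")
    for cond, sids in sorted(by_cond.items()):
        merged = pd.concat([abundances[sid] for sid in sids])
        means = merged.groupby("ref")["fraction"].mean().sort_values(ascending=False)
        top = ", ".join(f"{r}={f:.3f}" for r, f in means.head(5).items())
        lines.append(f"  {cond}: {top}")
    lines.append("")

    if not calls.empty:
        hits = calls[calls["call"] != "unmodified"]
        lines.append("Modified-site calls (untreated vs demethylase-treated):")
        if hits.empty:
            lines.append("  none")
        else:
            grouped = hits.groupby(["condition", "ref", "pos", "call"])
            for (cond, ref, pos, call), grp in grouped:
                conv = grp["conv_pos"].iloc[0]
                conv_s = f" (conventional {conv})" if pd.notna(conv) else ""
                mi = grp["MI_untreated"].mean()
                lb = " [lower bound]" if grp["lower_bound"].any() else ""
                lines.append(
                    f"  {cond}: {ref} pos {pos}{conv_s}: {call}, "
                    f"mean untreated MI {mi:.3f} over {len(grp)} replicate(s){lb}"
                )
        lines.append("")

    if het_rows:
        lines.append("Heteroplasmy at configured variant sites:")
        for row in het_rows:
            frac = ("insufficient coverage" if row["fraction"] is None
                    else f"{row['fraction']:.3f}")
            lines.append(f"  {row['sample']}: {row['ref']} pos {row['pos']} "
                         f"{row['ref_base']}>{row['alt_base']}: {frac} "
                         f"(coverage {row['coverage']})")
        lines.append("")

    if not comparisons.empty:
        lines.append("Condition comparison of abundance (paired t, raw p):")
        show = comparisons.dropna(subset=["p"]).sort_values("p").head(5)
        for _, row in show.iterrows():
            lines.append(f"  {row['ref']}: t={row['t']:.3f}, p={row['p']:.4f}")
        lines.append("")

    if not tail_freq.empty:
        lines.append("Oligo(A) tails (mean fraction of pool with tail >= 1 nt):")
        tailed = tail_freq[tail_freq["oligoA_len"] >= 1]
        per_sample = tailed.groupby(["sample", "ref", "pool"])["fraction"].sum()
        agg = per_sample.groupby(["ref", "pool"]).mean()
        for (ref, pool), frac in sorted(agg.items()):
            lines.append(f"  {ref} [{pool}]: {frac:.3f}")
        lines.append("")

    (out / "report.txt").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Bundled demo
# ---------------------------------------------------------------------------

_DEMO_CONFIG = """\
# End-to-end demo: two conditions (WT, MERRF) x 3 replicates x
# treated/untreated, all simulated.  The WT condition carries an
# m1A58-like demethylase-sensitive site on MT-TK (mature index 54) which
# is absent in MERRF; MERRF carries the m.8344 A>G-equivalent variant at
# heteroplasmy 0.8.
[run]
seed = {seed}
outdir = "run_out"

[references]
fasta = "references.fa"
metadata = "references.tsv"

[simulate]
total_reads = {reads}
seq_error_rate = 0.001
cca_absent_fraction = 0.3
oligoA_mean_cca_absent = 3.0

[simulate.relative_abundance]
MT-TK = 3.0

[[profiles]]          # m1A9-like, both conditions
ref = "MT-TK"
index = 9
fraction = 0.9
stop_prob = 0.45
mut_prob = 0.45
demethylase_sensitive = true

[[profiles]]          # m1A58-like: WT only (mature index 54)
ref = "MT-TK"
index = 54
fraction = 0.5
stop_prob = 0.45
mut_prob = 0.45
demethylase_sensitive = true
conditions = ["WT"]

[[profiles]]          # tau-m5s2U34-like: read-through mutations only
ref = "MT-TK"
index = 34
fraction = 0.8
stop_prob = 0.0
mut_prob = 0.25
demethylase_sensitive = false

[[variants]]          # m.8344 A>G equivalent, MERRF only
ref = "MT-TK"
index = 50
alt = "G"
fraction = 0.8
conditions = ["MERRF"]
{samples}
"""


def write_demo(directory: str | Path, seed: int = 11, reads: int = 1500) -> Path:
    """Write a complete runnable demo (references + config) and return the
    config path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    refset = synthetic_reference_set()
    write_reference_fasta(refset, directory / "references.fa")
    write_reference_metadata(refset, directory / "references.tsv")
    samples = []
    for cond in ("WT", "MERRF"):
        for rep in (1, 2, 3):
            for treated in (False, True):
                label = "treated" if treated else "untreated"
                samples.append(
                    f'\n[[samples]]\nid = "{cond}_{rep}_{label}"\n'
                    f'condition = "{cond}"\nreplicate = {rep}\n'
                    f"treated = {str(treated).lower()}\n"
                )
    config = directory / "config.toml"
    config.write_text(_DEMO_CONFIG.format(seed=seed, reads=reads,
                                          samples="".join(samples)))
    return config
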