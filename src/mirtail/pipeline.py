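"""End-to-end pipeline driver.

Wires the stages in a fixed order — preprocess, then the strict
quantification branch and the lenient modification branch in parallel over
the same clipped reads, then modification statistics, differential
expression, and an optional promoter motif scan — and writes every output
table plus a structured run log.

``process_study`` is the in-memory core used by the tests and the
acceptance analyses; ``run_pipeline`` wraps it with file I/O so that two
runs on the same inputs produce byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import diffexp, isomir, modstats, motifscan, preprocess, quantify, refio
from .simulate import TRUSEQ_ADAPTER


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and the printed settings of every stage."""

    reference_fasta: str
    reference_gff: str
    sample_sheet: str
    out_dir: str
    adapter: str = TRUSEQ_ADAPTER
    min_overlap: int = 8
    min_q: int = 20
    min_q_fraction: float = 0.95
    min_len: int = 12
    quant_max_len: int = 30
    window: int = 2  # +/- nt templated assignment window
    max_mismatches: int = 2
    count_threshold: int = 2
    frag_min: int = 13
    frag_max: int = 17
    pseudocount: float = 0.5
    base_mean_cutoff: float = 10.0
    alpha: float = 0.05
    promoter_fasta: str | None = None
    pwm_jaspar: str | None = None
    top_k: int = 3
    scan_shuffles: int = 200
    seed: int = 0


@dataclass
class StudyResult:
    """Every table the pipeline computes, in memory."""

    logs: pd.DataFrame
    count_matrix: quantify.CountMatrix
    loci: pd.DataFrame
    calls: dict[str, pd.DataFrame]
    profiles: pd.DataFrame
    tail_hist: pd.DataFrame
    arm_rates: pd.DataFrame
    arm_ratios: dict[str, float]
    fragments: pd.DataFrame
    fragment_fc: pd.DataFrame
    comparisons: pd.DataFrame | None
    diffexp: pd.DataFrame | None
    groups: dict[str, str] = field(default_factory=dict)


def process_study(
    reference: list[refio.HairpinRecord],
    sample_records: dict[str, list[tuple[str, str, int]]],
    groups: dict[str, str],
    cfg: PipelineConfig | None = None,
) -> StudyResult:
    """Run all analysis stages on in-memory reads.

    ``sample_records`` maps sample_id to (sequence, quality, count) raw-read
    records; ``groups`` maps sample_id to condition label ("A" or "B").
    """
    cfg = cfg or PipelineConfig("", "", "", "")
    logs = {}
    quant_reads: dict[str, list[refio.CollapsedRead]] = {}
    mod_reads: dict[str, list[refio.CollapsedRead]] = {}
    for sid, records in sample_records.items():
        collapsed, log = preprocess.preprocess_sample(
            records,
            cfg.adapter,
            sample_id=sid,
            min_overlap=cfg.min_overlap,
            min_fraction=cfg.min_q_fraction,
            min_q=cfg.min_q,
            min_len=cfg.min_len,
            max_len=None,
        )
        # modification branch: >= min_len, no upper cap
        mod_reads[sid] = collapsed
        # quantification branch: PAGE-like size selection caps inserts
        quant_reads[sid] = [r for r in collapsed if len(r.sequence) <= cfg.quant_max_len]
        logs[sid] = vars(log)
    logs_df = pd.DataFrame(logs).T.rename_axis("sample_id")

    cm, loci = quantify.build_count_matrix(quant_reads, reference, window=cfg.window)

    index = isomir.ReferenceIndex(reference, max_interior_mismatches=cfg.max_mismatches)
    calls = {
        sid: isomir.call_sample(reads, index, min_count=cfg.count_threshold)
        for sid, reads in mod_reads.items()
    }
    profiles = modstats.profile_table(calls)
    all_calls = pd.concat(
        [c.assign(sample_id=sid) for sid, c in calls.items()], ignore_index=True
    )
    tail_hist = modstats.tail_length_histogram(all_calls)
    arm_rates = modstats.arm_tailing_rates(all_calls)
    arm_ratios = modstats.arm_uridylation_ratio(all_calls)

    lib_sizes = {sid: int(cm.library_sizes[sid]) for sid in cm.library_sizes.index}
    fragments = modstats.fragment_counts(
        mod_reads, reference, lib_sizes, min_len=cfg.frag_min, max_len=cfg.frag_max
    )
    fragment_fc = modstats.fragment_fold_change(
        fragments, groups, lib_sizes, pseudocount=cfg.pseudocount
    )

    a_ids = [s for s, g in groups.items() if g == "A"]
    b_ids = [s for s, g in groups.items() if g == "B"]
    comparisons = None
    if len(a_ids) >= 2 and len(b_ids) >= 2:
        comparisons = modstats.compare_profiles(profiles.loc[a_ids], profiles.loc[b_ids])
    de = None
    if len(a_ids) >= 2 and len(b_ids) >= 2:
        de = diffexp.nb_wald_test(cm, groups, base_mean_cutoff=cfg.base_mean_cutoff)

    return StudyResult(
        logs=logs_df,
        count_matrix=cm,
        loci=loci,
        calls=calls,
        profiles=profiles,
        tail_hist=tail_hist,
        arm_rates=arm_rates,
        arm_ratios=arm_ratios,
        fragments=fragments,
        fragment_fc=fragment_fc,
        comparisons=comparisons,
        diffexp=de,
        groups=dict(groups),
    )


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """File-based pipeline: read inputs, run all stages, write all tables.

    Deterministic: repeated runs on the same inputs and seed produce
    byte-identical outputs.  Any stage error aborts with the stage name.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("refio"):
        reference = refio.read_hairpin_reference(cfg.reference_fasta, cfg.reference_gff)
        sheet = refio.read_sample_sheet(cfg.sample_sheet)

    with _stage("preprocess"):
        sample_records = {
            row.sample_id: list(preprocess.iter_fastq(row.path)) for row in sheet.itertuples()
        }
    groups = dict(zip(sheet["sample_id"], sheet["condition"]))

    with _stage("analysis"):
        result = process_study(reference, sample_records, groups, cfg)

    with _stage("write"):
        tables: dict[str, pd.DataFrame] = {
            "preprocess_log": result.logs,
            "count_matrix": result.count_matrix.counts,
            "library_sizes": result.count_matrix.library_sizes.to_frame(),
            "locus_hits": result.loci.set_index("sample_id"),
            "isomir_calls": pd.concat(
                [c.assign(sample_id=sid) for sid, c in result.calls.items()],
                ignore_index=True,
            ).set_index("sample_id"),
            "modification_profiles": result.profiles,
            "tail_histogram": result.tail_hist,
            "arm_tailing_rates": result.arm_rates,
            "arm_ratios": pd.DataFrame([result.arm_ratios], index=["all_samples"]),
            "fragments": result.fragments.set_index("mirna_id"),
            "fragment_fold_change": result.fragment_fc,
        }
        if result.comparisons is not None:
            tables["profile_comparisons"] = result.comparisons
        if result.diffexp is not None:
            tables["diffexp_results"] = result.diffexp
        refio.write_tables(tables, out_dir)

    if cfg.promoter_fasta and cfg.pwm_jaspar:
        with _stage("motifscan"):
            pwm = motifscan.read_jaspar(cfg.pwm_jaspar)
            rows = []
            for rec in SeqIO.parse(cfg.promoter_fasta, "fasta"):
                region = refio.normalize_sequence(rec.seq)
                _best, pval = motifscan.empirical_pvalue(
                    region, pwm, n_shuffles=cfg.scan_shuffles, seed=cfg.seed
                )
                for hit in motifscan.scan_region(region, pwm, cfg.top_k, region_id=rec.id):
                    rows.append(
                        (rec.id, hit.position, hit.strand, hit.score, hit.matched_seq, pval)
                    )
            hits_df = pd.DataFrame(
                rows,
                columns=["region_id", "position", "strand", "score", "matched_seq", "empirical_p"],
            ).set_index("region_id")
            refio.write_tables({"motif_hits": hits_df}, out_dir)

    with _stage("log"):
        with open(out_dir / "run_log.txt", "w") as fh:
            fh.write("stage order: preprocess -> quantify | isomir -> modstats -> diffexp")
            fh.write(f" -> motifscan\nseed: {cfg.seed}\n\nper-sample read accounting:\n")
            fh.write(result.logs.to_string())
            fh.write("\n")
    return out_dir


def make_fixture(out_dir, seed: int = 0, n_hairpins: int = 20, depth: int = 20_000):
    """Generate the small end-to-end test dataset (reference, FASTQs,
    sample sheet, ground truth) under ``out_dir``."""
    from .simulate import SimulationConfig, generate_reference, simulate_reads, write_study

    config = SimulationConfig(n_hairpins=n_hairpins, mean_depth=depth, seed=seed)
    reference = generate_reference(config)
    samples, truth = simulate_reads(reference, config)
    write_study(reference, samples, truth, out_dir)
    return reference, samples, truth
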