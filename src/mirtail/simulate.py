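"""Synthetic small-RNA-seq study generator with complete ground truth.

Emulates a two-condition (control A vs knockdown B), three-replicate small
RNA-seq experiment over a synthetic hairpin reference:

* templated isomiRs at the mature 3' end (+1/+2 extensions, -1/-2 trims),
* nontemplated 3' U- and A-tails with arm-specific rates (uridylation is
  concentrated on the 3p arm, mimicking tailing of the precursor 3' end),
* 13-17 nt 5'-anchored degradation fragments,
* per-miRNA differential expression between conditions,
* a condition-B multiplier on the 3p U-tail rate (knockdown of the
  uridylating activity) and on the fragment rate (impaired surveillance).

Every emitted read has exactly one provenance row in the ground truth, so
recovery of isoform classes, tail lengths, arm ratios and fold changes can be
checked against the truth.

Identifiability
---------------
Hairpin bases in the window where tails can attach (from 2 nt inside each
mature 3' end to 7 nt downstream of it, clipped at the hairpin end) are drawn
from {C, G} only.  A nontemplated U or A tail therefore never coincides with
the template, which makes the templated/nontemplated decomposition of every
simulated read unique under the maximal-templated-extension convention used
by the caller.  Without this restriction the ground truth itself would be
ambiguous.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .refio import HairpinRecord, MatureAnnotation, write_table

#: Illumina TruSeq small-RNA 3' adapter.
TRUSEQ_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

ISOFORM_CLASSES = ("canonical", "templated+1", "templated+2", "trim-1", "trim-2")
#: 3' templated offset of each isoform class.
ISOFORM_OFFSETS = {"canonical": 0, "templated+1": 1, "templated+2": 2, "trim-1": -1, "trim-2": -2}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and per-read generative model.

    Defaults encode the emulated study conditions: 2 conditions x 3
    replicates, ~10x more frequent uridylation on the 3p arm with modal
    U-tail length 3, arm-symmetric (mature-level) adenylation, a halved 3p
    U-tail rate and a 4x fragment rate in condition B.
    """

    n_hairpins: int = 30
    n_samples_per_condition: int = 3
    mean_depth: int = 200_000
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    isoform_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "canonical": 0.60,
            "templated+1": 0.03,
            "templated+2": 0.02,
            "trim-1": 0.22,
            "trim-2": 0.13,
        }
    )
    nta_u_rate: Mapping[str, float] = field(default_factory=lambda: {"5p": 0.003, "3p": 0.03})
    nta_a_rate: Mapping[str, float] = field(default_factory=lambda: {"5p": 0.05, "3p": 0.05})
    u_length_dist: Sequence[float] = (0.15, 0.25, 0.35, 0.15, 0.10)
    a_length_dist: Sequence[float] = (0.70, 0.15, 0.08, 0.05, 0.02)
    fragment_rate: float = 0.01
    de_fraction: float = 0.2
    de_log2fc: float = 1.0
    de_log2fc_overrides: Mapping[str, float] | None = None
    u_rate_multiplier_B_3p: float = 0.5
    fragment_multiplier_B: float = 4.0
    seq_error_rate: float = 0.0
    adapter_seq: str = TRUSEQ_ADAPTER
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_hairpins < 1:
            raise ValueError("n_hairpins must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if abs(sum(self.isoform_mix.values()) - 1.0) > 1e-9:
            raise ValueError("isoform_mix must sum to 1")
        if abs(sum(self.u_length_dist) - 1.0) > 1e-9 or abs(sum(self.a_length_dist) - 1.0) > 1e-9:
            raise ValueError("tail length distributions must sum to 1")
        for rates in (self.nta_u_rate, self.nta_a_rate):
            for v in rates.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("NTA rates must lie in [0, 1]")
        for arm in ("5p", "3p"):
            if self.nta_u_rate[arm] + self.nta_a_rate[arm] > 1.0:
                raise ValueError("per-arm U + A tail rates must not exceed 1")
        return self


@dataclass
class SimulatedSample:
    """One sample's reads, aggregated by identical composition.

    ``records`` rows: (sequence-with-adapter, count, provenance dict).
    Expanding each record ``count`` times yields the per-read FASTQ/truth.
    """

    sample_id: str
    condition: str
    replicate: int
    records: list[tuple[str, int, dict]]

    @property
    def n_reads(self) -> int:
        return sum(c for _, c, _ in self.records)


@dataclass
class GroundTruth:
    """The simulator's record of what it emitted.

    ``mirna`` — per-miRNA truth (abundance shares per condition, log2FC, DE
    flag, arm); ``reads`` — per-composition provenance with counts, one row
    group per emitted read; ``config`` — the generating configuration.
    """

    mirna: pd.DataFrame
    reads: pd.DataFrame
    config: SimulationConfig


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _tail_window(start: int, end: int, hairpin_len: int) -> tuple[int, int]:
    """Hairpin interval that must avoid A/T so tails stay nontemplated."""
    return max(start, end - 2), min(end + 7, hairpin_len)


def generate_reference(config: SimulationConfig, seed: int | None = None) -> list[HairpinRecord]:
    """Generate ``n_hairpins`` hairpins of 60-90 nt with 5p and 3p matures.

    The 5p mature sits in ~[4, 26), the 3p mature ends 4 nt before the
    hairpin 3' end; mature lengths are 20-23 nt.  The 13-nt 5' prefix of
    every mature is required to occur exactly once across the whole
    reference, which makes every templated isoform and 13-17 nt fragment
    (all 5'-anchored) map uniquely.  Bounded retries; error if distinctness
    cannot be satisfied.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cg = np.frombuffer(b"CG", dtype=np.uint8)

    hairpins: list[HairpinRecord] = []
    all_seqs: list[str] = []
    prefixes: set[str] = set()
    for i in range(config.n_hairpins):
        for _attempt in range(200):
            length = int(rng.integers(60, 91))
            seq = _random_seq(rng, length)
            len5 = int(rng.integers(20, 24))
            start5 = int(rng.integers(4, 28 - len5))  # 5p mature within ~[4, 27)
            end5 = start5 + len5
            len3 = int(rng.integers(20, 24))
            end3 = length - 4
            start3 = end3 - len3
            # keep tail-attachment windows template-free for U/A tails
            for s, e in (_tail_window(start5, end5, length), _tail_window(start3, end3, length)):
                seq[s:e] = cg[rng.integers(0, 2, size=e - s)]
            seq_str = seq.tobytes().decode()
            p5 = seq_str[start5 : start5 + 13]
            p3 = seq_str[start3 : start3 + 13]
            if p5 == p3 or p5 in prefixes or p3 in prefixes:
                continue
            occurrences = sum(s.count(p5) + s.count(p3) for s in all_seqs + [seq_str])
            if occurrences != 2:
                continue
            hid = f"hp-{i + 1:03d}"
            record = HairpinRecord(
                hid,
                seq_str,
                [
                    MatureAnnotation(f"mir-{i + 1:03d}-5p", "5p", start5, end5, seq_str[start5:end5]),
                    MatureAnnotation(f"mir-{i + 1:03d}-3p", "3p", start3, end3, seq_str[start3:end3]),
                ],
            ).validate()
            hairpins.append(record)
            all_seqs.append(seq_str)
            prefixes.update((p5, p3))
            break
        else:
            raise RuntimeError(f"could not generate a distinct hairpin after 200 retries (n={i})")
    return hairpins


def assign_effects(reference: list[HairpinRecord], config: SimulationConfig) -> pd.DataFrame:
    """Per-miRNA truth: abundance weight per condition, log2FC and DE flag.

    Abundances are lognormal; a ``de_fraction`` of miRNAs receives
    ``de_log2fc`` in condition B with alternating signs (or explicit values
    from ``de_log2fc_overrides``).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    rows = []
    for hp in reference:
        for m in hp.matures:
            rows.append((m.mirna_id, hp.hairpin_id, m.arm))
    truth = pd.DataFrame(rows, columns=["mirna_id", "hairpin_id", "arm"]).set_index("mirna_id")
    n = len(truth)
    truth["weight_A"] = rng.lognormal(config.abundance_mu, config.abundance_sigma, size=n)
    if config.de_log2fc_overrides is not None:
        lfc = pd.Series(0.0, index=truth.index)
        for k, v in config.de_log2fc_overrides.items():
            lfc[k] = v
    else:
        lfc = pd.Series(0.0, index=truth.index)
        n_de = int(round(config.de_fraction * n))
        de_ids = rng.choice(truth.index.to_numpy(), size=n_de, replace=False)
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        lfc[de_ids] = signs * config.de_log2fc
    truth["log2fc"] = lfc
    truth["is_de"] = lfc != 0.0
    truth["weight_B"] = truth["weight_A"] * 2.0 ** truth["log2fc"]
    for cond in ("A", "B"):
        truth[f"share_{cond}"] = truth[f"weight_{cond}"] / truth[f"weight_{cond}"].sum()
    return truth


def _tail_rates(config: SimulationConfig, arm: str, condition: str) -> tuple[float, float]:
    u = config.nta_u_rate[arm]
    if condition == "B" and arm == "3p":
        u *= config.u_rate_multiplier_B_3p
    return u, config.nta_a_rate[arm]


def _apply_sequencing_errors(
    rng: np.random.Generator, records: list[tuple[str, int, dict]], rate: float, insert_key: str
) -> list[tuple[str, int, dict]]:
    """Uniform substitutions within the insert only, never in the adapter."""
    out: list[tuple[str, int, dict]] = []
    for seq, count, meta in records:
        ilen = meta[insert_key]
        p_hit = 1.0 - (1.0 - rate) ** ilen
        n_err = int(rng.binomial(count, p_hit))
        if count - n_err > 0:
            out.append((seq, count - n_err, meta))
        for _ in range(n_err):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            pos = int(rng.integers(0, ilen))
            choices = _BASES[_BASES != arr[pos]]
            arr[pos] = choices[rng.integers(0, 3)]
            out.append((arr.tobytes().decode(), 1, {**meta, "has_error": True}))
    return out


def simulate_reads(
    reference: list[HairpinRecord], config: SimulationConfig
) -> tuple[list[SimulatedSample], GroundTruth]:
    """Simulate all samples of the two-condition study.

    Returns the per-sample aggregated reads (each record expands to
    ``count`` identical FASTQ reads) and the ground truth.
    """
    config.validate()
    truth_mirna = assign_effects(reference, config)
    matures = {
        m.mirna_id: (hp, m) for hp in reference for m in hp.matures
    }
    tail_lengths = np.arange(1, 6)

    samples: list[SimulatedSample] = []
    read_rows: list[dict] = []
    conditions = ["A"] * config.n_samples_per_condition + ["B"] * config.n_samples_per_condition
    for s_idx, condition in enumerate(conditions):
        replicate = s_idx % config.n_samples_per_condition + 1
        sample_id = f"{condition}{replicate}"
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7, s_idx]))
        shares = truth_mirna[f"share_{condition}"].to_numpy()
        n_per_mirna = rng.multinomial(config.mean_depth, shares)
        frag_rate = config.fragment_rate * (
            config.fragment_multiplier_B if condition == "B" else 1.0
        )
        records: list[tuple[str, int, dict]] = []
        iso_names = list(config.isoform_mix)
        iso_probs = np.array([config.isoform_mix[k] for k in iso_names])
        for mirna_id, n_m in zip(truth_mirna.index, n_per_mirna):
            if n_m == 0:
                continue
            hp, m = matures[mirna_id]
            arm = m.arm
            u_rate, a_rate = _tail_rates(config, arm, condition)
            n_frag = int(rng.binomial(n_m, frag_rate))
            frag_len_counts = rng.multinomial(n_frag, np.full(5, 0.2)) if n_frag else np.zeros(5, int)
            for flen, fcount in zip(range(13, 18), frag_len_counts):
                if fcount == 0:
                    continue
                insert = hp.sequence[m.start : m.start + flen]
                records.append(
                    (
                        insert + config.adapter_seq,
                        int(fcount),
                        {
                            "mirna_id": mirna_id,
                            "arm": arm,
                            "isoform_class": "fragment",
                            "three_offset": flen - (m.end - m.start),
                            "tail_class": "none",
                            "tail_len": 0,
                            "is_fragment": True,
                            "insert_len": flen,
                        },
                    )
                )
            iso_counts = rng.multinomial(n_m - n_frag, iso_probs)
            # tails: [U len 1..5, A len 1..5, untailed]
            tail_probs = np.concatenate(
                [
                    u_rate * np.asarray(config.u_length_dist),
                    a_rate * np.asarray(config.a_length_dist),
                    [1.0 - u_rate - a_rate],
                ]
            )
            for iso, n_iso in zip(iso_names, iso_counts):
                if n_iso == 0:
                    continue
                d3 = ISOFORM_OFFSETS[iso]
                core = hp.sequence[m.start : m.end + d3]
                tail_counts = rng.multinomial(n_iso, tail_probs)
                for slot, n_t in enumerate(tail_counts):
                    if n_t == 0:
                        continue
                    if slot < 5:
                        tail_class, tail_len = "U", int(tail_lengths[slot])
                        tail = "T" * tail_len
                    elif slot < 10:
                        tail_class, tail_len = "A", int(tail_lengths[slot - 5])
                        tail = "A" * tail_len
                    else:
                        tail_class, tail_len, tail = "none", 0, ""
                    insert = core + tail
                    records.append(
                        (
                            insert + config.adapter_seq,
                            int(n_t),
                            {
                                "mirna_id": mirna_id,
                                "arm": arm,
                                "isoform_class": iso,
                                "three_offset": d3,
                                "tail_class": tail_class,
                                "tail_len": tail_len,
                                "is_fragment": False,
                                "insert_len": len(insert),
                            },
                        )
                    )
        if config.seq_error_rate > 0.0:
            records = _apply_sequencing_errors(
                rng, records, config.seq_error_rate, insert_key="insert_len"
            )
        samples.append(SimulatedSample(sample_id, condition, replicate, records))
        for _seq, count, meta in records:
            read_rows.append({"sample_id": sample_id, "condition": condition, "count": count, **meta})

    reads_df = pd.DataFrame(read_rows)
    truth = GroundTruth(mirna=truth_mirna, reads=reads_df, config=config)
    return samples, truth


# ---------------------------------------------------------------------------
# File output


def write_sample_fastq(sample: SimulatedSample, path) -> int:
    """Expand a sample's aggregated records into a Phred+33 FASTQ file."""
    n = 0
    with open(path, "w") as fh:
        for seq, count, _meta in sample.records:
            qual = "I" * len(seq)
            for _ in range(count):
                n += 1
                fh.write(f"@{sample.sample_id}:{n}\n{seq}\n+\n{qual}\n")
    return n


def write_reference(reference: list[HairpinRecord], fasta_path, gff_path) -> None:
    """Write the hairpin FASTA and the mature-annotation GFF3 subset."""
    with open(fasta_path, "w") as fa:
        for hp in reference:
            fa.write(f">{hp.hairpin_id}\n{hp.sequence}\n")
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for hp in reference:
            for m in hp.matures:
                gff.write(
                    f"{hp.hairpin_id}\tmirtail\tmiRNA\t{m.start + 1}\t{m.end}\t.\t+\t.\t"
                    f"ID={m.mirna_id};arm={m.arm}\n"
                )


def write_ground_truth(truth: GroundTruth, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_table(truth.mirna, out_dir / "truth_mirna.tsv")
    truth.reads.to_csv(out_dir / "truth_reads.tsv", sep="\t", index=False)


def write_study(
    reference: list[HairpinRecord],
    samples: list[SimulatedSample],
    truth: GroundTruth,
    out_dir,
) -> Path:
    """Write reference, FASTQs, sample sheet and ground truth under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_reference(reference, out_dir / "reference.fa", out_dir / "reference.gff3")
    rows = []
    for s in samples:
        fq = out_dir / f"{s.sample_id}.fastq"
        write_sample_fastq(s, fq)
        rows.append((s.sample_id, s.condition, s.replicate, str(fq)))
    pd.DataFrame(rows, columns=["sample_id", "condition", "replicate", "path"]).to_csv(
        out_dir / "samples.tsv", sep="\t", index=False
    )
    write_ground_truth(truth, out_dir)
    return out_dir
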