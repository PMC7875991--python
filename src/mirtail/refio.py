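"""Reference data model and file I/O.

Holds the hairpin (pre-miRNA) reference with its mature-miRNA annotations and
the readers/writers for every external format the pipeline touches: FASTA
(hairpins, promoters, collapsed reads), a GFF3 subset carrying mature
annotations, and TSV tables.

Conventions
-----------
* Internal alphabet is DNA: ``U`` is converted to ``T`` on ingest and every
  sequence is uppercased.
* Internal coordinates are 0-based half-open.  GFF3 input is 1-based
  inclusive; the conversion happens at the boundary, nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

_RNA_TO_DNA = str.maketrans("Uu", "Tt")

#: TSV float serialization: 6 significant digits, stable and diffable.
FLOAT_FORMAT = "%.6g"


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA U residues to DNA T."""
    return str(seq).translate(_RNA_TO_DNA).upper()


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA located on its precursor hairpin.

    ``start``/``end`` are 0-based half-open coordinates on the hairpin;
    ``arm`` is ``"5p"`` or ``"3p"``.
    """

    mirna_id: str
    arm: str
    start: int
    end: int
    canonical_seq: str

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"{self.mirna_id}: arm must be '5p' or '3p', got {self.arm!r}")
        if not 16 <= self.end - self.start <= 28:
            raise ValueError(
                f"{self.mirna_id}: mature length {self.end - self.start} outside [16, 28]"
            )


@dataclass
class HairpinRecord:
    """A pre-miRNA hairpin sequence with its mature annotations."""

    hairpin_id: str
    sequence: str
    matures: list[MatureAnnotation] = field(default_factory=list)

    def validate(self) -> "HairpinRecord":
        if len(self.sequence) < 40:
            raise ValueError(f"{self.hairpin_id}: hairpin shorter than 40 nt")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.hairpin_id}: non-ACGT characters in sequence")
        for m in self.matures:
            if m.start < 0 or m.end > len(self.sequence):
                raise ValueError(
                    f"{m.mirna_id}: annotation [{m.start}, {m.end}) outside hairpin "
                    f"{self.hairpin_id} of length {len(self.sequence)}"
                )
            if m.canonical_seq != self.sequence[m.start : m.end]:
                raise ValueError(f"{m.mirna_id}: canonical sequence disagrees with hairpin slice")
        arms = sorted(self.matures, key=lambda m: m.start)
        for a, b in zip(arms, arms[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.hairpin_id}: overlapping matures {a.mirna_id} and {b.mirna_id}"
                )
            # A read must never satisfy the +/-2 assignment window of two
            # matures at once; that needs both start and end gaps > 4.
            if abs(b.start - a.start) <= 4 and abs(b.end - a.end) <= 4:
                raise ValueError(
                    f"{self.hairpin_id}: matures {a.mirna_id}/{b.mirna_id} too close "
                    "for unambiguous +/-2 assignment"
                )
        return self


@dataclass(frozen=True)
class CollapsedRead:
    """A unique read sequence and its multiplicity within one sample."""

    sequence: str
    count: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 12:
            raise ValueError(f"collapsed read shorter than 12 nt: {self.sequence!r}")
        if self.count < 1:
            raise ValueError(f"non-positive read count {self.count}")


def infer_arm(start: int, end: int, hairpin_length: int) -> str:
    """Arm from position: mature midpoint in the 5' half of the hairpin -> 5p."""
    return "5p" if (start + end) / 2 < hairpin_length / 2 else "3p"


_GFF_COLS = 9


def read_hairpin_reference(fasta_path, gff_path) -> list[HairpinRecord]:
    """Load hairpin FASTA plus a GFF3 subset of ``miRNA``-type mature rows.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    The ``ID`` attribute names the mature miRNA; an ``arm`` attribute is used
    when present, otherwise the arm is inferred from the mature midpoint.
    """
    hairpins: dict[str, HairpinRecord] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        hairpins[rec.id] = HairpinRecord(rec.id, normalize_sequence(rec.seq))

    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GFF_COLS:
                raise ValueError(f"{gff_path}:{lineno}: expected {_GFF_COLS} GFF3 columns")
            seqid, _source, ftype, start1, end1, _score, _strand, _frame, attrs = fields
            if ftype != "miRNA":
                continue
            if seqid not in hairpins:
                raise ValueError(
                    f"{gff_path}:{lineno}: annotation references missing hairpin {seqid!r}"
                )
            attributes = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "ID" not in attributes:
                raise ValueError(f"{gff_path}:{lineno}: miRNA row lacks an ID attribute")
            hp = hairpins[seqid]
            start = int(start1) - 1  # 1-based inclusive -> 0-based half-open
            end = int(end1)
            if start < 0 or end > len(hp.sequence):
                raise ValueError(
                    f"{attributes['ID']}: annotation [{start1}, {end1}] outside hairpin "
                    f"{seqid} (length {len(hp.sequence)})"
                )
            arm = attributes.get("arm") or infer_arm(start, end, len(hp.sequence))
            hp.matures.append(
                MatureAnnotation(
                    mirna_id=attributes["ID"],
                    arm=arm,
                    start=start,
                    end=end,
                    canonical_seq=hp.sequence[start:end],
                )
            )

    return [hp.validate() for hp in hairpins.values()]


_COLLAPSED_HEADER = re.compile(r"^>(\d+)-(\d+)$")


def read_collapsed_fasta(path, sample_id: str) -> list[CollapsedRead]:
    """Read a collapsed-FASTA file with ``>serial-count`` headers."""
    reads: list[CollapsedRead] = []
    count = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                m = _COLLAPSED_HEADER.match(line)
                if m is None:
                    raise ValueError(
                        f"{path}:{lineno}: malformed collapsed-FASTA header {line!r} "
                        "(expected '>serial-count')"
                    )
                count = int(m.group(2))
            else:
                if count is None:
                    raise ValueError(f"{path}:{lineno}: sequence line before any header")
                reads.append(CollapsedRead(normalize_sequence(line), count, sample_id))
                count = None
    return reads


def write_collapsed_fasta(reads, path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads, start=1):
            fh.write(f">{i}-{r.count}\n{r.sequence}\n")


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, condition, replicate, path."""
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    required = {"sample_id", "condition", "replicate", "path"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("sample sheet contains duplicate sample_ids")
    if (sheet.groupby("condition").size() < 1).any() or sheet["condition"].nunique() < 1:
        raise ValueError("each condition needs at least one sample")
    return sheet


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a TSV with deterministic column order, row sort and float format."""
    out = df.sort_index() if index else df
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tables(results: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write every result table as ``<name>.tsv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in sorted(results):
        p = out_dir / f"{name}.tsv"
        write_table(results[name], p)
        paths.append(p)
    return paths
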