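"""Adapter clipping, quality filtering and redundancy collapsing.

The pipeline order is clip -> quality -> length -> collapse.  Two branches
share this preprocessing: the quantification branch additionally caps insert
length at 30 nt (the emulated library was PAGE size-selected to 10-30 nt);
the modification branch keeps every adapter-containing insert of >= 12 nt.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator

from .refio import CollapsedRead

#: Phred+33 offset for quality strings.
PHRED_OFFSET = 33


@dataclass(frozen=True)
class RawRead:
    sequence: str
    qualities: str  # Phred+33 encoded, same length as sequence

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and quality strings differ in length")


def clip_adapter(sequence: str, adapter: str, min_overlap: int = 8) -> str | None:
    """Return the insert before the 3' adapter, or None if no adapter found.

    The insert ends at the leftmost exact match of an adapter prefix of
    length >= ``min_overlap`` that either spans the full adapter or extends
    to the read end.  Exact matching only: the clip contract has no
    mismatches.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    idx = sequence.find(adapter)
    if idx >= 0:
        return sequence[:idx]
    # adapter prefix running off the 3' end of the read
    start = max(len(sequence) - len(adapter) + 1, 0)
    for i in range(start, len(sequence) - min_overlap + 1):
        if adapter.startswith(sequence[i:]):
            return sequence[:i]
    return None


def quality_filter(qualities, min_fraction: float = 0.95, min_q: int = 20) -> bool:
    """True iff at least ``min_fraction`` of bases have Phred quality >= min_q.

    ``qualities`` may be a Phred+33 string or a sequence of integer scores.
    Empty reads fail.
    """
    n = len(qualities)
    if n == 0:
        return False
    if isinstance(qualities, str):
        cutoff = chr(min_q + PHRED_OFFSET)
        good = sum(1 for q in qualities if q >= cutoff)
    else:
        good = sum(1 for q in qualities if q >= min_q)
    return good / n >= min_fraction


def length_filter(insert: str | None, min_len: int = 12, max_len: int | None = None) -> bool:
    """True iff an adapter was found (insert is not None) and the insert
    length is >= ``min_len`` (and <= ``max_len`` when a cap applies)."""
    if insert is None:
        return False
    if len(insert) < min_len:
        return False
    return max_len is None or len(insert) <= max_len


def collapse(reads: Iterable[tuple[str, int]], sample_id: str = "") -> list[CollapsedRead]:
    """Collapse (sequence, multiplicity) pairs into unique records.

    Output order is deterministic: count descending, then lexicographic.
    Total count is conserved.
    """
    counter: Counter[str] = Counter()
    for seq, count in reads:
        counter[seq] += count
    return [
        CollapsedRead(seq, n, sample_id)
        for seq, n in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


@dataclass
class PreprocessLog:
    """Per-sample read accounting; every input read lands in exactly one bin."""

    reads_in: int = 0
    adapterless: int = 0
    clipped: int = 0
    quality_failed: int = 0
    length_failed: int = 0
    kept: int = 0
    collapsed_unique: int = 0

    def check(self) -> None:
        assert self.reads_in == self.adapterless + self.clipped
        assert self.clipped == self.quality_failed + self.length_failed + self.kept


def preprocess_sample(
    records: Iterable[tuple[str, str, int]],
    adapter: str,
    sample_id: str = "",
    min_overlap: int = 8,
    min_fraction: float = 0.95,
    min_q: int = 20,
    min_len: int = 12,
    max_len: int | None = None,
) -> tuple[list[CollapsedRead], PreprocessLog]:
    """Run clip -> quality -> length -> collapse over (seq, qual, count) records.

    The quality filter is applied to the clipped insert (adapter bases are
    discarded anyway).  ``count`` lets pre-aggregated identical reads pass
    through without expansion.
    """
    log = PreprocessLog()
    kept: list[tuple[str, int]] = []
    for seq, qual, count in records:
        log.reads_in += count
        insert = clip_adapter(seq, adapter, min_overlap)
        if insert is None:
            log.adapterless += count
            continue
        log.clipped += count
        if not quality_filter(qual[: len(insert)], min_fraction, min_q):
            log.quality_failed += count
            continue
        if not length_filter(insert, min_len, max_len):
            log.length_failed += count
            continue
        log.kept += count
        kept.append((insert, count))
    collapsed = collapse(kept, sample_id)
    log.collapsed_unique = len(collapsed)
    log.check()
    return collapsed, log


def iter_fastq(path) -> Iterator[tuple[str, str, int]]:
    """Yield (sequence, quality, 1) records from a FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        for _title, seq, qual in FastqGeneralIterator(fh):
            yield seq.upper().replace("U", "T"), qual, 1
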