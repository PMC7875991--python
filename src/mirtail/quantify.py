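"""Strict mapping and the +/-2 nt templated-window count matrix.

Reads are mapped against the hairpin reference in a sense orientation with no
mismatches over the full read length.  A hit is assigned to an annotated
mature miRNA when *both* ends lie independently within +/-2 nt of the
canonical ends — i.e. up to 2 nt longer (templated) and 2 nt shorter
isoforms are summed into the miRNA's count.  Tailed reads carry nontemplated
bases and therefore never survive the exact-match contract; they are counted
only by the lenient isomiR branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .refio import CollapsedRead, HairpinRecord, MatureAnnotation


@dataclass(frozen=True)
class StrictHit:
    """An exact sense-strand occurrence of a read on a hairpin."""

    hairpin_id: str
    start: int
    end: int


def map_strict(sequence: str, reference: Sequence[HairpinRecord]) -> list[StrictHit]:
    """All exact sense occurrences of ``sequence`` across all hairpins."""
    hits: list[StrictHit] = []
    for hp in reference:
        pos = hp.sequence.find(sequence)
        while pos >= 0:
            hits.append(StrictHit(hp.hairpin_id, pos, pos + len(sequence)))
            pos = hp.sequence.find(sequence, pos + 1)
    return hits


def assign_to_mature(
    hit: StrictHit, matures: Sequence[MatureAnnotation], window: int = 2
) -> str | None:
    """Assign a hit to a mature iff both offsets are within the window."""
    for m in matures:
        if abs(hit.start - m.start) <= window and abs(hit.end - m.end) <= window:
            return m.mirna_id
    return None


@dataclass
class CountMatrix:
    """miRNA x sample raw counts plus per-sample library sizes.

    ``library_sizes`` is the total collapsed count entering mapping, so each
    column sum is bounded by its library size.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def validate(self) -> "CountMatrix":
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=0) > self.library_sizes[self.counts.columns]).any():
            raise ValueError("column sum exceeds library size")
        return self


def build_count_matrix(
    samples: Mapping[str, Iterable[CollapsedRead]],
    reference: Sequence[HairpinRecord],
    window: int = 2,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Count matrix over all annotated miRNAs, plus a per-locus hit sidecar.

    A read assigned to the same mirna_id via several hairpin loci contributes
    its count once; a read assigned to distinct mirna_ids contributes once to
    each.  Library size = total collapsed count entering mapping.
    """
    matures_by_hairpin = {hp.hairpin_id: hp.matures for hp in reference}
    mirna_ids = sorted({m.mirna_id for hp in reference for m in hp.matures})
    sample_ids = list(samples)

    counts = pd.DataFrame(0, index=mirna_ids, columns=sample_ids, dtype=int)
    lib_sizes = pd.Series(0, index=sample_ids, dtype=int)
    locus_rows = []
    for sample_id, reads in samples.items():
        for read in reads:
            lib_sizes[sample_id] += read.count
            assigned: set[str] = set()
            for hit in map_strict(read.sequence, reference):
                mirna_id = assign_to_mature(hit, matures_by_hairpin[hit.hairpin_id], window)
                if mirna_id is not None:
                    assigned.add(mirna_id)
                    locus_rows.append(
                        (sample_id, mirna_id, hit.hairpin_id, hit.start, hit.end, read.count)
                    )
            for mirna_id in assigned:
                counts.loc[mirna_id, sample_id] += read.count
    loci = pd.DataFrame(
        locus_rows, columns=["sample_id", "mirna_id", "hairpin_id", "start", "end", "count"]
    )
    return CountMatrix(counts, lib_sizes).validate(), loci
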