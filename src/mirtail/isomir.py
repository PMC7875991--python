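"""IsomiR calling: lenient mapping and end-modification decomposition.

Each modification-branch read is decomposed into a hairpin-templated core
plus optional nontemplated 5'/3' additions (NTA):

* **Lenient mapping.** Every ungapped sense placement of the read on any
  hairpin is considered.  Maximal runs of terminal mismatches are candidate
  nontemplated additions (up to 3 nt at the 5' end, up to 8 nt at the 3'
  end, where a 3' overhang beyond the hairpin end is nontemplated by
  definition); at most 2 *interior* mismatches are tolerated, and the
  templated core must keep at least ``min_core`` matched-region bases.  All
  qualifying placements are reported.
* **Selection.** Fewest interior mismatches, then fewest total mismatches,
  then the placement whose implied mature has the smallest absolute 5'
  offset, then lexicographically smallest hairpin id, then leftmost start.
* **Decomposition.** Maximal templated extension: walking the read 3' end
  backwards, trailing bases that mismatch the template are the 3' tail;
  a tail base matching the template is always attributed to the template
  (the same convention that defines "templated" isoforms).  5' handled
  symmetrically.  Reads whose residual interior mismatches sit more than
  3 nt from both core ends are unclassifiable as end-modifications and are
  dropped from modification statistics.
* **Thresholding.** A (miRNA, modification signature) is kept iff its summed
  read count is >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .refio import CollapsedRead, HairpinRecord, MatureAnnotation

TAIL_CLASSES = ("none", "U", "A", "mixed")

#: calls-table columns shared across the package
CALL_COLUMNS = [
    "mirna_id",
    "arm",
    "five_offset",
    "three_templated_offset",
    "nta5",
    "nta3",
    "tail_class",
    "read_len",
    "count",
]


@dataclass(frozen=True)
class LenientAlignment:
    """An ungapped sense placement of a read on a hairpin.

    ``t5``/``t3`` are the lengths of the maximal terminal mismatch runs
    (candidate NTA); ``n_interior`` counts mismatches between them.
    """

    hairpin_id: str
    start: int  # hairpin coordinate of the read's first base
    t5: int
    t3: int
    n_interior: int
    read_length: int


@dataclass(frozen=True)
class IsomirCall:
    """One read's decomposition relative to its mature miRNA."""

    mirna_id: str
    arm: str
    five_offset: int  # positive = 5' trimmed, negative = templated 5' extension
    three_templated_offset: int  # positive = templated 3' extension, negative = trimmed
    nta5: str
    nta3: str
    tail_class: str


def classify_tail(nta3: str) -> str:
    if not nta3:
        return "none"
    if set(nta3) == {"T"}:
        return "U"
    if set(nta3) == {"A"}:
        return "A"
    return "mixed"


class ReferenceIndex:
    """Vectorized all-placements lenient mapper over a hairpin reference.

    Hairpin sequences are concatenated into one byte array separated by
    sentinel bytes that can never match a read base; a read is compared
    against every window in a single numpy pass.  Sentinels make windows
    that cross a hairpin boundary fail the interior-mismatch budget, while a
    3' overhang beyond a hairpin end shows up as a trailing mismatch run —
    exactly the candidate-tail semantics required.
    """

    def __init__(
        self,
        reference: Sequence[HairpinRecord],
        max_interior_mismatches: int = 2,
        max_tail3: int = 8,
        max_tail5: int = 3,
        min_core: int = 10,
    ):
        if max_tail3 >= 10 or max_tail5 >= 10:
            raise ValueError("terminal-run caps must stay below the sentinel pad width")
        self.reference = list(reference)
        self.hairpins = {hp.hairpin_id: hp for hp in self.reference}
        self.max_interior = max_interior_mismatches
        self.max_tail3 = max_tail3
        self.max_tail5 = max_tail5
        self.min_core = min_core

        pad = 10
        chunks: list[bytes] = []
        hp_idx: list[np.ndarray] = []
        local: list[np.ndarray] = []
        self._hp_ids: list[str] = []
        for i, hp in enumerate(self.reference):
            n = len(hp.sequence)
            chunks.append(hp.sequence.encode() + b"\xff" * pad)
            idx = np.full(n + pad, -1, dtype=np.int32)
            idx[:n] = i
            hp_idx.append(idx)
            local.append(np.arange(0, n + pad, dtype=np.int32))
            self._hp_ids.append(hp.hairpin_id)
        chunks.append(b"\xff" * 48)  # room for windows at the final hairpin's 3' end
        self.big = np.frombuffer(b"".join(chunks), dtype=np.uint8)
        tail_idx = np.full(48, -1, dtype=np.int32)
        self.hp_of_pos = np.concatenate(hp_idx + [tail_idx])
        self.local_of_pos = np.concatenate(local + [np.zeros(48, dtype=np.int32)])
        self.valid_start = self.hp_of_pos >= 0

    def map_lenient(self, sequence: str) -> list[LenientAlignment]:
        """Every qualifying ungapped sense placement of the read."""
        read = np.frombuffer(sequence.encode(), dtype=np.uint8)
        L = len(read)
        windows = sliding_window_view(self.big, L)
        n_win = windows.shape[0]
        pos = np.nonzero(self.valid_start[:n_win])[0]
        match = windows[pos] == read
        has_match = match.any(axis=1)
        t5 = match.argmax(axis=1)
        t3 = match[:, ::-1].argmax(axis=1)
        total_mm = L - match.sum(axis=1)
        interior = total_mm - t5 - t3
        ok = (
            has_match
            & (interior <= self.max_interior)
            & (t5 <= self.max_tail5)
            & (t3 <= self.max_tail3)
            & (L - t5 - t3 >= self.min_core)
        )
        out = []
        for k in np.nonzero(ok)[0]:
            p = pos[k]
            out.append(
                LenientAlignment(
                    hairpin_id=self._hp_ids[self.hp_of_pos[p]],
                    start=int(self.local_of_pos[p]),
                    t5=int(t5[k]),
                    t3=int(t3[k]),
                    n_interior=int(interior[k]),
                    read_length=L,
                )
            )
        return out

    def implied_mature(self, aln: LenientAlignment) -> MatureAnnotation | None:
        """The mature on that hairpin minimizing |5' offset| of the core;
        None when the smallest offset exceeds 5."""
        matures = self.hairpins[aln.hairpin_id].matures
        if not matures:
            return None
        core_start = aln.start + aln.t5
        best = min(matures, key=lambda m: (abs(core_start - m.start), m.mirna_id))
        return best if abs(core_start - best.start) <= 5 else None


def select_alignment(
    alignments: Sequence[LenientAlignment], index: ReferenceIndex
) -> LenientAlignment | None:
    """Deterministic choice among qualifying placements (see module docs)."""
    if not alignments:
        return None

    def key(aln: LenientAlignment):
        m = index.implied_mature(aln)
        offset = abs(aln.start + aln.t5 - m.start) if m is not None else 10**6
        return (aln.n_interior, aln.n_interior + aln.t5 + aln.t3, offset, aln.hairpin_id, aln.start)

    return min(alignments, key=key)


def call_isomir(
    sequence: str, alignment: LenientAlignment, index: ReferenceIndex
) -> IsomirCall | None:
    """Decompose an aligned read into templated core plus 5'/3' NTA."""
    mature = index.implied_mature(alignment)
    if mature is None:
        return None
    hp = index.hairpins[alignment.hairpin_id]
    L = alignment.read_length
    t5, t3 = alignment.t5, alignment.t3
    nta5 = sequence[:t5]
    nta3 = sequence[L - t3 :] if t3 else ""
    core_start = alignment.start + t5
    core_end = alignment.start + L - t3
    # residual interior mismatches: unclassifiable as end modifications when
    # more than 3 nt away from both core ends
    core_read = sequence[t5 : L - t3] if t3 else sequence[t5:]
    core_ref = hp.sequence[core_start:core_end]
    n_core = len(core_read)
    for i, (a, b) in enumerate(zip(core_read, core_ref)):
        if a != b and i > 3 and (n_core - 1 - i) > 3:
            return None
    return IsomirCall(
        mirna_id=mature.mirna_id,
        arm=mature.arm,
        five_offset=core_start - mature.start,
        three_templated_offset=core_end - mature.end,
        nta5=nta5,
        nta3=nta3,
        tail_class=classify_tail(nta3),
    )


def call_sample(
    reads: Sequence[CollapsedRead], index: ReferenceIndex, min_count: int = 2
) -> pd.DataFrame:
    """Call every collapsed read of a sample and threshold the signatures.

    Returns a table with one row per (miRNA, modification signature), read
    counts summed, signatures with total count < ``min_count`` dropped.
    """
    rows = []
    for read in reads:
        aln = select_alignment(index.map_lenient(read.sequence), index)
        if aln is None:
            continue
        call = call_isomir(read.sequence, aln, index)
        if call is None:
            continue
        rows.append(
            (
                call.mirna_id,
                call.arm,
                call.five_offset,
                call.three_templated_offset,
                call.nta5,
                call.nta3,
                call.tail_class,
                len(read.sequence),
                read.count,
            )
        )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return apply_count_threshold(calls, min_count)


def apply_count_threshold(calls: pd.DataFrame, min_count: int = 2) -> pd.DataFrame:
    """Sum counts per modification signature and keep those >= min_count."""
    if calls.empty:
        return calls.copy()
    signature = [c for c in CALL_COLUMNS if c != "count"]
    grouped = calls.groupby(signature, as_index=False, sort=True)["count"].sum()
    return grouped[grouped["count"] >= min_count].reset_index(drop=True)


def reconstruct_read(call: IsomirCall, hairpin: HairpinRecord, mature: MatureAnnotation) -> str:
    """Rebuild the read implied by a call; byte-identity with the original
    read holds for every kept call on error-free data."""
    core = hairpin.sequence[
        mature.start + call.five_offset : mature.end + call.three_templated_offset
    ]
    return call.nta5 + core + call.nta3
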