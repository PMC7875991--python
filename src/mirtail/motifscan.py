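"""PWM construction and log-odds scanning of promoter regions.

Builds a position weight matrix from a nucleotide count matrix (JASPAR-style
input supported via Biopython) and scans ~1 kb promoter regions on both
strands for transcription-factor binding sites, reporting the top-scoring
windows.  Instead of a promoter-corpus z-score background, significance is
assessed with an empirical p-value from shuffled-sequence resampling, which
keeps the scan self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .refio import reverse_complement

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
BASES = "ACGT"


@dataclass
class PWM:
    """Position weight matrix with a derived log-odds score matrix.

    ``counts`` is 4 x L (rows A, C, G, T); ``background`` sums to 1;
    ``logodds[b, j] = log2(((counts[b, j] + pc) / (colsum_j + 4 pc)) /
    background[b])`` in bits.
    """

    motif_id: str
    counts: np.ndarray
    background: np.ndarray
    pseudocount: float
    logodds: np.ndarray

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.logodds.argmax(axis=0))

    def max_score(self) -> float:
        return float(self.logodds.max(axis=0).sum())


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    position: int  # 0-based start on the forward region
    strand: str  # "+" or "-"
    score: float  # log-odds, bits
    matched_seq: str  # forward-strand subsequence at the window


def pwm_from_counts(
    counts,
    pseudocount: float = 0.25,
    background=None,
    motif_id: str = "pwm",
) -> PWM:
    """Log-odds PWM from a 4 x L non-negative count matrix."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
        raise ValueError("counts must be a 4 x L matrix with L >= 1")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if pseudocount <= 0 and (counts.sum(axis=0) == 0).any():
        raise ValueError("all-zero column requires a positive pseudocount")
    background = (
        np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    )
    if abs(background.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    colsum = counts.sum(axis=0)
    probs = (counts + pseudocount) / (colsum + 4 * pseudocount)
    logodds = np.log2(probs / background[:, None])
    return PWM(motif_id, counts, background, pseudocount, logodds)


def read_jaspar(path) -> PWM:
    """Read the first motif of a JASPAR-format count-matrix file."""
    from Bio import motifs

    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    counts = np.array([motif.counts[b] for b in BASES], dtype=float)
    return pwm_from_counts(counts, motif_id=motif.matrix_id or motif.name or "pwm")


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in region: {exc}") from None


def _window_scores(region: str, pwm: PWM) -> np.ndarray:
    idx = _encode(region)
    windows = sliding_window_view(idx, pwm.length)
    scores = pwm.logodds[windows, np.arange(pwm.length)].sum(axis=1)
    # round away summation-order noise so ties break by position, not by
    # floating-point accumulation order
    return np.round(scores, 10)


def scan_region(region: str, pwm: PWM, top_k: int = 3, region_id: str = "region") -> list[MotifHit]:
    """Score every window on both strands; return the top_k hits.

    A minus-strand hit at position p means the reverse complement of
    ``region[p:p+L]`` matches the motif.  Ties break deterministically by
    (position, strand) with "+" before "-".
    """
    L = pwm.length
    if len(region) < L:
        raise ValueError(f"region length {len(region)} shorter than motif length {L}")
    fwd = _window_scores(region, pwm)
    rev = _window_scores(reverse_complement(region), pwm)[::-1]  # rev[p] = window at p, - strand
    hits = [
        MotifHit(region_id, p, "+", float(fwd[p]), region[p : p + L]) for p in range(len(fwd))
    ] + [MotifHit(region_id, p, "-", float(rev[p]), region[p : p + L]) for p in range(len(rev))]
    hits.sort(key=lambda h: (-h.score, h.position, h.strand))
    return hits[:top_k]


def empirical_pvalue(
    region: str, pwm: PWM, n_shuffles: int = 200, seed: int = 0
) -> tuple[float, float]:
    """Empirical p-value of the region's best hit against shuffled regions.

    Shuffling preserves base composition; p = (1 + #shuffles with max score
    >= observed) / (n + 1).  Returns (best score, p).
    """
    rng = np.random.default_rng(seed)
    best = scan_region(region, pwm, top_k=1)[0].score
    chars = np.frombuffer(region.encode(), dtype=np.uint8)
    exceed = 0
    for _ in range(n_shuffles):
        shuffled = rng.permutation(chars).tobytes().decode()
        smax = max(
            _window_scores(shuffled, pwm).max(),
            _window_scores(reverse_complement(shuffled), pwm).max(),
        )
        if smax >= best:
            exceed += 1
    return best, (1 + exceed) / (n_shuffles + 1)
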