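"""Modification-frequency summaries, arm localization and fragment statistics.

Per-sample modification profiles (3'-trim / 3'-add / 5'-trim / 5'-add
frequencies, U/A tail histograms, mono vs oligo tails), the 3p/5p arm ratio
of uridylation used to localize tailing to the precursor, 13-17 nt
short-fragment quantification with fold changes between conditions,
replicate-level t-test comparisons, and the 2^-ddCt qPCR utility.

The denominator for all frequencies is the total count of mature-assigned
*isoform* reads in the modification branch (canonical reads included).  A
read contributes to every modification class it exhibits — a 5'-trimmed,
U-tailed read counts once under 5'-trim and once under 3'-add.  Calls that
look like degradation fragments (13-17 nt, 5'-anchored, 3' end at least 3 nt
inside the canonical end, untailed) are a separate species class with their
own surveillance statistics and are excluded from the isoform profiles —
their abundance shifts between conditions and would otherwise dilute every
tail frequency.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import map_strict
from .refio import CollapsedRead, HairpinRecord

MOD_CLASSES = ("trim3", "add3", "trim5", "add5")

#: profile statistics that are frequencies (testable across replicates)
FREQ_COLUMNS = (
    ["freq_" + c for c in MOD_CLASSES]
    + [f"freq_{t}_len{k}" for t in ("u", "a") for k in range(1, 6)]
    + [f"freq_{t}_{m}" for t in ("u", "a") for m in ("mono", "oligo")]
)


def _tail_len_bin(nta3: str) -> int:
    """Tail length reported up to 5; longer tails binned as 5."""
    return min(len(nta3), 5)


def fragment_like(calls: pd.DataFrame, min_len: int = 13, max_len: int = 17) -> pd.Series:
    """Boolean mask of calls that are degradation fragments rather than
    mature isoforms: short, 5'-anchored, deeply 3'-trimmed, untailed."""
    return (
        calls["read_len"].between(min_len, max_len)
        & (calls["five_offset"].abs() <= 2)
        & (calls["three_templated_offset"] <= -3)
        & (calls["nta3"].str.len() == 0)
    )


def isoform_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Mature-isoform calls: the fragment-like subset removed."""
    if calls.empty:
        return calls
    return calls[~fragment_like(calls)]


def modification_profile(calls: pd.DataFrame, sample_id: str | None = None) -> pd.Series:
    """One sample's modification profile from its thresholded calls table."""
    calls = isoform_calls(calls)
    denom = int(calls["count"].sum()) if not calls.empty else 0
    out: dict[str, float] = {"denominator": denom}
    for arm in ("5p", "3p"):
        out[f"denominator_{arm}"] = int(calls.loc[calls["arm"] == arm, "count"].sum())
    if denom == 0:
        for col in FREQ_COLUMNS:
            out[col] = float("nan")  # zero denominator: frequencies undefined
        return pd.Series(out, name=sample_id)

    counts = calls["count"]
    cls = {
        "trim3": counts[calls["three_templated_offset"] < 0].sum(),
        "add3": counts[calls["nta3"].str.len() > 0].sum(),
        "trim5": counts[calls["five_offset"] > 0].sum(),
        "add5": counts[calls["nta5"].str.len() > 0].sum(),
    }
    for c in MOD_CLASSES:
        out[f"freq_{c}"] = cls[c] / denom
    for tail, letter in (("u", "U"), ("a", "A")):
        tailed = calls[calls["tail_class"] == letter]
        lens = tailed["nta3"].map(_tail_len_bin)
        for k in range(1, 6):
            out[f"freq_{tail}_len{k}"] = tailed.loc[lens == k, "count"].sum() / denom
        out[f"freq_{tail}_mono"] = tailed.loc[lens == 1, "count"].sum() / denom
        out[f"freq_{tail}_oligo"] = tailed.loc[lens >= 2, "count"].sum() / denom
    return pd.Series(out, name=sample_id)


def profile_table(calls_by_sample: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Profiles for all samples, one row per sample."""
    return pd.DataFrame(
        {sid: modification_profile(c, sid) for sid, c in calls_by_sample.items()}
    ).T.rename_axis("sample_id")


def tail_length_histogram(calls: pd.DataFrame, arm: str | None = None) -> pd.DataFrame:
    """Percentage of reads by 3' tail class and length (1..5, >=5 binned).

    Percentages are of all mature-assigned reads in ``calls`` (optionally
    restricted to one arm); the histogram totals reconcile with the
    3'-addition U/A class counts.
    """
    calls = isoform_calls(calls)
    sub = calls if arm is None else calls[calls["arm"] == arm]
    denom = sub["count"].sum() if not sub.empty else 0
    hist = pd.DataFrame(0.0, index=pd.Index(range(1, 6), name="tail_length"), columns=["U", "A"])
    if denom == 0:
        return hist
    for letter in ("U", "A"):
        tailed = sub[sub["tail_class"] == letter]
        lens = tailed["nta3"].map(_tail_len_bin)
        for k in range(1, 6):
            hist.loc[k, letter] = 100.0 * tailed.loc[lens == k, "count"].sum() / denom
    return hist


def arm_tailing_rates(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-arm U- and A-tail frequencies (tailed count / arm denominator)."""
    calls = isoform_calls(calls)
    rows = {}
    for arm in ("5p", "3p"):
        sub = calls[calls["arm"] == arm]
        denom = sub["count"].sum()
        rows[arm] = {
            "denominator": denom,
            "u_count": sub.loc[sub["tail_class"] == "U", "count"].sum(),
            "a_count": sub.loc[sub["tail_class"] == "A", "count"].sum(),
        }
    df = pd.DataFrame(rows).T.rename_axis("arm")
    for t in ("u", "a"):
        df[f"{t}_rate"] = df[f"{t}_count"] / df["denominator"]
    return df


def arm_uridylation_ratio(calls: pd.DataFrame) -> dict[str, float]:
    """3p/5p ratio of U-tail frequency, with an A-tail companion.

    A ratio well above 1 indicates tailing of the precursor 3' end (which
    surfaces only on the 3p mature product); a ratio near 1 indicates
    tailing of mature miRNAs of both arms.  Alongside the plain ratio a
    continuity-corrected value ((c3p + 0.5) / (c5p + 0.5) on rates) is
    reported, finite even when one arm has zero tailed reads.
    """
    rates = arm_tailing_rates(calls)
    out: dict[str, float] = {}
    for t in ("u", "a"):
        c3, c5 = rates.loc["3p", f"{t}_count"], rates.loc["5p", f"{t}_count"]
        n3, n5 = rates.loc["3p", "denominator"], rates.loc["5p", "denominator"]
        if n3 == 0 or n5 == 0:
            raise ValueError("both arms need a nonzero read denominator")
        plain = (c3 / n3) / (c5 / n5) if c5 > 0 else float("inf")
        corrected = ((c3 + 0.5) / n3) / ((c5 + 0.5) / n5)
        out[f"{t}_ratio"] = plain
        out[f"{t}_ratio_corrected"] = corrected
    return out


def fragment_counts(
    samples: Mapping[str, Sequence[CollapsedRead]],
    reference: Sequence[HairpinRecord],
    library_sizes: Mapping[str, int],
    min_len: int = 13,
    max_len: int = 17,
    anchor_window: int = 2,
    min_inside: int = 3,
) -> pd.DataFrame:
    """Count 13-17 nt short fragments per (miRNA, sample).

    A fragment is an exactly-mapping read of insert length ``min_len`` to
    ``max_len`` whose 5' end is within +/-``anchor_window`` of a mature 5'
    end and whose 3' end lies at least ``min_inside`` nt inside the
    canonical 3' end.  Disjoint by construction from the +/-2 quantification
    window.  Rates are counts per library size.
    """
    matures_by_hairpin = {hp.hairpin_id: hp.matures for hp in reference}
    mirna_ids = sorted(m.mirna_id for hp in reference for m in hp.matures)
    rows = []
    for sample_id, reads in samples.items():
        counts: dict[str, int] = {m: 0 for m in mirna_ids}
        for read in reads:
            if not min_len <= len(read.sequence) <= max_len:
                continue
            assigned: set[str] = set()
            for hit in map_strict(read.sequence, reference):
                for m in matures_by_hairpin[hit.hairpin_id]:
                    if (
                        abs(hit.start - m.start) <= anchor_window
                        and hit.end <= m.end - min_inside
                    ):
                        assigned.add(m.mirna_id)
            for mirna_id in assigned:
                counts[mirna_id] += read.count
        lib = library_sizes[sample_id]
        for mirna_id in mirna_ids:
            rows.append((mirna_id, sample_id, counts[mirna_id], counts[mirna_id] / lib))
    return pd.DataFrame(rows, columns=["mirna_id", "sample_id", "count", "rate"])


def fragment_fold_change(
    fragments: pd.DataFrame,
    groups: Mapping[str, str],
    library_sizes: Mapping[str, int],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-miRNA fold change of fragment rates, condition B over A.

    Rates are library-size normalized and averaged across replicates; the
    pseudocount is scaled to rate units (``pseudocount / mean library
    size``) so FC stays finite and FC = 1 exactly when the rates are equal.
    """
    frag = fragments.copy()
    frag["condition"] = frag["sample_id"].map(groups)
    mean_rates = frag.pivot_table(index="mirna_id", columns="condition", values="rate")
    pc = pseudocount / float(np.mean(list(library_sizes.values())))
    out = pd.DataFrame(
        {
            "rate_A": mean_rates["A"],
            "rate_B": mean_rates["B"],
            "fold_change": (mean_rates["B"] + pc) / (mean_rates["A"] + pc),
        }
    )
    return out.rename_axis("mirna_id")


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_profiles(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame) -> pd.DataFrame:
    """Unpaired two-sided t-tests per profile statistic across replicates.

    Zero-variance guard: two constant, equal groups give p = 1; constant but
    unequal groups give p = 0 with an ``infinite_t`` flag.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("need at least 2 replicates per condition")
    rows = []
    cols = [c for c in FREQ_COLUMNS if c in profiles_a.columns and c in profiles_b.columns]
    for col in cols:
        a = profiles_a[col].to_numpy(dtype=float)
        b = profiles_b[col].to_numpy(dtype=float)
        flag = ""
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a[0] == b[0]:
                t, p = 0.0, 1.0
            else:
                t, p, flag = math.inf, 0.0, "infinite_t"
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append((col, a.mean(), b.mean(), t, p, _stars(p), flag))
    return pd.DataFrame(
        rows, columns=["statistic", "mean_A", "mean_B", "t", "pvalue", "stars", "flag"]
    ).set_index("statistic")


def ddct_fold_change(
    ct_target_b: float, ct_ref_b: float, ct_target_a: float, ct_ref_a: float
) -> float:
    """Relative expression by the 2^-ddCt method (condition B vs A)."""
    if min(ct_target_b, ct_ref_b, ct_target_a, ct_ref_a) <= 0:
        raise ValueError("Ct values must be positive")
    ddct = (ct_target_b - ct_ref_b) - (ct_target_a - ct_ref_a)
    return 2.0 ** (-ddct)
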