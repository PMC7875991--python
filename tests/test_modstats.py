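"""Modification frequencies, tail histograms, arm ratios, fragments, ddCt."""

import numpy as np
import pandas as pd
import pytest

from mirtail.modstats import (
    arm_uridylation_ratio,
    compare_profiles,
    ddct_fold_change,
    fragment_counts,
    fragment_fold_change,
    modification_profile,
    tail_length_histogram,
)
from mirtail.refio import CollapsedRead

CALL_COLS = [
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


def calls_frame(rows):
    # rows omit read_len; all these calls are mature-length (22 nt) reads
    rows = [(*r[:-1], 22, r[-1]) for r in rows]
    return pd.DataFrame(rows, columns=CALL_COLS)


class TestModificationProfile:
    def test_class_frequencies(self):
        rows = (
            [("m", "5p", 0, -1, "", "", "none", 1)] * 40  # 3'-trim
            + [("m", "5p", 0, 0, "", "TT", "U", 1)] * 10  # 3'-add
            + [("m", "5p", 1, 0, "", "", "none", 1)] * 5  # 5'-trim
            + [("m", "5p", 0, 0, "C", "", "none", 1)] * 1  # 5'-add
            + [("m", "5p", 0, 0, "", "", "none", 1)] * 44  # canonical
        )
        prof = modification_profile(calls_frame(rows))
        assert prof["denominator"] == 100
        assert prof["freq_trim3"] == pytest.approx(0.40)
        assert prof["freq_add3"] == pytest.approx(0.10)
        assert prof["freq_trim5"] == pytest.approx(0.05)
        assert prof["freq_add5"] == pytest.approx(0.01)

    def test_read_counts_in_every_class_it_exhibits(self):
        calls = calls_frame([("m", "5p", 2, 0, "", "TTT", "U", 7)])
        prof = modification_profile(calls)
        assert prof["freq_trim5"] == 1.0 and prof["freq_add3"] == 1.0

    def test_unmodified_reads_give_zero_frequencies(self):
        prof = modification_profile(calls_frame([("m", "5p", 0, 0, "", "", "none", 10)]))
        assert all(prof[f"freq_{c}"] == 0.0 for c in ("trim3", "add3", "trim5", "add5"))

    def test_zero_denominator_flagged_as_nan(self):
        prof = modification_profile(calls_frame([]))
        assert prof["denominator"] == 0 and np.isnan(prof["freq_trim3"])


class TestTailHistogram:
    def test_point_mass(self):
        calls = calls_frame([("m", "3p", 0, 0, "", "TTT", "U", 50)])
        hist = tail_length_histogram(calls)
        assert hist.loc[3, "U"] == 100.0
        assert hist.drop(index=3)["U"].sum() == 0.0

    def test_no_a_tails_empty_a_column(self):
        calls = calls_frame(
            [("m", "3p", 0, 0, "", "T", "U", 5), ("m", "3p", 0, 0, "", "", "none", 5)]
        )
        hist = tail_length_histogram(calls)
        assert (hist["A"] == 0.0).all()
        assert hist.loc[1, "U"] == 50.0

    def test_long_tails_binned_at_five(self):
        calls = calls_frame([("m", "3p", 0, 0, "", "T" * 7, "U", 4)])
        hist = tail_length_histogram(calls)
        assert hist.loc[5, "U"] == 100.0

    def test_histogram_mass_reconciles_with_add3_class(self):
        rows = [
            ("m", "3p", 0, 0, "", "TT", "U", 30),
            ("m", "3p", 0, 0, "", "A", "A", 10),
            ("m", "3p", 0, 0, "", "", "none", 60),
        ]
        calls = calls_frame(rows)
        hist = tail_length_histogram(calls)
        prof = modification_profile(calls)
        assert hist.to_numpy().sum() / 100.0 == pytest.approx(prof["freq_add3"])


class TestArmRatio:
    def make_calls(self, u3, u5, n3=1000, n5=1000, a3=0, a5=0):
        rows = []
        rows += [("m3", "3p", 0, 0, "", "TT", "U", u3)] if u3 else []
        rows += [("m5", "5p", 0, 0, "", "TT", "U", u5)] if u5 else []
        rows += [("m3", "3p", 0, 0, "", "A", "A", a3)] if a3 else []
        rows += [("m5", "5p", 0, 0, "", "A", "A", a5)] if a5 else []
        rows += [("m3", "3p", 0, 0, "", "", "none", n3 - u3 - a3)]
        rows += [("m5", "5p", 0, 0, "", "", "none", n5 - u5 - a5)]
        return calls_frame(rows)

    def test_tenfold_ratio(self):
        ratios = arm_uridylation_ratio(self.make_calls(u3=20, u5=2))
        assert ratios["u_ratio"] == pytest.approx(10.0)

    def test_equal_rates_give_unity(self):
        ratios = arm_uridylation_ratio(self.make_calls(u3=5, u5=5))
        assert ratios["u_ratio"] == pytest.approx(1.0)

    def test_zero_5p_count_reports_infinite_with_corrected_companion(self):
        ratios = arm_uridylation_ratio(self.make_calls(u3=20, u5=0))
        assert ratios["u_ratio"] == np.inf
        assert ratios["u_ratio_corrected"] == pytest.approx((20.5 / 1000) / (0.5 / 1000))


class TestFragments:
    def fragment_setup(self, tiny_reference):
        hp = tiny_reference[0]
        m5 = hp.matures[0]
        return hp, m5

    def test_fragment_window_rules(self, tiny_reference):
        hp, m5 = self.fragment_setup(tiny_reference)
        frag15 = CollapsedRead(hp.sequence[m5.start : m5.start + 15], 3, "s")
        long18 = CollapsedRead(hp.sequence[m5.start : m5.start + 18], 3, "s")
        shifted = CollapsedRead(hp.sequence[m5.start + 4 : m5.start + 19], 3, "s")
        table = fragment_counts(
            {"s": [frag15, long18, shifted]}, tiny_reference, {"s": 9}
        )
        by_mirna = table.set_index("mirna_id")["count"]
        assert by_mirna["mir-1-5p"] == 3  # only the anchored 15-mer counts

    def test_fold_change_of_equal_rates_is_one(self):
        frags = pd.DataFrame(
            {
                "mirna_id": ["m"] * 4,
                "sample_id": ["A1", "A2", "B1", "B2"],
                "count": [10, 10, 10, 10],
                "rate": [0.001] * 4,
            }
        )
        groups = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        fc = fragment_fold_change(frags, groups, {s: 10_000 for s in groups})
        assert fc.loc["m", "fold_change"] == pytest.approx(1.0)

    def test_sixfold_rate_increase_recovers_sixfold_fc(self):
        frags = pd.DataFrame(
            {
                "mirna_id": ["m"] * 4,
                "sample_id": ["A1", "A2", "B1", "B2"],
                "count": [100, 100, 600, 600],
                "rate": [0.01, 0.01, 0.06, 0.06],
            }
        )
        groups = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        fc = fragment_fold_change(frags, groups, {s: 10_000 for s in groups})
        assert fc.loc["m", "fold_change"] == pytest.approx(6.0, rel=0.01)


class TestFragmentExclusion:
    def test_fragment_like_calls_leave_the_isoform_denominator(self):
        """Deeply 3'-trimmed 13-17 nt calls are surveillance species, not
        isoforms: they must not dilute the modification frequencies."""
        rows = [
            ("m", "3p", 0, 0, "", "TT", "U", 22, 10),
            ("m", "3p", 0, 0, "", "", "none", 22, 90),
        ]
        frag = ("m", "3p", 0, -7, "", "", "none", 15, 300)
        with_frag = pd.DataFrame(rows + [frag], columns=CALL_COLS)
        without = pd.DataFrame(rows, columns=CALL_COLS)
        pd.testing.assert_series_equal(
            modification_profile(with_frag), modification_profile(without)
        )

    def test_mild_trims_and_tailed_short_reads_stay_in(self):
        from mirtail.modstats import fragment_like

        calls = pd.DataFrame(
            [
                ("m", "3p", 0, -2, "", "", "none", 20, 1),  # ordinary trim-2
                ("m", "3p", 0, -5, "", "TTT", "U", 20, 1),  # tailed, not a fragment
                ("m", "3p", 0, -7, "", "", "none", 15, 1),  # fragment
            ],
            columns=CALL_COLS,
        )
        assert list(fragment_like(calls)) == [False, False, True]


class TestCompareProfiles:
    def frame(self, values):
        return pd.DataFrame({"freq_u_oligo": values})

    def test_identical_constant_groups_guarded_to_p_one(self):
        out = compare_profiles(self.frame([0.1, 0.1]), self.frame([0.1, 0.1]))
        assert out.loc["freq_u_oligo", "pvalue"] == 1.0

    def test_constant_unequal_groups_flagged(self):
        out = compare_profiles(self.frame([0.1, 0.1]), self.frame([0.3, 0.3]))
        row = out.loc["freq_u_oligo"]
        assert row["pvalue"] == 0.0 and row["flag"] == "infinite_t"

    def test_strong_shift_highly_significant(self):
        out = compare_profiles(self.frame([10, 11, 9]), self.frame([20, 21, 19]))
        assert out.loc["freq_u_oligo", "pvalue"] < 0.001
        assert out.loc["freq_u_oligo", "stars"] == "***"

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            compare_profiles(self.frame([0.1]), self.frame([0.2, 0.3]))


class TestDdct:
    @pytest.mark.parametrize(
        "cts,expected",
        [((22, 15, 20, 15), 0.25), ((20, 15, 20, 15), 1.0), ((18, 15, 20, 15), 4.0)],
    )
    def test_fold_change_formula(self, cts, expected):
        assert ddct_fold_change(*cts) == pytest.approx(expected)

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change(0, 15, 20, 15)
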