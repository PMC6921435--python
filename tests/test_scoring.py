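"""Cohort tallies, status bands, change decisions and sensitivities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ecgdelta as e
from ecgdelta.pipeline import analyze_cohort, truth_to_series
from ecgdelta.scoring import PATTERN_NAME


class TestTally:
    def test_sixteen_participant_percentages(self):
        t = e.tally_directions(["D"] * 13 + ["I"] * 3)
        assert t.rounded_percentage("D") == 81
        assert t.rounded_percentage("I") == 19

    def test_all_equal_cohort(self):
        t = e.tally_directions(["E"] * 16)
        assert t.percentage("E") == 100.0

    def test_even_split(self):
        t = e.tally_directions(["D"] * 8 + ["I"] * 8)
        assert t.rounded_percentage("D") == t.rounded_percentage("I") == 50

    def test_percentages_sum_to_100_before_rounding(self):
        t = e.tally_directions(["D"] * 5 + ["I"] * 4 + ["E"] * 2)
        assert sum(t.percentage(d) for d in "IDE") == pytest.approx(100.0)

    def test_rejects_unknown_labels(self):
        with pytest.raises(ValueError):
            e.tally_directions(["I", "X"])


class TestClassifyStatus:
    @pytest.mark.parametrize("pct,expected", [
        (81, "h"), (75, "m"), (56, "l"),       # as printed beside those values
        (80, "h"), (60, "m"),                  # inclusive band boundaries
        (100, "h"), (59.9, "l"), (0, "l"),
    ])
    def test_band_assignment(self, pct, expected):
        assert e.classify_status(pct) == expected

    @given(st.floats(min_value=0, max_value=99))
    def test_monotone_in_percentage(self, pct):
        order = {"l": 0, "m": 1, "h": 2}
        assert order[e.classify_status(pct + 1.0)] >= order[e.classify_status(pct)]

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            e.classify_status(101.0)


class TestChangeDecisions:
    def test_six_high_or_moderate_statuses_score_six(self):
        d = e.statistical_change_decision(["h", "h", "h", "h", "m", "m"], "RR-I")
        assert (d.n_moderate, d.n_high, d.total, d.decision) == (2, 4, 6, "Yes")

    def test_all_low_scores_zero(self):
        d = e.statistical_change_decision(["l"] * 6, "QRS")
        assert (d.total, d.decision) == (0, "No")

    def test_three_is_below_the_change_threshold(self):
        d = e.statistical_change_decision(["m", "m", "h", "l", "l", "l"])
        assert (d.total, d.decision) == (3, "No")

    def test_wrong_parameter_count_raises(self):
        with pytest.raises(ValueError, match="6 parameter"):
            e.statistical_change_decision(["h"] * 5)

    @pytest.mark.parametrize("n_dec,expected", [
        (12, "Yes"),     # 75% decrease
        (9, "No"),       # 56%
        (10, "Yes"),     # 62.5% >= 60, boundary inclusive
    ])
    def test_spectral_threshold(self, n_dec, expected):
        t = e.tally_directions(["D"] * n_dec + ["I"] * (16 - n_dec), "ST",
                               "spectral-peak")
        assert e.spectral_change_decision(t).decision == expected


class TestSensitivity:
    def test_mostly_high_row(self):
        s = e.sensitivity(["h"] * 5 + ["l"])
        assert (s["S_l"], s["S_m"], s["S_h"]) == (16.7, 0.0, 83.3)

    def test_mixed_moderate_high_row(self):
        s = e.sensitivity(["m", "m", "h", "h", "h", "h"])
        assert (s["S_l"], s["S_m"], s["S_h"]) == (0.0, 33.3, 66.7)

    def test_unanimous_high(self):
        assert e.sensitivity(["h", "h"])["S_h"] == 100.0

    @given(st.lists(st.sampled_from(["l", "m", "h"]), min_size=1, max_size=20))
    def test_shares_sum_to_100_before_rounding(self, statuses):
        from collections import Counter
        counts = Counter(statuses)
        total = sum(100.0 * counts.get(k, 0) / len(statuses) for k in "lmh")
        assert total == pytest.approx(100.0)


# Cohort-level spectral percentages reported for a published 16-participant
# oral-glucose study, used here as fixed inputs to the decision layer.
REFERENCE_SPECTRAL_DECREASE = {
    "ST": 12, "QTC": 9, "QT": 10, "PRQ": 11, "QRS": 9,
    "P-H": 8, "R-H": 9, "HR": 12, "RR-I": 13,
}


def reference_spectral_matrix() -> pd.DataFrame:
    rows = []
    for seg, n_dec in REFERENCE_SPECTRAL_DECREASE.items():
        for p in range(16):
            rows.append({"participant": str(p + 1), "segment": seg,
                         "parameter": "spectral-peak",
                         "direction": "D" if p < n_dec else "I"})
    return pd.DataFrame(rows)


class TestBuildReport:
    def test_reference_spectral_statuses_give_published_yes_set(self):
        tables = e.build_report(reference_spectral_matrix())
        decisions = tables.decisions("spectral")
        assert {s for s, d in decisions.items() if d == "Yes"} == \
            {"ST", "QT", "PRQ", "HR", "RR-I"}

    def test_reference_spectral_sensitivity_row(self):
        tables = e.build_report(reference_spectral_matrix())
        row = tables.spectral_sensitivity.iloc[0]
        # dominant-pattern statuses across the nine segments: 4 l, 4 m, 1 h
        assert (row["S_l"], row["S_m"], row["S_h"]) == (44.4, 44.4, 11.1)

    def test_single_participant_percentages_are_binary(self):
        rows = [{"participant": "1", "segment": "HR", "parameter": p,
                 "direction": "I"} for p in ("md", "mn", "mdn", "Q3", "Q1", "Q")]
        tables = e.build_report(pd.DataFrame(rows))
        pct = tables.direction_percentages
        assert set(pct["percentage"]).issubset({0, 100})

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError, match="columns"):
            e.build_report(pd.DataFrame({"participant": [], "segment": []}))

    def test_pattern_names_rendered(self):
        tables = e.build_report(reference_spectral_matrix())
        assert set(tables.spectral_summary["pattern"]) <= set(PATTERN_NAME.values())


def small_cohort_result(effect, master_seed, n=8):
    cfg = e.SessionConfig(duration_s=1800.0, random_seed=17, noise_sd_mV=0.0)
    cohort = e.generate_cohort(n, cfg, effect, master_seed=master_seed)
    pairs = [(str(g.participant), truth_to_series(g.truth, "G", str(g.participant)),
              truth_to_series(ng.truth, "NG", str(ng.participant)))
             for g, ng in cohort]
    return analyze_cohort(pairs)


class TestEndToEndScoring:
    # a 30-min session with the effect landing 10 min in: same structure as
    # the full protocol at a fraction of the cost
    EFFECT = e.GlucoseEffectProfile(onset_s=600.0, ramp_s=300.0)
    NULL = e.GlucoseEffectProfile(onset_s=600.0, ramp_s=300.0, hr_gain=1.0,
                                  rr_gain=1.0, qt_gain=1.0, st_gain=1.0,
                                  prq_gain=1.0)

    def test_null_cohort_changes_nothing(self):
        for rep in range(5):
            res = small_cohort_result(self.NULL, master_seed=100 + rep)
            assert set(res.tables.decisions("statistical").values()) == {"No"}
            assert set(res.tables.decisions("spectral").values()) == {"No"}

    def test_effect_cohort_recovers_injected_pattern(self):
        res = small_cohort_result(self.EFFECT, master_seed=3)
        decisions = res.tables.decisions("statistical")
        for seg in ("HR", "RR-I", "QT", "ST", "PRQ"):
            assert decisions[seg] == "Yes", seg
        for seg in ("QRS", "R-H", "P-H"):
            assert decisions[seg] == "No", seg

    def test_hr_receives_high_statuses_on_most_parameters(self):
        res = small_cohort_result(self.EFFECT, master_seed=3)
        occ = res.tables.statistical_occurrence
        hr = occ[occ["segment"] == "HR"].iloc[0]
        assert hr["h"] >= 4

    def test_injected_directions_match_physiology(self):
        res = small_cohort_result(self.EFFECT, master_seed=3)
        matrix = res.tables.pattern_matrix
        med = matrix[matrix["parameter"] == "mdn"]
        by_seg = med.groupby("segment")["direction"].agg(lambda s: s.mode()[0])
        assert by_seg["HR"] == "I"
        for seg in ("RR-I", "QT", "ST", "PRQ"):
            assert by_seg[seg] == "D", seg
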