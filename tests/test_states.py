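"""State classification, visit extraction and transition statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shoalstates.errors import InsufficientDataError, ParameterError
from shoalstates.states import (
    StateThresholds,
    classify_point,
    completed_transitions,
    extract_visits,
    label_series,
    milling_handedness,
    persistence_survival,
    state_time_fractions,
    transition_completion_fraction,
    transition_stats,
)


class TestClassifyPoint:
    @pytest.mark.parametrize(
        "op, orr, k, expected",
        [
            (0.9, 0.1, 0.35, "P"),
            (0.2, 0.8, 0.35, "M"),
            (0.1, 0.1, 0.35, "S"),
            (0.5, 0.5, 0.35, "T"),
            (0.35, 0.35, 0.35, "T"),  # exact threshold: strict inequalities
            (0.65, 0.1, 0.35, "T"),
            (0.2, 0.8, 0.25, "M"),  # alternate k redraws the regions
            (0.2, 0.8, 0.45, "M"),  # wider k grows the milling region
            (0.4, 0.8, 0.25, "T"),
        ],
    )
    def test_region_assignment(self, op, orr, k, expected):
        assert classify_point(op, orr, k) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            classify_point(1.2, 0.1)

    def test_degenerate_k_rejected(self):
        with pytest.raises(ParameterError):
            StateThresholds(0.6)


class TestLabelSeries:
    def test_constant_series(self):
        labs = label_series(np.full(5, 0.9), np.full(5, 0.1))
        assert (labs == "P").all()

    def test_crossing_series(self):
        labs = label_series(
            np.array([0.9, 0.5, 0.2]), np.array([0.1, 0.5, 0.8])
        )
        assert list(labs) == ["P", "T", "M"]

    def test_empty_series(self):
        assert len(label_series(np.array([]), np.array([]))) == 0

    def test_nan_becomes_gap(self):
        labs = label_series(np.array([0.9, np.nan]), np.array([0.1, 0.1]))
        assert list(labs) == ["P", "G"]


class TestVisits:
    def test_run_lengths_to_durations(self):
        visits = extract_visits(np.array(list("PPPTTM")), fps=30)
        assert [(v.label, v.n_frames) for v in visits] == [("P", 3), ("T", 2), ("M", 1)]
        assert visits[0].duration == pytest.approx(0.1)
        assert visits[1].duration == pytest.approx(2 / 30)
        assert visits[2].duration == pytest.approx(1 / 30)

    def test_single_label(self):
        assert len(extract_visits(np.array(list("MMMM")), 30)) == 1

    def test_alternating(self):
        assert len(extract_visits(np.array(list("PTPT")), 30)) == 4

    def test_short_gap_bridged_same_label(self):
        labs = np.array(list("PPPP" + "G" * 10 + "PPPP"))
        visits = extract_visits(labs, fps=30, bridge_gap_s=1.0)
        assert len(visits) == 1
        assert visits[0].n_frames == 8  # gap frames excluded from duration

    def test_long_gap_splits_visits(self):
        labs = np.array(list("PPPP" + "G" * 40 + "PPPP"))
        visits = extract_visits(labs, fps=30, bridge_gap_s=1.0)
        assert len(visits) == 2
        assert visits[1].after_break

    def test_gap_between_different_labels_splits(self):
        labs = np.array(list("PPPP" + "G" * 5 + "MMMM"))
        visits = extract_visits(labs, fps=30, bridge_gap_s=1.0)
        assert [v.label for v in visits] == ["P", "M"]
        assert visits[1].after_break


class TestCompletedTransitions:
    def test_return_to_previous_state_is_not_a_transition(self):
        visits = extract_visits(np.array(list("PPTTPP")), 30)
        assert completed_transitions(visits) == []

    def test_chain_through_T(self):
        visits = extract_visits(np.array(list("PPTTMMSS")), 30)
        events = completed_transitions(visits)
        assert [(e.from_label, e.to_label) for e in events] == [("P", "M"), ("M", "S")]

    def test_direct_change_without_T_counts(self):
        visits = extract_visits(np.array(list("PPMM")), 30)
        events = completed_transitions(visits)
        assert [(e.from_label, e.to_label) for e in events] == [("P", "M")]

    def test_no_pairing_across_tracking_break(self):
        visits = extract_visits(np.array(list("PPPP" + "G" * 40 + "MMMM")), 30)
        assert completed_transitions(visits) == []

    def test_path_spans_source_to_destination(self):
        labs = np.array(list("PPTTMM"))
        o_p = np.array([0.9, 0.9, 0.5, 0.4, 0.2, 0.2])
        o_r = np.array([0.1, 0.1, 0.5, 0.6, 0.8, 0.8])
        visits = extract_visits(labs, 30)
        (ev,) = completed_transitions(visits, o_r, o_p)
        assert ev.path.shape == (4, 2)  # last P frame, 2 T frames, first M frame
        assert classify_point(ev.path[0, 1], ev.path[0, 0]) == "P"
        assert classify_point(ev.path[-1, 1], ev.path[-1, 0]) == "M"


def _oracle_transition_count(labels):
    """Brute force: drop T/G, collapse runs, count label changes."""
    core = [l for l in labels if l in "SPM"]
    collapsed = [core[0]] if core else []
    for l in core[1:]:
        if l != collapsed[-1]:
            collapsed.append(l)
    return max(0, len(collapsed) - 1)


@settings(max_examples=1000, deadline=None)
@given(st.lists(st.sampled_from("SPMT"), min_size=1, max_size=60))
def test_transition_extraction_matches_label_scan_oracle(labels):
    """Visit-based extraction equals a direct scan of the raw label sequence."""
    labels = np.array(labels)
    visits = extract_visits(labels, fps=30)
    events = completed_transitions(visits)
    assert len(events) == _oracle_transition_count(labels)
    non_t = [v for v in visits if v.label != "T"]
    assert len(events) <= max(0, len(non_t) - 1)


class TestOccupancyAndRates:
    def test_fractions_from_durations(self):
        visits = extract_visits(np.array(["P"] * 900 + ["M"] * 2100), fps=30)
        frac = state_time_fractions(visits)
        assert frac == pytest.approx({"P": 0.3, "M": 0.7, "S": 0.0, "T": 0.0})

    def test_all_transition(self):
        frac = state_time_fractions(extract_visits(np.array(["T"] * 10), 30))
        assert frac["T"] == pytest.approx(1.0)

    def test_quarter_quarter_half(self):
        visits = extract_visits(np.array(["P"] * 30 + ["T"] * 30 + ["S"] * 60), fps=30)
        frac = state_time_fractions(visits)
        assert (frac["P"], frac["T"], frac["S"]) == pytest.approx((0.25, 0.25, 0.5))

    def test_rate_per_minute(self):
        visits = extract_visits(
            np.array(list("".join(["PM"] * 5))), fps=30
        )  # 9 alternations
        events = completed_transitions(visits)
        stats = transition_stats(events, total_minutes=4.5)
        assert stats.rate_per_min == pytest.approx(2.0)

    def test_destination_fractions(self):
        visits = extract_visits(np.array(list("PPMMPPSSPPSS")), 30)
        events = completed_transitions(visits)
        stats = transition_stats(events, 1.0)
        assert stats.destination_fractions["P"]["M"] == pytest.approx(1 / 3)
        assert stats.destination_fractions["P"]["S"] == pytest.approx(2 / 3)

    def test_source_without_events_flagged(self):
        visits = extract_visits(np.array(list("PPSS")), 30)
        stats = transition_stats(completed_transitions(visits), 1.0)
        assert stats.destination_fractions["M"] is None


class TestPersistence:
    def test_empirical_survival(self):
        visits = extract_visits(
            np.array(["P"] * 30 + ["T"] + ["P"] * 60 + ["T"] + ["P"] * 120), fps=30
        )
        curve = persistence_survival(visits, "P")
        assert curve.prob_longer(0.0) == pytest.approx(1.0)
        assert curve.prob_longer(1.5) == pytest.approx(2 / 3)
        t, p = curve.curve()
        assert p[0] == 1.0
        assert np.all(np.diff(p) <= 0)

    def test_single_visit_step(self):
        curve = persistence_survival(extract_visits(np.array(["M"] * 60), 30), "M")
        assert curve.prob_longer(1.0) == 1.0
        assert curve.prob_longer(2.0) == 0.0

    def test_missing_label_raises(self):
        with pytest.raises(InsufficientDataError):
            persistence_survival(extract_visits(np.array(["P"]), 30), "M")


class TestCompletionFraction:
    def test_half_completed(self):
        labs = np.array(["P"] * 30 + ["T"] * 60 + ["M"] * 30 + ["T"] * 45 + ["M"] * 30)
        frac, n_c, n_q = transition_completion_fraction(extract_visits(labs, 30))
        assert (frac, n_c, n_q) == (0.5, 1, 2)

    def test_short_T_visit_excluded(self):
        labs = np.array(["P"] * 30 + ["T"] * 15 + ["M"] * 30)  # 0.5 s in T
        with pytest.raises(InsufficientDataError):
            transition_completion_fraction(extract_visits(labs, 30))


class TestHandedness:
    def test_sign_convention(self):
        labs = np.array(["M"] * 10)
        visits = extract_visits(labs, 30)
        assert milling_handedness(np.full(10, -0.8), visits) == (1, 0)

    def test_mixed_signs(self):
        labs = np.array(["M"] * 10 + ["P"] * 40 + ["M"] * 10)
        visits = extract_visits(labs, 30)
        signed = np.concatenate((np.full(10, 0.8), np.zeros(40), np.full(10, -0.8)))
        assert milling_handedness(signed, visits) == (1, 1)

    def test_exact_zero_tie_breaks_ccw(self):
        visits = extract_visits(np.array(["M"] * 10), 30)
        assert milling_handedness(np.zeros(10), visits) == (0, 1)
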