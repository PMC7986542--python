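"""Unit tests for the per-run gait parameter engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catgait.footfalls import (
    Footfall,
    Paw,
    Run,
    StepSequenceSummary,
    ab_sequence_pct,
    base_of_support,
    body_speed,
    compute_run_features,
    duty_cycle,
    max_contact_at_pct,
    regularity_index,
    stand_swing_cycle,
    step_sequence,
    stride_length,
    support_profile,
)

from .conftest import make_run, simple_paw_run


def seq_run(paws, dt=0.1):
    """One placement per paw label, spaced dt apart."""
    return make_run(
        [(p, i * dt, i * dt + dt / 2, i * dt, float(i), 0.0) for i, p in enumerate(paws)]
    )


class TestStride:
    def test_two_placements(self):
        run = make_run([("RF", 0, 0.1, 0, 0.0, 0.0), ("RF", 0.5, 0.6, 0.5, 10.0, 0.0)])
        assert stride_length(run, Paw.RF) == pytest.approx(10.0)

    def test_mean_over_pairs(self):
        run = make_run(
            [("RF", 0, 0.1, 0, 0.0, 0.0), ("RF", 0.5, 0.6, 0.5, 10.0, 0.0),
             ("RF", 1.0, 1.1, 1.0, 22.0, 0.0)]
        )
        assert stride_length(run, Paw.RF) == pytest.approx(11.0)  # mean of {10, 12}

    def test_single_placement_missing(self):
        run = make_run([("RF", 0, 0.1, 0, 0.0, 0.0)])
        assert math.isnan(stride_length(run, Paw.RF))
        assert math.isnan(stride_length(run, Paw.LH))


class TestStandSwingCycle:
    def test_forced_values(self):
        run = simple_paw_run("RF", [(1.0, 1.2), (1.3, 1.5)])
        stand, swing, cycle = stand_swing_cycle(run, Paw.RF)
        assert (stand, swing, cycle) == pytest.approx((0.2, 0.1, 0.3))

    def test_hand_means(self):
        run = simple_paw_run("RF", [(0, 0.2), (0.3, 0.5), (0.65, 0.9)])
        stand, swing, cycle = stand_swing_cycle(run, Paw.RF)
        assert (stand, swing, cycle) == pytest.approx((0.2, 0.125, 0.325))

    def test_single_placement_missing(self):
        run = simple_paw_run("RF", [(0, 0.2)])
        assert all(math.isnan(v) for v in stand_swing_cycle(run, Paw.RF))

    def test_overlapping_placements_error(self):
        run = simple_paw_run("RF", [(0, 0.5), (0.4, 0.9)])
        with pytest.raises(ValueError, match="overlapping"):
            stand_swing_cycle(run, Paw.RF)

    def test_stand_plus_swing_equals_cycle(self):
        run = simple_paw_run("LH", [(0, 0.17), (0.31, 0.52), (0.66, 0.81), (0.99, 1.2)])
        stand, swing, cycle = stand_swing_cycle(run, Paw.LH)
        assert stand + swing == pytest.approx(cycle, abs=1e-12)


class TestDutyCycle:
    @pytest.mark.parametrize(
        "contacts, expected",
        [
            ([(0, 0.2), (0.3, 0.5)], 200 / 3),  # stand .2 / cycle .3
            ([(0, 0.09), (0.135, 0.2)], 200 / 3),  # same ratio, smaller scale
            ([(0, 0.1), (0.2, 0.55), (0.7, 0.8)], 60.0),  # duties 50% and 70%
        ],
    )
    def test_values(self, contacts, expected):
        run = simple_paw_run("RF", contacts)
        assert duty_cycle(run, Paw.RF) == pytest.approx(expected)

    def test_missing(self):
        assert math.isnan(duty_cycle(simple_paw_run("RF", [(0, 0.1)]), Paw.RF))


class TestMaxContactAt:
    def test_forced(self):
        run = make_run([("RF", 1.0, 1.5, 1.2, 0, 0)])
        assert max_contact_at_pct(run, Paw.RF) == pytest.approx(40.0)

    def test_boundary_zero(self):
        run = make_run([("RF", 1.0, 1.5, 1.0, 0, 0)])
        assert max_contact_at_pct(run, Paw.RF) == pytest.approx(0.0)

    def test_mean(self):
        run = make_run([("RF", 0.0, 1.0, 0.4, 0, 0), ("RF", 2.0, 3.0, 2.6, 0, 0)])
        assert max_contact_at_pct(run, Paw.RF) == pytest.approx(50.0)

    def test_max_contact_outside_stand_rejected(self):
        with pytest.raises(ValueError, match="t_max_contact"):
            Footfall(paw=Paw.RF, t_contact=0.0, t_release=0.5, t_max_contact=0.7, x=0, y=0)


class TestBodySpeed:
    def test_uniform(self):
        placements = []
        for i, p in enumerate(["RF", "LF", "RH", "LH"]):
            placements += [
                (p, i * 0.01, i * 0.01 + 0.2, i * 0.01, 0.0, 0.0),
                (p, i * 0.01 + 0.4, i * 0.01 + 0.6, i * 0.01 + 0.4, 10.0, 0.0),
            ]
        assert body_speed(make_run(placements)) == pytest.approx(25.0)

    def test_mean_over_paws(self):
        placements = []
        for i, (p, v) in enumerate(zip(["RF", "LF", "RH", "LH"], [20, 20, 30, 30])):
            placements += [
                (p, i * 0.01, i * 0.01 + 0.2, i * 0.01, 0.0, 0.0),
                (p, i * 0.01 + 1.0, i * 0.01 + 1.2, i * 0.01 + 1.0, float(v), 0.0),
            ]
        assert body_speed(make_run(placements)) == pytest.approx(25.0)

    def test_stationary_zero(self):
        run = make_run([("RF", 0, 0.1, 0, 5.0, 1.0), ("RF", 0.5, 0.6, 0.5, 5.0, 1.0)])
        assert body_speed(run) == pytest.approx(0.0)

    def test_all_single_placements_missing(self):
        assert math.isnan(body_speed(seq_run(["RF", "LF", "RH", "LH"])))


class TestBaseOfSupport:
    def test_constant_width(self):
        run = make_run(
            [("RF", 0, 0.1, 0, 0.0, 3.0), ("LF", 0.05, 0.15, 0.05, 0.0, 1.0),
             ("RF", 0.4, 0.5, 0.4, 5.0, 3.0), ("LF", 0.45, 0.55, 0.45, 5.0, 1.0)]
        )
        assert base_of_support(run, "fore") == pytest.approx(2.0)

    def test_mean_of_widths(self):
        placements = []
        for i, w in enumerate([3.6, 4.0, 4.4]):
            placements.append(("LH", i * 1.0, i * 1.0 + 0.1, i * 1.0, 0.0, 0.0))
            placements.append(("RH", i * 1.0 + 0.2, i * 1.0 + 0.3, i * 1.0 + 0.2, 0.0, w))
        assert base_of_support(make_run(placements), "hind") == pytest.approx(4.0)

    def test_absolute_value_convention(self):
        run = make_run(
            [("LF", 0, 0.1, 0, 0.0, 2.5), ("RF", 0.05, 0.15, 0.05, 0.0, -0.5)]
        )
        assert base_of_support(run, "fore") == pytest.approx(3.0)

    def test_one_side_absent_missing(self):
        run = make_run([("RF", 0, 0.1, 0, 0.0, 1.0)])
        assert math.isnan(base_of_support(run, "fore"))


class TestStepSequence:
    def test_perfect_alternate(self):
        run = seq_run(["RF", "RH", "LF", "LH"] * 3)
        summary = step_sequence(run)
        assert summary.pp == 12
        assert summary.nssp_labels == ("AA",) * 3

    def test_greedy_scan_with_interruption(self):
        run = seq_run(["RF", "RH", "LF", "LH", "RF", "RF", "RH", "LF", "LH"])
        summary = step_sequence(run)
        assert summary.pp == 9
        assert summary.nssp_labels == ("AA", "AA")

    def test_repeated_paw_never_matches(self):
        assert step_sequence(seq_run(["RF"] * 4)).nssp_count == 0

    @pytest.mark.parametrize(
        "paws, label",
        [
            (["RF", "LF", "RH", "LH"], "CA"),
            (["LF", "RF", "LH", "RH"], "CB"),
            (["RF", "RH", "LF", "LH"], "AA"),
            (["LF", "RH", "RF", "LH"], "AB"),
            (["RF", "LF", "LH", "RH"], "RA"),
            (["LF", "RF", "RH", "LH"], "RB"),
        ],
    )
    def test_all_six_patterns_recognized(self, paws, label):
        assert step_sequence(seq_run(paws)).nssp_labels == (label,)

    def test_tie_break_by_paw_order(self):
        # simultaneous contacts ordered RF, LF, RH, LH -> cruciate CA
        run = make_run([(p, 0.0, 0.1, 0.0, 0.0, 0.0) for p in ["LH", "RH", "LF", "RF"]])
        assert step_sequence(run).nssp_labels == ("CA",)


class TestRegularityAndAb:
    def test_ri_perfect_walker_hits_ceiling(self):
        assert regularity_index(step_sequence(seq_run(["RF", "RH", "LF", "LH"] * 3))) == 100.0

    def test_ri_greedy_example(self):
        summary = step_sequence(seq_run(["RF", "RH", "LF", "LH", "RF", "RF", "RH", "LF", "LH"]))
        assert regularity_index(summary) == pytest.approx(800 / 9)  # 88.889%

    def test_ri_zero_and_missing(self):
        assert regularity_index(step_sequence(seq_run(["RF"] * 5))) == 0.0
        assert math.isnan(regularity_index(step_sequence(seq_run(["RF", "LF"]))))

    @pytest.mark.parametrize(
        "labels, expected",
        [(("AB", "AB", "AB"), 100.0), (("AB", "AA", "RA"), 100 / 3), (("AA", "AA"), 0.0)],
    )
    def test_ab_share(self, labels, expected):
        summary = StepSequenceSummary(placements=("RF",) * (4 * len(labels)), nssp_labels=labels)
        assert ab_sequence_pct(summary) == pytest.approx(expected)

    def test_ab_missing_without_patterns(self):
        summary = StepSequenceSummary(placements=("RF", "RF"), nssp_labels=())
        assert math.isnan(ab_sequence_pct(summary))


class TestSupportProfile:
    def test_four_paws_down(self):
        run = make_run([(p, 0.0, 1.0, 0.0, 0.0, 0.0) for p in ["RF", "LF", "RH", "LH"]])
        prof = support_profile(run)
        assert prof.pct_four == 100.0

    def test_diagonal_pair(self):
        run = make_run([("RF", 0, 1, 0, 0, 0), ("LH", 0, 1, 0, 0, 0)])
        assert support_profile(run).pct_diagonal == 100.0

    def test_girdle_and_lateral_pairs(self):
        run = make_run([("RF", 0, 1, 0, 0, 0), ("LF", 0, 1, 0, 0, 0)])
        assert support_profile(run).pct_girdle == 100.0
        run = make_run([("RF", 0, 1, 0, 0, 0), ("RH", 0, 1, 0, 0, 0)])
        assert support_profile(run).pct_lateral == 100.0

    def test_half_three_half_four(self):
        # LH joins the other three halfway through the sampled window
        run = make_run(
            [("RF", 0, 1, 0, 0, 0), ("LF", 0, 1, 0, 0, 0), ("RH", 0, 1, 0, 0, 0),
             ("LH", 0.5, 1.0, 0.5, 0, 0)]
        )
        prof = support_profile(run)
        assert prof.pct_three == pytest.approx(50.0)
        assert prof.pct_four == pytest.approx(50.0)

    def test_percentages_sum_to_100(self, perfect_run):
        assert sum(support_profile(perfect_run).as_dict().values()) == pytest.approx(100.0)

    def test_empty_run_rejected(self):
        with pytest.raises(ValueError):
            support_profile(Run(run_id="e", records=[]))


class TestInvariances:
    @settings(max_examples=25, derandomize=True)
    @given(shift=st.floats(-50, 50), dx=st.floats(-20, 20), dy=st.floats(-20, 20))
    def test_time_and_space_translation(self, shift, dx, dy):
        from catgait.synthetic import GaitTemplate, generate_run

        run = generate_run(GaitTemplate())
        moved = Run(
            run_id="m",
            records=[
                Footfall(r.paw, r.t_contact + shift, r.t_release + shift,
                         r.t_max_contact + shift, r.x + dx, r.y + dy)
                for r in run.records
            ],
            frame_rate=run.frame_rate,
        )
        a, b = compute_run_features(run), compute_run_features(moved)
        for k in a:
            if k.startswith("support_pct_"):
                # the camera tick grid is boundary-sensitive: a float shift
                # may move single ticks across contact edges
                assert a[k] == pytest.approx(b[k], abs=2.0), k
            else:
                assert a[k] == pytest.approx(b[k], abs=1e-9), k

    def test_x_scaling_scales_stride_and_speed_only(self, perfect_run):
        k = 2.5
        scaled = Run(
            run_id="s",
            records=[
                Footfall(r.paw, r.t_contact, r.t_release, r.t_max_contact, r.x * k, r.y)
                for r in perfect_run.records
            ],
            frame_rate=perfect_run.frame_rate,
        )
        a, b = compute_run_features(perfect_run), compute_run_features(scaled)
        # x dominates the generated geometry, so strides/speeds scale by k
        assert b["stride_length_rf"] == pytest.approx(k * a["stride_length_rf"])
        assert b["body_speed_lh"] == pytest.approx(k * a["body_speed_lh"])
        for name in ("duty_cycle_rf", "regularity_index", "max_contact_at_lf"):
            assert b[name] == pytest.approx(a[name], abs=1e-9)

    def test_missingness_propagates_per_paw(self):
        # a run where RH appears once: all RH pairwise parameters missing
        placements = []
        for i, p in enumerate(["RF", "LF", "LH"]):
            placements += [
                (p, i * 0.01, i * 0.01 + 0.1, i * 0.01, 0.0, 0.0),
                (p, i * 0.01 + 0.5, i * 0.01 + 0.6, i * 0.01 + 0.5, 8.0, 0.0),
            ]
        placements.append(("RH", 0.25, 0.3, 0.25, 4.0, 1.0))
        values = compute_run_features(make_run(placements))
        assert math.isnan(values["stride_length_rh"])
        assert math.isnan(values["swing_time_rh"])
        assert not math.isnan(values["max_contact_at_rh"])  # defined per placement
        assert not math.isnan(values["stride_length_rf"])
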