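"""Three-hit analysis chain: grouping, labeling, scatter test, reconstruction."""

import numpy as np
import pandas as pd
import pytest

from jpet_effcal.constants import C_CM_PER_NS
from jpet_effcal.selection import (
    SelectionConfig,
    angular_correlation,
    assign_scatter,
    energy_band_preselect,
    group_events,
    reconstruct_annihilation_point,
    scatter_test,
    scattering_angle,
    select_back_to_back,
    select_events,
)


def _hits_frame(times):
    return pd.DataFrame({"time_ns": times})


class TestGrouping:
    def test_three_hits_inside_window_form_one_event(self):
        assert group_events(_hits_frame([0.0, 50.0, 150.0]), 200.0) == [[0, 1, 2]]

    def test_two_separated_hits_form_nothing(self):
        assert group_events(_hits_frame([0.0, 300.0]), 200.0) == []

    def test_four_hit_group_is_discarded(self):
        assert group_events(_hits_frame([0.0, 10.0, 20.0, 30.0]), 200.0) == []

    def test_window_anchors_at_first_unconsumed_hit(self):
        # second group opens at t=250: {250, 380, 430} is one 3-hit event
        got = group_events(_hits_frame([0.0, 250.0, 380.0, 430.0]), 200.0)
        assert got == [[1, 2, 3]]


class TestPreselection:
    @pytest.mark.parametrize(
        "energies, expected",
        [
            ((150.0, 200.0, 100.0), True),
            ((150.0, 200.0, 600.0), False),  # prompt-like deposit vetoed
            ((70.0, 341.0, 30.0), True),     # closed band: edges pass
            ((30.0, 40.0, 100.0), False),    # only one hit inside the band
        ],
    )
    def test_band_and_veto(self, energies, expected):
        assert energy_band_preselect(energies, (70.0, 341.0), 400.0) is expected


class TestAngularCorrelation:
    @pytest.mark.parametrize(
        "azimuths, expected_sum, expected_diff",
        [
            ((0.0, 90.0, 180.0), 180.0, 0.0),
            ((0.0, 30.0, 180.0), 180.0, 120.0),
            ((0.0, 10.0, 20.0), 20.0, 0.0),
        ],
    )
    def test_sum_and_difference_of_two_smallest(self, azimuths, expected_sum, expected_diff):
        s, d = angular_correlation(azimuths)
        assert s == pytest.approx(expected_sum)
        assert d == pytest.approx(expected_diff)

    def test_back_to_back_labeling(self):
        assert select_back_to_back((0.0, 90.0, 180.0)) == (0, 2, 1)
        assert select_back_to_back((0.0, 30.0, 180.0)) == (0, 2, 1)
        assert select_back_to_back((0.0, 10.0, 20.0)) is None
        # sum 170 with the default 4 deg half-window: rejected
        assert select_back_to_back((0.0, 85.0, 170.0)) is None


class TestScatterTest:
    def test_hand_fixture_reproduces_s_values(self):
        # annihilation at the origin at t=0; primaries on opposite strips,
        # scatter hit C truly fed by primary A
        t_fly = 42.5 / C_CM_PER_NS
        a = np.array([42.5, 0.0, 0.0])
        b = np.array([-42.5, 0.0, 0.0])
        c = np.array([40.49, 23.375, 0.0])
        d_ac = np.linalg.norm(c - a)
        t_c = t_fly + d_ac / C_CM_PER_NS
        assert d_ac == pytest.approx(23.46, abs=5e-3)
        assert np.linalg.norm(c - b) == pytest.approx(86.22, abs=5e-3)
        assert scatter_test(t_c, c, t_fly, a) == pytest.approx(0.0, abs=1e-12)
        assert scatter_test(t_c, c, t_fly, b) == pytest.approx(-2.093, abs=1e-3)

    def test_assignment_regions(self):
        assert assign_scatter(0.0, -2.09) == 1
        assert assign_scatter(-2.09, 0.0) == 2
        assert assign_scatter(3.0, 3.0, accept_radius_ns=0.5) == 0
        # ambiguous: both inside the acceptance -> rejected
        assert assign_scatter(0.2, -0.3, accept_radius_ns=1.0) == 0


class TestReconstruction:
    def test_equal_times_give_the_midpoint(self):
        v = reconstruct_annihilation_point([42.5, 0, 0], 5.0, [-42.5, 0, 0], 5.0)
        np.testing.assert_allclose(v, [0.0, 0.0, 0.0], atol=1e-12)

    def test_one_ns_tof_shifts_by_c_over_two(self):
        v = reconstruct_annihilation_point([42.5, 0, 0], 5.0, [-42.5, 0, 0], 6.0)
        assert v[0] == pytest.approx(C_CM_PER_NS / 2.0)

    def test_coincident_positions_raise(self):
        with pytest.raises(ValueError):
            reconstruct_annihilation_point([1, 2, 3], 0.0, [1, 2, 3], 1.0)

    def test_scattering_angle_reference_values(self):
        assert scattering_angle([0, 0, 0], [42.5, 0, 0], [85.0, 0, 0]) == pytest.approx(0.0)
        assert scattering_angle([0, 0, 0], [42.5, 0, 0], [10.0, 0, 0]) == pytest.approx(180.0)
        assert scattering_angle(
            [0, 0, 0], [42.5, 0, 0], [40.49, 23.375, 0.0]
        ) == pytest.approx(94.91, abs=0.01)


class TestEndToEnd:
    def test_unsmeared_truth_pairs_have_vanishing_s_and_exact_deposits(
        self, unsmeared_hits, geometry
    ):
        ideal, _ = unsmeared_hits
        cfg = SelectionConfig(
            use_true_positions=True, use_reconstructed_vertex=True, vertex_margin_cm=3.0
        )
        selected, _ = select_events(ideal, geometry, cfg)
        # direct single-scatter events only: a scatter hit of a later
        # generation (intermediate interaction unregistered) or a merged
        # same-strip pile-up breaks the straight-flight premise of S = 0
        clean = selected[
            selected["clean_topology"]
            & (selected["gen_scatter"] == 1)
            & ~selected["any_merged"]
        ]
        assert len(clean) > 50
        # S for the true primary-scatter pair is identically zero
        s_true = np.where(
            clean["true_parent_slot"] == 1, clean["s_to_1_ns"], clean["s_to_2_ns"]
        )
        # exact up to the float64 resolution of the global event clock
        # (~1e-7 ns for timestamps near 1e9 ns)
        assert np.max(np.abs(s_true)) < 1e-6
        # minimal-|S| assignment is perfect without smearing
        assert (clean["min_s_pick"] == clean["true_parent_slot"]).all()
        # the reconstructed deposit equals the true one where the vertex,
        # hit positions and times are exact
        d_true = np.where(
            clean["true_parent_slot"] == 1, clean["e_true_p1_kev"], clean["e_true_p2_kev"]
        )
        np.testing.assert_allclose(clean["de_reco_kev"], d_true, atol=1e-4)

    def test_smeared_assignment_accuracy_is_near_98_percent(self, small_streams, geometry):
        ideal, _, _ = small_streams
        cfg = SelectionConfig(require_s_exclusive=False)
        selected, funnel = select_events(ideal, geometry, cfg)
        clean = selected[selected["clean_topology"]]
        assert len(clean) > 80
        acc = (clean["min_s_pick"] == clean["true_parent_slot"]).mean()
        assert 0.9 < acc <= 1.0
        assert funnel["selected"].iloc[0] == len(selected)

    def test_funnel_counts_are_monotone(self, small_streams, geometry):
        ideal, _, _ = small_streams
        _, funnel = select_events(ideal, geometry, SelectionConfig())
        row = funnel.iloc[0]
        stages = [
            "three_hit_groups",
            "band_preselected",
            "back_to_back",
            "scatter_assigned",
            "vertex_accepted",
            "selected",
        ]
        vals = [row[s] for s in stages]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
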