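"""Concentration control coefficients, impact classes and tolerance ranges."""

import math

import numpy as np
import pytest

from hepanet.dynamics import (
    PerturbationAction,
    PerturbationSpec,
    find_steady_state,
    realized_flux_fractions,
)
from hepanet.scenarios import (
    COSUBSTRATE_BACKGROUND,
    cosubstrate_y1_prediction,
)
from hepanet.sensitivity import (
    classify_impact,
    concentration_control_coefficient,
    records_to_frame,
    regulator_sensitivity,
    scan_branches,
    tolerance_range,
)


def analytic_ccc(f, delta, s=0.5):
    """Forward-difference coefficient from the toy's closed form."""
    y0 = cosubstrate_y1_prediction(f, s)
    y1 = cosubstrate_y1_prediction(f * (1 + delta), s)
    return (y1 - y0) / (f * delta) * (f / y0)


class TestClassifyImpact:
    @pytest.mark.parametrize("c,cls", [
        (2.781, "high"),      # printed example of a high-impact branch
        (2.098, "high"),
        (1.0, "high"),        # closed boundary as printed
        (0.995, "high"),      # the (0.99, 1) gap resolves upward
        (0.99, "moderate"),
        (0.5, "moderate"),
        (0.1, "moderate"),    # closed boundary as printed
        (-0.05, "low"),       # absolute value
        (0.099, "low"),
        (float("nan"), "unclassified"),
        (float("inf"), "unclassified"),
    ])
    def test_partition(self, c, cls):
        assert classify_impact(c) == cls

    def test_every_finite_value_has_exactly_one_class(self):
        for c in np.linspace(-3, 3, 601):
            assert classify_impact(float(c)) in ("high", "moderate", "low")


class TestControlCoefficient:
    def test_decoupled_target_zero(self, branch2):
        """A target with no path from the branch has zero sensitivity."""
        rec = concentration_control_coefficient(
            branch2, "X", "RA", target="Y2", delta=0.1)
        assert rec.stable
        assert abs(rec.coefficient) < 1e-9

    def test_matches_analytic_closed_form(self, cosub_toy):
        rec = concentration_control_coefficient(
            cosub_toy, "X", "RA", target="Y1", delta=0.1,
            background=COSUBSTRATE_BACKGROUND)
        assert rec.stable
        assert rec.coefficient == pytest.approx(analytic_ccc(0.3, 0.1),
                                                rel=1e-6)
        assert rec.impact == "high"

    def test_matches_independent_two_run_recomputation(self, cosub_toy):
        """Brute-force recomputation outside the scan machinery."""
        delta = 0.1
        rec = concentration_control_coefficient(
            cosub_toy, "X", "RA", target="Y1", delta=delta,
            background=COSUBSTRATE_BACKGROUND)
        ss0 = find_steady_state(cosub_toy, COSUBSTRATE_BACKGROUND)
        net1 = cosub_toy.with_branch_fraction("X", "RA", 0.3 * (1 + delta))
        ss1 = find_steady_state(net1, COSUBSTRATE_BACKGROUND)
        i = cosub_toy.index.resolve("Y1")
        f_star = realized_flux_fractions(net1, ss1.state, "X")["RA"]
        fd = ((ss1.state[i] - ss0.state[i]) / (f_star - 0.3)
              * (0.3 / ss0.state[i]))
        assert rec.coefficient == pytest.approx(fd, rel=1e-9)

    def test_unstable_run_flagged_not_raised(self, cosub_toy):
        """Pushing f past the co-substrate supply starves the system."""
        rec = concentration_control_coefficient(
            cosub_toy, "X", "RA", target="Y1", delta=0.9,
            background=COSUBSTRATE_BACKGROUND, t_end=5e4)
        assert not rec.stable
        assert math.isnan(rec.coefficient)
        assert rec.impact == "unclassified"


class TestScanBranches:
    def test_cardinality_and_ordering(self, cosub_toy):
        recs = scan_branches(cosub_toy, "Y1", deltas=(-0.1, 0.1),
                             background=COSUBSTRATE_BACKGROUND,
                             branches=[("X", "RA")])
        assert len(recs) == 2
        assert [r.delta for r in recs] == [-0.1, 0.1]

    def test_scan_equals_one_at_a_time_recomputation(self, cosub_toy):
        recs = scan_branches(cosub_toy, "Y1", deltas=(-0.1, 0.1),
                             background=COSUBSTRATE_BACKGROUND,
                             branches=[("X", "RA"), ("X", "snk_x")])
        for rec in recs:
            single = concentration_control_coefficient(
                cosub_toy, rec.branch, rec.child, target="Y1",
                delta=rec.delta, background=COSUBSTRATE_BACKGROUND)
            assert rec.coefficient == pytest.approx(single.coefficient,
                                                    rel=1e-9)

    def test_frame_is_sorted_and_typed(self, cosub_toy):
        recs = scan_branches(cosub_toy, "Y1", deltas=(0.1, -0.1),
                             background=COSUBSTRATE_BACKGROUND)
        df = records_to_frame(recs)
        assert list(df.columns) == ["branch", "child", "f", "delta", "target",
                                    "TG", "TG_star", "coefficient", "class",
                                    "stable", "mode"]
        assert df.sort_values(["branch", "child", "delta"]).equals(df)


class TestToleranceRange:
    def test_globally_stable_branch_spans_grid(self, branch2):
        tr = tolerance_range(branch2, "X", "RA", resolution=0.2)
        assert tr.f_lo == pytest.approx(0.2)
        assert tr.f_hi == pytest.approx(0.8)
        assert tr.mode_lo == "none" and tr.mode_hi == "none"

    def test_finite_upper_bound_from_cosubstrate_starvation(self, cosub_toy):
        """Beyond f = supply the condensation step starves: finite tolerance."""
        tr = tolerance_range(cosub_toy, "X", "RA",
                             background=COSUBSTRATE_BACKGROUND,
                             resolution=0.1, t_end=1e5)
        assert tr.f_hi == pytest.approx(0.4)
        assert tr.mode_hi == "non-convergence"
        assert tr.mode_lo == "none"
        assert tr.f_lo <= 0.3 <= tr.f_hi


class TestRegulatorSensitivity:
    def test_matrix_shape_and_decoupled_zero(self, liver_net):
        df = regulator_sensitivity(
            liver_net, "chol_b", "T_CHUP",
            regulators=["SREBP1C", "PPARA"], delta=0.1,
            background=None)
        assert list(df.columns) == ["branch", "child", "regulator",
                                    "coefficient", "impact", "stable"]
        assert len(df) == 2
        # without background every rebuilt baseline is normalized: zero
        assert np.allclose(df.coefficient.abs(), 0.0, atol=1e-8)
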