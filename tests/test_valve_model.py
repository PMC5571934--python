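"""Unit and property tests for the core parametric geometry."""

import math
from dataclasses import replace
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitralgeom import (
    AnnulusGeometry,
    DomainError,
    InfeasibleGeometryError,
    InvalidParameterError,
    LeafletDimensions,
    PosteriorPartition,
    ValveParameters,
    anterior_free_edge,
    anterior_point,
    check_continuity,
    elliptic_cylinder_point,
    junction_offset,
    partition_posterior,
    posterior_point,
    posterior_scallop_bounds,
)

PI = math.pi


class TestEllipticCylinderPoint:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((1.4, 1.04, 2.4, PI / 2, 1.0), (0.0, 1.04, 2.4)),
            ((1.4, 1.04, 2.4, 0.0, 0.0), (1.4, 0.0, 0.0)),
            ((1.0, 1.0, 1.0, PI / 4, 0.5), (math.sqrt(2) / 2, math.sqrt(2) / 2, 0.5)),
        ],
    )
    def test_known_points(self, args, expected):
        p = elliptic_cylinder_point(*args)
        assert p.as_tuple() == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("bad", [(-1, 1, 1), (1, 0, 1), (1, 1, -2)])
    def test_nonpositive_coefficients_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            elliptic_cylinder_point(*bad, 0.0, 0.0)


class TestAnteriorFreeEdge:
    @pytest.mark.parametrize(
        "y1, expected", [(PI / 2, 1.0), (0.0, 0.0), (PI / 6, 0.5)]
    )
    def test_sine_boundary(self, y1, expected):
        assert anterior_free_edge(y1) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("y1", [-0.1, PI + 0.1, 7.0])
    def test_out_of_domain(self, y1):
        with pytest.raises(DomainError):
            anterior_free_edge(y1)


class TestPartition:
    def test_default_widths_give_printed_junction_angles(self):
        theta1, theta2 = partition_posterior(1.6, 2.3, 1.5)
        assert theta1 == pytest.approx(35 * PI / 27, abs=1e-14)
        assert theta2 == pytest.approx(93 * PI / 54, abs=1e-14)

    @pytest.mark.parametrize(
        "widths, expected",
        [
            ((1.0, 1.0, 1.0), (4 * PI / 3, 5 * PI / 3)),
            ((1.0, 1.0, 2.0), (5 * PI / 4, 3 * PI / 2)),
        ],
    )
    def test_proportional_split(self, widths, expected):
        assert partition_posterior(*widths) == pytest.approx(expected, abs=1e-14)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            partition_posterior(1.0, -0.5, 1.0)

    @given(
        w=st.tuples(*[st.floats(0.2, 5.0)] * 3),
        k=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_tiling_and_scale_invariance(self, w, k):
        """Intervals tile [pi, 2pi]; angles are invariant under width rescaling."""
        theta1, theta2 = partition_posterior(*w)
        assert PI < theta1 < theta2 < 2 * PI
        spans = (theta1 - PI) + (theta2 - theta1) + (2 * PI - theta2)
        assert spans == pytest.approx(PI, abs=1e-12)
        scaled = partition_posterior(*(k * wi for wi in w))
        assert scaled == pytest.approx((theta1, theta2), rel=1e-12)

    def test_frequency_recovery_is_exact_in_rational_arithmetic(self):
        """Phase 8pi/9 with widths 1.6/2.3/1.5 yields frequencies 3, 54/23, 16/5."""
        w = [Fraction(16, 10), Fraction(23, 10), Fraction(15, 10)]
        total = sum(w)
        phi_over_pi = Fraction(8, 9)
        c1 = phi_over_pi / (w[0] / total)
        c2 = 1 / (w[1] / total)
        c3 = phi_over_pi / (w[2] / total)
        assert (c1, c2, c3) == (Fraction(3), Fraction(54, 23), Fraction(16, 5))
        part = ValveParameters().partition
        assert part.c1 == pytest.approx(3.0, abs=1e-12)
        assert part.c2 == pytest.approx(54 / 23, abs=1e-12)
        assert part.c3 == pytest.approx(16 / 5, abs=1e-12)


class TestJunctionOffset:
    def test_default_offset_value(self):
        delta = junction_offset(1.1, 1.4, 8 * PI / 9)
        assert delta == pytest.approx(11 / 14 * math.sin(PI / 9), abs=1e-15)
        assert delta == pytest.approx(0.26873, abs=5e-6)

    def test_phase_pi_gives_zero_offset(self):
        assert junction_offset(1.0, 1.0, PI) == pytest.approx(0.0, abs=1e-14)

    def test_tall_p1_offset(self):
        assert junction_offset(2.0, 1.0, 8 * PI / 9) == pytest.approx(
            2 * math.sin(PI / 9), abs=1e-15
        )

    def test_infeasible_when_middle_scallop_too_short(self):
        with pytest.raises(InfeasibleGeometryError):
            junction_offset(5.0, 1.0, 8 * PI / 9)


class TestScallopBounds:
    def test_commissures_collapse_to_zero(self, default_params):
        part = default_params.partition
        for y1, scallop in ((PI, "P1"), (2 * PI, "P3")):
            lo, up, sid = posterior_scallop_bounds(y1, part)
            assert sid == scallop
            assert lo == pytest.approx(0.0, abs=1e-12)
            assert up == pytest.approx(0.0, abs=1e-12)

    def test_junction_column_is_height_continuous(self, default_params):
        """At theta1 both P1's and P2's free edges sit at z = h_p1*sin(pi/9)."""
        part = default_params.partition
        dims = default_params.dims
        lo, up, sid = posterior_scallop_bounds(part.theta1, part)
        assert sid == "P2"
        assert lo == up == part.delta
        z = dims.h_p2 * lo
        assert z == pytest.approx(1.1 * math.sin(PI / 9), abs=1e-12)
        assert z == pytest.approx(0.37622, abs=5e-6)
        z_left = dims.h_p1 * math.sin(part.c1 * (part.theta1 - PI))
        assert z_left == pytest.approx(z, abs=1e-12)

    @given(y1=st.floats(PI, 2 * PI))
    @settings(max_examples=200, deadline=None)
    def test_upper_bound_never_below_lower(self, y1):
        part = ValveParameters().partition
        lo, up, _ = posterior_scallop_bounds(y1, part)
        assert up >= lo - 1e-12

    def test_out_of_domain(self, default_params):
        with pytest.raises(DomainError):
            posterior_scallop_bounds(0.5, default_params.partition)


class TestSurfacePoints:
    def test_anterior_known_points(self, default_params):
        assert anterior_point(default_params, PI / 2, 1.0).as_tuple() == pytest.approx(
            (0.0, 1.04, 2.4), abs=1e-14
        )
        assert anterior_point(default_params, 0.0, 0.0).as_tuple() == pytest.approx(
            (1.4, 0.0, 0.0), abs=1e-14
        )
        s = math.sqrt(3) / 2
        assert anterior_point(default_params, PI / 3, s).as_tuple() == pytest.approx(
            (0.7, 1.04 * s, 2.4 * s), abs=1e-14
        )

    def test_posterior_known_points(self, default_params):
        part = default_params.partition
        assert posterior_point(default_params, 3 * PI / 2, 0.0).as_tuple() == pytest.approx(
            (0.0, -2.11, 0.0), abs=1e-14
        )
        assert posterior_point(default_params, PI, 0.0).as_tuple() == pytest.approx(
            (-1.4, 0.0, 0.0), abs=1e-14
        )
        p = posterior_point(default_params, part.theta1, part.delta)
        assert p.z == pytest.approx(0.37622, abs=5e-6)

    def test_domain_violations(self, default_params):
        with pytest.raises(DomainError):
            anterior_point(default_params, PI / 2, 1.5)
        with pytest.raises(DomainError):
            posterior_point(default_params, 3 * PI / 2, 1.05)
        with pytest.raises(DomainError):
            posterior_point(default_params, PI / 2, 0.0)

    @given(y1=st.floats(0.0, PI), frac=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_anterior_cylinder_membership_and_sign(self, y1, frac):
        """Anterior points lie on the (1.4, 1.04) elliptic cylinder with y >= 0."""
        params = ValveParameters()
        p = anterior_point(params, y1, frac * anterior_free_edge(y1))
        r = (p.x / params.annulus.a) ** 2 + (p.y / params.annulus.sl_ant) ** 2
        assert r == pytest.approx(1.0, abs=1e-10)
        assert p.y >= -1e-12 and p.z >= -1e-12

    @given(y1=st.floats(PI, 2 * PI), frac=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_posterior_cylinder_membership_and_sign(self, y1, frac):
        """Posterior points lie on the (1.4, 2.11) cylinder with y <= 0."""
        params = ValveParameters()
        lo, up, _ = posterior_scallop_bounds(y1, params.partition)
        p = posterior_point(params, y1, lo + frac * (up - lo))
        r = (p.x / params.annulus.a) ** 2 + (p.y / params.annulus.sl_post) ** 2
        assert r == pytest.approx(1.0, abs=1e-10)
        assert p.y <= 1e-12 and p.z >= -1e-12


class TestContinuity:
    def test_defaults_are_continuous(self, default_params):
        assert check_continuity(default_params) <= 1e-12

    @given(
        h1=st.floats(0.5, 2.0),
        h3=st.floats(0.5, 2.0),
        w=st.tuples(*[st.floats(0.5, 3.0)] * 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_constructed_offset_always_continuous_at_first_junction(self, h1, h3, w):
        """delta by construction zeroes the P1/P2 gap; the P2/P3 gap is |h_p1-h_p3|*sin(pi-phi)."""
        dims = LeafletDimensions(h_p1=h1, h_p2=4.0, h_p3=h3, w_p1=w[0], w_p2=w[1], w_p3=w[2])
        params = ValveParameters(dims=dims)
        gap = check_continuity(params)
        expected_gap2 = abs(h1 - h3) * math.sin(PI - params.phi)
        assert gap == pytest.approx(expected_gap2, abs=1e-10)

    def test_matched_outer_heights_fully_continuous(self):
        dims = LeafletDimensions(h_p1=1.0, h_p2=2.0, h_p3=1.0)
        assert check_continuity(ValveParameters(dims=dims)) <= 1e-12

    def test_overridden_zero_offset_exposes_the_gap(self, default_params):
        part = replace(default_params.partition, delta=0.0)
        gap = check_continuity(default_params, partition=part)
        assert gap == pytest.approx(1.1 * math.sin(PI / 9), abs=1e-12)


class TestValidation:
    def test_annulus_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            AnnulusGeometry(ic=-2.8)

    def test_dimensions_reject_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            LeafletDimensions(h_p2=0.0)

    def test_partition_invariant_enforced(self):
        with pytest.raises(InvalidParameterError):
            PosteriorPartition(
                theta1=2.0, theta2=1.0, phi=8 * PI / 9, c1=3, c2=2, c3=3, delta=0.1
            )

    def test_annulus_derived_quantities(self):
        ann = AnnulusGeometry()
        assert ann.a == 1.4
        assert ann.septolateral_diameter == pytest.approx(3.15)
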