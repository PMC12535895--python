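"""Core system-matrix construction and eigen-geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from velstore import (
    CouplingTerms,
    DegenerateEigenstructureError,
    InvalidParameterError,
    TimeConstants,
    UndefinedRatioError,
    VSModel,
    build_normal,
    build_pull,
    coupling_from_tilt,
    eigenbasis,
    misalignment_angle,
    model_from_dict,
    model_to_dict,
    subjective_up,
    tilt_increase_pct,
    tilt_increase_pct_angle,
)
from velstore.model import with_yaw_gain

from conftest import random_model

TAN15 = math.tan(math.radians(15.0))


class TestConstruction:
    @pytest.mark.parametrize(
        "taus, expected_diag",
        [
            ((5.0, 5.0, 18.0), (-0.2, -0.2, -0.0556)),
            ((1.0, 1.0, 1.0), (-1.0, -1.0, -1.0)),
            ((5.0, 5.0, 12.0), (-0.2, -0.2, -0.0833)),
        ],
    )
    def test_normal_matrix_diagonal(self, taus, expected_diag):
        m = build_normal(TimeConstants(*taus))
        assert np.allclose(np.diag(m.matrix), expected_diag, atol=5e-5)
        assert np.count_nonzero(m.matrix - np.diag(np.diag(m.matrix))) == 0
        assert m.yaw_gain == 1.0

    @pytest.mark.parametrize("bad_tau", [0.0, -1.0, math.inf, math.nan])
    def test_nonpositive_time_constant_rejected(self, bad_tau):
        with pytest.raises(InvalidParameterError):
            TimeConstants(bad_tau, 5.0, 18.0)

    @pytest.mark.parametrize(
        "coupling, row, col",
        [
            (CouplingTerms(h_yr=0.04, h_yp=0.0), 0, 2),
            (CouplingTerms(h_yr=0.0, h_yp=0.04), 1, 2),
        ],
    )
    def test_pull_offdiagonal_placement(self, canonical_tcs, coupling, row, col):
        H = build_pull(canonical_tcs, coupling).matrix
        off = H - np.diag(np.diag(H))
        assert off[row, col] == 0.04
        off[row, col] = 0.0
        assert np.count_nonzero(off) == 0

    def test_zero_coupling_pull_equals_normal(self, canonical_tcs):
        pull = build_pull(canonical_tcs, CouplingTerms(0.0, 0.0))
        assert np.array_equal(pull.matrix, build_normal(canonical_tcs).matrix)

    def test_canonical_regime_predicate(self):
        assert TimeConstants(5, 5, 18).is_canonical()
        assert not TimeConstants(18, 5, 5).is_canonical()
        assert not TimeConstants(5, 5, 5).is_canonical()

    @pytest.mark.parametrize("k", [0.0, -0.5, 1.5, math.nan])
    def test_gain_outside_unit_interval_rejected(self, canonical_tcs, k):
        with pytest.raises(InvalidParameterError):
            VSModel(canonical_tcs, CouplingTerms(), yaw_gain=k)


class TestSubjectiveUp:
    def test_diagonal_model_aligned_with_head_vertical(self, canonical_tcs):
        for k in (1.0, 0.7):
            u = subjective_up(VSModel(canonical_tcs, CouplingTerms(), k))
            assert u.as_array() == pytest.approx([0.0, 0.0, k])

    def test_roll_component_is_tangent_of_designed_tilt(self, pull15):
        u = subjective_up(pull15)
        assert u.roll_component == pytest.approx(TAN15, abs=1e-12)
        assert u.pitch_component == 0.0
        assert u.yaw_component == 1.0

    def test_gain_scales_yaw_component_only(self, pull15):
        u = subjective_up(with_yaw_gain(pull15, 0.8))
        assert u.roll_component == pytest.approx(TAN15, abs=1e-12)
        assert u.yaw_component == 0.8


class TestEigenbasis:
    def test_diagonal_model_gives_standard_basis(self, canonical_tcs):
        basis = eigenbasis(build_normal(canonical_tcs))
        assert np.array_equal(
            np.stack([u.as_array() for u in basis]), np.eye(3)
        )

    def test_roll_pitch_eigenvectors_unaffected_by_coupling(self, pull15):
        u_roll, u_pitch, _ = eigenbasis(pull15)
        assert np.array_equal(u_roll.as_array(), [1, 0, 0])
        assert np.array_equal(u_pitch.as_array(), [0, 1, 0])

    def test_yaw_eigenvector_satisfies_eigen_equation(self, pull15):
        H = pull15.matrix
        u = eigenbasis(pull15)[2].as_array()
        h_yy = pull15.time_constants.h_yy
        assert np.max(np.abs(H @ u - h_yy * u)) < 1e-12

    def test_eigen_equation_over_random_models(self):
        """Each closed-form eigenvector solves H u = lambda u to 1e-10."""
        rng = np.random.default_rng(20250101)
        for _ in range(1000):
            m = random_model(rng)
            H = m.matrix
            tcs = m.time_constants
            for u, lam in zip(
                eigenbasis(m), (tcs.h_rr, tcs.h_pp, tcs.h_yy)
            ):
                vec = u.as_array()
                assert np.max(np.abs(H @ vec - lam * vec)) < 1e-10

    def test_degenerate_rates_with_coupling_raise(self):
        m = VSModel(TimeConstants(5, 5, 5), CouplingTerms(h_yr=0.05), 1.0)
        with pytest.raises(DegenerateEigenstructureError):
            eigenbasis(m)
        with pytest.raises(DegenerateEigenstructureError):
            misalignment_angle(m)

    def test_degenerate_rates_without_coupling_are_fine(self):
        m = VSModel(TimeConstants(5, 5, 5), CouplingTerms(), 1.0)
        assert misalignment_angle(m) == 0.0


class TestMisalignmentAngle:
    def test_zero_for_diagonal_models_any_gain(self, canonical_tcs):
        for k in (1.0, 0.8, 0.3):
            assert misalignment_angle(VSModel(canonical_tcs, CouplingTerms(), k)) == 0.0

    def test_yaw_time_constant_reduction_worked_example(self, canonical_tcs, pull15):
        shortened = VSModel(
            TimeConstants(5, 5, 12), pull15.coupling, 1.0
        )
        assert round(misalignment_angle(shortened), 1) == 18.4

    def test_gain_reduction_worked_example(self, pull15):
        assert round(misalignment_angle(with_yaw_gain(pull15, 0.8)), 1) == 18.5

    @given(st.floats(0.5, 59.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gain_tangent_ratio_is_reciprocal_gain(self, tilt):
        """tan(gamma(k)) / tan(gamma(1)) = 1/k exactly, any baseline."""
        tcs = TimeConstants(5, 5, 18)
        m = build_pull(tcs, coupling_from_tilt(tilt, "roll-yaw", tcs))
        k = 0.65
        t1 = math.tan(math.radians(misalignment_angle(m)))
        tk = math.tan(math.radians(misalignment_angle(with_yaw_gain(m, k))))
        assert tk / t1 == pytest.approx(1.0 / k, rel=1e-12)

    def test_monotone_in_yaw_time_constant(self, pull15):
        """Shorter tau_yaw (toward tau_roll) means larger misalignment."""
        gammas = [
            misalignment_angle(
                VSModel(TimeConstants(5, 5, tau), pull15.coupling, 1.0)
            )
            for tau in (18.0, 15.0, 12.0, 9.0, 6.0)
        ]
        assert all(a < b for a, b in zip(gammas, gammas[1:]))

    def test_monotone_in_gain(self, pull15):
        gammas = [
            misalignment_angle(with_yaw_gain(pull15, k))
            for k in (1.0, 0.9, 0.8, 0.6, 0.4)
        ]
        assert all(a < b for a, b in zip(gammas, gammas[1:]))


class TestCouplingFromTilt:
    def test_zero_tilt_gives_zero_coupling(self, canonical_tcs):
        c = coupling_from_tilt(0.0, "roll-yaw", canonical_tcs)
        assert c.is_zero()

    def test_fifteen_degree_coupling_value(self, canonical_tcs):
        # oracle: tan(15 deg) * (1/5 - 1/18) per the direction-cosine inverse
        expected = TAN15 * (1.0 / 5.0 - 1.0 / 18.0)
        c = coupling_from_tilt(15.0, "roll-yaw", canonical_tcs)
        assert c.h_yr == pytest.approx(expected, rel=1e-12)
        assert c.h_yr == pytest.approx(0.0387, abs=5e-5)
        assert c.h_yp == 0.0

    def test_pitch_plane_places_coupling_in_h_yp(self, canonical_tcs):
        c = coupling_from_tilt(10.0, "pitch-yaw", canonical_tcs)
        assert c.h_yr == 0.0 and c.h_yp != 0.0

    @pytest.mark.parametrize("tilt", [90.0, 120.0, -1.0])
    def test_out_of_range_tilt_rejected(self, canonical_tcs, tilt):
        with pytest.raises(InvalidParameterError):
            coupling_from_tilt(tilt, "roll-yaw", canonical_tcs)

    @pytest.mark.parametrize("tau_yaw", [8.0, 12.0, 18.0, 24.0, 30.0])
    @pytest.mark.parametrize("plane", ["roll-yaw", "pitch-yaw"])
    def test_round_trip_recovers_tilt(self, tau_yaw, plane):
        """coupling_from_tilt then misalignment_angle is the identity."""
        tcs = TimeConstants(5.0, 5.0, tau_yaw)
        for tilt in range(1, 61):
            m = build_pull(tcs, coupling_from_tilt(float(tilt), plane, tcs))
            assert misalignment_angle(m) == pytest.approx(tilt, abs=1e-9)


class TestTiltIncrease:
    def test_time_constant_scenario_gives_24_pct(self, pull15):
        after = VSModel(TimeConstants(5, 5, 12), pull15.coupling, 1.0)
        assert round(tilt_increase_pct(pull15, after)) == 24

    def test_gain_scenario_gives_25_pct(self, pull15):
        after = with_yaw_gain(pull15, 0.8)
        assert round(tilt_increase_pct(pull15, after)) == 25

    @pytest.mark.parametrize("baseline_tilt", [3.0, 5.0, 15.0, 40.0])
    def test_gain_effect_is_baseline_independent(self, baseline_tilt):
        """k = 0.8 yields 25% on the tangent scale at any baseline tilt."""
        tcs = TimeConstants(5, 5, 18)
        m = build_pull(tcs, coupling_from_tilt(baseline_tilt, "roll-yaw", tcs))
        assert tilt_increase_pct(m, with_yaw_gain(m, 0.8)) == pytest.approx(25.0)

    def test_angle_scale_variant_differs(self, pull15):
        """The plain angle ratio gives ~22.4%, not the tangent-scale 24%."""
        after = VSModel(TimeConstants(5, 5, 12), pull15.coupling, 1.0)
        assert tilt_increase_pct_angle(pull15, after) == pytest.approx(22.4, abs=0.1)

    def test_zero_baseline_is_undefined(self, canonical_tcs):
        normal = build_normal(canonical_tcs)
        with pytest.raises(UndefinedRatioError):
            tilt_increase_pct(normal, with_yaw_gain(normal, 0.8))


class TestSerialization:
    def test_round_trip(self, pull15):
        m = with_yaw_gain(pull15, 0.8)
        assert model_from_dict(model_to_dict(m)) == m

    def test_unknown_and_missing_keys_rejected(self, pull15):
        d = model_to_dict(pull15)
        d["bogus"] = 1.0
        with pytest.raises(InvalidParameterError, match="bogus"):
            model_from_dict(d)
        del d["bogus"], d["yaw_gain"]
        with pytest.raises(InvalidParameterError, match="yaw_gain"):
            model_from_dict(d)
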