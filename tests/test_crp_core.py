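import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crpkit import (
    PhasePortrait,
    PhaseWindows,
    compute_crp,
    compute_phase_angle,
    compute_velocity,
    normalize_amplitude,
    summarize_crp,
    unwrap_degrees,
)
from crpkit.crp_core import PhaseAngleSeries, normalize_max_abs
from crpkit.errors import CrpkitError, DegenerateSignalError, UndefinedPhaseError

GAIT_WINDOWS = PhaseWindows("gait", {"stance": (0, 62), "swing": (62, 101)})


class TestVelocity:
    def test_linear_ramp(self):
        theta = np.arange(10.0) * 2.0  # 2 deg per frame
        np.testing.assert_allclose(compute_velocity(theta, 120.0), 240.0)

    def test_constant_is_zero(self):
        np.testing.assert_allclose(compute_velocity(np.full(10, 5.0), 120.0), 0.0)

    def test_sinusoid_matches_analytic_derivative(self):
        t = np.arange(600) / 120.0
        theta = 10.0 * np.sin(2 * np.pi * t)
        v = compute_velocity(theta, 120.0)
        exact = 10.0 * 2 * np.pi * np.cos(2 * np.pi * t)
        peak = 10.0 * 2 * np.pi
        assert np.max(np.abs(v[1:-1] - exact[1:-1])) < 0.001 * peak

    def test_too_short_rejected(self):
        with pytest.raises(CrpkitError):
            compute_velocity(np.array([1.0, 2.0]), 120.0)


class TestNormalize:
    def test_symmetric_rescale(self):
        np.testing.assert_allclose(
            normalize_amplitude(np.array([0.0, 5.0, 10.0])), [-1, 0, 1]
        )
        np.testing.assert_allclose(normalize_amplitude(np.array([-2.0, 2.0])), [-1, 1])

    def test_constant_rejected(self):
        with pytest.raises(DegenerateSignalError):
            normalize_amplitude(np.array([3.0, 3.0, 3.0]))

    def test_extrema_attained_over_scope(self, rng):
        x = rng.normal(size=100)
        y = normalize_amplitude(x)
        assert y.min() == pytest.approx(-1) and y.max() == pytest.approx(1)

    def test_max_abs_preserves_zero(self):
        y = normalize_max_abs(np.array([-4.0, 0.0, 2.0]))
        np.testing.assert_allclose(y, [-1.0, 0.0, 0.5])


class TestPhaseAngle:
    @pytest.mark.parametrize(
        "th,v,expected", [(1, 0, 0.0), (0, 1, 90.0), (-1, 0, 180.0), (0, -1, -90.0)]
    )
    def test_quadrants(self, th, v, expected):
        series = compute_phase_angle(
            PhasePortrait(np.array([float(th)]), np.array([float(v)]))
        )
        assert series.phi[0] == pytest.approx(expected)

    def test_sinusoid_phase_decreases_linearly_from_90(self):
        # theta = sin(wt) -> phi = 90 - wt: one full cycle drops 360 deg
        t = np.linspace(0, 1, 101)
        portrait = PhasePortrait(np.sin(2 * np.pi * t), np.cos(2 * np.pi * t))
        phi = compute_phase_angle(portrait).phi
        expected = 90.0 - 360.0 * t
        np.testing.assert_allclose(phi, expected, atol=1e-9)

    def test_origin_at_first_sample_rejected(self):
        with pytest.raises(UndefinedPhaseError):
            compute_phase_angle(PhasePortrait(np.array([0.0, 1.0]), np.array([0.0, 0.0])))

    def test_origin_mid_series_carried_forward(self):
        portrait = PhasePortrait(np.array([1.0, 0.0, 1.0]), np.array([0.0, 0.0, 0.0]))
        series = compute_phase_angle(portrait)
        assert series.phi[1] == series.phi[0]
        assert series.carried_forward[1]

    def test_continuity_invariant(self, rng):
        portrait = PhasePortrait(rng.normal(size=500), rng.normal(size=500))
        phi = compute_phase_angle(portrait).phi
        assert np.max(np.abs(np.diff(phi))) <= 180.0


class TestUnwrap:
    def test_wraparound_restored(self):
        np.testing.assert_allclose(
            unwrap_degrees(np.array([170.0, -175.0, -160.0])), [170.0, 185.0, 200.0]
        )

    def test_continuous_series_unchanged(self):
        np.testing.assert_allclose(
            unwrap_degrees(np.array([0.0, 10.0, 20.0])), [0.0, 10.0, 20.0]
        )

    @settings(deadline=None, max_examples=100)
    @given(
        k0=st.integers(min_value=-3, max_value=3),
        phi=st.lists(
            st.floats(min_value=-1000, max_value=1000, allow_nan=False),
            min_size=1,
            max_size=40,
        ),
    )
    def test_shift_invariance(self, k0, phi):
        phi = np.asarray(phi)
        np.testing.assert_allclose(
            unwrap_degrees(phi + 360.0 * k0), unwrap_degrees(phi) + 360.0 * k0,
            atol=1e-6,
        )

    @settings(deadline=None, max_examples=100)
    @given(
        phi=st.lists(
            st.floats(min_value=-720, max_value=720, allow_nan=False),
            min_size=2,
            max_size=40,
        )
    )
    def test_unwrapped_differences_bounded(self, phi):
        out = unwrap_degrees(np.asarray(phi))
        d = np.diff(out)
        assert np.all(d > -180.0 - 1e-9) and np.all(d <= 180.0 + 1e-9)


class TestCrp:
    def test_pointwise_difference(self):
        crp = compute_crp(
            PhaseAngleSeries(np.array([30.0, 40.0])),
            PhaseAngleSeries(np.array([10.0, 20.0])),
            "TS",
        )
        np.testing.assert_allclose(crp.crp, [20.0, 20.0])

    def test_identical_inputs_in_phase(self):
        phi = PhaseAngleSeries(np.linspace(90, -270, 101))
        np.testing.assert_allclose(compute_crp(phi, phi, "TS").crp, 0.0)

    def test_antisymmetry(self, rng):
        a = PhaseAngleSeries(rng.normal(size=101).cumsum())
        b = PhaseAngleSeries(rng.normal(size=101).cumsum())
        fwd = compute_crp(a, b, "TS").crp
        rev = compute_crp(b, a, "TS").crp
        np.testing.assert_array_equal(fwd, -rev)

    def test_length_mismatch_rejected(self):
        with pytest.raises(CrpkitError):
            compute_crp(
                PhaseAngleSeries(np.zeros(5)), PhaseAngleSeries(np.zeros(6)), "TS"
            )

    @pytest.mark.parametrize("lag", [10.0, 30.0, 60.0, 90.0])
    def test_lag_between_sinusoids_recovered(self, lag):
        # the distal segment leads by the lag: phi = 90 - u for sin(u),
        # so CRP = phi_prox - phi_dist = +lag
        t = np.linspace(0, 1, 101)
        u = 2 * np.pi * t
        prox = compute_phase_angle(PhasePortrait(np.sin(u), np.cos(u)))
        dist = compute_phase_angle(
            PhasePortrait(np.sin(u + np.radians(lag)), np.cos(u + np.radians(lag)))
        )
        crp = compute_crp(prox, dist, "TS").crp
        mid = crp[10:90]
        assert np.mean(mid) == pytest.approx(lag, abs=1.0)


class TestSummaries:
    def test_constant_trials(self):
        curves = {"TS": [np.full(101, 10.0)] * 3}
        (stance, swing) = summarize_crp(curves, GAIT_WINDOWS)
        assert stance.rms == pytest.approx(10.0)
        assert stance.sd == pytest.approx(0.0)
        assert swing.n_trials == 3

    def test_across_trial_sd_is_sample_sd(self):
        curves = {"TS": [np.full(101, v) for v in (0.0, 10.0, 20.0)]}
        (stance, _) = summarize_crp(curves, GAIT_WINDOWS)
        assert stance.rms == pytest.approx(10.0)
        assert stance.sd == pytest.approx(10.0)  # sample SD of {0,10,20}

    def test_rms_of_sinusoidal_mean_curve(self):
        full = PhaseWindows("gait", {"cycle": (0, 1000)})
        x = 30.0 * np.sin(2 * np.pi * np.arange(1000) / 1000)
        (s,) = summarize_crp({"TS": [x, x]}, full)
        assert s.rms == pytest.approx(30.0 / np.sqrt(2), rel=0.005)

    def test_single_trial_needs_within_curve_mode(self):
        curves = {"TS": [np.arange(101.0)]}
        with pytest.raises(CrpkitError, match="within_curve"):
            summarize_crp(curves, GAIT_WINDOWS, sd_mode="across_trials")
        out = summarize_crp(curves, GAIT_WINDOWS, sd_mode="within_curve")
        assert out[0].sd > 0
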