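import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crpkit.errors import (
    EventDetectionError,
    EventOrderingError,
    FilterError,
    InsufficientCyclesError,
    InterpolationError,
)
from crpkit.preprocess import (
    Events,
    baseline_correct_grf,
    define_phase_windows,
    detect_contact_events,
    lowpass_filter,
    time_normalize,
)


def _sine(freq, fs=120.0, dur=10.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return t, amp * np.sin(2 * np.pi * freq * t)


def _fit_gain_phase(t, y, freq):
    """Least-squares amplitude and phase of a sinusoid at a known frequency
    (interior samples only, clear of filtfilt edge transients)."""
    sl = slice(len(t) // 4, -len(t) // 4)
    X = np.column_stack([np.sin(2 * np.pi * freq * t[sl]), np.cos(2 * np.pi * freq * t[sl])])
    a, b = np.linalg.lstsq(X, y[sl], rcond=None)[0]
    return np.hypot(a, b), np.degrees(np.arctan2(b, a))


class TestLowpassFilter:
    def test_constant_series_unchanged(self):
        x = np.full(200, 7.3)
        np.testing.assert_allclose(lowpass_filter(x, 120.0, 6.0, 4), x, atol=1e-9)

    def test_passband_sinusoid_preserved(self):
        t, x = _sine(1.0)
        gain, phase = _fit_gain_phase(t, lowpass_filter(x, 120.0, 6.0, 4), 1.0)
        assert gain == pytest.approx(1.0, abs=0.01)
        assert abs(phase) < 0.5

    def test_cutoff_gain_is_half_for_dual_pass(self):
        # |H|^2 at the corner = (1/sqrt(2))^2 for the forward-backward pass
        t, x = _sine(6.0)
        gain, phase = _fit_gain_phase(t, lowpass_filter(x, 120.0, 6.0, 4), 6.0)
        assert gain == pytest.approx(0.5, abs=0.02)
        assert abs(phase) < 0.5

    def test_idempotent_in_passband(self):
        # interior samples only: the boundary reflection used by the
        # zero-phase filter leaves a short edge transient either way
        _, x = _sine(0.5)
        once = lowpass_filter(x, 120.0, 6.0, 4)
        twice = lowpass_filter(once, 120.0, 6.0, 4)
        core = slice(120, -120)
        assert np.max(np.abs(twice[core] - once[core])) < 0.01 * np.max(np.abs(once))

    def test_too_short_series_rejected(self):
        with pytest.raises(FilterError):
            lowpass_filter(np.zeros(5), 120.0, 6.0, 4)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(FilterError):
            lowpass_filter(np.zeros(100), 120.0, 70.0, 4)


class TestEventDetection:
    def test_single_run(self):
        grf = np.array([0, 0, 50, 80, 50, 0, 0], dtype=float)
        ev = detect_contact_events(grf, 10.0, "generic", fs=40.0)
        # fs=40 -> debounce 1 sample; single contact run
        assert ev.initial_contacts.tolist() == [2]
        assert ev.toe_offs.tolist() == [5]

    def test_all_zero_grf(self):
        with pytest.raises(EventDetectionError, match="no contact"):
            detect_contact_events(np.zeros(100), 10.0, "gait", fs=120.0)

    def test_gait_needs_two_contacts(self):
        grf = np.zeros(100)
        grf[10:40] = 100.0
        with pytest.raises(InsufficientCyclesError):
            detect_contact_events(grf, 10.0, "gait", fs=120.0)

    def test_debounce_drops_short_spikes(self):
        grf = np.zeros(200)
        grf[50] = 500.0  # a 1-sample spike at 120 Hz is < 25 ms
        grf[80:120] = 400.0
        grf[160:199] = 400.0
        ev = detect_contact_events(grf, 10.0, "gait", fs=120.0)
        assert ev.initial_contacts.tolist() == [80, 160]

    def test_offset_below_threshold_is_ignored(self):
        grf = np.zeros(300)
        grf[50:150] = 300.0
        grf[200:290] = 300.0
        base = detect_contact_events(grf, 10.0, "gait", fs=120.0)
        shifted = detect_contact_events(grf + 5.0, 10.0, "gait", fs=120.0)
        assert base.initial_contacts.tolist() == shifted.initial_contacts.tolist()
        assert base.toe_offs.tolist() == shifted.toe_offs.tolist()

    def test_baseline_correction_removes_plate_offset(self, rng):
        grf = np.zeros(400)
        grf[100:300] = 600.0
        corrected = baseline_correct_grf(grf + 37.5)
        assert np.all(corrected >= 0)
        assert np.all(corrected[:100] == 0)
        assert corrected[200] == pytest.approx(600.0)


class TestPhaseWindows:
    def test_gait_stance_share(self):
        ev = Events("gait", [0, 100], [62])
        pw = define_phase_windows(ev, (0, 100), "gait", 101)
        assert pw.windows == {"stance": (0, 62), "swing": (62, 101)}

    def test_hop_three_phases(self):
        ev = Events("hop", [70], [40])
        pw = define_phase_windows(ev, (0, 100), "hop", 101)
        assert pw.windows == {
            "preflight": (0, 40),
            "flight": (40, 70),
            "landing": (70, 101),
        }

    def test_toe_off_outside_cycle_rejected(self):
        ev = Events("gait", [10, 100], [5])
        with pytest.raises(EventOrderingError):
            define_phase_windows(ev, (10, 100), "gait", 101)

    @settings(deadline=None, max_examples=200)
    @given(
        to_pct=st.integers(min_value=10, max_value=90),
        n_points=st.integers(min_value=21, max_value=201),
        span_len=st.integers(min_value=50, max_value=400),
    )
    def test_gait_windows_always_partition_the_base(self, to_pct, n_points, span_len):
        to = round(to_pct / 100 * span_len)
        ev = Events("gait", [0, span_len], [to])
        pw = define_phase_windows(ev, (0, span_len), "gait", n_points)
        (s_lo, s_hi), (w_lo, w_hi) = pw.windows["stance"], pw.windows["swing"]
        assert (s_lo, w_hi) == (0, n_points)
        assert s_hi == w_lo  # no gap, no overlap
        assert s_hi - s_lo >= 2 and w_hi - w_lo >= 2


class TestTimeNormalize:
    def test_linear_ramp(self):
        out = time_normalize(np.array([0.0, 1.0, 2.0, 3.0]), (0, 3), 5)
        np.testing.assert_allclose(out, [0, 0.75, 1.5, 2.25, 3])

    def test_constant(self):
        out = time_normalize(np.full(10, 4.2), (0, 9), 101)
        np.testing.assert_allclose(out, 4.2)

    def test_sinusoid_spline_accuracy(self):
        t = np.arange(120) / 120.0
        x = np.sin(2 * np.pi * 2.0 * t)
        out = time_normalize(x, (0, 119), 101)
        exact = np.sin(2 * np.pi * 2.0 * np.linspace(0, 119 / 120, 101))
        assert np.max(np.abs(out - exact)) < 1e-3

    def test_endpoints_exact(self):
        x = np.random.default_rng(0).normal(size=50)
        out = time_normalize(x, (3, 40), 101)
        assert out[0] == x[3] and out[-1] == x[40]

    def test_short_span_rejected(self):
        with pytest.raises(InterpolationError):
            time_normalize(np.arange(10.0), (0, 2), 101)
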