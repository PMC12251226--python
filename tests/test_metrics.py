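"""AP landmark and APD90 computations on traces with known geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apdbench.metrics import (
    NoDepolarisationError,
    NoRepolarisationError,
    QCThresholds,
    TraceError,
    VoltageTrace,
    ap_markers,
    apd90,
    beat_average_apd90,
    peak_voltage,
    qc_flags,
    read_trace_csv,
    resting_potential,
    write_trace_csv,
)
from apdbench.synth import EADBump, StepOffset, SynthTraceParams, synth_trace


def square_ap(rest=-85.0, plateau=35.0, apd=300.0, cycle=1000.0, dt=0.05, t_up=5.0):
    """Idealised square AP: instantaneous edges, plateau of length ``apd``."""
    t = np.arange(0.0, cycle + dt / 2, dt)
    v = np.full(t.size, rest)
    v[(t >= t_up) & (t < t_up + apd)] = plateau
    return VoltageTrace(t, v)


class TestTraceValidation:
    def test_rejects_non_uniform_grid(self):
        with pytest.raises(TraceError):
            VoltageTrace(np.array([0.0, 1.0, 3.0]), np.zeros(3))

    def test_rejects_short_trace(self):
        with pytest.raises(TraceError):
            VoltageTrace(np.array([0.0]), np.array([1.0]))

    def test_rejects_mismatched_lengths(self):
        with pytest.raises(TraceError):
            VoltageTrace(np.arange(5.0), np.zeros(4))


class TestPeakVoltage:
    def test_constant_trace(self):
        tr = VoltageTrace(np.arange(0, 200, 0.05), np.full(4000, -85.0))
        assert peak_voltage(tr) == -85.0

    def test_matches_sorting_oracle(self, rng):
        v = np.where(rng.random(100) < 0.05, 40.0, -85.0)
        tr = VoltageTrace(np.arange(100) * 0.05, v)
        # brute force: sort and linearly interpolate the 95 % position
        s = np.sort(v)
        pos = 0.95 * (len(s) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        expected = s[lo] + (pos - lo) * (s[hi] - s[lo])
        assert peak_voltage(tr) == pytest.approx(expected, abs=1e-12)

    def test_single_outlier_suppressed(self):
        v = np.full(2000, -85.0)
        v[700] = 40.0  # impalement spike
        tr = VoltageTrace(np.arange(2000) * 0.05, v)
        assert peak_voltage(tr) == pytest.approx(-85.0, abs=1e-9)


class TestRestingPotential:
    def test_constant(self):
        tr = VoltageTrace(np.arange(0, 200, 0.05), np.full(4000, -85.0))
        assert resting_potential(tr) == pytest.approx(-85.0)

    def test_symmetric_ramp_averages_to_midpoint(self):
        # final 150 ms ramp -80 -> -90: mean is -85
        t = np.arange(0, 300, 0.05)
        v = np.full(t.size, -80.0)
        ramp = t > t[-1] - 150.0
        v[ramp] = -80.0 + (t[ramp] - (t[-1] - 150.0)) / 150.0 * -10.0
        tr = VoltageTrace(t, v)
        assert resting_potential(tr) == pytest.approx(-85.0, abs=0.01)

    def test_short_trace_rejected(self):
        tr = VoltageTrace(np.arange(0, 100, 0.05), np.zeros(2000))
        with pytest.raises(TraceError):
            resting_potential(tr)

    def test_synthetic_generator_rmp(self):
        trace, truth = synth_trace(SynthTraceParams(rmp=-86.0, noise_sd=0.0))
        assert resting_potential(trace) == pytest.approx(-86.0, abs=1e-9)


class TestAPD90:
    def test_square_pulse_geometry(self):
        tr = square_ap(apd=300.0)
        assert apd90(tr) == pytest.approx(300.0, abs=0.1)

    def test_linear_decline_closed_form(self):
        # square upstroke to +35 then linear decline to -85 over 400 ms:
        # V90 = -73 mV is crossed at 90 % of the decline -> APD90 = 360 ms
        dt = 0.05
        t = np.arange(0.0, 1000.0 + dt / 2, dt)
        v = np.full(t.size, -85.0)
        decline = (t >= 5.0) & (t < 405.0)
        v[decline] = 35.0 - (t[decline] - 5.0) / 400.0 * 120.0
        tr = VoltageTrace(t, v)
        m = ap_markers(tr)
        assert m.peak < 35.0  # percentile peak sits below the instantaneous max
        # closed form from the line equation, using the measured references
        v90 = m.peak - 0.9 * (m.peak - m.rmp)
        t_cross = 5.0 + (35.0 - v90) / 120.0 * 400.0
        assert m.apd90 == pytest.approx(t_cross - m.upstroke_time, abs=0.05)

    def test_offset_invariance(self):
        trace, _ = synth_trace(SynthTraceParams(noise_sd=0.0))
        shifted = VoltageTrace(trace.time, trace.voltage + 10.0, trace.beat_boundaries)
        assert apd90(shifted) == pytest.approx(apd90(trace), abs=1e-9)

    def test_time_shift_invariance(self):
        trace, _ = synth_trace(SynthTraceParams(noise_sd=0.0))
        shifted = VoltageTrace(trace.time + 137.0, trace.voltage, trace.beat_boundaries)
        assert apd90(shifted) == pytest.approx(apd90(trace), abs=1e-9)

    def test_no_depolarisation(self):
        tr = VoltageTrace(np.arange(0, 1000, 0.05), np.full(20000, -85.0))
        with pytest.raises(NoDepolarisationError):
            apd90(tr)

    def test_no_repolarisation(self):
        # depolarises right at the end of the record and never comes back
        t = np.arange(0.0, 300.0, 0.05)
        v = np.full(t.size, -85.0)
        late = t >= 250.0
        v[late] = -85.0 + (t[late] - 250.0) / 50.0 * 120.0
        with pytest.raises(NoRepolarisationError):
            apd90(VoltageTrace(t, v))

    def test_resampling_adequacy(self):
        trace, _ = synth_trace(SynthTraceParams(noise_sd=0.0))
        coarse = VoltageTrace(trace.time[::2], trace.voltage[::2])
        fine_beat = VoltageTrace(trace.time, trace.voltage)
        assert apd90(coarse) == pytest.approx(apd90(fine_beat), abs=0.1)

    @settings(deadline=None, max_examples=25)
    @given(
        apd=st.floats(150.0, 400.0),
        rest=st.floats(-95.0, -75.0),
        peak=st.floats(10.0, 45.0),
    )
    def test_generator_ground_truth_property(self, apd, rest, peak):
        trace, truth = synth_trace(SynthTraceParams(
            rmp=rest, peak=peak, apd90_true=apd, noise_sd=0.0))
        assert apd90(trace) == pytest.approx(apd, abs=1e-6)


class TestBeatAveraging:
    def test_identical_beats(self):
        trace, _ = synth_trace(SynthTraceParams(n_beats=30, noise_sd=0.0))
        assert beat_average_apd90(trace, 30) == pytest.approx(280.0, abs=1e-6)

    def test_jittered_beats_match_generator_mean(self):
        trace, truth = synth_trace(SynthTraceParams(
            n_beats=30, per_beat_apd_jitter_sd=2.0, noise_sd=0.0, seed=7))
        assert beat_average_apd90(trace, 30) == pytest.approx(
            truth.mean_apd90, abs=1e-5)

    def test_too_few_beats(self):
        trace, _ = synth_trace(SynthTraceParams(n_beats=5, noise_sd=0.0))
        with pytest.raises(TraceError, match="5 beats"):
            beat_average_apd90(trace, 30)


class TestQCFlags:
    def test_clean_trace(self):
        trace, _ = synth_trace(SynthTraceParams(n_beats=10, noise_sd=0.2, seed=3))
        flags = qc_flags(trace)
        assert not flags.discontinuity
        assert not flags.apd90_shift_with_discontinuity
        assert not flags.ead
        assert not flags.non_physiological

    def test_step_offset_without_apd_change(self):
        # +8 mV electrode step at beat 5: discontinuity, but APD90 retained
        trace, _ = synth_trace(SynthTraceParams(
            n_beats=10, noise_sd=0.0, artifacts=(StepOffset(beat=5, offset_mv=8.0),)))
        flags = qc_flags(trace)
        assert flags.discontinuity
        assert not flags.apd90_shift_with_discontinuity

    def test_ead_bump_flagged(self):
        trace, _ = synth_trace(SynthTraceParams(
            n_beats=6, noise_sd=0.0,
            artifacts=(EADBump(beat=3, amplitude_mv=15.0, onset_fraction=0.5),)))
        assert qc_flags(trace).ead

    def test_flag_implication_invariant(self):
        # apd90_shift_with_discontinuity implies discontinuity by construction
        trace, _ = synth_trace(SynthTraceParams(
            n_beats=8, noise_sd=0.5, seed=11,
            artifacts=(StepOffset(beat=4, offset_mv=12.0),)))
        flags = qc_flags(trace, QCThresholds())
        assert flags.discontinuity or not flags.apd90_shift_with_discontinuity


class TestTraceIO:
    def test_roundtrip(self, tmp_path):
        trace, _ = synth_trace(SynthTraceParams(n_beats=3, noise_sd=0.3, seed=5))
        f = tmp_path / "trace.csv"
        write_trace_csv(trace, f)
        back = read_trace_csv(f)
        assert np.allclose(back.time, trace.time)
        assert np.allclose(back.voltage, trace.voltage)
        assert back.beat_boundaries == trace.beat_boundaries
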