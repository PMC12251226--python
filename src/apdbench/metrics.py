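"""Action-potential landmarks and APD90 from membrane-voltage traces.

The conventions follow sharp-electrode trabecula work: the *peak* voltage is
the upper 95th percentile of the beat's samples (robust to impalement
spikes), the resting membrane potential (RMP) is the mean voltage over the
last 150 ms of the beat, and APD90 is the time from the upstroke (maximum
dV/dt) to the first downward crossing of the 90 %-repolarisation level

    V90 = peak - 0.9 * (peak - RMP),

with linear interpolation between samples.  Multi-beat records can be
averaged (study convention: 30 consecutive beats at the end of steady 1 Hz
pacing) and screened for electrode-movement discontinuities and early
after-depolarisations (EADs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "VoltageTrace", "APMarkers", "QCFlags", "QCThresholds",
    "TraceError", "NoDepolarisationError", "NoRepolarisationError",
    "peak_voltage", "resting_potential", "apd90", "ap_markers",
    "beat_average_apd90", "qc_flags", "read_trace_csv", "write_trace_csv",
]

#: Minimum peak-to-rest amplitude (mV) for a beat to count as an AP.
DEPOLARISATION_THRESHOLD_MV = 20.0

#: Window (ms) over which the resting potential is averaged.
RMP_WINDOW_MS = 150.0


class TraceError(ValueError):
    """Invalid or degenerate voltage trace."""


class NoDepolarisationError(TraceError):
    """The trace contains no action potential (peak - RMP below threshold)."""


class NoRepolarisationError(TraceError):
    """Voltage never recrosses the 90 %-repolarisation level after the peak."""


@dataclass(frozen=True)
class VoltageTrace:
    """A uniformly sampled membrane-potential record of one or more beats.

    Parameters
    ----------
    time : array of ms, strictly increasing with constant step.
    voltage : array of mV, same length as ``time``.
    beat_boundaries : optional cycle-start indices for multi-beat records.
    """

    time: np.ndarray
    voltage: np.ndarray
    beat_boundaries: tuple[int, ...] | None = None

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.voltage, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise TraceError("time and voltage must be 1-D arrays of equal length")
        if t.size < 2:
            raise TraceError("trace needs at least two samples")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise TraceError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise TraceError("time grid must be uniform")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "voltage", v)
        if self.beat_boundaries is not None:
            bb = tuple(int(i) for i in self.beat_boundaries)
            if any(b < 0 or b >= t.size for b in bb) or list(bb) != sorted(set(bb)):
                raise TraceError("beat_boundaries must be sorted unique valid indices")
            object.__setattr__(self, "beat_boundaries", bb)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def n_beats(self) -> int:
        return 1 if not self.beat_boundaries else len(self.beat_boundaries)

    def beats(self) -> Iterator["VoltageTrace"]:
        """Iterate over single-beat sub-traces."""
        if not self.beat_boundaries:
            yield self
            return
        edges = list(self.beat_boundaries) + [self.time.size]
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi - lo >= 2:
                yield VoltageTrace(self.time[lo:hi], self.voltage[lo:hi])


@dataclass(frozen=True)
class APMarkers:
    """Landmarks of a single action potential."""

    peak: float          # mV, 95th percentile of the beat's voltage
    rmp: float           # mV, mean of the last 150 ms
    v90: float           # mV, 90 %-repolarisation level
    apd90: float         # ms
    upstroke_time: float  # ms, time of maximum dV/dt


@dataclass(frozen=True)
class QCFlags:
    discontinuity: bool
    apd90_shift_with_discontinuity: bool
    ead: bool
    non_physiological: bool


@dataclass(frozen=True)
class QCThresholds:
    """Configurable screening thresholds.

    The experimental rules ("sudden" voltage changes, EADs judged by eye)
    need explicit numbers in software; these defaults are declared, not
    inferred from the recordings.
    """

    jump_mv: float = 5.0            # beat-to-beat RMP/peak jump -> discontinuity
    apd_shift_ms: float = 20.0      # APD90 jump coinciding with a discontinuity
    ead_slope_mv_per_ms: float = 0.05
    ead_sustain_ms: float = 5.0
    rmp_bounds_mv: tuple[float, float] = (-105.0, -50.0)


def peak_voltage(trace: VoltageTrace) -> float:
    """Upper 95th percentile of the beat's voltage samples."""
    return float(np.percentile(trace.voltage, 95.0))


def resting_potential(trace: VoltageTrace) -> float:
    """Mean voltage over the final 150 ms of the trace."""
    if trace.duration < RMP_WINDOW_MS:
        raise TraceError(
            f"trace spans {trace.duration:.1f} ms; "
            f">= {RMP_WINDOW_MS:.0f} ms needed for the resting potential"
        )
    t_end = trace.time[-1]
    mask = trace.time > t_end - RMP_WINDOW_MS
    return float(np.mean(trace.voltage[mask]))


def _upstroke_time(trace: VoltageTrace) -> float:
    """Time of maximum dV/dt, refined by parabolic interpolation.

    Forward differences estimate the slope at interval midpoints; a
    parabola through the maximum and its neighbours removes the grid bias
    for smooth upstrokes.  Ties (ideal square edges) resolve to the first
    maximal interval.
    """
    v = trace.voltage
    t = trace.time
    d = np.diff(v)
    i = int(np.argmax(d))
    tm = 0.5 * (t[i] + t[i + 1])
    if 0 < i < d.size - 1:
        a, b, c = d[i - 1], d[i], d[i + 1]
        denom = a - 2 * b + c
        if denom < 0 and a < b and c < b:  # strict local max: refine
            tm += 0.5 * trace.dt * (a - c) / denom
    return float(tm)


def ap_markers(trace: VoltageTrace) -> APMarkers:
    """All landmarks of a single-beat trace.

    Raises
    ------
    NoDepolarisationError
        if peak - RMP is below the 20 mV amplitude threshold.
    NoRepolarisationError
        if voltage never falls back through V90 after the peak.
    """
    peak = peak_voltage(trace)
    rmp = resting_potential(trace)
    if peak - rmp <= DEPOLARISATION_THRESHOLD_MV:
        raise NoDepolarisationError(
            f"peak - RMP = {peak - rmp:.2f} mV <= {DEPOLARISATION_THRESHOLD_MV} mV"
        )
    v90 = peak - 0.9 * (peak - rmp)
    t_up = _upstroke_time(trace)
    t_cross = _downward_crossing(trace, v90)
    return APMarkers(peak=peak, rmp=rmp, v90=v90, apd90=float(t_cross - t_up),
                     upstroke_time=t_up)


def _downward_crossing(trace: VoltageTrace, level: float) -> float:
    """First downward crossing of ``level`` after the voltage maximum."""
    v = trace.voltage
    t = trace.time
    i_peak = int(np.argmax(v))
    seg = v[i_peak:]
    below = seg < level
    if not below.any():
        raise NoRepolarisationError(f"voltage never recrosses {level:.2f} mV")
    j = int(np.argmax(below))  # first sample below the level
    if j == 0:
        return float(t[i_peak])
    k = i_peak + j
    v0, v1 = v[k - 1], v[k]
    frac = (v0 - level) / (v0 - v1)
    t_lin = float(t[k - 1] + frac * (t[k] - t[k - 1]))
    # quadratic refinement through the three samples around the crossing
    # (smooth repolarisation has curvature; linear interpolation alone
    # leaves ~1e-5 ms errors at 0.05 ms sampling)
    if 1 <= k - 1 and k + 1 < v.size:
        t0, t1_, t2 = t[k - 1], t[k], t[k + 1]
        y0, y1, y2 = v[k - 1] - level, v[k] - level, v[k + 1] - level
        # Newton's divided differences for the parabola through the points
        d01 = (y1 - y0) / (t1_ - t0)
        d12 = (y2 - y1) / (t2 - t1_)
        a = (d12 - d01) / (t2 - t0)
        # one Newton step from the linear estimate on the parabola
        p = y0 + d01 * (t_lin - t0) + a * (t_lin - t0) * (t_lin - t1_)
        dp = d01 + a * (2.0 * t_lin - t0 - t1_)
        if dp != 0.0:
            t_q = t_lin - p / dp
            if t0 <= t_q <= t2:
                # second Newton step for good measure
                p2 = y0 + d01 * (t_q - t0) + a * (t_q - t0) * (t_q - t1_)
                dp2 = d01 + a * (2.0 * t_q - t0 - t1_)
                if dp2 != 0.0:
                    t_q2 = t_q - p2 / dp2
                    if t0 <= t_q2 <= t2:
                        return float(t_q2)
                return float(t_q)
    return t_lin


def apd90(trace: VoltageTrace) -> float:
    """APD90 (ms) of a single-beat trace: upstroke to the V90 crossing."""
    return ap_markers(trace).apd90


def beat_average_apd90(trace: VoltageTrace, n_beats: int = 30) -> float:
    """Mean APD90 over the final ``n_beats`` beats of a multi-beat record."""
    beats = list(trace.beats())
    if len(beats) < n_beats:
        raise TraceError(f"trace has {len(beats)} beats; {n_beats} requested")
    return float(np.mean([apd90(b) for b in beats[-n_beats:]]))


def _beat_has_ead(beat: VoltageTrace, thresholds: QCThresholds) -> bool:
    """Positive dV/dt sustained during the 10-90 % repolarisation phase."""
    try:
        peak = peak_voltage(beat)
        rmp = resting_potential(beat)
    except TraceError:
        return False
    amp = peak - rmp
    if amp <= DEPOLARISATION_THRESHOLD_MV:
        return False
    v10 = peak - 0.1 * amp
    v90 = peak - 0.9 * amp
    v = beat.voltage
    i_peak = int(np.argmax(v))
    in_window = np.zeros(v.size, dtype=bool)
    in_window[i_peak:] = (v[i_peak:] < v10) & (v[i_peak:] > v90)
    # stop the window at the first v90 crossing (ignore diastole)
    past = np.nonzero(v[i_peak:] <= v90)[0]
    if past.size:
        in_window[i_peak + past[0]:] = False
    slope = np.gradient(v, beat.time)
    rising = in_window & (slope > thresholds.ead_slope_mv_per_ms)
    need = max(1, int(round(thresholds.ead_sustain_ms / beat.dt)))
    run = 0
    for r in rising:
        run = run + 1 if r else 0
        if run >= need:
            return True
    return False


def qc_flags(trace: VoltageTrace, thresholds: QCThresholds | None = None) -> QCFlags:
    """Screen a multi-beat record for artefacts.

    ``discontinuity``: a beat-to-beat jump in RMP or peak voltage above
    ``jump_mv`` (electrode movement).  ``apd90_shift_with_discontinuity``:
    such a jump coinciding with an APD90 change above ``apd_shift_ms`` —
    the condition under which the experimental pipeline discards the data.
    ``ead``: sustained positive dV/dt during the repolarisation phase.
    ``non_physiological``: a beat with no depolarisation / no
    repolarisation, or RMP outside plausible bounds.
    """
    th = thresholds or QCThresholds()
    beats = list(trace.beats())
    if len(beats) < 2:
        raise TraceError("qc_flags needs a multi-beat trace with boundaries")

    rmps, peaks, apds, broken = [], [], [], False
    for b in beats:
        try:
            m = ap_markers(b)
            rmps.append(m.rmp)
            peaks.append(m.peak)
            apds.append(m.apd90)
        except TraceError:
            broken = True
            rmps.append(np.nan)
            peaks.append(np.nan)
            apds.append(np.nan)

    rmps_a, peaks_a, apds_a = map(np.asarray, (rmps, peaks, apds))
    d_rmp = np.abs(np.diff(rmps_a))
    d_peak = np.abs(np.diff(peaks_a))
    d_apd = np.abs(np.diff(apds_a))
    jump = (d_rmp > th.jump_mv) | (d_peak > th.jump_mv)
    discontinuity = bool(np.nansum(jump) > 0)
    shift = bool(np.nansum(jump & (d_apd > th.apd_shift_ms)) > 0)

    ead = any(_beat_has_ead(b, th) for b in beats)

    lo, hi = th.rmp_bounds_mv
    rmp_bad = bool(np.any((rmps_a < lo) | (rmps_a > hi)))
    non_phys = broken or rmp_bad

    return QCFlags(
        discontinuity=discontinuity,
        apd90_shift_with_discontinuity=shift and discontinuity,
        ead=ead,
        non_physiological=non_phys,
    )


def read_trace_csv(path) -> VoltageTrace:
    """Read a trace from CSV with columns time_ms, voltage_mV[, beat_index]."""
    import pandas as pd

    df = pd.read_csv(path)
    if "time_ms" not in df or "voltage_mV" not in df:
        raise TraceError("trace CSV needs time_ms and voltage_mV columns")
    bb = None
    if "beat_index" in df:
        idx = df["beat_index"].to_numpy()
        starts = np.nonzero(np.r_[True, np.diff(idx) != 0])[0]
        bb = tuple(int(i) for i in starts)
    return VoltageTrace(df["time_ms"].to_numpy(float), df["voltage_mV"].to_numpy(float), bb)


def write_trace_csv(trace: VoltageTrace, path) -> None:
    import pandas as pd

    data = {"time_ms": trace.time, "voltage_mV": trace.voltage}
    if trace.beat_boundaries:
        idx = np.zeros(trace.time.size, dtype=int)
        for k, b in enumerate(trace.beat_boundaries):
            idx[b:] = k
        data["beat_index"] = idx
    pd.DataFrame(data).to_csv(path, index=False)
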