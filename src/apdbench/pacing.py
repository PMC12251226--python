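"""1 Hz pacing protocol: drive a model to steady state and record one AP.

Protocol (matching the trabecula experiments' simulation counterpart):
1500 pre-pacing cycles at 1 Hz, then the next AP recorded at 0.05 ms
resolution.  Drug effects enter purely as conductance scaling of IKr
(g_Kr x (1 - ikr_block)) and ICaL (g_CaL x (1 - ical_block)).

Integration uses each model's compiled hybrid Rush-Larsen / forward-Euler
kernel on a fixed per-phase step schedule; see docs/methods.md for the
numerical-accuracy guards (step halving, cross-check against SciPy's
adaptive integrators).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:
    from apdbench.models.core import ModelDefinition, SolverSettings

__all__ = [
    "BlockSpec", "PacingResult", "SolverFailure",
    "apply_block", "pace_to_steady", "record_beat", "simulate_delta_apd90",
    "clear_baseline_cache",
]


class SolverFailure(RuntimeError):
    """Non-finite state during pacing; carries the pace index and a snapshot."""

    def __init__(self, message: str, pace_index: int, state: np.ndarray):
        super().__init__(message)
        self.pace_index = pace_index
        self.state = state


@dataclass(frozen=True)
class BlockSpec:
    """Fractional IKr / ICaL conductance block; (0, 0) is the no-drug case."""

    ikr_block: float = 0.0
    ical_block: float = 0.0

    def __post_init__(self):
        for name, v in (("ikr_block", self.ikr_block), ("ical_block", self.ical_block)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {v}")

    @property
    def is_identity(self) -> bool:
        return self.ikr_block == 0.0 and self.ical_block == 0.0


@dataclass(frozen=True)
class PacingResult:
    trace: "VoltageTrace"  # type: ignore[name-defined]  # apdbench.metrics.VoltageTrace
    steady_state: np.ndarray
    convergence_metric: float  # |APD90(last pace) - APD90(previous pace)| in ms


def apply_block(model: "ModelDefinition", block: BlockSpec) -> "ModelDefinition":
    """Scale g_Kr by (1 - ikr_block) and g_CaL by (1 - ical_block)."""
    if block.is_identity:
        return model.copy()
    out = model.copy()
    out.parameters[model.block_targets["ikr"]] *= 1.0 - block.ikr_block
    out.parameters[model.block_targets["ical"]] *= 1.0 - block.ical_block
    return out


def _solver_arrays(model, cycle_length: float, dt_scale: float):
    return model.solver.arrays(cycle_length, scale=dt_scale)


def pace_to_steady(
    model: "ModelDefinition",
    n_paces: int = 1500,
    cycle_length: float = 1000.0,
    dt_scale: float = 1.0,
    _chunk: int = 100,
) -> np.ndarray:
    """State vector after ``n_paces`` cycles at ``cycle_length`` ms.

    Deterministic for fixed inputs.  Paces run in chunks with a finiteness
    check so a blow-up reports the offending pace index.
    """
    if n_paces < 1:
        raise ValueError("n_paces must be >= 1")
    stim = model.stimulus
    if cycle_length <= stim.duration:
        raise ValueError("cycle_length must exceed the stimulus duration")
    bounds, dts, _ = _solver_arrays(model, cycle_length, dt_scale)
    y = model.initial_state.copy()
    p = model.param_vector()
    done = 0
    while done < n_paces:
        n = min(_chunk, n_paces - done)
        try:
            model.kernel.pace(y, p, n, cycle_length, stim.amplitude,
                              stim.duration, bounds, dts)
        except (ZeroDivisionError, OverflowError) as exc:
            raise SolverFailure(
                f"arithmetic blow-up within paces {done + 1}..{done + n} "
                f"of {model.name}: {exc}", pace_index=done + n, state=y,
            ) from exc
        done += n
        if not np.all(np.isfinite(y)):
            raise SolverFailure(
                f"non-finite state within paces {done - n + 1}..{done} of {model.name}",
                pace_index=done, state=y,
            )
    return y


def record_beat(
    model: "ModelDefinition",
    state: np.ndarray,
    dt_out: float = 0.05,
    cycle_length: float = 1000.0,
    dt_scale: float = 1.0,
):
    """Record one paced AP from ``state`` on a uniform grid (both endpoints).

    Returns the trace; ``state`` is not modified.  The grid has
    ``cycle_length / dt_out + 1`` samples.
    """
    from apdbench.metrics import VoltageTrace

    stim = model.stimulus
    bounds, _, subs = _solver_arrays(model, cycle_length, dt_scale)
    y = np.array(state, dtype=np.float64).copy()
    v = model.kernel.record(
        y, model.param_vector(), cycle_length, stim.amplitude, stim.duration,
        dt_out, bounds, subs,
    )
    if not np.all(np.isfinite(v)):
        raise SolverFailure(f"non-finite voltage while recording {model.name}",
                            pace_index=-1, state=y)
    t = np.arange(v.size) * dt_out
    return VoltageTrace(t, v)


def pace_and_record(
    model: "ModelDefinition",
    n_paces: int = 1500,
    cycle_length: float = 1000.0,
    dt_out: float = 0.05,
    dt_scale: float = 1.0,
) -> PacingResult:
    """Full protocol: pre-pace, then record the next AP.

    The convergence metric compares the APD90 of the recorded AP with that
    of the pace before it (recorded the same way).
    """
    from apdbench.metrics import apd90

    if n_paces < 2:
        raise ValueError("need >= 2 paces for a convergence metric")
    state = pace_to_steady(model, n_paces - 1, cycle_length, dt_scale)
    prev = record_beat(model, state, dt_out, cycle_length, dt_scale)
    # recording advanced a copy; advance the real state one pace
    state = _advance(model, state, 1, cycle_length, dt_scale)
    trace = record_beat(model, state, dt_out, cycle_length, dt_scale)
    try:
        conv = abs(apd90(trace) - apd90(prev))
    except Exception:
        conv = float("nan")
    return PacingResult(trace=trace, steady_state=state, convergence_metric=conv)


def _advance(model, state, n_paces, cycle_length, dt_scale):
    stim = model.stimulus
    bounds, dts, _ = _solver_arrays(model, cycle_length, dt_scale)
    y = np.array(state, dtype=np.float64).copy()
    model.kernel.pace(y, model.param_vector(), n_paces, cycle_length,
                      stim.amplitude, stim.duration, bounds, dts)
    return y


# ---------------------------------------------------------------------------
# baseline cache: (model name, parameter digest, protocol) -> (state, APD90)

_BASELINE_CACHE: dict = {}


def _cache_key(model, n_paces, cycle_length, dt_scale):
    digest = hashlib.sha256(model.param_vector().tobytes()).hexdigest()[:16]
    return (model.name, digest, n_paces, float(cycle_length), float(dt_scale))


def clear_baseline_cache() -> None:
    _BASELINE_CACHE.clear()


def _steady_apd90(model, n_paces, cycle_length, dt_scale, cache=True):
    """(state after pre-pacing, APD90 of the next AP) with validity checks.

    The AP after the recorded one is also measured.  The outcome is NaN
    — a flagged repolarisation-failure result rather than an arbitrary
    degenerate beat — if either beat fails to produce a measurable AP,
    if the two consecutive APD90s differ by more than 30 ms (2:1
    repolarisation failure under near-complete IKr block; stable
    micro-alternans of a few ms is a valid steady response and is not
    flagged), or if the diastolic potential sits outside physiological
    bounds (e.g. ORd at 100 % IKr block settles at a permanently
    depolarised membrane potential).
    """
    from apdbench.metrics import (NoDepolarisationError, NoRepolarisationError,
                                  QCThresholds, ap_markers)

    key = _cache_key(model, n_paces, cycle_length, dt_scale)
    if cache and key in _BASELINE_CACHE:
        return _BASELINE_CACHE[key]
    state = pace_to_steady(model, n_paces, cycle_length, dt_scale)
    trace = record_beat(model, state, 0.05, cycle_length, dt_scale)
    next_state = _advance(model, state, 1, cycle_length, dt_scale)
    check = record_beat(model, next_state, 0.05, cycle_length, dt_scale)
    lo, hi = QCThresholds().rmp_bounds_mv
    try:
        m1 = ap_markers(trace)
        m2 = ap_markers(check)
        value = m1.apd90
        if abs(m2.apd90 - value) > 30.0 or not (lo < m1.rmp < hi and lo < m2.rmp < hi):
            value = float("nan")
    except (NoRepolarisationError, NoDepolarisationError):
        value = float("nan")
    if cache:
        _BASELINE_CACHE[key] = (state, value)
    return state, value


def simulate_delta_apd90(
    model: "ModelDefinition",
    block: BlockSpec,
    n_paces: int = 1500,
    cycle_length: float = 1000.0,
    dt_scale: float = 1.0,
) -> float:
    """APD90(blocked, steady) - APD90(unblocked, steady) in ms.

    The unblocked baseline is simulated once per model configuration and
    cached.  A blocked AP that fails to repolarise within the cycle yields
    NaN (a flagged no-repolarisation outcome, not an exception); block
    (0, 0) returns exactly 0.
    """
    if block.is_identity:
        return 0.0
    _, base = _steady_apd90(model, n_paces, cycle_length, dt_scale)
    if np.isnan(base):
        return float("nan")
    blocked = apply_block(model, block)
    _, apd = _steady_apd90(blocked, n_paces, cycle_length, dt_scale)
    return float(apd - base)
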