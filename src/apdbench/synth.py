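"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators make every pipeline stage testable without external data:

``synth_trace``
    Parametric multi-beat AP voltage traces with *known* landmarks.  Each
    beat is piecewise smooth — rest, half-cosine upstroke, flat plateau,
    smoothstep (cubic) repolarisation, rest — constructed so that the
    analytic V90 crossing falls exactly ``apd90_true`` after the point of
    maximum dV/dt.  Gaussian noise, per-beat APD jitter, baseline step
    artefacts (electrode movement) and EAD bumps are applied on top, so
    the ground truth stays known.

``synth_study``
    Synthetic trabecula studies: per-condition ΔAPD90 samples drawn
    around a known ground-truth inhibition-response surface with a stated
    per-trabecula noise SD.  Records carry the *sampled* mean and SEM
    (sd/sqrt(n)), mirroring how the experimental summaries are formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from apdbench.benchmark import ExperimentalRecord, SurfaceFit, evaluate_surface
from apdbench.metrics import VoltageTrace
from apdbench.pharmacology import DrugCondition, DrugEntry, drug_block

__all__ = [
    "StepOffset", "EADBump", "SynthTraceParams", "SynthTraceTruth",
    "SynthStudyParams", "SynthStudyTruth", "synth_trace", "synth_study",
]

# u where the descending smoothstep 3u^2 - 2u^3 has covered 90 % of the fall
_U90 = brentq(lambda u: 3 * u ** 2 - 2 * u ** 3 - 0.9, 0.5, 1.0, xtol=1e-15)


@dataclass(frozen=True)
class StepOffset:
    """Baseline discontinuity: constant voltage offset from ``beat`` onward."""

    beat: int
    offset_mv: float


@dataclass(frozen=True)
class EADBump:
    """Secondary depolarisation during repolarisation of one beat.

    ``onset_fraction`` places the bump centre within the repolarisation
    phase (0 = plateau end, 1 = repolarisation end).
    """

    beat: int
    amplitude_mv: float
    onset_fraction: float = 0.5
    width_ms: float = 6.0  # Gaussian sigma; must out-pace the base fall


@dataclass(frozen=True)
class SynthTraceParams:
    rmp: float = -86.0               # mV
    peak: float = 35.0               # mV
    apd90_true: float = 280.0        # ms
    upstroke_ms: float = 1.0
    plateau_fraction: float = 0.5    # of APD90 spent at the flat plateau
    n_beats: int = 1
    cycle_length: float = 1000.0     # ms
    noise_sd: float = 0.0            # mV
    per_beat_apd_jitter_sd: float = 0.0  # ms
    artifacts: tuple = ()
    seed: int = 0
    dt: float = 0.05                 # ms
    upstroke_start: float = 5.0      # ms into each cycle

    def __post_init__(self):
        if not self.rmp < self.peak:
            raise ValueError("rmp must be below peak")
        if not 0 < self.apd90_true < self.cycle_length:
            raise ValueError("apd90_true must lie within the cycle")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.plateau_fraction < 1:
            raise ValueError("plateau_fraction must be in (0, 1)")
        # repolarisation must finish before the RMP window of the beat
        t_rep_end = (self.upstroke_start + self.upstroke_ms / 2
                     + self.plateau_fraction * self.apd90_true
                     + (1 - self.plateau_fraction) * self.apd90_true / _U90)
        if t_rep_end > self.cycle_length - 150.0:
            raise ValueError("AP does not finish 150 ms before the cycle end")


@dataclass(frozen=True)
class SynthTraceTruth:
    """Generator bookkeeping for one synthetic trace."""

    rmp: float
    peak: float
    apd90_per_beat: tuple[float, ...]
    upstroke_time_per_beat: tuple[float, ...]  # time of max dV/dt, absolute ms

    @property
    def mean_apd90(self) -> float:
        return float(np.mean(self.apd90_per_beat))


def _one_beat(t: np.ndarray, pr: SynthTraceParams, apd: float) -> np.ndarray:
    """Noise-free beat on local time grid ``t`` (0 = cycle start)."""
    v = np.full(t.size, pr.rmp)
    tu = pr.upstroke_start
    up = pr.upstroke_ms
    amp = pr.peak - pr.rmp
    t_ref = tu + up / 2            # max-slope instant = APD start
    t_flat_end = t_ref + pr.plateau_fraction * apd
    t_rep = (1 - pr.plateau_fraction) * apd / _U90  # repolarisation span

    rising = (t >= tu) & (t < tu + up)
    v[rising] = pr.rmp + amp * 0.5 * (1 - np.cos(np.pi * (t[rising] - tu) / up))
    v[(t >= tu + up) & (t < t_flat_end)] = pr.peak
    rep = (t >= t_flat_end) & (t < t_flat_end + t_rep)
    u = (t[rep] - t_flat_end) / t_rep
    v[rep] = pr.peak - amp * (3 * u ** 2 - 2 * u ** 3)
    return v


def synth_trace(params: SynthTraceParams) -> tuple[VoltageTrace, SynthTraceTruth]:
    """Generate a multi-beat synthetic trace plus its ground-truth record."""
    pr = params
    rng = np.random.default_rng(pr.seed)
    n_per_beat = int(round(pr.cycle_length / pr.dt))
    jitter = (rng.normal(0.0, pr.per_beat_apd_jitter_sd, pr.n_beats)
              if pr.per_beat_apd_jitter_sd > 0 else np.zeros(pr.n_beats))
    t_local = np.arange(n_per_beat) * pr.dt

    segments, apds, upstrokes = [], [], []
    for b in range(pr.n_beats):
        apd = pr.apd90_true + jitter[b]
        segments.append(_one_beat(t_local, pr, apd))
        apds.append(apd)
        upstrokes.append(b * pr.cycle_length + pr.upstroke_start + pr.upstroke_ms / 2)
    v = np.concatenate(segments)
    t = np.arange(v.size) * pr.dt

    for art in pr.artifacts:
        if isinstance(art, StepOffset):
            v[art.beat * n_per_beat:] += art.offset_mv
        elif isinstance(art, EADBump):
            pr_b = apds[art.beat]
            t_ref = art.beat * pr.cycle_length + pr.upstroke_start + pr.upstroke_ms / 2
            t_flat_end = t_ref + pr.plateau_fraction * pr_b
            t_rep = (1 - pr.plateau_fraction) * pr_b / _U90
            centre = t_flat_end + art.onset_fraction * t_rep
            v += art.amplitude_mv * np.exp(-0.5 * ((t - centre) / art.width_ms) ** 2)
        else:
            raise TypeError(f"unknown artifact {art!r}")

    if pr.noise_sd > 0:
        v = v + rng.normal(0.0, pr.noise_sd, v.size)

    boundaries = tuple(b * n_per_beat for b in range(pr.n_beats))
    trace = VoltageTrace(t, v, beat_boundaries=boundaries)
    truth = SynthTraceTruth(
        rmp=pr.rmp, peak=pr.peak,
        apd90_per_beat=tuple(apds),
        upstroke_time_per_beat=tuple(upstrokes),
    )
    return trace, truth


# ---------------------------------------------------------------------------
# synthetic trabecula studies


@dataclass(frozen=True)
class SynthStudyParams:
    truth_surface: SurfaceFit
    conditions: tuple[DrugCondition, ...]
    drug_panel: Mapping[tuple[str, str], DrugEntry] | None = None  # None -> packaged table 3
    dataset: Literal["CiPA", "Pharm"] = "Pharm"
    n_trabeculae: int = 5
    per_trabecula_sd: float = 15.0   # ms
    baseline_mean: float = 320.0     # ms
    baseline_sd: float = 50.0        # ms
    seed: int = 0

    def __post_init__(self):
        if self.per_trabecula_sd <= 0:
            raise ValueError("per_trabecula_sd must be > 0")
        if self.n_trabeculae < 2:
            raise ValueError("need n >= 2 trabeculae for a SEM")


@dataclass(frozen=True)
class SynthStudyTruth:
    """Ground truth per condition: block fractions and surface ΔAPD90."""

    blocks: tuple[tuple[float, float], ...]
    true_delta_apd90: tuple[float, ...]


def synth_study(
    params: SynthStudyParams,
) -> tuple[tuple[ExperimentalRecord, ...], SynthStudyTruth]:
    """Sample a synthetic trabecula study around the truth surface.

    For each condition, the true ΔAPD90 is the surface evaluated at the
    condition's (IKr, ICaL) block; per-trabecula responses are Normal
    around it and summarised into an :class:`ExperimentalRecord` with the
    *observed* mean and SEM, as the experimental pipeline would.
    """
    pr = params
    rng = np.random.default_rng(pr.seed)
    records, blocks, truths = [], [], []
    for cond in pr.conditions:
        blk = drug_block(cond, pr.dataset, table=pr.drug_panel)
        truth = float(evaluate_surface(pr.truth_surface, blk.ikr_block, blk.ical_block))
        samples = rng.normal(truth, pr.per_trabecula_sd, pr.n_trabeculae)
        sem = float(np.std(samples, ddof=1) / np.sqrt(pr.n_trabeculae))
        records.append(ExperimentalRecord(
            drug=cond.drug,
            concentration=cond.concentration,
            mean_delta_apd90=float(np.mean(samples)),
            sem=sem,
            n_trabeculae=pr.n_trabeculae,
            mean_baseline_apd90=pr.baseline_mean,
            baseline_sd=pr.baseline_sd,
        ))
        blocks.append((blk.ikr_block, blk.ical_block))
        truths.append(truth)
    return tuple(records), SynthStudyTruth(blocks=tuple(blocks),
                                           true_delta_apd90=tuple(truths))
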