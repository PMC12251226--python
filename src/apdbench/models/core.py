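"""Domain types for the AP model library.

A :class:`ModelDefinition` is a parameterised ODE system: named states, a
named parameter set (maximal conductances / permeabilities and external
ion concentrations among them), a right-hand side, and a stimulus
definition.  Drug block and model variants act on it purely through
conductance scaling, so the pacing engine never needs model-specific code
beyond the compiled kernel each model ships.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "StimulusSpec", "ModelDefinition", "ConductanceScaling", "ModelKernel",
    "ModelNotRegisteredError", "ModelNotImplementedError", "UnknownConductanceError",
    "apply_conductance_scaling", "set_external_concentrations",
]


class ModelNotRegisteredError(KeyError):
    """Requested name is not in the model registry."""


class ModelNotImplementedError(NotImplementedError):
    """The model is registered (extended tier) but has no runnable dynamics."""


class UnknownConductanceError(KeyError):
    """A scaling factor names a parameter that is not a conductance of the model."""


@dataclass(frozen=True)
class StimulusSpec:
    """External pacing stimulus, kept as published for each model."""

    amplitude: float                       # A/F; negative = depolarising (inward)
    duration: float                        # ms
    offset_within_cycle: float = 0.0       # ms from cycle start
    carried_ion: Literal["K", "none"] = "K"

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.amplitude == 0:
            raise ValueError("stimulus amplitude must be non-zero")


@dataclass(frozen=True)
class SolverSettings:
    """Fixed-step integration schedule (ms) for one pacing cycle.

    The cycle is split into phases (upstroke+stimulus window, plateau,
    diastole) with one step size each; hybrid Rush-Larsen/forward-Euler
    stepping is applied inside the model kernels.  ``scale`` divides every
    step size, for step-halving robustness checks.
    """

    phase_bounds: tuple[float, ...]   # e.g. (0, 5, 400) — last phase runs to the cycle end
    phase_dts: tuple[float, ...]
    record_substeps: tuple[int, ...]  # kernel sub-steps per 0.05 ms output sample, per phase

    def arrays(self, cycle_length: float, scale: float = 1.0):
        bounds = np.asarray(list(self.phase_bounds) + [cycle_length], dtype=np.float64)
        dts = np.asarray(self.phase_dts, dtype=np.float64) * scale
        subs = np.asarray(
            [max(1, int(round(s / scale))) for s in self.record_substeps], dtype=np.int64
        )
        if bounds.size != dts.size + 1:
            raise ValueError("need one step size per phase")
        return bounds, dts, subs


@dataclass(frozen=True)
class ModelKernel:
    """Compiled numerics of one model: single step, pacing loop, recorder, RHS."""

    step: Callable
    pace: Callable
    record: Callable
    rhs: Callable  # rhs(y, p, istim) -> dy


@dataclass
class ModelDefinition:
    """A human ventricular AP model as a parameterised ODE system."""

    name: str
    state_names: tuple[str, ...]
    initial_state: np.ndarray
    parameters: dict[str, float]
    param_names: tuple[str, ...]
    conductances: tuple[str, ...]          # parameters that scale linearly with channel density
    block_targets: Mapping[str, str]       # {"ikr": <param>, "ical": <param>}
    concentration_params: Mapping[str, str]  # {"Ko": <param>, "Nao": ..., "Cao": ...}
    stimulus: StimulusSpec
    kernel: ModelKernel
    solver: SolverSettings
    cell_type: Literal["endocardial", "epicardial", "mid"] = "endocardial"
    tier: Literal["required", "extended"] = "required"
    citation: str = ""

    def __post_init__(self):
        self.initial_state = np.array(self.initial_state, dtype=np.float64)
        if len(self.state_names) != self.initial_state.size:
            raise ValueError("initial_state length must equal state_names length")
        for g in self.conductances:
            if self.parameters[g] < 0:
                raise ValueError(f"maximal conductance {g} must be >= 0")
        missing = [n for n in self.param_names if n not in self.parameters]
        if missing:
            raise ValueError(f"parameters missing: {missing}")

    def param_vector(self) -> np.ndarray:
        return np.array([self.parameters[n] for n in self.param_names], dtype=np.float64)

    def rhs(self, t: float, y: np.ndarray, istim: float = 0.0) -> np.ndarray:
        """State derivative at (t, y); autonomous apart from the stimulus."""
        return self.kernel.rhs(np.asarray(y, dtype=np.float64), self.param_vector(), istim)

    def copy(self) -> "ModelDefinition":
        return replace(
            self,
            parameters=dict(self.parameters),
            initial_state=self.initial_state.copy(),
        )


@dataclass(frozen=True)
class ConductanceScaling:
    """Named multiplicative factors on a base model's conductances."""

    target: str
    factors: Mapping[str, float] = field(default_factory=dict)
    added_components: tuple[str, ...] = ()

    def __post_init__(self):
        for k, v in self.factors.items():
            if v < 0:
                raise ValueError(f"scaling factor {k} must be >= 0")


def apply_conductance_scaling(
    base: ModelDefinition, scaling: ConductanceScaling
) -> ModelDefinition:
    """Return a copy of ``base`` with conductances multiplied by the factors.

    Every factor must name an existing conductance of the base model.
    Added components (e.g. borrowing another model's INaL formulation)
    change the equation structure, which the compiled kernels do not
    support; requesting one raises :class:`ModelNotImplementedError`.
    """
    if scaling.added_components:
        raise ModelNotImplementedError(
            f"added components {list(scaling.added_components)} are not supported: "
            "structural model extensions are not implemented"
        )
    unknown = [k for k in scaling.factors if k not in base.conductances]
    if unknown:
        raise UnknownConductanceError(
            f"unknown conductance(s) {unknown}; scalable parameters of "
            f"{base.name}: {sorted(base.conductances)}"
        )
    out = base.copy()
    for k, v in scaling.factors.items():
        out.parameters[k] = out.parameters[k] * v
    return out


def set_external_concentrations(
    model: ModelDefinition, ko: float, nao: float, cao: float
) -> ModelDefinition:
    """Copy of ``model`` with external K+/Na+/Ca2+ set (mM).

    The study's experimental bath used 4 / 148.35 / 1.8 mM.
    """
    if min(ko, nao, cao) <= 0:
        raise ValueError("external concentrations must be positive")
    out = model.copy()
    out.parameters[model.concentration_params["Ko"]] = float(ko)
    out.parameters[model.concentration_params["Nao"]] = float(nao)
    out.parameters[model.concentration_params["Cao"]] = float(cao)
    return out
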