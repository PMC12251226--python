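"""Registry of the study's 11 human ventricular AP models and variants.

Three models are shipped as runnable native implementations (required
tier): TP (ten Tusscher-Panfilov 2006), GPB (Grandi-Pasqualini-Bers 2010)
and ORd (O'Hara-Rudy 2011), each transcribed from its publication.  The
remaining roster entries (the Mann et al. rescalings TP-M/GPB-M/ORd-M,
the Krogh-Madsen ORd-KM rescaling, BPS, ToR-ORd, ORd-CiPA, TNNP) are
registered as extended tier: their published parameterisations are not
bundled, and requesting them raises an explicit not-implemented error —
never a silent fallback.  Printed reference constants for the roster
(e.g. each model's IKs maximal conductance where reported) live in the
packaged model-roster table (see :mod:`apdbench.datasets`).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

from apdbench.models.core import (
    ModelDefinition,
    ModelKernel,
    ModelNotImplementedError,
    ModelNotRegisteredError,
    SolverSettings,
    StimulusSpec,
)

__all__ = ["get_model", "list_models", "required_models", "load_manifest",
           "parameter_checksum"]


def _from_module(mod) -> ModelDefinition:
    return ModelDefinition(
        name=mod.NAME,
        state_names=mod.STATE_NAMES,
        initial_state=mod.INITIAL_STATE.copy(),
        parameters=dict(mod.DEFAULT_PARAMS),
        param_names=mod.PARAM_NAMES,
        conductances=mod.CONDUCTANCES,
        block_targets=dict(mod.BLOCK_TARGETS),
        concentration_params=dict(mod.CONC_PARAMS),
        stimulus=StimulusSpec(
            amplitude=mod.STIM_AMPLITUDE,
            duration=mod.STIM_DURATION,
            carried_ion=mod.STIM_CARRIED,
        ),
        kernel=ModelKernel(step=mod.step, pace=mod.PACE, record=mod.RECORD, rhs=mod.rhs),
        solver=SolverSettings(
            phase_bounds=mod.PHASE_BOUNDS,
            phase_dts=mod.PHASE_DTS,
            record_substeps=mod.RECORD_SUBSTEPS,
        ),
        cell_type=mod.CELL_TYPE,
        tier="required",
        citation=mod.CITATION,
    )


def _build_tp() -> ModelDefinition:
    from apdbench.models import tp06

    return _from_module(tp06)


def _build_ord() -> ModelDefinition:
    from apdbench.models import ord2011

    return _from_module(ord2011)


def _build_gpb() -> ModelDefinition:
    from apdbench.models import gpb2010

    return _from_module(gpb2010)


_REQUIRED = {"TP": _build_tp, "ORd": _build_ord, "GPB": _build_gpb}

_EXTENDED_REASON = {
    "TP-M": "Mann et al. (2016) conductance rescaling + ORd INaL component not bundled",
    "GPB-M": "Mann et al. (2016) conductance rescaling + ORd INaL component not bundled",
    "ORd-M": "Mann et al. (2016) conductance rescaling not bundled",
    "ORd-KM": "Krogh-Madsen et al. (2017) conductance rescaling not bundled",
    "BPS": "Bartolucci et al. (2020) equation set not bundled",
    "ToR-ORd": "Tomek et al. (2019) equation set not bundled",
    "ORd-CiPA": "Dutta et al. (2017) Markov IKr component not bundled",
    "TNNP": "ten Tusscher et al. (2004) equation set not bundled",
}

#: Full study roster, in the roster table's order.
ALL_MODELS = ("BPS", "GPB", "GPB-M", "ORd", "ORd-CiPA", "ORd-KM", "ORd-M",
              "ToR-ORd", "TNNP", "TP", "TP-M")


def required_models() -> tuple[str, ...]:
    return tuple(sorted(_REQUIRED))


def list_models() -> tuple[str, ...]:
    return ALL_MODELS


def get_model(name: str) -> ModelDefinition:
    """A fresh, independent :class:`ModelDefinition` for ``name``.

    Raises :class:`ModelNotRegisteredError` for unknown names and
    :class:`ModelNotImplementedError` for extended-tier roster entries
    whose dynamics are not bundled.
    """
    if name in _REQUIRED:
        return _REQUIRED[name]()
    if name in _EXTENDED_REASON:
        raise ModelNotImplementedError(
            f"model {name!r} is registered as extended tier but not implemented: "
            f"{_EXTENDED_REASON[name]}"
        )
    raise ModelNotRegisteredError(f"model not registered: {name!r}")


def parameter_checksum(model: ModelDefinition) -> str:
    """Stable digest of the parameter table, for provenance tracking."""
    text = ";".join(f"{k}={model.parameters[k]!r}" for k in sorted(model.parameters))
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def load_manifest() -> dict:
    """The packaged registry manifest (tiers, citations, parameter checksums)."""
    with resources.files("apdbench.data").joinpath("models.json").open("r") as fh:
        return json.load(fh)
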