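"""Model registry, conductance scaling, concentrations, CellML import."""

import numpy as np
import pytest

from apdbench.models import (
    ALL_MODELS,
    ConductanceScaling,
    ModelNotImplementedError,
    ModelNotRegisteredError,
    StimulusSpec,
    UnknownConductanceError,
    apply_conductance_scaling,
    get_model,
    load_manifest,
    parameter_checksum,
    required_models,
    set_external_concentrations,
)
from apdbench.models.cellml import CellMLParseError, load_cellml

REQUIRED = required_models()


class TestRegistry:
    def test_roster_is_complete(self):
        assert len(ALL_MODELS) == 11
        for name in ("TP", "GPB", "ORd", "BPS", "ToR-ORd", "TNNP", "TP-M"):
            assert name in ALL_MODELS

    def test_unknown_model(self):
        with pytest.raises(ModelNotRegisteredError, match="not registered"):
            get_model("HodgkinHuxley1952")

    @pytest.mark.parametrize("name", ["TP-M", "GPB-M", "ORd-M", "ORd-KM",
                                      "BPS", "ToR-ORd", "ORd-CiPA", "TNNP"])
    def test_extended_tier_explicit_not_implemented(self, name):
        with pytest.raises(ModelNotImplementedError, match="not implemented"):
            get_model(name)

    @pytest.mark.parametrize("name", REQUIRED)
    def test_repeated_calls_independent_copies(self, name):
        a, b = get_model(name), get_model(name)
        a.parameters[a.block_targets["ikr"]] = 0.0
        assert b.parameters[b.block_targets["ikr"]] > 0.0

    @pytest.mark.parametrize("name", REQUIRED)
    def test_invariants(self, name):
        m = get_model(name)
        assert len(m.state_names) == m.initial_state.size
        assert m.cell_type == "endocardial"
        assert all(m.parameters[g] >= 0 for g in m.conductances)
        assert m.stimulus.duration > 0 and m.stimulus.amplitude != 0

    @pytest.mark.parametrize("name", REQUIRED)
    def test_rhs_finite_and_quiescent_at_initial_state(self, name):
        m = get_model(name)
        dy = m.rhs(0.0, m.initial_state)
        assert np.all(np.isfinite(dy))
        assert abs(dy[0]) < 0.1  # resting dV/dt below 0.1 mV/ms

    def test_manifest_checksums_match_registry(self):
        manifest = load_manifest()
        entries = {e["name"]: e for e in manifest["models"]}
        assert set(entries) == set(ALL_MODELS)
        for name in REQUIRED:
            assert entries[name]["tier"] == "required"
            assert entries[name]["parameter_checksum"] == \
                parameter_checksum(get_model(name))


class TestPrintedConductances:
    def test_tp_gks(self, tp):
        assert tp.parameters["g_Ks"] == pytest.approx(0.392)

    def test_roster_reference_gks(self, tables):
        gks = {r.model: r.gks_ms_per_uf for r in tables.table4}
        assert gks["TP"] == pytest.approx(0.392)
        assert gks["ToR-ORd"] == pytest.approx(0.0011)
        assert gks["ORd-M"] == pytest.approx(0.0196)

    def test_native_models_agree_with_roster(self, tables):
        gks = {r.model: r.gks_ms_per_uf for r in tables.table4}
        for name in REQUIRED:
            assert get_model(name).parameters["g_Ks"] == pytest.approx(gks[name])


class TestConductanceScaling:
    def test_identity_scaling_preserves_rhs(self, tp):
        scaled = apply_conductance_scaling(
            tp, ConductanceScaling("TP", {g: 1.0 for g in tp.conductances}))
        y = tp.initial_state + 0.001
        assert np.array_equal(scaled.rhs(0.0, y), tp.rhs(0.0, y))

    def test_compositionality(self, tp, rng):
        a = {g: float(f) for g, f in zip(tp.conductances,
                                         rng.uniform(0.5, 1.5, len(tp.conductances)))}
        b = {g: float(f) for g, f in zip(tp.conductances,
                                         rng.uniform(0.5, 1.5, len(tp.conductances)))}
        ab = {g: a[g] * b[g] for g in a}
        two_step = apply_conductance_scaling(
            apply_conductance_scaling(tp, ConductanceScaling("TP", a)),
            ConductanceScaling("TP", b))
        one_step = apply_conductance_scaling(tp, ConductanceScaling("TP", ab))
        for g in a:
            assert two_step.parameters[g] == pytest.approx(one_step.parameters[g])

    def test_zero_factor_removes_current(self, tp):
        blocked = apply_conductance_scaling(tp, ConductanceScaling("TP", {"g_Kr": 0.0}))
        assert blocked.parameters["g_Kr"] == 0.0
        rescaled = apply_conductance_scaling(blocked,
                                             ConductanceScaling("TP", {"g_Kr": 5.0}))
        y = tp.initial_state * 1.001
        assert np.array_equal(rescaled.rhs(0.0, y), blocked.rhs(0.0, y))

    def test_unknown_conductance_named_in_error(self, tp):
        with pytest.raises(UnknownConductanceError, match="g_Funny"):
            apply_conductance_scaling(tp, ConductanceScaling("TP", {"g_Funny": 2.0}))

    def test_added_components_not_supported(self, tp):
        with pytest.raises(ModelNotImplementedError, match="ORd_INaL"):
            apply_conductance_scaling(
                tp, ConductanceScaling("TP", {}, added_components=("ORd_INaL",)))

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            ConductanceScaling("TP", {"g_Kr": -0.5})


class TestExternalConcentrations:
    def test_values_set_and_rest_unchanged(self, tp):
        m = set_external_concentrations(tp, 4.0, 148.35, 1.8)
        assert m.parameters["Ko"] == 4.0
        assert m.parameters["Nao"] == 148.35
        assert m.parameters["Cao"] == 1.8
        for k, v in tp.parameters.items():
            if k not in ("Ko", "Nao", "Cao"):
                assert m.parameters[k] == v

    def test_identity_when_defaults(self, tp):
        m = set_external_concentrations(
            tp, tp.parameters["Ko"], tp.parameters["Nao"], tp.parameters["Cao"])
        assert m.parameters == tp.parameters
        assert np.array_equal(m.rhs(0.0, tp.initial_state),
                              tp.rhs(0.0, tp.initial_state))

    @pytest.mark.parametrize("bad", [(0.0, 140, 2), (5.4, -1, 2), (5.4, 140, 0)])
    def test_non_positive_rejected(self, tp, bad):
        with pytest.raises(ValueError):
            set_external_concentrations(tp, *bad)


class TestStimulusSpec:
    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(amplitude=0.0, duration=1.0)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(amplitude=-52.0, duration=0.0)


SYNTHETIC_CELLML = """<?xml version="1.0" encoding="UTF-8"?>
<model name="synthetic_gate_model" xmlns="http://www.cellml.org/cellml/1.0#">
  <component name="environment">
    <variable name="time" units="ms" public_interface="out"/>
  </component>
  <component name="membrane">
    <variable name="time" units="ms" public_interface="in"/>
    <variable name="V" units="mV" initial_value="-85.0" public_interface="out"/>
    <variable name="g_Ks" units="mS_per_uF" initial_value="0.392"/>
    <variable name="E_K" units="mV" initial_value="-86.0"/>
    <variable name="x" units="dimensionless" public_interface="in"/>
    <variable name="i_Ks" units="A_per_F"/>
    <math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><eq/>
        <ci>i_Ks</ci>
        <apply><times/>
          <ci>g_Ks</ci>
          <apply><power/><ci>x</ci><cn cellml:units="dimensionless"
            xmlns:cellml="http://www.cellml.org/cellml/1.0#">2</cn></apply>
          <apply><minus/><ci>V</ci><ci>E_K</ci></apply>
        </apply>
      </apply>
      <apply><eq/>
        <apply><diff/><bvar><ci>time</ci></bvar><ci>V</ci></apply>
        <apply><minus/><ci>i_Ks</ci></apply>
      </apply>
    </math>
  </component>
  <component name="gate">
    <variable name="time" units="ms" public_interface="in"/>
    <variable name="V" units="mV" public_interface="in"/>
    <variable name="x" units="dimensionless" initial_value="0.1"
      public_interface="out"/>
    <variable name="tau" units="ms" initial_value="50.0"/>
    <variable name="x_inf" units="dimensionless"/>
    <math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><eq/>
        <ci>x_inf</ci>
        <apply><divide/>
          <cn cellml:units="dimensionless"
            xmlns:cellml="http://www.cellml.org/cellml/1.0#">1</cn>
          <apply><plus/>
            <cn cellml:units="dimensionless"
              xmlns:cellml="http://www.cellml.org/cellml/1.0#">1</cn>
            <apply><exp/>
              <apply><divide/>
                <apply><minus/>
                  <apply><minus/><cn cellml:units="mV"
                    xmlns:cellml="http://www.cellml.org/cellml/1.0#">5</cn></apply>
                  <ci>V</ci>
                </apply>
                <cn cellml:units="mV"
                  xmlns:cellml="http://www.cellml.org/cellml/1.0#">14</cn>
              </apply>
            </apply>
          </apply>
        </apply>
      </apply>
      <apply><eq/>
        <apply><diff/><bvar><ci>time</ci></bvar><ci>x</ci></apply>
        <apply><divide/>
          <apply><minus/><ci>x_inf</ci><ci>x</ci></apply>
          <ci>tau</ci>
        </apply>
      </apply>
    </math>
  </component>
  <connection>
    <map_components component_1="environment" component_2="membrane"/>
    <map_variables variable_1="time" variable_2="time"/>
  </connection>
  <connection>
    <map_components component_1="environment" component_2="gate"/>
    <map_variables variable_1="time" variable_2="time"/>
  </connection>
  <connection>
    <map_components component_1="membrane" component_2="gate"/>
    <map_variables variable_1="V" variable_2="V"/>
    <map_variables variable_1="x" variable_2="x"/>
  </connection>
</model>
"""


class TestCellMLImport:
    """The loader is exercised on a small synthetic two-component model
    (an IKs-like gate driving a leaky membrane)."""

    @pytest.fixture()
    def model_file(self, tmp_path):
        f = tmp_path / "synthetic_gate_model.cellml"
        f.write_text(SYNTHETIC_CELLML)
        return f

    def test_states_parameters_and_initials(self, model_file):
        model = load_cellml(model_file)
        assert model.name == "synthetic_gate_model"
        assert len(model.state_names) == 2
        by_name = dict(zip(model.state_names, model.initial_state))
        assert by_name["membrane__V"] == -85.0
        assert by_name["gate__x"] == 0.1
        assert model.parameters["membrane__g_Ks"] == pytest.approx(0.392)

    def test_rhs_matches_hand_computation(self, model_file):
        model = load_cellml(model_file)
        iv, ix = model.state_names.index("membrane__V"), model.state_names.index("gate__x")
        y = np.zeros(2)
        y[iv], y[ix] = -40.0, 0.3
        dy = model.rhs(0.0, y)
        x_inf = 1.0 / (1.0 + np.exp((-5.0 - (-40.0)) / 14.0))
        assert dy[ix] == pytest.approx((x_inf - 0.3) / 50.0)
        assert dy[iv] == pytest.approx(-0.392 * 0.3 ** 2 * (-40.0 + 86.0))

    def test_parameter_override(self, model_file):
        model = load_cellml(model_file)
        iv = model.state_names.index("membrane__V")
        y = np.array([-40.0, 0.3]) if iv == 0 else np.array([0.3, -40.0])
        dy = model.rhs(0.0, y, parameters={"membrane__g_Ks": 0.0})
        assert dy[iv] == pytest.approx(0.0)

    def test_invalid_file(self, tmp_path):
        f = tmp_path / "broken.cellml"
        f.write_text("this is not xml <<<")
        with pytest.raises(CellMLParseError):
            load_cellml(f)

    def test_non_cellml_xml(self, tmp_path):
        f = tmp_path / "other.xml"
        f.write_text("<foo xmlns='http://example.org/ns'/>")
        with pytest.raises(CellMLParseError, match="namespace"):
            load_cellml(f)

    def test_unsupported_construct_named(self, tmp_path):
        bad = SYNTHETIC_CELLML.replace(
            "<apply><exp/>", "<apply><arctanh/>").replace("</model>", "</model>")
        f = tmp_path / "unsupported.cellml"
        f.write_text(bad)
        with pytest.raises(CellMLParseError, match="arctanh"):
            load_cellml(f)
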