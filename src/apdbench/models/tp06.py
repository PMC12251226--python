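"""ten Tusscher & Panfilov (2006) human ventricular cell, endocardial variant.

Hodgkin-Huxley-type model with 19 states: membrane potential, bulk K+/Na+
and three-compartment Ca2+ handling (cytosol, subspace, SR) with a
four-parameter RyR release gate, and 13 gating variables.  Transcribed
from the published equation set; maximal conductances are the endocardial
parameterisation (g_to = 0.073, g_Ks = 0.392 mS/uF).

Units: ms, mV, mM, currents in A/F.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from apdbench.models.engine import make_driver

NAME = "TP"
CELL_TYPE = "endocardial"
CITATION = (
    "ten Tusscher KHWJ, Panfilov AV. Alternans and spiral breakup in a human "
    "ventricular tissue model. Am J Physiol Heart Circ Physiol 291:H1088-H1100, 2006 "
    "(endocardial parameterisation)."
)

STATE_NAMES = (
    "V", "Ki", "Nai", "Cai", "Cass", "CaSR",
    "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2", "fCass", "Rbar",
)

PARAM_NAMES = (
    "g_Na", "g_K1", "g_to", "g_Kr", "g_Ks", "g_CaL", "g_pCa", "g_pK",
    "g_bNa", "g_bCa", "k_NaCa", "P_NaK",
    "Vmax_up", "V_rel", "V_leak", "V_xfer",
    "Ko", "Nao", "Cao",
)

DEFAULT_PARAMS = {
    "g_Na": 14.838,      # mS/uF
    "g_K1": 5.405,
    "g_to": 0.073,       # endocardial
    "g_Kr": 0.153,
    "g_Ks": 0.392,       # endocardial
    "g_CaL": 3.98e-5,    # cm^3 uF^-1 ms^-1
    "g_pCa": 0.1238,
    "g_pK": 0.0146,
    "g_bNa": 0.00029,
    "g_bCa": 0.000592,
    "k_NaCa": 1000.0,    # A/F
    "P_NaK": 2.724,      # A/F
    "Vmax_up": 0.006375,  # mM/ms
    "V_rel": 0.102,      # 1/ms
    "V_leak": 0.00036,   # 1/ms
    "V_xfer": 0.0038,    # 1/ms
    "Ko": 5.4,           # mM
    "Nao": 140.0,
    "Cao": 2.0,
}

CONDUCTANCES = (
    "g_Na", "g_K1", "g_to", "g_Kr", "g_Ks", "g_CaL", "g_pCa", "g_pK",
    "g_bNa", "g_bCa", "k_NaCa", "P_NaK",
)
BLOCK_TARGETS = {"ikr": "g_Kr", "ical": "g_CaL"}
CONC_PARAMS = {"Ko": "Ko", "Nao": "Nao", "Cao": "Cao"}

# Published initial conditions; the study protocol is a fixed 1500 paces
# from here, not a convergence test.
INITIAL_STATE = np.array([
    -86.2,       # V
    138.3,       # Ki
    7.67,        # Nai
    0.00007,     # Cai
    0.00007,     # Cass
    1.3,         # CaSR
    0.0,         # m
    0.75,        # h
    0.75,        # j
    0.0,         # xr1
    1.0,         # xr2
    0.0,         # xs
    0.0,         # r
    1.0,         # s
    0.0,         # d
    1.0,         # f
    1.0,         # f2
    1.0,         # fCass
    1.0,         # Rbar
])

STIM_AMPLITUDE = -52.0  # A/F
STIM_DURATION = 1.0     # ms
STIM_CARRIED = "K"

# integration schedule: fine over stimulus/upstroke, mid over the plateau
# (subspace Ca2+ is the stiffest non-gate state), coarse in diastole
PHASE_BOUNDS = (0.0, 2.0, 450.0)
PHASE_DTS = (0.01, 0.05, 0.2)
RECORD_SUBSTEPS = (5, 1, 1)  # sub-steps per 0.05 ms output sample

_R = 8314.472
_T = 310.0
_F = 96485.3415
_RTF = _R * _T / _F
_CM = 0.185       # uF
_V_C = 0.016404   # um^3 (scaled)
_V_SR = 0.001094
_V_SS = 0.00005468


@njit(cache=True)
def _gates(y, p, ginf, gtau):
    V = y[0]
    Cass = y[4]
    CaSR = y[5]

    # INa gates
    minf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((V - 50.0) / 200.0))
    ginf[6] = minf
    gtau[6] = am * bm

    hinf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V < -40.0:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 310000.0 * np.exp(0.3485 * V)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    ginf[7] = hinf
    gtau[7] = 1.0 / (ah + bh)

    if V < -40.0:
        aj = ((-25428.0 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78)) / (1.0 + np.exp(0.311 * (V + 79.23)))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    else:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    ginf[8] = hinf
    gtau[8] = 1.0 / (aj + bj)

    # IKr activation / inactivation
    ginf[9] = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    gtau[9] = axr1 * bxr1

    ginf[10] = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    gtau[10] = axr2 * bxr2

    # IKs
    ginf[11] = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
    gtau[11] = axs * bxs + 80.0

    # Ito (endocardial s gate)
    ginf[12] = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    gtau[12] = 9.5 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8
    ginf[13] = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
    gtau[13] = 1000.0 * np.exp(-(V + 67.0) ** 2 / 1000.0) + 8.0

    # ICaL gates
    ginf[14] = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    gtau[14] = ad * bd + gd

    ginf[15] = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    gtau[15] = (1102.5 * np.exp(-(V + 27.0) ** 2 / 225.0)
                + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
                + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)

    ginf[16] = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    gtau[16] = (562.0 * np.exp(-(V + 27.0) ** 2 / 240.0)
                + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
                + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))

    css = (Cass / 0.05) ** 2
    ginf[17] = 0.6 / (1.0 + css) + 0.4
    gtau[17] = 80.0 / (1.0 + css) + 2.0

    # RyR recovery gate Rbar: dR = -k2 Cass R + k4 (1-R)
    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / CaSR) ** 2)
    k2 = 0.045 * kcasr
    k4 = 0.005
    rate = k2 * Cass + k4
    gtau[18] = 1.0 / rate
    ginf[18] = k4 / rate


@njit(cache=True)
def _fluxes(y, p, istim, dy):
    V = y[0]
    Ki = y[1]
    Nai = y[2]
    Cai = y[3]
    Cass = y[4]
    CaSR = y[5]
    m = y[6]
    h = y[7]
    j = y[8]
    xr1 = y[9]
    xr2 = y[10]
    xs = y[11]
    r = y[12]
    s = y[13]
    d = y[14]
    f = y[15]
    f2 = y[16]
    fCass = y[17]
    Rbar = y[18]

    Ko = p[16]
    Nao = p[17]
    Cao = p[18]

    EK = _RTF * np.log(Ko / Ki)
    ENa = _RTF * np.log(Nao / Nai)
    EKs = _RTF * np.log((Ko + 0.03 * Nao) / (Ki + 0.03 * Nai))
    ECa = 0.5 * _RTF * np.log(Cao / Cai)

    INa = p[0] * m ** 3 * h * j * (V - ENa)

    vk = V - EK
    aK1 = 0.1 / (1.0 + np.exp(0.06 * (vk - 200.0)))
    bK1 = (3.0 * np.exp(0.0002 * (vk + 100.0)) + np.exp(0.1 * (vk - 10.0))) / (
        1.0 + np.exp(-0.5 * vk))
    IK1 = p[1] * (aK1 / (aK1 + bK1)) * np.sqrt(Ko / 5.4) * vk

    Ito = p[2] * r * s * vk
    IKr = p[3] * np.sqrt(Ko / 5.4) * xr1 * xr2 * vk
    IKs = p[4] * xs * xs * (V - EKs)

    z = 2.0 * (V - 15.0) / _RTF
    if abs(V - 15.0) < 1e-6:
        drive = _RTF / 2.0 * (0.25 * Cass - Cao)
    else:
        ez = np.exp(z)
        drive = (V - 15.0) * (0.25 * Cass * ez - Cao) / (ez - 1.0)
    ICaL = p[5] * d * f * f2 * fCass * 4.0 * _F / _RTF * drive

    vfrt = V / _RTF
    INaCa = p[10] * (np.exp(0.35 * vfrt) * Nai ** 3 * Cao
                     - np.exp(-0.65 * vfrt) * Nao ** 3 * Cai * 2.5) / (
        (87.5 ** 3 + Nao ** 3) * (1.38 + Cao) * (1.0 + 0.1 * np.exp(-0.65 * vfrt)))

    INaK = p[11] * Ko * Nai / ((Ko + 1.0) * (Nai + 40.0) * (
        1.0 + 0.1245 * np.exp(-0.1 * vfrt) + 0.0353 * np.exp(-vfrt)))

    IpCa = p[6] * Cai / (Cai + 0.0005)
    IpK = p[7] * vk / (1.0 + np.exp((25.0 - V) / 5.98))
    IbNa = p[8] * (V - ENa)
    IbCa = p[9] * (V - ECa)

    dy[0] = -(IK1 + Ito + IKr + IKs + ICaL + INaK + INa + IbNa + INaCa
              + IbCa + IpK + IpCa + istim)

    cvf = _CM / (_V_C * _F)
    dy[1] = -(IK1 + Ito + IKr + IKs + IpK + istim - 2.0 * INaK) * cvf
    dy[2] = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * cvf

    # Ca2+ subsystem
    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / CaSR) ** 2)
    k1 = 0.15 / kcasr
    O = k1 * Cass * Cass * Rbar / (0.06 + k1 * Cass * Cass)
    Irel = p[13] * O * (CaSR - Cass)
    Ileak = p[14] * (CaSR - Cai)
    Iup = p[12] / (1.0 + 0.00025 ** 2 / (Cai * Cai))
    Ixfer = p[15] * (Cass - Cai)

    bufc = 1.0 / (1.0 + 0.2 * 0.001 / (Cai + 0.001) ** 2)
    bufsr = 1.0 / (1.0 + 10.0 * 0.3 / (CaSR + 0.3) ** 2)
    bufss = 1.0 / (1.0 + 0.4 * 0.00025 / (Cass + 0.00025) ** 2)

    dy[3] = bufc * ((Ileak - Iup) * _V_SR / _V_C + Ixfer
                    - (IbCa + IpCa - 2.0 * INaCa) * _CM / (2.0 * _V_C * _F))
    dy[5] = bufsr * (Iup - Irel - Ileak)
    dy[4] = bufss * (-ICaL * _CM / (2.0 * _V_SS * _F)
                     + Irel * _V_SR / _V_SS - Ixfer * _V_C / _V_SS)


_N_STATES = len(STATE_NAMES)
_GATE_LO = 6  # states 6..18 are Rush-Larsen gates


@njit(cache=True)
def step(y, p, istim, dt):
    ginf = np.empty(_N_STATES, dtype=np.float64)
    gtau = np.empty(_N_STATES, dtype=np.float64)
    dy = np.empty(_N_STATES, dtype=np.float64)
    _gates(y, p, ginf, gtau)
    _fluxes(y, p, istim, dy)
    for i in range(_GATE_LO):
        y[i] += dt * dy[i]
    for g in range(_GATE_LO, _N_STATES):
        y[g] = ginf[g] + (y[g] - ginf[g]) * np.exp(-dt / gtau[g])


@njit(cache=True)
def rhs(y, p, istim):
    ginf = np.empty(_N_STATES, dtype=np.float64)
    gtau = np.empty(_N_STATES, dtype=np.float64)
    dy = np.empty(_N_STATES, dtype=np.float64)
    _gates(y, p, ginf, gtau)
    _fluxes(y, p, istim, dy)
    for g in range(_GATE_LO, _N_STATES):
        dy[g] = (ginf[g] - y[g]) / gtau[g]
    return dy


PACE, RECORD = make_driver(step)
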