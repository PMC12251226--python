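"""Grandi-Pasqualini-Bers (2010) human ventricular cell, endocardial variant.

39-state model with junctional-cleft / subsarcolemmal / cytosolic
compartments for Na+ and Ca2+, explicit buffer state variables
(troponin, calmodulin, myosin, SR-membrane and sarcolemmal sites,
calsequestrin, Na+ buffers), a Shannon-type 3-state RyR, and chloride
currents (Ca-activated and background).  Intracellular K+ is held
constant, as in the published code.  Endocardial Ito: total conductance
0.3x the epicardial value, 96.4 % slow / 3.6 % fast.

Numerics note: free Ca2+ in the tiny junctional cleft relaxes on a
~0.01 ms timescale, so the stepper advances all buffer states with
Rush-Larsen updates and debits the *realised* buffer uptake from the
ion pools, which keeps mass exactly conserved under splitting.

Units: ms, mV, mM, A/F.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from apdbench.models.engine import make_driver

NAME = "GPB"
CELL_TYPE = "endocardial"
CITATION = (
    "Grandi E, Pasqualini FS, Bers DM. A novel computational model of the human "
    "ventricular action potential and Ca transient. J Mol Cell Cardiol "
    "48:112-121, 2010 (endocardial Ito parameterisation)."
)

STATE_NAMES = (
    "V", "Naj", "Nasl", "Nai", "Ki", "Caj", "Casl", "Cai", "Casr",
    "m", "h", "j", "d", "f", "fcaBj", "fcaBsl",
    "xtos", "ytos", "xtof", "ytof", "xkr", "xks",
    "RyRr", "RyRo", "RyRi",
    "NaBj", "NaBsl",
    "TnCL", "TnCHc", "TnCHm", "CaM", "Myoc", "Myom", "SRB",
    "SLLj", "SLLsl", "SLHj", "SLHsl", "Csqnb",
)

PARAM_NAMES = (
    "g_Na", "g_CaL", "g_Kr", "g_Ks", "g_K1", "g_to_slow", "g_to_fast",
    "g_Kp", "g_ClCa", "g_ClB", "g_NaB", "g_CaB", "IbarNCX", "IbarNaK",
    "IbarSLCaP", "Ko", "Nao", "Cao",
)

DEFAULT_PARAMS = {
    "g_Na": 23.0,              # mS/uF
    "g_CaL": 1.0,              # dimensionless scale on all ICaL permeabilities
    "g_Kr": 0.035,             # mS/uF (before sqrt(Ko/5.4))
    "g_Ks": 0.0035,
    "g_K1": 0.35,              # mS/uF (before sqrt(Ko/5.4))
    "g_to_slow": 0.13 * 0.3 * 0.964,   # endocardial
    "g_to_fast": 0.13 * 0.3 * 0.036,   # endocardial
    "g_Kp": 0.002,
    "g_ClCa": 0.5 * 0.109625,
    "g_ClB": 9e-3,
    "g_NaB": 0.597e-3,
    "g_CaB": 5.513e-4,
    "IbarNCX": 4.5,            # A/F
    "IbarNaK": 1.8,            # A/F
    "IbarSLCaP": 0.0673,       # A/F
    "Ko": 5.4,
    "Nao": 140.0,
    "Cao": 1.8,
}

CONDUCTANCES = (
    "g_Na", "g_CaL", "g_Kr", "g_Ks", "g_K1", "g_to_slow", "g_to_fast",
    "g_Kp", "g_ClCa", "g_ClB", "g_NaB", "g_CaB", "IbarNCX", "IbarNaK",
    "IbarSLCaP",
)
BLOCK_TARGETS = {"ikr": "g_Kr", "ical": "g_CaL"}
CONC_PARAMS = {"Ko": "Ko", "Nao": "Nao", "Cao": "Cao"}

# 1 Hz steady diastolic state of this endocardial parameterisation
# (settled for 300 cycles from the published initial conditions, whose
# epicardial Ito leaves a small residual dV/dt here).
INITIAL_STATE = np.array([
    -81.37755644,      # V
    8.238171211,       # Naj
    8.237182016,       # Nasl
    8.237358415,       # Nai
    120.0,             # Ki (constant)
    0.0001789923781,   # Caj
    0.0001075479375,   # Casl
    8.968175869e-05,   # Cai
    0.5708841851,      # Casr
    0.003854784124,    # m
    0.6234780602,      # h
    0.6216640954,      # j
    2.962162052e-06,   # d
    0.9950895046,      # f
    0.02511145869,     # fcaBj
    0.01545179217,     # fcaBsl
    0.0004430882254,   # xtos
    0.7962618192,      # ytos
    0.0004430783988,   # xtof
    0.9999957789,      # ytof
    0.02476095495,     # xkr
    0.004303469557,    # xks
    0.8926362701,      # RyRr
    7.985984959e-07,   # RyRo
    9.605233128e-08,   # RyRi
    3.416427548,       # NaBj
    0.7454292495,      # NaBsl
    0.00914722794,     # TnCL
    0.1179976025,      # TnCHc
    0.01033699751,     # TnCHm
    0.0003036574467,   # CaM
    0.001981333194,    # Myoc
    0.1375019961,      # Myom
    0.002225855762,    # SRB
    0.007532724907,    # SLLj
    0.01018247487,     # SLLsl
    0.07440066344,     # SLHj
    0.1170966476,      # SLHsl
    1.215756556,       # Csqnb
])

STIM_AMPLITUDE = -9.5  # A/F
STIM_DURATION = 5.0    # ms
STIM_CARRIED = "none"  # intracellular K+ is clamped

PHASE_BOUNDS = (0.0, 7.0, 450.0)
PHASE_DTS = (0.01, 0.02, 0.05)
RECORD_SUBSTEPS = (5, 5, 1)

_FRDY = 96485.0
_R = 8314.0
_T = 310.0
_FORT = _FRDY / (_R * _T)

_CMEM = 1.3810e-10  # F
_VCELL = np.pi * 10.25 ** 2 * 100.0 * 1e-15  # L
_VMYO = 0.65 * _VCELL
_VSR = 0.035 * _VCELL
_VSL = 0.02 * _VCELL
_VJUNC = 0.0539 * 0.01 * _VCELL
_JCA_JUNCSL = 8.2413e-13   # L/ms
_JCA_SLMYO = 3.7243e-12
_JNA_JUNCSL = 1.8313e-14
_JNA_SLMYO = 1.6386e-12

_FJUNC = 0.11
_FSL = 1.0 - _FJUNC
_FJUNC_CAL = 0.9
_FSL_CAL = 1.0 - _FJUNC_CAL

_CLI = 15.0
_CLO = 150.0
_MGI = 1.0

# ICaL permeabilities (cm/s), scaled jointly by the g_CaL parameter
_PCA = 0.5 * 5.4e-4
_PK = 0.5 * 2.7e-7
_PNA = 0.5 * 1.5e-8

# buffer site definitions: Bmax (mM), kon (1/(mM ms)), koff (1/ms)
_BMAX_NAJ = 7.561
_BMAX_NASL = 1.65
_KON_NA = 0.1e-3
_KOFF_NA = 1e-3
_BMAX_TNCLOW = 70e-3
_KON_TNCL = 32.7
_KOFF_TNCL = 19.6e-3
_BMAX_TNCHIGH = 140e-3
_KON_TNCHCA = 2.37
_KOFF_TNCHCA = 0.032e-3
_KON_TNCHMG = 3e-3
_KOFF_TNCHMG = 3.33e-3
_BMAX_CAM = 24e-3
_KON_CAM = 34.0
_KOFF_CAM = 238e-3
_BMAX_MYOSIN = 140e-3
_KON_MYOCA = 13.8
_KOFF_MYOCA = 0.46e-3
_KON_MYOMG = 0.0157
_KOFF_MYOMG = 0.057e-3
_BMAX_SR = 19.0 * 0.9e-3
_KON_SR = 100.0
_KOFF_SR = 60e-3
_BMAX_SLLSL = 37.4e-3 * _VMYO / _VSL
_BMAX_SLLJ = 4.6e-3 * _VMYO / _VJUNC * 0.1
_BMAX_SLHSL = 13.4e-3 * _VMYO / _VSL
_BMAX_SLHJ = 1.65e-3 * _VMYO / _VJUNC * 0.1
_KON_SLL = 100.0
_KOFF_SLL = 1300e-3
_KON_SLH = 100.0
_KOFF_SLH = 30e-3
_BMAX_CSQN = 140e-3 * _VMYO / _VSR
_KON_CSQN = 100.0
_KOFF_CSQN = 65.0

_N_STATES = len(STATE_NAMES)
_GATE_LO = 9
_GATE_HI = 22   # HH-type gates: 9..21
_BUF_LO = 25
_BUF_HI = 39    # buffer states: 25..38 (RL + realised-delta debit)


@njit(cache=True)
def _gates(y, p, ginf, gtau):
    V = y[0]
    Caj = y[5]
    Casl = y[6]

    # INa (m, h, j)
    mss = 1.0 / (1.0 + np.exp(-(56.86 + V) / 9.03)) ** 2
    taum = 0.1292 * np.exp(-((V + 45.79) / 15.54) ** 2) \
        + 0.06487 * np.exp(-((V - 4.823) / 51.12) ** 2)
    ginf[9] = mss
    gtau[9] = taum
    hss = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V < -40.0:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    ginf[10] = hss
    gtau[10] = 1.0 / (ah + bh)
    if V < -40.0:
        aj = ((-2.5428e4 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
              * (V + 37.78)) / (1.0 + np.exp(0.311 * (V + 79.23)))
        bj = 0.02424 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    else:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    ginf[11] = hss
    gtau[11] = 1.0 / (aj + bj)

    # ICaL d, f
    dss = 1.0 / (1.0 + np.exp(-(V + 5.0) / 6.0))
    x = V + 5.0
    if abs(x) < 1e-6:
        taud = dss / 0.21  # limit of dss*(1-exp(-x/6))/(0.035*x)
    else:
        taud = dss * (1.0 - np.exp(-x / 6.0)) / (0.035 * x)
    ginf[12] = dss
    gtau[12] = taud
    fss = 1.0 / (1.0 + np.exp((V + 35.0) / 9.0)) + 0.6 / (1.0 + np.exp((50.0 - V) / 20.0))
    ginf[13] = fss
    gtau[13] = 1.0 / (0.0197 * np.exp(-(0.0337 * (V + 14.5)) ** 2) + 0.02)
    # Ca-dependent inactivation (bound fractions, linear in state)
    ginf[14] = 1.7 * Caj / (1.7 * Caj + 11.9e-3)
    gtau[14] = 1.0 / (1.7 * Caj + 11.9e-3)
    ginf[15] = 1.7 * Casl / (1.7 * Casl + 11.9e-3)
    gtau[15] = 1.0 / (1.7 * Casl + 11.9e-3)

    # Ito slow/fast
    xtoss = 1.0 / (1.0 + np.exp(-(V - 19.0) / 13.0))
    ytoss = 1.0 / (1.0 + np.exp((V + 19.5) / 5.0))
    ginf[16] = xtoss
    gtau[16] = 9.0 / (1.0 + np.exp((V + 3.0) / 15.0)) + 0.5
    ginf[17] = ytoss
    gtau[17] = 800.0 / (1.0 + np.exp((V + 60.0) / 10.0)) + 30.0
    ginf[18] = xtoss
    gtau[18] = 8.5 * np.exp(-((V + 45.0) / 50.0) ** 2) + 0.5
    ginf[19] = ytoss
    gtau[19] = 85.0 * np.exp(-((V + 40.0) ** 2) / 220.0) + 7.0

    # IKr activation
    ginf[20] = 1.0 / (1.0 + np.exp(-(V + 10.0) / 5.0))
    gtau[20] = (550.0 / (1.0 + np.exp((-22.0 - V) / 9.0))
                * 6.0 / (1.0 + np.exp((V + 11.0) / 9.0))
                + 230.0 / (1.0 + np.exp((V + 40.0) / 20.0)))

    # IKs activation
    ginf[21] = 1.0 / (1.0 + np.exp(-(V + 3.8) / 14.25))
    gtau[21] = 990.1 / (1.0 + np.exp(-(V + 2.436) / 14.12))


@njit(cache=True)
def _buffers(y, ginf, gtau):
    """Rush-Larsen targets for all buffer states (linear in the state)."""
    Naj = y[1]
    Nasl = y[2]
    Caj = y[5]
    Casl = y[6]
    Cai = y[7]
    Casr = y[8]

    # Na buffers
    r = _KON_NA * Naj
    gtau[25] = 1.0 / (r + _KOFF_NA)
    ginf[25] = r * _BMAX_NAJ * gtau[25]
    r = _KON_NA * Nasl
    gtau[26] = 1.0 / (r + _KOFF_NA)
    ginf[26] = r * _BMAX_NASL * gtau[26]

    # cytosolic Ca buffers
    r = _KON_TNCL * Cai
    gtau[27] = 1.0 / (r + _KOFF_TNCL)
    ginf[27] = r * _BMAX_TNCLOW * gtau[27]
    r = _KON_TNCHCA * Cai
    gtau[28] = 1.0 / (r + _KOFF_TNCHCA)
    ginf[28] = r * (_BMAX_TNCHIGH - y[29]) * gtau[28]
    r = _KON_TNCHMG * _MGI
    gtau[29] = 1.0 / (r + _KOFF_TNCHMG)
    ginf[29] = r * (_BMAX_TNCHIGH - y[28]) * gtau[29]
    r = _KON_CAM * Cai
    gtau[30] = 1.0 / (r + _KOFF_CAM)
    ginf[30] = r * _BMAX_CAM * gtau[30]
    r = _KON_MYOCA * Cai
    gtau[31] = 1.0 / (r + _KOFF_MYOCA)
    ginf[31] = r * (_BMAX_MYOSIN - y[32]) * gtau[31]
    r = _KON_MYOMG * _MGI
    gtau[32] = 1.0 / (r + _KOFF_MYOMG)
    ginf[32] = r * (_BMAX_MYOSIN - y[31]) * gtau[32]
    r = _KON_SR * Cai
    gtau[33] = 1.0 / (r + _KOFF_SR)
    ginf[33] = r * _BMAX_SR * gtau[33]

    # sarcolemmal sites
    r = _KON_SLL * Caj
    gtau[34] = 1.0 / (r + _KOFF_SLL)
    ginf[34] = r * _BMAX_SLLJ * gtau[34]
    r = _KON_SLL * Casl
    gtau[35] = 1.0 / (r + _KOFF_SLL)
    ginf[35] = r * _BMAX_SLLSL * gtau[35]
    r = _KON_SLH * Caj
    gtau[36] = 1.0 / (r + _KOFF_SLH)
    ginf[36] = r * _BMAX_SLHJ * gtau[36]
    r = _KON_SLH * Casl
    gtau[37] = 1.0 / (r + _KOFF_SLH)
    ginf[37] = r * _BMAX_SLHSL * gtau[37]

    # calsequestrin
    r = _KON_CSQN * Casr
    gtau[38] = 1.0 / (r + _KOFF_CSQN)
    ginf[38] = r * _BMAX_CSQN * gtau[38]


@njit(cache=True)
def _fluxes(y, p, istim, dy):
    """Derivatives of V, concentrations (buffering excluded) and RyR states."""
    V = y[0]
    Naj = y[1]
    Nasl = y[2]
    Nai = y[3]
    Ki = y[4]
    Caj = y[5]
    Casl = y[6]
    Cai = y[7]
    Casr = y[8]
    m = y[9]
    h = y[10]
    j = y[11]
    d = y[12]
    f = y[13]
    fcaBj = y[14]
    fcaBsl = y[15]
    xtos = y[16]
    ytos = y[17]
    xtof = y[18]
    ytof = y[19]
    xkr = y[20]
    xks = y[21]
    RyRr = y[22]
    RyRo = y[23]
    RyRi = y[24]

    Ko = p[15]
    Nao = p[16]
    Cao = p[17]

    ena_junc = np.log(Nao / Naj) / _FORT
    ena_sl = np.log(Nao / Nasl) / _FORT
    ek = np.log(Ko / Ki) / _FORT
    eca_junc = np.log(Cao / Caj) / (2.0 * _FORT)
    eca_sl = np.log(Cao / Casl) / (2.0 * _FORT)
    ecl = np.log(_CLI / _CLO) / _FORT

    # INa
    gna3 = p[0] * m ** 3 * h * j
    I_Na_junc = _FJUNC * gna3 * (V - ena_junc)
    I_Na_sl = _FSL * gna3 * (V - ena_sl)

    # INa background
    I_nabk_junc = _FJUNC * p[10] * (V - ena_junc)
    I_nabk_sl = _FSL * p[10] * (V - ena_sl)

    # INaK
    sigma = (np.exp(Nao / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V * _FORT)
                  + 0.0365 * sigma * np.exp(-V * _FORT))
    KmNaip = 11.0
    KmKo = 1.5
    I_nak_junc = _FJUNC * p[13] * fnak * Ko \
        / (1.0 + (KmNaip / Naj) ** 4) / (Ko + KmKo)
    I_nak_sl = _FSL * p[13] * fnak * Ko \
        / (1.0 + (KmNaip / Nasl) ** 4) / (Ko + KmKo)
    I_nak = I_nak_junc + I_nak_sl

    # IKr
    gkr = p[2] * np.sqrt(Ko / 5.4)
    rkr = 1.0 / (1.0 + np.exp((V + 74.0) / 24.0))
    I_kr = gkr * xkr * rkr * (V - ek)

    # IKs
    eks = np.log((Ko + 0.01833 * Nao) / (Ki + 0.01833 * Nai)) / _FORT
    I_ks = p[3] * xks * xks * (V - eks)

    # IKp
    kp_kp = 1.0 / (1.0 + np.exp(7.488 - V / 5.98))
    I_kp = p[7] * kp_kp * (V - ek)

    # Ito
    I_tos = p[5] * xtos * ytos * (V - ek)
    I_tof = p[6] * xtof * ytof * (V - ek)
    I_to = I_tos + I_tof

    # IK1
    aki = 1.02 / (1.0 + np.exp(0.2385 * (V - ek - 59.215)))
    bki = (0.49124 * np.exp(0.08032 * (V + 5.476 - ek))
           + np.exp(0.06175 * (V - ek - 594.31))) \
        / (1.0 + np.exp(-0.5143 * (V - ek + 4.753)))
    kiss = aki / (aki + bki)
    I_ki = p[4] * np.sqrt(Ko / 5.4) * kiss * (V - ek)

    # ICl(Ca) and background Cl
    I_ClCa = (_FJUNC * p[8] / (1.0 + 0.1 / Caj)
              + _FSL * p[8] / (1.0 + 0.1 / Casl)) * (V - ecl)
    I_Clbk = p[9] * (V - ecl)

    # ICaL
    vf = V * _FORT
    vff = V * _FRDY * _FORT
    if abs(V) < 1e-6:
        ibarca_j = _PCA * 2.0 * _FRDY * 0.341 * (Caj - Cao)
        ibarca_sl = _PCA * 2.0 * _FRDY * 0.341 * (Casl - Cao)
        ibark = _PK * _FRDY * 0.75 * (Ki - Ko)
        ibarna_j = _PNA * _FRDY * 0.75 * (Naj - Nao)
        ibarna_sl = _PNA * _FRDY * 0.75 * (Nasl - Nao)
    else:
        e2 = np.exp(2.0 * vf)
        e1 = np.exp(vf)
        ibarca_j = _PCA * 4.0 * vff * (0.341 * Caj * e2 - 0.341 * Cao) / (e2 - 1.0)
        ibarca_sl = _PCA * 4.0 * vff * (0.341 * Casl * e2 - 0.341 * Cao) / (e2 - 1.0)
        ibark = _PK * vff * (0.75 * Ki * e1 - 0.75 * Ko) / (e1 - 1.0)
        ibarna_j = _PNA * vff * (0.75 * Naj * e1 - 0.75 * Nao) / (e1 - 1.0)
        ibarna_sl = _PNA * vff * (0.75 * Nasl * e1 - 0.75 * Nao) / (e1 - 1.0)
    scale = p[1] * 0.45
    df_ = d * f
    I_Ca_junc = _FJUNC_CAL * ibarca_j * df_ * (1.0 - fcaBj) * scale
    I_Ca_sl = _FSL_CAL * ibarca_sl * df_ * (1.0 - fcaBsl) * scale
    I_CaK = ibark * df_ * (_FJUNC_CAL * (1.0 - fcaBj)
                           + _FSL_CAL * (1.0 - fcaBsl)) * scale
    I_CaNa_junc = _FJUNC_CAL * ibarna_j * df_ * (1.0 - fcaBj) * scale
    I_CaNa_sl = _FSL_CAL * ibarna_sl * df_ * (1.0 - fcaBsl) * scale

    # INCX
    KmCai = 3.59e-3
    KmCao = 1.3
    KmNai = 12.29
    KmNao = 87.5
    ksat = 0.32
    nu = 0.27
    Kdact = 0.150e-3
    Ka_junc = 1.0 / (1.0 + (Kdact / Caj) ** 2)
    Ka_sl = 1.0 / (1.0 + (Kdact / Casl) ** 2)
    expnu = np.exp(nu * vf)
    expnu1 = np.exp((nu - 1.0) * vf)
    s1_junc = expnu * Naj ** 3 * Cao
    s2_junc = expnu1 * Nao ** 3 * Caj
    s3_junc = (KmCai * Nao ** 3 * (1.0 + (Naj / KmNai) ** 3)
               + KmNao ** 3 * Caj * (1.0 + Caj / KmCai)
               + KmCao * Naj ** 3 + Naj ** 3 * Cao + Nao ** 3 * Caj)
    I_ncx_junc = _FJUNC * p[12] * Ka_junc * (s1_junc - s2_junc) / s3_junc \
        / (1.0 + ksat * expnu1)
    s1_sl = expnu * Nasl ** 3 * Cao
    s2_sl = expnu1 * Nao ** 3 * Casl
    s3_sl = (KmCai * Nao ** 3 * (1.0 + (Nasl / KmNai) ** 3)
             + KmNao ** 3 * Casl * (1.0 + Casl / KmCai)
             + KmCao * Nasl ** 3 + Nasl ** 3 * Cao + Nao ** 3 * Casl)
    I_ncx_sl = _FSL * p[12] * Ka_sl * (s1_sl - s2_sl) / s3_sl \
        / (1.0 + ksat * expnu1)

    # sarcolemmal Ca pump
    c16 = Caj ** 1.6
    I_pca_junc = _FJUNC * p[14] * c16 / (0.5e-3 ** 1.6 + c16)
    c16 = Casl ** 1.6
    I_pca_sl = _FSL * p[14] * c16 / (0.5e-3 ** 1.6 + c16)

    # Ca background
    I_cabk_junc = _FJUNC * p[11] * (V - eca_junc)
    I_cabk_sl = _FSL * p[11] * (V - eca_sl)

    # SR fluxes
    MaxSR = 15.0
    MinSR = 1.0
    kCaSR = MaxSR - (MaxSR - MinSR) / (1.0 + (0.45 / Casr) ** 2.5)
    koSRCa = 10.0 / kCaSR
    kiSRCa = 0.5 * kCaSR
    kim = 0.005
    kom = 0.06
    RI = 1.0 - RyRr - RyRo - RyRi
    dy[22] = (kim * RI - kiSRCa * Caj * RyRr) - (koSRCa * Caj ** 2 * RyRr - kom * RyRo)
    dy[23] = (koSRCa * Caj ** 2 * RyRr - kom * RyRo) - (kiSRCa * Caj * RyRo - kim * RyRi)
    dy[24] = (kiSRCa * Caj * RyRo - kim * RyRi) - (kom * RyRi - koSRCa * Caj ** 2 * RI)
    J_SRCarel = 25.0 * RyRo * (Casr - Caj)
    hsr = 1.787
    num = (Cai / 0.246e-3) ** hsr - (Casr / 1.7) ** hsr
    J_serca = 5.3114e-3 * num / (1.0 + (Cai / 0.246e-3) ** hsr + (Casr / 1.7) ** hsr)
    J_SRleak = 5.348e-6 * (Casr - Caj)

    # current totals
    I_Na_tot_junc = I_Na_junc + I_nabk_junc + 3.0 * I_ncx_junc \
        + 3.0 * I_nak_junc + I_CaNa_junc
    I_Na_tot_sl = I_Na_sl + I_nabk_sl + 3.0 * I_ncx_sl + 3.0 * I_nak_sl + I_CaNa_sl
    I_K_tot = I_to + I_kr + I_ks + I_ki - 2.0 * I_nak + I_CaK + I_kp
    I_Ca_tot_junc = I_Ca_junc + I_cabk_junc + I_pca_junc - 2.0 * I_ncx_junc
    I_Ca_tot_sl = I_Ca_sl + I_cabk_sl + I_pca_sl - 2.0 * I_ncx_sl
    I_Cl_tot = I_ClCa + I_Clbk
    I_tot = (I_Na_tot_junc + I_Na_tot_sl) + I_Cl_tot \
        + (I_Ca_tot_junc + I_Ca_tot_sl) + I_K_tot

    dy[0] = -(I_tot + istim)

    # Na compartments (buffering handled by the stepper)
    dy[1] = -I_Na_tot_junc * _CMEM / (_VJUNC * _FRDY) \
        + _JNA_JUNCSL / _VJUNC * (Nasl - Naj)
    dy[2] = -I_Na_tot_sl * _CMEM / (_VSL * _FRDY) \
        + _JNA_JUNCSL / _VSL * (Naj - Nasl) + _JNA_SLMYO / _VSL * (Nai - Nasl)
    dy[3] = _JNA_SLMYO / _VMYO * (Nasl - Nai)
    dy[4] = 0.0  # Ki clamped

    # Ca compartments (buffering handled by the stepper)
    dy[5] = -I_Ca_tot_junc * _CMEM / (_VJUNC * 2.0 * _FRDY) \
        + _JCA_JUNCSL / _VJUNC * (Casl - Caj) \
        + J_SRCarel * _VSR / _VJUNC + J_SRleak * _VMYO / _VJUNC
    dy[6] = -I_Ca_tot_sl * _CMEM / (_VSL * 2.0 * _FRDY) \
        + _JCA_JUNCSL / _VSL * (Caj - Casl) + _JCA_SLMYO / _VSL * (Cai - Casl)
    dy[7] = -J_serca * _VSR / _VMYO + _JCA_SLMYO / _VMYO * (Casl - Cai)
    dy[8] = J_serca - (J_SRleak * _VMYO / _VSR + J_SRCarel)


# which Ca/Na pool each buffer state debits: state index -> pool index
_BUF_POOL = np.array([1, 2, 7, 7, 7, 7, 7, 7, 7, 5, 6, 5, 6, 8], dtype=np.int64)
# buffer states 25..38 in order: NaBj, NaBsl, TnCL, TnCHc, TnCHm, CaM,
# Myoc, Myom, SRB, SLLj, SLLsl, SLHj, SLHsl, Csqnb


# dominant linear relaxation rates (1/ms) of the small compartments, used
# for semi-implicit updates (explicit Euler is unstable for Caj at 0.05 ms)
_B_NAJ = _JNA_JUNCSL / _VJUNC
_B_NASL = (_JNA_JUNCSL + _JNA_SLMYO) / _VSL
_B_CAJ = _JCA_JUNCSL / _VJUNC
_B_CASL = (_JCA_JUNCSL + _JCA_SLMYO) / _VSL


@njit(cache=True)
def _exchange_buffers(y, ginf, gtau, half_dt):
    """Pool<->buffer exchange over ``half_dt``: Rush-Larsen buffer updates
    with the realised uptake debited from the pools.  Sub-cycled at
    <= 0.0125 ms: calsequestrin and the low-affinity sarcolemmal sites
    have equilibrium slopes >> 1, making the explicit coupling unstable
    for larger exchange steps."""
    m_sub = int(np.ceil(half_dt / 0.0125))
    dt_b = half_dt / m_sub
    for _s in range(m_sub):
        _buffers(y, ginf, gtau)
        for k in range(_BUF_LO, _BUF_HI):
            new = ginf[k] + (y[k] - ginf[k]) * np.exp(-dt_b / gtau[k])
            y[_BUF_POOL[k - _BUF_LO]] -= new - y[k]
            y[k] = new
        # free concentrations must stay positive (guards the Nernst logs)
        for i in range(1, 9):
            if y[i] < 1e-10:
                y[i] = 1e-10


@njit(cache=True)
def step(y, p, istim, dt):
    """Strang-style split step: half buffer exchange, flux/gate update,
    half buffer exchange (second-order in the stiff exchange terms)."""
    ginf = np.empty(_N_STATES, dtype=np.float64)
    gtau = np.empty(_N_STATES, dtype=np.float64)
    dy = np.empty(_N_STATES, dtype=np.float64)
    _exchange_buffers(y, ginf, gtau, 0.5 * dt)
    _gates(y, p, ginf, gtau)
    _fluxes(y, p, istim, dy)
    # V, bulk concentrations, RyR: explicit Euler
    y[0] += dt * dy[0]
    y[3] += dt * dy[3]
    y[7] += dt * dy[7]
    y[8] += dt * dy[8]
    for i in range(22, 25):
        y[i] += dt * dy[i]
    # small compartments: trapezoidal semi-implicit in their dominant
    # linear relaxation rate
    y[1] = (y[1] + dt * (dy[1] + 0.5 * _B_NAJ * y[1])) / (1.0 + 0.5 * dt * _B_NAJ)
    y[2] = (y[2] + dt * (dy[2] + 0.5 * _B_NASL * y[2])) / (1.0 + 0.5 * dt * _B_NASL)
    y[5] = (y[5] + dt * (dy[5] + 0.5 * _B_CAJ * y[5])) / (1.0 + 0.5 * dt * _B_CAJ)
    y[6] = (y[6] + dt * (dy[6] + 0.5 * _B_CASL * y[6])) / (1.0 + 0.5 * dt * _B_CASL)
    # HH gates: Rush-Larsen
    for g in range(_GATE_LO, _GATE_HI):
        y[g] = ginf[g] + (y[g] - ginf[g]) * np.exp(-dt / gtau[g])
    _exchange_buffers(y, ginf, gtau, 0.5 * dt)


@njit(cache=True)
def rhs(y, p, istim):
    ginf = np.empty(_N_STATES, dtype=np.float64)
    gtau = np.empty(_N_STATES, dtype=np.float64)
    dy = np.empty(_N_STATES, dtype=np.float64)
    _gates(y, p, ginf, gtau)
    _buffers(y, ginf, gtau)
    _fluxes(y, p, istim, dy)
    for g in range(_GATE_LO, _GATE_HI):
        dy[g] = (ginf[g] - y[g]) / gtau[g]
    for k in range(_BUF_LO, _BUF_HI):
        db = (ginf[k] - y[k]) / gtau[k]
        dy[k] = db
        dy[_BUF_POOL[k - _BUF_LO]] -= db
    return dy


PACE, RECORD = make_driver(step)
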