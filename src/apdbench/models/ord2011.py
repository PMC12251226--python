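"""O'Hara-Rudy (2011) human ventricular cell, endocardial variant.

41-state model: four-compartment Na+/K+/Ca2+ handling (myoplasm,
subspace, NSR, JSR), CaMKII-dependent phosphorylation split for INa,
INaL, Ito, ICaL, Jrel and Jup, Markov-reduced INaCa (Kang-Hilgemann) and
INaK (Smith-Crampin) formulations, and HH gating elsewhere.  Transcribed
from the published equation set with endocardial maximal conductances
(g_Kr = 0.046, g_Ks = 0.0034, g_K1 = 0.1908 mS/uF, P_Ca = 1e-4).

Units: ms, mV, mM, A/F.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from apdbench.models.engine import make_driver

NAME = "ORd"
CELL_TYPE = "endocardial"
CITATION = (
    "O'Hara T, Virag L, Varro A, Rudy Y. Simulation of the undiseased human "
    "cardiac ventricular action potential: model formulation and experimental "
    "validation. PLoS Comput Biol 7(5):e1002061, 2011 (endocardial variant)."
)

STATE_NAMES = (
    "V", "Nai", "Nass", "Ki", "Kss", "Cai", "Cass", "Cansr", "Cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1", "Jrelnp", "Jrelp", "CaMKt",
)

PARAM_NAMES = (
    "g_Na", "g_NaL", "g_to", "P_Ca", "g_Kr", "g_Ks", "g_K1", "g_NaCa",
    "P_NaK", "g_Kb", "P_Nab", "P_Cab", "g_pCa", "Ko", "Nao", "Cao",
)

DEFAULT_PARAMS = {
    "g_Na": 75.0,
    "g_NaL": 0.0075,
    "g_to": 0.02,
    "P_Ca": 0.0001,
    "g_Kr": 0.046,
    "g_Ks": 0.0034,
    "g_K1": 0.1908,
    "g_NaCa": 0.0008,
    "P_NaK": 30.0,
    "g_Kb": 0.003,
    "P_Nab": 3.75e-10,
    "P_Cab": 2.5e-8,
    "g_pCa": 0.0005,
    "Ko": 5.4,
    "Nao": 140.0,
    "Cao": 1.8,
}

CONDUCTANCES = (
    "g_Na", "g_NaL", "g_to", "P_Ca", "g_Kr", "g_Ks", "g_K1", "g_NaCa",
    "P_NaK", "g_Kb", "P_Nab", "P_Cab", "g_pCa",
)
BLOCK_TARGETS = {"ikr": "g_Kr", "ical": "P_Ca"}
CONC_PARAMS = {"Ko": "Ko", "Nao": "Nao", "Cao": "Cao"}

# Published initial conditions (1000 ms cycle length, endocardial).
INITIAL_STATE = np.array([
    -87.5,        # V
    7.268,        # Nai
    7.268,        # Nass
    144.65,       # Ki
    144.65,       # Kss
    8.6e-5,       # Cai
    8.49e-5,      # Cass
    1.61,         # Cansr
    1.56,         # Cajsr
    0.0074621,    # m
    0.692591,     # hf
    0.692574,     # hs
    0.692477,     # j
    0.448501,     # hsp
    0.692413,     # jp
    0.000194015,  # mL
    0.496116,     # hL
    0.265885,     # hLp
    0.00101185,   # a
    0.999542,     # iF
    0.589579,     # iS
    0.000515567,  # ap
    0.999542,     # iFp
    0.641861,     # iSp
    2.43e-9,      # d
    1.0,          # ff
    0.910671,     # fs
    1.0,          # fcaf
    0.99982,      # fcas
    0.999977,     # jca
    0.002749414,  # nca
    1.0,          # ffp
    1.0,          # fcafp
    8.26608e-6,   # xrf
    0.453268,     # xrs
    0.270492,     # xs1
    0.0001963,    # xs2
    0.996801,     # xk1
    2.53943e-5,   # Jrelnp
    3.17262e-7,   # Jrelp
    0.0124065,    # CaMKt
])

STIM_AMPLITUDE = -80.0  # A/F
STIM_DURATION = 0.5     # ms
STIM_CARRIED = "K"

PHASE_BOUNDS = (0.0, 2.0, 500.0)
PHASE_DTS = (0.005, 0.025, 0.1)
RECORD_SUBSTEPS = (10, 2, 1)

_R = 8314.0
_T = 310.0
_F = 96485.0
_RTF = _R * _T / _F

# cell geometry (cm, uF, uL) as published
_L = 0.01
_RAD = 0.0011
_VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
_AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
_ACAP = 2.0 * _AGEO
_VMYO = 0.68 * _VCELL
_VNSR = 0.0552 * _VCELL
_VJSR = 0.0048 * _VCELL
_VSS = 0.02 * _VCELL

_KMCAMK = 0.15
_CAMKO = 0.05
_KMCAM = 0.0015


@njit(cache=True)
def _gates(y, p, ginf, gtau):
    V = y[0]
    Cass = y[6]

    # INa
    ginf[9] = 1.0 / (1.0 + np.exp(-(V + 39.57) / 9.871))
    gtau[9] = 1.0 / (6.765 * np.exp((V + 11.64) / 34.77)
                     + 8.552 * np.exp(-(V + 77.42) / 5.955))
    hss = 1.0 / (1.0 + np.exp((V + 82.90) / 6.086))
    ginf[10] = hss
    gtau[10] = 1.0 / (1.432e-5 * np.exp(-(V + 1.196) / 6.285)
                      + 6.149 * np.exp((V + 0.5096) / 20.27))
    ginf[11] = hss
    ths = 1.0 / (0.009794 * np.exp(-(V + 17.95) / 28.05)
                 + 0.3343 * np.exp((V + 5.730) / 56.66))
    gtau[11] = ths
    ginf[12] = hss
    tj = 2.038 + 1.0 / (0.02136 * np.exp(-(V + 100.6) / 8.281)
                        + 0.3052 * np.exp((V + 0.9941) / 38.45))
    gtau[12] = tj
    ginf[13] = 1.0 / (1.0 + np.exp((V + 89.1) / 6.086))
    gtau[13] = 3.0 * ths
    ginf[14] = hss
    gtau[14] = 1.46 * tj

    # INaL
    ginf[15] = 1.0 / (1.0 + np.exp(-(V + 42.85) / 5.264))
    gtau[15] = gtau[9]
    ginf[16] = 1.0 / (1.0 + np.exp((V + 87.61) / 7.488))
    gtau[16] = 200.0
    ginf[17] = 1.0 / (1.0 + np.exp((V + 93.81) / 7.488))
    gtau[17] = 600.0

    # Ito (endocardial: no epicardial delta on inactivation taus)
    ginf[18] = 1.0 / (1.0 + np.exp(-(V - 14.34) / 14.82))
    gtau[18] = 1.0515 / (1.0 / (1.2089 * (1.0 + np.exp(-(V - 18.4099) / 29.3814)))
                         + 3.5 / (1.0 + np.exp((V + 100.0) / 29.3814)))
    iss = 1.0 / (1.0 + np.exp((V + 43.94) / 5.711))
    tiF = 4.562 + 1.0 / (0.3933 * np.exp(-(V + 100.0) / 100.0)
                         + 0.08004 * np.exp((V + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * np.exp(-(V + 96.52) / 59.05)
                         + 1.780e-8 * np.exp((V + 114.1) / 8.079))
    ginf[19] = iss
    gtau[19] = tiF
    ginf[20] = iss
    gtau[20] = tiS
    ginf[21] = 1.0 / (1.0 + np.exp(-(V - 24.34) / 14.82))
    gtau[21] = gtau[18]
    dti_develop = 1.354 + 1e-4 / (np.exp((V - 167.4) / 15.89)
                                  + np.exp(-(V - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + np.exp((V + 70.0) / 20.0))
    ginf[22] = iss
    gtau[22] = tiF * dti_develop * dti_recover
    ginf[23] = iss
    gtau[23] = tiS * dti_develop * dti_recover

    # ICaL
    ginf[24] = 1.0 / (1.0 + np.exp(-(V + 3.940) / 4.230))
    gtau[24] = 0.6 + 1.0 / (np.exp(-0.05 * (V + 6.0)) + np.exp(0.09 * (V + 14.0)))
    fss = 1.0 / (1.0 + np.exp((V + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(V + 20.0) / 10.0)
                       + 0.0045 * np.exp((V + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (3.5e-5 * np.exp(-(V + 5.0) / 4.0)
                          + 3.5e-5 * np.exp((V + 5.0) / 6.0))
    ginf[25] = fss
    gtau[25] = tff
    ginf[26] = fss
    gtau[26] = tfs
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(V - 4.0) / 7.0)
                         + 0.04 * np.exp((V - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-V / 3.0) + 0.00012 * np.exp(V / 7.0))
    ginf[27] = fss
    gtau[27] = tfcaf
    ginf[28] = fss
    gtau[28] = tfcas
    ginf[29] = fss
    gtau[29] = 75.0
    # nca: d(nca)/dt = anca*k2n - nca*km2n
    jca = y[29]
    km2n = jca * 1.0
    anca = 1.0 / (1000.0 / km2n + (1.0 + 0.002 / Cass) ** 4)
    ginf[30] = anca * 1000.0 / km2n
    gtau[30] = 1.0 / km2n
    ginf[31] = fss
    gtau[31] = 2.5 * tff
    ginf[32] = fss
    gtau[32] = 2.5 * tfcaf

    # IKr
    xrss = 1.0 / (1.0 + np.exp(-(V + 8.337) / 6.789))
    ginf[33] = xrss
    gtau[33] = 12.98 + 1.0 / (0.3652 * np.exp((V - 31.66) / 3.869)
                              + 4.123e-5 * np.exp(-(V - 47.78) / 20.38))
    ginf[34] = xrss
    gtau[34] = 1.865 + 1.0 / (0.06629 * np.exp((V - 34.70) / 7.355)
                              + 1.128e-5 * np.exp(-(V - 29.74) / 25.94))

    # IKs
    xs1ss = 1.0 / (1.0 + np.exp(-(V + 11.60) / 8.932))
    ginf[35] = xs1ss
    gtau[35] = 817.3 + 1.0 / (2.326e-4 * np.exp((V + 48.28) / 17.80)
                              + 0.001292 * np.exp(-(V + 210.0) / 230.0))
    ginf[36] = xs1ss
    gtau[36] = 1.0 / (0.01 * np.exp((V - 50.0) / 20.0)
                      + 0.0193 * np.exp(-(V + 66.54) / 31.0))

    # IK1
    Ko = p[13]
    ginf[37] = 1.0 / (1.0 + np.exp(-(V + 2.5538 * Ko + 144.59)
                                   / (1.5692 * Ko + 3.8115)))
    gtau[37] = 122.2 / (np.exp(-(V + 127.2) / 20.36) + np.exp((V + 236.8) / 69.33))


@njit(cache=True)
def _fluxes(y, p, istim, dy, ginf, gtau):
    """Non-gate derivatives.  Also fills ginf/gtau for the two Jrel gates
    (38, 39), whose targets depend on ICaL computed here."""
    V = y[0]
    Nai = y[1]
    Nass = y[2]
    Ki = y[3]
    Kss = y[4]
    Cai = y[5]
    Cass = y[6]
    Cansr = y[7]
    Cajsr = y[8]
    CaMKt = y[40]

    Ko = p[13]
    Nao = p[14]
    Cao = p[15]

    ENa = _RTF * np.log(Nao / Nai)
    EK = _RTF * np.log(Ko / Ki)
    EKs = _RTF * np.log((Ko + 0.01833 * Nao) / (Ki + 0.01833 * Nai))

    CaMKb = _CAMKO * (1.0 - CaMKt) / (1.0 + _KMCAM / Cass)
    CaMKa = CaMKb + CaMKt
    fp = 1.0 / (1.0 + _KMCAMK / CaMKa)  # phosphorylated fraction

    # INa
    m = y[9]
    h = 0.99 * y[10] + 0.01 * y[11]
    hp = 0.99 * y[10] + 0.01 * y[13]
    INa = p[0] * (V - ENa) * m ** 3 * ((1.0 - fp) * h * y[12] + fp * hp * y[14])

    INaL = p[1] * (V - ENa) * y[15] * ((1.0 - fp) * y[16] + fp * y[17])

    # Ito
    i_ = 1.0 / (1.0 + np.exp((V - 213.6) / 151.2))
    Aif = i_
    Ais = 1.0 - Aif
    ito_i = Aif * y[19] + Ais * y[20]
    ito_ip = Aif * y[22] + Ais * y[23]
    Ito = p[2] * (V - EK) * ((1.0 - fp) * y[18] * ito_i + fp * y[21] * ito_ip)

    # ICaL / ICaNa / ICaK
    vfrt = V / _RTF
    vffrt = V * _F / _RTF
    if abs(V) < 1e-6:
        PhiCaL = 2.0 * _F * (Cass - 0.341 * Cao)
        PhiCaNa = 0.75 * _F * (Nass - Nao)
        PhiCaK = 0.75 * _F * (Kss - Ko)
    else:
        e2 = np.exp(2.0 * vfrt)
        e1 = np.exp(vfrt)
        PhiCaL = 4.0 * vffrt * (Cass * e2 - 0.341 * Cao) / (e2 - 1.0)
        PhiCaNa = vffrt * (0.75 * Nass * e1 - 0.75 * Nao) / (e1 - 1.0)
        PhiCaK = vffrt * (0.75 * Kss * e1 - 0.75 * Ko) / (e1 - 1.0)
    PCa = p[3]
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    Afcaf = 0.3 + 0.6 / (1.0 + np.exp((V - 10.0) / 10.0))
    f_ = 0.6 * y[25] + 0.4 * y[26]
    fca = Afcaf * y[27] + (1.0 - Afcaf) * y[28]
    fp_ = 0.6 * y[31] + 0.4 * y[26]
    fcap = Afcaf * y[32] + (1.0 - Afcaf) * y[28]
    d_ = y[24]
    jca = y[29]
    nca = y[30]
    op = d_ * (f_ * (1.0 - nca) + jca * fca * nca)
    opp = d_ * (fp_ * (1.0 - nca) + jca * fcap * nca)
    fICaLp = fp
    ICaL = (1.0 - fICaLp) * PCa * PhiCaL * op + fICaLp * PCap * PhiCaL * opp
    ICaNa = ((1.0 - fICaLp) * PCaNa * PhiCaNa * op
             + fICaLp * 0.00125 * PCap * PhiCaNa * opp)
    ICaK = ((1.0 - fICaLp) * PCaK * PhiCaK * op
            + fICaLp * 3.574e-4 * PCap * PhiCaK * opp)

    # IKr
    Axrf = 1.0 / (1.0 + np.exp((V + 54.81) / 38.21))
    xr = Axrf * y[33] + (1.0 - Axrf) * y[34]
    rkr = 1.0 / ((1.0 + np.exp((V + 55.0) / 75.0))
                 * (1.0 + np.exp((V - 10.0) / 30.0)))
    IKr = p[4] * np.sqrt(Ko / 5.4) * xr * rkr * (V - EK)

    # IKs
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / Cai) ** 1.4)
    IKs = p[5] * KsCa * y[35] * y[36] * (V - EKs)

    # IK1
    rk1 = 1.0 / (1.0 + np.exp((V + 105.8 - 2.6 * Ko) / 9.493))
    IK1 = p[6] * np.sqrt(Ko) * rk1 * y[37] * (V - EK)

    # INaCa (myoplasmic 80 %, subspace 20 %)
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.1670
    hca = np.exp(qca * vfrt)
    hna = np.exp(qna * vfrt)

    Gncx = p[7]
    KmCaAct = 150.0e-6

    # myoplasmic
    h1 = 1.0 + Nai / kna3 * (1.0 + hna)
    h2 = Nai * hna / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + Nai / kna1 * (1.0 + Nai / kna2)
    h5 = Nai * Nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + Nao / kna3 * (1.0 + 1.0 / hna)
    h8 = Nao / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + Nao / kna1 * (1.0 + Nao / kna2)
    h11 = Nao * Nao / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * Cao * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * Cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / Cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (JncxNa + 2.0 * JncxCa)

    # subspace
    h1 = 1.0 + Nass / kna3 * (1.0 + hna)
    h2 = Nass * hna / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + Nass / kna1 * (1.0 + Nass / kna2)
    h5 = Nass * Nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * Cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo_ss = 1.0 / (1.0 + (KmCaAct / Cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo_ss * (JncxNa + 2.0 * JncxCa)

    # INaK
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p_ = 1899.0
    k3m = 79300.0
    k4p_ = 639.0
    k4m = 40.0
    Knai = 9.073 * np.exp(-0.1550 * vfrt / 3.0)
    Knao = 27.78 * np.exp((1.0 + 0.1550) * vfrt / 3.0)
    Kki = 0.5
    Kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    H = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    P_ = eP / (1.0 + H / Khp + Nai / Knap + Ki / Kxkur)
    a1 = (k1p * (Nai / Knai) ** 3
          / ((1.0 + Nai / Knai) ** 3 + (1.0 + Ki / Kki) ** 2 - 1.0))
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (Nao / Knao) ** 3
          / ((1.0 + Nao / Knao) ** 3 + (1.0 + Ko / Kko) ** 2 - 1.0))
    a3 = (k3p_ * (Ko / Kko) ** 2
          / ((1.0 + Nao / Knao) ** 3 + (1.0 + Ko / Kko) ** 2 - 1.0))
    b3 = k3m * P_ * H / (1.0 + MgATP / Kmgatp)
    a4 = k4p_ * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (Ki / Kki) ** 2
          / ((1.0 + Nai / Knai) ** 3 + (1.0 + Ki / Kki) ** 2 - 1.0))
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    INaK = p[8] * (JnakNa + JnakK)

    # background and pump currents
    xkb = 1.0 / (1.0 + np.exp(-(V - 14.48) / 18.34))
    IKb = p[9] * xkb * (V - EK)
    if abs(V) < 1e-6:
        INab = p[10] * _F * (Nai - Nao)
        ICab = p[11] * 2.0 * _F * (Cai - 0.341 * Cao)
    else:
        e1 = np.exp(vfrt)
        e2 = np.exp(2.0 * vfrt)
        INab = p[10] * vffrt * (Nai * e1 - Nao) / (e1 - 1.0)
        ICab = p[11] * 4.0 * vffrt * (Cai * e2 - 0.341 * Cao) / (e2 - 1.0)
    IpCa = p[12] * Cai / (0.0005 + Cai)

    # diffusion fluxes
    JdiffNa = (Nass - Nai) / 2.0
    JdiffK = (Kss - Ki) / 2.0
    Jdiff = (Cass - Cai) / 0.2

    # SR release (gates 38, 39 driven by ICaL)
    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / Cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / Cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    ginf[38] = Jrel_inf
    gtau[38] = tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrelp_inf = a_relp * (-ICaL) / (1.0 + (1.5 / Cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / Cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    ginf[39] = Jrelp_inf
    gtau[39] = tau_relp
    fJrelp = fp
    Jrel = (1.0 - fJrelp) * y[38] + fJrelp * y[39]

    # SERCA uptake and SR translocation
    Jupnp = 0.004375 * Cai / (Cai + 0.00092)
    Jupp = 2.75 * 0.004375 * Cai / (Cai + 0.00092 - 0.00017)
    fJupp = fp
    Jleak = 0.0039375 * Cansr / 15.0
    Jup = (1.0 - fJupp) * Jupnp + fJupp * Jupp - Jleak
    Jtr = (Cansr - Cajsr) / 100.0

    # membrane potential
    dy[0] = -(INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
              + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + istim)

    # CaMK
    dy[40] = 0.05 * CaMKb * (CaMKb + CaMKt) - 0.00068 * CaMKt

    # ionic concentrations
    cf = _ACAP / (_F * _VMYO)
    cfss = _ACAP / (_F * _VSS)
    dy[1] = -(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) * cf \
        + JdiffNa * _VSS / _VMYO
    dy[2] = -(ICaNa + 3.0 * INaCa_ss) * cfss - JdiffNa
    dy[3] = -(Ito + IKr + IKs + IK1 + IKb + istim - 2.0 * INaK) * cf \
        + JdiffK * _VSS / _VMYO
    dy[4] = -ICaK * cfss - JdiffK

    Bcai = 1.0 / (1.0 + 0.05 * 0.00238 / (0.00238 + Cai) ** 2
                  + 0.07 * 0.0005 / (0.0005 + Cai) ** 2)
    dy[5] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * cf / 2.0
                    - Jup * _VNSR / _VMYO + Jdiff * _VSS / _VMYO)
    Bcass = 1.0 / (1.0 + 0.047 * 0.00087 / (0.00087 + Cass) ** 2
                   + 1.124 * 0.0087 / (0.0087 + Cass) ** 2)
    dy[6] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * cfss / 2.0
                     + Jrel * _VJSR / _VSS - Jdiff)
    dy[7] = Jup - Jtr * _VJSR / _VNSR
    Bcajsr = 1.0 / (1.0 + 10.0 * 0.8 / (0.8 + Cajsr) ** 2)
    dy[8] = Bcajsr * (Jtr - Jrel)


_N_STATES = len(STATE_NAMES)
_GATE_LO = 9
_GATE_HI = 40  # gates are states 9..39; 40 (CaMKt) is Euler


@njit(cache=True)
def step(y, p, istim, dt):
    ginf = np.empty(_N_STATES, dtype=np.float64)
    gtau = np.empty(_N_STATES, dtype=np.float64)
    dy = np.empty(_N_STATES, dtype=np.float64)
    _gates(y, p, ginf, gtau)
    _fluxes(y, p, istim, dy, ginf, gtau)
    for i in range(_GATE_LO):
        y[i] += dt * dy[i]
    y[40] += dt * dy[40]
    for g in range(_GATE_LO, _GATE_HI):
        y[g] = ginf[g] + (y[g] - ginf[g]) * np.exp(-dt / gtau[g])


@njit(cache=True)
def rhs(y, p, istim):
    ginf = np.empty(_N_STATES, dtype=np.float64)
    gtau = np.empty(_N_STATES, dtype=np.float64)
    dy = np.empty(_N_STATES, dtype=np.float64)
    _gates(y, p, ginf, gtau)
    _fluxes(y, p, istim, dy, ginf, gtau)
    for g in range(_GATE_LO, _GATE_HI):
        dy[g] = (ginf[g] - y[g]) / gtau[g]
    return dy


PACE, RECORD = make_driver(step)
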