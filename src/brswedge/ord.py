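"""O'Hara–Rudy (ORd) human ventricular myocyte model, endo/epi variants.

Numba-compiled kernel evaluating the full ionic model for an array of cells.
The kernel returns, for every cell, (a) steady-state value and time constant
for each gating-type state (advanced with Rush–Larsen exponential updates),
(b) time-derivatives of voltage, concentrations and CaMK-trapped fraction
(advanced with forward Euler), and (c) a per-current breakdown.

Conductance multipliers (``gto``, ``gks``, ``gna``) scale the respective
maximal conductances only.  ``ina_tt=True`` replaces the ORd fast-sodium
formulation with the ten Tusscher/Panfilov 2006 one, the substitution widely
used to obtain nominal conduction velocity in tissue simulations; its maximal
conductance ``GNA_TT`` is calibrated against the package's strand-CV contract
(0.6–0.7 m/s at sigma_l = 0.18 S/m).

Units: mV, ms, mM, uA/uF.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# State vector layout (41 states)
# ---------------------------------------------------------------------------
# Euler block (voltage, concentrations, CaMK):
IV, INAI, INASS, IKI, IKSS, ICAI, ICASS, ICANSR, ICAJSR, ICAMKT = range(10)
# Rush-Larsen block (gates + nca + SR-release fluxes):
(IM, IHF, IHS, IJ, IHSP, IJP, IML, IHL, IHLP, IA, IIF, IIS, IAP, IIFP, IISP,
 ID, IFF, IFS, IFCAF, IFCAS, IJCA, IFFP, IFCAFP, INCA,
 IXRF, IXRS, IXS1, IXS2, IXK1, IJRELNP, IJRELP) = range(10, 41)

N_STATES = 41
N_RL = 31          # relaxation states, indices 10..40
N_EULER = 10       # indices 0..9

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr", "CaMKt",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp", "a", "iF", "iS",
    "ap", "iFp", "iSp", "d", "ff", "fs", "fcaf", "fcas", "jca", "ffp",
    "fcafp", "nca", "xrf", "xrs", "xs1", "xs2", "xk1", "Jrelnp", "Jrelp",
)

# Gate states constrained to [0,1] (nca and the Jrel fluxes are not gates).
GATE_MASK = np.zeros(N_STATES, dtype=bool)
GATE_MASK[IM:IFCAFP + 1] = True
GATE_MASK[INCA] = False
GATE_MASK[IXRF:IXK1 + 1] = True

CURRENT_NAMES = (
    "INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr", "IKs", "IK1",
    "INaCa_i", "INaCa_ss", "INaK", "INab", "IKb", "IpCa", "ICab",
)
N_CURRENTS = 16

# Extracellular concentrations (mM) and physical constants
NAO = 140.0
CAO = 1.8
KO = 5.4
RGAS = 8314.0
TEMP = 310.0
FARADAY = 96485.0

# Cell geometry (cm)
_L = 0.01
_RAD = 0.0011
_VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
_AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
ACAP = 2.0 * _AGEO
VMYO = 0.68 * _VCELL
VNSR = 0.0552 * _VCELL
VJSR = 0.0048 * _VCELL
VSS = 0.02 * _VCELL

# ten Tusscher 2006 fast-sodium maximal conductance (published value
# 14.838 mS/uF), recalibrated to 9.6 mS/uF so a 1D strand at
# sigma_l = 0.18 S/m conducts at ~0.65 m/s (see docs/methods.md).
GNA_TT = 9.6

# Passive membrane used for simulated ablation: weak leak toward the
# resting potential (no regenerative currents; the region follows its
# neighbours electrotonically instead of clamping a boundary dipole)
G_PASSIVE = 0.05    # mS/uF
E_PASSIVE = -85.0   # mV


def initial_state() -> np.ndarray:
    """Published ORd resting initial conditions (endo formulation at rest)."""
    y = np.zeros(N_STATES)
    y[IV] = -87.0
    y[INAI] = 7.0
    y[INASS] = 7.0
    y[IKI] = 145.0
    y[IKSS] = 145.0
    y[ICAI] = 1.0e-4
    y[ICASS] = 1.0e-4
    y[ICANSR] = 1.2
    y[ICAJSR] = 1.2
    y[ICAMKT] = 0.0
    for idx in (IHF, IHS, IJ, IHSP, IJP, IHL, IHLP, IIF, IIS, IIFP, IISP,
                IFF, IFS, IFCAF, IFCAS, IJCA, IFFP, IFCAFP, IXK1):
        y[idx] = 1.0
    return y


@njit(cache=True)
def _g_expm1(x):
    """x / (exp(x) - 1): the GHK driving-term factor, finite at x = 0."""
    if abs(x) < 1e-7:
        return 1.0 - 0.5 * x
    return x / (np.exp(x) - 1.0)


@njit(cache=True)
def _cell_kernel(y, epi, gto_s, gks_s, gna_s, ist, ina_tt, xinf, tau, deul, cur):
    """Evaluate the ORd model for one cell.

    Fills ``xinf``/``tau`` (length 31, for states 10..40), ``deul`` (length
    10, d/dt of states 0..9) and ``cur`` (length 16, current breakdown).
    """
    v = y[IV]
    nai = y[INAI]
    nass = y[INASS]
    ki = y[IKI]
    kss = y[IKSS]
    cai = y[ICAI]
    cass = y[ICASS]
    cansr = y[ICANSR]
    cajsr = y[ICAJSR]
    camkt = y[ICAMKT]

    # CaMK
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - camkt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + camkt
    dCaMKt = aCaMK * CaMKb * (CaMKb + camkt) - bCaMK * camkt
    fp = 1.0 / (1.0 + KmCaMK / CaMKa)  # phosphorylated fraction, shared form

    # reversal potentials
    rtf = RGAS * TEMP / FARADAY
    ENa = rtf * np.log(NAO / nai)
    EK = rtf * np.log(KO / ki)
    PKNa = 0.01833
    EKs = rtf * np.log((KO + PKNa * NAO) / (ki + PKNa * nai))
    vfrt = v / rtf
    vffrt = v * FARADAY / rtf

    # ----------------------------------------------------------------- INa
    if ina_tt:
        # ten Tusscher/Panfilov 2006 formulation in the m/hf/j slots
        mss_tt = 1.0 / ((1.0 + np.exp((-56.86 - v) / 9.03)) ** 2)
        am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
        bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0))
        xinf[IM - 10] = mss_tt
        tau[IM - 10] = am * bm
        hss_tt = 1.0 / ((1.0 + np.exp((v + 71.55) / 7.43)) ** 2)
        if v >= -40.0:
            ah = 0.0
            bh = 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
        else:
            ah = 0.057 * np.exp(-(v + 80.0) / 6.8)
            bh = 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v)
        xinf[IHF - 10] = hss_tt
        tau[IHF - 10] = 1.0 / (ah + bh)
        if v >= -40.0:
            aj = 0.0
            bj = 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
        else:
            aj = ((-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
                  * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23))))
            bj = 0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
        xinf[IJ - 10] = hss_tt
        tau[IJ - 10] = 1.0 / (aj + bj)
        # unused ORd inactivation slots relax with their ORd kinetics
        hssp = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))
        ths = 1.0 / (0.009794 * np.exp(-(v + 17.95) / 28.05)
                     + 0.3343 * np.exp((v + 5.730) / 56.66))
        xinf[IHS - 10] = 1.0 / ((1.0 + np.exp((v + 71.55) / 7.43)) ** 2)
        tau[IHS - 10] = ths
        xinf[IHSP - 10] = hssp
        tau[IHSP - 10] = 3.0 * ths
        xinf[IJP - 10] = hss_tt
        tau[IJP - 10] = 1.46 / (ah + bh + 1e-12) if (ah + bh) > 0 else 1.0
        INa = (GNA_TT * gna_s * (y[IM] ** 3) * y[IHF] * y[IJ] * (v - ENa))
    else:
        mss = 1.0 / (1.0 + np.exp(-(v + 39.57) / 9.871))
        tm = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77)
                    + 8.552 * np.exp(-(v + 77.42) / 5.955))
        xinf[IM - 10] = mss
        tau[IM - 10] = tm
        hss = 1.0 / (1.0 + np.exp((v + 82.90) / 6.086))
        thf = 1.0 / (1.432e-5 * np.exp(-(v + 1.196) / 6.285)
                     + 6.149 * np.exp((v + 0.5096) / 20.27))
        ths = 1.0 / (0.009794 * np.exp(-(v + 17.95) / 28.05)
                     + 0.3343 * np.exp((v + 5.730) / 56.66))
        xinf[IHF - 10] = hss
        tau[IHF - 10] = thf
        xinf[IHS - 10] = hss
        tau[IHS - 10] = ths
        jss = hss
        tj = 2.038 + 1.0 / (0.02136 * np.exp(-(v + 100.6) / 8.281)
                            + 0.3052 * np.exp((v + 0.9941) / 38.45))
        xinf[IJ - 10] = jss
        tau[IJ - 10] = tj
        hssp = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))
        xinf[IHSP - 10] = hssp
        tau[IHSP - 10] = 3.0 * ths
        xinf[IJP - 10] = jss
        tau[IJP - 10] = 1.46 * tj
        Ahf = 0.99
        Ahs = 1.0 - Ahf
        h = Ahf * y[IHF] + Ahs * y[IHS]
        hp = Ahf * y[IHF] + Ahs * y[IHSP]
        GNa = 75.0 * gna_s
        INa = (GNa * (v - ENa) * (y[IM] ** 3)
               * ((1.0 - fp) * h * y[IJ] + fp * hp * y[IJP]))

    # ---------------------------------------------------------------- INaL
    mLss = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
    tmL = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77)
                 + 8.552 * np.exp(-(v + 77.42) / 5.955))
    xinf[IML - 10] = mLss
    tau[IML - 10] = tmL
    hLss = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
    thL = 200.0
    xinf[IHL - 10] = hLss
    tau[IHL - 10] = thL
    hLssp = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))
    xinf[IHLP - 10] = hLssp
    tau[IHLP - 10] = 3.0 * thL
    GNaL = 0.0075 * gna_s
    if epi:
        GNaL *= 0.6
    INaL = GNaL * (v - ENa) * y[IML] * ((1.0 - fp) * y[IHL] + fp * y[IHLP])

    # ----------------------------------------------------------------- Ito
    ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + np.exp((v + 100.0) / 29.3814)))
    xinf[IA - 10] = ass
    tau[IA - 10] = ta
    iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
    if epi:
        delta_epi = 1.0 - 0.95 / (1.0 + np.exp((v + 70.0) / 5.0))
    else:
        delta_epi = 1.0
    tiF = 4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * np.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * np.exp((v + 114.1) / 8.079))
    tiF *= delta_epi
    tiS *= delta_epi
    xinf[IIF - 10] = iss
    tau[IIF - 10] = tiF
    xinf[IIS - 10] = iss
    tau[IIS - 10] = tiS
    AiF = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_gate = AiF * y[IIF] + AiS * y[IIS]
    assp = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
    xinf[IAP - 10] = assp
    tau[IAP - 10] = ta
    dti_develop = 1.354 + 1.0e-4 / (np.exp((v - 167.4) / 15.89)
                                    + np.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
    xinf[IIFP - 10] = iss
    tau[IIFP - 10] = dti_develop * dti_recover * tiF
    xinf[IISP - 10] = iss
    tau[IISP - 10] = dti_develop * dti_recover * tiS
    ip_gate = AiF * y[IIFP] + AiS * y[IISP]
    Gto = 0.02 * gto_s
    if epi:
        Gto *= 4.0
    Ito = Gto * (v - EK) * ((1.0 - fp) * y[IA] * i_gate + fp * y[IAP] * ip_gate)

    # ---------------------------------------------------------------- ICaL
    dss = 1.0 / (1.0 + np.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0)) + np.exp(0.09 * (v + 14.0)))
    xinf[ID - 10] = dss
    tau[ID - 10] = td
    fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * np.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * np.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * np.exp((v + 5.0) / 6.0))
    Aff = 0.6
    Afs = 1.0 - Aff
    xinf[IFF - 10] = fss
    tau[IFF - 10] = tff
    xinf[IFS - 10] = fss
    tau[IFS - 10] = tfs
    f = Aff * y[IFF] + Afs * y[IFS]
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0)
                         + 0.04 * np.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0)
                           + 0.00012 * np.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    xinf[IFCAF - 10] = fcass
    tau[IFCAF - 10] = tfcaf
    xinf[IFCAS - 10] = fcass
    tau[IFCAS - 10] = tfcas
    fca = Afcaf * y[IFCAF] + Afcas * y[IFCAS]
    xinf[IJCA - 10] = fcass
    tau[IJCA - 10] = 75.0
    xinf[IFFP - 10] = fss
    tau[IFFP - 10] = 2.5 * tff
    f_p = Aff * y[IFFP] + Afs * y[IFS]
    xinf[IFCAFP - 10] = fcass
    tau[IFCAFP - 10] = 2.5 * tfcaf
    fca_p = Afcaf * y[IFCAFP] + Afcas * y[IFCAS]
    Kmn = 0.002
    k2n = 1000.0
    km2n = y[IJCA] * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)
    # linear relaxation of nca toward anca*k2n/km2n with rate km2n
    xinf[INCA - 10] = anca * k2n / km2n
    tau[INCA - 10] = 1.0 / km2n
    # vffrt/(2*vfrt) = F/2 and vffrt/vfrt = F, so the GHK fluxes reduce to
    # a finite product with x/(exp(x)-1) even at v = 0
    PhiCaL = 4.0 * (FARADAY / 2.0) \
        * (cass * np.exp(2.0 * vfrt) - 0.341 * CAO) * _g_expm1(2.0 * vfrt)
    PhiCaNa = FARADAY * (0.75 * nass * np.exp(vfrt) - 0.75 * NAO) \
        * _g_expm1(vfrt)
    PhiCaK = FARADAY * (0.75 * kss * np.exp(vfrt) - 0.75 * KO) \
        * _g_expm1(vfrt)
    PCa = 0.0001
    if epi:
        PCa *= 1.2
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    nca = y[INCA]
    d_gate = y[ID]
    ICaL = ((1.0 - fp) * PCa * PhiCaL * d_gate * (f * (1.0 - nca) + y[IJCA] * fca * nca)
            + fp * PCap * PhiCaL * d_gate * (f_p * (1.0 - nca) + y[IJCA] * fca_p * nca))
    ICaNa = ((1.0 - fp) * PCaNa * PhiCaNa * d_gate * (f * (1.0 - nca) + y[IJCA] * fca * nca)
             + fp * PCaNap * PhiCaNa * d_gate * (f_p * (1.0 - nca) + y[IJCA] * fca_p * nca))
    ICaK = ((1.0 - fp) * PCaK * PhiCaK * d_gate * (f * (1.0 - nca) + y[IJCA] * fca * nca)
            + fp * PCaKp * PhiCaK * d_gate * (f_p * (1.0 - nca) + y[IJCA] * fca_p * nca))

    # ----------------------------------------------------------------- IKr
    xrss = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * np.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * np.exp(-(v - 29.74) / 25.94))
    xinf[IXRF - 10] = xrss
    tau[IXRF - 10] = txrf
    xinf[IXRS - 10] = xrss
    tau[IXRS - 10] = txrs
    Axrf = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    xr = Axrf * y[IXRF] + Axrs * y[IXRS]
    rkr = 1.0 / ((1.0 + np.exp((v + 55.0) / 75.0))
                 * (1.0 + np.exp((v - 10.0) / 30.0)))
    GKr = 0.046
    if epi:
        GKr *= 1.3
    IKr = GKr * np.sqrt(KO / 5.4) * xr * rkr * (v - EK)

    # ----------------------------------------------------------------- IKs
    xs1ss = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80)
                          + 0.001292 * np.exp(-(v + 210.0) / 230.0))
    xinf[IXS1 - 10] = xs1ss
    tau[IXS1 - 10] = txs1
    xs2ss = xs1ss
    txs2 = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0)
                  + 0.0193 * np.exp(-(v + 66.54) / 31.0))
    xinf[IXS2 - 10] = xs2ss
    tau[IXS2 - 10] = txs2
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034 * gks_s
    if epi:
        GKs *= 1.4
    IKs = GKs * KsCa * y[IXS1] * y[IXS2] * (v - EKs)

    # ----------------------------------------------------------------- IK1
    xk1ss = 1.0 / (1.0 + np.exp(-(v + 2.5538 * KO + 144.59)
                                / (1.5692 * KO + 3.8115)))
    txk1 = 122.2 / (np.exp(-(v + 127.2) / 20.36) + np.exp((v + 236.8) / 69.33))
    xinf[IXK1 - 10] = xk1ss
    tau[IXK1 - 10] = txk1
    rk1 = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * KO) / 9.493))
    GK1 = 0.1908
    if epi:
        GK1 *= 1.2
    IK1 = GK1 * np.sqrt(KO) * rk1 * y[IXK1] * (v - EK)

    # --------------------------------------------------------------- INaCa
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
    KmCaAct = 150.0e-6
    zna = 1.0
    zca = 2.0

    # myoplasmic exchanger
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + NAO / kna1 * (1.0 + NAO / kna2)
    h11 = NAO * NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * CAO * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
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
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    Gncx = 0.0008
    if epi:
        Gncx *= 1.1
    INaCa_i = 0.8 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # subspace exchanger
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # ---------------------------------------------------------------- INaK
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p = 1899.0
    k3m = 79300.0
    k4p = 639.0
    k4m = 40.0
    Knai0 = 9.073
    Knao0 = 27.78
    delta = -0.1550
    Knai = Knai0 * np.exp(delta * vfrt / 3.0)
    Knao = Knao0 * np.exp((1.0 - delta) * vfrt / 3.0)
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
    P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3) / ((1.0 + nai / Knai) ** 3
                                      + (1.0 + ki / Kki) ** 2 - 1.0)
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (NAO / Knao) ** 3) / ((1.0 + NAO / Knao) ** 3
                                      + (1.0 + KO / Kko) ** 2 - 1.0)
    a3 = (k3p * (KO / Kko) ** 2) / ((1.0 + NAO / Knao) ** 3
                                    + (1.0 + KO / Kko) ** 2 - 1.0)
    b3 = (k3m * P * H) / (1.0 + MgATP / Kmgatp)
    a4 = (k4p * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2) / ((1.0 + nai / Knai) ** 3
                                    + (1.0 + ki / Kki) ** 2 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b1 * a4
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    zk = 1.0
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0
    if epi:
        Pnak *= 0.9
    INaK = Pnak * (zna * JnakNa + zk * JnakK)

    # ------------------------------------------------- background / minor
    xkb = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
    GKb = 0.003
    if epi:
        GKb *= 0.6
    IKb = GKb * xkb * (v - EK)
    PNab = 3.75e-10
    INab = PNab * FARADAY * (nai * np.exp(vfrt) - NAO) * _g_expm1(vfrt)
    PCab = 2.5e-8
    ICab = PCab * 4.0 * (FARADAY / 2.0) \
        * (cai * np.exp(2.0 * vfrt) - 0.341 * CAO) * _g_expm1(2.0 * vfrt)
    GpCa = 0.0005
    IpCa = GpCa * cai / (0.0005 + cai)

    # ------------------------------------------------------ fluxes, SR
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    xinf[IJRELNP - 10] = Jrel_inf
    tau[IJRELNP - 10] = tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    xinf[IJRELP - 10] = Jrel_infp
    tau[IJRELP - 10] = tau_relp
    Jrel = (1.0 - fp) * y[IJRELNP] + fp * y[IJRELP]

    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    if epi:
        Jupnp *= 1.3
        Jupp *= 1.3
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fp) * Jupnp + fp * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # ------------------------------------------------------ balance ODEs
    cmdnmax = 0.05
    if epi:
        cmdnmax *= 1.3
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8

    cur[0] = INa
    cur[1] = INaL
    cur[2] = Ito
    cur[3] = ICaL
    cur[4] = ICaNa
    cur[5] = ICaK
    cur[6] = IKr
    cur[7] = IKs
    cur[8] = IK1
    cur[9] = INaCa_i
    cur[10] = INaCa_ss
    cur[11] = INaK
    cur[12] = INab
    cur[13] = IKb
    cur[14] = IpCa
    cur[15] = ICab

    Itot = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
            + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab)

    deul[IV] = -(Itot + ist)
    deul[INAI] = (-(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab)
                  * ACAP / (FARADAY * VMYO) + JdiffNa * VSS / VMYO)
    deul[INASS] = (-(ICaNa + 3.0 * INaCa_ss) * ACAP / (FARADAY * VSS)
                   - JdiffNa)
    deul[IKI] = (-(Ito + IKr + IKs + IK1 + IKb + ist - 2.0 * INaK)
                 * ACAP / (FARADAY * VMYO) + JdiffK * VSS / VMYO)
    deul[IKSS] = -ICaK * ACAP / (FARADAY * VSS) - JdiffK
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / ((kmcmdn + cai) ** 2)
                  + trpnmax * kmtrpn / ((kmtrpn + cai) ** 2))
    deul[ICAI] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i)
                         * ACAP / (2.0 * FARADAY * VMYO)
                         - Jup * VNSR / VMYO + Jdiff * VSS / VMYO)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / ((KmBSR + cass) ** 2)
                   + BSLmax * KmBSL / ((KmBSL + cass) ** 2))
    deul[ICASS] = Bcass * (-(ICaL - 2.0 * INaCa_ss)
                           * ACAP / (2.0 * FARADAY * VSS)
                           + Jrel * VJSR / VSS - Jdiff)
    deul[ICANSR] = Jup - Jtr * VJSR / VNSR
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / ((kmcsqn + cajsr) ** 2))
    deul[ICAJSR] = Bcajsr * (Jtr - Jrel)
    deul[ICAMKT] = dCaMKt


@njit(cache=True)
def step_cells(Y, epi, gto, gks, gna, passive, istim, dt, ina_tt):
    """Advance all cells by one time step of ``dt`` ms, in place.

    Rush–Larsen exponential update for the 31 relaxation states, forward
    Euler for voltage / concentrations / CaMKt.  Passive (ablated) cells
    keep a leak membrane holding the resting potential; their gating states
    are frozen.
    """
    n = Y.shape[0]
    xinf = np.empty(N_RL)
    tau = np.empty(N_RL)
    deul = np.empty(N_EULER)
    cur = np.empty(N_CURRENTS)
    for c in range(n):
        if passive[c]:
            v = Y[c, IV]
            Y[c, IV] = v + dt * (-(G_PASSIVE * (v - E_PASSIVE)) - istim[c])
            continue
        _cell_kernel(Y[c], epi[c], gto[c], gks[c], gna[c], istim[c],
                     ina_tt, xinf, tau, deul, cur)
        for s in range(N_EULER):
            Y[c, s] += dt * deul[s]
        for g in range(N_RL):
            x = Y[c, 10 + g]
            Y[c, 10 + g] = xinf[g] + (x - xinf[g]) * np.exp(-dt / tau[g])


def derivatives(state, epi, scales=(1.0, 1.0, 1.0), i_stim=0.0,
                ina_tt=False):
    """Time-derivative of one cell state plus per-current breakdown.

    Parameters
    ----------
    state : array-like, shape (41,)
    epi : bool — epicardial (True) or endocardial (False) variant.
    scales : (gto_scale, gks_scale, gna_scale)
    i_stim : stimulus current in uA/uF (negative = depolarizing).

    Returns
    -------
    dydt : ndarray (41,)
    currents : dict name -> value (uA/uF)
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},)")
    if not np.all(np.isfinite(y)):
        bad = int(np.flatnonzero(~np.isfinite(y))[0])
        raise ValueError(f"non-finite state variable {STATE_NAMES[bad]!r}")
    xinf = np.empty(N_RL)
    tau = np.empty(N_RL)
    deul = np.empty(N_EULER)
    cur = np.empty(N_CURRENTS)
    gto_s, gks_s, gna_s = scales
    _cell_kernel(y, bool(epi), float(gto_s), float(gks_s), float(gna_s),
                 float(i_stim), bool(ina_tt), xinf, tau, deul, cur)
    dydt = np.empty(N_STATES)
    dydt[:N_EULER] = deul
    dydt[N_EULER:] = (xinf - y[N_EULER:]) / tau
    return dydt, dict(zip(CURRENT_NAMES, cur))
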