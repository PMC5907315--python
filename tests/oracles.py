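"""Independent symbolic transcription of the published flux expressions.

Every formula below is typed directly from the source tables as a sympy
expression and evaluated with 40-digit mpmath arithmetic.  It shares no
code with the package's flux functions, so agreement at 1e-12 relative
tolerance is a genuine dual-route check.
"""

import mpmath
import sympy as sp

mpmath.mp.dps = 40

(CAC, CAM, PSI, NADHM, NAD, ADPM, ADPI, ATPI, HM, PTPL, PTPH,
 IP3, CAER, H) = sp.symbols(
    "CAC CAM PSI NADHM NAD ADPM ADPI ATPI HM PTPL PTPH IP3 CAER H")

# --- mitochondrial Ca2+ handling -------------------------------------------
MWC_NUM = (CAC / 6) * (1 + CAC / 6) ** 3
MWC_DEN = (1 + CAC / 6) ** 4 + 50 / (1 + CAC / sp.Rational(38, 100)) ** sp.Rational(28, 10)
MWC = MWC_NUM / MWC_DEN
VDUNI = (PSI - 91) / sp.Rational(1335, 100)
J_UNI = (300 * VDUNI * (MWC - CAM * sp.exp(-VDUNI))
         / (1 - sp.exp(-VDUNI))) * (1 - PTPH)
J_NC = (3 * sp.exp((PSI - 91) / sp.Rational(534, 10))
        * (1 / (1 + sp.Rational(94, 300) ** 2))
        * (1 / (1 + sp.Rational(3, 1000) * 1000 / CAM))) * (1 - PTPH)

# --- respiration ------------------------------------------------------------
ARES = sp.Float("1.35e18", 40) * sp.sqrt(NADHM) / sp.sqrt(NAD)
VDRES = sp.exp(sp.Rational(191, 1000) * PSI)
J_RES_H = 360 * sp.Rational(4, 10) * (
    (sp.Float("7e-7", 40) + sp.Float("2.54e-3", 40) * ARES
     - sp.Rational(639, 1000) * VDRES)
    / (sp.Float("7.58e13", 40) + sp.Float("1.57e-4", 40) * ARES
       + (sp.Rational(173, 100) + ARES * sp.Float("1.06e-17", 40)) * VDRES))
J_O = 30 * sp.Rational(4, 10) * (
    (ARES * sp.Float("2.55e-3", 40) + ARES * sp.Float("2.00e-5", 40)
     - sp.Rational(639, 1000) * VDRES + VDRES * ARES * sp.Float("8.63e-18", 40))
    / ((1 + ARES * sp.Float("2.08e-18", 40)) * sp.Float("7.54e13", 40)
       + (sp.Rational(173, 100) + sp.Float("1.06e-17", 40) * ARES) * VDRES))

# --- F0/F1 ATPase ------------------------------------------------------------
ATPM = 12 * 1000 / 1000 - ADPM
ADPMF = sp.Rational(8, 10) * ADPM
AF1 = sp.Float("1.71e9", 40) * ATPM / (ADPMF * 20)
VDF1 = sp.exp(sp.Rational(112, 1000) * PSI)
F_DEN = (sp.Float("1e7", 40) + sp.Rational(135, 1000) * AF1) * 275 \
    + (sp.Rational(774, 100) + sp.Float("6.65e-8", 40) * AF1) * VDF1
J_P_F1 = -60 * sp.Rational(7, 10) * (
    (sp.Rational(105, 10) * AF1 - 166 * VDF1
     + sp.Float("4.85e-12", 40) * AF1 * VDF1) / F_DEN)
J_H_F1 = -180 * sp.Rational(7, 10) * (
    (sp.Rational(213, 1000) + sp.Rational(105, 10) * AF1 - 169 * VDF1) / F_DEN)

# --- leak, ANT ---------------------------------------------------------------
J_H_LEAK = sp.Rational(2, 10) * (PSI + sp.Rational(246, 10))
ADPIF = sp.Rational(3, 10) * ADPI
ADP3M = sp.Rational(45, 100) * ADPMF
ADP3I = sp.Rational(45, 100) * ADPIF
ATP4I = sp.Rational(5, 100) * ATPI
ATP4M = sp.Rational(5, 100) * ATPM
ANT1 = (ATP4I / ADP3I) * (ADP3M / ATP4M) * sp.exp(-PSI / sp.Rational(267, 10))
ANT2 = 1 + (ATP4I / ADP3I) * sp.exp(-PSI / sp.Rational(534, 10))
ANT3 = 1 + (ADP3M / ATP4M)
J_ANT = 900 * (1 - ANT1) / (ANT2 * ANT3)

# --- glycolysis, hydrolysis, PDH coupling ------------------------------------
GLC = 1
J_GLY = (sp.Rational(1233, 10) * (1 + sp.Rational(166, 100) * GLC)
         * (GLC * ATPI) * sp.Rational(249, 10000)) / (
    1 + 4 * ATPI + (1 + sp.Rational(283, 100) * ATPI) * sp.Rational(13, 10) * GLC
    + (1 + sp.Rational(266, 100) * ATPI) * sp.Rational(16, 100) * GLC ** 2)
J_HYD = 41 * ATPI + sp.Rational(301, 10) / (
    1 + (sp.Rational(87, 10) / GLC) ** sp.Rational(27, 10))
F_PDH = 1 / (1 + sp.Rational(11, 10)
             * (1 + 15 / (1 + CAM / sp.Rational(5, 100)) ** 2))
J_RED = 20 + sp.Float("6.3944", 40) * F_PDH * J_GLY
J_P_TCA = sp.Rational(20, 3) + sp.Rational(84, 100) * F_PDH * J_GLY

# --- ER handling -------------------------------------------------------------
J_SERCA = 110 * CAC ** 2 / (sp.Rational(4, 10) ** 2 + CAC ** 2)
J_ER_OUT = (3000 * (IP3 / (IP3 + sp.Rational(25, 100))) ** 3
            * (CAC / (CAC + 1)) ** 3 * H ** 3
            + sp.Rational(1, 10)) * (CAER - CAC)

# --- PTP fluxes --------------------------------------------------------------
J_PTP_H = 3 * PTPL * PSI * (
    HM - sp.Float("3.98e-8", 40) * sp.exp(-sp.Rational(37434, 1000) * PSI)
    / (1 - sp.exp(-sp.Rational(37434, 1000) * PSI)))
J_PTP_CA = sp.Rational(4, 10) * PTPL * J_UNI * (1 - 2 * PTPH)

_ARGS = (CAC, CAM, PSI, NADHM, NAD, ADPM, ADPI, ATPI, HM, PTPL, PTPH,
         IP3, CAER, H)

EXPRESSIONS = {
    "J_uni": J_UNI,
    "J_nc": J_NC,
    "J_res_H": J_RES_H,
    "J_o": J_O,
    "J_p_F1": J_P_F1,
    "J_H_F1": J_H_F1,
    "J_H_leak": J_H_LEAK,
    "J_ANT": J_ANT,
    "J_p_TCA": J_P_TCA,
    "J_red": J_RED,
    "J_gly_total": J_GLY,
    "J_hyd": J_HYD,
    "J_serca": J_SERCA,
    "J_er_out": J_ER_OUT,
    "J_PTP_H": J_PTP_H,
    "J_PTP_Ca": J_PTP_CA,
    "f_PDH": F_PDH,
}

_FUNCS = {name: sp.lambdify(_ARGS, expr, modules="mpmath")
          for name, expr in EXPRESSIONS.items()}


def reference_fluxes(state: dict) -> dict:
    """Evaluate every published flux expression at ``state`` (40 digits)."""
    args = [mpmath.mpf(repr(float(state[k]))) for k in
            ("CAC", "CAM", "PSI", "NADH_m", "NAD", "ADP_m", "ADP_i",
             "ATP_i", "H_M", "PTPl", "PTPh", "IP3", "CAER", "h")]
    return {name: float(fn(*args)) for name, fn in _FUNCS.items()}
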