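"""Right-hand side and Jacobian of the 8-ODE thin-film clotting model.

Core dynamic species (all uM):

====  ==========  =====================================================
idx   symbol      meaning
====  ==========  =====================================================
0     TF*         active tissue factor (TF:VIIa) in the film
1     IXa         factor IXa (acts within intrinsic tenase)
2     Xa          factor Xa (acts within prothrombinase)
3     XIa         factor XIa on activated platelets
4     IIa         free (unbound) thrombin
5     IIa.E       thrombin bound to the weak fibrin E-domain site
6     IIa.G       thrombin bound to the high-affinity gamma'-chain site
7     Fn          fibrin monomer formed (non-decreasing)
====  ==========  =====================================================

Three cumulative quadratures ride along for bookkeeping and are not part
of the core system: thrombin produced (8), thrombin lost to inactivation
(9) and thrombin lost to elution (10).  By construction

    produced = free + bound(E) + bound(G) + inactivated + eluted

at every instant, which the simulator verifies as a mass-balance check.
Prothrombin fragment F1.2 is released one-for-one with thrombin
production, so the produced quadrature doubles as cumulative F1.2.

Binding sites are generated in proportion to fibrin: the total site
concentration for site s is ``sites_per_fibrin_s * Fn``, and thrombin
adsorbs reversibly (kf, kr).  Bound thrombin is protected from both
inactivation and elution, which is what lets fibrin act as a thrombin
buffer ("antithrombin-I" activity).
"""

from __future__ import annotations

import numpy as np

# state indices
I_TF, I_IXA, I_XA, I_XIA, I_IIA, I_BE, I_BG, I_FN = range(8)
I_CUM_PROD, I_CUM_INACT, I_CUM_ELUT = 8, 9, 10
N_STATE = 11

STATE_NAMES = (
    "TFstar",
    "IXa",
    "Xa",
    "XIa",
    "IIa_free",
    "IIa_weakE",
    "IIa_gamma",
    "fibrin",
    "IIa_produced",
    "IIa_inactivated",
    "IIa_eluted",
)

# packed-parameter indices (see RateSet.packed)
_R1, _R2, _R3, _R4, _R5, _R6, _R7 = range(7)
_KTF, _KIXA, _KXA, _KXIA, _KIIA, _KIN, _KEL2 = range(7, 14)
_KFW, _KRW, _SW, _KFG, _KRG, _SG = range(14, 20)


def rhs(y: np.ndarray, t: float, p: np.ndarray) -> np.ndarray:
    """Time derivative of the state vector (odeint calling convention)."""
    tf = y[I_TF]
    ixa = y[I_IXA]
    xa = y[I_XA]
    xia = y[I_XIA]
    iia = y[I_IIA]
    be = y[I_BE]
    bg = y[I_BG]
    fn = y[I_FN]

    bind_w = p[_KFW] * iia * (p[_SW] * fn - be) - p[_KRW] * be
    bind_g = p[_KFG] * iia * (p[_SG] * fn - bg) - p[_KRG] * bg
    prod = p[_R4] * xa

    out = np.empty(N_STATE)
    out[I_TF] = -p[_KTF] * tf
    out[I_IXA] = p[_R2] * tf + p[_R7] * xia - p[_KIXA] * ixa
    out[I_XA] = p[_R1] * tf + p[_R3] * ixa - p[_KXA] * xa
    out[I_XIA] = p[_R6] * iia - p[_KXIA] * xia
    out[I_IIA] = prod - p[_KIIA] * iia - bind_w - bind_g
    out[I_BE] = bind_w
    out[I_BG] = bind_g
    out[I_FN] = p[_R5] * iia
    out[I_CUM_PROD] = prod
    out[I_CUM_INACT] = p[_KIN] * iia
    out[I_CUM_ELUT] = p[_KEL2] * iia
    return out


def jacobian(y: np.ndarray, t: float, p: np.ndarray) -> np.ndarray:
    """Analytic Jacobian d(rhs)/dy; the binding terms make the system stiff."""
    iia = y[I_IIA]
    be = y[I_BE]
    bg = y[I_BG]
    fn = y[I_FN]

    dbw_di = p[_KFW] * (p[_SW] * fn - be)
    dbw_de = -p[_KFW] * iia - p[_KRW]
    dbw_df = p[_KFW] * iia * p[_SW]
    dbg_di = p[_KFG] * (p[_SG] * fn - bg)
    dbg_dg = -p[_KFG] * iia - p[_KRG]
    dbg_df = p[_KFG] * iia * p[_SG]

    J = np.zeros((N_STATE, N_STATE))
    J[I_TF, I_TF] = -p[_KTF]
    J[I_IXA, I_TF] = p[_R2]
    J[I_IXA, I_XIA] = p[_R7]
    J[I_IXA, I_IXA] = -p[_KIXA]
    J[I_XA, I_TF] = p[_R1]
    J[I_XA, I_IXA] = p[_R3]
    J[I_XA, I_XA] = -p[_KXA]
    J[I_XIA, I_IIA] = p[_R6]
    J[I_XIA, I_XIA] = -p[_KXIA]
    J[I_IIA, I_XA] = p[_R4]
    J[I_IIA, I_IIA] = -p[_KIIA] - dbw_di - dbg_di
    J[I_IIA, I_BE] = -dbw_de
    J[I_IIA, I_BG] = -dbg_dg
    J[I_IIA, I_FN] = -dbw_df - dbg_df
    J[I_BE, I_IIA] = dbw_di
    J[I_BE, I_BE] = dbw_de
    J[I_BE, I_FN] = dbw_df
    J[I_BG, I_IIA] = dbg_di
    J[I_BG, I_BG] = dbg_dg
    J[I_BG, I_FN] = dbg_df
    J[I_FN, I_IIA] = p[_R5]
    J[I_CUM_PROD, I_XA] = p[_R4]
    J[I_CUM_INACT, I_IIA] = p[_KIN]
    J[I_CUM_ELUT, I_IIA] = p[_KEL2]
    return J


def initial_state(tf0_uM: float) -> np.ndarray:
    """All species start at zero except active TF laid down on the wall."""
    y0 = np.zeros(N_STATE)
    y0[I_TF] = tf0_uM
    return y0
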