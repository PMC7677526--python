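"""Closed-loop lumped-parameter (0D) circulation.

Eight compartments: four elastance heart chambers (LA, LV, RA, RV), a
systemic arterial (aortic windkessel) and venous compartment, and a
pulmonary arterial and venous compartment.  Heart valves are ideal diodes
in series with a resistance.  Respiration drives periodic intrathoracic
and abdominal pressure offsets; the lung-volume waveform feeds the
pulmonary stretch reflex.

Chamber pressure follows a time-varying elastance with an exponential
diastolic branch::

    P_tm(V, t) = E(t) (V - V_u) + (1 - a(t)) A (exp(B (V - V_u)) - 1)
    E(t)       = E_min + a(t) (scale * E_max - E_min)

where ``a(t)`` is the normalized activation (0 in diastole, 1 at peak
systole) driven by the time since the last sinoatrial beat, and ``scale``
is the autonomic contractility factor.  Units throughout: mmHg, mL, s.

Volumes are the integrated states; the sum of all eight volume derivatives
is identically zero (closed loop, mass conservation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "ChamberParams",
    "ValveParams",
    "RespirationState",
    "chamber_elastance",
    "chamber_pressure",
    "valve_flow",
    "respiration_drive",
    "cardiovascular_derivatives",
    "default_cv_params",
    "NCV",
    "CV_AUX_COLS",
]

# ---------------------------------------------------------------------------
# packed circulation parameter vector
# ---------------------------------------------------------------------------
# chambers: E_max, E_min, V_u, A_ed, B_ed  (lv, rv, la, ra)
LV_EMAX, LV_EMIN, LV_VU, LV_A, LV_B = 0, 1, 2, 3, 4
RV_EMAX, RV_EMIN, RV_VU, RV_A, RV_B = 5, 6, 7, 8, 9
LA_EMAX, LA_EMIN, LA_VU, LA_A, LA_B = 10, 11, 12, 13, 14
RA_EMAX, RA_EMIN, RA_VU, RA_A, RA_B = 15, 16, 17, 18, 19
# valves
R_MV, R_AV, R_TV, R_PVALVE = 20, 21, 22, 23
# vasculature
C_AO, VU_AO, C_SV, R_VR, C_PA, VU_PA, R_PA, C_PV, VU_PV, R_PVN = (
    24, 25, 26, 27, 28, 29, 30, 31, 32, 33,
)
ABD_FRAC = 34      # fraction of abdominal pressure felt by systemic veins
# beat timing (activation waveform descriptors)
AV_DELAY0 = 35     # atrio-ventricular delay at reference RR, s
TSYS0 = 36         # ventricular systole duration at reference RR, s
TAS0 = 37          # atrial systole duration at reference RR, s
RR_REF = 38        # reference RR interval, s
# respiration
PIT0 = 39          # end-expiratory intrathoracic pressure, mmHg
PIT_AMP = 40       # inspiratory intrathoracic swing, mmHg
PABD0 = 41         # baseline abdominal pressure, mmHg
PABD_AMP = 42      # inspiratory abdominal swing, mmHg
FRC = 43           # functional residual capacity, L
VT_REST = 44       # resting tidal volume, L
VT_SLOPE = 45      # tidal-volume increase at full exercise intensity, L
TRESP_REST = 46    # resting respiratory period, s
TRESP_PEAK = 47    # respiratory period at peak exercise, s
INIT_PSV = 48      # nominal systemic venous filling pressure (sets blood volume), mmHg
INIT_PPV = 49      # nominal pulmonary venous filling pressure, mmHg
ACT_EXP = 50       # RR-exponent of systole/AV-delay duration scaling
TAU_REL = 51       # ventricular relaxation time constant, s
LUSI = 52          # lusitropic speed-up of relaxation per unit contractility
R_CHAR = 53        # aortic characteristic resistance, mmHg.s/mL
NCVP = 54

NCV = 8  # compartment count: V_la, V_lv, V_ra, V_rv, V_ao, V_sv, V_pa, V_pv
IV_LA, IV_LV, IV_RA, IV_RV, IV_AO, IV_SV, IV_PA, IV_PV = range(8)

# auxiliary (derived) output layout of cv_rhs
CV_AUX_COLS = [
    "P_la", "P_lv", "P_ra", "P_rv", "P_ao", "P_sv", "P_pa", "P_pv",
    "Q_mv", "Q_av", "Q_tv", "Q_pval", "Q_as", "Q_vr", "Q_pa", "Q_pvn",
    "act_v", "act_a",
]
NAUX_CV = len(CV_AUX_COLS)


def default_cv_params() -> np.ndarray:
    """Healthy-cohort circulation parameters (starting calibration)."""
    p = np.zeros(NCVP)
    # left ventricle; diastolic branch anchored to the cohort
    # end-diastolic pressure/volume working points
    p[LV_EMAX], p[LV_EMIN], p[LV_VU] = 2.6, 0.055, 10.0
    p[LV_A], p[LV_B] = 0.0067, 0.042
    # right ventricle
    p[RV_EMAX], p[RV_EMIN], p[RV_VU] = 0.80, 0.015, 10.0
    p[RV_A], p[RV_B] = 0.50, 0.011
    # left atrium
    p[LA_EMAX], p[LA_EMIN], p[LA_VU] = 0.35, 0.16, 3.0
    p[LA_A], p[LA_B] = 0.0, 0.0
    # right atrium
    p[RA_EMAX], p[RA_EMIN], p[RA_VU] = 0.20, 0.10, 3.0
    p[RA_A], p[RA_B] = 0.0, 0.0
    # valves
    p[R_MV], p[R_AV], p[R_TV], p[R_PVALVE] = 0.006, 0.004, 0.006, 0.004
    # systemic circulation
    p[C_AO], p[VU_AO] = 2.6, 50.0
    p[C_SV], p[R_VR] = 80.0, 0.030
    # pulmonary circulation
    p[C_PA], p[VU_PA] = 5.0, 30.0
    p[R_PA] = 0.08
    p[C_PV], p[VU_PV] = 25.0, 60.0
    p[R_PVN] = 0.015
    p[ABD_FRAC] = 0.3
    # beat timing
    p[AV_DELAY0], p[TSYS0], p[TAS0], p[RR_REF] = 0.12, 0.30, 0.15, 0.85
    # respiration
    p[PIT0], p[PIT_AMP] = -2.0, 2.5
    p[PABD0], p[PABD_AMP] = 2.0, 1.0
    p[FRC], p[VT_REST], p[VT_SLOPE] = 2.3, 0.5, 1.5
    p[TRESP_REST], p[TRESP_PEAK] = 5.0, 1.2
    p[INIT_PSV], p[INIT_PPV] = 3.15, 6.5
    p[ACT_EXP] = 0.5
    p[TAU_REL], p[LUSI] = 0.11, 3.0
    p[R_CHAR] = 0.015
    return p


# ---------------------------------------------------------------------------
# elemental operations (njit kernels shared with the engine)
# ---------------------------------------------------------------------------
@njit(cache=True)
def _activation(t: float, dur: float) -> float:
    """Normalized half-sine-squared activation in [0, 1]."""
    if t < 0.0 or t >= dur or dur <= 0.0:
        return 0.0
    s = math.sin(math.pi * t / dur)
    return s * s


@njit(cache=True)
def _activation_relax(t: float, dur: float, tau_rel: float) -> float:
    """Ventricular activation: sin^2 upstroke to the mid-systolic peak,
    then exponential isovolumic-relaxation tail with time constant
    ``tau_rel``.  The tail is an absolute time cost, so it consumes a
    larger fraction of the cycle at short RR intervals."""
    if t < 0.0 or dur <= 0.0:
        return 0.0
    half = 0.5 * dur
    if t < half:
        s = math.sin(math.pi * t / dur)
        return s * s
    a = math.exp(-(t - half) / tau_rel)
    return a


@njit(cache=True)
def _elastance(act: float, e_max: float, e_min: float, scale: float) -> float:
    return e_min + act * (scale * e_max - e_min)


@njit(cache=True)
def _chamber_p(
    v: float, act: float, e_max: float, e_min: float, v_u: float,
    a_ed: float, b_ed: float, scale: float,
) -> float:
    """Transmural chamber pressure at volume v and activation act."""
    dv = v - v_u
    p = _elastance(act, e_max, e_min, scale) * dv
    if a_ed > 0.0 and dv > 0.0:
        p += (1.0 - act) * a_ed * (math.exp(b_ed * dv) - 1.0)
    return p


@njit(cache=True)
def _diode_flow(p_up: float, p_down: float, r: float) -> float:
    dp = p_up - p_down
    if dp <= 0.0:
        return 0.0
    return dp / r


@njit(cache=True)
def _resp_waves(phase: float, intensity: float, p: np.ndarray):
    """(P_it, P_abd, V_L, T_resp) at a given respiratory phase in [0,1)."""
    s = math.sin(math.pi * phase)
    v = s * s
    vt = p[VT_REST] + p[VT_SLOPE] * intensity
    p_it = p[PIT0] - p[PIT_AMP] * math.sqrt(vt / p[VT_REST]) * v
    p_abd = p[PABD0] + p[PABD_AMP] * v
    v_l = p[FRC] + vt * v
    t_resp = p[TRESP_REST] - (p[TRESP_REST] - p[TRESP_PEAK]) * intensity
    return p_it, p_abd, v_l, t_resp


@njit(cache=True)
def cv_rhs(
    vols: np.ndarray,
    t_clock: float,
    rr: float,
    p_it: float,
    p_abd: float,
    c_lv_scale: float,
    c_rv_scale: float,
    r_as: float,
    v_usv: float,
    cao_scale: float,
    p_pump: float,
    p: np.ndarray,
    dvdt: np.ndarray,
    aux: np.ndarray,
):
    """Volume derivatives and derived pressures/flows of the circulation.

    ``t_clock`` is the time since the last SA beat, ``rr`` the latched RR
    interval.  Controlled quantities (contractility scales, systemic
    resistance, venous unstressed volume, aortic compliance scale) are
    supplied by the autonomic effectors.
    """
    sq = (rr / p[RR_REF]) ** p[ACT_EXP]
    act_a = _activation(t_clock, p[TAS0] * sq)
    # lusitropy: adrenergic drive shortens relaxation
    tau_rel = p[TAU_REL] * sq ** 0.5 / (1.0 + p[LUSI] * (c_lv_scale - 1.0))
    act_v = _activation_relax(t_clock - p[AV_DELAY0] * sq, p[TSYS0] * sq, tau_rel)

    p_la = _chamber_p(vols[IV_LA], act_a, p[LA_EMAX], p[LA_EMIN], p[LA_VU],
                      p[LA_A], p[LA_B], 1.0) + p_it
    p_lv = _chamber_p(vols[IV_LV], act_v, p[LV_EMAX], p[LV_EMIN], p[LV_VU],
                      p[LV_A], p[LV_B], c_lv_scale) + p_it
    p_ra = _chamber_p(vols[IV_RA], act_a, p[RA_EMAX], p[RA_EMIN], p[RA_VU],
                      p[RA_A], p[RA_B], 1.0) + p_it
    p_rv = _chamber_p(vols[IV_RV], act_v, p[RV_EMAX], p[RV_EMIN], p[RV_VU],
                      p[RV_A], p[RV_B], c_rv_scale) + p_it

    # windkessel pressure; the reported aortic (root) pressure adds the
    # characteristic-resistance drop during ejection
    p_wk = (vols[IV_AO] - p[VU_AO]) / (p[C_AO] * cao_scale)
    # muscle pump: rhythmic compression of the veins of the exercising
    # limbs, expressed as a mean venous pressurization
    p_sv = (vols[IV_SV] - v_usv) / p[C_SV] + p[ABD_FRAC] * p_abd + p_pump
    p_pa = (vols[IV_PA] - p[VU_PA]) / p[C_PA] + p_it
    p_pv = (vols[IV_PV] - p[VU_PV]) / p[C_PV] + p_it

    q_mv = _diode_flow(p_la, p_lv, p[R_MV])
    q_av = _diode_flow(p_lv, p_wk, p[R_AV] + p[R_CHAR])
    q_tv = _diode_flow(p_ra, p_rv, p[R_TV])
    q_pval = _diode_flow(p_rv, p_pa, p[R_PVALVE])
    p_ao = p_wk + p[R_CHAR] * q_av
    q_as = (p_wk - p_sv) / r_as
    q_vr = (p_sv - p_ra) / p[R_VR]
    q_pa = (p_pa - p_pv) / p[R_PA]
    q_pvn = (p_pv - p_la) / p[R_PVN]

    dvdt[IV_LA] = q_pvn - q_mv
    dvdt[IV_LV] = q_mv - q_av
    dvdt[IV_AO] = q_av - q_as
    dvdt[IV_SV] = q_as - q_vr
    dvdt[IV_RA] = q_vr - q_tv
    dvdt[IV_RV] = q_tv - q_pval
    dvdt[IV_PA] = q_pval - q_pa
    dvdt[IV_PV] = q_pa - q_pvn

    aux[0] = p_la
    aux[1] = p_lv
    aux[2] = p_ra
    aux[3] = p_rv
    aux[4] = p_ao
    aux[5] = p_sv
    aux[6] = p_pa
    aux[7] = p_pv
    aux[8] = q_mv
    aux[9] = q_av
    aux[10] = q_tv
    aux[11] = q_pval
    aux[12] = q_as
    aux[13] = q_vr
    aux[14] = q_pa
    aux[15] = q_pvn
    aux[16] = act_v
    aux[17] = act_a


# ---------------------------------------------------------------------------
# public (validated) operations and domain types
# ---------------------------------------------------------------------------
@dataclass
class ChamberParams:
    """Time-varying elastance chamber.

    ``A_ed``/``B_ed`` shape the exponential diastolic branch of the
    pressure-volume relation; the activation waveform is half-sine-squared
    with duration scaling as sqrt(RR / RR_ref).
    """

    E_max: float          # mmHg/mL
    E_min: float          # mmHg/mL
    V_unstressed: float   # mL
    A_ed: float = 0.0     # mmHg
    B_ed: float = 0.0     # 1/mL
    systole_duration: float = 0.30  # s at reference RR
    rr_ref: float = 0.85  # s

    def __post_init__(self):
        if not (self.E_max >= self.E_min > 0):
            raise ValueError("require E_max >= E_min > 0")
        if self.V_unstressed < 0:
            raise ValueError("V_unstressed must be >= 0")


@dataclass
class ValveParams:
    """Ideal diode in series with an opening resistance."""

    R_open: float  # mmHg.s/mL

    def __post_init__(self):
        if self.R_open <= 0:
            raise ValueError("R_open must be > 0")


@dataclass
class RespirationState:
    phase: float            # dimensionless in [0, 1)
    period: float           # s
    P_intrathoracic: float  # mmHg
    P_abdominal: float      # mmHg
    V_L: float              # lung volume, L


def chamber_elastance(
    t_since_beat: float,
    period: float,
    params: ChamberParams,
    contractility_scale: float = 1.0,
) -> float:
    """Instantaneous chamber elastance E(t) in mmHg/mL.

    Bounded by E_min and contractility_scale * E_max; continuous in t.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    if not 0 <= t_since_beat < period:
        raise ValueError("t_since_beat must lie in [0, period)")
    if contractility_scale <= 0:
        raise ValueError("contractility_scale must be > 0")
    dur = params.systole_duration * math.sqrt(period / params.rr_ref)
    act = _activation(t_since_beat, dur)
    return _elastance(act, params.E_max, params.E_min, contractility_scale)


def chamber_pressure(
    volume: float,
    t_since_beat: float,
    period: float,
    params: ChamberParams,
    contractility_scale: float = 1.0,
    external_pressure: float = 0.0,
) -> float:
    """Chamber pressure (mmHg) incl. diastolic nonlinearity and P_ext."""
    if period <= 0:
        raise ValueError("period must be > 0")
    dur = params.systole_duration * math.sqrt(period / params.rr_ref)
    act = _activation(t_since_beat, dur)
    return _chamber_p(
        volume, act, params.E_max, params.E_min, params.V_unstressed,
        params.A_ed, params.B_ed, contractility_scale,
    ) + external_pressure


def valve_flow(p_upstream: float, p_downstream: float, params: ValveParams) -> float:
    """Diode-resistance valve flow in mL/s (never negative)."""
    if not (math.isfinite(p_upstream) and math.isfinite(p_downstream)):
        raise ValueError("pressures must be finite")
    return _diode_flow(p_upstream, p_downstream, params.R_open)


def respiration_drive(
    t: float, T_resp: float, intensity: float = 0.0, params: np.ndarray | None = None
) -> RespirationState:
    """Respiratory pressure/volume waveforms at time t for a fixed period."""
    if T_resp <= 0:
        raise ValueError("T_resp must be > 0")
    p = default_cv_params() if params is None else params
    phase = (t / T_resp) % 1.0
    p_it, p_abd, v_l, _ = _resp_waves(phase, intensity, p)
    return RespirationState(phase, T_resp, p_it, p_abd, v_l)


def cardiovascular_derivatives(
    volumes,
    t_since_beat: float,
    period: float,
    resp: RespirationState,
    contractility_lv: float = 1.0,
    contractility_rv: float = 1.0,
    R_as: float = 0.93,
    V_usv: float = 2400.0,
    C_ao_scale: float = 1.0,
    muscle_pump: float = 0.0,
    params: np.ndarray | None = None,
    return_aux: bool = False,
):
    """d/dt of the eight compartment volumes (mL/s); mass-conserving.

    Raises FloatingPointError with a state dump if a volume is negative or
    derivatives are non-finite.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    p = default_cv_params() if params is None else params
    v = np.asarray(volumes, dtype=float)
    if v.shape != (NCV,):
        raise ValueError(f"expected {NCV} compartment volumes")
    if np.any(v < 0):
        raise FloatingPointError(f"negative compartment volume: {v!r}")
    dvdt = np.empty(NCV)
    aux = np.empty(NAUX_CV)
    cv_rhs(
        v, float(t_since_beat), float(period),
        resp.P_intrathoracic, resp.P_abdominal,
        float(contractility_lv), float(contractility_rv),
        float(R_as), float(V_usv), float(C_ao_scale), float(muscle_pump),
        p, dvdt, aux,
    )
    if not np.all(np.isfinite(dvdt)):
        raise FloatingPointError(
            f"non-finite derivatives; volumes={v!r} aux={aux!r}"
        )
    if return_aux:
        return dvdt, dict(zip(CV_AUX_COLS, aux))
    return dvdt
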