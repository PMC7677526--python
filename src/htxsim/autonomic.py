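"""Autonomic controller: reflex afferents, efferents and effectors.

Structure follows the short-term arterial-pressure control models of the
Ursino school: a sigmoidal aortic baroreceptor afferent, a pulmonary
stretch-receptor afferent proportional to lung volume, an exponentially
decreasing sympathetic and sigmoidally increasing vagal efferent, and
first-order effector blocks with logarithmic static characteristics for
peripheral resistance, venous unstressed volume and ventricular
contractility.  The heart-period effector of the original formulation is
replaced by neurotransmitter kinetics: sympathetic firing maps linearly to
an isoprenaline (Iso) increment and vagal firing to an acetylcholine (ACh)
increment, which the sinoatrial-cell model converts into a depolarization
rate.

Exercise enters through (i) additive central-command terms on both
efferent branches, (ii) a muscle mechano/metaboreflex that dilates the
peripheral bed (first-order, up to -50% resistance at peak intensity in
the healthy cohort), (iii) adrenal release of circulating catecholamines
(first-order Iso_circ), (iv) a rise of the baroreflex operating point (up
to +90% at peak), (v) linear stiffening of the arterial compliances, and
(vi) shortening of the respiratory period from 5 s at rest to 1.2 s at
peak exercise.

Cardiac denervation of the transplanted heart is expressed through the
cohort gain factors ``g_vagal_hr`` (0 after transplant), ``g_symp_hr`` and
``g_symp_elast`` (both 0.05 after transplant); the peripheral (vascular)
effector pathways remain intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "AfferentState",
    "EfferentActivities",
    "EffectorOutputs",
    "default_control_params",
    "baroreflex_afferent",
    "pulmonary_afferent",
    "efferent_pathways",
    "effector_statics",
    "exercise_modulation",
    "adrenal_target",
]

# ---------------------------------------------------------------------------
# packed controller parameter vector
# ---------------------------------------------------------------------------
P_SET_BASAL = 0    # baroreflex operating point at rest, mmHg
F_AB_MIN = 1       # baroreceptor firing floor, spikes/s
F_AB_MAX = 2       # baroreceptor firing ceiling, spikes/s
K_AB = 3           # baroreceptor sigmoid width, mmHg
TAU_PBAR = 4       # afferent pressure filter time constant, s
F_ES0 = 5          # sympathetic firing at zero afferent drive, spikes/s
F_ES_INF = 6       # sympathetic firing floor, spikes/s
K_ES = 7           # sympathetic exponential constant, s
F_ES_MIN = 8       # effector threshold on sympathetic firing, spikes/s
F_EV0 = 9          # vagal sigmoid lower level, spikes/s
F_EV_INF = 10      # vagal sigmoid upper level, spikes/s
K_EV = 11          # vagal sigmoid width, spikes/s
F_AB_HALF = 12     # vagal sigmoid midpoint on baroreceptor firing, spikes/s
W_SP = 13          # lung-stretch weight on sympathetic drive
W_VP = 14          # lung-stretch weight on vagal drive
G_AP = 15          # stretch-receptor gain, spikes/s per L
F_AP_REF = 16      # stretch firing at resting mean lung volume, spikes/s
CC_S = 17          # central-command sympathetic drive at I=1, afferent units
CC_V = 18          # central-command vagal inhibition at I=1, spikes/s
G_E = 19           # contractility effector gain, 1/ln-unit
TAU_E = 20         # contractility effector time constant, s
G_R = 21           # resistance effector gain, mmHg.s/mL per ln-unit
TAU_R = 22         # resistance effector time constant, s
R_AS0 = 23         # systemic resistance at zero sympathetic drive, mmHg.s/mL
G_VU = 24          # unstressed-volume effector gain, mL per ln-unit
TAU_VU = 25        # unstressed-volume time constant, s
V_USV0 = 26        # venous unstressed volume at zero sympathetic drive, mL
G_ISO = 27         # sympathetic -> Iso increment gain, conc per spikes/s
TAU_ISO = 28       # Iso effector time constant, s
G_ACH = 29         # vagal -> ACh increment gain, conc per spikes/s
TAU_ACH = 30       # ACh effector time constant, s
G_ADR = 31         # adrenal Iso_circ at I=1, concentration units
TAU_ADR = 32       # adrenal release time constant, s
TAU_MET = 33       # mechano/metaboreflex time constant, s
PSET_GAIN = 34     # fractional operating-point rise at I=1
VASO_MAX = 35      # fractional peripheral-resistance drop at I=1 (healthy)
VASO_FACTOR = 36   # cohort vasodilatory capacity factor
CAO_SLOPE = 37     # fractional aortic compliance drop at I=1
G_VAGAL_HR = 38    # cohort vagal HR-pathway gain factor
G_SYMP_HR = 39     # cohort sympathetic HR-pathway gain factor
G_SYMP_E = 40      # cohort sympathetic contractility gain factor
BASAL_ACH = 41     # basal ACh concentration, model units
BASAL_ISO = 42     # basal Iso concentration, model units
VASO_SHAPE = 43    # saturation constant of metabolic vasodilation vs intensity
CE_CIRC = 44       # inotropic gain of circulating catecholamines, 1/conc
MUSCLE_PUMP = 45   # mean venous pressurization by the muscle pump, mmHg
ADR_EXP = 46       # convexity of adrenal release vs intensity (exponent)
ADR_I0 = 47        # intensity threshold of adrenal release
NCTP = 48


def default_control_params() -> np.ndarray:
    """Healthy-control parameter vector (basal tone uncalibrated)."""
    p = np.zeros(NCTP)
    p[P_SET_BASAL] = 91.0
    p[F_AB_MIN], p[F_AB_MAX], p[K_AB] = 2.52, 47.78, 11.758
    p[TAU_PBAR] = 2.0
    p[F_ES0], p[F_ES_INF], p[K_ES], p[F_ES_MIN] = 16.11, 2.10, 0.0675, 2.66
    p[F_EV0], p[F_EV_INF], p[K_EV], p[F_AB_HALF] = 3.2, 6.3, 7.06, 25.0
    p[W_SP], p[W_VP] = -0.10, 0.20
    p[G_AP], p[F_AP_REF] = 11.76, 30.0
    p[CC_S], p[CC_V] = 20.0, 12.0
    p[G_E], p[TAU_E] = 0.50, 8.0
    p[G_R], p[TAU_R], p[R_AS0] = 0.08, 6.0, 0.88
    p[G_VU], p[TAU_VU], p[V_USV0] = 350.0, 20.0, 2700.0
    p[G_ISO], p[TAU_ISO] = 0.3, 2.0
    p[G_ACH], p[TAU_ACH] = 3.0, 1.5
    p[G_ADR], p[TAU_ADR] = 106.0, 30.0
    p[TAU_MET] = 25.0
    p[PSET_GAIN] = 0.90
    p[VASO_MAX] = 0.675
    p[VASO_FACTOR] = 1.0
    p[CAO_SLOPE] = 0.60
    p[G_VAGAL_HR] = 1.0
    p[G_SYMP_HR] = 1.0
    p[G_SYMP_E] = 1.0
    p[BASAL_ACH] = 0.0
    p[BASAL_ISO] = 0.0
    p[VASO_SHAPE] = 0.30
    p[CE_CIRC] = 0.010
    p[MUSCLE_PUMP] = 5.3
    p[ADR_EXP] = 1.1
    p[ADR_I0] = 0.15
    return p


# ---------------------------------------------------------------------------
# njit kernels
# ---------------------------------------------------------------------------
@njit(cache=True)
def _baro_firing(p_ao: float, p_set: float, p: np.ndarray) -> float:
    x = (p_ao - p_set) / p[K_AB]
    if x > 50.0:
        x = 50.0
    elif x < -50.0:
        x = -50.0
    e = math.exp(x)
    return (p[F_AB_MIN] + p[F_AB_MAX] * e) / (1.0 + e)


@njit(cache=True)
def _efferents(f_ab: float, f_ap: float, intensity: float, p: np.ndarray):
    """Sympathetic and vagal efferent firing (spikes/s)."""
    x = f_ab + p[W_SP] * (f_ap - p[F_AP_REF]) - p[CC_S] * intensity
    if x < 0.0:
        x = 0.0
    f_es = p[F_ES_INF] + (p[F_ES0] - p[F_ES_INF]) * math.exp(-p[K_ES] * x)
    e = math.exp((f_ab - p[F_AB_HALF]) / p[K_EV])
    f_ev = (p[F_EV0] + p[F_EV_INF] * e) / (1.0 + e)
    f_ev -= p[W_VP] * (f_ap - p[F_AP_REF]) + p[CC_V] * intensity
    if f_ev < 0.0:
        f_ev = 0.0
    return f_es, f_ev


@njit(cache=True)
def _symp_static(f_es: float, p: np.ndarray) -> float:
    """Logarithmic static characteristic of sympathetic effectors."""
    d = f_es - p[F_ES_MIN]
    if d <= 0.0:
        return 0.0
    return math.log(d + 1.0)


@njit(cache=True)
def _vaso_activation(intensity: float, p: np.ndarray) -> float:
    """Saturating metabolic-vasodilation activation in [0, 1].

    Normalized so the healthy cohort reaches 1 at intensity 1; the shape
    constant makes the exercising bed near-fully dilated already at
    moderate absolute workload."""
    tau = p[VASO_SHAPE]
    return (1.0 - math.exp(-intensity / tau)) / (1.0 - math.exp(-1.0 / tau))


@njit(cache=True)
def _exercise_mod(intensity: float, p: np.ndarray):
    """(P_set, cao_scale, vaso_target) at a given intensity fraction."""
    p_set = p[P_SET_BASAL] * (1.0 + p[PSET_GAIN] * intensity)
    cao_scale = 1.0 - p[CAO_SLOPE] * intensity
    vaso = p[VASO_MAX] * p[VASO_FACTOR] * _vaso_activation(intensity, p)
    return p_set, cao_scale, vaso


# ---------------------------------------------------------------------------
# domain types and validated wrappers
# ---------------------------------------------------------------------------
@dataclass
class AfferentState:
    baroreceptor_firing: float      # spikes/s
    pulmonary_stretch_firing: float  # spikes/s


@dataclass
class EfferentActivities:
    f_symp: float  # spikes/s
    f_vagal: float  # spikes/s


@dataclass
class EffectorOutputs:
    """Instantaneous effector values fed to circulation and SA node."""

    R_as: float          # mmHg.s/mL
    V_usv: float         # mL
    E_lv_scale: float    # dimensionless
    E_rv_scale: float    # dimensionless
    dACh: float          # concentration increment
    dIso: float          # concentration increment
    C_ao_scale: float    # dimensionless


def baroreflex_afferent(p_ao: float, p_set: float, params: np.ndarray | None = None) -> float:
    """Baroreceptor firing (spikes/s): saturating sigmoid centered at p_set."""
    if p_set <= 0:
        raise ValueError("p_set must be > 0")
    p = default_control_params() if params is None else params
    return _baro_firing(float(p_ao), float(p_set), p)


def pulmonary_afferent(v_l: float, params: np.ndarray | None = None) -> float:
    """Pulmonary stretch-receptor firing, linear in lung volume (L)."""
    p = default_control_params() if params is None else params
    return p[G_AP] * float(v_l)


def efferent_pathways(
    afferents: AfferentState,
    central_command: float = 0.0,
    params: np.ndarray | None = None,
) -> EfferentActivities:
    """Sympathetic/vagal efferent firing from afferents + central command.

    Sympathetic firing decreases with baroreceptor firing and increases
    with central command; vagal firing does the opposite (floored at 0).
    """
    p = default_control_params() if params is None else params
    f_es, f_ev = _efferents(
        float(afferents.baroreceptor_firing),
        float(afferents.pulmonary_stretch_firing),
        float(central_command),
        p,
    )
    return EfferentActivities(f_es, f_ev)


def effector_statics(
    eff: EfferentActivities,
    intensity: float = 0.0,
    params: np.ndarray | None = None,
) -> EffectorOutputs:
    """Steady-state effector outputs for constant efferent firing.

    The dynamic (first-order) states relax toward these values with the
    configured time constants; the engine integrates those states, this
    function exposes the static maps for calibration and testing.
    """
    p = default_control_params() if params is None else params
    sig = _symp_static(eff.f_symp, p)
    _, cao_scale, vaso = _exercise_mod(float(intensity), p)
    r_as = (p[R_AS0] + p[G_R] * sig) * (1.0 - vaso)
    v_usv = p[V_USV0] - p[G_VU] * sig
    e_scale_lv = 1.0 + p[G_SYMP_E] * p[G_E] * sig
    e_scale_rv = 1.0 + p[G_SYMP_E] * p[G_E] * sig
    d_ach = p[G_VAGAL_HR] * p[G_ACH] * eff.f_vagal
    d_iso = p[G_SYMP_HR] * p[G_ISO] * max(eff.f_symp - p[F_ES_MIN], 0.0)
    return EffectorOutputs(r_as, v_usv, e_scale_lv, e_scale_rv, d_ach, d_iso,
                           cao_scale)


def adrenal_target(intensity: float, params: np.ndarray | None = None) -> float:
    """Steady circulating-catecholamine level at a given intensity.

    The static map is convex with a low-workload threshold: circulating
    catecholamines stay near basal below ~10% intensity and rise
    disproportionately at higher workloads, as in exercise
    plasma-catecholamine measurements."""
    if not 0.0 <= intensity <= 1.0:
        raise ValueError("intensity must be in [0, 1]")
    p = default_control_params() if params is None else params
    x = (float(intensity) - p[ADR_I0]) / (1.0 - p[ADR_I0])
    if x <= 0.0:
        return 0.0
    return p[G_ADR] * x ** p[ADR_EXP]


def exercise_modulation(intensity: float, params: np.ndarray | None = None):
    """Intensity-dependent protocol quantities.

    Returns a dict with T_resp (s), P_set (mmHg), vaso_target (fractional
    resistance reduction), C_ao_scale and the mechano/metaboreflex
    activation (== intensity; its vascular effect relaxes with tau_met).
    """
    if not 0.0 <= intensity <= 1.0:
        raise ValueError("intensity must be in [0, 1]")
    p = default_control_params() if params is None else params
    p_set, cao_scale, vaso = _exercise_mod(float(intensity), p)
    t_resp = 5.0 - (5.0 - 1.2) * float(intensity)
    return {
        "T_resp": t_resp,
        "P_set": p_set,
        "vaso_target": vaso,
        "C_ao_scale": cao_scale,
        "mechano_metabo_activation": float(intensity),
    }
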