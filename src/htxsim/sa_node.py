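"""Single-cell sinoatrial (SA) node pacemaker model.

A Hodgkin-Huxley-type membrane model of a human SA-node cell that fires
spontaneous action potentials.  The diastolic depolarization is carried by
the hyperpolarization-activated "funny" current (I_f) and a background
inward current against a deactivating delayed-rectifier K+ current; the
upstroke is carried by the L-type Ca2+ current.  Autonomic modulation
enters through the concentrations of acetylcholine (ACh, vagal) and
isoprenaline (Iso, beta-sympathomimetic surrogate for the adrenergic
transmitters):

* ACh activates a muscarinic K+ current (I_KACh), shifts I_f activation to
  more negative potentials and reduces the L-type conductance -> slowing.
* Iso shifts I_f activation to more positive potentials, increases the
  L-type conductance, accelerates gate kinetics and SERCA reuptake
  -> acceleration.

Concentrations are expressed in nanomolar-equivalent model units; the
half-saturation constants ``K_ACH``/``K_ISO`` set the scale.  Membrane
potential is in mV, time in s, currents in mV/s (per unit capacitance).

The intrinsic rate with both modulation factors at identity (ACh = Iso = 0)
is calibrated to 74 bpm, matching the spontaneous beating rate reported
for isolated human SA-node cells (73 +/- 3 bpm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "SAParams",
    "BeatSeries",
    "default_sa_params",
    "sa_initial_state",
    "gate_rates",
    "sa_currents",
    "sa_derivatives",
    "detect_beats",
    "simulate_cell",
    "NSA",
]

# State layout: [V_m, y, d, f, n, Ca_i]
NSA = 6

# ---------------------------------------------------------------------------
# parameter vector layout (indices into the packed float64 array)
# ---------------------------------------------------------------------------
G_F = 0        # funny-current conductance, 1/s
E_F = 1        # funny-current reversal, mV
VY_HALF = 2    # I_f activation midpoint, mV
K_Y = 3        # I_f activation slope, mV
TAU_Y0 = 4     # I_f gate time constant floor, s
TAU_Y_AMP = 5  # I_f gate time constant peak amplitude, s
G_CAL = 6      # L-type Ca conductance, 1/s
E_CA = 7       # Ca reversal, mV
VD_HALF = 8    # d-gate midpoint, mV
K_D = 9        # d-gate slope, mV
TAU_D = 10     # d-gate time constant, s
VF_HALF = 11   # f-gate midpoint, mV
K_FG = 12      # f-gate slope, mV
TAU_F = 13     # f-gate time constant, s
G_K = 14       # delayed-rectifier conductance, 1/s
E_K = 15       # K reversal, mV
VN_HALF = 16   # n-gate midpoint, mV
K_N = 17       # n-gate slope, mV
TAU_N0 = 18    # n-gate time constant floor, s
TAU_N_AMP = 19 # n-gate time constant amplitude, s
G_KACH = 20    # ACh-activated K conductance, 1/s
G_B = 21       # background inward conductance, 1/s
E_B = 22       # background reversal, mV
I_NAK = 23     # Na/K pump current (outward), mV/s
K_ACH = 24     # ACh half-saturation, model units
K_ISO = 25     # Iso half-saturation, model units
S_ISO = 26     # I_f activation shift per unit iso effect, mV
S_ACH = 27     # I_f activation shift per unit ACh effect, mV
A_ISO = 28     # fractional L-type conductance increase at full iso
B_ACH = 29     # fractional L-type conductance decrease at full ACh
D_SHIFT_ISO = 30  # d-gate midpoint shift at full iso, mV
D_SHIFT_ACH = 31  # d-gate midpoint shift at full ACh, mV
TAU_SPEED_ISO = 32  # fractional gate-kinetics speed-up at full iso
K_CA_IN = 33   # Ca influx coupling, mM per (mV)
TAU_CA = 34    # Ca removal (SERCA) time constant, s
CA_REST = 35   # resting Ca level, mM
K_FCA = 36     # Ca-dependent inactivation half-saturation, mM
NSAP = 37


def default_sa_params() -> np.ndarray:
    """Packed parameter vector of the calibrated cell (intrinsic 74 bpm)."""
    p = np.zeros(NSAP)
    p[G_F] = 2.0
    p[E_F] = -22.0
    p[VY_HALF] = -60.0
    p[K_Y] = 9.0
    p[TAU_Y0] = 0.08
    p[TAU_Y_AMP] = 2.8
    p[G_CAL] = 350.0
    p[E_CA] = 45.0
    p[VD_HALF] = -35.0
    p[K_D] = 5.0
    p[TAU_D] = 0.002
    p[VF_HALF] = -45.0
    p[K_FG] = 4.0
    p[TAU_F] = 0.060
    p[G_K] = 170.0
    p[E_K] = -87.0
    p[VN_HALF] = -30.0
    p[K_N] = 7.0
    p[TAU_N0] = 0.040
    p[TAU_N_AMP] = 0.200
    p[G_KACH] = 3.0
    p[G_B] = 0.08
    p[E_B] = 0.0
    p[I_NAK] = 13.4
    p[K_ACH] = 30.0
    p[K_ISO] = 30.0
    p[S_ISO] = 11.0
    p[S_ACH] = 8.0
    p[A_ISO] = 0.5
    p[B_ACH] = 0.3
    p[D_SHIFT_ISO] = 5.0
    p[D_SHIFT_ACH] = 3.0
    p[TAU_SPEED_ISO] = 1.1
    p[K_CA_IN] = 2.0e-6
    p[TAU_CA] = 0.060
    p[CA_REST] = 1.0e-4
    p[K_FCA] = 6.0e-4
    return p


def sa_initial_state() -> np.ndarray:
    """Late-diastolic starting point; settles within a couple of beats."""
    return np.array([-60.0, 0.3, 0.01, 0.9, 0.1, 1.5e-4])


@njit(cache=True)
def receptor_occupancy(ach: float, iso: float, p: np.ndarray):
    """Michaelis saturation of the two neurotransmitter effects in [0, 1)."""
    ae = ach / (ach + p[K_ACH])
    ie = iso / (iso + p[K_ISO])
    return ae, ie


@njit(cache=True)
def gate_rates(v: float, ae: float, ie: float, p: np.ndarray):
    """Steady states and time constants of the four gating variables.

    Returns (y_inf, tau_y, d_inf, tau_d, f_inf, tau_f, n_inf, tau_n).
    """
    speed = 1.0 + p[TAU_SPEED_ISO] * ie

    vy = p[VY_HALF] + p[S_ISO] * ie - p[S_ACH] * ae
    y_inf = 1.0 / (1.0 + math.exp((v - vy) / p[K_Y]))
    # activation (hyperpolarized) is slow -- it is the pacemaker clock;
    # deactivation at depolarized potentials is fast
    tau_y = (
        p[TAU_Y0]
        + p[TAU_Y_AMP] / (1.0 + math.exp((v - (vy + 10.0)) / 8.0))
    ) / speed

    vd = p[VD_HALF] - p[D_SHIFT_ISO] * ie + p[D_SHIFT_ACH] * ae
    d_inf = 1.0 / (1.0 + math.exp(-(v - vd) / p[K_D]))
    tau_d = p[TAU_D]

    f_inf = 1.0 / (1.0 + math.exp((v - p[VF_HALF]) / p[K_FG]))
    tau_f = p[TAU_F]

    n_inf = 1.0 / (1.0 + math.exp(-(v - p[VN_HALF]) / p[K_N]))
    tau_n = (p[TAU_N0] + p[TAU_N_AMP] / math.cosh((v - p[VN_HALF]) / 15.0)) / speed

    return y_inf, tau_y, d_inf, tau_d, f_inf, tau_f, n_inf, tau_n


@njit(cache=True)
def sa_currents(s: np.ndarray, ae: float, ie: float, p: np.ndarray):
    """Membrane currents in mV/s: (I_f, I_CaL, I_K, I_KACh, I_b, I_NaK)."""
    v = s[0]
    y = s[1]
    d = s[2]
    f = s[3]
    n = s[4]
    ca = s[5]

    i_f = p[G_F] * y * (v - p[E_F])
    f_ca = p[K_FCA] / (p[K_FCA] + ca)
    g_cal = p[G_CAL] * (1.0 + p[A_ISO] * ie) * (1.0 - p[B_ACH] * ae)
    i_cal = g_cal * d * f * f_ca * (v - p[E_CA])
    i_k = p[G_K] * n * n * (v - p[E_K])
    # GIRK channels rectify: conductance falls off above E_K
    rect = 1.0 / (1.0 + math.exp((v + 40.0) / 18.0))
    i_kach = p[G_KACH] * ae * rect * (v - p[E_K])
    i_b = p[G_B] * (v - p[E_B])
    i_nak = p[I_NAK] * (1.0 - 0.1 * ie)
    return i_f, i_cal, i_k, i_kach, i_b, i_nak


@njit(cache=True)
def sa_rhs(s: np.ndarray, ach: float, iso: float, p: np.ndarray, out: np.ndarray):
    """Time derivatives of the SA-cell state (written into ``out``)."""
    ae, ie = receptor_occupancy(ach, iso, p)
    i_f, i_cal, i_k, i_kach, i_b, i_nak = sa_currents(s, ae, ie, p)
    y_inf, tau_y, d_inf, tau_d, f_inf, tau_f, n_inf, tau_n = gate_rates(
        s[0], ae, ie, p
    )
    out[0] = -(i_f + i_cal + i_k + i_kach + i_b + i_nak)
    out[1] = (y_inf - s[1]) / tau_y
    out[2] = (d_inf - s[2]) / tau_d
    out[3] = (f_inf - s[3]) / tau_f
    out[4] = (n_inf - s[4]) / tau_n
    ca_in = p[K_CA_IN] * max(0.0, -i_cal)
    tau_ca = p[TAU_CA] / (1.0 + 0.6 * ie)
    out[5] = ca_in - (s[5] - p[CA_REST]) / tau_ca


@njit(cache=True)
def _simulate_cell_core(s0, duration, dt, ach, iso, p, sample_dt):
    """Fixed-step RK4 integration of the isolated cell with on-line beat
    (action-potential peak) detection.  Returns sampled (t, V_m) and beat
    times."""
    n_steps = int(duration / dt)
    stride = max(1, int(round(sample_dt / dt)))
    n_samp = n_steps // stride + 1
    ts = np.empty(n_samp)
    vs = np.empty(n_samp)
    beats = np.empty(4096)
    nb = 0

    s = s0.copy()
    k1 = np.empty(NSA)
    k2 = np.empty(NSA)
    k3 = np.empty(NSA)
    k4 = np.empty(NSA)
    tmp = np.empty(NSA)

    ts[0] = 0.0
    vs[0] = s[0]
    isamp = 1

    v_prev = s[0]
    dv_prev = 0.0
    t_last_beat = -1.0

    for i in range(n_steps):
        t = i * dt
        sa_rhs(s, ach, iso, p, k1)
        for j in range(NSA):
            tmp[j] = s[j] + 0.5 * dt * k1[j]
        sa_rhs(tmp, ach, iso, p, k2)
        for j in range(NSA):
            tmp[j] = s[j] + 0.5 * dt * k2[j]
        sa_rhs(tmp, ach, iso, p, k3)
        for j in range(NSA):
            tmp[j] = s[j] + dt * k3[j]
        sa_rhs(tmp, ach, iso, p, k4)
        for j in range(NSA):
            s[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])

        t_next = t + dt
        dv = s[0] - v_prev
        # peak = rising-to-falling sign change above threshold, outside lockout
        if (
            dv_prev > 0.0
            and dv <= 0.0
            and v_prev > -20.0
            and (t_next - t_last_beat) > 0.15
        ):
            if nb < beats.shape[0]:
                beats[nb] = t
                nb += 1
            t_last_beat = t_next
        dv_prev = dv
        v_prev = s[0]

        if (i + 1) % stride == 0 and isamp < n_samp:
            ts[isamp] = t_next
            vs[isamp] = s[0]
            isamp += 1

    return ts[:isamp], vs[:isamp], beats[:nb], s


@dataclass
class SAParams:
    """Thin named wrapper around the packed parameter vector."""

    values: np.ndarray = field(default_factory=default_sa_params)

    def copy(self) -> "SAParams":
        return SAParams(self.values.copy())


@dataclass
class BeatSeries:
    """Detected action-potential peaks and the derived instantaneous rate."""

    beat_times: np.ndarray  # s, ascending

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)

    @property
    def instantaneous_rate(self) -> np.ndarray:
        """bpm, one value per RR interval (60/RR)."""
        return 60.0 / self.rr_intervals

    def mean_rate(self, t_from: float = 0.0, t_to: float = np.inf) -> float:
        """Mean of the reciprocal RR intervals whose ending beat lies in
        [t_from, t_to]; 0.0 if fewer than two beats qualify."""
        bt = self.beat_times
        rr = self.rr_intervals
        if rr.size == 0:
            return 0.0
        mask = (bt[1:] >= t_from) & (bt[1:] <= t_to)
        if not mask.any():
            return 0.0
        return float(np.mean(60.0 / rr[mask]))


def sa_derivatives(state, ach: float = 0.0, iso: float = 0.0, params=None):
    """Derivatives of the SA-cell state at given neurotransmitter levels."""
    p = params.values if isinstance(params, SAParams) else params
    if p is None:
        p = default_sa_params()
    s = np.asarray(state, dtype=float)
    out = np.empty(NSA)
    sa_rhs(s, float(ach), float(iso), p, out)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            f"non-finite SA-cell derivatives at state {s!r}"
        )
    return out


def detect_beats(t, vm, threshold: float = -20.0, lockout: float = 0.15) -> BeatSeries:
    """Locate action-potential peaks in a (t, V_m) trace.

    A beat is a local maximum of V_m above ``threshold`` mV, with a
    ``lockout`` s refractory window to reject secondary wiggles.
    """
    t = np.asarray(t, dtype=float)
    vm = np.asarray(vm, dtype=float)
    if t.shape != vm.shape:
        raise ValueError("t and vm must have matching shapes")
    from scipy.signal import find_peaks

    if t.size < 3:
        warnings.warn("trace too short for peak detection")
        return BeatSeries(np.empty(0))
    dt = np.median(np.diff(t))
    dist = max(1, int(round(lockout / dt)))
    idx, _ = find_peaks(vm, height=threshold, distance=dist)
    if idx.size == 0:
        warnings.warn("no action-potential peaks found")
    return BeatSeries(t[idx])


def simulate_cell(
    duration: float,
    ach: float = 0.0,
    iso: float = 0.0,
    params=None,
    dt: float = 2.0e-4,
    sample_dt: float = 1.0e-3,
    return_trace: bool = False,
):
    """Integrate the isolated cell and report its steady pacing rate.

    The rate is the mean of 60/RR over the final two-thirds of the window
    (the first third absorbs the initial transient).  A quiescent cell is
    reported as rate 0 with a warning.

    Returns ``(rate_bpm, BeatSeries)`` or, with ``return_trace=True``,
    ``(rate_bpm, BeatSeries, t, vm)``.
    """
    if duration < 10.0:
        raise ValueError("duration must be at least 10 s")
    if ach < 0 or iso < 0:
        raise ValueError("neurotransmitter concentrations must be >= 0")
    p = params.values if isinstance(params, SAParams) else params
    if p is None:
        p = default_sa_params()
    ts, vs, beats, _ = _simulate_cell_core(
        sa_initial_state(), float(duration), dt, float(ach), float(iso), p, sample_dt
    )
    series = BeatSeries(beats)
    rate = series.mean_rate(t_from=duration / 3.0)
    if rate == 0.0:
        warnings.warn("SA cell quiescent: no sustained pacing detected")
    if return_trace:
        return rate, series, ts, vs
    return rate, series
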