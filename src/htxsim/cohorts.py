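"""Cohort construction: healthy controls and early heart-transplant recipients.

The healthy cohort is the reference parameterization.  The HTxR cohort is
derived from it by a fixed, documented delta list expressing efferent
cardiac denervation and the peripheral sequelae of transplantation:

* vagal heart-rate effector gain        x 0     (complete vagal denervation)
* sympathetic heart-rate effector gain  x 0.05  (95% reduction)
* sympathetic elastance effector gain   x 0.05  (95% reduction)
* total peripheral resistance           x 1.15
* peripheral (systemic) compliances     x 0.8
* mechano/metaboreflex vasodilation     x 0.9
* peak protocol intensity               0.5 of healthy MTP

Basal neurotransmitter tone ("not-null" basal concentrations of ACh and
Iso) is calibrated per cohort by deterministic bisection on a scalar tone
index so the 300-s closed-loop resting heart rate matches the cohort
target (93.8 bpm HTxR, 69.5 bpm healthy).
"""

from __future__ import annotations

import numpy as np

from . import autonomic as au
from . import hemodynamics as hd
from .config import CohortConfig

__all__ = [
    "build_healthy",
    "build_htxr",
    "resting_heart_rate",
    "calibrate_basal_tone",
    "HEALTHY_MTP",
    "HTXR_MTP",
]

HEALTHY_MTP = 1032.0   # kpm/min, healthy-control peak exercise intensity
HTXR_MTP = 522.0       # kpm/min, ~50% of the healthy MTP

# frozen results of the shipped basal-tone calibration (see calibrate_basal_tone)
_HEALTHY_BASAL = (0.0, 10.15625)   # (ACh, Iso), model concentration units
_HTXR_BASAL = (0.0, 10.9375)

# cohort body surface areas; calibrated so resting LVEDVI matches the
# pooled imaging data (65.7 / 51.9 mL/m^2)
_HEALTHY_BSA = 1.9351
_HTXR_BSA = 2.0630

_PROV_PAPER = [
    "P_SET_BASAL", "PSET_GAIN", "VASO_MAX", "TRESP_REST", "TRESP_PEAK",
    "G_VAGAL_HR", "G_SYMP_HR", "G_SYMP_E", "VASO_FACTOR",
]
_PROV_CALIBRATED = [
    "BASAL_ACH", "BASAL_ISO", "G_ISO", "G_ACH", "G_ADR", "G_E", "G_R",
    "G_VU", "R_AS0", "V_USV0", "CAO_SLOPE", "CC_S", "CC_V",
    "LV_EMAX", "LV_EMIN", "LV_A", "LV_B", "RV_EMAX", "C_AO", "C_SV",
    "R_MV", "R_PVN", "R_VR", "I_NAK", "G_F", "G_B", "G_KACH",
    "TAU_Y_AMP", "S_ISO", "S_ACH", "A_ISO", "B_ACH",
]


def build_healthy() -> CohortConfig:
    """Age/gender-matched healthy control cohort (complete, validated)."""
    prov = {nm: "paper" for nm in _PROV_PAPER}
    prov.update({nm: "calibrated" for nm in _PROV_CALIBRATED})
    prov["mtp"] = "paper"
    prov["bsa"] = "calibrated"
    cfg = CohortConfig(
        label="healthy",
        bsa=_HEALTHY_BSA,
        mtp=HEALTHY_MTP,
        peak_intensity=1.0,
        provenance=prov,
    )
    cfg.basal_ach, cfg.basal_iso = _HEALTHY_BASAL
    return cfg.validate()


def build_htxr(healthy: CohortConfig | None = None) -> CohortConfig:
    """Early-HTxR cohort derived from the healthy config by the delta list."""
    base = build_healthy() if healthy is None else healthy
    cfg = base.copy()
    cfg.label = "htxr"
    cfg.bsa = _HTXR_BSA
    cfg.mtp = HTXR_MTP
    cfg.peak_intensity = 0.5
    c = cfg.control
    c[au.G_VAGAL_HR] = 0.0           # vagal HR gain reduced by 100%
    c[au.G_SYMP_HR] *= 0.05          # sympathetic HR gain reduced by 95%
    c[au.G_SYMP_E] *= 0.05           # sympathetic elastance gain reduced by 95%
    c[au.R_AS0] *= 1.15              # total peripheral resistance +15%
    c[au.G_R] *= 1.15
    c[au.VASO_FACTOR] *= 0.9         # vasodilatory capacity -10%
    cfg.cv[hd.C_AO] *= 0.8           # peripheral compliance -20%
    cfg.cv[hd.C_SV] *= 0.8
    cfg.basal_ach, cfg.basal_iso = _HTXR_BASAL
    cfg.provenance["bsa"] = "calibrated"
    return cfg.validate()


def resting_heart_rate(
    config: CohortConfig,
    duration: float = 300.0,
    transient: float = 60.0,
    solver=None,
) -> float:
    """Closed-loop resting HR: mean of 60/RR over the post-transient window."""
    from .engine import integrate

    res = integrate(config, duration=duration, solver=solver)
    return res.beats.mean_rate(t_from=transient, t_to=duration)


def calibrate_basal_tone(
    config: CohortConfig,
    target_resting_hr: float,
    tol: float = 0.5,
    max_tone: float = 400.0,
    duration: float = 300.0,
    max_iter: int = 40,
    solver=None,
) -> tuple:
    """Find basal (ACh, Iso) reproducing a target resting HR by bisection.

    A deterministic, reproducible alternative to tuning the tone by hand:
    the 1-D search runs along a fixed ray: if the zero-tone
    closed-loop HR is below the target the ray raises basal Iso, otherwise
    basal ACh (resting HR is monotone increasing in Iso and decreasing in
    ACh).  Returns the calibrated (basal_ACh, basal_Iso) and leaves them
    set on ``config``.

    Raises RuntimeError reporting the achievable interval when the target
    cannot be bracketed within ``max_tone``.
    """
    cfg = config

    def hr_at(ach: float, iso: float) -> float:
        cfg.basal_ach = ach
        cfg.basal_iso = iso
        return resting_heart_rate(cfg, duration=duration, solver=solver)

    hr0 = hr_at(0.0, 0.0)
    if abs(hr0 - target_resting_hr) <= tol:
        return (0.0, 0.0)
    direction = "iso" if hr0 < target_resting_hr else "ach"

    def hr_tone(u: float) -> float:
        return hr_at(0.0, u) if direction == "iso" else hr_at(u, 0.0)

    lo, hi = 0.0, max_tone
    hr_hi = hr_tone(hi)
    bracketed = (
        hr0 < target_resting_hr <= hr_hi
        if direction == "iso"
        else hr_hi <= target_resting_hr < hr0
    )
    if not bracketed:
        interval = sorted([hr0, hr_hi])
        raise RuntimeError(
            f"target {target_resting_hr} bpm unreachable; achievable "
            f"closed-loop range is [{interval[0]:.1f}, {interval[1]:.1f}] bpm"
        )
    u = hi
    hr_u = hr_hi
    for _ in range(max_iter):
        if abs(hr_u - target_resting_hr) <= tol:
            break
        mid = 0.5 * (lo + hi)
        hr_u = hr_tone(mid)
        u = mid
        rising = direction == "iso"
        if (hr_u < target_resting_hr) == rising:
            lo = mid
        else:
            hi = mid
    tone = (0.0, u) if direction == "iso" else (u, 0.0)
    cfg.basal_ach, cfg.basal_iso = tone
    return tone
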