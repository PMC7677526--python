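"""Reflex arcs: afferent sigmoids, efferent signs, effector statics and
first-order dynamics, exercise modulation."""

import numpy as np
import pytest

from htxsim import autonomic as au
from htxsim import build_healthy, build_htxr
from htxsim.autonomic import (
    AfferentState,
    EfferentActivities,
    adrenal_target,
    baroreflex_afferent,
    default_control_params,
    effector_statics,
    efferent_pathways,
    exercise_modulation,
    pulmonary_afferent,
)


def _rest_afferents(p=None):
    p = default_control_params() if p is None else p
    f_ab = baroreflex_afferent(p[au.P_SET_BASAL], p[au.P_SET_BASAL], p)
    return AfferentState(f_ab, p[au.F_AP_REF])


# ---------------------------------------------------------------------------
# afferents
# ---------------------------------------------------------------------------
def test_baroreflex_midpoint_at_operating_point():
    p = default_control_params()
    mid = 0.5 * (p[au.F_AB_MIN] + p[au.F_AB_MAX])
    assert baroreflex_afferent(91.0, 91.0) == pytest.approx(mid)


def test_baroreflex_monotone_and_saturating():
    p = default_control_params()
    grid = np.linspace(0.0, 350.0, 200)
    firing = np.array([baroreflex_afferent(x, 91.0) for x in grid])
    assert np.all(np.diff(firing) >= 0)
    assert firing[0] == pytest.approx(p[au.F_AB_MIN], abs=0.15)
    assert firing[-1] == pytest.approx(p[au.F_AB_MAX], abs=0.15)


def test_baroreflex_setpoint_shift_with_exercise():
    # rest 91 mmHg; peak exercise +90% -> 172.9 mmHg
    assert exercise_modulation(0.0)["P_set"] == pytest.approx(91.0)
    assert exercise_modulation(1.0)["P_set"] == pytest.approx(172.9)


def test_baroreflex_rejects_nonpositive_setpoint():
    with pytest.raises(ValueError):
        baroreflex_afferent(90.0, 0.0)


# ---------------------------------------------------------------------------
# efferents
# ---------------------------------------------------------------------------
def test_basal_efferent_pair_near_cited_values():
    eff = efferent_pathways(_rest_afferents(), 0.0)
    assert eff.f_symp == pytest.approx(4.67, abs=0.3)
    assert eff.f_vagal == pytest.approx(4.75, abs=0.3)


def test_pressure_rise_inhibits_sympathetic_excites_vagal():
    p = default_control_params()
    lo = efferent_pathways(AfferentState(
        baroreflex_afferent(80.0, 91.0), p[au.F_AP_REF]))
    hi = efferent_pathways(AfferentState(
        baroreflex_afferent(110.0, 91.0), p[au.F_AP_REF]))
    assert hi.f_symp < lo.f_symp
    assert hi.f_vagal > lo.f_vagal


def test_central_command_excites_sympathetic_inhibits_vagal():
    aff = _rest_afferents()
    base = efferent_pathways(aff, 0.0)
    drive = efferent_pathways(aff, 1.0)
    assert drive.f_symp > base.f_symp
    assert drive.f_vagal < base.f_vagal
    assert drive.f_vagal >= 0.0


# ---------------------------------------------------------------------------
# effectors
# ---------------------------------------------------------------------------
def test_basal_systemic_resistance_near_published_initial_value():
    # "initial value of 0.97 mmHg s/mL" at basal sympathetic tone
    out = effector_statics(efferent_pathways(_rest_afferents()))
    assert out.R_as == pytest.approx(0.97, abs=0.02)


def test_htxr_vagal_hr_pathway_is_null():
    c = build_htxr().control
    eff = EfferentActivities(f_symp=5.0, f_vagal=8.0)
    out = effector_statics(eff, params=c)
    assert out.dACh == 0.0
    # sympathetic HR pathway at 5% of healthy
    h = effector_statics(eff, params=build_healthy().control)
    assert out.dIso == pytest.approx(0.05 * h.dIso)


def test_htxr_elastance_gain_is_5_percent():
    h = build_healthy().control
    t = build_htxr().control
    assert t[au.G_SYMP_E] == pytest.approx(0.05 * h[au.G_SYMP_E])
    eff = EfferentActivities(10.0, 3.0)
    gain_h = effector_statics(eff, params=h).E_lv_scale - 1.0
    gain_t = effector_statics(eff, params=t).E_lv_scale - 1.0
    assert gain_t == pytest.approx(0.05 * gain_h)


def test_sympathetic_statics_monotone_in_firing():
    outs = [effector_statics(EfferentActivities(f, 4.0)) for f in (3.0, 8.0, 14.0)]
    assert outs[0].R_as < outs[1].R_as < outs[2].R_as
    assert outs[0].V_usv > outs[1].V_usv > outs[2].V_usv
    assert outs[0].dIso < outs[1].dIso < outs[2].dIso


# ---------------------------------------------------------------------------
# exercise modulation and adrenal release
# ---------------------------------------------------------------------------
def test_exercise_endpoints():
    rest = exercise_modulation(0.0)
    peak = exercise_modulation(1.0)
    assert rest["T_resp"] == pytest.approx(5.0)
    assert peak["T_resp"] == pytest.approx(1.2)
    assert rest["vaso_target"] == pytest.approx(0.0)
    # healthy peripheral resistance target: -50% or more of the basal value
    assert 0.5 <= peak["vaso_target"] <= 0.75
    assert rest["C_ao_scale"] == pytest.approx(1.0)
    assert peak["C_ao_scale"] < 1.0


def test_htxr_vasodilation_10_percent_weaker():
    h = exercise_modulation(1.0, build_healthy().control)
    t = exercise_modulation(1.0, build_htxr().control)
    assert t["vaso_target"] == pytest.approx(0.9 * h["vaso_target"])


def test_adrenal_rest_contribution_is_zero_and_monotone():
    assert adrenal_target(0.0) == 0.0
    vals = [adrenal_target(i) for i in (0.0, 0.25, 0.5, 0.75, 1.0)]
    assert np.all(np.diff(vals) > 0)
    with pytest.raises(ValueError):
        adrenal_target(1.5)


def test_pulmonary_afferent_linear_in_lung_volume():
    p = default_control_params()
    assert pulmonary_afferent(2.55) == pytest.approx(p[au.G_AP] * 2.55)


# ---------------------------------------------------------------------------
# first-order effector dynamics vs closed form
# ---------------------------------------------------------------------------
def test_adrenal_step_response_matches_exponential(htxr):
    """Step 0 -> 0.5 intensity: Iso_circ follows the first-order closed
    form G * I * (1 - exp(-t/tau)) within 0.5%."""
    from htxsim import integrate
    from htxsim.protocols import Protocol

    res = integrate(htxr, protocol=Protocol([(0.5, 150.0)]))
    df = res.timeseries
    p = htxr.control
    target = au.adrenal_target(0.5, p)
    tau = p[au.TAU_ADR]
    want = target * (1.0 - np.exp(-df["t"] / tau))
    err = np.max(np.abs(df["Iso_circ"].to_numpy() - want.to_numpy()))
    assert err < 0.005 * target


def test_mechanometabo_step_response_matches_exponential(htxr):
    from htxsim import integrate
    from htxsim.protocols import Protocol

    res = integrate(htxr, protocol=Protocol([(0.5, 120.0)]))
    df = res.timeseries
    tau = htxr.control[au.TAU_MET]
    want = 0.5 * (1.0 - np.exp(-df["t"] / tau))
    err = np.max(np.abs(df["x_met"].to_numpy() - want.to_numpy()))
    assert err < 0.005 * 0.5


def test_effectors_bounded_for_bounded_inputs(healthy_rest):
    df = healthy_rest.timeseries
    for col, lo, hi in [
        ("x_E", 0.0, 4.0), ("x_R", 0.0, 4.0), ("x_V", 0.0, 4.0),
        ("x_iso", 0.0, 100.0), ("x_ach", 0.0, 50.0),
        ("Iso_circ", -1e-9, 60.0), ("x_met", -1e-9, 1.0),
    ]:
        v = df[col].to_numpy()
        assert np.all(np.isfinite(v))
        assert v.min() >= lo - 1e-9 and v.max() <= hi
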