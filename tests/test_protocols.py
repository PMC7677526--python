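"""Protocols, window summaries, pooling arithmetic and reference comparison."""

import numpy as np
import pandas as pd
import pytest

from htxsim import (
    bsa_du_bois,
    compare_to_reference,
    load_reference_table,
    map_from_cuff,
    pool_moments,
)
from htxsim.protocols import (
    HemodynamicSummary,
    PooledStat,
    Protocol,
    summarize_window,
)
from htxsim.sa_node import BeatSeries


# ---------------------------------------------------------------------------
# protocol construction
# ---------------------------------------------------------------------------
def test_rest_protocol_is_single_300s_segment():
    p = Protocol.rest()
    assert p.segments == [(0.0, 300.0)]


def test_htxr_staircase_has_five_exercise_steps():
    p = Protocol.exercise_staircase(0.5)
    assert p.segments[0] == (0.0, 300.0)
    assert [round(i, 2) for i, _ in p.segments[1:]] == [0.1, 0.2, 0.3, 0.4, 0.5]
    assert all(d == 300.0 for _, d in p.segments)


def test_healthy_staircase_final_segment_is_full_intensity():
    p = Protocol.exercise_staircase(1.0)
    assert p.segments[-1][0] == pytest.approx(1.0)
    assert len(p.segments) == 11


def test_protocol_rejects_invalid_segments():
    with pytest.raises(ValueError):
        Protocol([(1.5, 300.0)])
    with pytest.raises(ValueError):
        Protocol([(0.5, 0.0)])


# ---------------------------------------------------------------------------
# window summaries on constructed waveforms
# ---------------------------------------------------------------------------
def _synthetic_window(n_beats=20, fs=100.0):
    """1 Hz beats; sinusoidal aortic pressure and triangular-ish LV volume."""
    t = np.arange(0.0, n_beats + 1.0, 1.0 / fs)
    p_ao = 93.0 + 20.0 * np.sin(2 * np.pi * t)
    v_lv = 90.0 + 30.0 * np.cos(2 * np.pi * t)  # per-beat max 120, min 60
    df = pd.DataFrame({
        "t": t,
        "P_ao": p_ao,
        "P_lv": 5.0 + 0.0 * t,
        "P_la": 6.0 + 0.0 * t,
        "V_lv": v_lv,
        "Q_av": np.full_like(t, 100.0),
        "R_as": np.full_like(t, 0.97),
    })
    beats = BeatSeries(np.arange(0.0, n_beats + 0.5, 1.0))
    return df, beats


def test_summary_of_constructed_pressure_waveform():
    df, beats = _synthetic_window()
    s = summarize_window(df, bsa=2.0, beats=beats)
    assert s.SBP == pytest.approx(113.0, abs=0.1)
    assert s.DBP == pytest.approx(73.0, abs=0.1)
    assert s.MAP == pytest.approx(93.0, abs=0.2)
    assert s.HR == pytest.approx(60.0, abs=1e-9)
    assert s.CO == pytest.approx(100.0 * 60 / 1000)
    assert s.SVR == pytest.approx(0.97)


def test_summary_of_constructed_volume_waveform():
    df, beats = _synthetic_window()
    s = summarize_window(df, bsa=2.0, beats=beats)
    assert s.SV == pytest.approx(60.0, abs=0.2)      # EDV 120 - ESV 60
    assert s.LVEDVI == pytest.approx(60.0, abs=0.1)  # 120 / 2.0 m^2


def test_summary_matches_independent_per_beat_loop(healthy_rest, healthy):
    """Beat-wise quantities recomputed by an independent segmentation loop
    over the same trace agree with summarize_window."""
    win = healthy_rest.window(60.0, 300.0)
    s = summarize_window(win, healthy.bsa, beats=healthy_rest.beats)

    t = win["t"].to_numpy()
    bt = healthy_rest.beats.beat_times
    bt = bt[(bt >= t[0]) & (bt <= t[-1])]
    sbp, dbp, sv = [], [], []
    for b0, b1 in zip(bt[:-1], bt[1:]):
        m = (t >= b0) & (t < b1)
        sbp.append(win["P_ao"].to_numpy()[m].max())
        dbp.append(win["P_ao"].to_numpy()[m].min())
        sv.append(win["V_lv"].to_numpy()[m].max()
                  - win["V_lv"].to_numpy()[m].min())
    assert s.SBP == pytest.approx(np.mean(sbp), abs=1e-9)
    assert s.DBP == pytest.approx(np.mean(dbp), abs=1e-9)
    # SV uses the pre-upstroke end-diastolic sample, not the raw max
    assert s.SV == pytest.approx(np.mean(sv), rel=0.02)
    assert s.HR == pytest.approx(np.mean(60.0 / np.diff(bt)), abs=1e-9)


def test_summary_rejects_short_window():
    df, beats = _synthetic_window(n_beats=5)
    with pytest.raises(ValueError, match="too short"):
        summarize_window(df, bsa=2.0, beats=beats)
    with pytest.raises(ValueError):
        summarize_window(df, bsa=0.0, beats=beats)


# ---------------------------------------------------------------------------
# pooling arithmetic
# ---------------------------------------------------------------------------
def test_map_from_cuff():
    assert map_from_cuff(120.0, 80.0) == pytest.approx(93.3333, abs=1e-3)
    assert map_from_cuff(150.0, 90.0) == pytest.approx(110.0)
    with pytest.raises(ValueError):
        map_from_cuff(100.0, 100.0)


def test_pool_single_study_is_identity():
    p = pool_moments([{"mean": 10.0, "sd": 2.0, "n": 5}])
    assert p.mean == 10.0 and p.sd == pytest.approx(2.0) and p.n == 5


def test_pool_identical_studies_keeps_mean():
    p = pool_moments([{"mean": 10.0, "sd": 2.0, "n": 5}] * 2)
    assert p.mean == pytest.approx(10.0)
    assert p.n == 10


def test_pool_matches_brute_force_moment_combination():
    """Pooled variance equals np.var over explicitly constructed samples
    with the exact per-study moments."""
    rng = np.random.default_rng(42)
    studies, samples = [], []
    for m, s, n in ((8.0, 1.0, 10), (12.0, 1.0, 10), (9.5, 2.5, 7)):
        z = rng.normal(size=n)
        z = (z - z.mean()) / z.std(ddof=1)  # exact sample moments
        x = m + s * z
        studies.append({"mean": m, "sd": s, "n": n})
        samples.append(x)
    p = pool_moments(studies)
    allx = np.concatenate(samples)
    assert p.mean == pytest.approx(allx.mean())
    assert p.variance == pytest.approx(np.var(allx, ddof=1), rel=1e-12)


def test_pool_median_range_substitution():
    # median -> mean; sd = range / 4
    p = pool_moments([{"median": 10.0, "range": 8.0, "n": 5}])
    assert p.mean == 10.0 and p.sd == pytest.approx(2.0)


def test_pool_rejects_bad_records():
    with pytest.raises(ValueError):
        pool_moments([])
    with pytest.raises(ValueError):
        pool_moments([{"mean": 1.0, "n": 3}])
    with pytest.raises(ValueError):
        PooledStat(mean=1.0, variance=-1.0, n=2)


def test_bsa_du_bois():
    assert bsa_du_bois(180.0, 75.0) == pytest.approx(1.94, abs=0.01)
    # power-law scaling in weight
    assert bsa_du_bois(180.0, 150.0) / bsa_du_bois(180.0, 75.0) == \
        pytest.approx(2 ** 0.425)
    with pytest.raises(ValueError):
        bsa_du_bois(0.0, 75.0)


# ---------------------------------------------------------------------------
# reference comparison
# ---------------------------------------------------------------------------
def _summary(**kw):
    base = dict(HR=93.8, CO=5.2, SV=55.4, SBP=111.3, DBP=81.7, MAP=91.5,
                SVR=1.08, LVEDVI=51.9, LVEDP=2.8, LAP=4.0)
    base.update(kw)
    return HemodynamicSummary(**base)


def test_compare_z_scores_and_pass_flags():
    ref = load_reference_table("table1")
    rep = compare_to_reference(_summary(), ref, cohort="htxr", condition="rest")
    hr = rep[rep.variable == "HR"].iloc[0]
    # z recomputed by hand for one row: (93.8 - 92.7) / 10.3
    assert hr.z == pytest.approx((93.8 - 92.7) / 10.3)
    assert hr.within_1sd
    exact = compare_to_reference(_summary(HR=92.7), ref, "htxr", "rest")
    assert exact[exact.variable == "HR"].iloc[0].z == pytest.approx(0.0)


def test_compare_lists_unknown_variables_without_failing():
    ref = load_reference_table("table1")
    rep = compare_to_reference(_summary(), ref, cohort="htxr", condition="peak")
    mtp = rep[rep.variable == "MTP"]
    assert len(mtp) == 1 and not mtp.iloc[0].within_1sd  # no model MTP value


def test_reference_tables_load_with_expected_shape():
    t1 = load_reference_table("table1")
    t2 = load_reference_table("table2")
    for t in (t1, t2):
        assert {"condition", "cohort", "variable", "mean", "sd", "n"} <= set(t.columns)
    assert len(t1) == 34
    assert (t1.sd > 0).all()
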