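"""Simulation protocols, summary hemodynamics and literature-pooling utilities.

Protocols are sequences of (exercise intensity, duration) segments.
Intensity is expressed as a fraction of the healthy-control maximum
tolerated power (MTP, 1,032 kpm/min), so the HTxR protocol terminates at
intensity 0.5 (522 kpm/min).  The standard graded test increases intensity
in steps of 10% of MTP, 300 s per step; summary hemodynamics are averaged
per segment after discarding the first 60 s as transient.

Summary definitions (per 300-s window):

* HR: mean of the reciprocal RR intervals of detected SA-node beats
* MAP: time-average of aortic pressure
* SBP/DBP: per-beat maximum/minimum of aortic pressure, averaged over beats
* CO: time-average of left-ventricular outflow
* SV: per-beat end-diastolic minus end-systolic LV volume, averaged
* SVR: time-average of the (controlled) systemic resistance
* LVEDVI: per-beat end-diastolic LV volume averaged, divided by cohort BSA
* LVEDP/LAP: LV pressure at end-diastole (instant of the per-beat volume
  maximum) averaged over beats / mean left-atrial pressure

The pooling utilities implement the literature arithmetic used to build
the reference tables: MAP = (SBP + 2 DBP)/3 from cuff pressures, median ->
mean and range/4 -> variance substitutions, n-weighted pooled moments, and
the Du Bois body-surface-area formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .sa_node import BeatSeries, detect_beats

__all__ = [
    "Protocol",
    "HemodynamicSummary",
    "PooledStat",
    "run_protocol",
    "summarize_window",
    "map_from_cuff",
    "pool_moments",
    "bsa_du_bois",
    "compare_to_reference",
    "load_reference_table",
]


@dataclass
class Protocol:
    """Sequence of (intensity fraction, duration s) segments."""

    segments: list
    cohort: str = ""

    def __post_init__(self):
        for inten, dur in self.segments:
            if not 0.0 <= inten <= 1.0:
                raise ValueError("intensity must be in [0, 1]")
            if dur <= 0:
                raise ValueError("segment duration must be > 0")

    @classmethod
    def rest(cls, duration: float = 300.0, cohort: str = "") -> "Protocol":
        return cls([(0.0, duration)], cohort)

    @classmethod
    def exercise_staircase(
        cls,
        peak_intensity: float,
        step: float = 0.1,
        segment_duration: float = 300.0,
        include_rest: bool = True,
        cohort: str = "",
    ) -> "Protocol":
        """Graded test: rest, then +10%-of-MTP steps up to the peak."""
        segs = [(0.0, segment_duration)] if include_rest else []
        n = int(round(peak_intensity / step))
        for i in range(1, n + 1):
            segs.append((min(i * step, peak_intensity), segment_duration))
        return cls(segs, cohort)

    @classmethod
    def ramp_hold(
        cls,
        intensity: float,
        hold: float = 300.0,
        lead: float = 120.0,
        cohort: str = "",
    ) -> "Protocol":
        """Shortened protocol: jump to the target intensity, settle during
        ``lead`` s, then a ``hold`` s measurement segment."""
        segs = []
        if lead > 0:
            segs.append((intensity, lead))
        segs.append((intensity, hold))
        return cls(segs, cohort)


@dataclass
class HemodynamicSummary:
    """Per-window mean hemodynamics in clinical units."""

    HR: float       # bpm
    CO: float       # L/min
    SV: float       # mL
    SBP: float      # mmHg
    DBP: float      # mmHg
    MAP: float      # mmHg
    SVR: float      # mmHg.s/mL
    LVEDVI: float   # mL/m^2
    LVEDP: float    # mmHg
    LAP: float      # mmHg
    intensity: float = 0.0
    n_beats: int = 0

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def summarize_window(
    timeseries: pd.DataFrame,
    bsa: float,
    beats: BeatSeries | None = None,
    min_beats: int = 10,
) -> HemodynamicSummary:
    """Summary hemodynamics of one analysis window.

    ``timeseries`` needs columns t, P_ao, P_lv, P_la, V_lv, Q_av, R_as,
    V_m (V_m only when ``beats`` is not supplied).  Beats outside the
    window are ignored; windows with fewer than ``min_beats`` beats raise
    ValueError.
    """
    if bsa <= 0:
        raise ValueError("BSA must be > 0")
    t = timeseries["t"].to_numpy()
    if beats is None:
        beats = detect_beats(t, timeseries["V_m"].to_numpy())
    bt = beats.beat_times
    bt = bt[(bt >= t[0]) & (bt <= t[-1])]
    if bt.size < min_beats:
        raise ValueError(
            f"window too short: {bt.size} beats (< {min_beats})"
        )

    p_ao = timeseries["P_ao"].to_numpy()
    p_lv = timeseries["P_lv"].to_numpy()
    p_la = timeseries["P_la"].to_numpy()
    v_lv = timeseries["V_lv"].to_numpy()
    q_av = timeseries["Q_av"].to_numpy()
    r_as = timeseries["R_as"].to_numpy()
    act_v = timeseries["act_v"].to_numpy() if "act_v" in timeseries else None

    idx = np.searchsorted(t, bt)
    sbp = np.empty(idx.size - 1)
    dbp = np.empty(idx.size - 1)
    edv = np.empty(idx.size - 1)
    esv = np.empty(idx.size - 1)
    edp = np.empty(idx.size - 1)
    for i in range(idx.size - 1):
        lo, hi = idx[i], idx[i + 1]
        sbp[i] = p_ao[lo:hi].max()
        dbp[i] = p_ao[lo:hi].min()
        # end diastole: the last sample before the ventricular-activation
        # upstroke of this beat (atrial kick included, contraction not),
        # so the steep pressure rise between two output samples cannot
        # contaminate the end-diastolic pressure
        j = lo + int(np.argmax(v_lv[lo:hi]))
        if act_v is not None:
            ipk = lo + int(np.argmax(act_v[lo:hi]))
            pre = np.nonzero(act_v[lo:ipk] <= 1e-3)[0]
            if pre.size:
                j = lo + int(pre[-1])
        edv[i] = v_lv[j]
        esv[i] = v_lv[lo:hi].min()
        edp[i] = p_lv[j]

    rr = np.diff(bt)
    hr = float(np.mean(60.0 / rr))
    co = float(np.mean(q_av)) * 60.0 / 1000.0  # mL/s -> L/min
    inten = float(timeseries["intensity"].iloc[-1]) if "intensity" in timeseries else 0.0
    return HemodynamicSummary(
        HR=hr,
        CO=co,
        SV=float(np.mean(edv - esv)),
        SBP=float(np.mean(sbp)),
        DBP=float(np.mean(dbp)),
        MAP=float(np.mean(p_ao)),
        SVR=float(np.mean(r_as)),
        LVEDVI=float(np.mean(edv)) / bsa,
        LVEDP=float(np.mean(edp)),
        LAP=float(np.mean(p_la)),
        intensity=inten,
        n_beats=int(bt.size),
    )


def run_protocol(
    config,
    protocol: Protocol,
    transient: float = 60.0,
    solver=None,
):
    """Run a protocol in the closed loop and summarize every segment.

    Returns (list of HemodynamicSummary, SimulationResult).  Segments the
    solver failed in (or that are shorter than the transient) are skipped
    with a None placeholder; the full time series is always returned.
    """
    from .engine import integrate

    res = integrate(config, protocol=protocol, solver=solver)
    summaries = []
    for (t0, t1, inten) in res.segments:
        if res.failed or t1 - t0 <= transient:
            summaries.append(None)
            continue
        win = res.window(t0 + transient, t1)
        try:
            s = summarize_window(win, config.bsa, beats=res.beats)
            s.intensity = inten
            summaries.append(s)
        except ValueError:
            summaries.append(None)
    return summaries, res


# ---------------------------------------------------------------------------
# literature pooling arithmetic
# ---------------------------------------------------------------------------
@dataclass
class PooledStat:
    mean: float
    variance: float
    n: int

    def __post_init__(self):
        if self.variance < 0 or self.n < 1:
            raise ValueError("require variance >= 0 and n >= 1")

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


def map_from_cuff(sbp: float, dbp: float) -> float:
    """Mean arterial pressure from cuff pressures: (SBP + 2 DBP)/3."""
    if not sbp > dbp > 0:
        raise ValueError("require SBP > DBP > 0")
    return (sbp + 2.0 * dbp) / 3.0


def pool_moments(studies: Iterable) -> PooledStat:
    """n-weighted pooled mean and variance across study records.

    Each record is a mapping with ``n`` and either ``mean`` or ``median``,
    and either ``sd`` or ``range`` (median substitutes the mean; the
    standard deviation of a range-reporting study is range/4).  The pooled
    variance combines within-study and between-study second moments:

        s^2 = [sum((n_i-1) s_i^2 + n_i m_i^2) - N m_bar^2] / (N - 1)
    """
    studies = list(studies)
    if not studies:
        raise ValueError("study list is empty")
    ms, vs, ns = [], [], []
    for rec in studies:
        rec = dict(rec)
        n = int(rec["n"])
        if n < 1:
            raise ValueError("each study needs n >= 1")
        if "mean" in rec and rec["mean"] is not None:
            m = float(rec["mean"])
        elif "median" in rec and rec["median"] is not None:
            m = float(rec["median"])
        else:
            raise ValueError("record needs mean or median")
        if "sd" in rec and rec["sd"] is not None:
            s = float(rec["sd"])
        elif "range" in rec and rec["range"] is not None:
            s = float(rec["range"]) / 4.0
        else:
            raise ValueError("record needs sd or range")
        ms.append(m)
        vs.append(s * s)
        ns.append(n)
    ms, vs, ns = np.array(ms), np.array(vs), np.array(ns)
    n_tot = int(ns.sum())
    m_pool = float(np.sum(ns * ms) / n_tot)
    if n_tot > 1:
        ss = np.sum((ns - 1) * vs + ns * ms ** 2)
        var = float((ss - n_tot * m_pool ** 2) / (n_tot - 1))
        var = max(var, 0.0)
    else:
        var = float(vs[0])
    return PooledStat(m_pool, var, n_tot)


def bsa_du_bois(height_cm: float, weight_kg: float) -> float:
    """Du Bois body surface area: 0.007184 W^0.425 H^0.725 (m^2)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be > 0")
    return 0.007184 * weight_kg ** 0.425 * height_cm ** 0.725


# ---------------------------------------------------------------------------
# comparison against the packaged reference tables
# ---------------------------------------------------------------------------
def load_reference_table(name: str = "table1") -> pd.DataFrame:
    """Packaged pooled-literature table ('table1' or 'table2')."""
    fn = f"{name}_reference.csv"
    with resources.files("htxsim.data").joinpath(fn).open() as fh:
        return pd.read_csv(fh, comment="#")


def compare_to_reference(
    summary,
    reference: pd.DataFrame,
    cohort: str,
    condition: str = "rest",
) -> pd.DataFrame:
    """Compare model summary values with pooled literature mean +/- SD.

    A variable passes if |model - mean| <= 1 SD (the between-patient
    variability criterion).  Unknown/missing variables are listed with
    NaN, not fatal.  Returns a tidy report DataFrame.
    """
    vals = summary.as_dict() if hasattr(summary, "as_dict") else dict(summary)
    ref = reference[
        (reference["cohort"] == cohort) & (reference["condition"] == condition)
    ]
    rows = []
    for _, r in ref.iterrows():
        var = r["variable"]
        model = vals.get(var, np.nan)
        sd = float(r["sd"])
        z = (model - float(r["mean"])) / sd if sd > 0 else np.nan
        rows.append({
            "variable": var,
            "condition": condition,
            "cohort": cohort,
            "model": model,
            "ref_mean": float(r["mean"]),
            "ref_sd": sd,
            "ref_n": int(r["n"]),
            "z": z,
            "within_1sd": bool(abs(z) <= 1.0) if np.isfinite(z) else False,
        })
    return pd.DataFrame(rows)
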