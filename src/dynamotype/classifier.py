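"""Dynamotype classification from boundary scaling-law fits.

Candidate laws (constant; square root of the distance to a free bifurcation
time; logarithmic ISI divergence at offset) are fitted to the amplitude and
ISI/frequency series of the first and last spikes of a seizure.  Model
selection uses a small-sample corrected information criterion; the winning
laws plus the DC-shift test yield the onset and offset bifurcation class.

Without a DC-coupled channel some classes are indistinguishable in
principle, so grouped labels are emitted: SN without a baseline shift and
SubH at onset; SH without a shift and SNIC at offset.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .features import (
    BackgroundStats,
    BoundaryWindow,
    DCShiftResult,
    Recording,
    SpikeSeries,
    background_stats,
    detect_dc_shift,
    detect_spikes,
    extract_boundary_windows,
)

__all__ = [
    "ONSET_CLASSES",
    "OFFSET_CLASSES",
    "UNCLASSIFIED",
    "ScalingFit",
    "DynamotypeLabel",
    "fit_scaling_models",
    "classify_onset",
    "classify_offset",
    "classify_seizure",
    "tabulate_cohort",
]

UNCLASSIFIED = "unclassified"
ONSET_CLASSES = ("SupH", "SNIC", "SN(+DC)", "SN(-DC)/SubH", UNCLASSIFIED)
OFFSET_CLASSES = ("SupH", "FLC", "SH(+DC)", "SH(-DC)/SNIC", UNCLASSIFIED)

# operational thresholds (surfaced in every report)
NEAR_ZERO_FRACTION = 0.45  # 'starts/ends at zero': boundary amp below this fraction of the window max (operational point above the smallest detectable amplitude)
SNIC_FIRST_ISI_RATIO = 3.0  # 'frequency from zero': first ISI > 3x window median
SLOWING_LAST_ISI_RATIO = 2.0  # 'slowing': last ISI > 2x window median
ACCEL_RATIO = 1.6  # sustained acceleration/deceleration across a window
TBIF_SLACK = 5.0  # free bifurcation time within +/- 5 s of the mark


@dataclass
class ScalingFit:
    """One candidate law fitted to a boundary series."""

    law: str  # 'constant' | 'sqrt' | 'log'
    target: str  # 'amplitude' | 'isi' | 'frequency'
    params: tuple
    t_bif: float  # estimated bifurcation time (relative to the mark)
    rss: float
    r2: float
    aicc: float
    n: int
    trend: int  # sign of the change along the window
    available: bool = True

    @property
    def key(self):
        return (self.law, self.target)


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _r2(y: np.ndarray, rss: float) -> float:
    ss = float(np.sum((y - y.mean()) ** 2))
    if ss == 0:
        return 1.0 if rss < 1e-12 else -math.inf
    return 1.0 - rss / ss


def _fit_constant(t, y, target) -> ScalingFit:
    c = float(np.mean(y))
    rss = float(np.sum((y - c) ** 2))
    trend = int(np.sign(y[-1] - y[0])) if len(y) > 1 else 0
    return ScalingFit(
        law="constant",
        target=target,
        params=(c,),
        t_bif=math.nan,
        rss=rss,
        r2=_r2(y, rss),
        aicc=_aicc(rss, len(y), 1),
        n=len(y),
        trend=trend,
    )


def _fit_sqrt(t, y, target, boundary) -> ScalingFit:
    """y = c * sqrt(|t - t_bif|) with t_bif free on the correct side.

    At onset the bifurcation time precedes the first spike (growth away
    from zero); at offset it follows the last spike (decay toward zero).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)

    def rss_at(tb):
        w = np.sqrt(np.abs(t - tb))
        denom = float(w @ w)
        if denom == 0:
            return np.inf, 0.0
        c = float(w @ y) / denom
        r = y - c * w
        return float(r @ r), c

    eps = 1e-3
    if boundary == "onset":
        lo, hi = t[0] - TBIF_SLACK, t[0] - eps
    else:
        lo, hi = t[-1] + eps, t[-1] + TBIF_SLACK
    res = minimize_scalar(lambda tb: rss_at(tb)[0], bounds=(lo, hi), method="bounded")
    tb = float(res.x)
    rss, c = rss_at(tb)
    pred_sign = 1 if boundary == "onset" else -1  # grows from / decays to zero
    return ScalingFit(
        law="sqrt",
        target=target,
        params=(c,),
        t_bif=tb,
        rss=rss,
        r2=_r2(y, rss),
        aicc=_aicc(rss, len(y), 2),
        n=len(y),
        trend=pred_sign,
        available=np.isfinite(rss),
    )


def _fit_inv_sqrt_isi(t, isi, boundary) -> ScalingFit:
    """Square-root frequency law, fitted in ISI units for comparability:
    ISI = 1 / (c * sqrt(|t - t_bif|)).  All rate laws are scored on the
    same target variable, so their information criteria are commensurable.
    """
    t = np.asarray(t, dtype=float)
    isi = np.asarray(isi, dtype=float)

    def rss_at(tb):
        w = np.sqrt(np.abs(t - tb))
        u = 1.0 / np.maximum(w, 1e-9)
        denom = float(u @ u)
        beta = float(u @ isi) / denom if denom else 0.0
        r = isi - beta * u
        return float(r @ r), beta

    eps = 1e-3
    if boundary == "onset":
        lo, hi = t[0] - TBIF_SLACK, t[0] - eps
    else:
        lo, hi = t[-1] + eps, t[-1] + TBIF_SLACK
    res = minimize_scalar(lambda tb: rss_at(tb)[0], bounds=(lo, hi), method="bounded")
    tb = float(res.x)
    rss, beta = rss_at(tb)
    return ScalingFit(
        law="sqrt",
        target="frequency",
        params=(1.0 / beta if beta else math.inf,),
        t_bif=tb,
        rss=rss,
        r2=_r2(isi, rss),
        aicc=_aicc(rss, len(isi), 2),
        n=len(isi),
        trend=1 if boundary == "offset" else -1,  # ISI shrinks from onset, grows to offset
        available=bool(np.isfinite(rss) and beta > 0),
    )


def _fit_log_isi(t, isi, t_mark) -> ScalingFit:
    """Offset only: ISI = a + b * (-ln(t_bif - t)), b > 0 (divergence)."""
    t = np.asarray(t, dtype=float)
    isi = np.asarray(isi, dtype=float)

    def fit_at(tb):
        x = -np.log(tb - t)
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, isi, rcond=None)
        r = isi - A @ coef
        return float(r @ r), coef

    eps = 1e-3
    lo, hi = t[-1] + eps, t[-1] + TBIF_SLACK
    res = minimize_scalar(lambda tb: fit_at(tb)[0], bounds=(lo, hi), method="bounded")
    tb = float(res.x)
    rss, coef = fit_at(tb)
    a, b = float(coef[0]), float(coef[1])
    return ScalingFit(
        law="log",
        target="isi",
        params=(a, b),
        t_bif=tb,
        rss=rss,
        r2=_r2(isi, rss),
        aicc=_aicc(rss, len(isi), 3),
        n=len(isi),
        trend=1,
        available=bool(np.isfinite(rss) and b > 0),
    )


def fit_scaling_models(window: BoundaryWindow, boundary: str) -> list[ScalingFit]:
    """Fit all candidate laws to one boundary window.

    Amplitude: constant and square-root (growth at onset, decay at offset).
    ISI/frequency: constant ISI, square-root frequency, and (offset only)
    the logarithmic ISI law.  Fits on fewer than four spikes are refused.
    """
    if boundary not in ("onset", "offset"):
        raise ValueError("boundary must be 'onset' or 'offset'")
    t = window.times
    if len(t) < 4:
        raise ValueError("need at least 4 spikes to fit scaling laws")
    out = []
    # subtract the background peak-to-peak floor: small spikes ride on it,
    # and the 'grows from / decays to zero' laws concern the true amplitude
    a = np.maximum(window.amplitudes - window.amp_floor, 0.0) + 1e-9
    out.append(_fit_constant(t, a, "amplitude"))
    out.append(_fit_sqrt(t, a, "amplitude", boundary))
    ok = np.isfinite(window.isis)
    t_isi = t[ok]
    isi = window.isis[ok]
    if len(isi) >= 4:
        out.append(_fit_constant(t_isi, isi, "isi"))
        out.append(_fit_inv_sqrt_isi(t_isi, isi, boundary))
        if boundary == "offset":
            out.append(_fit_log_isi(t_isi, isi, t_mark=0.0))
    return out


def _best(fits, target_set, laws=("constant", "sqrt", "log")):
    cand = [f for f in fits if f.target in target_set and f.available and f.law in laws]
    if not cand:
        return None, math.inf
    order = sorted(cand, key=lambda f: (f.aicc, {"constant": 0, "sqrt": 1, "log": 2}[f.law]))
    best = order[0]
    runner = order[1].aicc if len(order) > 1 else best.aicc + 10.0
    return best, runner - best.aicc


def _confidence(margin: float, low_n: bool) -> float:
    conf = 1.0 / (1.0 + math.exp(-margin / 4.0))
    return conf * (0.5 if low_n else 1.0)


def classify_onset(fits: list[ScalingFit], dc: DCShiftResult, window: BoundaryWindow):
    """Onset class from the fitted laws and the DC-shift test.

    Decision order: amplitude growing as sqrt from near zero (SupH);
    frequency growing as sqrt from near zero (SNIC); abrupt onset with a
    baseline shift (SN(+DC)); otherwise the grouped SN(-DC)/SubH class.
    """
    amp_best, amp_margin = _best(fits, {"amplitude"})
    freq_best, freq_margin = _best(fits, {"isi", "frequency"})
    if amp_best is None or freq_best is None:
        return UNCLASSIFIED, 0.0
    a = np.maximum(window.amplitudes - window.amp_floor, 0.0)
    amax = float(a.max())
    first_small = amax > 0 and a[0] < NEAR_ZERO_FRACTION * amax
    isis = window.isis[np.isfinite(window.isis)]
    # 'frequency from zero': either a dominant long first interval, or a
    # strong overall acceleration across the window (a sqrt-law passage
    # sampled at consecutive spikes bounds the single-interval ratio)
    med = float(np.median(isis)) if len(isis) else math.nan
    # a gradual deceleration pattern distinguishes the true sqrt-frequency
    # passage from a single fold-ghost latency (one long gap, then abrupt
    # full-rate spiking): the second interval must still be long
    first_isi_long = (
        len(isis) >= 3
        and isis[0] > SNIC_FIRST_ISI_RATIO * med
        and isis[1] > 1.15 * med
    )
    accel_strong = (
        len(isis) >= 6
        and float(np.median(isis[:3])) > ACCEL_RATIO * float(np.median(isis[-3:]))
    )
    const_amp = [f for f in fits if f.target == "amplitude" and f.law == "constant"]
    amp_margin_const = (
        const_amp[0].aicc - amp_best.aicc if const_amp and amp_best.law == "sqrt" else 0.0
    )
    sqrt_dominant = amp_margin_const > 6.0 and amax > 0 and a[0] < 0.65 * amax
    if amp_best.law == "sqrt" and (first_small or sqrt_dominant):
        return "SupH", _confidence(amp_margin, window.low_n)
    if (
        freq_best.law == "sqrt"
        and freq_best.target == "frequency"
        and (first_isi_long or accel_strong)
    ):
        return "SNIC", _confidence(freq_margin, window.low_n)
    if dc.assessable and dc.present:
        return "SN(+DC)", _confidence(4.0, window.low_n)
    return "SN(-DC)/SubH", _confidence(2.0, window.low_n)


def classify_offset(fits: list[ScalingFit], dc: DCShiftResult, window: BoundaryWindow):
    """Offset class and the slowing flag.

    ISI slowing (square-root or logarithmic divergence winning over
    constant, with a clearly long final interval) makes the offset the
    SH family -- split by the DC shift when assessable.  A square-root
    amplitude decay to near zero with non-slowing ISI is SupH; anything
    else is FLC.
    """
    amp_best, amp_margin = _best(fits, {"amplitude"})
    isi_best, isi_margin = _best(fits, {"isi", "frequency"})
    if amp_best is None or isi_best is None:
        return UNCLASSIFIED, "not assessed", 0.0
    # how clearly the winning rate law beats the constant alternative
    const_isi = [f for f in fits if f.target == "isi" and f.law == "constant"]
    margin_vs_const = (
        const_isi[0].aicc - isi_best.aicc if const_isi and isi_best.law != "constant" else 0.0
    )
    isis = window.isis[np.isfinite(window.isis)]
    last_isi_long = (
        len(isis) >= 3 and isis[-1] > SLOWING_LAST_ISI_RATIO * float(np.median(isis))
    )
    decel_strong = (
        len(isis) >= 6
        and float(np.median(isis[-3:])) > ACCEL_RATIO * float(np.median(isis[:3]))
    )
    # near a homoclinic the period diverges only logarithmically, so over a
    # finite spike window the observable slowing may be gradual: accept a
    # monotone interval growth when a divergence law clearly wins the fit
    monotone_mild = (
        len(isis) >= 8
        and float(np.median(isis[-3:])) > 1.1 * float(np.median(isis[:3]))
        and margin_vs_const > 2.0  # the divergence law must win clearly
    )
    slowing = isi_best.law in ("sqrt", "log") and (
        last_isi_long or decel_strong or monotone_mild
    )
    flag = "slowing" if slowing else "constant"
    if len(isis) < 3:
        flag = "not assessed"
    if slowing:
        if dc.assessable and dc.present:
            return "SH(+DC)", flag, _confidence(isi_margin, window.low_n)
        return "SH(-DC)/SNIC", flag, _confidence(isi_margin, window.low_n)
    a = np.maximum(window.amplitudes - window.amp_floor, 0.0)
    amax = float(a.max())
    last_small = amax > 0 and a[-1] < NEAR_ZERO_FRACTION * amax
    const_amp = [f for f in fits if f.target == "amplitude" and f.law == "constant"]
    amp_margin_const = (
        const_amp[0].aicc - amp_best.aicc if const_amp and amp_best.law == "sqrt" else 0.0
    )
    sqrt_dominant = amp_margin_const > 6.0 and amax > 0 and a[-1] < 0.65 * amax
    if amp_best.law == "sqrt" and (last_small or sqrt_dominant):
        return "SupH", flag, _confidence(amp_margin, window.low_n)
    return "FLC", flag, _confidence(2.0, window.low_n)


@dataclass
class DynamotypeLabel:
    """Classified onset/offset pair with evidence and confidence."""

    onset: str
    offset: str
    slowing: str  # 'slowing' | 'constant' | 'not assessed'
    confidence: float
    evidence: dict = field(default_factory=dict)

    def __str__(self):
        return f"{self.onset} / {self.offset}"


def classify_seizure(
    rec: Recording | dict,
    n_spikes: int = 10,
    threshold_sd: float = 3.0,
    baseline_window: float = 0.45,
) -> DynamotypeLabel:
    """Full pipeline: features -> scaling fits -> onset/offset decision.

    ``rec`` is a single recording, or a dict with keys among {'DC', 'AC'}
    when both couplings were acquired; spikes are detected on the DC-coupled
    channel if that is all there is, and the DC-shift test runs only on a
    DC-coupled channel.  With fewer than four detected spikes both labels
    are 'unclassified'.
    """
    if isinstance(rec, dict):
        rec_dc = rec.get("DC")
        rec_sig = rec.get("AC") or rec_dc
    else:
        rec_dc = rec if rec.coupling == "DC" else None
        rec_sig = rec
    stats = background_stats(rec_sig)
    series = detect_spikes(
        rec_sig, stats, threshold_sd=threshold_sd, baseline_window=baseline_window
    )
    evidence: dict = {
        "n_spikes": len(series),
        "thresholds": {
            "spike_sd": threshold_sd,
            "near_zero_fraction": NEAR_ZERO_FRACTION,
            "snic_first_isi_ratio": SNIC_FIRST_ISI_RATIO,
            "slowing_last_isi_ratio": SLOWING_LAST_ISI_RATIO,
        },
    }
    defloored = np.maximum(series.amplitudes - series.amp_floor, 0.0) if len(series) else np.array([])
    indistinct = (
        len(series) >= 4
        and series.amp_floor > 0
        and float(np.median(defloored)) < 2.0 * series.amp_floor
    )
    if len(series) < 4 or indistinct:
        evidence["reason"] = (
            "fewer than 4 spikes" if len(series) < 4
            else "spikes not distinguishable from background"
        )
        return DynamotypeLabel(UNCLASSIFIED, UNCLASSIFIED, "not assessed", 0.0, evidence)
    if rec_dc is not None:
        stats_dc = background_stats(rec_dc)
        dc_on = detect_dc_shift(rec_dc, "onset", stats_dc)
        dc_off = detect_dc_shift(rec_dc, "offset", stats_dc)
    else:
        dc_on = DCShiftResult(assessable=False, boundary="onset")
        dc_off = DCShiftResult(assessable=False, boundary="offset")
    win_on, win_off = extract_boundary_windows(series, n_spikes)
    fits_on = fit_scaling_models(win_on, "onset")
    fits_off = fit_scaling_models(win_off, "offset")
    onset, conf_on = classify_onset(fits_on, dc_on, win_on)
    offset, slowing, conf_off = classify_offset(fits_off, dc_off, win_off)
    # a secondary-onset annotation: an abrupt onset that develops sqrt
    # amplitude growth a few seconds in is labelled by its first bifurcation
    evidence.update(
        {
            "fits_onset": fits_on,
            "fits_offset": fits_off,
            "dc_onset": dc_on,
            "dc_offset": dc_off,
            "windows": {"onset": win_on, "offset": win_off},
        }
    )
    return DynamotypeLabel(
        onset=onset,
        offset=offset,
        slowing=slowing,
        confidence=min(conf_on, conf_off),
        evidence=evidence,
    )


def tabulate_cohort(
    labels: list[DynamotypeLabel],
    patients: list | None = None,
    durations: list | None = None,
    min_offset_duration: float = 25.0,
):
    """Cohort tables: counts per onset class, offset class and pair, plus
    per-patient offset-slowing diversity.

    Seizures shorter than ``min_offset_duration`` are excluded from the
    offset tabulation (too few terminal spikes to judge the offset ISI).
    Returns a dict of pandas objects.
    """
    import pandas as pd

    n = len(labels)
    patients = list(patients) if patients is not None else ["p0"] * n
    durations = list(durations) if durations is not None else [math.inf] * n
    rows = []
    for lab, pat, dur in zip(labels, patients, durations):
        rows.append(
            {
                "patient": pat,
                "onset": lab.onset,
                "offset": lab.offset if dur >= min_offset_duration else "excluded",
                "slowing": lab.slowing if dur >= min_offset_duration else "not assessed",
                "duration": dur,
            }
        )
    df = pd.DataFrame(rows)
    included = df[df["offset"] != "excluded"]
    pair = (
        included.groupby(["onset", "offset"]).size().unstack(fill_value=0)
        if len(included)
        else pd.DataFrame()
    )
    diversity = (
        included[included["slowing"] != "not assessed"]
        .groupby("patient")["slowing"]
        .nunique()
        .rename("offset_diversity")
    )
    return {
        "seizures": df,
        "onset_counts": df["onset"].value_counts(),
        "offset_counts": included["offset"].value_counts() if len(included) else pd.Series(dtype=int),
        "pair_table": pair,
        "offset_diversity": diversity,
        "n_excluded_offset": int((df["offset"] == "excluded").sum()),
    }
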