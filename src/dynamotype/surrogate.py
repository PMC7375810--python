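"""Surrogate seizure generator with prescribed onset/offset scaling laws.

Builds spike trains whose first/last spikes follow the amplitude and
frequency laws of the six seizure bifurcations (square-root growth for SupH,
square-root frequency for SNIC, logarithmic inter-spike-interval divergence
for SH, abrupt behaviour for SN/SubH/FLC), renders them as biphasic
transients on Gaussian background, and emulates AC-coupled hardware by
high-pass filtering a DC-coupled channel that may carry baseline steps.

These fixtures give the classifier analytic ground truth that is
independent of the differential-equation simulator.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "ONSET_LABELS",
    "OFFSET_LABELS",
    "ScalingLawSpec",
    "SurrogateSeizureSpec",
    "SpikeTrain",
    "Waveform",
    "gen_spike_train",
    "render_waveform",
    "ac_filter",
]

ONSET_LABELS = ("SN", "SubH", "SupH", "SNIC")
OFFSET_LABELS = ("SH", "SNIC", "SupH", "FLC")


@dataclass(frozen=True)
class ScalingLawSpec:
    """One scaling law: how amplitude or frequency depends on the distance
    ``|t - t_bif|`` to the bifurcation time."""

    law: str  # 'constant' | 'sqrt' | 'log'
    applies_to: str  # 'amplitude' | 'frequency'
    t_bif: float
    coefficient: float = 1.0

    def __post_init__(self):
        if self.law not in ("constant", "sqrt", "log"):
            raise ValueError(f"unknown law {self.law!r}")
        if self.applies_to not in ("amplitude", "frequency"):
            raise ValueError(f"law applies to amplitude or frequency, not {self.applies_to!r}")


@dataclass(frozen=True)
class SurrogateSeizureSpec:
    """Ground-truth recipe for one surrogate seizure.

    Amplitudes are in units of the background standard deviation; a spike
    amplitude of 10 therefore means SNR 10.  ``n_law`` spikes at each end of
    the seizure follow the onset/offset law; the middle runs at the nominal
    rate and amplitude.  DC-shift fields describe a baseline step on the
    DC-coupled channel at the corresponding boundary (polarity 0 disables).
    """

    onset: str = "SN"
    offset: str = "SH"
    duration: float = 60.0
    rate: float = 8.0  # nominal mid-seizure spike rate (Hz)
    amplitude: float = 10.0  # nominal peak-to-peak, in background-SD units
    n_law: int = 10
    dc_onset_polarity: int = 0  # -1, 0, +1
    dc_offset_polarity: int = 0
    dc_magnitude: float = 6.0  # in background-SD units
    dc_rise: float = 0.3  # s
    dc_persist: float = 2.0  # s
    isi_jitter: float = 0.0  # multiplicative, fractional
    amp_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.onset not in ONSET_LABELS:
            raise ValueError(f"onset must be one of {ONSET_LABELS}")
        if self.offset not in OFFSET_LABELS:
            raise ValueError(f"offset must be one of {OFFSET_LABELS}")
        if self.duration <= 0 or self.rate <= 0 or self.amplitude <= 0:
            raise ValueError("duration, rate and amplitude must be positive")
        if self.dc_onset_polarity and self.onset != "SN":
            raise ValueError("an onset DC shift is admissible only for SN onsets")
        if self.dc_offset_polarity and self.offset != "SH":
            raise ValueError("an offset DC shift is admissible only for SH offsets")
        if self.dc_rise >= self.dc_persist:
            raise ValueError("DC rise time must be shorter than its persistence")

    @property
    def grouped_onset(self) -> str:
        """Ground-truth onset class in the grouped taxonomy."""
        if self.onset == "SupH":
            return "SupH"
        if self.onset == "SNIC":
            return "SNIC"
        if self.onset == "SN" and self.dc_onset_polarity:
            return "SN(+DC)"
        return "SN(-DC)/SubH"

    @property
    def grouped_offset(self) -> str:
        if self.offset == "SupH":
            return "SupH"
        if self.offset == "FLC":
            return "FLC"
        if self.offset == "SH" and self.dc_offset_polarity:
            return "SH(+DC)"
        return "SH(-DC)/SNIC"


@dataclass
class SpikeTrain:
    """Spike times (s, within [0, duration]) and peak-to-peak amplitudes
    (background-SD units), with the generating spec as ground truth."""

    times: np.ndarray
    amplitudes: np.ndarray
    spec: SurrogateSeizureSpec

    def __post_init__(self):
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if np.any(self.amplitudes <= 0):
            raise ValueError("spike amplitudes must be positive")

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.times)


# ---------------------------------------------------------------------------
# spike-train synthesis
# ---------------------------------------------------------------------------

def _onset_window(spec: SurrogateSeizureSpec):
    """Times and amplitudes of the first ``n_law`` spikes (t=0 is onset)."""
    k = spec.n_law
    isi = 1.0 / spec.rate
    t_span = k * isi  # time over which the onset law unfolds
    if spec.onset == "SupH":
        # constant rate; amplitude grows as sqrt(t - t_on): the first spike
        # sits half an interval after onset, so it starts near zero
        t = isi * (np.arange(k) + 0.5)
        a = spec.amplitude * np.sqrt(t / t_span)
    elif spec.onset == "SNIC":
        # frequency f = rate * sqrt(t/T): long first interval, then
        # acceleration; each gap is the instantaneous period 1/f.  The law
        # span T is generous so the whole window stays on the law
        T = 3.0 * t_span
        times = []
        t0 = 0.01 * T
        for _ in range(k):
            times.append(t0)
            t0 = t0 + isi / math.sqrt(min(t0 / T, 1.0))
        t = np.array(times)
        a = np.full(k, spec.amplitude)
    else:  # SN / SubH: abrupt full-amplitude spiking
        t = isi * np.arange(1, k + 1)
        a = np.full(k, spec.amplitude)
    return t, a


def _offset_window(spec: SurrogateSeizureSpec):
    """Times/amplitudes of the last ``n_law`` spikes (t=0 is offset; times
    negative, increasing toward 0)."""
    k = spec.n_law
    isi = 1.0 / spec.rate
    t_span = k * isi
    if spec.offset == "SH":
        # ISI = isi * (1 + 0.8 * ln(t_span / (t_off - t))): logarithmic
        # divergence of the inter-spike interval toward the offset, steep
        # enough that the terminal slowing survives measurement jitter
        times = []
        t = -0.02 * t_span  # last spike just before the homoclinic time
        for _ in range(k):
            times.append(t)
            gap = isi * (1.0 + 0.8 * math.log(t_span / (-t)))
            t = t - gap
        t = np.array(times[::-1])
        a = np.full(k, spec.amplitude)
    elif spec.offset == "SNIC":
        # frequency f = rate * sqrt((t_off - t)/T): deceleration with a
        # long final interval
        T = 3.0 * t_span
        times = []
        t0 = -0.01 * T
        for _ in range(k):
            times.append(t0)
            t0 = t0 - isi / math.sqrt(min(-t0 / T, 1.0))
        t = np.array(times[::-1])
        a = np.full(k, spec.amplitude)
    elif spec.offset == "SupH":
        t = -isi * (np.arange(k, 0, -1) - 0.5)
        a = spec.amplitude * np.sqrt(-t / t_span)
    else:  # FLC: abrupt stop at full amplitude
        t = -isi * np.arange(k, 0, -1)
        a = np.full(k, spec.amplitude)
    return t, a


def gen_spike_train(spec: SurrogateSeizureSpec) -> SpikeTrain:
    """Generate spike times and amplitudes following the spec's laws.

    With zero jitter the onset/offset windows follow their scaling laws
    exactly; the middle of the seizure runs at the nominal rate with a
    smooth (linear) interpolation between the window edges.  Jitter is
    multiplicative per spike, seeded.
    """
    isi = 1.0 / spec.rate
    t_on, a_on = _onset_window(spec)
    t_off_rel, a_off = _offset_window(spec)
    t_off = spec.duration + t_off_rel  # absolute times of the tail spikes
    lead = t_on[-1]
    tail0 = t_off[0]
    if tail0 - lead < 2 * isi:
        raise ValueError(
            "duration too short for the requested onset/offset law windows"
        )
    mid_t = np.arange(lead + isi, tail0 - 0.5 * isi, isi)
    # amplitudes interpolate between the two window edges
    if len(mid_t):
        w = (mid_t - lead) / (tail0 - lead)
        mid_a = a_on[-1] * (1 - w) + a_off[0] * w
    else:
        mid_a = np.array([])
    t = np.concatenate([t_on, mid_t, t_off])
    a = np.concatenate([a_on, mid_a, a_off])

    if spec.isi_jitter > 0 or spec.amp_jitter > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.isi_jitter > 0:
            gaps = np.diff(np.concatenate([[0.0], t]))
            gaps = gaps * np.clip(
                1.0 + spec.isi_jitter * rng.standard_normal(len(gaps)), 0.3, 3.0
            )
            t = np.cumsum(gaps)
            t = t / t[-1] * (spec.duration + t_off_rel[-1])
        if spec.amp_jitter > 0:
            a = a * np.clip(
                1.0 + spec.amp_jitter * rng.standard_normal(len(a)), 0.2, 3.0
            )
    if np.any(np.diff(t) <= 0) or np.any(a <= 0):
        raise ValueError("spec implies non-positive inter-spike interval or amplitude")
    return SpikeTrain(times=t, amplitudes=a, spec=spec)


# ---------------------------------------------------------------------------
# waveform rendering
# ---------------------------------------------------------------------------

def _biphasic_kernel(fs: float, width: float) -> np.ndarray:
    """Biphasic transient (derivative of a Gaussian), unit peak-to-peak.

    ``width`` is the full width at half maximum of each lobe's envelope.
    """
    sigma = width / 2.355
    half = int(round(4 * sigma * fs))
    tt = np.arange(-half, half + 1) / fs
    k = -tt / sigma * np.exp(-(tt**2) / (2 * sigma**2))
    return k / (k.max() - k.min())


def _dc_step(t: np.ndarray, t0: float, magnitude: float, rise: float, persist: float):
    """Baseline step: sigmoid rise over ``rise`` s at ``t0``, a plateau for
    ``persist`` s, then a linear return to baseline."""
    arg = np.clip(-(t - t0) / (rise / 8.0), -60.0, 60.0)
    out = magnitude / (1.0 + np.exp(arg))
    t_end = t0 + persist
    fall = np.clip((t - t_end) / max(persist, 1.0), 0.0, 1.0)
    return out * (1.0 - fall)


@dataclass
class Waveform:
    """Rendered surrogate: a DC-coupled channel and its AC-filtered twin."""

    t: np.ndarray
    dc: np.ndarray
    ac: np.ndarray
    fs: float
    onset: float  # marked seizure onset (s from record start)
    offset: float
    background_sd: float
    train: SpikeTrain


def render_waveform(
    train: SpikeTrain,
    fs: float = 512.0,
    kernel_width: float = 0.05,
    background_sd: float = 1.0,
    pre: float = 15.0,
    post: float = 10.0,
    ac_cutoff: float = 0.3,
    seed: int | None = None,
) -> Waveform:
    """Render a spike train as sampled waveforms.

    Each spike becomes a biphasic transient of the given width whose
    peak-to-peak amplitude is ``amplitude * background_sd``; the background
    is white Gaussian noise.  The DC channel carries the spec's baseline
    steps; the AC channel is the zero-phase high-pass filtered version
    (hardware emulation).
    """
    if kernel_width >= 0.2:
        raise ValueError("spikes are fast transients: kernel width must be < 200 ms")
    if fs * kernel_width < 8:
        raise ValueError("sampling rate too low to resolve the spike kernel")
    spec = train.spec
    dur = pre + spec.duration + post
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    x = rng.standard_normal(n) * background_sd
    kern = _biphasic_kernel(fs, kernel_width)
    half = len(kern) // 2
    for ti, ai in zip(train.times, train.amplitudes):
        i = int(round((pre + ti) * fs))
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        x[lo:hi] += ai * background_sd * kern[lo - (i - half) : len(kern) - (i + half + 1 - hi)]
    dc = x.copy()
    if spec.dc_onset_polarity:
        dc += _dc_step(
            t,
            pre,
            spec.dc_onset_polarity * spec.dc_magnitude * background_sd,
            spec.dc_rise,
            spec.dc_persist,
        )
    if spec.dc_offset_polarity:
        dc += _dc_step(
            t,
            pre + spec.duration,
            spec.dc_offset_polarity * spec.dc_magnitude * background_sd,
            spec.dc_rise,
            spec.dc_persist,
        )
    ac = ac_filter(dc, fs, ac_cutoff)
    return Waveform(
        t=t,
        dc=dc,
        ac=ac,
        fs=fs,
        onset=pre,
        offset=pre + spec.duration,
        background_sd=background_sd,
        train=train,
    )


def ac_filter(waveform: np.ndarray, fs: float, cutoff: float = 0.3) -> np.ndarray:
    """Zero-phase high-pass filter emulating AC-coupled recording hardware.

    Removes baseline steps (after settling) while leaving oscillatory
    content above the cutoff untouched.
    """
    if not 0 < cutoff < fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    sos = signal.butter(2, cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(waveform, dtype=float))
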