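"""Beat detection and per-contraction kinetics.

A contraction cycle is summarized by its diastolic force F_D (minimum within
a window of +/- 50% of the stimulus interval around the peak), peak force
F_max, amplitude F_amp = F_max - F_D, and the 10%-threshold kinetics: TTP90
(first force <= 0.1*F_amp moving backward from the peak, to the peak), TTR90
(peak to first force <= 0.1*F_amp moving forward) and CD90 = TTP90 + TTR90.
Times are reported at sample resolution; no sub-sample interpolation.

Candidate peaks are local maxima whose prominence strictly exceeds the
minimum peak height (maximum noise amplitude plus one noise SD). Only
rocking-free periods are analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .preprocess import AnalyzableTrace, NoiseEstimate

BEATING_THRESHOLD_UN = 50.0  # screening rule: beating iff any F_amp > 50 μN


@dataclass
class Beat:
    peak_time: float                  # s
    peak_index: int
    F_D: float = np.nan               # μN
    F_max: float = np.nan             # μN
    F_amp: float = np.nan             # μN
    TTP90: float = np.nan             # ms
    TTR90: float = np.nan             # ms
    CD90: float = np.nan              # ms
    stimulus_time: Optional[float] = None
    captured: bool = False
    measurable: bool = False


@dataclass
class PeriodSummary:
    pacing_hz: float
    n_beats: int
    n_stimuli: int
    F_amp: float = np.nan
    F_D: float = np.nan
    TTP90: float = np.nan
    TTR90: float = np.nan
    CD90: float = np.nan


def candidate_peak_indices(force: np.ndarray, min_height: float) -> np.ndarray:
    """Local maxima with prominence strictly above ``min_height``."""
    force = np.asarray(force, dtype=float)
    idx, _ = find_peaks(force)
    if idx.size == 0:
        return idx
    prom = peak_prominences(force, idx)[0]
    return idx[prom > min_height]


def detect_beats(trace: AnalyzableTrace, noise: NoiseEstimate,
                 stimulus_times: np.ndarray | None = None) -> list[Beat]:
    """Candidate beats: threshold-passing peaks inside rocker-off spans.

    Each beat is associated to the nearest preceding stimulus when one exists
    within the current stimulus interval; when several candidate peaks fall
    within one stimulus interval the highest is kept (ties: earlier).
    """
    if trace.force.size == 0:
        return []
    stim = np.asarray(trace.stimulus_times if stimulus_times is None else stimulus_times,
                      dtype=float)
    fs = trace.sample_rate
    idx = candidate_peak_indices(trace.force, noise.peak_threshold)
    if idx.size == 0:
        return []
    t_peak = idx / fs
    keep = trace.in_valid_interval(t_peak)
    idx, t_peak = idx[keep], t_peak[keep]

    beats: list[Beat] = []
    if stim.size:
        owner = np.searchsorted(stim, t_peak, side="right") - 1
    else:
        owner = np.full(t_peak.size, -1)
    # keep the highest peak per owning stimulus interval
    best: dict[int, int] = {}
    for k, (i, o) in enumerate(zip(idx, owner)):
        if o < 0:
            beats.append(Beat(peak_time=float(t_peak[k]), peak_index=int(i)))
            continue
        o = int(o)
        if o not in best or trace.force[i] > trace.force[idx[best[o]]]:
            best[o] = k
    for o, k in sorted(best.items()):
        i = idx[k]
        t = float(t_peak[k])
        t_stim = float(stim[o])
        nxt = stim[o + 1] if o + 1 < stim.size else np.inf
        captured = t < nxt
        beats.append(Beat(peak_time=t, peak_index=int(i),
                          stimulus_time=t_stim, captured=captured))
    beats.sort(key=lambda b: b.peak_time)
    return beats


def measure_beat(force: np.ndarray, sample_rate: float, beat: Beat,
                 stimulus_interval_ms: float) -> Beat:
    """Fill F_D/F_max/F_amp and the 10%-threshold kinetics of one beat."""
    half = int(round(0.5 * stimulus_interval_ms / 1000.0 * sample_rate))
    i = beat.peak_index
    lo = max(0, i - half)
    hi = min(force.size, i + half + 1)
    seg = force[lo:hi]
    beat.F_max = float(force[i])
    beat.F_D = float(seg.min())
    beat.F_amp = beat.F_max - beat.F_D
    thr = beat.F_D + 0.1 * beat.F_amp
    back = np.flatnonzero(force[lo:i + 1] <= thr)
    fwd = np.flatnonzero(force[i:hi] <= thr)
    if back.size == 0 or fwd.size == 0:
        beat.measurable = False
        return beat
    i_on = lo + back[-1]       # first sample <= threshold moving backward
    i_off = i + fwd[0]         # first sample <= threshold moving forward
    beat.TTP90 = (i - i_on) / sample_rate * 1000.0
    beat.TTR90 = (i_off - i) / sample_rate * 1000.0
    beat.CD90 = beat.TTP90 + beat.TTR90
    beat.measurable = True
    return beat


def measure_beats(trace: AnalyzableTrace, beats: list[Beat],
                  stimulus_interval_ms: float) -> list[Beat]:
    return [measure_beat(trace.force, trace.sample_rate, b, stimulus_interval_ms)
            for b in beats]


def classify_beating(beats: list[Beat],
                     threshold: float = BEATING_THRESHOLD_UN) -> bool:
    """Screening rule: beating iff any beat amplitude strictly exceeds the
    threshold (default 50 μN)."""
    return any(np.isfinite(b.F_amp) and b.F_amp > threshold for b in beats)


def summarize_period(beats: list[Beat], n_stimuli: int,
                     pacing_hz: float = np.nan) -> PeriodSummary:
    """Arithmetic means of per-beat parameters over measurable beats."""
    ok = [b for b in beats if b.measurable]
    s = PeriodSummary(pacing_hz=pacing_hz, n_beats=len(ok), n_stimuli=n_stimuli)
    if ok:
        s.F_amp = float(np.mean([b.F_amp for b in ok]))
        s.F_D = float(np.mean([b.F_D for b in ok]))
        s.TTP90 = float(np.mean([b.TTP90 for b in ok]))
        s.TTR90 = float(np.mean([b.TTR90 for b in ok]))
        s.CD90 = float(np.mean([b.CD90 for b in ok]))
    return s


def beats_table(beats: list[Beat]) -> pd.DataFrame:
    """Per-beat table (CSV-ready)."""
    return pd.DataFrame([b.__dict__ for b in beats])
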