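"""Conditioning of raw force recordings.

The device streams at 400 Hz; analysis operates at 200 Hz after pairwise
mean downsampling. Denoising is a central moving median (radius 10) followed
by a central moving mean (radius 5), radii in samples at 200 Hz; edges are
handled by window truncation. Sensor noise is estimated from 200 ms windows
directly before stimuli delivered at <= 1 Hz during rocking-free periods:
contractions are always over well before the next stimulus at such rates, so
those windows contain nothing but noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import ForceRecording

log = logging.getLogger(__name__)

ANALYSIS_RATE = 200.0   # Hz
MEDIAN_RADIUS = 10      # samples -> 21-sample window
MEAN_RADIUS = 5         # samples -> 11-sample window
NOISE_WINDOW_S = 0.200
SLOW_PACING_MIN_ISI_S = 1.0   # preceding inter-stimulus interval >= 1 s (ties included)


@dataclass(frozen=True)
class NoiseEstimate:
    """Pooled sensor-noise statistics from pre-stimulus windows."""

    sd: float             # μN, pooled SD after per-window demeaning
    max_amplitude: float  # μN, max over windows of (max - min)
    n_windows: int

    @property
    def peak_threshold(self) -> float:
        """Minimum peak height used by beat detection."""
        return self.max_amplitude + self.sd


@dataclass
class AnalyzableTrace:
    """Denoised 200 Hz trace restricted (logically) to rocker-off spans."""

    sample_rate: float
    force: np.ndarray
    valid_intervals: list[tuple[float, float]]   # rocker-off spans, s
    stimulus_times: np.ndarray
    stimuli: pd.DataFrame | None = None

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.force.size) / self.sample_rate

    def in_valid_interval(self, t: float | np.ndarray):
        t = np.asarray(t, dtype=float)
        ok = np.zeros(t.shape, dtype=bool)
        for a, b in self.valid_intervals:
            ok |= (t >= a) & (t < b)
        return ok


def downsample_mean(recording: ForceRecording) -> ForceRecording:
    """400 -> 200 Hz by averaging consecutive sample pairs.

    Stimulus timestamps are carried over unchanged; an odd trailing sample
    is dropped.
    """
    if not np.isclose(recording.sample_rate, 2 * ANALYSIS_RATE):
        raise ValueError(f"expected a 400 Hz recording, got {recording.sample_rate} Hz")
    f = recording.force
    if f.size % 2:
        log.info("downsample_mean: dropping odd trailing sample")
        f = f[:-1]
    out = f.reshape(-1, 2).mean(axis=1)
    return ForceRecording(
        sample_rate=ANALYSIS_RATE, force=out,
        stimulus_times=recording.stimulus_times.copy(),
        rocker_intervals=list(recording.rocker_intervals),
        stimuli=None if recording.stimuli is None else recording.stimuli.copy(),
        ground_truth=recording.ground_truth,
    )


def denoise(force: np.ndarray) -> np.ndarray:
    """Central moving median (21-sample window) then moving mean (11 samples).

    Edge windows are truncated rather than padded.
    """
    force = np.asarray(force, dtype=float)
    win_med = 2 * MEDIAN_RADIUS + 1
    if force.size < win_med:
        raise ValueError(f"trace shorter than the {win_med}-sample median window")
    s = pd.Series(force)
    med = s.rolling(win_med, center=True, min_periods=1).median()
    out = med.rolling(2 * MEAN_RADIUS + 1, center=True, min_periods=1).mean()
    return out.to_numpy()


def make_analyzable(recording: ForceRecording) -> AnalyzableTrace:
    """Downsample if needed, denoise, and attach rocker-off spans."""
    rec = recording
    if np.isclose(rec.sample_rate, 2 * ANALYSIS_RATE):
        rec = downsample_mean(rec)
    elif not np.isclose(rec.sample_rate, ANALYSIS_RATE):
        raise ValueError(f"unsupported sample rate {rec.sample_rate} Hz")
    return AnalyzableTrace(
        sample_rate=rec.sample_rate,
        force=denoise(rec.force),
        valid_intervals=rec.rocker_off_spans(),
        stimulus_times=rec.stimulus_times,
        stimuli=rec.stimuli,
    )


def estimate_noise(trace: AnalyzableTrace,
                   stimulus_times: np.ndarray | None = None) -> NoiseEstimate:
    """Pool 200 ms pre-stimulus windows at slow pacing into a noise estimate.

    A window qualifies when the preceding inter-stimulus interval is at least
    1 s (pacing <= 1 Hz, ties included) and the whole window lies inside a
    rocker-off span. Windows that would overlap a rocker-on interval are
    excluded. Each window is demeaned before pooling.
    """
    stim = np.asarray(trace.stimulus_times if stimulus_times is None else stimulus_times,
                      dtype=float)
    fs = trace.sample_rate
    n_win = int(round(NOISE_WINDOW_S * fs))
    pooled: list[np.ndarray] = []
    max_amp = 0.0
    n_windows = 0
    for i, t in enumerate(stim):
        isi = t - stim[i - 1] if i > 0 else np.inf
        if isi < SLOW_PACING_MIN_ISI_S:
            continue
        a, b = t - NOISE_WINDOW_S, t
        if not (trace.in_valid_interval(a) and trace.in_valid_interval(max(a, b - 1e-9))):
            continue
        # require the whole window within one rocker-off span
        if not any(a >= lo and b <= hi for lo, hi in trace.valid_intervals):
            continue
        i1 = int(round(t * fs))
        i0 = i1 - n_win
        if i0 < 0 or i1 > trace.force.size:
            continue
        w = trace.force[i0:i1]
        pooled.append(w - w.mean())
        max_amp = max(max_amp, float(w.max() - w.min()))
        n_windows += 1
    if n_windows == 0:
        raise ValueError(
            "no qualifying pre-stimulus noise window (need rocker-off pacing <= 1 Hz); "
            "supply a fallback NoiseEstimate explicitly"
        )
    allw = np.concatenate(pooled)
    sd = float(allw.std(ddof=1)) if allw.size > 1 else 0.0
    return NoiseEstimate(sd=sd, max_amplitude=max_amp, n_windows=n_windows)
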