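"""Pacing protocols and capture analysis: refractory period and f_max.

The S1-S2 protocol paces at a 0.5 Hz baseline; after 22 s of normal pacing,
three intertwined S2 extrastimuli are delivered at a defined coupling
interval, followed by another 22 s of baseline pacing and a 6 s train at the
frequency corresponding to that interval (e.g., 500 ms -> 2 Hz). The scheme
repeats down a fixed ladder of S2 intervals. An S2 counts as captured when a
peak (any positive excursion above the minimum peak height) occurs between
the S2 stimulus and the following S1 stimulus; a ladder step is captured only
if all three of its S2 beats are. The refractory period is the interval
immediately preceding the first not-captured step.

For the maximum captured frequency, a separate ladder of constant-frequency
trains (25 beats per step, 0.2-5.0 Hz) is analyzed: a frequency is captured
iff each of the last five stimuli of its train elicits a detected beat, and
f_max is the last captured frequency before the first non-captured one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .beats import candidate_peak_indices
from .preprocess import AnalyzableTrace, NoiseEstimate
from .protocol import ProtocolScript

#: Printed S2 coupling-interval ladder, ms, strictly decreasing.
S2_LADDER_MS: tuple[float, ...] = (
    750, 500, 400, 300, 275, 250, 240, 230, 220, 210,
    200, 190, 180, 170, 160, 150, 140, 130, 120, 110, 100,
)

#: Printed constant-frequency ladder, Hz, strictly increasing.
FREQUENCY_LADDER_HZ: tuple[float, ...] = (
    0.2, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0,
)


def s2_interval_to_frequency(interval_ms: float) -> float:
    """Pacing frequency (Hz) corresponding to an S2 interval (ms)."""
    if interval_ms <= 0:
        raise ValueError("interval must be > 0")
    return 1000.0 / interval_ms


@dataclass(frozen=True)
class S1S2Protocol:
    """Configuration of the S1-S2 extrastimulus protocol."""

    baseline_interval_ms: float = 2000.0
    ladder_ms: tuple[float, ...] = S2_LADDER_MS
    settle_s: float = 22.0
    train_s: float = 6.0
    n_s2: int = 3
    s2_spacing_beats: int = 4   # S1 beats between consecutive S2 insertions (>= 3)
    rocker_during_settle: bool = True

    def __post_init__(self):
        if any(nxt >= prv for prv, nxt in zip(self.ladder_ms[:-1], self.ladder_ms[1:])) or \
           any(x <= 0 for x in self.ladder_ms):
            raise ValueError("S2 ladder must be strictly decreasing and positive")

    def build(self) -> ProtocolScript:
        return build_s1s2_protocol(self)


@dataclass(frozen=True)
class FrequencyProtocol:
    """Configuration of the incremental constant-frequency protocol."""

    ladder_hz: tuple[float, ...] = FREQUENCY_LADDER_HZ
    beats_per_step: int = 25
    start_s: float = 2.0

    def __post_init__(self):
        if any(nxt <= prv for prv, nxt in zip(self.ladder_hz[:-1], self.ladder_hz[1:])) or \
           any(x <= 0 for x in self.ladder_hz):
            raise ValueError("frequency ladder must be strictly increasing and positive")

    def build(self) -> ProtocolScript:
        return build_frequency_protocol(self)


def build_s1s2_protocol(config: S1S2Protocol | None = None) -> ProtocolScript:
    """Emit the stimulation script of the S1-S2 protocol.

    Each ladder step: 22 s of 0.5 Hz S1 pacing, three S2 insertions (each
    delivered at the S2 interval after a regular S1, with the S1 grid
    continuing unshifted and the S2s separated by >= 3 S1 beats), another
    22 s of baseline pacing, then a 6 s constant train at 1000/interval Hz.
    """
    cfg = config or S1S2Protocol()
    base_s = cfg.baseline_interval_ms / 1000.0
    rows: list[dict] = []
    rocker: list[tuple[float, float]] = []
    t = 0.0

    def s1_run(t0: float, n: int, step: int) -> float:
        for j in range(n):
            rows.append(dict(time_s=t0 + j * base_s, kind="S1",
                             interval_ms=cfg.baseline_interval_ms, step=step))
        return t0 + n * base_s

    for step, interval in enumerate(cfg.ladder_ms):
        n_settle = max(1, int(round(cfg.settle_s / base_s)))
        settle_start = t
        t = s1_run(t, n_settle, step)
        if cfg.rocker_during_settle and cfg.settle_s >= 12:
            rocker.append((settle_start + 2.0, settle_start + cfg.settle_s - 8.0))
        # S2 phase: S2 after an S1, then s2_spacing_beats S1 beats, repeat
        for k in range(cfg.n_s2):
            rows.append(dict(time_s=t, kind="S1",
                             interval_ms=cfg.baseline_interval_ms, step=step))
            rows.append(dict(time_s=t + interval / 1000.0, kind="S2",
                             interval_ms=interval, step=step))
            t += base_s
            n_between = cfg.s2_spacing_beats if k < cfg.n_s2 - 1 else 1
            t = s1_run(t, n_between, step)
        t = s1_run(t, max(1, int(round(cfg.settle_s / base_s))), step)
        # constant-frequency train at the corresponding frequency
        f = s2_interval_to_frequency(interval)
        n_train = max(1, int(round(cfg.train_s * f)))
        for j in range(n_train):
            rows.append(dict(time_s=t + j * interval / 1000.0, kind="train",
                             interval_ms=interval, step=step))
        t += n_train * interval / 1000.0 + base_s
    st = pd.DataFrame(rows, columns=["time_s", "kind", "interval_ms", "step"])
    return ProtocolScript(stimuli=st, rocker_on=rocker)


def build_frequency_protocol(config: FrequencyProtocol | None = None) -> ProtocolScript:
    """Emit the incremental constant-frequency script (25 beats per step)."""
    cfg = config or FrequencyProtocol()
    rows: list[dict] = []
    t = cfg.start_s
    for step, f in enumerate(cfg.ladder_hz):
        interval_s = 1.0 / f
        for j in range(cfg.beats_per_step):
            rows.append(dict(time_s=t + j * interval_s, kind="train",
                             interval_ms=1000.0 * interval_s, step=step))
        t += cfg.beats_per_step * interval_s
    st = pd.DataFrame(rows, columns=["time_s", "kind", "interval_ms", "step"])
    return ProtocolScript(stimuli=st, rocker_on=[])


# ---------------------------------------------------------------------------
# capture analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CensoredValue:
    """A measured value with an explicit censoring flag (never a sentinel)."""

    value: Optional[float]
    flag: str   # 'measured' | 'below_min' | 'above_max' | 'at_max' | 'unevaluable'

    @property
    def is_measured(self) -> bool:
        return self.flag == "measured"


def _window_has_peak(trace: AnalyzableTrace, t0: float, t1: float,
                     min_height: float) -> bool:
    """Open-interval capture test: a prominent local maximum in (t0, t1)."""
    fs = trace.sample_rate
    i0 = int(np.floor(t0 * fs)) + 1
    i1 = int(np.ceil(t1 * fs))
    i0, i1 = max(0, i0), min(trace.force.size, i1)
    if i1 - i0 < 3:
        return False
    return candidate_peak_indices(trace.force[i0:i1], min_height).size > 0


def detect_capture_s2(trace: AnalyzableTrace, stimuli: pd.DataFrame,
                      noise: NoiseEstimate) -> pd.DataFrame:
    """Per-ladder-step S2 capture table.

    For every S2 stimulus the open interval up to the following S1 stimulus is
    searched for a detected peak; a step is captured iff all of its S2 beats
    are. Steps whose S2 stimuli are missing from the log are unevaluable.
    """
    thr = noise.peak_threshold
    times = stimuli["time_s"].to_numpy(float)
    rows = []
    s2 = stimuli[stimuli["kind"] == "S2"]
    expected = s2.groupby("step")["interval_ms"].first()
    for step, interval in expected.items():
        grp = s2[s2["step"] == step]
        n_expected = len(grp)
        caps = []
        for t in grp["time_s"]:
            later = times[times > t + 1e-9]
            if later.size == 0:
                caps.append(None)
                continue
            caps.append(_window_has_peak(trace, float(t), float(later[0]), thr))
        evaluable = n_expected >= 3 and all(c is not None for c in caps)
        captured = evaluable and all(caps)
        rows.append(dict(step=int(step), interval_ms=float(interval),
                         n_s2=n_expected, evaluable=evaluable, captured=bool(captured)))
    out = pd.DataFrame(rows).sort_values("interval_ms", ascending=False)
    return out.reset_index(drop=True)


def refractory_period(capture_table: pd.DataFrame) -> CensoredValue:
    """RP = ladder interval immediately preceding the first not-captured step."""
    tab = capture_table.sort_values("interval_ms", ascending=False).reset_index(drop=True)
    for i, row in tab.iterrows():
        if not row["evaluable"]:
            return CensoredValue(None, "unevaluable")
        if not row["captured"]:
            if i == 0:
                return CensoredValue(None, "above_max")
            return CensoredValue(float(tab.loc[i - 1, "interval_ms"]), "measured")
    return CensoredValue(None, "below_min")


def detect_capture_frequency(trace: AnalyzableTrace, stimuli: pd.DataFrame,
                             noise: NoiseEstimate, kind: str = "train",
                             n_test: int = 5) -> pd.DataFrame:
    """Per-frequency capture table from constant-frequency trains.

    The last ``n_test`` stimuli of each train are tested individually (peak in
    the open stimulus-to-next-stimulus window; the final stimulus uses one
    nominal interval); the frequency is captured iff all of them are.
    """
    thr = noise.peak_threshold
    rows = []
    trains = stimuli[stimuli["kind"] == kind]
    for step in sorted(trains["step"].unique()):
        grp = trains[trains["step"] == step].sort_values("time_s")
        interval_s = float(grp["interval_ms"].iloc[0]) / 1000.0
        f = 1.0 / interval_s
        t = grp["time_s"].to_numpy(float)
        if t.size < n_test:
            rows.append(dict(step=int(step), frequency_hz=f, evaluable=False,
                             captured=False))
            continue
        caps = []
        for j in range(t.size - n_test, t.size):
            t1 = t[j + 1] if j + 1 < t.size else t[j] + interval_s
            caps.append(_window_has_peak(trace, t[j], t1, thr))
        rows.append(dict(step=int(step), frequency_hz=f, evaluable=True,
                         captured=all(caps)))
    out = pd.DataFrame(rows).sort_values("frequency_hz").reset_index(drop=True)
    return out


def max_frequency(trace: AnalyzableTrace, stimuli: pd.DataFrame,
                  noise: NoiseEstimate, kind: str = "train") -> CensoredValue:
    """f_max = last captured frequency before the first non-captured one."""
    tab = detect_capture_frequency(trace, stimuli, noise, kind=kind)
    if tab.empty:
        return CensoredValue(None, "unevaluable")
    last_captured = None
    for _, row in tab.iterrows():
        if not row["evaluable"]:
            return CensoredValue(None, "unevaluable")
        if row["captured"]:
            last_captured = float(row["frequency_hz"])
        else:
            if last_captured is None:
                return CensoredValue(None, "below_min")
            return CensoredValue(last_captured, "measured")
    return CensoredValue(last_captured, "at_max")


def rp_percent_change(rp_before: CensoredValue | float,
                      rp_after: CensoredValue | float) -> float:
    """Percent change of the refractory period, 100*(after-before)/before."""
    def _val(x):
        if isinstance(x, CensoredValue):
            if not x.is_measured:
                raise ValueError(f"censored refractory period ({x.flag}) has no percent change")
            return x.value
        return float(x)

    b, a = _val(rp_before), _val(rp_after)
    return 100.0 * (a - b) / b
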