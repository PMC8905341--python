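"""Force-recording container and its on-disk CSV/JSON schema (v1).

A recording is what the culture device streams: a force trace at a nominal
400 Hz, the stimulation timestamps recorded in synchrony, and the rocker
(medium agitation) schedule. Simulated recordings additionally carry a
ground-truth sidecar (true activation times and twitch parameters) used by
parameter-recovery tests.

Files written for base path ``<base>``:
  <base>_trace.csv   columns time_s, force_uN
  <base>_events.csv  columns event, time_s, end_s, kind, interval_ms, step
                     (event = 'stimulus' rows use time_s/kind/interval_ms/step;
                      event = 'rocker_on' rows use time_s/end_s)
  <base>_truth.json  optional ground-truth sidecar
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1


@dataclass
class ForceRecording:
    sample_rate: float                      # Hz
    force: np.ndarray                       # μN
    stimulus_times: np.ndarray              # s
    rocker_intervals: list[tuple[float, float]] = field(default_factory=list)  # rocker ON spans
    stimuli: Optional[pd.DataFrame] = None  # full stimulus log (time_s, kind, interval_ms, step)
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.stimulus_times.size and np.any(np.diff(self.stimulus_times) <= 0):
            raise ValueError("stimulus_times must be strictly increasing")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.force.size) / self.sample_rate

    @property
    def duration_s(self) -> float:
        return self.force.size / self.sample_rate

    def rocker_off_spans(self) -> list[tuple[float, float]]:
        spans: list[tuple[float, float]] = []
        t = 0.0
        for a, b in sorted(self.rocker_intervals):
            if a > t:
                spans.append((t, a))
            t = max(t, b)
        if t < self.duration_s:
            spans.append((t, self.duration_s))
        return spans

    # -- IO ----------------------------------------------------------------

    def write(self, base: str | Path) -> None:
        base = Path(base)
        base.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"time_s": self.time, "force_uN": self.force}).to_csv(
            base.with_name(base.name + "_trace.csv"), index=False
        )
        if self.stimuli is not None:
            ev = self.stimuli.copy()
        else:
            ev = pd.DataFrame(
                dict(time_s=self.stimulus_times, kind="S1",
                     interval_ms=np.nan, step=-1)
            )
        ev.insert(0, "event", "stimulus")
        ev["end_s"] = np.nan
        rock = pd.DataFrame(
            [dict(event="rocker_on", time_s=a, end_s=b, kind="", interval_ms=np.nan, step=-1)
             for a, b in self.rocker_intervals]
        )
        cols = ["event", "time_s", "end_s", "kind", "interval_ms", "step"]
        out = pd.concat([ev[cols], rock[cols] if len(rock) else rock], ignore_index=True)
        out.to_csv(base.with_name(base.name + "_events.csv"), index=False)
        meta = {"schema_version": SCHEMA_VERSION, "sample_rate_hz": self.sample_rate}
        if self.ground_truth is not None:
            meta["ground_truth"] = _jsonify(self.ground_truth)
        base.with_name(base.name + "_truth.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, base: str | Path) -> "ForceRecording":
        base = Path(base)
        trace = pd.read_csv(base.with_name(base.name + "_trace.csv"))
        events = pd.read_csv(base.with_name(base.name + "_events.csv"))
        meta_path = base.with_name(base.name + "_truth.json")
        sample_rate = None
        truth = None
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            sample_rate = meta.get("sample_rate_hz")
            truth = meta.get("ground_truth")
        if sample_rate is None:
            dt = np.median(np.diff(trace["time_s"].to_numpy()))
            sample_rate = 1.0 / dt
        stim = events[events["event"] == "stimulus"]
        rock = events[events["event"] == "rocker_on"]
        stimuli = stim[["time_s", "kind", "interval_ms", "step"]].reset_index(drop=True)
        return cls(
            sample_rate=float(sample_rate),
            force=trace["force_uN"].to_numpy(float),
            stimulus_times=stim["time_s"].to_numpy(float),
            rocker_intervals=[(float(a), float(b)) for a, b in zip(rock["time_s"], rock["end_s"])],
            stimuli=stimuli,
            ground_truth=truth,
        )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
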