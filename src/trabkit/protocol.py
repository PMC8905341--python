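"""Stimulation protocol scripts.

A :class:`ProtocolScript` is the simulator-facing description of a pacing
experiment: an ordered table of stimulus events (regular S1 beats, inserted
S2 extrastimuli, constant-frequency train pulses), the biphasic pulse shape,
and the rocker (medium agitation) schedule. The culture device consumes the
same information as plain-text commands; ``to_text``/``from_text`` round-trip
that format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Biphasic field-stimulation pulse: 3 ms negative, 1 ms pause, 3 ms positive.
DEFAULT_PULSE_SHAPE = (3.0, 1.0, 3.0)

STIM_COLUMNS = ["time_s", "kind", "interval_ms", "step"]


@dataclass
class ProtocolScript:
    """Ordered stimulation script plus rocker schedule.

    ``stimuli`` columns:
      time_s      stimulus instant (s from recording start), strictly increasing
      kind        'S1' | 'S2' | 'train'
      interval_ms for S2: the S2 coupling interval; for train pulses: the
                  train's inter-stimulus interval; for S1: the baseline interval
      step        ladder-step index the stimulus belongs to (-1 for plain S1)

    ``rocker_on`` lists (start_s, end_s) spans during which the agitation
    rocker runs; everything outside is rocking-free and analyzable.
    """

    stimuli: pd.DataFrame
    rocker_on: list[tuple[float, float]] = field(default_factory=list)
    pulse_shape_ms: tuple[float, float, float] = DEFAULT_PULSE_SHAPE
    duration_s: float | None = None

    def __post_init__(self) -> None:
        st = self.stimuli.reset_index(drop=True)
        missing = [c for c in STIM_COLUMNS if c not in st.columns]
        if missing:
            raise ValueError(f"stimuli table missing columns {missing}")
        t = st["time_s"].to_numpy(float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("stimulus times must be strictly increasing")
        if np.any(st["interval_ms"].to_numpy(float) <= 0):
            raise ValueError("all stimulus intervals must be > 0")
        for a, b in self.rocker_on:
            if b <= a:
                raise ValueError("rocker intervals must have end > start")
        self.stimuli = st
        if self.duration_s is None:
            tail = 5.0
            self.duration_s = float(t[-1] + tail) if t.size else tail

    @property
    def stimulus_times(self) -> np.ndarray:
        return self.stimuli["time_s"].to_numpy(float)

    def rocker_off_spans(self) -> list[tuple[float, float]]:
        """Complement of rocker_on within [0, duration]."""
        spans: list[tuple[float, float]] = []
        t = 0.0
        for a, b in sorted(self.rocker_on):
            if a > t:
                spans.append((t, a))
            t = max(t, b)
        if t < self.duration_s:
            spans.append((t, self.duration_s))
        return spans

    # -- text command format ----------------------------------------------

    def to_text(self) -> str:
        lines = [
            "# trabkit protocol v1",
            f"PULSE_MS {self.pulse_shape_ms[0]:g} {self.pulse_shape_ms[1]:g} {self.pulse_shape_ms[2]:g}",
            f"DURATION_S {self.duration_s:g}",
        ]
        for a, b in self.rocker_on:
            lines.append(f"ROCKER_ON {a:g} {b:g}")
        for row in self.stimuli.itertuples(index=False):
            lines.append(
                f"STIM {row.time_s:.6f} {row.kind} {row.interval_ms:g} {int(row.step)}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ProtocolScript":
        pulse = DEFAULT_PULSE_SHAPE
        duration = None
        rocker: list[tuple[float, float]] = []
        rows = []
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            cmd = tok[0].upper()
            if cmd == "PULSE_MS":
                pulse = (float(tok[1]), float(tok[2]), float(tok[3]))
            elif cmd == "DURATION_S":
                duration = float(tok[1])
            elif cmd == "ROCKER_ON":
                rocker.append((float(tok[1]), float(tok[2])))
            elif cmd == "STIM":
                rows.append(
                    dict(time_s=float(tok[1]), kind=tok[2],
                         interval_ms=float(tok[3]), step=int(tok[4]))
                )
            else:
                raise ValueError(f"unknown protocol command {cmd!r}")
        st = pd.DataFrame(rows, columns=STIM_COLUMNS)
        return cls(stimuli=st, rocker_on=rocker, pulse_shape_ms=pulse, duration_s=duration)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def read(cls, path: str | Path) -> "ProtocolScript":
        return cls.from_text(Path(path).read_text())


def simple_train(frequency_hz: float, n_beats: int, start_s: float = 2.0,
                 rocker_on: Iterable[tuple[float, float]] = ()) -> ProtocolScript:
    """A single constant-frequency S1 train (the minimal useful protocol)."""
    interval = 1000.0 / frequency_hz
    t = start_s + np.arange(n_beats) * (interval / 1000.0)
    st = pd.DataFrame(
        dict(time_s=t, kind="S1", interval_ms=interval, step=-1)
    )
    return ProtocolScript(stimuli=st, rocker_on=list(rocker_on))
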