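"""Co-analysis of contractile force and intracellular Ca2+ photometry.

The two acquisition systems run on independent clocks but both log the
electrical stimulation pulses; synchronization matches the two stimulus
sequences, estimates the clock offset by least squares over the matched
pairs, and resamples the fluorescence trace onto the force time base.
Per-beat amplitudes (10%-threshold machinery, same as for force) are
normalized to the response to the first 0.5 Hz stimulus, which yields the
force-frequency relationship of both signals and the post-rest ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import ForceRecording

CA_CSV_COLUMNS = ("time_s", "fluorescence_au")


@dataclass
class AlignedPair:
    """Force and Ca2+ on a common (force) time base."""

    sample_rate: float
    time: np.ndarray
    force: np.ndarray            # μN
    ca: np.ndarray               # arbitrary fluorescence units
    stimulus_times: np.ndarray   # s, force clock
    offset_s: float              # ca clock minus force clock
    jitter_ms: float             # residual RMS of matched stimulus pairs
    n_matched: int = 0


def _match_events(t_force: np.ndarray, t_ca: np.ndarray,
                  tol_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Best pairing of two event lists under an unknown constant offset.

    Scans candidate offsets (all pairwise differences), keeps the one that
    matches the most events within ``tol_s``, then returns the matched pairs.
    Robust to a few missing events in either log.
    """
    diffs = (t_force[:, None] - t_ca[None, :]).ravel()
    diffs.sort()
    # densest cluster of pairwise differences = candidate offset
    best_count, best_off = 0, 0.0
    j = 0
    for i in range(diffs.size):
        while diffs[i] - diffs[j] > 2 * tol_s:
            j += 1
        if i - j + 1 > best_count:
            best_count = i - j + 1
            best_off = 0.5 * (diffs[i] + diffs[j])
    # greedy nearest matching at the candidate offset
    fi, ci = [], []
    used = np.zeros(t_ca.size, dtype=bool)
    for i, t in enumerate(t_force):
        d = np.abs((t_ca + best_off) - t)
        d[used] = np.inf
        k = int(np.argmin(d))
        if d[k] <= tol_s:
            fi.append(i)
            ci.append(k)
            used[k] = True
    return np.asarray(fi, dtype=int), np.asarray(ci, dtype=int)


def synchronize(force_rec: ForceRecording, ca_rec: ForceRecording,
                tol_s: float = 0.05) -> AlignedPair:
    """Align a photometry recording to a force recording via stimulus logs.

    The offset is the least-squares (mean-difference) solution over matched
    stimulus pairs. Raises if fewer than two stimuli can be matched or if
    the sequences disagree on more than 20% of the shorter log.
    """
    tf = np.asarray(force_rec.stimulus_times, float)
    tc = np.asarray(ca_rec.stimulus_times, float)
    if tf.size < 2 or tc.size < 2:
        raise ValueError("both recordings need >= 2 stimulus timestamps")
    fi, ci = _match_events(tf, tc, tol_s)
    n_min = min(tf.size, tc.size)
    if fi.size < 2 or fi.size < 0.8 * n_min:
        raise ValueError(
            f"stimulus sequences unmatched: only {fi.size} of {n_min} events pair up"
        )
    resid = tc[ci] - tf[fi]
    offset = float(resid.mean())   # ca clock minus force clock
    jitter_ms = float(np.sqrt(np.mean((resid - offset) ** 2)) * 1000.0)
    t_force = force_rec.time
    ca_resampled = np.interp(t_force, ca_rec.time - offset, ca_rec.force)
    return AlignedPair(
        sample_rate=force_rec.sample_rate, time=t_force,
        force=force_rec.force, ca=ca_resampled,
        stimulus_times=tf, offset_s=offset, jitter_ms=jitter_ms,
        n_matched=int(fi.size),
    )


def _beat_amplitudes(signal: np.ndarray, sample_rate: float,
                     stimulus_times: np.ndarray) -> pd.DataFrame:
    """Per-stimulus amplitude: baseline (window minimum) subtracted peak
    within the stimulus-to-next-stimulus window."""
    t = np.asarray(stimulus_times, float)
    rows = []
    n = signal.size
    for i, t0 in enumerate(t):
        if i + 1 < t.size:
            t1 = t[i + 1]
        elif t.size > 1:
            t1 = t0 + float(np.median(np.diff(t)))
        else:
            t1 = t0 + 2.0
        i0 = int(round(t0 * sample_rate))
        i1 = min(n, int(round(t1 * sample_rate)) + 1)
        if i1 - i0 < 3 or i0 >= n:
            rows.append(dict(stimulus_time=t0, amplitude=np.nan, baseline=np.nan))
            continue
        seg = signal[i0:i1]
        rows.append(dict(stimulus_time=t0, amplitude=float(seg.max() - seg.min()),
                         baseline=float(seg.min())))
    return pd.DataFrame(rows)


def normalize_to_first(aligned: AlignedPair, signal: str = "force",
                       noise_floor: float = 0.0) -> pd.DataFrame:
    """Per-beat amplitudes normalized to the first stimulus' response.

    After baseline (diastolic offset) subtraction per beat, each amplitude is
    divided by the amplitude of the first beat, which is 1 by construction.
    """
    if signal not in ("force", "ca"):
        raise ValueError("signal must be 'force' or 'ca'")
    y = aligned.force if signal == "force" else aligned.ca
    amps = _beat_amplitudes(y, aligned.sample_rate, aligned.stimulus_times)
    first = amps["amplitude"].iloc[0]
    if not np.isfinite(first) or first <= noise_floor:
        raise ValueError("first beat is below the noise floor; cannot normalize")
    amps["normalized"] = amps["amplitude"] / first
    return amps


def frequency_response(aligned: AlignedPair, stimuli: pd.DataFrame,
                       noise_floor: float = 0.0) -> pd.DataFrame:
    """Normalized force and Ca amplitude plus capture fraction per frequency.

    ``stimuli`` is the protocol log (time_s, interval_ms, step); amplitudes
    are averaged per step after normalization to the first beat.
    """
    f_amps = normalize_to_first(aligned, "force", noise_floor)
    c_amps = normalize_to_first(aligned, "ca")
    merged = stimuli.reset_index(drop=True).copy()
    merged["force_norm"] = f_amps["normalized"]
    merged["ca_norm"] = c_amps["normalized"]
    merged["force_amp"] = f_amps["amplitude"]
    rows = []
    for step, grp in merged.groupby("step"):
        fhz = 1000.0 / grp["interval_ms"].iloc[0]
        captured = grp["force_amp"] > noise_floor
        rows.append(dict(
            step=int(step), frequency_hz=fhz,
            force_norm=float(grp.loc[captured, "force_norm"].mean()),
            ca_norm=float(grp.loc[captured, "ca_norm"].mean()),
            capture_fraction=float(captured.mean()),
        ))
    return pd.DataFrame(rows).sort_values("frequency_hz").reset_index(drop=True)


def post_rest_ratio(aligned: AlignedPair, min_pause_s: float = 4.0,
                    n_pre: int = 3, noise_floor: float = 0.0,
                    ca_noise_floor: float = 0.0) -> tuple[float, float]:
    """(force ratio, Ca ratio) of the post-rest beat.

    The post-rest beat is the first stimulus following a pause of at least
    ``min_pause_s``; its amplitude is divided by the mean amplitude of the
    last ``n_pre`` captured beats before the pause. Noise floors are in the
    respective signal's units (μN for force, fluorescence units for Ca).
    """
    t = aligned.stimulus_times
    gaps = np.diff(t)
    idx = np.flatnonzero(gaps >= min_pause_s)
    if idx.size == 0:
        raise ValueError(f"no pause >= {min_pause_s}s in the stimulus sequence")
    i_rest = int(idx[0]) + 1   # first beat after the first qualifying pause
    out = []
    for sig, floor in (("force", noise_floor), ("ca", ca_noise_floor)):
        amps = normalize_to_first(aligned, sig)["amplitude"].to_numpy()
        post = amps[i_rest]
        if not np.isfinite(post) or post <= floor:
            raise ValueError("post-rest beat not detected")
        pre = amps[:i_rest]
        pre = pre[np.isfinite(pre) & (pre > floor)]
        if pre.size == 0:
            raise ValueError("no captured pre-rest beats")
        out.append(float(post / pre[-n_pre:].mean()))
    return out[0], out[1]


def read_ca_csv(path) -> ForceRecording:
    """Read a photometry CSV (time_s, fluorescence_au) plus an optional
    ``<stem>_events.csv`` stimulus log next to it."""
    from pathlib import Path

    path = Path(path)
    df = pd.read_csv(path)
    dt = float(np.median(np.diff(df["time_s"].to_numpy())))
    ev_path = path.with_name(path.stem + "_events.csv")
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        stim = ev["time_s"].to_numpy(float)
    else:
        stim = np.array([])
    return ForceRecording(sample_rate=1.0 / dt,
                          force=df["fluorescence_au"].to_numpy(float),
                          stimulus_times=stim)
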