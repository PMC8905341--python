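"""End-to-end orchestration: simulate -> preprocess -> beats -> pacing ->
Ca2+/force -> confocal -> molecular stats -> combined JSON report.

All defaults equal the study conditions: 500 μN preload, 50 μN beating
screen, the printed S2 and frequency ladders, mode + k*SD segmentation
thresholds, the 7.5% myocyte rule and the 25 mN/mm spring constant for
deflection inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import beats as beats_mod
from . import ca_force, confocal, molstats, pacing, preprocess, simulate
from .params import TissueParams
from .protocol import ProtocolScript

SPRING_CONSTANT_MN_MM = 25.0   # spring wire stiffness of the culture chamber
PRELOAD_UN = 500.0


def deflection_to_force(deflection_mm: float,
                        spring_constant_mN_mm: float = SPRING_CONSTANT_MN_MM) -> float:
    """Force (μN) from spring-wire deflection (mm): F = d * k, k in mN/mm."""
    if spring_constant_mN_mm <= 0:
        raise ValueError("spring_constant must be > 0")
    return deflection_mm * spring_constant_mN_mm * 1000.0


def build_ca_protocol(frequencies_hz: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0),
                      beats_per_step: int = 12, post_rest_hz: float = 0.2,
                      n_post: int = 3, start_s: float = 2.0) -> ProtocolScript:
    """Reduced frequency-ladder protocol used during Ca2+ imaging: a few
    frequency steps of 12 beats each, then a drop to 0.2 Hz, which creates a
    5 s pause before the post-rest beat."""
    rows = []
    t = start_s
    for step, f in enumerate(frequencies_hz):
        iv = 1.0 / f
        for j in range(beats_per_step):
            rows.append(dict(time_s=t + j * iv, kind="train",
                             interval_ms=1000.0 * iv, step=step))
        t += beats_per_step * iv
    t += 1.0 / post_rest_hz - 1.0 / frequencies_hz[-1]
    for j in range(n_post):
        rows.append(dict(time_s=t + j / post_rest_hz, kind="train",
                         interval_ms=1000.0 / post_rest_hz, step=len(frequencies_hz)))
    st = pd.DataFrame(rows, columns=["time_s", "kind", "interval_ms", "step"])
    return ProtocolScript(stimuli=st, rocker_on=[])


@dataclass
class RunConfig:
    """Configuration of a simulate-then-analyze pipeline run."""

    seed: int = 0
    output_dir: str | None = None
    tissue: TissueParams = field(default_factory=TissueParams)
    beating_threshold_uN: float = beats_mod.BEATING_THRESHOLD_UN
    preload_uN: float = PRELOAD_UN
    spring_constant_mN_mm: float = SPRING_CONSTANT_MN_MM
    s1s2: pacing.S1S2Protocol = field(default_factory=pacing.S1S2Protocol)
    frequency: pacing.FrequencyProtocol = field(default_factory=pacing.FrequencyProtocol)
    include_confocal: bool = True
    confocal_shape: tuple[int, int, int] = (48, 96, 96)
    include_molecular: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if isinstance(d.get("tissue"), dict):
            d["tissue"] = TissueParams(**d["tissue"])
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(_as_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _seed(base: int, k: int) -> int:
    return (int(base) * 1000003 + k) % (2**31 - 1)


def analyze_recording(recording, beating_threshold_uN: float = beats_mod.BEATING_THRESHOLD_UN):
    """Preprocess, estimate noise, detect and measure beats per pacing step."""
    trace = preprocess.make_analyzable(recording)
    noise = preprocess.estimate_noise(trace)
    summaries = []
    all_beats = []
    stimuli = trace.stimuli
    for step, grp in stimuli.groupby("step"):
        iv_ms = float(grp["interval_ms"].iloc[0])
        t = grp["time_s"].to_numpy(float)
        det = beats_mod.detect_beats(trace, noise, t)
        det = [b for b in det if b.stimulus_time is not None]
        det = beats_mod.measure_beats(trace, det, iv_ms)
        all_beats.extend(det)
        s = beats_mod.summarize_period(det, n_stimuli=len(grp), pacing_hz=1000.0 / iv_ms)
        summaries.append(dict(step=int(step), **s.__dict__))
    return trace, noise, all_beats, pd.DataFrame(summaries)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return (and optionally write) the report."""
    cfg = config
    report: dict = dict(manifest=dict(
        seed=cfg.seed, config_hash=cfg.hash(),
        python=platform.python_version(),
        numpy=np.__version__, pandas=pd.__version__,
    ))

    # --- force recording under the frequency protocol: beats + f_max -------
    freq_protocol = cfg.frequency.build()
    rec = simulate.simulate_recording(cfg.tissue, freq_protocol, seed=_seed(cfg.seed, 1))
    trace, noise, all_beats, summaries = analyze_recording(rec, cfg.beating_threshold_uN)
    beating = beats_mod.classify_beating(all_beats, cfg.beating_threshold_uN)
    fmax = pacing.max_frequency(trace, trace.stimuli, noise)
    report["beats"] = dict(
        beating=bool(beating), n_beats=len(all_beats),
        noise_sd_uN=noise.sd, noise_max_amplitude_uN=noise.max_amplitude,
        period_summaries=_as_jsonable(summaries.to_dict(orient="records")),
    )
    report["f_max"] = dict(value_hz=fmax.value, flag=fmax.flag)

    # --- S1-S2 protocol: refractory period ---------------------------------
    s1s2 = cfg.s1s2.build()
    rec2 = simulate.simulate_recording(cfg.tissue, s1s2, seed=_seed(cfg.seed, 2))
    trace2 = preprocess.make_analyzable(rec2)
    noise2 = preprocess.estimate_noise(trace2)
    cap = pacing.detect_capture_s2(trace2, trace2.stimuli, noise2)
    rp = pacing.refractory_period(cap)
    report["refractory_period"] = dict(
        value_ms=rp.value, flag=rp.flag,
        capture_table=_as_jsonable(cap.to_dict(orient="records")),
    )

    # --- Ca2+/force co-registration ----------------------------------------
    ca_protocol = build_ca_protocol()
    frec = simulate.simulate_recording(cfg.tissue, ca_protocol, seed=_seed(cfg.seed, 3))
    crec = simulate.simulate_ca_recording(cfg.tissue, ca_protocol,
                                          seed=_seed(cfg.seed, 4), clock_offset_s=0.25)
    aligned = ca_force.synchronize(frec, crec)
    ffr = ca_force.frequency_response(aligned, ca_protocol.stimuli,
                                      noise_floor=noise.peak_threshold)
    pr_force, pr_ca = ca_force.post_rest_ratio(aligned)
    report["ca_force"] = dict(
        offset_s=aligned.offset_s, jitter_ms=aligned.jitter_ms,
        frequency_response=_as_jsonable(ffr.to_dict(orient="records")),
        post_rest_force_ratio=pr_force, post_rest_ca_ratio=pr_ca,
    )

    # --- confocal segmentation ---------------------------------------------
    if cfg.include_confocal:
        vcfg = simulate.VolumeConfig(shape=cfg.confocal_shape)
        stack, truth = simulate.simulate_volume(vcfg, seed=_seed(cfg.seed, 5))
        seg = confocal.segment_stack(stack)
        report["confocal"] = dict(
            fractions=seg.fractions, true_fractions=truth.fractions,
            n_segments=int(seg.segment_aact.shape[0]),
            n_myocyte_segments=int(seg.segment_aact["myocyte"].sum()),
        )

    # --- molecular: qPCR + viability + statistics --------------------------
    if cfg.include_molecular:
        ratios_true = {"ATP2A2": 0.5, "KCNJ2": 3.0, "KCNJ4": 0.5,
                       "CACNA1C": 0.7, "GJA1": 1.0}
        eff = {g: 1.95 for g in list(ratios_true) + list(molstats.REFERENCE_GENES)}
        ct = simulate.simulate_ct_table(ratios_true, eff, replicate_sd=0.1,
                                        seed=_seed(cfg.seed, 6))
        expr = {g: molstats.expression_ratio(ct, g)["ratio"] for g in ratios_true}
        plate = simulate.simulate_plate(seed=_seed(cfg.seed, 7))
        prot = molstats.bradford_quantify(
            plate["standards"]["conc_mg_ml"], plate["standards"]["a595"],
            plate["samples"]["bradford_a595"],
        )
        samples = plate["samples"].assign(protein_mg=prot["protein"].to_numpy())
        samples["relative_absorbance"] = [
            molstats.mtt_relative_absorbance(a, p)
            for a, p in zip(samples["formazan_a595"], samples["protein_mg"])
        ]
        grp = samples.groupby("group")["relative_absorbance"]
        p_viab = molstats.welch_t(*(g.to_numpy() for _, g in grp))
        report["molecular"] = dict(
            expression_ratios=expr,
            viability=dict(
                group_means=grp.mean().to_dict(),
                welch_p=p_viab,
            ),
        )

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(_as_jsonable(report), indent=1))
    return report
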