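"""Synthetic raw-data generators with known ground truth.

Every input kind the analysis pipeline consumes can be generated here:
force recordings under arbitrary pacing protocols, Ca2+ photometry traces,
4-channel 3D confocal volumes, qPCR Ct tables with dilution series, and
MTT/Bradford plate readings. All generators are deterministic given their
seed, and each records the ground truth needed for parameter-recovery tests.

The excitation model is deliberately phenomenological. A stimulus elicits an
activation iff the time since the previous activation is at least the current
refractory period; refractoriness restitutes with the preceding diastolic
interval DI as

    RP(DI) = rp_min + (rp_max - rp_min) * (1 - exp(-DI / restitution_tau)),

so a tissue can show a long refractory period to an S2 delivered after slow
baseline pacing yet still follow a fast steady train (short DI -> short RP).
Each activation adds a smooth single-peaked twitch scaled by force-frequency,
post-rest, alternans and drug factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .params import TissueParams
from .protocol import ProtocolScript
from .recording import ForceRecording

DEVICE_SAMPLE_RATE = 400.0  # Hz, as streamed by the culture device
MAX_DURATION_S = 7200.0

# Geometry of the twitch waveform (ms). The apex is a symmetric low-slope
# "tent" (robust location under centered median/mean filtering and additive
# noise) and each 10%-amplitude crossing sits in the middle of a linear
# segment spanning the moving-mean window, where centered filters are exactly
# unbiased; monotone cubic blends connect apex and crossing zones.
_TENT_HALF_MS = 40.0
_TENT_SLOPE_REL = 3.3e-4   # apex slope as a fraction of amplitude per ms
_LIN_HALF_MS = 25.0        # half-length of the linear crossing zone


def _hermite(t, t0, t1, v0, v1, m0, m1):
    h = t1 - t0
    s = (t - t0) / h
    return ((2 * s**3 - 3 * s**2 + 1) * v0 + (s**3 - 2 * s**2 + s) * h * m0
            + (-2 * s**3 + 3 * s**2) * v1 + (s**3 - s**2) * h * m1)


def _twitch_side(trel: np.ndarray, amplitude: float, t90: float,
                 tent: float, lin_half: float) -> np.ndarray:
    """One flank of the twitch; ``trel`` >= 0 is distance from the peak (ms)."""
    s_t = _TENT_SLOPE_REL * amplitude
    m1 = 0.1 * amplitude / lin_half
    v = np.empty_like(trel)
    a = trel <= tent
    v[a] = amplitude - s_t * trel[a]
    b = (trel > tent) & (trel <= t90 - lin_half)
    if b.any():
        v[b] = _hermite(trel[b], tent, t90 - lin_half,
                        amplitude - s_t * tent, 0.1 * amplitude + m1 * lin_half,
                        -s_t, -m1)
    c = trel > t90 - lin_half
    v[c] = 0.1 * amplitude - m1 * (trel[c] - t90)
    return np.clip(v, 0.0, None)


def make_twitch(amplitude: float, ttp90: float, ttr90: float, dt: float) -> np.ndarray:
    """Single twitch waveform sampled at step ``dt`` (all times in ms).

    Smooth, single-peaked and non-negative, starting and ending at zero; the
    peak sample equals ``amplitude`` exactly and the 10%-amplitude crossings
    are placed so the rise-to-peak time equals ``ttp90`` and the peak-to-10%
    fall time equals ``ttr90``, each within dt/2 on the sample grid.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if ttp90 <= 0 or ttr90 <= 0 or dt <= 0:
        raise ValueError("ttp90, ttr90 and dt must be > 0")
    if ttp90 < 2 * dt or ttr90 < 2 * dt:
        raise ValueError("ttp90/ttr90 shorter than 2*dt cannot be resolved")
    lin_r = min(_LIN_HALF_MS, 0.45 * ttp90)
    lin_f = min(_LIN_HALF_MS, 0.45 * ttr90)
    tent = min(
        _TENT_HALF_MS,
        max(dt, 0.85 * (ttp90 - lin_r - dt)),
        max(dt, 0.85 * (ttr90 - lin_f - dt)),
    )
    n_pre = int(round((ttp90 + lin_r) / dt))
    n_post = int(round((ttr90 + lin_f) / dt))
    t = (np.arange(n_pre + n_post + 1) - n_pre) * dt
    w = np.empty_like(t)
    neg = t <= 0
    w[neg] = _twitch_side(-t[neg], amplitude, ttp90, tent, lin_r)
    w[~neg] = _twitch_side(t[~neg], amplitude, ttr90, tent, lin_f)
    w[0] = 0.0
    w[-1] = 0.0
    return w


def twitch_peak_index(ttp90: float, dt: float) -> int:
    """Sample index of the peak of :func:`make_twitch` output."""
    lin_r = min(_LIN_HALF_MS, 0.45 * ttp90)
    return int(round((ttp90 + lin_r) / dt))


# ---------------------------------------------------------------------------
# excitation model
# ---------------------------------------------------------------------------

def simulate_activations(params: TissueParams, protocol: ProtocolScript) -> pd.DataFrame:
    """Run the refractoriness/restitution gate over a protocol's stimuli.

    Returns one row per stimulus with columns ``time_s``, ``activated``,
    ``di_ms`` (coupling interval to the previous activation) and
    ``amp_factor`` (twitch scale relative to the baseline amplitude).
    Deterministic: no randomness enters the activation model.
    """
    params.validate()
    rows = []
    t_last = None
    _, rp_hi = params.rp_range()
    rp_cur = rp_hi  # fully rested
    alt_parity = 0
    alt_ratio = params.alternans_ratio
    if params.drug is not None and params.drug.alternans and alt_ratio >= 1.0:
        alt_ratio = 0.4
    for t in protocol.stimulus_times:
        if t_last is None:
            di_ms = math.inf
        else:
            di_ms = (t - t_last) * 1000.0
        activated = di_ms >= rp_cur - 1e-9
        amp_factor = 0.0
        if activated:
            amp_factor = 1.0
            if math.isfinite(di_ms):
                f_inst = 1000.0 / di_ms
                amp_factor *= max(0.0, 1.0 + params.ffr_slope * (f_inst - 0.5))
                if di_ms >= params.post_rest_pause_s * 1000.0:
                    prf = params.drug.post_rest_factor if params.drug else 1.0
                    amp_factor *= 1.0 + (params.post_rest_gain - 1.0) * prf
                if alt_ratio < 1.0 and di_ms < 1.5 * rp_hi:
                    alt_parity ^= 1
                    if alt_parity == 0:
                        amp_factor *= alt_ratio
                else:
                    alt_parity = 0
            rp_cur = params.refractory_period(min(di_ms, 1e12))
            t_last = t
        rows.append(dict(time_s=t, activated=activated, di_ms=di_ms, amp_factor=amp_factor))
    return pd.DataFrame(rows)


def _render_trace(activations: pd.DataFrame, duration_s: float,
                  rocker_on: list[tuple[float, float]], *,
                  sample_rate: float, baseline: float, amplitude: float,
                  ttp90: float, ttr90: float, noise_sd: float,
                  rocker_amp: float, rocker_freq: float,
                  rng: np.random.Generator) -> np.ndarray:
    n = int(round(duration_s * sample_rate))
    trace = np.full(n, baseline, dtype=float)
    dt_ms = 1000.0 / sample_rate
    if amplitude > 0:
        unit = make_twitch(1.0, ttp90, ttr90, dt_ms)
        act = activations[activations["activated"]]
        for t, fac in zip(act["time_s"], act["amp_factor"]):
            if fac <= 0:
                continue
            i0 = int(round(t * sample_rate))
            j0 = max(0, -i0)
            i1 = min(n, i0 + unit.size)
            if i0 + j0 < n:
                trace[i0 + j0:i1] += amplitude * fac * unit[j0: i1 - i0]
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, size=n)
    if rocker_amp > 0:
        tt = np.arange(n) / sample_rate
        phase = rng.uniform(0, 2 * np.pi, size=2)
        for a, b in rocker_on:
            sel = (tt >= a) & (tt < b)
            ts = tt[sel]
            trace[sel] += rocker_amp * np.sin(2 * np.pi * rocker_freq * ts + phase[0])
            trace[sel] += 0.5 * rocker_amp * np.sin(2 * np.pi * 0.15 * ts + phase[1])
    return trace


def simulate_recording(params: TissueParams, protocol: ProtocolScript,
                       seed: int, sample_rate: float = DEVICE_SAMPLE_RATE,
                       max_duration_s: float = MAX_DURATION_S) -> ForceRecording:
    """Render a force recording (μN, default 400 Hz) for a pacing protocol.

    Ground truth (true activation times, per-beat amplitudes, twitch kinetics,
    blocked stimuli) is stored on the returned recording.
    """
    params.validate()
    if protocol.duration_s > max_duration_s:
        raise ValueError(
            f"protocol duration {protocol.duration_s:.0f}s exceeds limit {max_duration_s:.0f}s"
        )
    rng = np.random.default_rng(seed)
    acts = simulate_activations(params, protocol)
    trace = _render_trace(
        acts, protocol.duration_s, protocol.rocker_on,
        sample_rate=sample_rate, baseline=params.diastolic_force,
        amplitude=params.amplitude, ttp90=params.ttp90, ttr90=params.ttr90,
        noise_sd=params.noise_sd, rocker_amp=params.rocker_artifact_amp,
        rocker_freq=params.rocker_artifact_freq, rng=rng,
    )
    captured = acts[acts["activated"]]
    truth = dict(
        activation_times_s=captured["time_s"].to_numpy(),
        amplitudes_uN=(params.amplitude * captured["amp_factor"]).to_numpy(),
        blocked_stimulus_times_s=acts.loc[~acts["activated"], "time_s"].to_numpy(),
        ttp90_ms=params.ttp90, ttr90_ms=params.ttr90,
        diastolic_force_uN=params.diastolic_force,
        seed=seed,
    )
    return ForceRecording(
        sample_rate=sample_rate, force=trace,
        stimulus_times=protocol.stimulus_times,
        rocker_intervals=list(protocol.rocker_on),
        stimuli=protocol.stimuli.copy(),
        ground_truth=truth,
    )


def simulate_ca_recording(params: TissueParams, protocol: ProtocolScript,
                          seed: int, *, sample_rate: float = 500.0,
                          clock_offset_s: float = 0.0,
                          ca_amplitude_au: float = 1.0,
                          ca_baseline_au: float = 0.2,
                          ca_kinetics_factor: float = 0.6,
                          noise_sd_au: float = 0.01) -> ForceRecording:
    """Photometry trace (arbitrary fluorescence units) for the same tissue.

    The Ca2+ transient precedes and is faster than the twitch; here it shares
    the activation sequence and is rendered with accelerated kinetics. The
    photometry rig runs on its own clock: all its timestamps (trace and
    stimulus log) are shifted by ``clock_offset_s`` relative to the force
    recording, which the synchronization step must recover.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    acts = simulate_activations(params, protocol)
    # the photometry rig records on its own clock: every event (and the
    # rendered transients) appears shifted by the clock offset
    acts = acts.assign(time_s=acts["time_s"] + clock_offset_s)
    trace = _render_trace(
        acts, protocol.duration_s + max(0.0, clock_offset_s), [],
        sample_rate=sample_rate, baseline=ca_baseline_au,
        amplitude=ca_amplitude_au,
        ttp90=params.ttp90 * ca_kinetics_factor,
        ttr90=params.ttr90 * ca_kinetics_factor,
        noise_sd=noise_sd_au, rocker_amp=0.0, rocker_freq=0.0, rng=rng,
    )
    stimuli = protocol.stimuli.copy()
    stimuli["time_s"] = stimuli["time_s"] + clock_offset_s
    return ForceRecording(
        sample_rate=sample_rate, force=trace,
        stimulus_times=stimuli["time_s"].to_numpy(),
        stimuli=stimuli,
        ground_truth=dict(clock_offset_s=clock_offset_s),
    )


# ---------------------------------------------------------------------------
# confocal volumes
# ---------------------------------------------------------------------------

@dataclass
class VolumeConfig:
    """Geometry and imaging configuration of the synthetic tissue volume.

    The tissue is a brick lattice of cells separated by WGA-positive walls
    (extracellular matrix). A configurable fraction of cells carries
    sarcomeric alpha-actinin striations (period ~2 μm along x); Cx43 puncta
    sit on longitudinal (x-facing) junctions between two striated cells;
    each cell has one ellipsoidal nucleus. Imaging applies depth attenuation
    exp(-z/lambda), a Gaussian PSF and Poisson+Gaussian noise.
    """

    shape: tuple[int, int, int] = (64, 128, 128)   # (z, y, x) voxels
    voxel_size_um: tuple[float, float, float] = (0.2, 0.2, 0.2)
    cell_size_um: float = 6.4
    wall_thickness_um: float = 0.8
    lattice_offset_um: float | None = None   # default cell_size/4, so no wall
                                             # plane coincides with stack borders
    myocyte_fraction: float = 0.65
    sarcomere_period_um: float = 2.0
    sarcomere_duty: float = 0.25   # Z-disc band width as a fraction of the period
    aact_intensity_sigma: float = 0.25  # lognormal sigma of per-cell aACT brightness
    background: float = 20.0
    wga_intensity: float = 200.0
    aact_intensity: float = 180.0
    cx43_intensity: float = 220.0
    dapi_intensity: float = 200.0
    cx43_puncta_per_junction: float = 5.0
    psf_sigma_um: tuple[float, float, float] = (0.3, 0.12, 0.12)
    attenuation_lambda_um: float | None = 40.0
    poisson_noise: bool = True
    gaussian_noise_sd: float = 3.0

    # channel labels accepted by render configs
    CHANNELS = ("WGA", "Cx43", "aACT", "DAPI")


@dataclass
class GroundTruthVolume:
    """Per-voxel class labels and true structure fractions.

    labels: 0 = other cell interior, 1 = ECM (wall), 2 = myocyte interior.
    """

    labels: np.ndarray
    fractions: dict[str, float]
    voxel_size_um: tuple[float, float, float]
    n_cells: int = 0
    n_myocytes: int = 0


def simulate_volume(config: VolumeConfig | None = None, seed: int = 0,
                    channels: tuple[str, ...] = VolumeConfig.CHANNELS):
    """Generate a 4-channel confocal stack and its ground truth.

    Returns ``(VolumeStack, GroundTruthVolume)``.
    """
    from .confocal import VolumeStack  # local import avoids a module cycle

    cfg = config or VolumeConfig()
    for ch in channels:
        if ch not in VolumeConfig.CHANNELS:
            raise ValueError(f"unknown channel {ch!r}")
    if min(cfg.shape) < 32:
        raise ValueError("volume dimensions must be >= 32 voxels per axis")
    rng = np.random.default_rng(seed)
    nz, ny, nx = cfg.shape
    vz, vy, vx = cfg.voxel_size_um
    cs, wt = cfg.cell_size_um, cfg.wall_thickness_um
    off = cfg.lattice_offset_um if cfg.lattice_offset_um is not None else cs / 4
    z, y, x = np.meshgrid(
        np.arange(nz) * vz + off, np.arange(ny) * vy + off,
        np.arange(nx) * vx + off, indexing="ij",
    )
    # wall where any coordinate is within wt of a lattice plane
    def near_wall(c):
        m = np.mod(c, cs)
        return (m < wt / 2) | (m > cs - wt / 2)

    wall = near_wall(z) | near_wall(y) | near_wall(x)
    iz, iy, ix = (z // cs).astype(int), (y // cs).astype(int), (x // cs).astype(int)
    n_cells_axis = (int(np.ceil((nz * vz + off) / cs)), int(np.ceil((ny * vy + off) / cs)),
                    int(np.ceil((nx * vx + off) / cs)))
    cell_id = (iz * n_cells_axis[1] + iy) * n_cells_axis[2] + ix
    n_cells = int(np.prod(n_cells_axis))
    is_myo_cell = rng.random(n_cells) < cfg.myocyte_fraction
    myo = is_myo_cell[cell_id] & ~wall

    labels = np.zeros(cfg.shape, dtype=np.uint8)
    labels[wall] = 1
    labels[myo] = 2

    # sarcomeric Z-disc bands along x inside myocyte cells: smooth periodic
    # Gaussian bands; the ground-truth aACT region is the band at full width
    # half maximum (width = sarcomere_duty * period)
    period = cfg.sarcomere_period_um
    half_w = 0.5 * cfg.sarcomere_duty * period
    offs = np.abs(np.mod(x, period) - 0.5 * period)
    dist_band = 0.5 * period - offs          # distance to nearest band center
    sigma_band = half_w / np.sqrt(2 * np.log(2))
    band_profile = np.exp(-dist_band**2 / (2 * sigma_band**2))
    stripes = (dist_band <= half_w) & myo

    # Cx43 puncta on x-facing walls between two myocyte cells
    xwall = near_wall(x) & ~near_wall(y) & ~near_wall(z)
    left_id = np.clip(((x - wt) // cs).astype(int), 0, n_cells_axis[2] - 1)
    right_id = np.clip(((x + wt) // cs).astype(int), 0, n_cells_axis[2] - 1)
    lid = (iz * n_cells_axis[1] + iy) * n_cells_axis[2] + left_id
    rid = (iz * n_cells_axis[1] + iy) * n_cells_axis[2] + right_id
    junction = xwall & is_myo_cell[lid] & is_myo_cell[rid] & (lid != rid)
    jidx = np.flatnonzero(junction)
    n_junction_cells = max(1, int(is_myo_cell.sum()))
    n_puncta = int(cfg.cx43_puncta_per_junction * n_junction_cells)
    puncta = np.zeros(cfg.shape, dtype=bool)
    if jidx.size and n_puncta:
        chosen = rng.choice(jidx, size=min(n_puncta, jidx.size), replace=False)
        puncta.flat[chosen] = True
        # gap-junction plaques are ~0.5-1 um across, several voxels here
        puncta = ndi.binary_dilation(puncta, iterations=4)

    # nuclei: one ellipsoid per cell center
    dapi = np.zeros(cfg.shape, dtype=bool)
    rad = cs / 5.0
    centers_z = (np.arange(n_cells_axis[0]) + 0.5) * cs - off
    centers_y = (np.arange(n_cells_axis[1]) + 0.5) * cs - off
    centers_x = (np.arange(n_cells_axis[2]) + 0.5) * cs - off
    for czc in centers_z:
        for cyc in centers_y:
            for cxc in centers_x:
                dz = np.abs(np.arange(nz) * vz - czc)
                dy = np.abs(np.arange(ny) * vy - cyc)
                dx = np.abs(np.arange(nx) * vx - cxc)
                if dz.min() > rad or dy.min() > rad or dx.min() > rad:
                    continue
                ell = ((dz[:, None, None] / rad) ** 2
                       + (dy[None, :, None] / rad) ** 2
                       + (dx[None, None, :] / (1.5 * rad)) ** 2) <= 1.0
                dapi |= ell

    # sarcomeric staining brightness varies strongly between cells
    cell_gain = np.exp(rng.normal(0.0, cfg.aact_intensity_sigma, size=n_cells))
    raw = {
        "WGA": cfg.background + cfg.wga_intensity * wall,
        "aACT": cfg.background + cfg.aact_intensity * cell_gain[cell_id]
                * band_profile * (myo & ~wall),
        "Cx43": cfg.background + cfg.cx43_intensity * puncta,
        "DAPI": cfg.background + cfg.dapi_intensity * dapi,
    }

    att = None
    if cfg.attenuation_lambda_um:
        att = np.exp(-(np.arange(nz) * vz) / cfg.attenuation_lambda_um)[:, None, None]
    sigma_vox = tuple(s / v for s, v in zip(cfg.psf_sigma_um, cfg.voxel_size_um))
    imaged = {}
    for ch in channels:
        img = raw[ch].astype(float)
        if att is not None:
            img = img * att
        if any(s > 0 for s in sigma_vox):
            img = ndi.gaussian_filter(img, sigma=sigma_vox)
        if cfg.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if cfg.gaussian_noise_sd > 0:
            img = img + rng.normal(0, cfg.gaussian_noise_sd, size=img.shape)
        imaged[ch] = img

    total = labels.size
    fractions = dict(
        ecm=float(wall.sum()) / total,
        myocyte=float(myo.sum()) / total,
        aact=float(stripes.sum()) / total,
        cx43=float(puncta.sum()) / total,
    )
    truth = GroundTruthVolume(
        labels=labels, fractions=fractions, voxel_size_um=cfg.voxel_size_um,
        n_cells=n_cells, n_myocytes=int(is_myo_cell.sum()),
    )
    stack = VolumeStack(channels=imaged, voxel_size_um=cfg.voxel_size_um)
    return stack, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables and viability plates
# ---------------------------------------------------------------------------

DILUTION_SERIES = (1 / 5, 1 / 25, 1 / 125, 1 / 625)


def simulate_ct_table(true_ratios: dict[str, float],
                      efficiencies: dict[str, float],
                      reference_genes: tuple[str, ...] = ("EEF2", "HPRT1"),
                      n_pairs: int = 8, replicate_sd: float = 0.0,
                      seed: int = 0, ct0: float = 20.0,
                      loading_sd: float = 0.3,
                      dilutions: tuple[float, ...] = DILUTION_SERIES) -> pd.DataFrame:
    """Ct table with paired fresh/cultured samples and per-gene dilution series.

    ``true_ratios`` maps gene -> cultured/fresh expression ratio (reference
    genes are forced to ratio 1). Ct values follow
    Ct = Ct0 - log(template)/log(E) + noise; a per-sample loading factor is
    shared by all genes of that sample so that reference-gene normalization
    has something real to remove.
    """
    for g, e in efficiencies.items():
        if not (1.0 < e <= 2.0):
            raise ValueError(f"efficiency for {g} must be in (1, 2], got {e}")
    if replicate_sd < 0:
        raise ValueError("replicate_sd must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(dict.fromkeys(list(true_ratios) + list(reference_genes)))
    ratios = {g: (1.0 if g in reference_genes else float(true_ratios.get(g, 1.0)))
              for g in genes}
    loading = {("fresh", s): math.exp(rng.normal(0, loading_sd)) for s in range(n_pairs)}
    loading.update({("cultured", s): math.exp(rng.normal(0, loading_sd))
                    for s in range(n_pairs)})
    rows = []
    for g in genes:
        e = efficiencies[g]
        for s in range(n_pairs):
            for group in ("fresh", "cultured"):
                template = loading[(group, s)] * (ratios[g] if group == "cultured" else 1.0)
                ct = ct0 - math.log(template) / math.log(e)
                reps = ct + rng.normal(0, replicate_sd, size=3)
                rows.append(dict(gene=g, sample_id=f"S{s}", group=group,
                                 dilution=np.nan, ct_1=reps[0], ct_2=reps[1], ct_3=reps[2]))
        for d in dilutions:
            ct = ct0 - math.log(d) / math.log(e)
            reps = ct + rng.normal(0, replicate_sd, size=3)
            rows.append(dict(gene=g, sample_id="stock", group="dilution",
                             dilution=d, ct_1=reps[0], ct_2=reps[1], ct_3=reps[2]))
    return pd.DataFrame(rows)


def simulate_plate(n_per_group: int = 5, viability: dict[str, float] | None = None,
                   seed: int = 0, protein_mg: tuple[float, float] = (1.0, 4.0),
                   bradford_slope: float = 0.1, formazan_per_mg: float = 0.25,
                   noise_sd: float = 0.01,
                   standards_mg: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0)
                   ) -> dict[str, pd.DataFrame]:
    """MTT/Bradford plate readings for fresh vs cultured trabeculae.

    ``viability`` maps group -> relative metabolic activity (formazan produced
    per mg protein, in units of ``formazan_per_mg``). Returns a dict with a
    BSA ``standards`` table (conc_mg_ml, a595) and a ``samples`` table
    (sample_id, group, formazan_a595, bradford_a595, true_protein_mg).
    """
    viability = viability or {"fresh": 1.0, "cultured": 1.0}
    rng = np.random.default_rng(seed)
    standards = pd.DataFrame(dict(
        conc_mg_ml=standards_mg,
        a595=[bradford_slope * c + rng.normal(0, noise_sd) for c in standards_mg],
    ))
    rows = []
    for group, v in viability.items():
        for i in range(n_per_group):
            protein = rng.uniform(*protein_mg)
            rows.append(dict(
                sample_id=f"{group}-{i}", group=group,
                formazan_a595=v * formazan_per_mg * protein + rng.normal(0, noise_sd),
                bradford_a595=bradford_slope * protein + rng.normal(0, noise_sd),
                true_protein_mg=protein,
            ))
    return dict(standards=standards, samples=pd.DataFrame(rows))
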