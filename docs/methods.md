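# Methods

This note documents the models behind `trabkit`: what the analysis computes,
what the synthetic-data generator emulates, which parameters matter, and the
numerical choices made where the design was open.

## Force analysis chain

The device streams force at 400 Hz together with stimulation timestamps.
Analysis operates at 200 Hz after pairwise mean downsampling, followed by a
centered moving median (radius 10 samples → 21-sample window) and a centered
moving mean (radius 5 → 11 samples). Filter radii are interpreted in samples
at 200 Hz — the only self-consistent reading — and edge windows are
truncated, not padded. Only rocking-free periods are analyzed: the medium
agitation rocker couples into the spring wire as low-frequency artifact.

Sensor noise is estimated from the 200 ms windows directly before stimuli
delivered at pacing ≤ 1 Hz (preceding inter-stimulus interval ≥ 1000 ms,
ties included): contractions are over well before such a stimulus, so those
windows contain only noise. Windows overlapping a rocker-on span are
discarded rather than shortened — purity over count. Each window is demeaned
before pooling; the estimate carries the pooled SD and the maximum
peak-to-peak amplitude, whose sum is the minimum peak height for beat
detection.

Beats are local maxima whose topographic prominence strictly exceeds that
minimum peak height. Prominence stands in for "height above the local
diastolic level": it is offset-free and robust to slow baseline drift. When
two candidates fall within one stimulus interval the higher wins (ties:
earlier). Per beat, F_D is the minimum force within ±50% of the stimulus
interval around the peak, F_amp = F_max − F_D, and the kinetics use the
first sample at or below F_D + 0.1·F_amp moving backward (TTP90) and forward
(TTR90) from the peak, at sample resolution with no interpolation — the
"first occurrence" rule is inherently sample-level, so one sample (5 ms) is
the natural measurement granularity. Beats without a 10% crossing inside the
window (fused beats at fast pacing) are flagged unmeasurable and excluded
from period means.

## Capture analysis

An S2 extrastimulus is captured when a prominent peak occurs in the open
interval between the S2 stimulus and the following S1; a ladder step is
captured only when all three of its S2 beats are. The refractory period is
the ladder interval immediately preceding the first not-captured step, so it
is quantized to the ladder (750, 500, 400, 300, … ms): any true capture
threshold in (300, 400] reads out as 400 ms. A frequency-ladder step is
captured when each of the last five stimuli of its train elicits a peak in
its stimulus-to-stimulus window; f_max is the last captured frequency before
the first non-captured one. Fully-captured and never-captured ladders are
right-/left-censored and always reported with explicit flags rather than
sentinel values. The same peak rule drives both capture tests and beat
detection — a single definition of "a contraction happened".

One caveat inherited from the window rule: at S2 intervals shorter than the
time to peak of the preceding S1 twitch (≈120 ms and below with default
kinetics), the still-rising S1 twitch can be re-detected inside the S2
window and the step reads "captured". This cannot affect the refractory
period, which is determined by the *first* failure higher up the ladder, but
capture tables should not be interpreted below the first failure.

## The excitation–contraction simulator

The generator is phenomenological — no ionic currents. A stimulus elicits an
activation iff the time since the previous activation is at least the
current refractory period, and refractoriness restitutes with the preceding
diastolic interval DI:

    RP(DI) = rp_min + (rp_max − rp_min) · (1 − exp(−DI / τ)),

with defaults rp_min 150 ms, rp_max 350 ms, τ 1000 ms. Restitution is what
lets a tissue show a long RP to an S2 delivered after slow baseline pacing
yet still follow a fast steady train: with rp_max 380/rp_min 150 the S1–S2
protocol reads RP = 400 ms while all 25-beat trains up to 5 Hz capture
fully. τ = 1000 ms keeps the fixed point of the beat-to-beat map stable at
high rates; much shorter τ traps the model in a self-sustaining 2:1 rhythm
at intermediate frequencies. Setting rp_min = rp_max disables restitution
and gives an exactly known capture threshold — the configuration used for
the worked examples. Each activation's twitch is scaled by a linear
force–frequency factor (1 + slope·(f − 0.5 Hz), default slope −0.10/Hz, i.e.
a negative FFR), a post-rest gain (default 1.3 after pauses ≥ 4 s; drug
presets can blunt the potentiation, emulating high SERCA activity), and
amplitude alternans near the capture limit when enabled. Gaussian sensor
noise (default 5 μN) and, during rocker-on spans, a 1 Hz sinusoid (60 rpm)
plus slow wander are added. Drug presets: isoprenaline (amplitude ×2.15,
kinetics ×0.63, RP ×0.70, post-rest potentiation ×0.3) and dofetilide
(amplitude ×1.2, RP ×1.25, alternans on).

Default tissue parameters are the study conditions: 300 μN twitches on a
500 μN preload, TTP90 150 ms, TTR90 250 ms (atrial contraction is roughly
twice as fast as relaxation).

### Twitch waveform

The twitch shape is a design decision with a sharp constraint: the analysis
chain's fixed median+mean filters are *exactly* unbiased only on locally
symmetric extrema and on locally linear segments. Centered filters displace
the argmax of an asymmetric peak by 2–3 samples and shift 10% crossings
outward on curved flanks — with a raised-cosine twitch the measured TTP90
would carry a systematic +15 ms bias that no parameter recovery could
remove. The waveform therefore consists of (i) a symmetric low-slope tent
apex (half-width 40 ms, slope 3.3·10⁻⁴ of the amplitude per ms — shallow
enough to cost <1% amplitude under filtering, steep enough that noise cannot
displace the maximum by more than ~1 sample), (ii) linear segments of
±25 ms — the moving-mean window — centered on each 10% crossing, and (iii)
monotone cubic Hermite blends connecting them. Peak sample equals the
requested amplitude exactly; crossings land within half a sample of the
requested TTP90/TTR90. Residual filter attenuation of the peak is ≈1%, which
is why a noiseless 300 μN twitch measures ≈297 μN: the identity
"measured amplitude = true amplitude" holds only to the precision of the
denoising filters themselves.

## Ca²⁺/force co-registration

Both acquisition systems log the stimulation pulses on their own clocks. The
synchronizer scans candidate offsets (the densest cluster of pairwise event
differences), greedily matches events within 50 ms, refuses when fewer than
80% of the shorter log pairs up, and takes the mean residual as the offset —
exact to numerical precision whenever the logs share the stimulus sequence,
independent of trace noise, and robust to a few missing events. The
fluorescence trace is linearly resampled onto the force time base
(photometry rates far exceed the signal bandwidth). Ca²⁺ amplitudes use the
same per-stimulus window machinery as force; only amplitudes are reported —
no Ca²⁺ kinetics metrics and no absolute calibration. The post-rest
comparison anchors on the last 3 captured pre-rest beats (a choice; the
count is configurable) and is confounded by the FFR at the pre-rest rate —
comparisons across conditions should hold the protocol fixed.

## Confocal pipeline

Stacks are (z, y, x) with default voxel 0.1 × 0.1 × 0.2 μm (synthetic
volumes use 0.2³ μm for tractable extents). Depth attenuation is corrected
by per-plane gain matching against the top plane; the plane statistic is the
median of voxels above half the plane's bright level (99.5th percentile
above the stack mode). An earlier per-plane-mode statistic proved fragile
when the foreground fraction varies between planes — dense wall planes vs
sparse interior planes gave gains wrong by several fold — whereas the
half-bright cut adapts to each plane's own brightness. Richardson–Lucy
deconvolution (scikit-image backend, clipping off) is optional and off by
default: measured PSFs are instrument-specific; synthetic tests inject the
generator's known PSF.

Channel masks: global thresholds at histogram mode + k·SD (k = 1 WGA, 3
Cx43, 2 DAPI; mode from a 256-bin histogram of the intensity range; strict
>). Alpha-actinin varies too much in intensity for a global cut, so a
20 × 20 × 2 voxel box mean (x, y, z) is subtracted and the residual is
thresholded at its mode + 1 SD — insensitive to multiplicative shading. The
Cx43 mask is opened with an ellipsoidal element of 0.2 μm physical radius
(per-axis voxel radii; axes coarser than the radius stay in-plane), applied
to the binary mask, not the intensities, for determinism. Cells are
partitioned by watershed on the inverted Euclidean distance map of the
non-WGA space (physical units); seeds are local maxima with ≥4 μm
separation on a lightly smoothed (σ = 1 voxel) distance map — raw EDT
plateaus in brick-shaped cells otherwise shatter one cell into dozens of
seeds — and connected plateau maxima collapse to one seed. Interior pockets
unreachable from any seed become segments of their own, so segment volumes
sum exactly to the non-WGA volume. Segments with ≥7.5% alpha-actinin-positive
voxels (inclusive) are myocytes. Volume fractions use the full stack volume
as denominator, with the unclassified remainder (neither ECM nor myocyte)
reported separately; per-sample results average the sample's stacks.

### Synthetic volumes

A brick lattice of 6.4 μm cells (offset a quarter cell so no wall coincides
with the stack border) separated by 0.8 μm WGA-positive walls; 65% of cells
are myocytes carrying sarcomeric Z-disc bands — smooth periodic Gaussian
bands along x, 2 μm period, 0.5 μm FWHM, with per-cell lognormal brightness
(σ = 0.25) reflecting the strong staining variability of real sections (the
reason the pipeline uses a local threshold at all); ground truth counts the
FWHM band region. Cx43 plaques (~1 μm, 5 per longitudinal myocyte–myocyte
junction) sit on x-facing walls; each cell holds one ellipsoidal nucleus.
Imaging applies exp(−z/λ) attenuation (λ = 40 μm), a Gaussian PSF
(σ = 0.12 μm in-plane, 0.3 μm axial) and Poisson + Gaussian (σ = 3) noise.
These geometry choices were co-designed with the fixed mode+k·SD rules: the
thresholds select a fixed-contrast contour, so recovery of the geometric
ground truth to ±10% relative presumes structures larger than the PSF and
realistic duty cycles — thin-wall (≲2·PSF) or punctate structures are
systematically eroded or inflated by any fixed-contour rule, on real data as
here. What passing recovery tests shows is that the pipeline is unbiased for
tissue at these scales; it does not certify sub-resolution structures, real
staining artifacts, or anisotropic cell shapes, which the lattice does not
emulate.

## Molecular statistics

Efficiency per gene and experiment from the 1:5…1:625 dilution series:
least-squares slope of Ct vs log10(relative template), E = 10^(−1/slope); a
non-negative slope is refused. Expression ratios are efficiency-corrected
with ΔCt = mean Ct(control) − mean Ct(treated) (triplicates averaged per
sample first), so upregulation gives ratio > 1, and are normalized to the
geometric mean of the reference-gene terms (EEF2, HPRT1) — the standard
convention when the combination rule is unstated. Bradford protein comes
from a linear BSA standard curve inverted for samples, flagging
extrapolation beyond the standard range; MTT viability is formazan A595
divided by protein. Paired and Welch two-sided t-tests are scipy-backed;
zero-variance-equal-mean inputs return p = 1 by convention (logged). The
Holm step-down adjustment is implemented directly (sort ascending,
adjusted_i = max_{j≤i} min(1, (m−j+1)·p_(j)), original order restored) and
cross-checked against statsmodels in the test suite.

The synthetic Ct generator draws a per-sample loading factor shared by all
genes of that sample — exactly the nuisance reference-gene normalization
removes — and models Ct = Ct₀ − log(template)/log(E) + noise.

## Problem sizes and determinism

Tests and the acceptance script run the full printed protocols: the S1–S2
script (≈1600 s of simulated recording, 1447 stimuli) and the 12-step
frequency ladder (300 stimuli) simulate and analyze in a few seconds each;
segmentation tests use 48×96×96 and 64×128×128 voxel volumes (10 seeds).
Statistical calibration uses 10,000 simulated null pairs at n = 8. Every
stochastic component consumes a `numpy.random.default_rng` seed; identical
seeds give bit-identical recordings, volumes and tables.

## Known limitations

- No biophysical membrane or Ca²⁺-cycling model: the restitution gate and
  scaling factors reproduce the *readouts* (capture, RP, f_max, FFR,
  post-rest) but not their mechanisms; the mechanical RP reported here is a
  surrogate, not the electrical refractory period.
- The rocker artifact is a stand-in (sinusoid + wander); real artifact
  spectra are device-specific.
- Capture tables are unreliable below the first failure (S1-rise
  re-detection, see above).
- Fixed-contour thresholds tie fraction accuracy to structure scale; see the
  synthetic-volume section.
- Ca²⁺ amplitudes are relative; indicator saturation and calibration are out
  of scope.
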