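"""Ground-truth tissue parameters for the excitation-contraction simulator.

The simulator is phenomenological: a stimulus elicits a contraction if and
only if the tissue is past its refractory period, refractoriness restitutes
with the preceding diastolic interval, and each elicited twitch is scaled by
force-frequency, post-rest and drug factors. No ionic currents are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional


@dataclass(frozen=True)
class DrugEffect:
    """Multiplicative/additive modifiers applied on top of baseline physiology.

    amplitude_factor scales twitch amplitude, kinetics_factor scales TTP90 and
    TTR90 (values < 1 accelerate the twitch), rp_shift_ms shifts both ends of
    the refractory-period range, and alternans enables amplitude alternans in
    rate ranges close to the capture limit.
    """

    amplitude_factor: float = 1.0
    kinetics_factor: float = 1.0
    rp_shift_ms: float = 0.0
    rp_factor: float = 1.0
    alternans: bool = False
    post_rest_factor: float = 1.0   # scales post-rest potentiation (gain - 1)


#: Beta-adrenergic agonist preset: strong positive inotropy, faster kinetics,
#: shortened refractoriness, and a blunted post-rest response (high SERCA
#: activity refills the SR quickly, so a pause potentiates less).
ISOPRENALINE = DrugEffect(amplitude_factor=2.15, kinetics_factor=0.63,
                          rp_factor=0.70, post_rest_factor=0.3)

#: IKr-blocker preset: prolonged refractoriness, mild positive inotropy,
#: alternans near the capture limit.
DOFETILIDE = DrugEffect(amplitude_factor=1.2, rp_factor=1.25, alternans=True)


@dataclass(frozen=True)
class TissueParams:
    """True physiology of a simulated trabecula.

    Times are in ms, forces in μN, frequencies in Hz. Defaults describe a
    healthy cultured human atrial trabecula: ~300 μN twitches on a 500 μN
    diastolic preload, TTP90 ≈ 150 ms, TTR90 ≈ 250 ms, a mildly negative
    force-frequency relationship and moderate post-rest potentiation.
    """

    amplitude_base: float = 300.0     # μN
    ttp90_true: float = 150.0         # ms
    ttr90_true: float = 250.0         # ms
    diastolic_force: float = 500.0    # μN, device preload
    rp_min: float = 150.0             # ms, fully restituted-away floor
    rp_max: float = 350.0             # ms, fully rested refractory period
    restitution_tau: float = 1000.0   # ms
    ffr_slope: float = -0.10          # fractional amplitude change per Hz
    post_rest_gain: float = 1.3       # ≥ 1, potentiation of the post-rest beat
    post_rest_pause_s: float = 4.0    # s, minimum pause that counts as rest
    alternans_ratio: float = 1.0      # weak-beat fraction of full amplitude
    noise_sd: float = 5.0             # μN, Gaussian sensor noise
    rocker_artifact_amp: float = 30.0  # μN
    rocker_artifact_freq: float = 1.0  # Hz (60 rpm rocker)
    drug: Optional[DrugEffect] = None

    def validate(self) -> None:
        if self.amplitude_base < 0:
            raise ValueError("amplitude_base must be >= 0")
        if not (0 < self.rp_min <= self.rp_max):
            raise ValueError("require 0 < rp_min <= rp_max")
        if self.restitution_tau <= 0:
            raise ValueError("restitution_tau must be > 0")
        if self.ttp90_true <= 0 or self.ttr90_true <= 0:
            raise ValueError("ttp90_true and ttr90_true must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.post_rest_gain < 1:
            raise ValueError("post_rest_gain must be >= 1")
        if not (0 <= self.alternans_ratio <= 1):
            raise ValueError("alternans_ratio must be in [0, 1]")

    # -- effective (drug-modified) physiology ------------------------------

    @property
    def amplitude(self) -> float:
        f = self.drug.amplitude_factor if self.drug else 1.0
        return self.amplitude_base * f

    @property
    def ttp90(self) -> float:
        f = self.drug.kinetics_factor if self.drug else 1.0
        return self.ttp90_true * f

    @property
    def ttr90(self) -> float:
        f = self.drug.kinetics_factor if self.drug else 1.0
        return self.ttr90_true * f

    def rp_range(self) -> tuple[float, float]:
        lo, hi = self.rp_min, self.rp_max
        if self.drug:
            lo = lo * self.drug.rp_factor + self.drug.rp_shift_ms
            hi = hi * self.drug.rp_factor + self.drug.rp_shift_ms
        return lo, hi

    def refractory_period(self, diastolic_interval_ms: float) -> float:
        """Restituted refractory period after a given diastolic interval (ms)."""
        lo, hi = self.rp_range()
        import math

        return lo + (hi - lo) * (1.0 - math.exp(-diastolic_interval_ms / self.restitution_tau))

    def with_drug(self, drug: Optional[DrugEffect]) -> "TissueParams":
        return replace(self, drug=drug)


def fixed_threshold_params(capture_threshold_ms: float, **overrides) -> TissueParams:
    """Tissue with restitution disabled: a stimulus captures iff its coupling
    interval is >= ``capture_threshold_ms``. Convenient for worked examples
    with an exactly known capture boundary."""
    kw = dict(rp_min=capture_threshold_ms, rp_max=capture_threshold_ms)
    kw.update(overrides)
    return TissueParams(**kw)
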