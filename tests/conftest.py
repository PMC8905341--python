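import numpy as np
import pytest

import trabkit as tk
from trabkit import pacing, preprocess, simulate


@pytest.fixture(scope="session")
def s1s2_protocol():
    return pacing.S1S2Protocol().build()


@pytest.fixture(scope="session")
def frequency_protocol():
    return pacing.FrequencyProtocol().build()


def analyze(recording):
    trace = preprocess.make_analyzable(recording)
    noise = preprocess.estimate_noise(trace)
    return trace, noise


@pytest.fixture(scope="session")
def control_s1s2_analysis(s1s2_protocol):
    """Simulated control tissue (capture threshold 350 ms) under the full
    S1-S2 protocol, preprocessed, with its capture table."""
    params = tk.fixed_threshold_params(350.0, noise_sd=2.0, ffr_slope=0.0,
                                       rocker_artifact_amp=30.0)
    rec = simulate.simulate_recording(params, s1s2_protocol, seed=1)
    trace, noise = analyze(rec)
    table = pacing.detect_capture_s2(trace, trace.stimuli, noise)
    return dict(recording=rec, trace=trace, noise=noise, capture_table=table)


@pytest.fixture(scope="session")
def noiseless_train_beats():
    """12 noiseless 300 μN twitches at 0.5 Hz, detected and measured."""
    from trabkit import beats

    prot = tk.protocol.simple_train(0.5, 12, start_s=2.0)
    params = tk.TissueParams(noise_sd=0.0, rocker_artifact_amp=0.0)
    rec = simulate.simulate_recording(params, prot, seed=1)
    trace, noise = analyze(rec)
    bs = beats.measure_beats(trace, beats.detect_beats(trace, noise), 2000.0)
    return dict(recording=rec, trace=trace, noise=noise, beats=bs, params=params)
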