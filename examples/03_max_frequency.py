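"""Maximum captured frequency from the incremental frequency ladder.

Pacing rises 0.2 -> 5.0 Hz, 25 beats per step; a frequency is captured iff
each of the last five stimuli elicits a detected beat. A healthy tissue
follows every tested frequency (f_max = 5 Hz, right-censored), while a
tissue refractory below 350 ms falls into 2:1 capture from 3 Hz upward and
reads f_max = 2.5 Hz.
"""

import trabkit as tk
from trabkit import pacing, preprocess, simulate

protocol = pacing.FrequencyProtocol().build()

for label, threshold in [("control", 150.0), ("dofetilide", 350.0)]:
    params = tk.fixed_threshold_params(threshold, noise_sd=2.0, ffr_slope=0.0)
    rec = simulate.simulate_recording(params, protocol, seed=3)
    trace = preprocess.make_analyzable(rec)
    noise = preprocess.estimate_noise(trace)
    table = pacing.detect_capture_frequency(trace, trace.stimuli, noise)
    fm = pacing.max_frequency(trace, trace.stimuli, noise)
    row = " ".join(f"{f:g}:{'Y' if c else 'n'}"
                   for f, c in zip(table["frequency_hz"], table["captured"]))
    print(f"{label:>10}: {row}")
    print(f"{'':>10}  f_max = {fm.value:g} Hz ({fm.flag})")
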