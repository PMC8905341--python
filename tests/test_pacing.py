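"""Stimulation protocol builders and RP / f_max capture analysis."""

import numpy as np
import pandas as pd
import pytest

import trabkit as tk
from trabkit import pacing, preprocess, simulate

PRINTED_S2_LADDER = (750, 500, 400, 300, 275, 250, 240, 230, 220, 210,
                     200, 190, 180, 170, 160, 150, 140, 130, 120, 110, 100)
PRINTED_FREQ_LADDER = (0.2, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)


class TestProtocols:
    def test_interval_to_frequency(self):
        assert pacing.s2_interval_to_frequency(500.0) == 2.0
        assert pacing.s2_interval_to_frequency(1000.0) == 1.0
        assert pacing.s2_interval_to_frequency(200.0) == 5.0
        with pytest.raises(ValueError):
            pacing.s2_interval_to_frequency(0.0)

    def test_default_ladders_match_printed_protocol(self):
        assert pacing.S2_LADDER_MS == PRINTED_S2_LADDER
        assert pacing.FREQUENCY_LADDER_HZ == PRINTED_FREQ_LADDER

    def test_s1s2_script_has_three_s2_per_step(self, s1s2_protocol):
        s2 = s1s2_protocol.stimuli[s1s2_protocol.stimuli["kind"] == "S2"]
        assert len(s2) == 63
        assert s2["step"].nunique() == 21
        assert (s2.groupby("step").size() == 3).all()

    def test_s2_inserted_at_interval_after_regular_s1(self, s1s2_protocol):
        st = s1s2_protocol.stimuli
        for row in st[st["kind"] == "S2"].itertuples():
            prev = st[(st["time_s"] < row.time_s) & (st["kind"] == "S1")].iloc[-1]
            assert row.time_s - prev.time_s == pytest.approx(row.interval_ms / 1000.0)

    def test_train_frequency_matches_s2_interval(self, s1s2_protocol):
        st = s1s2_protocol.stimuli
        step = st[(st["step"] == 1) & (st["kind"] == "train")]   # 500 ms step
        dt = np.diff(step["time_s"].to_numpy())
        assert np.allclose(dt, 0.5)                              # 2 Hz
        assert len(step) == 12                                   # 6 s at 2 Hz

    def test_empty_ladder_is_baseline_only(self):
        prot = pacing.build_s1s2_protocol(pacing.S1S2Protocol(ladder_ms=()))
        assert (prot.stimuli["kind"] == "S1").all() or prot.stimuli.empty

    def test_frequency_protocol_25_beats_per_step(self, frequency_protocol):
        st = frequency_protocol.stimuli
        assert (st.groupby("step").size() == 25).all()
        five_hz = st[st["interval_ms"] == 200.0]["time_s"].to_numpy()
        assert five_hz[-1] - five_hz[0] == pytest.approx(24 * 0.2)  # 25 beats span 5 s

    def test_invalid_ladders_refused(self):
        with pytest.raises(ValueError):
            pacing.S1S2Protocol(ladder_ms=(400.0, 500.0))
        with pytest.raises(ValueError):
            pacing.FrequencyProtocol(ladder_hz=(1.0, 0.5))


def table(rows):
    return pd.DataFrame(rows, columns=["step", "interval_ms", "n_s2",
                                       "evaluable", "captured"])


class TestRefractoryPeriod:
    def test_failure_at_300_gives_rp_400(self):
        t = table([(i, iv, 3, True, iv >= 350) for i, iv in enumerate(PRINTED_S2_LADDER)])
        rp = pacing.refractory_period(t)
        assert rp.value == 400.0 and rp.flag == "measured"

    def test_failure_at_400_gives_rp_500(self):
        t = table([(i, iv, 3, True, iv >= 450) for i, iv in enumerate(PRINTED_S2_LADDER)])
        assert pacing.refractory_period(t).value == 500.0

    def test_all_captured_is_left_censored(self):
        t = table([(i, iv, 3, True, True) for i, iv in enumerate(PRINTED_S2_LADDER)])
        assert pacing.refractory_period(t).flag == "below_min"

    def test_first_step_failure_is_right_censored(self):
        t = table([(i, iv, 3, True, False) for i, iv in enumerate(PRINTED_S2_LADDER)])
        assert pacing.refractory_period(t).flag == "above_max"

    def test_unevaluable_step_before_failure(self):
        rows = [(i, iv, 3, iv != 500, iv >= 350) for i, iv in enumerate(PRINTED_S2_LADDER)]
        assert pacing.refractory_period(table(rows)).flag == "unevaluable"


class TestCaptureDetection:
    def test_control_tissue_rp_400(self, control_s1s2_analysis):
        tab = control_s1s2_analysis["capture_table"]
        captured = set(tab.loc[tab["captured"], "interval_ms"])
        # the three steps above the 350 ms threshold are captured and the
        # steps just below it are not (far below the threshold the window may
        # re-detect the still-rising S1 twitch, which cannot affect RP)
        assert {750.0, 500.0, 400.0} <= captured
        assert not captured & {300.0, 275.0, 250.0, 240.0, 230.0}
        rp = pacing.refractory_period(tab)
        assert rp.value == 400.0 and rp.flag == "measured"

    def test_two_of_three_s2_captured_is_not_captured(self):
        # trace with twitches after only two of the three S2 stimuli
        from trabkit.preprocess import AnalyzableTrace, NoiseEstimate
        from trabkit.simulate import make_twitch

        fs = 200.0
        force = np.zeros(int(fs * 40))
        rows = []
        t = 2.0
        for k in range(3):
            rows.append(dict(time_s=t, kind="S1", interval_ms=2000.0, step=0))
            rows.append(dict(time_s=t + 0.5, kind="S2", interval_ms=500.0, step=0))
            if k < 2:   # third S2 elicits nothing
                w = make_twitch(300.0, 150.0, 250.0, 1000.0 / fs)
                i0 = int(round((t + 0.5) * fs))
                force[i0:i0 + w.size] += w
            rows.append(dict(time_s=t + 2.0, kind="S1", interval_ms=2000.0, step=0))
            t += 4.0
        stimuli = pd.DataFrame(rows).sort_values("time_s").reset_index(drop=True)
        trace = AnalyzableTrace(sample_rate=fs, force=force,
                                valid_intervals=[(0.0, 40.0)],
                                stimulus_times=stimuli["time_s"].to_numpy())
        tab = pacing.detect_capture_s2(trace, stimuli,
                                       NoiseEstimate(5.0, 20.0, 4))
        assert not bool(tab.loc[0, "captured"])

    def test_zero_amplitude_tissue_captures_nothing(self, s1s2_protocol):
        params = tk.TissueParams(amplitude_base=0.0, noise_sd=1.0,
                                 rocker_artifact_amp=0.0)
        rec = simulate.simulate_recording(params, s1s2_protocol, seed=9)
        trace = preprocess.make_analyzable(rec)
        noise = preprocess.estimate_noise(trace)
        tab = pacing.detect_capture_s2(trace, trace.stimuli, noise)
        assert not tab["captured"].any()
        assert pacing.refractory_period(tab).flag == "above_max"


def fmax_of(params, frequency_protocol, seed=1):
    rec = simulate.simulate_recording(params, frequency_protocol, seed=seed)
    trace = preprocess.make_analyzable(rec)
    noise = preprocess.estimate_noise(trace)
    return pacing.max_frequency(trace, trace.stimuli, noise)


class TestMaxFrequency:
    def test_two_to_one_alternans_above_2p5_hz(self, frequency_protocol):
        fm = fmax_of(tk.fixed_threshold_params(350.0, noise_sd=2.0, ffr_slope=0.0),
                     frequency_protocol)
        assert fm.value == 2.5 and fm.flag == "measured"

    def test_full_capture_flags_at_max(self, frequency_protocol):
        fm = fmax_of(tk.fixed_threshold_params(150.0, noise_sd=2.0, ffr_slope=0.0),
                     frequency_protocol)
        assert fm.value == 5.0 and fm.flag == "at_max"

    def test_no_capture_is_below_min(self, frequency_protocol):
        fm = fmax_of(tk.TissueParams(amplitude_base=0.0, noise_sd=1.0,
                                     rocker_artifact_amp=0.0), frequency_protocol)
        assert fm.flag == "below_min"

    def test_short_train_unevaluable(self):
        from trabkit.preprocess import AnalyzableTrace, NoiseEstimate

        stimuli = pd.DataFrame(dict(time_s=[1.0, 2.0, 3.0], kind="train",
                                    interval_ms=1000.0, step=0))
        trace = AnalyzableTrace(200.0, np.zeros(1000), [(0.0, 5.0)],
                                stimuli["time_s"].to_numpy())
        fm = pacing.max_frequency(trace, stimuli, NoiseEstimate(1.0, 2.0, 1))
        assert fm.flag == "unevaluable"


class TestPhysiologyProperties:
    def test_rp_monotone_in_capture_threshold(self, s1s2_protocol, frequency_protocol):
        rps, fms = [], []
        for thr in (250.0, 350.0):
            p = tk.fixed_threshold_params(thr, noise_sd=2.0, ffr_slope=0.0)
            rec = simulate.simulate_recording(p, s1s2_protocol, seed=5)
            trace = preprocess.make_analyzable(rec)
            noise = preprocess.estimate_noise(trace)
            rps.append(pacing.refractory_period(
                pacing.detect_capture_s2(trace, trace.stimuli, noise)).value)
            fms.append(fmax_of(p, frequency_protocol, seed=5).value)
        assert rps[1] >= rps[0]
        assert fms[1] <= fms[0]

    def test_restitution_allows_high_fmax_despite_long_rp(self, s1s2_protocol,
                                                          frequency_protocol):
        # strong restitution: S2 after slow pacing sees a long RP, but fast
        # steady trains shorten it -> RP 400 ms yet 5 Hz captured
        p = tk.TissueParams(rp_min=150.0, rp_max=380.0, restitution_tau=1000.0,
                            noise_sd=2.0, ffr_slope=0.0, rocker_artifact_amp=30.0)
        rec = simulate.simulate_recording(p, s1s2_protocol, seed=2)
        trace = preprocess.make_analyzable(rec)
        noise = preprocess.estimate_noise(trace)
        rp = pacing.refractory_period(
            pacing.detect_capture_s2(trace, trace.stimuli, noise))
        fm = fmax_of(p, frequency_protocol, seed=3)
        assert rp.value == 400.0
        assert fm.value == 5.0 and fm.flag == "at_max"

    def test_rp_quantization_within_ladder_step(self, s1s2_protocol):
        # any true threshold in (300, 400] reads out as RP = 400 ms
        for thr, seed in [(310.0, 0), (350.0, 1), (400.0, 2)]:
            p = tk.fixed_threshold_params(thr, noise_sd=5.0, ffr_slope=0.0)
            rec = simulate.simulate_recording(p, s1s2_protocol, seed=seed)
            trace = preprocess.make_analyzable(rec)
            noise = preprocess.estimate_noise(trace)
            rp = pacing.refractory_period(
                pacing.detect_capture_s2(trace, trace.stimuli, noise))
            assert rp.value == 400.0, f"threshold {thr}"

    def test_disabled_restitution_matches_rp_and_fmax(self, s1s2_protocol,
                                                      frequency_protocol):
        # with restitution off, RP and the period of f_max agree within one
        # ladder step
        p = tk.fixed_threshold_params(350.0, noise_sd=2.0, ffr_slope=0.0)
        rec = simulate.simulate_recording(p, s1s2_protocol, seed=4)
        trace = preprocess.make_analyzable(rec)
        noise = preprocess.estimate_noise(trace)
        rp = pacing.refractory_period(
            pacing.detect_capture_s2(trace, trace.stimuli, noise))
        fm = fmax_of(p, frequency_protocol, seed=4)
        period_ms = 1000.0 / fm.value
        ladder = sorted(PRINTED_S2_LADDER)
        i_rp = ladder.index(rp.value)
        i_fm = min(range(len(ladder)), key=lambda i: abs(ladder[i] - period_ms))
        assert abs(i_rp - i_fm) <= 1


class TestPercentChange:
    def test_dofetilide_magnitude(self):
        assert pacing.rp_percent_change(400.0, 500.0) == pytest.approx(25.0)

    def test_no_change(self):
        assert pacing.rp_percent_change(400.0, 400.0) == 0.0

    def test_half_increase(self):
        assert pacing.rp_percent_change(200.0, 300.0) == pytest.approx(50.0)

    def test_censored_inputs_refused(self):
        with pytest.raises(ValueError):
            pacing.rp_percent_change(pacing.CensoredValue(None, "below_min"), 400.0)
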