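"""Filter design, chain application, and the CF/OF pipelines."""

import numpy as np
import pytest
from scipy.signal import periodogram

from eegparity import (
    CHANNELS_1020,
    FilterSpec,
    apply_filter_chain,
    build_calibration_schedule,
    conventional_pipeline,
    design_filter_chain,
    online_pipeline,
    load_trials,
    save_trials,
    synthesize_session,
)
from eegparity.synthetic import RawSession, SynthesisParams
from conftest import quiet_params, sinusoid_session

FS = 300.0


class TestDesign:
    def test_bandpass_minus3db_at_edges(self):
        f = design_filter_chain(FilterSpec(), FS)
        mags = f.bandpass_magnitude([1.0, 20.0])
        assert np.allclose(mags, 1 / np.sqrt(2), rtol=1e-6)

    def test_bandpass_near_unity_at_geometric_mean(self):
        f = design_filter_chain(FilterSpec(), FS)
        assert f.bandpass_magnitude(np.sqrt(20.0))[0] == pytest.approx(1.0,
                                                                       rel=0.01)

    def test_zero_phase_notch_attenuation(self):
        f = design_filter_chain(FilterSpec(), FS)
        assert f.notch_magnitude(60.0)[0] < 1e-3

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            design_filter_chain(FilterSpec(band_high=80.0), FS)
        with pytest.raises(ValueError):
            FilterSpec(band_low=0.0).validate(FS)

    @pytest.mark.parametrize("band", [(1.0, 10.0), (0.2, 20.0),
                                      (1.0, 20.0), (0.1, 50.0)])
    def test_published_band_sweep_designs(self, band):
        spec = FilterSpec(band_low=band[0], band_high=band[1])
        f = design_filter_chain(spec, FS)
        assert np.allclose(f.bandpass_magnitude(list(band)), 1 / np.sqrt(2),
                           rtol=1e-6)


class TestApplyChain:
    def test_zero_input_zero_output(self):
        spec = FilterSpec()
        f = design_filter_chain(spec, FS)
        out = apply_filter_chain(np.zeros((3, 3000)), f, spec)
        assert out.shape == (3, 1500)
        assert np.all(out == 0.0)

    def test_line_frequency_rejected(self):
        # steady state (past the causal bandpass start-up transient)
        spec = FilterSpec()
        f = design_filter_chain(spec, FS)
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 60.0 * t)[None, :]
        out = apply_filter_chain(x, f, spec)[:, int(2 * FS / 2):]
        assert np.sqrt((out ** 2).mean()) < 1e-3 * np.sqrt((x ** 2).mean())

    def test_inband_steady_state_gain(self):
        spec = FilterSpec()
        f = design_filter_chain(spec, FS)
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        out = apply_filter_chain(x, f, spec)
        steady = out[0, out.shape[1] // 2:]
        expected = float(f.bandpass_magnitude(10.0)[0]
                         * f.notch_magnitude(10.0)[0])
        assert steady.max() == pytest.approx(expected, rel=0.02)

    def test_zero_phase_notch_leaves_no_delay(self):
        from scipy.signal import filtfilt
        spec = FilterSpec()
        f = design_filter_chain(spec, FS)
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = filtfilt(f.notch_b, f.notch_a, x)

        def crossing_times(sig):
            idx = np.flatnonzero(np.diff(np.signbit(sig)))
            return idx + sig[idx] / (sig[idx] - sig[idx + 1])

        xc = crossing_times(x)
        yc = crossing_times(y)
        # every interior input crossing has an output crossing within one
        # sample (edge effects can add crossings at the very ends)
        shifts = [np.min(np.abs(yc - c)) for c in xc[5:-5]]
        assert max(shifts) < 1.0

    def test_short_segment_error_names_minimum(self):
        spec = FilterSpec()
        f = design_filter_chain(spec, FS)
        with pytest.raises(ValueError, match=str(f.min_segment_len)):
            apply_filter_chain(np.zeros((1, 10)), f, spec)

    def test_no_energy_above_twice_band_edge(self):
        # broadband noise in, downsampled out: power above 2x band_high
        # must be negligible (no aliasing from the decimation)
        rng = np.random.default_rng(0)
        spec = FilterSpec()
        f = design_filter_chain(spec, FS)
        x = rng.normal(size=(1, int(30 * FS)))
        out = apply_filter_chain(x, f, spec)[0]
        freqs, power = periodogram(out, fs=FS / spec.downsample_factor)
        assert power[freqs > 40.0].sum() < 0.01 * power.sum()


class TestPipelines:
    def test_cf_counts_and_window(self, default_schedule):
        p = quiet_params(seed=1)
        raw = synthesize_session(default_schedule, p)
        data = conventional_pipeline(raw, FilterSpec(), trial_window_s=0.5)
        assert data.trials.shape == (1100, 19, 75)
        assert data.n_targets == 99
        assert data.provenance == "CF"
        assert data.effective_fs == 150.0

    def test_zero_signal_gives_zero_trials_both_pipelines(self):
        sched = build_calibration_schedule(5, seed=1)
        p = quiet_params(p300_amp_uV=0.0, n200_amp_uV=0.0)
        raw = synthesize_session(sched, p)
        cf = conventional_pipeline(raw, FilterSpec())
        of = online_pipeline(raw, FilterSpec())
        assert np.all(cf.trials == 0.0)
        assert np.all(of.trials == 0.0)
        assert cf.trials.shape == of.trials.shape

    def test_shape_and_label_parity(self, default_schedule):
        p = SynthesisParams(seed=4)
        raw = synthesize_session(default_schedule, p)
        cf = conventional_pipeline(raw, FilterSpec())
        of = online_pipeline(raw, FilterSpec())
        assert cf.trials.shape == of.trials.shape
        assert np.array_equal(cf.labels, of.labels)
        assert of.provenance == "OF"

    def test_cf_of_agreement_on_stationary_input(self):
        raw = sinusoid_session()
        spec = FilterSpec()
        cf = conventional_pipeline(raw, spec)
        rms = np.sqrt((cf.trials ** 2).mean())
        discrepancies = []
        for buf in (0.25, 0.5, 1.0):
            of = online_pipeline(raw, spec, buffer_s=buf)
            discrepancies.append(np.abs(cf.trials - of.trials).max() / rms)
        assert discrepancies[-1] < 0.02
        assert np.all(np.diff(discrepancies) <= 0)

    @pytest.mark.parametrize("band", [(1.0, 10.0), (0.2, 20.0),
                                      (1.0, 20.0), (0.1, 50.0)])
    def test_band_sweep_produces_full_datasets(self, band):
        sched = build_calibration_schedule(4, seed=2)
        raw = synthesize_session(sched, SynthesisParams(seed=2))
        spec = FilterSpec(band_low=band[0], band_high=band[1])
        for data in (conventional_pipeline(raw, spec),
                     online_pipeline(raw, spec)):
            assert data.n_trials == sched.n_stimuli
            assert data.band == band

    def test_onset_past_record_is_reported(self):
        sched = build_calibration_schedule(3, seed=1)
        short = np.zeros((19, int(2.0 * FS)))
        raw = RawSession(short, FS, list(CHANNELS_1020), sched, 0)
        with pytest.raises(ValueError):
            conventional_pipeline(raw, FilterSpec())
        with pytest.raises(ValueError):
            online_pipeline(raw, FilterSpec())

    def test_trials_roundtrip(self, tmp_path):
        sched = build_calibration_schedule(3, seed=1)
        raw = synthesize_session(sched, SynthesisParams(seed=3))
        data = online_pipeline(raw, FilterSpec())
        save_trials(data, tmp_path / "trials")
        back = load_trials(tmp_path / "trials")
        assert np.array_equal(back.trials, data.trials)
        assert np.array_equal(back.labels, data.labels)
        assert back.provenance == data.provenance
        assert back.band == data.band
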