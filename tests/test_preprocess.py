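"""Conditioning, segmentation, Morlet decomposition, baseline normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from burstdecode import preprocess as pp
from tests.conftest import make_trialset

FS = 2048.0


def noise_recording(n_ch=2, dur=20.0, seed=0):
    rng = np.random.default_rng(seed)
    return pp.Recording(signal=rng.standard_normal((n_ch, int(dur * FS))),
                        fs=FS, contact_labels=[f"c{i+2}" for i in range(n_ch)])


class TestConditioning:
    def test_zero_mean_unit_variance(self):
        out = pp.condition_signal(noise_recording())
        assert np.all(np.abs(out.signal.mean(axis=1)) < 1e-8)
        assert np.all(np.abs(out.signal.var(axis=1) - 1) < 1e-6)

    def test_slow_component_attenuated_20db(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t) + 0.5 * np.sin(2 * np.pi * 20.0 * t)
        rec = pp.Recording(signal=x[None], fs=FS, contact_labels=["c2"])
        out = pp.condition_signal(rec)

        def ratio(sig):
            f, p = sps.periodogram(sig, fs=FS)
            return p[np.argmin(np.abs(f - 1.0))] / p[np.argmin(np.abs(f - 20.0))]

        # relative 1 Hz content must drop by >= 20 dB (factor 100 in power)
        assert ratio(out.signal[0]) < ratio(x) / 100.0

    def test_flat_channel_excluded(self):
        rec = noise_recording(n_ch=3)
        rec.signal[1] = 4.2
        out = pp.condition_signal(rec)
        assert out.excluded == ["c3"]
        assert out.contact_labels == ["c2", "c4"]

    def test_clipped_channel_excluded(self):
        rec = noise_recording(n_ch=2)
        rec.signal[0] = np.clip(rec.signal[0], -1.0, 1.0)
        out = pp.condition_signal(rec)
        assert "c2" in out.excluded

    def test_all_flat_raises(self):
        rec = noise_recording(n_ch=1)
        rec.signal[:] = 0.0
        with pytest.raises(ValueError):
            pp.condition_signal(rec)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            pp.condition_signal(noise_recording(dur=5.0))

    def test_whole_record_order_differs_from_per_epoch(self):
        """Conditioning the whole record (the pipeline's order) is not the
        same operation as conditioning each epoch separately, and epochs cut
        from the conditioned record are exact slices of it."""
        rec = noise_recording(dur=40.0, seed=3)
        rec.signal[0, : int(15 * FS)] *= 5.0  # non-stationary variance
        whole = pp.condition_signal(rec)
        events = pd.DataFrame({
            "trial": [0, 1], "block_type": "fixed_limb",
            "cue_s": [10.0, 30.0], "move_on_s": [10.5, 30.5],
            "move_off_s": [11.5, 31.5], "limb": ["upper", "lower"]})
        trials = pp.segment_trials(whole, events, pre_s=4.0, post_s=3.0,
                                   pad_s=0.5)
        i0 = int(round((10.0 - 4.5) * FS))
        assert np.array_equal(trials.epochs[0],
                              whole.signal[:, i0:i0 + trials.epochs.shape[2]])
        per_epoch = (trials.epochs[0] - trials.epochs[0].mean(axis=1, keepdims=True))
        per_epoch /= per_epoch.std(axis=1, keepdims=True)
        assert not np.allclose(per_epoch, trials.epochs[0], atol=1e-3)


class TestSegmentation:
    def events(self, cues):
        n = len(cues)
        return pd.DataFrame({
            "trial": np.arange(n), "block_type": "fixed_limb",
            "cue_s": np.asarray(cues, dtype=float),
            "move_on_s": np.asarray(cues, dtype=float) + 0.5,
            "move_off_s": np.asarray(cues, dtype=float) + 1.5,
            "limb": (["upper", "lower"] * (n // 2 + 1))[:n],
        })

    def test_epoch_count_and_length(self):
        rec = noise_recording(dur=45.0)
        trials = pp.segment_trials(rec, self.events([10.0, 20.0, 30.0]),
                                   pre_s=4.0, post_s=3.0, pad_s=0.5)
        assert trials.epochs.shape == (3, 2, int(8.0 * FS))
        assert trials.n_dropped == 0

    def test_out_of_bounds_trial_dropped(self):
        rec = noise_recording(dur=45.0)
        trials = pp.segment_trials(rec, self.events([2.0, 20.0]),
                                   pre_s=4.0, post_s=3.0, pad_s=0.5)
        assert trials.n_trials == 1 and trials.n_dropped == 1

    def test_empty_events(self):
        rec = noise_recording(dur=45.0)
        trials = pp.segment_trials(rec, self.events([]))
        assert trials.n_trials == 0

    def test_rest_chunking(self):
        rec = noise_recording(dur=60.0)
        rest = pp.segment_rest(rec, rest_end_s=50.0, chunk_s=7.0)
        assert rest.n_trials == 7  # chunks at 0.5 + 7k, last ending <= 50
        assert rest.baseline == (-4.0, -3.5)


class TestMorlet:
    def tone_trials(self, freq, amp=1.0, n_ch=1, dur=3.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(dur * FS)) / FS
        x = amp * np.sin(2 * np.pi * freq * t) + 1e-3 * rng.standard_normal(
            (n_ch, len(t)))
        return make_trialset(x[None] if x.ndim == 2 else x[None, None])

    def test_pure_tone_peak_row(self):
        tf = pp.morlet_decompose(self.tone_trials(20.0),
                                 freqs=np.arange(8.0, 101.0),
                                 out_span=(-0.5, 0.5))
        prof = tf.power[0, 0].mean(axis=1)
        assert tf.freqs[np.argmax(prof)] == pytest.approx(20.0, abs=1.0)
        assert prof[tf.freqs == 100.0][0] < 0.01 * prof.max()

    def test_power_is_quadratic_in_amplitude(self):
        tf1 = pp.morlet_decompose(self.tone_trials(20.0, amp=1.0),
                                  freqs=np.arange(18.0, 23.0),
                                  out_span=(-0.5, 0.5))
        tf2 = pp.morlet_decompose(self.tone_trials(20.0, amp=2.0),
                                  freqs=np.arange(18.0, 23.0),
                                  out_span=(-0.5, 0.5))
        ratio = tf2.power[0, 0, 2].mean() / tf1.power[0, 0, 2].mean()
        assert ratio == pytest.approx(4.0, rel=0.01)

    def test_two_tone_ridges_match_fft_peaks(self):
        """Ridge frequencies agree with an FFT periodogram of the same
        signal to within 1 Hz."""
        t = np.arange(int(3.0 * FS)) / FS
        x = np.sin(2 * np.pi * 15.0 * t) + 0.7 * np.sin(2 * np.pi * 40.0 * t)
        trials = make_trialset(x[None, None])
        freqs = np.arange(8.0, 61.0)
        tf = pp.morlet_decompose(trials, freqs=freqs, out_span=(-0.5, 0.5))
        prof = tf.power[0, 0].mean(axis=1)
        f, p = sps.periodogram(x, fs=FS)
        fft_peaks = sorted(
            f[np.argsort(p)[-2:]])
        lo = freqs[np.argmax(prof[freqs < 25])]
        hi = freqs[freqs >= 25][np.argmax(prof[freqs >= 25])]
        assert abs(lo - fft_peaks[0]) <= 1.0
        assert abs(hi - fft_peaks[1]) <= 1.0

    def test_matches_mne_reference(self):
        """Independent oracle: power correlates ~1 with MNE's Morlet TFR and
        differs only by a constant wavelet-normalization factor."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(0)
        sig = rng.standard_normal((2, 2, int(3.0 * FS))).astype(np.float32)
        trials = make_trialset(sig)
        freqs = np.array([10.0, 25.0, 80.0, 200.0, 450.0])
        tf = pp.morlet_decompose(trials, freqs=freqs, out_span=(-0.5, 0.5))
        ref = mne.time_frequency.tfr_array_morlet(
            sig.astype(float), sfreq=FS, freqs=freqs, n_cycles=7.0,
            output="power", zero_mean=True)
        idx = np.round((tf.times + 1.5) * FS).astype(int)
        ref_p = ref[..., idx]
        for fi in range(len(freqs)):
            a = tf.power[:, :, fi].ravel().astype(float)
            b = ref_p[:, :, fi].ravel()
            assert np.corrcoef(a, b)[0, 1] > 0.999
            assert np.median(a / b) == pytest.approx(0.5, rel=0.01)

    def test_frequency_grid_bounds_checked(self):
        with pytest.raises(ValueError):
            pp.morlet_decompose(self.tone_trials(20.0),
                                freqs=np.array([1.0, 10.0]))

    def test_edge_samples_marked_invalid_without_padding(self):
        trials = make_trialset(np.random.default_rng(0).standard_normal(
            (1, 1, int(3.0 * FS))), pad_s=0.0, pre_s=1.5, post_s=1.5)
        tf = pp.morlet_decompose(trials, freqs=np.array([8.0, 100.0]),
                                 out_span=(-1.5, 1.5))
        assert not tf.valid[0, 0] and not tf.valid[0, -1]  # 8 Hz edges
        assert tf.valid[:, len(tf.times) // 2].all()
        assert tf.valid[1].sum() > tf.valid[0].sum()  # shorter wavelet


class TestBaseline:
    def test_baseline_window_mean_is_one(self):
        trials = make_trialset(np.random.default_rng(1).standard_normal(
            (3, 2, int(3.0 * FS))))
        tf = pp.morlet_decompose(trials, freqs=np.arange(8.0, 30.0),
                                 out_span=(-1.0, 1.0))
        norm = pp.baseline_normalize(tf, baseline=(-0.9, -0.4))
        sel = (norm.times >= -0.9) & (norm.times < -0.4)
        means = norm.power[:, :, :, sel].mean(axis=3)
        assert np.allclose(means, 1.0, atol=1e-5)

    def test_matches_direct_recomputation(self):
        trials = make_trialset(np.random.default_rng(2).standard_normal(
            (2, 1, int(3.0 * FS))))
        tf = pp.morlet_decompose(trials, freqs=np.arange(8.0, 15.0),
                                 out_span=(-1.0, 1.0))
        norm = pp.baseline_normalize(tf, baseline=(-0.9, -0.4))
        sel = (tf.times >= -0.9) & (tf.times < -0.4)
        expected = tf.power / tf.power[:, :, :, sel].mean(axis=3)[..., None]
        assert np.allclose(norm.power, expected, rtol=1e-6)

    def test_known_power_step_gives_ratio_two(self):
        t = np.arange(int(3.0 * FS)) / FS
        amp = np.where(t > 1.8, np.sqrt(2.0), 1.0)  # power doubles post "cue"
        x = amp * np.sin(2 * np.pi * 20.0 * t)
        trials = make_trialset(x[None, None])
        tf = pp.morlet_decompose(trials, freqs=np.arange(18.0, 23.0),
                                 out_span=(-1.0, 1.0))
        norm = pp.baseline_normalize(tf, baseline=(-0.9, -0.4))
        late = norm.power[0, 0, 2, norm.times > 0.5].mean()
        assert late == pytest.approx(2.0, rel=0.05)

    def test_zero_baseline_flagged(self):
        trials = make_trialset(np.zeros((1, 1, int(3.0 * FS))))
        tf = pp.morlet_decompose(trials, freqs=np.arange(8.0, 10.0),
                                 out_span=(-1.0, 1.0))
        norm = pp.baseline_normalize(tf, baseline=(-0.9, -0.4))
        assert norm.baseline_invalid.all()
        assert np.isnan(norm.power).all()

    def test_baseline_outside_span_raises(self):
        trials = make_trialset(np.random.default_rng(0).standard_normal(
            (1, 1, int(3.0 * FS))))
        tf = pp.morlet_decompose(trials, freqs=np.arange(8.0, 10.0),
                                 out_span=(-0.2, 0.5))
        with pytest.raises(ValueError):
            pp.baseline_normalize(tf, baseline=(-2.0, -1.5))


def test_morlet_power_tracks_bandpass_variance():
    """Total 8-100 Hz Morlet power correlates with bandpass variance across
    epochs (Parseval-style sanity on band-limited noise)."""
    rng = np.random.default_rng(4)
    n_ep = 100
    sig = rng.standard_normal((n_ep, 1, int(2.0 * FS)))
    scale = rng.uniform(0.5, 2.0, n_ep)[:, None, None]
    sig *= scale
    trials = make_trialset(sig, pre_s=0.5, post_s=0.5)
    tf = pp.morlet_decompose(trials, freqs=np.arange(8.0, 101.0, 4.0),
                             out_span=(-0.4, 0.4))
    total = tf.power[:, 0].sum(axis=(1, 2))
    sos = sps.butter(4, (8, 100), btype="bandpass", fs=FS, output="sos")
    bp = sps.sosfiltfilt(sos, sig[:, 0], axis=1)
    var = bp[:, int(0.6 * FS):int(1.4 * FS)].var(axis=1)
    assert np.corrcoef(total, var)[0, 1] > 0.95
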