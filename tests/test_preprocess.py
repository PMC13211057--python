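"""Excision, filtering, resampling, ICA ocular removal, epoching, scaling."""

import numpy as np
import pytest

from eegdecoder.channels import STANDARD_19
from eegdecoder.io import ArtifactAnnotations, RawRecording, TrialSet
from eegdecoder.preprocess import (
    PipelineConfig,
    apply_filters,
    apply_normalizer,
    epoch_runs,
    fit_channel_normalizer,
    preprocess_recording,
    remove_annotated_segments,
    remove_ocular_components,
    resample,
)


def _rec(data, fs=256.0, subject="s", label=None):
    return RawRecording(subject, fs, list(STANDARD_19), data, class_label=label)


class TestExcision:
    def test_two_intervals_give_three_runs(self, noise_recording, simple_annotations):
        runs = remove_annotated_segments(noise_recording, simple_annotations)
        assert len(runs.segments) == 3
        assert runs.total_duration_s == pytest.approx(285.0)
        assert runs.offsets_s == [0.0, 20.0, 55.0]

    def test_empty_annotations_identity(self, noise_recording):
        runs = remove_annotated_segments(noise_recording, ArtifactAnnotations([]))
        assert len(runs.segments) == 1
        assert np.array_equal(runs.segments[0], noise_recording.data)

    def test_overlapping_intervals_merged_before_excision(self, noise_recording):
        ann = ArtifactAnnotations([(10.0, 30.0), (20.0, 40.0)])
        runs = remove_annotated_segments(noise_recording, ann)
        assert len(runs.segments) == 2
        assert runs.total_duration_s == pytest.approx(270.0)

    def test_conservation_to_one_sample(self, noise_recording, rng):
        """Excised + retained durations must equal the recording duration."""
        onsets = np.sort(rng.uniform(0, 280, size=6))
        ann = ArtifactAnnotations([(float(a), float(a + rng.uniform(1, 8))) for a in onsets])
        runs = remove_annotated_segments(noise_recording, ann)
        merged = ann.clipped(noise_recording.duration_s).merged()
        excised_samples = sum(
            int(np.floor(b * 256)) - int(np.floor(a * 256)) for a, b in merged)
        retained = sum(s.shape[1] for s in runs.segments)
        assert retained + excised_samples == noise_recording.n_samples

    def test_interval_outside_recording_is_clipped(self, noise_recording):
        ann = ArtifactAnnotations([(295.0, 330.0)])
        runs = remove_annotated_segments(noise_recording, ann)
        assert runs.total_duration_s == pytest.approx(295.0)


class TestFilters:
    fs = 256.0

    def _tone(self, freq, seconds=20):
        t = np.arange(int(seconds * self.fs)) / self.fs
        return np.sin(2 * np.pi * freq * t)[None, :]

    def test_notch_attenuates_50hz_by_20db(self):
        x = self._tone(50.0)
        y = apply_filters(x, self.fs)
        core = slice(int(2 * self.fs), -int(2 * self.fs))
        ratio = np.sqrt(np.mean(y[0, core] ** 2) / np.mean(x[0, core] ** 2))
        assert ratio <= 0.1

    def test_passband_preserves_10hz_within_10pct(self):
        x = self._tone(10.0)
        y = apply_filters(x, self.fs)
        core = slice(int(2 * self.fs), -int(2 * self.fs))
        ratio = np.sqrt(np.mean(y[0, core] ** 2) / np.mean(x[0, core] ** 2))
        assert 0.9 <= ratio <= 1.1

    def test_dc_removed(self):
        x = np.full((1, 4096), 37.0)
        y = apply_filters(x, self.fs)
        assert np.max(np.abs(y[0, 512:-512])) <= 1e-6 * 37.0

    def test_output_length_equals_input_length(self, rng):
        x = rng.standard_normal((3, 2000))
        assert apply_filters(x, self.fs).shape == x.shape

    def test_short_run_skipped_unchanged(self, rng):
        x = rng.standard_normal((2, 40))
        y = apply_filters(x, self.fs)
        assert np.array_equal(x, y)

    def test_rate_too_low_rejected(self):
        with pytest.raises(ValueError):
            apply_filters(np.zeros((1, 1000)), fs=60.0, high_hz=40.0)


class TestResample:
    def test_512_to_256_matches_decimated_sinusoid(self):
        fs = 512.0
        t = np.arange(int(10 * fs)) / fs
        x = np.tile(np.sin(2 * np.pi * 10 * t), (19, 1))
        rec = _rec(x, fs=fs)
        out = resample(rec, 256.0)
        t2 = np.arange(out.n_samples) / 256.0
        ref = np.sin(2 * np.pi * 10 * t2)
        core = slice(256, -256)
        r = np.corrcoef(out.data[0, core], ref[core])[0, 1]
        assert r > 0.999
        assert abs(out.n_samples - 256.0 * rec.duration_s) <= 1

    def test_identity_when_rates_match(self, noise_recording):
        out = resample(noise_recording, 256.0)
        assert np.array_equal(out.data, noise_recording.data)

    def test_upsampling_refused(self, noise_recording):
        with pytest.raises(ValueError, match="not supported"):
            resample(noise_recording, 512.0)


class TestOcularRemoval:
    fs = 256.0

    def _blinky_run(self, rng, seconds=60):
        """EEG-like noise plus a strong frontal blink source with ground truth."""
        n = int(seconds * self.fs)
        data = rng.standard_normal((19, n)) * 15.0
        blink = np.zeros(n)
        for onset in np.arange(2.0, seconds - 2.0, 3.0):
            i0 = int(onset * self.fs)
            m = int(1.0 * self.fs)
            blink[i0:i0 + m] += 0.5 * (1 - np.cos(2 * np.pi * np.arange(m) / m))
        topo = np.zeros(19)
        topo[STANDARD_19.index("FP1")] = 1.0
        topo[STANDARD_19.index("FP2")] = 0.9
        topo[STANDARD_19.index("F3")] = 0.3
        topo[STANDARD_19.index("F4")] = 0.3
        data += topo[:, None] * blink[None, :] * 150.0
        return data, blink

    def test_blink_suppressed_posterior_preserved(self, rng):
        data, blink = self._blinky_run(rng)
        cleaned = remove_ocular_components(data, self.fs, list(STANDARD_19), seed=2025)
        fp1 = STANDARD_19.index("FP1")
        corr_before = abs(np.corrcoef(data[fp1], blink)[0, 1])
        corr_after = abs(np.corrcoef(cleaned[fp1], blink)[0, 1])
        assert corr_after <= 0.5 * corr_before
        post = [STANDARD_19.index(c) for c in ("O1", "OZ", "O2")]
        rms_before = np.sqrt(np.mean(data[post] ** 2))
        rms_after = np.sqrt(np.mean(cleaned[post] ** 2))
        assert abs(rms_after - rms_before) / rms_before <= 0.10

    def test_no_ocular_source_passes_through(self, rng):
        data = rng.standard_normal((19, int(60 * self.fs))) * 15.0
        cleaned = remove_ocular_components(data, self.fs, list(STANDARD_19), seed=2025)
        for c in range(19):
            assert np.corrcoef(data[c], cleaned[c])[0, 1] > 0.95

    def test_short_run_skipped(self, rng):
        data = rng.standard_normal((19, int(5 * self.fs)))
        out = remove_ocular_components(data, self.fs, list(STANDARD_19), seed=1)
        assert np.array_equal(out, data)


class TestEpoching:
    def _runs_from(self, rec, ann=None):
        return remove_annotated_segments(rec, ann or ArtifactAnnotations([]))

    def test_200s_run_gives_40_trials(self, rng):
        rec = _rec(rng.standard_normal((19, int(200 * 256))), label="AD")
        ts = epoch_runs(self._runs_from(rec), cap_per_subject=40)
        assert ts.n_trials == 40
        assert ts.n_samples == 1280

    def test_87s_gives_17_trials(self, rng):
        rec = _rec(rng.standard_normal((19, int(87 * 256))))
        ts = epoch_runs(self._runs_from(rec), cap_per_subject=40)
        assert ts.n_trials == 17

    def test_subfive_second_run_gives_zero_trials(self, rng):
        rec = _rec(rng.standard_normal((19, int(4.9 * 256))))
        ts = epoch_runs(self._runs_from(rec))
        assert ts.n_trials == 0

    def test_no_trial_crosses_excision_boundary(self, rng):
        rec = _rec(np.arange(19 * 300 * 256, dtype=float).reshape(19, -1))
        ann = ArtifactAnnotations([(100.0, 103.0)])
        runs = remove_annotated_segments(rec, ann)
        ts = epoch_runs(runs, cap_per_subject=1000)
        # every trial must be a contiguous slice of the original recording
        for trial in ts.trials:
            first = trial[0]
            diffs = np.diff(first)
            assert np.allclose(diffs, diffs[0])

    def test_epoch_then_excise_equals_excise_then_epoch_on_clean_input(self, rng):
        rec = _rec(rng.standard_normal((19, int(50 * 256))))
        direct = epoch_runs(self._runs_from(rec))
        via_empty_excision = epoch_runs(
            remove_annotated_segments(rec, ArtifactAnnotations([])))
        assert np.array_equal(direct.trials, via_empty_excision.trials)


class TestNormalization:
    def test_zscore_on_fitting_set(self, rng):
        trials = (rng.standard_normal((20, 19, 1280)) * 12 + 3).astype(np.float32)
        ts = TrialSet(trials, np.array(["s"] * 20), None, 256.0)
        params = fit_channel_normalizer(ts)
        out = apply_normalizer(ts, params)
        flat = out.trials.transpose(1, 0, 2).reshape(19, -1)
        assert np.max(np.abs(flat.mean(axis=1))) <= 1e-5
        assert np.all(np.abs(flat.std(axis=1) - 1) <= 1e-3)

    def test_constant_channel_maps_to_zero(self, rng):
        trials = rng.standard_normal((4, 19, 1280)).astype(np.float32)
        trials[:, 7, :] = 5.0
        ts = TrialSet(trials, np.array(["s"] * 4), None, 256.0)
        out = apply_normalizer(ts, fit_channel_normalizer(ts))
        assert np.all(np.isfinite(out.trials))
        assert np.allclose(out.trials[:, 7, :], 0.0)

    def test_train_fitted_params_leave_shifted_test_off_center(self, rng):
        train = TrialSet(rng.standard_normal((10, 19, 1280)).astype(np.float32),
                         np.array(["a"] * 10), None, 256.0)
        test = TrialSet((rng.standard_normal((10, 19, 1280)) + 4).astype(np.float32),
                        np.array(["b"] * 10), None, 256.0)
        params = fit_channel_normalizer(train)
        out = apply_normalizer(test, params)
        assert abs(float(out.trials.mean())) > 1.0


class TestFullPipeline:
    def test_synthetic_subject_to_trials(self):
        from eegdecoder.synth import default_class_effects, small_cohort_spec, iter_cohort

        spec = small_cohort_spec(n_subjects_per_class=1, duration_s=70)
        _, rec, ann = next(iter(iter_cohort(spec)))
        cfg = PipelineConfig(apply_ica=False, trials_per_subject_cap=10)
        ts = preprocess_recording(rec, ann, cfg)
        assert 1 <= ts.n_trials <= 10
        assert ts.trials.shape[1:] == (19, 1280)
        assert set(ts.labels) == {"AD"}
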