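"""Synthetic cohort generator: determinism, class signatures, artifacts."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import mannwhitneyu, poisson

from eegdecoder.channels import POSTERIOR, STANDARD_19
from eegdecoder.io import DatasetManifest
from eegdecoder.synth import (
    ClassEffectParams,
    CohortSpec,
    default_class_effects,
    generate_cohort,
    generate_subject_recording,
    iter_cohort,
    sample_subject_params,
    small_cohort_spec,
)


def _params(class_label="CNTRL", spec=None, seed=0, **overrides):
    spec = spec or small_cohort_spec()
    sp = sample_subject_params(class_label, spec, np.random.default_rng(seed))
    for k, v in overrides.items():
        setattr(sp, k, v)
    return sp


class TestSubjectSampling:
    def test_same_substream_gives_identical_params(self):
        spec = small_cohort_spec()
        a = sample_subject_params("AD", spec, np.random.default_rng(11))
        b = sample_subject_params("AD", spec, np.random.default_rng(11))
        assert a.peak_freq_offset_hz == b.peak_freq_offset_hz
        assert a.gain_multiplier == b.gain_multiplier
        assert np.array_equal(a.channel_mixing, b.channel_mixing)

    def test_gain_multiplier_median_near_one(self):
        # LogNormal(0, 0.2) has median exactly 1
        spec = small_cohort_spec()
        rng = np.random.default_rng(5)
        draws = [sample_subject_params("AD", spec, rng).gain_multiplier
                 for _ in range(1000)]
        assert 0.9 <= np.median(draws) <= 1.1

    def test_control_class_has_no_pswc(self):
        assert default_class_effects()["CNTRL"].pswc_rate_hz == 0.0
        assert default_class_effects()["AD"].pswc_rate_hz == 0.0
        assert default_class_effects()["CJD"].pswc_rate_hz == pytest.approx(1.0)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            sample_subject_params("MCI", small_cohort_spec(), np.random.default_rng(0))


class TestRecordingSynthesis:
    def test_periodic_pswc_autocorrelation_peaks_at_period(self):
        """With a 1 Hz rate and zero jitter the rectified sharp-wave train
        must repeat every 256 samples at 256 Hz."""
        ce = default_class_effects()["CJD"]
        sp = _params("CJD", recording_duration_s=300.0, artifact_rate_per_min=0.0,
                     blink_rate_per_min=0.0)
        rec, ann = generate_subject_recording(sp, ce, pswc_jitter_frac=0.0,
                                              return_components=True)
        comp = np.abs(rec.meta["components"]["pswc"])
        comp = comp - comp.mean()
        ac = np.correlate(comp, comp, mode="full")[len(comp) - 1:]
        # strongest non-zero-lag peak within one second must sit at lag 256
        lag = np.argmax(ac[128:384]) + 128
        assert lag == 256

    def test_zero_gains_give_zero_recording(self):
        ce = ClassEffectParams(rhythm_center_hz=10.0, rhythm_bandwidth_hz=2.0,
                               rhythm_gain=0.0, slowing_gain=0.0, pswc_rate_hz=0.0,
                               pswc_amplitude=0.0, background_1f_exponent=1.0,
                               background_gain=0.0)
        sp = _params(recording_duration_s=20.0, artifact_rate_per_min=0.0,
                     blink_rate_per_min=0.0)
        rec, ann = generate_subject_recording(sp, ce)
        assert np.all(rec.data == 0.0)
        assert ann.intervals == []

    def test_artifact_count_follows_poisson_rate(self):
        """rate 2/min over 300 s -> lambda = 10 per recording; the total over
        20 independent subjects must fall in the Poisson(200) 99% interval."""
        ce = default_class_effects()["CNTRL"]
        total = 0
        for seed in range(20):
            sp = _params(seed=seed, recording_duration_s=300.0,
                         artifact_rate_per_min=2.0, blink_rate_per_min=0.0)
            sp.seed = seed
            _, ann = generate_subject_recording(sp, ce)
            total += len(ann.intervals)
        lo, hi = poisson.ppf([0.005, 0.995], 20 * 10)
        assert lo <= total <= hi

    def test_annotated_intervals_cover_injected_artifacts(self):
        ce = default_class_effects()["CNTRL"]
        sp = _params(recording_duration_s=60.0, artifact_rate_per_min=4.0,
                     blink_rate_per_min=0.0)
        rec, ann = generate_subject_recording(sp, ce)
        assert all(0 <= a < b <= 60.0 for a, b in ann.merged())


class TestCohort:
    def test_default_cohort_is_12_per_class(self):
        spec = CohortSpec()
        assert spec.n_subjects_per_class == 12
        assert len(spec.classes) == 3
        assert spec.sampling_rate_hz == 256.0

    def test_cohort_files_and_manifest(self, tmp_path):
        spec = small_cohort_spec(n_subjects_per_class=2, duration_s=20)
        manifest = generate_cohort(spec, tmp_path)
        assert len(manifest.subjects) == 6
        assert len(list(tmp_path.glob("*.edf"))) == 6
        assert len(list(tmp_path.glob("*_artifacts.json"))) == 6
        reloaded = DatasetManifest.load(tmp_path / "manifest.json")
        assert [s["subject_id"] for s in reloaded.subjects] == \
            [s["subject_id"] for s in manifest.subjects]

    def test_same_seed_is_byte_identical(self, tmp_path):
        spec = small_cohort_spec(n_subjects_per_class=1, duration_s=20)
        generate_cohort(spec, tmp_path / "a")
        generate_cohort(spec, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_adding_subjects_preserves_existing_ones(self, tmp_path):
        small = small_cohort_spec(n_subjects_per_class=1, duration_s=20)
        large = small_cohort_spec(n_subjects_per_class=2, duration_s=20)
        recs_small = {sp.subject_id: rec.data for sp, rec, _ in iter_cohort(small)}
        recs_large = {sp.subject_id: rec.data for sp, rec, _ in iter_cohort(large)}
        for sid, data in recs_small.items():
            assert np.array_equal(data, recs_large[sid])

    def test_sparse_subject_flag_leaves_17_usable_trials(self):
        from eegdecoder.preprocess import (
            PipelineConfig, epoch_runs, remove_annotated_segments,
        )

        spec = small_cohort_spec(n_subjects_per_class=1, duration_s=300,
                                 include_sparse_subject=True)
        for sp, rec, ann in iter_cohort(spec):
            if sp.class_label != "CJD":
                continue
            runs = remove_annotated_segments(rec, ann)
            ts = epoch_runs(runs, duration_s=5.0, cap_per_subject=40)
            assert ts.n_trials == 17


class TestSpectralSeparability:
    def test_theta_alpha_ratio_orders_ad_above_control(self):
        """Posterior theta/alpha band-power ratio must be stochastically
        larger for the slowed (AD-like) class than for controls
        (Mann-Whitney p < 0.01 at 12 vs 12 subjects, default seed)."""
        post_idx = [STANDARD_19.index(c) for c in POSTERIOR]
        ratios = {"AD": [], "CNTRL": []}
        for sp, rec, _ in iter_cohort(CohortSpec(duration_s=120.0)):
            if sp.class_label not in ratios:
                continue
            f, p = sps.welch(rec.data[post_idx], fs=rec.sampling_rate_hz, nperseg=1024)
            theta = p[:, (f >= 4) & (f <= 7)].mean()
            alpha = p[:, (f >= 8) & (f <= 12)].mean()
            ratios[sp.class_label].append(theta / alpha)
        assert len(ratios["AD"]) == len(ratios["CNTRL"]) == 12
        p = mannwhitneyu(ratios["AD"], ratios["CNTRL"], alternative="greater").pvalue
        assert p < 0.01

    def test_clean_signal_sufficiency_at_default_rate(self):
        """Every subject must retain enough artifact-free signal for at
        least 17 five-second trials."""
        from eegdecoder.preprocess import remove_annotated_segments

        for sp, rec, ann in iter_cohort(CohortSpec(n_subjects_per_class=2)):
            runs = remove_annotated_segments(rec, ann)
            assert runs.total_duration_s >= 85.0
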