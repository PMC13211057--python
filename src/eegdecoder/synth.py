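"""Synthetic EEG cohort generator.

Emulates the statistical structure of a three-class clinical EEG study
(Alzheimer's disease, Creutzfeldt-Jakob disease, healthy controls): 19-channel
10-20 recordings at 256 Hz with class-dependent spectral signatures, strong
inter-subject variability, ocular blink activity, and embedded acquisition
artifacts whose exact extents are emitted as clinician-style annotations.

The class signatures are canonical clinical EEG phenotypes, used here as a
documented, learnable ground truth — not a biophysical model of the diseases:

* CNTRL — dominant ~10 Hz posterior alpha rhythm over a 1/f background;
* AD    — attenuated, slowed alpha plus amplified diffuse 2-7 Hz (theta/delta)
  power ("EEG slowing");
* CJD   — superimposed quasi-periodic (~1 Hz) generalized triphasic
  sharp-wave complexes (PSWCs).

Every random draw descends deterministically from a master seed through
per-subject substreams keyed on (class, subject index), so enlarging a cohort
never perturbs previously generated subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .channels import STANDARD_19
from .io import (
    CLASSES,
    ArtifactAnnotations,
    DatasetManifest,
    RawRecording,
    write_annotations,
    write_recording,
)

# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassEffectParams:
    """Population-level signal parameters for one diagnostic class.

    Gains are standard deviations in microvolts of the respective source
    before spatial mixing; ``pswc_rate_hz`` is the mean repetition rate of
    periodic sharp-wave complexes (0 disables them).
    """

    rhythm_center_hz: float
    rhythm_bandwidth_hz: float
    rhythm_gain: float
    slowing_gain: float
    pswc_rate_hz: float
    pswc_amplitude: float
    background_1f_exponent: float
    background_gain: float

    def __post_init__(self) -> None:
        for name in ("rhythm_gain", "slowing_gain", "pswc_amplitude", "background_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pswc_rate_hz != 0 and not (0.5 <= self.pswc_rate_hz <= 2.0):
            raise ValueError("pswc_rate_hz must be 0 or within [0.5, 2] Hz")
        if not (1.6 < self.rhythm_center_hz < 40.0):
            raise ValueError("rhythm_center_hz must survive the 1.6-40 Hz band-pass")


def default_class_effects() -> dict[str, ClassEffectParams]:
    """Default class signatures (amplitudes in uV, scalp-realistic)."""
    return {
        "CNTRL": ClassEffectParams(
            rhythm_center_hz=10.0, rhythm_bandwidth_hz=2.0, rhythm_gain=14.0,
            slowing_gain=2.0, pswc_rate_hz=0.0, pswc_amplitude=0.0,
            background_1f_exponent=1.0, background_gain=7.0,
        ),
        "AD": ClassEffectParams(
            rhythm_center_hz=8.5, rhythm_bandwidth_hz=2.0, rhythm_gain=4.0,
            slowing_gain=14.0, pswc_rate_hz=0.0, pswc_amplitude=0.0,
            background_1f_exponent=1.2, background_gain=7.0,
        ),
        "CJD": ClassEffectParams(
            rhythm_center_hz=9.0, rhythm_bandwidth_hz=2.0, rhythm_gain=5.0,
            slowing_gain=7.0, pswc_rate_hz=1.0, pswc_amplitude=45.0,
            background_1f_exponent=1.1, background_gain=7.0,
        ),
    }


def strong_effect_class_effects() -> dict[str, ClassEffectParams]:
    """Strong-effect setting: class contrasts at the unambiguous end of the
    clinical spectrum (florid presentations), used by recovery sanity runs.

    Controls show a prominent posterior alpha; the AD-like class shows
    marked diffuse slowing with severely attenuated alpha; the CJD-like
    class shows high-amplitude periodic sharp-wave complexes (textbook
    PSWCs commonly exceed 100 uV). Subject-level variability distributions
    are identical to the default setting.
    """
    return {
        "CNTRL": ClassEffectParams(
            rhythm_center_hz=10.0, rhythm_bandwidth_hz=2.0, rhythm_gain=16.0,
            slowing_gain=2.0, pswc_rate_hz=0.0, pswc_amplitude=0.0,
            background_1f_exponent=1.0, background_gain=7.0,
        ),
        "AD": ClassEffectParams(
            rhythm_center_hz=8.5, rhythm_bandwidth_hz=2.0, rhythm_gain=3.0,
            slowing_gain=22.0, pswc_rate_hz=0.0, pswc_amplitude=0.0,
            background_1f_exponent=1.2, background_gain=7.0,
        ),
        # CJD keeps *low* continuous slow activity so the periodic complexes
        # (not total slow-band power, which they also carry) are its marker
        "CJD": ClassEffectParams(
            rhythm_center_hz=9.0, rhythm_bandwidth_hz=2.0, rhythm_gain=4.0,
            slowing_gain=3.0, pswc_rate_hz=1.0, pswc_amplitude=80.0,
            background_1f_exponent=1.1, background_gain=7.0,
        ),
    }


@dataclass
class SubjectParams:
    """Subject-level draw: jittered spectral peak, overall gain, topographies."""

    subject_id: str
    class_label: str
    peak_freq_offset_hz: float
    gain_multiplier: float
    channel_mixing: np.ndarray  # C x S, sources = (rhythm, slowing, pswc, ocular)
    recording_duration_s: float
    artifact_rate_per_min: float
    blink_rate_per_min: float
    sampling_rate_hz: float
    seed: int

    def __post_init__(self) -> None:
        if self.gain_multiplier <= 0:
            raise ValueError("gain_multiplier must be positive")
        if self.recording_duration_s < 5:
            raise ValueError("recording must allow at least one 5-s trial")
        self.channel_mixing = np.asarray(self.channel_mixing, dtype=float)
        if not np.all(np.isfinite(self.channel_mixing)):
            raise ValueError("channel_mixing must be finite")


@dataclass
class CohortSpec:
    """Study design: balanced three-class cohort, 12 subjects per class,
    5-minute 256 Hz recordings, about one annotated artifact per minute."""

    n_subjects_per_class: int = 12
    classes: tuple[str, ...] = CLASSES
    sampling_rate_hz: float = 256.0
    duration_s: float = 300.0
    artifact_rate_per_min: float = 1.0
    blink_rate_per_min: float = 8.0
    class_effects: dict[str, ClassEffectParams] = field(default_factory=default_class_effects)
    master_seed: int = 2025
    include_sparse_subject: bool = False  # one CJD subject left with ~17 usable trials

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ValueError("need at least one subject per class")
        for c in self.classes:
            if c not in self.class_effects:
                raise ValueError(f"no class effects defined for {c!r}")


# ---------------------------------------------------------------------------
# spectral building blocks
# ---------------------------------------------------------------------------

def _shaped_noise(rng: np.random.Generator, n: int, fs: float, shape_fn) -> np.ndarray:
    """Unit-variance Gaussian noise whose amplitude spectrum is shape_fn(f)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    gain = shape_fn(f)
    gain[0] = 0.0
    shaped = np.fft.irfft(spec * gain, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def one_over_f_noise(rng, n, fs, exponent):
    return _shaped_noise(rng, n, fs, lambda f: np.where(f > 0, np.maximum(f, 0.1) ** (-exponent / 2.0), 0.0))


def narrowband_rhythm(rng, n, fs, center_hz, bandwidth_hz):
    """Amplitude-modulated narrowband oscillation (Gaussian spectral bump)."""
    sigma = max(bandwidth_hz / 2.355, 1e-3)  # FWHM -> sigma
    return _shaped_noise(rng, n, fs, lambda f: np.exp(-0.5 * ((f - center_hz) / sigma) ** 2))


def band_noise(rng, n, fs, lo, hi):
    return _shaped_noise(rng, n, fs, lambda f: ((f >= lo) & (f <= hi)).astype(float))


def pswc_template(fs: float) -> np.ndarray:
    """Triphasic sharp-wave complex, ~0.35 s, unit peak amplitude."""
    t = np.arange(-0.175, 0.175, 1.0 / fs)
    lobe = lambda mu, sigma: np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    w = -0.5 * lobe(-0.07, 0.025) + 1.0 * lobe(0.0, 0.03) - 0.35 * lobe(0.09, 0.045)
    return w / np.max(np.abs(w))


def pswc_train(rng, n, fs, rate_hz, jitter_frac=0.1):
    """Quasi-periodic train of triphasic complexes; unit peak amplitude."""
    out = np.zeros(n)
    if rate_hz <= 0:
        return out
    period = 1.0 / rate_hz
    tmpl = pswc_template(fs)
    half = len(tmpl) // 2
    t = period * rng.uniform(0.5, 1.0)
    while t * fs < n:
        c = int(round(t * fs))
        lo, hi = c - half, c - half + len(tmpl)
        s_lo, s_hi = max(lo, 0), min(hi, n)
        out[s_lo:s_hi] += tmpl[s_lo - lo : len(tmpl) - (hi - s_hi)]
        t += period * (1.0 + jitter_frac * rng.uniform(-1.0, 1.0))
    return out


def blink_train(rng, n, fs, rate_per_min):
    """Smooth ocular deflections (0.5-2 s raised-cosine bumps), unit amplitude."""
    out = np.zeros(n)
    lam = rate_per_min * (n / fs) / 60.0
    for _ in range(rng.poisson(lam)):
        dur = rng.uniform(0.5, 2.0)
        onset = rng.uniform(0, max(n / fs - dur, 0))
        i0 = int(onset * fs)
        m = int(dur * fs)
        if m > 1 and i0 + m <= n:
            out[i0 : i0 + m] += 0.5 * (1 - np.cos(2 * np.pi * np.arange(m) / m))
    return out


# ---------------------------------------------------------------------------
# topographies
# ---------------------------------------------------------------------------

_REGION = {
    "frontal_pole": ("FP1", "FP2"),
    "frontal": ("F7", "F3", "FZ", "F4", "F8"),
    "central_temporal": ("T3", "C3", "C4", "T4"),
    "parietal": ("T5", "P3", "PZ", "P4", "T6"),
    "occipital": ("O1", "OZ", "O2"),
}


def _topo(weights_by_region: dict[str, float], channels=STANDARD_19) -> np.ndarray:
    w = np.zeros(len(channels))
    for region, value in weights_by_region.items():
        for ch in _REGION[region]:
            if ch in channels:
                w[list(channels).index(ch)] = value
    return w


def base_mixing(channels=STANDARD_19) -> np.ndarray:
    """C x 4 spatial mixing for (rhythm, slowing, pswc, ocular) sources."""
    rhythm = _topo({"frontal_pole": 0.1, "frontal": 0.2, "central_temporal": 0.4,
                    "parietal": 0.8, "occipital": 1.0}, channels)
    slowing = _topo({"frontal_pole": 0.8, "frontal": 0.9, "central_temporal": 0.8,
                     "parietal": 0.6, "occipital": 0.5}, channels)
    pswc = _topo({"frontal_pole": 0.9, "frontal": 1.0, "central_temporal": 0.9,
                  "parietal": 0.8, "occipital": 0.7}, channels)
    ocular = _topo({"frontal_pole": 1.0, "frontal": 0.35, "central_temporal": 0.08,
                    "parietal": 0.02, "occipital": 0.01}, channels)
    return np.stack([rhythm, slowing, pswc, ocular], axis=1)


# ---------------------------------------------------------------------------
# hierarchical sampling
# ---------------------------------------------------------------------------

def _subject_rng(master_seed: int, class_label: str, index: int) -> np.random.Generator:
    # counter-based substream: keyed on (master seed, class, subject index)
    return np.random.default_rng([master_seed, CLASSES.index(class_label), index])


def sample_subject_params(
    class_label: str,
    spec: CohortSpec,
    rng: np.random.Generator,
    subject_id: str | None = None,
) -> SubjectParams:
    """Draw subject-level parameters from the cohort's hierarchical model.

    ``peak_freq_offset ~ Normal(0, 0.5 Hz)``, ``gain_multiplier ~
    LogNormal(0, 0.2)`` (median 1), topographies perturbed by Normal(0, 0.05).
    """
    if class_label not in spec.classes:
        raise ValueError(f"unknown class {class_label!r}")
    mixing = base_mixing() + rng.normal(0.0, 0.05, size=(len(STANDARD_19), 4))
    mixing = np.clip(mixing, 0.0, None)
    return SubjectParams(
        subject_id=subject_id or f"{class_label}-anon",
        class_label=class_label,
        peak_freq_offset_hz=float(rng.normal(0.0, 0.5)),
        gain_multiplier=float(np.exp(rng.normal(0.0, 0.2))),
        channel_mixing=mixing,
        recording_duration_s=spec.duration_s,
        artifact_rate_per_min=spec.artifact_rate_per_min,
        blink_rate_per_min=spec.blink_rate_per_min,
        sampling_rate_hz=spec.sampling_rate_hz,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# recording synthesis
# ---------------------------------------------------------------------------

def generate_subject_recording(
    sp: SubjectParams,
    ce: ClassEffectParams,
    pswc_jitter_frac: float = 0.1,
    return_components: bool = False,
    forced_artifact_intervals: list[tuple[float, float]] | None = None,
) -> tuple[RawRecording, ArtifactAnnotations]:
    """Render one subject's continuous recording plus its artifact annotations.

    The signal is a per-channel 1/f^beta background plus four spatially mixed
    sources (class rhythm, diffuse slowing, PSWC train, ocular blinks), with
    injected acquisition artifacts — alternating electrode-pop steps and
    high-amplitude movement bursts — whose exact extents become the returned
    annotations. All channels are in microvolts.
    """
    fs = sp.sampling_rate_hz
    n = int(round(sp.recording_duration_s * fs))
    rng = np.random.default_rng(sp.seed)
    C = sp.channel_mixing.shape[0]
    g = sp.gain_multiplier

    background = np.zeros((C, n))
    if ce.background_gain > 0:
        for c in range(C):
            background[c] = one_over_f_noise(rng, n, fs, ce.background_1f_exponent)
        background *= ce.background_gain * g

    center = ce.rhythm_center_hz + sp.peak_freq_offset_hz
    center = float(np.clip(center, 2.0, 39.0))
    sources = np.zeros((4, n))
    if ce.rhythm_gain > 0:
        sources[0] = narrowband_rhythm(rng, n, fs, center, ce.rhythm_bandwidth_hz) * ce.rhythm_gain * g
    if ce.slowing_gain > 0:
        sources[1] = band_noise(rng, n, fs, 2.0, 7.0) * ce.slowing_gain * g
    if ce.pswc_rate_hz > 0 and ce.pswc_amplitude > 0:
        sources[2] = pswc_train(rng, n, fs, ce.pswc_rate_hz, pswc_jitter_frac) * ce.pswc_amplitude * g
    if sp.blink_rate_per_min > 0:
        sources[3] = blink_train(rng, n, fs, sp.blink_rate_per_min) * 120.0

    data = background + sp.channel_mixing @ sources

    # acquisition artifacts with exact annotated extents
    if forced_artifact_intervals is not None:
        intervals = [tuple(map(float, iv)) for iv in forced_artifact_intervals]
    else:
        lam = sp.artifact_rate_per_min * sp.recording_duration_s / 60.0
        intervals = []
        for _ in range(rng.poisson(lam)):
            dur = rng.uniform(1.0, 4.0)
            onset = rng.uniform(0.0, max(sp.recording_duration_s - dur, 0.0))
            intervals.append((onset, onset + dur))
        intervals.sort()
    for k, (a, b) in enumerate(intervals):
        i0, i1 = int(a * fs), min(int(b * fs), n)
        if i1 <= i0:
            continue
        if k % 2 == 0:  # electrode-pop step on a few channels
            chans = rng.choice(C, size=rng.integers(1, 4), replace=False)
            data[chans, i0:i1] += rng.choice([-1.0, 1.0]) * rng.uniform(400.0, 900.0)
        else:  # movement burst across the scalp
            w = rng.uniform(0.3, 1.0, size=(C, 1))
            data[:, i0:i1] += w * rng.standard_normal((C, i1 - i0)) * 300.0

    data = np.clip(data, -3200.0, 3200.0)  # keep within EDF physical range

    ann = ArtifactAnnotations(intervals).clipped(sp.recording_duration_s)
    meta: dict = {}
    merged = ann.merged()
    clean_s = sp.recording_duration_s - sum(b - a for a, b in merged)
    if clean_s < 5.0:
        meta["insufficient_clean_signal"] = True
    if return_components:
        meta["components"] = {
            "background": background,
            "rhythm": sources[0],
            "slowing": sources[1],
            "pswc": sources[2],
            "ocular": sources[3],
        }
    rec = RawRecording(
        subject_id=sp.subject_id,
        sampling_rate_hz=fs,
        channel_names=list(STANDARD_19),
        data=data,
        class_label=sp.class_label,
        meta=meta,
    )
    return rec, ann


#: crafted clean runs (30 + 30 + 27 s) leaving exactly 17 five-second trials
_SPARSE_CLEAN_RUNS = [(5.0, 35.0), (100.0, 130.0), (200.0, 227.0)]


def _sparse_intervals(duration_s: float) -> list[tuple[float, float]]:
    edges = [0.0]
    for a, b in _SPARSE_CLEAN_RUNS:
        edges += [a, b]
    edges.append(duration_s)
    return [(edges[i], edges[i + 1]) for i in range(0, len(edges), 2) if edges[i] < edges[i + 1]]


def iter_cohort(spec: CohortSpec):
    """Yield ``(SubjectParams, RawRecording, ArtifactAnnotations)`` for every
    subject of the cohort, deterministically from the master seed."""
    for class_label in spec.classes:
        ce = spec.class_effects[class_label]
        for i in range(spec.n_subjects_per_class):
            rng = _subject_rng(spec.master_seed, class_label, i)
            sp = sample_subject_params(
                class_label, spec, rng, subject_id=f"S{class_label}{i:02d}"
            )
            forced = None
            if spec.include_sparse_subject and class_label == "CJD" and i == 0:
                forced = _sparse_intervals(spec.duration_s)
            rec, ann = generate_subject_recording(sp, ce, forced_artifact_intervals=forced)
            yield sp, rec, ann


def generate_cohort(spec: CohortSpec, out_dir) -> DatasetManifest:
    """Write one EDF + one JSON annotation sidecar per subject and a manifest.

    The whole cohort is a pure function of (spec, master_seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sp, rec, ann in iter_cohort(spec):
        rec_path = out_dir / f"{sp.subject_id}.edf"
        ann_path = out_dir / f"{sp.subject_id}_artifacts.json"
        write_recording(rec, rec_path)
        write_annotations(ann, ann_path)
        entries.append(
            {
                "subject_id": sp.subject_id,
                "label": sp.class_label,
                "recording_path": rec_path.name,
                "annotation_path": ann_path.name,
                "n_trials": None,  # filled after preprocessing
            }
        )
    manifest = DatasetManifest(
        subjects=entries,
        sampling_rate_hz=spec.sampling_rate_hz,
        channel_names=list(STANDARD_19),
        seed=spec.master_seed,
    )
    manifest.save(out_dir / "manifest.json")
    return manifest


def small_cohort_spec(
    n_subjects_per_class: int = 2,
    duration_s: float = 70.0,
    master_seed: int = 2025,
    **kwargs,
) -> CohortSpec:
    """Convenience reduced-size cohort for quick experiments and tests."""
    return CohortSpec(
        n_subjects_per_class=n_subjects_per_class,
        duration_s=duration_s,
        master_seed=master_seed,
        **kwargs,
    )
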