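"""Containers and file formats for the EEG classification pipeline.

Continuous recordings travel as EDF (the de-facto clinical interchange
format), artifact intervals as JSON sidecars, and epoched trial tensors as a
raw little-endian float32 binary plus a JSON manifest. Class labels live in
manifests only, never inside EDF headers, mirroring the anonymized
organization of the clinical source data.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .channels import STANDARD_19, match_channels, normalize_channel_name

CLASSES: tuple[str, ...] = ("AD", "CJD", "CNTRL")

#: EDF physical range in microvolts; with a +/-32767 digital range this gives
#: exactly 0.1 uV resolution, negligible against scalp EEG amplitudes.
EDF_PHYS_MAX_UV = 3276.7
EDF_DIG_MAX = 32767


class EEGDecoderError(Exception):
    """Base class for package errors."""


class ChannelMismatchError(EEGDecoderError):
    """A requested channel is absent or ambiguous in a recording."""


class FormatError(EEGDecoderError):
    """A file could not be parsed in the expected format."""


class IntegrityError(EEGDecoderError):
    """On-disk manifest and binary payload disagree."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """One subject's continuous multichannel EEG in microvolts.

    ``data`` has shape (channels, samples); ``class_label`` is ``None`` in
    inference mode (labels are carried by manifests, not recordings).
    """

    subject_id: str
    sampling_rate_hz: float
    channel_names: list[str]
    data: np.ndarray
    class_label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (C, T), got shape {self.data.shape}")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.class_label is not None and self.class_label not in CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class ArtifactAnnotations:
    """Clinician-style list of corrupted intervals, seconds from start."""

    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for onset, offset in self.intervals:
            onset, offset = float(onset), float(offset)
            if not (onset < offset):
                raise ValueError(f"interval onset {onset} must precede offset {offset}")
            if onset < 0:
                raise ValueError(f"negative interval onset {onset}")
            cleaned.append((onset, offset))
        self.intervals = sorted(cleaned)

    def merged(self) -> list[tuple[float, float]]:
        """Union of intervals: overlapping or touching intervals coalesce."""
        out: list[tuple[float, float]] = []
        for onset, offset in self.intervals:
            if out and onset <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], offset))
            else:
                out.append((onset, offset))
        return out

    def clipped(self, duration_s: float) -> "ArtifactAnnotations":
        """Clip intervals to [0, duration]; drops intervals fully outside."""
        kept = [
            (max(0.0, a), min(duration_s, b))
            for a, b in self.intervals
            if a < duration_s and b > 0
        ]
        return ArtifactAnnotations([(a, b) for a, b in kept if a < b])


@dataclass
class TrialSet:
    """N fixed-length epochs with per-trial subject ids and class labels.

    ``trials`` is float32 with shape (N, C, T); all trials of one subject
    share a single label.
    """

    trials: np.ndarray
    subject_ids: np.ndarray
    labels: np.ndarray | None
    sampling_rate_hz: float
    channel_names: list[str] = field(default_factory=lambda: list(STANDARD_19))

    def __post_init__(self) -> None:
        self.trials = np.ascontiguousarray(self.trials, dtype=np.float32)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.trials.ndim != 3:
            raise ValueError(f"trials must be 3-D (N, C, T), got {self.trials.shape}")
        n = self.trials.shape[0]
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length must match trial count")
        if self.trials.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length must match trial count")
            for sid in np.unique(self.subject_ids):
                subj_labels = np.unique(self.labels[self.subject_ids == sid])
                if len(subj_labels) > 1:
                    raise ValueError(
                        f"subject {sid!r} carries conflicting labels {subj_labels.tolist()}"
                    )

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    def subjects(self) -> list[str]:
        """Unique subject ids in first-appearance order."""
        seen: dict[str, None] = {}
        for sid in self.subject_ids:
            seen.setdefault(str(sid), None)
        return list(seen)

    def subject_label(self, subject_id: str) -> str:
        mask = self.subject_ids == subject_id
        if self.labels is None or not mask.any():
            raise KeyError(subject_id)
        return str(self.labels[mask][0])

    def select_subjects(self, subject_ids) -> "TrialSet":
        wanted = set(map(str, subject_ids))
        mask = np.array([str(s) in wanted for s in self.subject_ids])
        return TrialSet(
            self.trials[mask],
            self.subject_ids[mask],
            None if self.labels is None else self.labels[mask],
            self.sampling_rate_hz,
            list(self.channel_names),
        )

    def trial_counts(self) -> dict[str, int]:
        return {s: int(np.sum(self.subject_ids == s)) for s in self.subjects()}


def concatenate_trialsets(parts: list[TrialSet]) -> TrialSet:
    if not parts:
        raise ValueError("nothing to concatenate")
    fs = parts[0].sampling_rate_hz
    chans = parts[0].channel_names
    for p in parts[1:]:
        if p.sampling_rate_hz != fs or p.channel_names != chans:
            raise ValueError("trial sets disagree on rate or montage")
    labels = None
    if all(p.labels is not None for p in parts):
        labels = np.concatenate([p.labels for p in parts])
    return TrialSet(
        np.concatenate([p.trials for p in parts]),
        np.concatenate([p.subject_ids for p in parts]),
        labels,
        fs,
        list(chans),
    )


@dataclass
class DatasetManifest:
    """Index of a cohort on disk: one entry per subject plus global fields."""

    subjects: list[dict]
    sampling_rate_hz: float
    channel_names: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [s["subject_id"] for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids in manifest")

    def save(self, path) -> None:
        payload = {
            "sampling_rate_hz": self.sampling_rate_hz,
            "channel_names": list(self.channel_names),
            "seed": self.seed,
            "subjects": self.subjects,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            subjects=payload["subjects"],
            sampling_rate_hz=payload["sampling_rate_hz"],
            channel_names=payload["channel_names"],
            seed=payload.get("seed"),
        )


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_recording(rec: RawRecording, path) -> None:
    """Write a recording as plain EDF (16-bit, 1-second data records).

    The physical range is fixed at +/-3276.7 uV so the quantization step is
    0.1 uV. The sampling rate must be a whole number of samples per second
    and the recording a whole number of seconds (pad or trim upstream).
    Labels are never written into the header.
    """
    fs = rec.sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    if rec.n_samples % fs != 0:
        raise ValueError(
            f"recording length {rec.n_samples} is not a whole number of "
            f"1-s records at {fs} Hz"
        )
    n_records = rec.n_samples // fs
    ns = rec.n_channels
    if np.max(np.abs(rec.data)) > EDF_PHYS_MAX_UV:
        raise ValueError(
            f"amplitude exceeds the EDF physical range +/-{EDF_PHYS_MAX_UV} uV"
        )

    start = datetime.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join(
        [
            _edf_field(0, 8),
            _edf_field(f"{rec.subject_id} X X X", 80),
            _edf_field("Startdate 01-JAN-2000 X X X", 80),
            _edf_field(start.strftime("%d.%m.%y"), 8),
            _edf_field(start.strftime("%H.%M.%S"), 8),
            _edf_field(256 * (ns + 1), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),
            _edf_field(ns, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_edf_field(c, 16) for c in rec.channel_names),
            b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(ns)),
            b"".join(_edf_field("uV", 8) for _ in range(ns)),
            b"".join(_edf_field(f"-{EDF_PHYS_MAX_UV}", 8) for _ in range(ns)),
            b"".join(_edf_field(f"{EDF_PHYS_MAX_UV}", 8) for _ in range(ns)),
            b"".join(_edf_field(-EDF_DIG_MAX, 8) for _ in range(ns)),
            b"".join(_edf_field(EDF_DIG_MAX, 8) for _ in range(ns)),
            b"".join(_edf_field("", 80) for _ in range(ns)),
            b"".join(_edf_field(fs, 8) for _ in range(ns)),
            b"".join(_edf_field("", 32) for _ in range(ns)),
        ]
    )
    # digital = physical / 0.1 uV, rounded to nearest integer
    scale = EDF_PHYS_MAX_UV / EDF_DIG_MAX
    digital = np.rint(rec.data / scale).astype("<i2")
    # record-major layout: per record, contiguous block per channel
    blocks = digital.reshape(ns, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        fh.write(np.ascontiguousarray(blocks).tobytes())


def read_recording(path, expected_channels: list[str] | None = None) -> RawRecording:
    """Read an EDF recording, normalizing channel order to ``expected_channels``.

    Returns data in microvolts at the file's native rate. Channel matching is
    case-insensitive and ignores reference suffixes.
    """
    import mne

    expected = list(expected_channels) if expected_channels else list(STANDARD_19)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"could not parse {path} as EDF: {exc}") from exc
    idx = match_channels(list(raw.ch_names), expected)
    data_uv = raw.get_data()[idx] * 1e6
    return RawRecording(
        subject_id=path.stem,
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_names=[normalize_channel_name(c) for c in expected],
        data=data_uv,
    )


# ---------------------------------------------------------------------------
# annotation sidecars
# ---------------------------------------------------------------------------

def read_annotations(path) -> ArtifactAnnotations:
    """Read a JSON sidecar: a list of ``{"onset_s", "offset_s"}`` objects."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"annotation sidecar {path} is not valid JSON") from exc
    if not isinstance(payload, list):
        raise FormatError("annotation sidecar must be a JSON array")
    intervals = []
    for item in payload:
        try:
            intervals.append((float(item["onset_s"]), float(item["offset_s"])))
        except (KeyError, TypeError) as exc:
            raise FormatError(f"malformed annotation entry {item!r}") from exc
    return ArtifactAnnotations(intervals)


def write_annotations(ann: ArtifactAnnotations, path) -> None:
    payload = [{"onset_s": a, "offset_s": b} for a, b in ann.intervals]
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# trial container: raw little-endian float32 + JSON manifest
# ---------------------------------------------------------------------------

def save_trialset(ts: TrialSet, directory) -> None:
    """Write ``trials.bin`` (little-endian IEEE-754 float32, C-order N x C x T)
    plus ``trialset.json`` describing shapes, subjects and labels."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arr = np.ascontiguousarray(ts.trials, dtype="<f4")
    (directory / "trials.bin").write_bytes(arr.tobytes())
    manifest = {
        "shape": list(arr.shape),
        "dtype": "<f4",
        "order": "C",
        "sampling_rate_hz": ts.sampling_rate_hz,
        "channel_names": list(ts.channel_names),
        "subject_ids": [str(s) for s in ts.subject_ids],
        "labels": None if ts.labels is None else [str(l) for l in ts.labels],
    }
    (directory / "trialset.json").write_text(json.dumps(manifest, indent=2))


def load_trialset(directory) -> TrialSet:
    directory = Path(directory)
    manifest = json.loads((directory / "trialset.json").read_text())
    shape = tuple(manifest["shape"])
    raw = (directory / "trials.bin").read_bytes()
    expected_bytes = int(np.prod(shape)) * 4
    if len(raw) != expected_bytes:
        raise IntegrityError(
            f"trials.bin holds {len(raw)} bytes but manifest shape {shape} "
            f"implies {expected_bytes}"
        )
    trials = np.frombuffer(raw, dtype="<f4").reshape(shape)
    labels = manifest["labels"]
    return TrialSet(
        trials=trials.copy(),
        subject_ids=np.array(manifest["subject_ids"]),
        labels=None if labels is None else np.array(labels),
        sampling_rate_hz=manifest["sampling_rate_hz"],
        channel_names=list(manifest["channel_names"]),
    )
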