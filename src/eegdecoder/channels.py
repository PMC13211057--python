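"""Scalp montage conventions for the 19-channel 10-20 clinical setup.

The recordings this package targets use 19 data electrodes of the 10-20
international system with Cz as the reference electrode; Cz therefore never
appears as a data channel. The canonical order below runs anterior to
posterior, left to right, ending at O2.
"""

from __future__ import annotations

# 21 classic 10-20 positions minus the Cz reference and minus Fpz,
# leaving 19 data channels (Oz retained).
STANDARD_19: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "FZ", "F4", "F8",
    "T3", "C3", "C4", "T4",
    "T5", "P3", "PZ", "P4", "T6",
    "O1", "OZ", "O2",
)

FRONTAL_PROXIES: tuple[str, ...] = ("FP1", "FP2")

#: channels used when averaging posterior power (alpha-band diagnostics)
POSTERIOR: tuple[str, ...] = ("P3", "PZ", "P4", "O1", "OZ", "O2")


def normalize_channel_name(name: str) -> str:
    """Canonicalize a clinical channel label.

    Matching is case-insensitive and ignores reference suffixes, so
    ``"Fp1-Cz"``, ``"fp1"`` and ``"FP1 "`` all map to ``"FP1"``. ``"EEG Fp1"``
    style prefixes are stripped as well.
    """
    s = name.strip().upper()
    if s.startswith("EEG "):
        s = s[4:]
    s = s.split("-")[0].strip()
    return s


def match_channels(available: list[str], expected: list[str]) -> list[int]:
    """Map ``expected`` labels onto indices into ``available``.

    Raises ``ChannelMismatchError`` naming the offending labels when a
    requested channel is missing or ambiguous.
    """
    from .io import ChannelMismatchError

    norm_avail = [normalize_channel_name(c) for c in available]
    indices: list[int] = []
    missing: list[str] = []
    for ch in expected:
        target = normalize_channel_name(ch)
        hits = [i for i, c in enumerate(norm_avail) if c == target]
        if len(hits) != 1:
            missing.append(ch)
        else:
            indices.append(hits[0])
    if missing:
        raise ChannelMismatchError(
            f"channels missing or ambiguous in recording: {missing}; "
            f"available: {sorted(set(norm_avail))}"
        )
    return indices
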