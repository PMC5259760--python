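"""Reading recordings and cutting them into discrete vocalization segments.

A recording's intensity contour is the rectified waveform low-pass filtered
at a few Hz; runs of intensity above a fraction of the file maximum, padded
by a fixed margin and merged when the margins touch another supra-threshold
run, delimit individual vocalizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfiltfilt

from callometry.errors import (
    ConsistencyError,
    DegenerateInputError,
    FormatError,
)

__all__ = [
    "AudioClip",
    "IntensityEnvelope",
    "SegmentationParams",
    "Segment",
    "read_audio",
    "write_audio",
    "intensity_envelope",
    "segment",
    "extract",
    "segment_snr_db",
    "snr_filter",
]


@dataclass(frozen=True)
class AudioClip:
    """Mono audio: normalized samples in [-1, 1] at a fixed rate in Hz."""

    samples: np.ndarray
    rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise DegenerateInputError(
                f"clip {self.source_id!r} must hold at least one sample"
            )
        if not np.all(np.isfinite(samples)):
            raise DegenerateInputError(
                f"clip {self.source_id!r} contains non-finite samples"
            )
        if self.rate <= 0:
            raise DegenerateInputError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass(frozen=True)
class IntensityEnvelope:
    """Non-negative intensity contour at the source clip's rate."""

    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if np.any(values < 0):
            raise DegenerateInputError("envelope values must be >= 0")


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the envelope threshold segmenter.

    cutoff_hz / filter_order define the Butterworth low-pass applied to the
    rectified waveform; threshold_frac is the fraction of the file's maximum
    intensity a sample must exceed to count as part of a vocalization;
    margin_ms pads each supra-threshold run on both sides; runs shorter than
    min_duration_ms after merging are dropped as click artifacts.
    """

    cutoff_hz: float = 5.0
    filter_order: int = 3
    threshold_frac: float = 0.05
    margin_ms: float = 100.0
    min_duration_ms: float = 50.0
    snr_cutoff_db: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.threshold_frac < 1:
            raise DegenerateInputError("threshold_frac must lie in (0, 1)")
        if self.margin_ms < 0:
            raise DegenerateInputError("margin_ms must be >= 0")


@dataclass(frozen=True, order=True)
class Segment:
    """Half-open sample interval [start, end) of one vocalization."""

    start: int
    end: int
    source_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ConsistencyError(
                f"invalid segment [{self.start}, {self.end})"
            )

    def duration_s(self, rate: float) -> float:
        return (self.end - self.start) / rate


def read_audio(path) -> AudioClip:
    """Read a PCM WAV file as a normalized mono clip.

    Stereo channels are averaged; integer PCM is scaled by the type's
    full-scale value so amplitudes land in [-1, 1].
    """
    try:
        rate, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.dtype.kind == "i":
        scale = float(np.iinfo(data.dtype).max) + 1.0
        samples = data.astype(float) / scale
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned
        info = np.iinfo(data.dtype)
        half = (info.max + 1) / 2.0
        samples = (data.astype(float) - half) / half
    elif data.dtype.kind == "f":
        samples = data.astype(float)
    else:
        raise FormatError(f"unsupported sample encoding in {path}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    import os

    return AudioClip(samples, float(rate), os.path.basename(str(path)))


def write_audio(path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV."""
    scaled = np.clip(clip.samples, -1.0, 1.0) * 32767.0
    wavfile.write(path, int(round(clip.rate)), scaled.astype(np.int16))


def intensity_envelope(
    clip: AudioClip, params: SegmentationParams | None = None
) -> IntensityEnvelope:
    """Rectify then zero-phase Butterworth low-pass the waveform.

    Zero-phase (forward-backward) filtering keeps segment boundaries
    symmetric: a causal filter would drag every onset late by the group
    delay.  Negative filter ringing is clipped at zero so the contour stays
    a valid intensity.
    """
    params = params or SegmentationParams()
    nyquist = clip.rate / 2.0
    if params.cutoff_hz >= nyquist:
        raise DegenerateInputError("cutoff must be below the Nyquist rate")
    sos = butter(
        params.filter_order, params.cutoff_hz, btype="low", fs=clip.rate,
        output="sos",
    )
    # sosfiltfilt needs > 3 * (2*order + 1) samples of padding headroom
    min_len = 6 * (2 * params.filter_order + 1) + 1
    if len(clip.samples) < min_len:
        raise DegenerateInputError(
            f"clip {clip.source_id!r} too short to filter "
            f"({len(clip.samples)} < {min_len} samples)"
        )
    filtered = sosfiltfilt(sos, np.abs(clip.samples))
    return IntensityEnvelope(np.maximum(filtered, 0.0), clip.rate)


def _supra_runs(values: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal half-open runs where values strictly exceed threshold."""
    idx = np.flatnonzero(values > threshold)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(run_starts.tolist(), run_ends.tolist()))


def segment(
    envelope: IntensityEnvelope, params: SegmentationParams | None = None,
    source_id: str = "",
) -> list[Segment]:
    """Cut an intensity envelope into padded, merged vocalization segments.

    The threshold is relative (a fraction of the file's maximum intensity),
    so segmentation is invariant to global gain.  Each supra-threshold run
    gets a margin on both sides; margins that reach into another run (or
    another margin) merge the runs into one segment.  An all-zero envelope
    yields no segments.
    """
    params = params or SegmentationParams()
    values = envelope.values
    if values.size == 0:
        raise DegenerateInputError("empty envelope")
    peak = float(values.max())
    if peak <= 0:
        return []
    threshold = params.threshold_frac * peak
    runs = _supra_runs(values, threshold)
    if not runs:
        return []
    margin = int(round(params.margin_ms / 1000.0 * envelope.rate))
    n = len(values)
    padded = [
        (max(0, s - margin), min(n, e + margin)) for s, e in runs
    ]
    merged: list[list[int]] = [list(padded[0])]
    for s, e in padded[1:]:
        if s <= merged[-1][1]:  # touching or overlapping after padding
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    min_len = params.min_duration_ms / 1000.0 * envelope.rate
    return [
        Segment(s, e, source_id)
        for s, e in merged
        if (e - s) >= min_len
    ]


def extract(clip: AudioClip, segments: list[Segment]) -> list[AudioClip]:
    """Slice one sub-clip per segment; source_id gains the segment index."""
    out = []
    for i, seg in enumerate(segments):
        if seg.end > len(clip.samples):
            raise ConsistencyError(
                f"segment [{seg.start}, {seg.end}) exceeds clip of "
                f"{len(clip.samples)} samples"
            )
        out.append(
            AudioClip(
                clip.samples[seg.start:seg.end].copy(),
                clip.rate,
                f"{clip.source_id}#{i}",
            )
        )
    return out


def segment_snr_db(clip: AudioClip, segments: list[Segment]) -> list[float]:
    """Per-segment SNR: segment RMS against the RMS of inter-segment audio.

    Stands in for manual signal-to-noise triage: the audio outside all
    segments estimates the background level.  With no inter-segment audio
    (or silent background) the SNR is +inf.
    """
    mask = np.ones(len(clip.samples), dtype=bool)
    for seg in segments:
        mask[seg.start:seg.end] = False
    noise = clip.samples[mask]
    noise_rms = float(np.sqrt(np.mean(noise**2))) if noise.size else 0.0
    out = []
    for seg in segments:
        sig = clip.samples[seg.start:seg.end]
        sig_rms = float(np.sqrt(np.mean(sig**2)))
        if noise_rms == 0.0:
            out.append(np.inf if sig_rms > 0 else 0.0)
        else:
            out.append(20.0 * np.log10(sig_rms / noise_rms)
                       if sig_rms > 0 else -np.inf)
    return out


def snr_filter(
    clip: AudioClip,
    segments: list[Segment],
    cutoff_db: float,
    log: list | None = None,
) -> list[Segment]:
    """Drop segments whose estimated SNR falls below cutoff_db.

    Excluded segments are appended to ``log`` as (segment, snr_db) pairs.
    """
    snrs = segment_snr_db(clip, segments)
    kept = []
    for seg, snr in zip(segments, snrs):
        if snr >= cutoff_db:
            kept.append(seg)
        elif log is not None:
            log.append((seg, snr))
    return kept
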