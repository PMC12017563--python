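"""Campaign metadata and audio input.

A recording campaign is a set of mono PCM WAV files plus one metadata table
(CSV, UTF-8, header row) with the fixed columns ``file`` and ``start``
followed by one column per categorical label (e.g. site, replicate, period).
Recordings are high-pass filtered as whole files — so no per-segment edge
transients — and then cut into fixed-length, non-overlapping analysis
segments; a trailing remainder shorter than one segment is discarded.
"""

from __future__ import annotations

import wave
import warnings
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "CampaignError",
    "FilterSpec",
    "RecordingEntry",
    "AudioSegment",
    "read_campaign",
    "load_audio",
    "highpass",
    "segment_waveform",
    "segment_recording",
]

#: metadata columns that are not labels
RESERVED_COLUMNS = ("file", "start")


class CampaignError(ValueError):
    """Raised for malformed campaign metadata or audio."""


@dataclass(frozen=True)
class FilterSpec:
    """High-pass Butterworth filter applied to each whole recording.

    Defaults: 8th-order zero-phase filter at 70 Hz, removing hydrophone DC
    drift and low-frequency flow noise below the band of interest. Zero
    phase means forward-backward application: the magnitude response is
    squared and the group delay is zero.
    """

    cutoff_hz: float = 70.0
    order: int = 8
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise CampaignError(f"cutoff_hz must be positive, got {self.cutoff_hz}")
        if self.order < 1:
            raise CampaignError(f"filter order must be >= 1, got {self.order}")


@dataclass
class RecordingEntry:
    """One row of the campaign table, with header facts read from the WAV."""

    file_path: Path
    start_time: datetime
    labels: dict[str, str]
    sample_rate: int
    duration: float  # seconds
    row: int  # 0-based row index in the metadata table


@dataclass
class AudioSegment:
    """A fixed-length slice of one (possibly filtered) recording."""

    samples: np.ndarray
    sample_rate: int
    source: RecordingEntry | None = None
    offset: float = 0.0  # seconds from recording start

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def _read_wav_header(path: Path) -> tuple[int, int, int]:
    """Return (sample_rate, n_frames, n_channels) of a PCM WAV file."""
    with wave.open(str(path), "rb") as wf:
        return wf.getframerate(), wf.getnframes(), wf.getnchannels()


def load_audio(entry: RecordingEntry | Path | str) -> np.ndarray:
    """Read a mono 16-bit PCM WAV into a float array scaled to [-1, 1)."""
    path = entry.file_path if isinstance(entry, RecordingEntry) else Path(entry)
    with wave.open(str(path), "rb") as wf:
        if wf.getnchannels() != 1:
            raise CampaignError(
                f"{path}: expected mono audio, got {wf.getnchannels()} channels"
            )
        if wf.getsampwidth() != 2:
            raise CampaignError(
                f"{path}: expected 16-bit PCM, got {8 * wf.getsampwidth()}-bit"
            )
        raw = wf.readframes(wf.getnframes())
    return np.frombuffer(raw, dtype="<i2").astype(np.float64) / 32768.0


def read_campaign(
    metadata_table: Path | str | pd.DataFrame,
    audio_root: Path | str | None = None,
) -> list[RecordingEntry]:
    """Read the campaign metadata table and validate the referenced audio.

    Parameters
    ----------
    metadata_table
        CSV path (columns ``file``, ``start``, then one column per label)
        or an equivalent DataFrame.
    audio_root
        Directory that relative ``file`` paths are resolved against;
        defaults to the directory containing the CSV.

    Returns
    -------
    One :class:`RecordingEntry` per table row, in row order, with duration
    and sample rate read from each WAV header. All entries must be mono and
    share the sample rate of the first entry (no resampling is attempted).
    """
    if isinstance(metadata_table, pd.DataFrame):
        table = metadata_table.copy()
        root = Path(audio_root) if audio_root is not None else Path.cwd()
    else:
        table_path = Path(metadata_table)
        table = pd.read_csv(table_path, dtype=str)
        root = Path(audio_root) if audio_root is not None else table_path.parent

    for col in RESERVED_COLUMNS:
        if col not in table.columns:
            raise CampaignError(f"metadata table lacks required column {col!r}")
    label_names = [c for c in table.columns if c not in RESERVED_COLUMNS]
    if not label_names:
        raise CampaignError("metadata table must have at least one label column")

    entries: list[RecordingEntry] = []
    for i, rec in enumerate(table.to_dict("records")):
        path = Path(str(rec["file"]))
        if not path.is_absolute():
            path = root / path
        if not path.exists():
            raise CampaignError(f"row {i}: audio file not found: {path}")
        labels = {name: str(rec[name]) for name in label_names}
        if any(v in ("", "nan", "None") for v in labels.values()):
            raise CampaignError(f"row {i}: empty label value in {labels}")
        try:
            start = datetime.fromisoformat(str(rec["start"]))
        except ValueError as exc:
            raise CampaignError(f"row {i}: bad start datetime {rec['start']!r}") from exc
        rate, n_frames, n_channels = _read_wav_header(path)
        if n_channels != 1:
            raise CampaignError(f"row {i}: {path} is not mono ({n_channels} channels)")
        entries.append(
            RecordingEntry(
                file_path=path,
                start_time=start,
                labels=labels,
                sample_rate=rate,
                duration=n_frames / rate,
                row=i,
            )
        )

    rates = {e.sample_rate for e in entries}
    if len(rates) > 1:
        raise CampaignError(f"mixed sample rates in campaign: {sorted(rates)}")
    _warn_schedule_gaps(entries)
    return entries


def _warn_schedule_gaps(entries: list[RecordingEntry]) -> None:
    """Warn (but proceed) when a label group's duty cycle has gaps.

    Groups rows by their full label tuple, sorts by start time, and compares
    consecutive spacings against the group's modal spacing.
    """
    groups: dict[tuple, list[datetime]] = {}
    for e in entries:
        groups.setdefault(tuple(sorted(e.labels.items())), []).append(e.start_time)
    for key, starts in groups.items():
        if len(starts) < 3:
            continue
        starts = sorted(starts)
        deltas = np.array([(b - a).total_seconds() for a, b in zip(starts, starts[1:])])
        vals, counts = np.unique(deltas, return_counts=True)
        modal = vals[np.argmax(counts)]
        n_gaps = int(np.sum(deltas > modal * 1.5))
        if n_gaps:
            warnings.warn(
                f"campaign group {dict(key)} has {n_gaps} gap(s) larger than the "
                f"modal cycle of {modal:.0f} s; proceeding",
                stacklevel=3,
            )


def highpass(
    waveform: np.ndarray, sample_rate: int, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """High-pass Butterworth filter of a whole waveform.

    With ``spec.zero_phase`` the filter is applied forward and backward
    (``sosfiltfilt``), giving zero group delay and a squared magnitude
    response; otherwise a single causal pass is used.
    """
    waveform = np.asarray(waveform, dtype=np.float64)
    if waveform.size == 0:
        raise CampaignError("cannot filter an empty waveform")
    nyquist = sample_rate / 2
    if spec.cutoff_hz >= nyquist:
        raise CampaignError(
            f"cutoff {spec.cutoff_hz} Hz is not below the Nyquist frequency {nyquist} Hz"
        )
    sos = signal.butter(spec.order, spec.cutoff_hz, btype="highpass", fs=sample_rate, output="sos")
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, waveform)
    return signal.sosfilt(sos, waveform)


def segment_waveform(
    waveform: np.ndarray,
    sample_rate: int,
    segment_length_s: float = 1.0,
    source: RecordingEntry | None = None,
) -> list[AudioSegment]:
    """Cut a waveform into contiguous non-overlapping fixed-length segments.

    The trailing remainder shorter than one segment is discarded. A waveform
    shorter than one segment yields an empty list.
    """
    if segment_length_s <= 0:
        raise CampaignError(f"segment_length_s must be positive, got {segment_length_s}")
    seg_n = segment_length_s * sample_rate
    if abs(seg_n - round(seg_n)) > 1e-9:
        raise CampaignError(
            f"segment length {segment_length_s} s is not an integer number of "
            f"samples at {sample_rate} Hz"
        )
    seg_n = int(round(seg_n))
    n_segments = len(waveform) // seg_n
    return [
        AudioSegment(
            samples=waveform[i * seg_n : (i + 1) * seg_n],
            sample_rate=sample_rate,
            source=source,
            offset=i * segment_length_s,
        )
        for i in range(n_segments)
    ]


def segment_recording(
    entry: RecordingEntry,
    filter_spec: FilterSpec | None = FilterSpec(),
    segment_length_s: float = 1.0,
) -> list[AudioSegment]:
    """Load, (optionally) high-pass filter, and segment one recording.

    The filter is applied to the whole file before cutting, so segment
    boundaries carry no filter transients.
    """
    waveform = load_audio(entry)
    if filter_spec is not None:
        waveform = highpass(waveform, entry.sample_rate, filter_spec)
    return segment_waveform(waveform, entry.sample_rate, segment_length_s, source=entry)
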