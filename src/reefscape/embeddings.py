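"""Initial acoustic embeddings of one-second segments.

Each segment is projected into a high-dimensional acoustic space by one of:

* ``mel_spectrum`` — natural-log energies of ``n_mels`` mel bands computed
  from a single power spectrum of the whole segment (64 dimensions at the
  defaults);
* ``mel_spectrogram`` — the natural-log mel band energies of a short-time
  Fourier transform, flattened row-major over (band, frame). At 44.1 kHz
  with a 2048-sample window and 0.01 s hop this is 64 bands x 100 frames =
  6400 dimensions with a 441-sample hop;
* ``cnn_embed`` — a pluggable external embedding adapter (e.g. a pretrained
  CNN); no network ships with this package.

Conventions (declared, since published pipelines differ): HTK mel scale,
triangular filters with unit peak spanning [fmin, fmax]; periodic Hann
window; frames left-aligned with no centering, the last window zero-padded;
per-bin ("spectrum"-scaled) power so a stationary tone yields comparable
band energies from both mel operations; band energies floored at
``ENERGY_FLOOR`` before the natural log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from scipy import signal as _signal

from .campaign import AudioSegment

__all__ = [
    "ENERGY_FLOOR",
    "MelSpec",
    "EmbeddingVector",
    "EmbeddingAdapter",
    "AdapterError",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filterbank",
    "mel_spectrum",
    "mel_spectrogram",
    "cnn_embed",
    "embedder",
]

#: floor applied to linear band energies before the natural log (full scale = 1)
ENERGY_FLOOR = 1e-12

#: duration fed to CNN adapters, the leading part of each 1-s segment
CNN_INPUT_SECONDS = 0.96


class AdapterError(RuntimeError):
    """Raised when no CNN adapter is registered or an adapter misbehaves."""


@dataclass(frozen=True)
class MelSpec:
    """Mel analysis parameters.

    ``fmin``/``fmax`` bound the band of interest (70–2000 Hz by default,
    where most fish sounds and boat noise fall); ``n_fft`` is the STFT
    window length in samples and ``hop_s`` the hop in seconds (441 samples
    at 44.1 kHz).
    """

    n_mels: int = 64
    fmin: float = 70.0
    fmax: float = 2000.0
    n_fft: int = 2048
    hop_s: float = 0.01

    def validate(self, sample_rate: int) -> None:
        if not (0 <= self.fmin < self.fmax <= sample_rate / 2):
            raise ValueError(
                f"need 0 <= fmin < fmax <= Nyquist, got ({self.fmin}, {self.fmax}) "
                f"at {sample_rate} Hz"
            )
        if self.n_mels < 1:
            raise ValueError("n_mels must be >= 1")
        hop = self.hop_s * sample_rate
        if hop <= 0 or abs(hop - round(hop)) > 1e-9:
            raise ValueError(
                f"hop of {self.hop_s} s is not a positive integer number of samples "
                f"at {sample_rate} Hz"
            )

    def hop_samples(self, sample_rate: int) -> int:
        return int(round(self.hop_s * sample_rate))


@dataclass
class EmbeddingVector:
    """One segment's coordinates in the initial acoustic space."""

    values: np.ndarray
    dim_names: list[str]
    segment: AudioSegment | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) != len(self.dim_names):
            raise ValueError("values and dim_names must be 1-d and equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains NaN/Inf")


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    """HTK mel scale."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, fmin: float, fmax: float, freqs: np.ndarray
) -> np.ndarray:
    """Triangular unit-peak mel filters evaluated on the FFT bin frequencies.

    Returns an (n_mels, len(freqs)) weight matrix. Band edges are n_mels + 2
    points equally spaced on the mel scale between fmin and fmax.
    """
    edges = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2))
    lower, center, upper = edges[:-2], edges[1:-1], edges[2:]
    f = np.asarray(freqs, dtype=np.float64)[None, :]
    up = (f - lower[:, None]) / (center - lower)[:, None]
    down = (upper[:, None] - f) / (upper - center)[:, None]
    return np.clip(np.minimum(up, down), 0.0, None)


def _power_spectrum(frames: np.ndarray, window: np.ndarray) -> np.ndarray:
    """Per-bin ('spectrum'-scaled) one-sided power of windowed frames.

    For a stationary sine of amplitude A the powers around its peak sum to
    ~A^2/2 regardless of the window length, which keeps whole-segment and
    framed analyses on the same scale.
    """
    spec = np.fft.rfft(frames * window, axis=-1)
    power = (np.abs(spec) ** 2) * (2.0 / window.sum() ** 2)
    power[..., 0] /= 2.0
    if frames.shape[-1] % 2 == 0:
        power[..., -1] /= 2.0
    return power


def mel_spectrum(segment: AudioSegment, spec: MelSpec = MelSpec()) -> EmbeddingVector:
    """Natural-log mel band energies of the whole segment (one vector).

    A single Hann-windowed power spectrum over the full segment is pooled by
    the mel filterbank; band energies are floored at :data:`ENERGY_FLOOR`
    before the natural log, so digital silence maps to ``log(ENERGY_FLOOR)``
    in every band.
    """
    spec.validate(segment.sample_rate)
    x = np.asarray(segment.samples, dtype=np.float64)
    window = _signal.get_window("hann", len(x), fftbins=True)
    power = _power_spectrum(x[None, :], window)[0]
    freqs = np.fft.rfftfreq(len(x), 1.0 / segment.sample_rate)
    fb = mel_filterbank(spec.n_mels, spec.fmin, spec.fmax, freqs)
    energies = np.maximum(fb @ power, ENERGY_FLOOR)
    names = [f"mel{k:02d}" for k in range(spec.n_mels)]
    return EmbeddingVector(np.log(energies), names, segment)


def mel_spectrogram(segment: AudioSegment, spec: MelSpec = MelSpec()) -> EmbeddingVector:
    """Flattened natural-log mel spectrogram of the segment.

    Frames start every ``hop`` samples from sample 0 (left-aligned, no
    centering); the number of frames is ``len(segment) // hop`` — exactly
    100 for a 1-s segment at 44.1 kHz and a 0.01 s hop — and windows running
    past the end are zero-padded. Flattening is row-major over
    (mel band, frame); dimension names encode both indices.
    """
    spec.validate(segment.sample_rate)
    x = np.asarray(segment.samples, dtype=np.float64)
    hop = spec.hop_samples(segment.sample_rate)
    n_frames = len(x) // hop
    if n_frames < 1:
        raise ValueError("segment shorter than one hop")
    padded = np.concatenate([x, np.zeros(spec.n_fft)])
    idx = np.arange(spec.n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = padded[idx]
    window = _signal.get_window("hann", spec.n_fft, fftbins=True)
    power = _power_spectrum(frames, window)  # (n_frames, n_bins)
    freqs = np.fft.rfftfreq(spec.n_fft, 1.0 / segment.sample_rate)
    fb = mel_filterbank(spec.n_mels, spec.fmin, spec.fmax, freqs)
    energies = np.maximum(power @ fb.T, ENERGY_FLOOR).T  # (n_mels, n_frames)
    names = [
        f"mel{k:02d}_t{j:03d}" for k in range(spec.n_mels) for j in range(n_frames)
    ]
    return EmbeddingVector(np.log(energies).ravel(order="C"), names, segment)


@runtime_checkable
class EmbeddingAdapter(Protocol):
    """External embedding callable (e.g. a pretrained CNN wrapper).

    Must declare its output dimensionality via ``n_dims`` and map a
    (samples, sample_rate) pair to a 1-d vector of that length.
    """

    n_dims: int

    def __call__(self, samples: np.ndarray, sample_rate: int) -> np.ndarray: ...


def cnn_embed(segment: AudioSegment, adapter: EmbeddingAdapter | None) -> EmbeddingVector:
    """Embed a segment through an external adapter.

    Only the first :data:`CNN_INPUT_SECONDS` of the segment are passed to
    the adapter (the conventional CNN input length for 1-s audio; the
    trailing 0.04 s are unused).
    """
    if adapter is None:
        raise AdapterError(
            "no CNN embedding adapter registered; use the mel_spectrum or "
            "mel_spectrogram embeddings instead"
        )
    n_in = int(round(CNN_INPUT_SECONDS * segment.sample_rate))
    out = np.asarray(adapter(np.asarray(segment.samples)[:n_in], segment.sample_rate))
    if out.ndim != 1 or len(out) != adapter.n_dims:
        raise AdapterError(
            f"adapter declared {adapter.n_dims} dims but returned shape {out.shape}"
        )
    names = [f"cnn{k:03d}" for k in range(adapter.n_dims)]
    return EmbeddingVector(out, names, segment)


def embedder(
    kind: str,
    spec: MelSpec = MelSpec(),
    adapter: EmbeddingAdapter | None = None,
    fallback_to_mel: bool = False,
) -> Callable[[AudioSegment], EmbeddingVector]:
    """Return the embedding callable for a config string.

    Requesting ``cnn_adapter`` without a registered adapter raises, directing
    the user to the mel embeddings — unless ``fallback_to_mel`` is set, in
    which case the pipeline proceeds with ``mel_spectrum`` after a warning.
    """
    if kind == "cnn_adapter" and adapter is None and fallback_to_mel:
        import warnings

        warnings.warn("no CNN adapter registered; falling back to mel_spectrum")
        kind = "mel_spectrum"
    if kind == "mel_spectrum":
        return lambda seg: mel_spectrum(seg, spec)
    if kind == "mel_spectrogram":
        return lambda seg: mel_spectrogram(seg, spec)
    if kind == "cnn_adapter":
        return lambda seg: cnn_embed(seg, adapter)
    raise ValueError(f"unknown embedding kind {kind!r}")
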