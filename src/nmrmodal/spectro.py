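"""Short-time Fourier transform and power spectrograms of FIDs.

The STFT matrix collects the unnormalized DFTs of windowed signal
segments: frame ``m`` is the ``n_fft``-point DFT of the length-``M``
windowed segment starting at sample ``m*R`` (hop ``R = M - L``, overlap
``L``), zero-padded after windowing.  The number of frames obtainable
from a length-``Nx`` signal is

    k = floor((Nx - L) / (M - L)).

The power spectrogram is the squared magnitude ``|X|**2``, cropped (or
zero-padded) along time to a fixed number of frames so that every sample
maps onto one common time-frequency grid — 256 frames x 1024 bins at the
default acquisition geometry (16,384 points, 10,016 Hz spectral width,
Hann window of 64, hop 32).  Because the FID decays, the early frames
kept by the crop carry nearly all the signal energy.

Frequency bins are two-sided and centered (-sw/2 ... +sw/2) by default,
matching a spectrogram drawn against a physical frequency axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import get_window

from .errors import InputTooShortError, InvalidParameterError, ShapeError
from .fid import FIDRecord

__all__ = [
    "STFTParams",
    "STFTMatrix",
    "Spectrogram",
    "frame_count",
    "stft",
    "spectrogram",
    "fid_to_spectrogram",
    "export_spectrogram",
    "read_spectrogram_ascii",
]

ASCII_FLOAT_FORMAT = "%.17g"


@dataclass(frozen=True)
class STFTParams:
    """Window/hop/FFT-size/frame-crop configuration.

    Attributes
    ----------
    window : str
        Window name accepted by :func:`scipy.signal.get_window`
        (symmetric sampling); default Hann.
    window_length : int
        M, samples per frame (default 64).
    overlap : int
        L, samples shared by successive frames (default 32).
    n_fft : int
        NDFT, DFT length after zero-padding (default 1024, >= M).
    sidedness : str
        "twosided-centered" (default) or "onesided".
    n_frames_out : int
        Time-axis crop target of the spectrogram (default 256).
    """

    window: str = "hann"
    window_length: int = 64
    overlap: int = 32
    n_fft: int = 1024
    sidedness: str = "twosided-centered"
    n_frames_out: int = 256

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise InvalidParameterError("window_length must be >= 1")
        if not 0 <= self.overlap <= self.window_length - 1:
            raise InvalidParameterError(
                f"overlap must lie in [0, M-1]; got L={self.overlap}, "
                f"M={self.window_length}"
            )
        if self.n_fft < self.window_length:
            raise InvalidParameterError("n_fft must be >= window_length")
        if self.n_frames_out < 1:
            raise InvalidParameterError("n_frames_out must be >= 1")
        if self.sidedness not in ("twosided-centered", "onesided"):
            raise InvalidParameterError(f"unknown sidedness {self.sidedness!r}")

    @property
    def hop(self) -> int:
        """R = M - L."""
        return self.window_length - self.overlap

    @property
    def n_bins(self) -> int:
        if self.sidedness == "onesided":
            return self.n_fft // 2 + 1
        return self.n_fft

    def window_samples(self) -> np.ndarray:
        return get_window(self.window, self.window_length, fftbins=False)


@dataclass
class STFTMatrix:
    """Complex STFT values, frames x bins, with physical axes."""

    values: np.ndarray
    frame_times_s: np.ndarray
    bin_freqs_hz: np.ndarray
    params: STFTParams
    sample_id: str = ""
    group_label: str | None = None

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class Spectrogram:
    """Nonnegative power matrix P_SP with time and frequency axes."""

    power: np.ndarray
    frame_times_s: np.ndarray
    bin_freqs_hz: np.ndarray
    sample_id: str = ""
    group_label: str | None = None
    params: STFTParams = field(default_factory=STFTParams)

    @property
    def shape(self) -> tuple[int, int]:
        return self.power.shape


def frame_count(n_samples: int, window_length: int, overlap: int) -> int:
    """Number of full frames: ``floor((Nx - L) / (M - L))``."""
    if window_length <= overlap:
        raise InvalidParameterError(
            f"window_length must exceed overlap; got M={window_length}, L={overlap}"
        )
    if overlap < 0:
        raise InvalidParameterError("overlap must be >= 0")
    if n_samples < window_length:
        raise InputTooShortError(
            f"signal of {n_samples} samples is shorter than one window "
            f"({window_length})"
        )
    return (n_samples - overlap) // (window_length - overlap)


def stft(record: FIDRecord | np.ndarray, params: STFTParams | None = None) -> STFTMatrix:
    """STFT of an FID: one row per frame, unnormalized forward DFT."""
    params = params or STFTParams()
    if isinstance(record, FIDRecord):
        x = record.signal
        sw = record.spectral_width_hz
        sample_id = record.sample_id
        group_label = record.group_label
    else:
        x = np.asarray(record, dtype=np.complex128)
        sw = 10_016.0  # physical axis only; values unaffected
        sample_id = ""
        group_label = None
    M, L, R = params.window_length, params.overlap, params.hop
    k = frame_count(x.shape[0], M, L)

    idx = np.arange(k)[:, None] * R + np.arange(M)[None, :]
    frames = x[idx] * params.window_samples()[None, :]
    X = np.fft.fft(frames, n=params.n_fft, axis=1)
    dwell = 1.0 / sw
    if params.sidedness == "twosided-centered":
        X = np.fft.fftshift(X, axes=1)
        freqs = np.fft.fftshift(np.fft.fftfreq(params.n_fft, d=dwell))
    else:
        X = X[:, : params.n_fft // 2 + 1]
        freqs = np.fft.rfftfreq(params.n_fft, d=dwell)
    times = (np.arange(k) * R + M / 2.0) * dwell
    return STFTMatrix(
        values=X, frame_times_s=times, bin_freqs_hz=freqs, params=params,
        sample_id=sample_id, group_label=group_label,
    )


def spectrogram(stft_out: STFTMatrix, n_frames_out: int | None = None) -> Spectrogram:
    """Power spectrogram ``|X|**2`` cropped/zero-padded to ``n_frames_out`` frames."""
    params = stft_out.params
    n_out = params.n_frames_out if n_frames_out is None else n_frames_out
    if n_out < 1:
        raise InvalidParameterError("n_frames_out must be >= 1")
    power = np.abs(stft_out.values) ** 2
    k = power.shape[0]
    R = params.hop
    dwell = (
        stft_out.frame_times_s[1] - stft_out.frame_times_s[0]
    ) / R if k > 1 else 1.0
    if k >= n_out:
        power = power[:n_out]
        times = stft_out.frame_times_s[:n_out]
    else:
        pad = np.zeros((n_out - k, power.shape[1]))
        power = np.vstack([power, pad])
        extra = (np.arange(k, n_out) * R + params.window_length / 2.0) * dwell
        times = np.concatenate([stft_out.frame_times_s, extra])
    return Spectrogram(
        power=power,
        frame_times_s=times,
        bin_freqs_hz=stft_out.bin_freqs_hz,
        sample_id=stft_out.sample_id,
        group_label=stft_out.group_label,
        params=params,
    )


def fid_to_spectrogram(record: FIDRecord, params: STFTParams | None = None) -> Spectrogram:
    """Convenience: STFT then power spectrogram at the configured crop."""
    return spectrogram(stft(record, params))


def export_spectrogram(
    spec: Spectrogram,
    image_path: str | Path | None = None,
    ascii_path: str | Path | None = None,
) -> list[Path]:
    """Export a spectrogram as a grayscale TIFF and/or an ASCII matrix.

    The TIFF is single-channel 32-bit float, uncompressed, holding the
    log10-scaled power (for display dynamic range); row 0 is the first
    frame.  The ASCII file holds the raw power matrix, one frame per
    line, single-space separated, full double precision, and re-parses to
    the power matrix exactly at printed precision.
    """
    written: list[Path] = []
    if ascii_path is not None:
        ascii_path = Path(ascii_path)
        np.savetxt(ascii_path, spec.power, fmt=ASCII_FLOAT_FORMAT, delimiter=" ")
        written.append(ascii_path)
    if image_path is not None:
        import tifffile

        image_path = Path(image_path)
        peak = float(spec.power.max())
        floor = peak * 1e-12 if peak > 0 else 1.0
        display = np.log10(np.maximum(spec.power, floor)).astype(np.float32)
        tifffile.imwrite(image_path, display, compression=None)
        written.append(image_path)
    return written


def read_spectrogram_ascii(path: str | Path) -> np.ndarray:
    """Read the power matrix back from an ASCII export."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.size == 0:
        raise ShapeError(f"{path}: empty spectrogram file")
    return arr
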