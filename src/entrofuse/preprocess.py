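"""EEG preprocessing: channel selection, resampling, clip extraction,
powerline notch, db6 wavelet band split and threshold artifact removal.

The pipeline order is: select lateral-temporal channels -> downsample to
256 Hz -> extract clip-only segments -> 50 Hz bandstop -> 5-level db6 DWT
band split (delta/theta/alpha/beta/gamma) -> per-band wavelet threshold
artifact correction.  Artifact coefficients are detected per decomposition
level with the threshold

    T_j = mean(C_j) + 2 * std(C_j)        (sample std, ddof=1)

and any coefficient with |c| > T_j is halved once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pywt
from scipy import signal

from .errors import (
    ChannelNotFoundError,
    InsufficientDataError,
    NyquistError,
    ProtocolMismatchError,
    UpsampleNotSupportedError,
    WrongRateError,
)
from .synth import BANDS, ClipProtocol

__all__ = [
    "Recording",
    "BandedRecording",
    "select_channels",
    "downsample",
    "extract_clip_segments",
    "notch_50hz",
    "band_decompose",
    "threshold_level",
    "remove_artifacts",
    "preprocess_subject",
    "DEFAULT_WAVELET",
    "DWT_LEVELS",
]

DEFAULT_WAVELET = "db6"
DWT_LEVELS = 5
_BAND_FS = 256.0

#: DWT detail level feeding each band at 256 Hz (A5 carries delta).
_BAND_TO_LEVEL = {"gamma": 2, "beta": 3, "alpha": 4, "theta": 5, "delta": "A"}


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is (n_channels, n_samples) in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: list
    subject_id: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must equal channel count")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BandedRecording:
    """Per-channel delta/theta/alpha/beta/gamma signals at 256 Hz.

    ``bands`` maps band name -> (n_channels, n_samples) array; all bands
    share the sample count of the signal they were decomposed from.
    ``clip_index`` (optional) maps each sample back to its film clip.
    """

    bands: dict
    fs: float
    channel_labels: list
    subject_id: str | None = None
    artifact_corrected: bool = False
    clip_index: np.ndarray | None = None
    clip_labels: np.ndarray | None = None

    def __post_init__(self):
        lengths = {b: arr.shape for b, arr in self.bands.items()}
        shapes = set(lengths.values())
        if len(shapes) != 1:
            raise ValueError(f"band arrays disagree in shape: {lengths}")
        if tuple(self.bands) != BANDS:
            self.bands = {b: self.bands[b] for b in BANDS}

    @property
    def n_channels(self) -> int:
        return next(iter(self.bands.values())).shape[0]

    @property
    def n_samples(self) -> int:
        return next(iter(self.bands.values())).shape[1]


def select_channels(rec: Recording, wanted) -> Recording:
    """Restrict a recording to ``wanted`` labels, in the wanted order."""
    index = {lab: i for i, lab in enumerate(rec.channel_labels)}
    rows = []
    for lab in wanted:
        if lab not in index:
            raise ChannelNotFoundError(f"channel {lab!r} not in recording")
        rows.append(index[lab])
    return Recording(data=rec.data[rows].copy(), fs=rec.fs,
                     channel_labels=list(wanted), subject_id=rec.subject_id)


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase anti-aliased resampling to ``target_fs``."""
    if target_fs > rec.fs:
        raise UpsampleNotSupportedError(
            f"target_fs {target_fs} exceeds recording fs {rec.fs}")
    if target_fs == rec.fs:
        return Recording(rec.data.copy(), rec.fs, list(rec.channel_labels),
                         rec.subject_id)
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = signal.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    return Recording(out, target_fs, list(rec.channel_labels), rec.subject_id)


def extract_clip_segments(rec: Recording, protocol: ClipProtocol):
    """Keep clip-only samples, dropping hints and intervals.

    Returns ``(clip_recording, clip_index)`` where ``clip_index[i]`` is the
    0-based clip covering concatenated sample ``i``.
    """
    fs = rec.fs
    pieces, idx = [], []
    for c, (start_s, end_s) in enumerate(protocol.clip_spans()):
        i0 = int(round(start_s * fs))
        i1 = int(round(end_s * fs))
        if i1 > rec.n_samples:
            raise ProtocolMismatchError(
                f"clip {c} ends at sample {i1} but recording has {rec.n_samples}")
        pieces.append(rec.data[:, i0:i1])
        idx.append(np.full(i1 - i0, c, dtype=int))
    out = Recording(np.concatenate(pieces, axis=1), fs,
                    list(rec.channel_labels), rec.subject_id)
    return out, np.concatenate(idx)


def notch_50hz(rec: Recording, q: float = 30.0) -> Recording:
    """Zero-phase IIR notch at 50 Hz (powerline rejection)."""
    if rec.fs <= 100:
        raise NyquistError(f"fs {rec.fs} too low for a 50 Hz notch")
    b, a = signal.iirnotch(50.0, q, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.data, axis=1)
    return Recording(out, rec.fs, list(rec.channel_labels), rec.subject_id)


def _band_reconstructions(x: np.ndarray) -> dict:
    """Single-level DWT band reconstructions of one channel at 256 Hz."""
    coeffs = pywt.wavedec(x, DEFAULT_WAVELET, level=DWT_LEVELS, mode="symmetric")
    # coeffs = [cA5, cD5, cD4, cD3, cD2, cD1]
    out = {}
    for band in BANDS:
        sel = [np.zeros_like(c) for c in coeffs]
        lvl = _BAND_TO_LEVEL[band]
        pos = 0 if lvl == "A" else DWT_LEVELS - lvl + 1
        sel[pos] = coeffs[pos]
        rec = pywt.waverec(sel, DEFAULT_WAVELET, mode="symmetric")
        out[band] = rec[: x.shape[0]]
    return out


def band_decompose(rec: Recording, clip_index: np.ndarray | None = None,
                   clip_labels: np.ndarray | None = None) -> BandedRecording:
    """Split each channel into five clinical bands via 5-level db6 DWT.

    Band mapping at 256 Hz: D2 -> gamma (32-64 Hz), D3 -> beta (16-32),
    D4 -> alpha (8-16), D5 -> theta (4-8), A5 -> delta (0-4).  The D1
    (64-128 Hz) details fall outside the named bands and are discarded.
    """
    if abs(rec.fs - _BAND_FS) > 1e-6:
        raise WrongRateError(f"band_decompose requires fs=256, got {rec.fs}")
    bands = {b: np.empty_like(rec.data) for b in BANDS}
    for ch in range(rec.n_channels):
        recon = _band_reconstructions(rec.data[ch])
        for b in BANDS:
            bands[b][ch] = recon[b]
    return BandedRecording(bands=bands, fs=rec.fs,
                           channel_labels=list(rec.channel_labels),
                           subject_id=rec.subject_id,
                           artifact_corrected=False,
                           clip_index=clip_index, clip_labels=clip_labels)


def threshold_level(c_j: np.ndarray):
    """Threshold one coefficient level: T_j = mean + 2*sample-std; halve outliers.

    Any coefficient with ``|c| > T_j`` is considered an artifact coefficient
    and halved, in a single pass.  Returns ``(T_j, corrected)``.
    """
    c_j = np.asarray(c_j, dtype=float)
    if c_j.size < 2:
        raise InsufficientDataError("threshold_level needs at least 2 coefficients")
    t_j = float(np.mean(c_j) + 2.0 * np.std(c_j, ddof=1))
    corrected = np.where(np.abs(c_j) > t_j, c_j / 2.0, c_j)
    return t_j, corrected


def remove_artifacts(banded: BandedRecording) -> BandedRecording:
    """Wavelet-threshold artifact correction applied independently per band.

    Each band signal is re-decomposed (db6, 5 levels), every coefficient
    level is corrected by :func:`threshold_level`, and the band is
    reconstructed.  Halving is applied once per level per pass.
    """
    out = {}
    for b, arr in banded.bands.items():
        corrected = np.empty_like(arr)
        for ch in range(arr.shape[0]):
            coeffs = pywt.wavedec(arr[ch], DEFAULT_WAVELET, level=DWT_LEVELS,
                                  mode="symmetric")
            new_coeffs = [threshold_level(c)[1] for c in coeffs]
            rec = pywt.waverec(new_coeffs, DEFAULT_WAVELET, mode="symmetric")
            corrected[ch] = rec[: arr.shape[1]]
        out[b] = corrected
    return BandedRecording(bands=out, fs=banded.fs,
                           channel_labels=list(banded.channel_labels),
                           subject_id=banded.subject_id,
                           artifact_corrected=True,
                           clip_index=banded.clip_index,
                           clip_labels=banded.clip_labels)


def preprocess_subject(rec: Recording, protocol: ClipProtocol,
                       channels=None, target_fs: float = _BAND_FS) -> BandedRecording:
    """Full pipeline for one subject; returns the artifact-corrected bands.

    ``channels=None`` keeps all channels (the synthetic generator already
    emits only the twelve lateral-temporal electrodes).
    """
    if channels is not None:
        rec = select_channels(rec, channels)
    rec = downsample(rec, target_fs)
    rec, clip_index = extract_clip_segments(rec, protocol)
    rec = notch_50hz(rec)
    banded = band_decompose(rec, clip_index=clip_index,
                            clip_labels=protocol.labels)
    return remove_artifacts(banded)
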