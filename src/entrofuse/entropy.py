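"""Windowed entropy features: MSE, approximate, fuzzy, Renyi and
differential entropy over non-overlapping 1-second windows.

Conventions
-----------
* Template matching (SE/AE/FE) uses the Chebyshev distance with a match
  when d <= r; the tolerance defaults to r = 0.2 * population std of the
  window (computed once at scale 1 for MSE and reused across scales).
* Sample entropy excludes self-matches; approximate entropy includes them
  (the classical definitions).
* Fuzzy entropy removes each template's own baseline (mean) and replaces
  the hard match by exp(-(d/r)^n), self-matches excluded.
* Renyi entropy estimates p(i) from an equal-width histogram of the window.
* All logarithms are natural; entropies are reported in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .errors import (
    DegenerateToleranceError,
    EmptyInputError,
    EmptyOutputError,
    InsufficientDataError,
    InvalidIndexError,
)
from .preprocess import BandedRecording
from .synth import BANDS

__all__ = [
    "EntropyParams",
    "FeatureMatrix",
    "FEATURES",
    "coarse_grain",
    "sample_entropy",
    "multiscale_entropy",
    "approximate_entropy",
    "fuzzy_entropy",
    "renyi_entropy",
    "differential_entropy",
    "extract_features",
]

#: Canonical feature order used in matrices and fusion.
FEATURES = ("mse", "ae", "fe", "re", "de")

_WINDOW_S = 1.0


@dataclass(frozen=True)
class EntropyParams:
    """Shared parameters of the entropy estimators.

    m=2 and r = 0.2 * window std follow the standard SE/AE setting for
    1-second (256-sample) EEG windows; n=2 is the usual fuzzy-gradient
    exponent and q=2 the two-order (collision) Renyi index.
    """

    m: int = 2
    r_factor: float = 0.2
    n: float = 2.0
    q: float = 2.0
    tau_max: int = 5
    histogram_bins: int = 10

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.tau_max < 1:
            raise ValueError("tau_max must be >= 1")
        if self.q < 0 or self.q == 1:
            raise InvalidIndexError("q must be >= 0 and != 1")
        if self.histogram_bins < 1:
            raise ValueError("histogram_bins must be >= 1")


@dataclass
class FeatureMatrix:
    """Feature rows x 1-second window columns with row metadata.

    ``row_meta`` columns: channel, band, feature, scale (NaN for
    single-scale features).  ``clip_index`` maps each window column to its
    film clip when the source carried clip annotations.
    """

    values: np.ndarray
    row_meta: pd.DataFrame
    window_times: np.ndarray
    clip_index: np.ndarray | None = None
    subject_id: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.row_meta) != self.values.shape[0]:
            raise ValueError("row_meta length must equal row count")
        if len(self.window_times) != self.values.shape[1]:
            raise ValueError("window_times length must equal column count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Block-average a series at scale ``tau`` (trailing remainder dropped)."""
    x = np.asarray(x, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau > x.shape[0]:
        raise EmptyOutputError(f"tau={tau} exceeds series length {x.shape[0]}")
    if tau == 1:
        return x.copy()
    n_blocks = x.shape[0] // tau
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                   r_factor: float = 0.2) -> float:
    """SE = -ln(A/B): conditional probability that m-matches extend to m+1.

    ``r=None`` sets r = r_factor * population std of ``x``.  Returns NaN
    when either count is zero (entropy undefined).
    """
    x = np.ascontiguousarray(x, dtype=float)
    if x.shape[0] <= m + 1:
        raise InsufficientDataError(f"need length > m+1={m + 1}, got {x.shape[0]}")
    if r is None:
        r = r_factor * float(np.std(x))
    if r <= 0:
        raise DegenerateToleranceError(f"tolerance r must be > 0, got {r}")
    a, b = _kernels.sampen_counts(x, m, r)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def multiscale_entropy(x: np.ndarray, params: EntropyParams = EntropyParams()) -> np.ndarray:
    """Sample entropy of the coarse-grained series at scales 1..tau_max.

    The tolerance is fixed from the scale-1 window (r = r_factor * std) and
    reused at every scale, the standard MSE convention.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < params.tau_max * (params.m + 2):
        raise InsufficientDataError(
            f"need >= tau_max*(m+2)={params.tau_max * (params.m + 2)} samples, "
            f"got {x.shape[0]}")
    r = params.r_factor * float(np.std(x))
    out = np.empty(params.tau_max)
    for tau in range(1, params.tau_max + 1):
        out[tau - 1] = sample_entropy(coarse_grain(x, tau), params.m, r)
    return out


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                        r_factor: float = 0.2) -> float:
    """AE = Phi^m - Phi^(m+1), self-matches included (Pincus)."""
    x = np.ascontiguousarray(x, dtype=float)
    if x.shape[0] <= m + 1:
        raise InsufficientDataError(f"need length > m+1={m + 1}, got {x.shape[0]}")
    if r is None:
        r = r_factor * float(np.std(x))
    if r < 0:
        raise DegenerateToleranceError(f"tolerance r must be >= 0, got {r}")
    phi_m, phi_m1 = _kernels.apen_phis(x, m, r)
    return float(phi_m - phi_m1)


def fuzzy_entropy(x: np.ndarray, m: int = 2, n: float = 2.0,
                  r: float | None = None, r_factor: float = 0.2) -> float:
    """FE = ln(O^m / O^(m+1)) with exponential similarity exp(-(d/r)^n).

    Templates are centred on their own mean before the Chebyshev distance,
    so the similarity is insensitive to local baseline drift; self-matches
    are excluded.
    """
    x = np.ascontiguousarray(x, dtype=float)
    if x.shape[0] <= m + 1:
        raise InsufficientDataError(f"need length > m+1={m + 1}, got {x.shape[0]}")
    if r is None:
        r = r_factor * float(np.std(x))
    if r <= 0:
        raise DegenerateToleranceError(f"tolerance r must be > 0, got {r}")
    d_m, d_m1 = _kernels.fuzzy_distances(x, m)
    u = np.concatenate([d_m, d_m1]) / r
    u = u * u if n == 2 else u ** n
    sims = np.exp(-u)
    o_m = sims[: d_m.size].mean()
    o_m1 = sims[d_m.size:].mean()
    return float(np.log(o_m / o_m1))


def renyi_entropy(x: np.ndarray, q: float = 2.0, histogram_bins: int = 10) -> float:
    """Order-q Renyi entropy of the window's amplitude histogram (nats).

    p(i) is the relative frequency over ``histogram_bins`` equal-width bins
    spanning the window's range; empty bins contribute nothing.
    """
    if q < 0 or q == 1:
        raise InvalidIndexError(f"q must be >= 0 and != 1, got {q}")
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise InsufficientDataError("empty window")
    counts, _ = np.histogram(x, bins=histogram_bins)
    p = counts[counts > 0] / x.size
    return float(np.log(np.sum(p ** q)) / (1.0 - q))


def differential_entropy(x: np.ndarray) -> float:
    """Gaussian-approximation DE = 0.5 * ln(2*pi*e*sigma^2), sigma^2 ddof=1.

    Returns -inf for zero-variance windows (flagged sentinel; imputed at
    matrix assembly).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise InsufficientDataError("need at least 2 samples")
    var = float(np.var(x, ddof=1))
    if var <= 0:
        return float("-inf")
    return float(0.5 * np.log(2.0 * np.pi * np.e * var))


def _window_slices(n_samples: int, win: int, clip_index: np.ndarray | None):
    """Start indices and clip ids of non-overlapping windows.

    Windows are aligned to clip starts and never straddle a clip boundary;
    without clip annotations the whole signal is tiled from sample 0.
    """
    starts, clips = [], []
    if clip_index is None:
        for s in range(0, (n_samples // win) * win, win):
            starts.append(s)
            clips.append(-1)
    else:
        boundaries = np.flatnonzero(np.diff(clip_index)) + 1
        seg_starts = np.concatenate([[0], boundaries])
        seg_ends = np.concatenate([boundaries, [n_samples]])
        for s0, s1 in zip(seg_starts, seg_ends):
            c = int(clip_index[s0])
            for s in range(s0, s0 + ((s1 - s0) // win) * win, win):
                starts.append(s)
                clips.append(c)
    return np.array(starts, dtype=int), np.array(clips, dtype=int)


def _window_features(w: np.ndarray, feature: str, params: EntropyParams) -> np.ndarray:
    """One window's value(s) for one feature; NaN where undefined."""
    sd = float(np.std(w))
    if feature == "de":
        v = differential_entropy(w)
        return np.array([v if np.isfinite(v) else np.nan])
    if feature == "re":
        return np.array([renyi_entropy(w, params.q, params.histogram_bins)])
    if sd == 0.0:  # degenerate window: matching tolerance collapses
        n_out = params.tau_max if feature == "mse" else 1
        return np.full(n_out, np.nan)
    r = params.r_factor * sd
    if feature == "mse":
        return multiscale_entropy(w, params)
    if feature == "ae":
        return np.array([approximate_entropy(w, params.m, r)])
    if feature == "fe":
        return np.array([fuzzy_entropy(w, params.m, params.n, r)])
    raise ValueError(f"unknown feature {feature!r}")


def extract_features(banded: BandedRecording,
                     params: EntropyParams = EntropyParams(),
                     feature_set=FEATURES) -> FeatureMatrix:
    """Assemble the (channel x band [x scale]) x window feature matrix.

    Each single entropy contributes one row per (channel, band) — 60 rows
    for 12 channels and 5 bands; MSE contributes tau_max rows per pair
    (300 rows at five scales).  Windows are 1 s, non-overlapping, aligned
    to clip starts.  Undefined values (zero-variance windows, vanishing
    match counts) are imputed with the feature row's median.
    """
    if banded.n_samples == 0:
        raise EmptyInputError("banded recording has no samples")
    feature_set = [f for f in FEATURES if f in set(feature_set)]
    if not feature_set:
        raise ValueError("feature_set selects no known feature")
    win = int(round(_WINDOW_S * banded.fs))
    starts, win_clips = _window_slices(banded.n_samples, win, banded.clip_index)
    if starts.size == 0:
        raise InsufficientDataError("no complete 1 s window in recording")

    rows, meta = [], []
    for feature in feature_set:
        scales = range(1, params.tau_max + 1) if feature == "mse" else (None,)
        for ch, ch_label in enumerate(banded.channel_labels):
            for band in BANDS:
                sig = banded.bands[band][ch]
                block = np.empty((len(tuple(scales)) if feature == "mse" else 1,
                                  starts.size))
                for w_i, s in enumerate(starts):
                    block[:, w_i] = _window_features(sig[s:s + win], feature, params)
                for k in range(block.shape[0]):
                    rows.append(block[k])
                    meta.append((ch_label, band, feature,
                                 k + 1 if feature == "mse" else np.nan))
    values = np.vstack(rows)

    # impute undefined entries with the row median so downstream
    # normalisation and the classifier see finite inputs
    for i in range(values.shape[0]):
        bad = ~np.isfinite(values[i])
        if bad.any():
            med = np.nanmedian(np.where(np.isfinite(values[i]), values[i], np.nan))
            values[i, bad] = med if np.isfinite(med) else 0.0

    row_meta = pd.DataFrame(meta, columns=["channel", "band", "feature", "scale"])
    window_times = starts / banded.fs
    clip_index = None if banded.clip_index is None else win_clips
    return FeatureMatrix(values=values, row_meta=row_meta,
                         window_times=window_times, clip_index=clip_index,
                         subject_id=banded.subject_id)
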