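"""Synthetic emotion-EEG cohort generator.

Emulates a film-clip emotion-elicitation session: a picture hint precedes
each two-minute clip and a self-assessment interval follows it, with clip
labels drawn from {-1 (negative), 0 (neutral), 1 (positive)}.  Twelve
lateral-temporal channels are synthesised at 1000 Hz so the downsampling
path of the preprocessing pipeline is exercised.

The signal model is deliberately simple: per-band sinusoid mixtures with
random frequencies/phases plus a 1/f (pink) background, with the per-band
oscillation amplitude and the pink-noise share both modulated by the clip's
emotion label.  Gamma-band power is ordered positive > negative > neutral
and broadband complexity positive ~ negative > neutral, the qualitative
structure reported for lateral-temporal EEG during emotional film viewing.
Blink and movement artifacts are injected as low-frequency raised-cosine
transients and broadband bursts respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ProtocolError

__all__ = [
    "BANDS",
    "BAND_EDGES",
    "DEFAULT_CHANNELS",
    "ClipProtocol",
    "SynthConfig",
    "generate_protocol",
    "generate_subject",
    "generate_cohort",
]

#: Canonical band order used throughout the package.
BANDS = ("delta", "theta", "alpha", "beta", "gamma")

#: Dyadic band edges (Hz) matching a 5-level DWT at 256 Hz.
BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 16.0),
    "beta": (16.0, 32.0),
    "gamma": (32.0, 64.0),
}

#: Twelve lateral-temporal electrodes (10-20 system).
DEFAULT_CHANNELS = (
    "FT7", "T7", "TP7", "P7", "C5", "CP5",
    "FT8", "T8", "TP8", "P8", "C6", "CP6",
)

#: Baseline RMS amplitude (uV) of each band's oscillatory component.
_BAND_RMS = {"delta": 14.0, "theta": 8.0, "alpha": 10.0, "beta": 5.0, "gamma": 3.0}

#: Number of sinusoids mixed per band.
_N_SINES = 3

LABELS = (-1, 0, 1)


def _default_band_power_map() -> dict:
    """Per-emotion multiplicative gain on each band's oscillation RMS.

    Emotional engagement raises signal energy globally (gamma included, so
    gamma power is ordered positive > negative > neutral), with a uniform
    gain across bands: a uniform profile keeps the *relative* spectral
    composition identical between classes, so amplitude-invariant
    regularity features carry no power information and the power axis is
    read exclusively by differential entropy.
    """
    return {
        1: {b: 1.30 for b in BANDS},
        -1: {b: 1.06 for b in BANDS},
        0: {b: 1.00 for b in BANDS},
    }


def _default_complexity_map() -> dict:
    """Pink-noise amplitude share per emotion (positive ~ negative > neutral).

    The oscillatory amplitude of each band is reduced in quadrature so the
    total band RMS stays at its gain-determined target: the noise share
    changes signal *regularity* (what SE/FE/MSE measure) while band *power*
    (what DE measures) is controlled by ``band_power_map`` alone.
    """
    return {1: 0.60, -1: 0.60, 0: 0.20}


def _default_richness_map() -> dict:
    """Sinusoidal components per band per emotion.

    Neutral viewing is modelled as a single rhythmic generator per band;
    emotional engagement recruits several independent generators, which
    entropy features register as a step up in irregularity.
    """
    return {1: 3, -1: 3, 0: 1}


@dataclass(frozen=True)
class ClipProtocol:
    """Ordered film-clip schedule: (label, duration_s) pairs plus hint/interval gaps."""

    clips: tuple  # of (label, duration_s)
    hint_s: float = 5.0
    interval_s: float = 45.0

    def __post_init__(self):
        for label, dur in self.clips:
            if label not in LABELS:
                raise ProtocolError(f"label {label!r} not in {LABELS}")
            if dur <= 0:
                raise ProtocolError(f"clip duration must be positive, got {dur}")
        if self.hint_s < 0 or self.interval_s < 0:
            raise ProtocolError("hint_s and interval_s must be non-negative")

    @property
    def n_clips(self) -> int:
        return len(self.clips)

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for lab, _ in self.clips], dtype=int)

    def total_duration(self) -> float:
        """Full session length in seconds (hints + clips + intervals)."""
        return sum(self.hint_s + dur + self.interval_s for _, dur in self.clips)

    def clip_spans(self) -> list:
        """(start_s, end_s) of each clip on the session timeline."""
        spans, cursor = [], 0.0
        for _, dur in self.clips:
            cursor += self.hint_s
            spans.append((cursor, cursor + dur))
            cursor += dur + self.interval_s
        return spans


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level generation parameters."""

    n_subjects: int = 23
    n_channels: int = 12
    fs: float = 1000.0
    band_power_map: dict = field(default_factory=_default_band_power_map)
    complexity_map: dict = field(default_factory=_default_complexity_map)
    richness_map: dict = field(default_factory=_default_richness_map)
    artifact_rate: float = 6.0  # events / minute
    subject_gain_jitter: float = 0.20  # sd of per-subject log-normal gain
    clip_gain_jitter: float = 0.15  # sd of per-clip, per-band log-normal gain
    seed: int = 0

    def __post_init__(self):
        if self.fs < 512:
            raise ConfigurationError(f"fs must be >= 512 Hz, got {self.fs}")
        if self.n_subjects < 1 or self.n_channels < 1:
            raise ConfigurationError("n_subjects and n_channels must be >= 1")
        if self.artifact_rate < 0:
            raise ConfigurationError("artifact_rate must be >= 0")
        for lab, gains in self.band_power_map.items():
            if lab not in LABELS:
                raise ConfigurationError(f"band_power_map label {lab!r} invalid")
            if any(g <= 0 for g in gains.values()):
                raise ConfigurationError("band gains must be > 0")
        for lab, p in self.complexity_map.items():
            if not 0.0 <= p < 1.0:
                raise ConfigurationError("complexity proportions must lie in [0, 1)")
        for lab, k in self.richness_map.items():
            if k < 1:
                raise ConfigurationError("richness (sinusoids per band) must be >= 1")


def generate_protocol(n_clips: int, seed: int, *, clip_s: float = 120.0,
                      hint_s: float = 5.0, interval_s: float = 45.0) -> ClipProtocol:
    """Label-balanced pseudo-random clip schedule.

    ``n_clips`` must be divisible by 3 so each emotion gets the same number
    of clips (5 per class for 15-clip sessions, 7 for 21-clip sessions).
    """
    if n_clips % 3 != 0 or n_clips <= 0:
        raise ProtocolError(
            f"n_clips must be a positive multiple of 3, got {n_clips}")
    rng = np.random.default_rng(seed)
    labels = np.repeat(LABELS, n_clips // 3)
    labels = labels[rng.permutation(n_clips)]
    clips = tuple((int(lab), float(clip_s)) for lab in labels)
    return ClipProtocol(clips=clips, hint_s=hint_s, interval_s=interval_s)


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float = 0.5, hi: float = 128.0) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping, band-limited to [lo, hi] Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    keep = (freqs >= lo) & (freqs <= hi)
    scale[keep] = 1.0 / np.sqrt(freqs[keep])
    spec *= scale
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _segment(rng: np.random.Generator, n: int, fs: float, n_channels: int,
             gains: dict, complexity: float, channel_scale: np.ndarray,
             amp_scale: float = 1.0, n_sines: int = _N_SINES) -> np.ndarray:
    """One timeline segment: per-band sinusoid mixtures + 1/f background.

    ``complexity`` p is the noise amplitude share of each band's RMS
    budget: the band carries sqrt(1 - p^2) * target of sinusoidal
    oscillation and p * target of 1/f noise synthesised within the band's
    own frequency range.  Total band RMS therefore stays at its
    ``band_power_map`` target for any p — the noise share moves signal
    regularity (SE/FE/MSE) without moving band power (DE).
    """
    t = np.arange(n) / fs
    out = np.zeros((n_channels, n))
    for band in BANDS:
        lo, hi = BAND_EDGES[band]
        target = _BAND_RMS[band] * gains[band] * amp_scale
        osc_rms = np.sqrt(1.0 - complexity ** 2) * target
        noise_rms = complexity * target
        for ch in range(n_channels):
            comp = np.zeros(n)
            freqs = rng.uniform(lo, hi, n_sines)
            phases = rng.uniform(0, 2 * np.pi, n_sines)
            weights = rng.uniform(0.5, 1.0, n_sines)
            for f, ph, w in zip(freqs, phases, weights):
                comp += w * np.sin(2 * np.pi * f * t + ph)
            rms = np.sqrt(np.mean(comp ** 2))
            if rms > 0:
                comp *= osc_rms / rms
            comp += noise_rms * _pink_noise(rng, n, fs, lo, hi)
            out[ch] += comp * channel_scale[ch]
    return out


def _inject_artifacts(rng: np.random.Generator, data: np.ndarray, fs: float,
                      rate_per_min: float,
                      gain_envelope: np.ndarray | None = None) -> np.ndarray:
    """Add blink (raised-cosine, <4 Hz content) and movement (broadband burst) events.

    ``gain_envelope`` (per-sample scalar) scales event amplitudes with the
    local signal gain, keeping the artifact-to-signal ratio independent of
    the emotion condition.
    """
    n_ch, n = data.shape
    duration_min = n / fs / 60.0
    n_events = rng.poisson(rate_per_min * duration_min)
    out = data.copy()
    for _ in range(n_events):
        kind = "blink" if rng.uniform() < 0.7 else "movement"
        if kind == "blink":
            dur = rng.uniform(0.3, 0.5)
            amp = rng.uniform(60.0, 120.0)
        else:
            dur = rng.uniform(1.0, 2.0)
            amp = rng.uniform(30.0, 60.0)
        width = int(dur * fs)
        start = rng.integers(0, max(1, n - width))
        sl = slice(start, start + width)
        if gain_envelope is not None:
            amp *= gain_envelope[start]
        ch_weights = rng.uniform(0.4, 1.0, n_ch)
        if kind == "blink":
            # raised cosine: smooth low-frequency transient
            shape = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
            out[:, sl] += amp * np.outer(ch_weights, shape)
        else:
            env = np.hanning(width)
            burst = rng.standard_normal(width) * env
            out[:, sl] += amp * np.outer(ch_weights, burst)
    return out


def generate_subject(protocol: ClipProtocol, config: SynthConfig,
                     subject_seed: int, subject_id: str = "S00"):
    """Synthesise one subject's full-session recording.

    Hints and intervals are rendered as neutral-gain resting background at
    reduced amplitude; clips follow the emotion-dependent band-power and
    complexity maps.  A subject-level log-normal gain plus per-channel
    scale jitter make cross-subject normalisation non-trivial.  Artifacts
    draw from their own random stream, so ``artifact_rate=0`` reproduces
    the artifact-free signal bit-for-bit under the same seed.
    """
    from .preprocess import Recording  # local import to avoid a cycle

    rng = np.random.default_rng(subject_seed)
    artifact_rng = np.random.default_rng(
        np.random.SeedSequence([subject_seed, 0xA27]).generate_state(1)[0])
    fs = config.fs
    subj_gain = float(np.exp(rng.normal(0.0, config.subject_gain_jitter)))
    channel_scale = subj_gain * np.exp(rng.normal(0.0, 0.1, config.n_channels))

    neutral_gains = config.band_power_map[0]
    neutral_p = config.complexity_map[0]
    neutral_k = config.richness_map[0]
    segments = []
    envelope = []  # per-sample mean gain, for artifact amplitude scaling
    for label, dur in protocol.clips:
        if protocol.hint_s > 0:
            n_hint = int(round(protocol.hint_s * fs))
            segments.append(_segment(rng, n_hint, fs, config.n_channels,
                                     neutral_gains, neutral_p, channel_scale,
                                     0.7, neutral_k))
            envelope.append(np.full(n_hint, 0.7 * subj_gain *
                                    np.mean(list(neutral_gains.values()))))
        n_clip = int(round(dur * fs))
        # per-clip, per-band gain jitter: clips of one emotion vary around
        # their class mean, so no single band is a perfect discriminant
        base = config.band_power_map[label]
        jitter = np.exp(rng.normal(0.0, config.clip_gain_jitter, len(BANDS)))
        gains = {b: base[b] * j for b, j in zip(BANDS, jitter)}
        segments.append(_segment(rng, n_clip, fs, config.n_channels,
                                 gains, config.complexity_map[label],
                                 channel_scale, 1.0,
                                 config.richness_map[label]))
        envelope.append(np.full(n_clip, subj_gain *
                                np.mean(list(gains.values()))))
        if protocol.interval_s > 0:
            n_int = int(round(protocol.interval_s * fs))
            segments.append(_segment(rng, n_int, fs, config.n_channels,
                                     neutral_gains, neutral_p, channel_scale,
                                     0.7, neutral_k))
            envelope.append(np.full(n_int, 0.7 * subj_gain *
                                    np.mean(list(neutral_gains.values()))))
    data = np.concatenate(segments, axis=1)
    data = _inject_artifacts(artifact_rng, data, fs, config.artifact_rate,
                             np.concatenate(envelope))
    labels = list(DEFAULT_CHANNELS[:config.n_channels])
    if config.n_channels > len(DEFAULT_CHANNELS):
        labels += [f"CH{i}" for i in range(len(DEFAULT_CHANNELS), config.n_channels)]
    return Recording(data=data, fs=fs, channel_labels=labels, subject_id=subject_id)


def subject_seeds(config: SynthConfig) -> np.ndarray:
    """Stable per-subject seeds derived from the cohort seed."""
    ss = np.random.SeedSequence(config.seed)
    return ss.generate_state(config.n_subjects)


def generate_cohort(config: SynthConfig, protocol: ClipProtocol | None = None,
                    n_clips: int = 15):
    """Generate ``config.n_subjects`` independent subjects.

    Every subject follows the same protocol by default (one schedule drawn
    from ``config.seed``), mirroring a fixed experimental session design.
    Returns a list of (Recording, ClipProtocol, subject_id).
    """
    if protocol is None:
        protocol = generate_protocol(n_clips, seed=config.seed)
    seeds = subject_seeds(config)
    cohort = []
    for i, s in enumerate(seeds):
        sid = f"S{i:02d}"
        rec = generate_subject(protocol, config, int(s), subject_id=sid)
        cohort.append((rec, protocol, sid))
    return cohort
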