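"""Feature normalisation, per-window label sequences, entropy-feature
fusion and cross-subject train/test splitting.

Normalisation is per subject and per feature row (min-max to [-1, 1]):
each subject's own range is used, which removes between-subject amplitude
offsets before the cross-subject classifier sees the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import FeatureMatrix
from .errors import AlignmentError, InvalidSplitError
from .synth import ClipProtocol

__all__ = [
    "LabeledSequence",
    "CohortSplit",
    "normalize",
    "build_labels",
    "fuse",
    "split_subjects",
]


@dataclass
class LabeledSequence:
    """Per-window emotion labels in {-1, 0, 1}, aligned to feature columns."""

    labels: np.ndarray
    window_times: np.ndarray
    clip_index: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.window_times = np.asarray(self.window_times, dtype=float)
        self.clip_index = np.asarray(self.clip_index, dtype=int)
        if not (len(self.labels) == len(self.window_times) == len(self.clip_index)):
            raise AlignmentError("labels, window_times and clip_index must align")
        bad = set(np.unique(self.labels)) - {-1, 0, 1}
        if bad:
            raise ValueError(f"labels outside {{-1,0,1}}: {bad}")

    def __len__(self):
        return len(self.labels)


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint subject partition into training and testing groups."""

    train_ids: tuple
    test_ids: tuple
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise InvalidSplitError("train and test subjects overlap")


def normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Min-max map each feature row to [-1, 1]; constant rows map to 0."""
    v = fm.values
    lo = v.min(axis=1, keepdims=True)
    hi = v.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(v)
    nz = (span > 0).ravel()
    out[nz] = 2.0 * (v[nz] - lo[nz]) / span[nz] - 1.0
    return FeatureMatrix(values=out, row_meta=fm.row_meta.copy(),
                         window_times=fm.window_times.copy(),
                         clip_index=None if fm.clip_index is None else fm.clip_index.copy(),
                         subject_id=fm.subject_id)


def build_labels(protocol: ClipProtocol, n_windows_per_clip,
                 window_s: float = 1.0) -> LabeledSequence:
    """One label per window from the clip covering it.

    ``n_windows_per_clip`` is either a single int (same window count for
    every clip) or a sequence of per-clip counts, matching the windowing of
    feature extraction.
    """
    if np.isscalar(n_windows_per_clip):
        counts = [int(n_windows_per_clip)] * protocol.n_clips
    else:
        counts = [int(c) for c in n_windows_per_clip]
    if len(counts) != protocol.n_clips:
        raise AlignmentError(
            f"{len(counts)} window counts for {protocol.n_clips} clips")
    labels, clip_idx, times = [], [], []
    spans = protocol.clip_spans()
    for c, ((lab, _), (start_s, _)) in enumerate(zip(protocol.clips, spans)):
        labels.extend([lab] * counts[c])
        clip_idx.extend([c] * counts[c])
        times.extend(start_s + np.arange(counts[c]) * window_s)
    return LabeledSequence(labels=np.array(labels), window_times=np.array(times),
                           clip_index=np.array(clip_idx))


def labels_for(fm: FeatureMatrix, protocol: ClipProtocol) -> LabeledSequence:
    """Label sequence aligned to an extracted feature matrix's windows."""
    if fm.clip_index is None:
        raise AlignmentError("feature matrix carries no clip annotations")
    counts = [int(np.sum(fm.clip_index == c)) for c in range(protocol.n_clips)]
    seq = build_labels(protocol, counts)
    if len(seq) != fm.n_windows:
        raise AlignmentError(
            f"{len(seq)} labels for {fm.n_windows} feature columns")
    return seq


def fuse(features) -> FeatureMatrix:
    """Row-wise concatenation of feature matrices sharing the same windows."""
    features = list(features)
    if not features:
        raise AlignmentError("nothing to fuse")
    first = features[0]
    for fm in features[1:]:
        if fm.n_windows != first.n_windows:
            raise AlignmentError(
                f"column mismatch: {fm.n_windows} vs {first.n_windows}")
        if not np.allclose(fm.window_times, first.window_times):
            raise AlignmentError("window_times differ between matrices")
    if len(features) == 1:
        fm = first
        return FeatureMatrix(values=fm.values.copy(), row_meta=fm.row_meta.copy(),
                             window_times=fm.window_times.copy(),
                             clip_index=None if fm.clip_index is None else fm.clip_index.copy(),
                             subject_id=fm.subject_id)
    values = np.vstack([fm.values for fm in features])
    row_meta = pd.concat([fm.row_meta for fm in features], ignore_index=True)
    return FeatureMatrix(values=values, row_meta=row_meta,
                         window_times=first.window_times.copy(),
                         clip_index=None if first.clip_index is None else first.clip_index.copy(),
                         subject_id=first.subject_id)


def split_subjects(ids, n_test: int, seed: int) -> CohortSplit:
    """Random subject-wise split (default 18 train / 5 test for 23 ids)."""
    ids = list(ids)
    if n_test >= len(ids):
        raise InvalidSplitError(
            f"n_test={n_test} must be smaller than the cohort size {len(ids)}")
    if n_test < 1:
        raise InvalidSplitError("n_test must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    test = tuple(ids[i] for i in sorted(order[:n_test]))
    train = tuple(ids[i] for i in sorted(order[n_test:]))
    return CohortSplit(train_ids=train, test_ids=test, seed=seed)
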