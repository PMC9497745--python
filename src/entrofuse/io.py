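"""Readers and writers for recordings, protocols, feature matrices, labels,
splits and trained models.

Recordings travel as a TSV sample matrix (columns = channels) plus a JSON
sidecar carrying the sampling rate and labels; EDF input is supported via
mne when available.  Feature matrices are TSV with row-metadata columns and
a ``# key: value`` header block.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import ModelConfig, TrainedModel
from .entropy import FeatureMatrix
from .fusion import CohortSplit, LabeledSequence
from .preprocess import BandedRecording, Recording
from .synth import BANDS, ClipProtocol

__all__ = [
    "save_recording", "load_recording",
    "save_protocol", "load_protocol",
    "save_feature_matrix", "load_feature_matrix",
    "save_labels", "load_labels",
    "save_split", "load_split",
    "save_banded", "load_banded",
    "save_model", "load_model",
]


def save_recording(rec: Recording, base: str | Path) -> None:
    """Write ``<base>.tsv`` (samples x channels) and ``<base>.json`` sidecar."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(base.with_suffix(".tsv"), sep="\t", index=False,
              float_format="%.6f")
    sidecar = {"fs": rec.fs, "channel_labels": list(rec.channel_labels),
               "subject_id": rec.subject_id, "units": "uV"}
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_recording(path: str | Path) -> Recording:
    """Load an EDF file (via mne) or a TSV matrix with its JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne  # optional dependency, EDF input only

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(data=raw.get_data() * 1e6, fs=raw.info["sfreq"],
                         channel_labels=list(raw.ch_names),
                         subject_id=path.stem)
    df = pd.read_csv(path.with_suffix(".tsv"), sep="\t")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return Recording(data=df.to_numpy().T, fs=sidecar["fs"],
                     channel_labels=sidecar["channel_labels"],
                     subject_id=sidecar.get("subject_id"))


def save_protocol(protocol: ClipProtocol, path: str | Path) -> None:
    rows = []
    for c, ((lab, dur), (start, end)) in enumerate(
            zip(protocol.clips, protocol.clip_spans())):
        rows.append({"clip_index": c, "label": lab,
                     "start_s": start, "end_s": end})
    df = pd.DataFrame(rows)
    df.attrs = {}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# hint_s: {protocol.hint_s}\n")
        fh.write(f"# interval_s: {protocol.interval_s}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_protocol(path: str | Path) -> ClipProtocol:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            key, val = line[1:].split(":", 1)
            meta[key.strip()] = float(val)
            body_start += 1
        else:
            break
    df = pd.read_csv(path, sep="\t", skiprows=body_start)
    clips = tuple((int(r.label), float(r.end_s - r.start_s))
                  for r in df.itertuples())
    return ClipProtocol(clips=clips, hint_s=meta.get("hint_s", 5.0),
                        interval_s=meta.get("interval_s", 45.0))


def save_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = fm.row_meta.copy()
    for j in range(fm.n_windows):
        body[f"w{j}"] = fm.values[:, j]
    with open(path, "w") as fh:
        fh.write(f"# subject_id: {fm.subject_id}\n")
        fh.write("# window_times: " + ",".join(f"{t:g}" for t in fm.window_times) + "\n")
        if fm.clip_index is not None:
            fh.write("# clip_index: " + ",".join(str(c) for c in fm.clip_index) + "\n")
        body.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def load_feature_matrix(path: str | Path) -> FeatureMatrix:
    meta = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, val = line[1:].split(":", 1)
            meta[key.strip()] = val.strip()
            n_header += 1
    df = pd.read_csv(path, sep="\t", skiprows=n_header)
    meta_cols = ["channel", "band", "feature", "scale"]
    win_cols = [c for c in df.columns if c.startswith("w")]
    values = df[win_cols].to_numpy()
    window_times = np.array([float(t) for t in meta["window_times"].split(",")])
    clip_index = None
    if "clip_index" in meta:
        clip_index = np.array([int(c) for c in meta["clip_index"].split(",")])
    sid = meta.get("subject_id")
    return FeatureMatrix(values=values, row_meta=df[meta_cols].copy(),
                         window_times=window_times, clip_index=clip_index,
                         subject_id=None if sid == "None" else sid)


def save_labels(seq: LabeledSequence, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"window_index": np.arange(len(seq)),
                  "time_s": seq.window_times,
                  "clip_index": seq.clip_index,
                  "label": seq.labels}).to_csv(path, sep="\t", index=False)


def load_labels(path: str | Path) -> LabeledSequence:
    df = pd.read_csv(path, sep="\t")
    return LabeledSequence(labels=df["label"].to_numpy(),
                           window_times=df["time_s"].to_numpy(),
                           clip_index=df["clip_index"].to_numpy())


def save_split(split: CohortSplit, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps({
        "train_ids": list(split.train_ids),
        "test_ids": list(split.test_ids),
        "seed": split.seed}, indent=1))


def load_split(path: str | Path) -> CohortSplit:
    d = json.loads(Path(path).read_text())
    return CohortSplit(train_ids=tuple(d["train_ids"]),
                       test_ids=tuple(d["test_ids"]), seed=d["seed"])


def save_banded(banded: BandedRecording, out_dir: str | Path) -> None:
    """One TSV per band (samples x channels) plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for b in BANDS:
        pd.DataFrame(banded.bands[b].T, columns=banded.channel_labels).to_csv(
            out_dir / f"{b}.tsv", sep="\t", index=False, float_format="%.6f")
    sidecar = {"fs": banded.fs, "channel_labels": list(banded.channel_labels),
               "subject_id": banded.subject_id,
               "artifact_corrected": banded.artifact_corrected}
    if banded.clip_index is not None:
        sidecar["clip_index"] = banded.clip_index.tolist()
    if banded.clip_labels is not None:
        sidecar["clip_labels"] = np.asarray(banded.clip_labels).tolist()
    (out_dir / "banded.json").write_text(json.dumps(sidecar))


def load_banded(in_dir: str | Path) -> BandedRecording:
    in_dir = Path(in_dir)
    sidecar = json.loads((in_dir / "banded.json").read_text())
    bands = {}
    for b in BANDS:
        bands[b] = pd.read_csv(in_dir / f"{b}.tsv", sep="\t").to_numpy().T
    clip_index = sidecar.get("clip_index")
    clip_labels = sidecar.get("clip_labels")
    return BandedRecording(
        bands=bands, fs=sidecar["fs"],
        channel_labels=sidecar["channel_labels"],
        subject_id=sidecar.get("subject_id"),
        artifact_corrected=sidecar.get("artifact_corrected", False),
        clip_index=None if clip_index is None else np.array(clip_index),
        clip_labels=None if clip_labels is None else np.array(clip_labels))


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialise parameters (npz) with a JSON config/loss snapshot."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.params)
    cfg = {k: v for k, v in vars(model.config).items()}
    path.with_suffix(".json").write_text(json.dumps({
        "architecture": model.architecture,
        "config": cfg,
        "loss_log": model.loss_log}, indent=1))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    params = {k: data[k] for k in data.files}
    meta = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(**meta["config"])
    return TrainedModel(architecture=meta["architecture"], params=params,
                        config=config, loss_log=meta["loss_log"])
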