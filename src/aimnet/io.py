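"""Plain-text file interchange for cohorts, matrices, and epoch tensors.

Continuous recordings travel as CSV matrices (one row per channel, first
column the channel label), events as a BIDS-events-like TSV
(onset_sample, onset_seconds, label), scores and manifests as CSV/JSON.
Connectivity matrices are square CSVs with a channel-label header
row/column, plus a long-format TSV (chan_a, chan_b, value) for
statistics. Epoch tensors use a compressed ``.npz`` container with a
JSON sidecar describing window, rate, labels and band.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochTensor
from .simulate import ContinuousRecording, PerformanceRecord

FLOAT_FMT = "%.4f"


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# continuous recordings


def write_recording(rec: ContinuousRecording, base: Path) -> list[Path]:
    """Write ``<base>.csv`` (signal) and ``<base>_events.tsv``; returns paths."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    sig_path = base.with_suffix(".csv")
    with open(sig_path, "w") as f:
        for label, row in zip(rec.channel_labels, rec.samples):
            f.write(label + "," + ",".join(FLOAT_FMT % v for v in row) + "\n")
    paths = [sig_path]
    ev_path = base.parent / (base.name + "_events.tsv")
    ev = pd.DataFrame(
        {
            "onset_sample": rec.events,
            "onset_seconds": rec.events / rec.sampling_rate,
            "label": "shot",
        }
    )
    ev.to_csv(ev_path, sep="\t", index=False, float_format="%.4f")
    paths.append(ev_path)
    meta = {
        "subject_id": rec.subject_id,
        "condition_label": rec.condition_label,
        "sampling_rate": rec.sampling_rate,
        "channel_labels": list(rec.channel_labels),
        "resting_segments": {k: list(v) for k, v in rec.resting_segments.items()},
    }
    meta_path = base.parent / (base.name + ".json")
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    paths.append(meta_path)
    return paths


def read_recording(base: Path) -> ContinuousRecording:
    base = Path(base)
    meta = json.loads((base.parent / (base.name + ".json")).read_text())
    labels = []
    rows = []
    with open(base.with_suffix(".csv")) as f:
        for line in f:
            label, _, rest = line.partition(",")
            labels.append(label)
            rows.append(np.fromiter(map(float, rest.split(",")), dtype=np.float64))
    ev_path = base.parent / (base.name + "_events.tsv")
    events = (
        pd.read_csv(ev_path, sep="\t")["onset_sample"].to_numpy(dtype=np.int64)
        if ev_path.exists()
        else np.empty(0, dtype=np.int64)
    )
    return ContinuousRecording(
        subject_id=meta["subject_id"],
        condition_label=meta["condition_label"],
        sampling_rate=meta["sampling_rate"],
        samples=np.vstack(rows),
        channel_labels=tuple(labels),
        events=events,
        resting_segments={k: tuple(v) for k, v in meta["resting_segments"].items()},
    )


# ---------------------------------------------------------------------------
# matrices


def write_matrix(matrix, path: Path) -> Path:
    """Square CSV with channel labels as header row and first column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = list(matrix.channel_labels)
    df = pd.DataFrame(matrix.values, index=labels, columns=labels)
    df.to_csv(path, float_format="%.6f")
    return path


def read_matrix(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), tuple(df.columns)


def matrix_long_format(matrix) -> pd.DataFrame:
    """Upper-triangle edges as (chan_a, chan_b, value) rows."""
    labels = list(matrix.channel_labels)
    v = matrix.values
    iu, ju = np.triu_indices(len(labels), k=1)
    return pd.DataFrame(
        {
            "chan_a": [labels[i] for i in iu],
            "chan_b": [labels[j] for j in ju],
            "value": v[iu, ju],
        }
    )


# ---------------------------------------------------------------------------
# epoch tensors


def write_epochs(epochs: EpochTensor, base: Path) -> list[Path]:
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    npz = base.with_suffix(".npz")
    np.savez_compressed(npz, data=epochs.data, retained_trial_ids=epochs.retained_trial_ids)
    sidecar = base.parent / (base.name + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "window": list(epochs.window),
                "sampling_rate": epochs.sampling_rate,
                "channel_labels": list(epochs.channel_labels),
                "band_label": epochs.band_label,
                "subject_id": epochs.subject_id,
                "condition_label": epochs.condition_label,
            },
            indent=1,
            sort_keys=True,
        )
    )
    return [npz, sidecar]


def read_epochs(base: Path) -> EpochTensor:
    base = Path(base)
    meta = json.loads((base.parent / (base.name + ".json")).read_text())
    arrays = np.load(base.with_suffix(".npz"))
    return EpochTensor(
        data=arrays["data"],
        window=tuple(meta["window"]),
        sampling_rate=meta["sampling_rate"],
        channel_labels=tuple(meta["channel_labels"]),
        retained_trial_ids=arrays["retained_trial_ids"],
        band_label=meta["band_label"],
        subject_id=meta["subject_id"],
        condition_label=meta["condition_label"],
    )


# ---------------------------------------------------------------------------
# cohort


def write_scores(records: list[PerformanceRecord], path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for shot, score in enumerate(rec.ring_scores):
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "condition": rec.condition_label,
                    "shot": shot,
                    "ring_score": score,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_cohort(out_dir: Path, subjects, manifest: dict) -> list[Path]:
    """Write every recording, score table, and the ground-truth manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    score_records = []
    for s in subjects:
        sub_dir = out_dir / s.subject_id
        for cond, rec in s.recordings.items():
            paths += write_recording(rec, sub_dir / f"{s.subject_id}_{cond}")
        paths += write_recording(s.resting, sub_dir / f"{s.subject_id}_resting")
        score_records += list(s.performance.values())
    paths.append(write_scores(score_records, out_dir / "scores.csv"))
    manifest_path = out_dir / "ground_truth.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    paths.append(manifest_path)
    return paths


def read_cohort_recordings(data_dir: Path):
    """Yield (subject_id, condition, recording) for every written recording."""
    data_dir = Path(data_dir)
    for sub_dir in sorted(p for p in data_dir.iterdir() if p.is_dir()):
        for meta_path in sorted(sub_dir.glob("*.json")):
            base = meta_path.parent / meta_path.stem
            rec = read_recording(base)
            yield rec.subject_id, rec.condition_label, rec
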