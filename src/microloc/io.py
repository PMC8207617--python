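"""Readers and writers for the HPA-challenge on-disk layout and the
CSV artifacts the pipeline produces.

A dataset directory holds one grayscale file per channel per sample —
``<id>_red.png``, ``<id>_green.png``, ``<id>_blue.png``,
``<id>_yellow.png`` (PNG or TIFF) — plus a ``train.csv`` with header
``Id,Target`` where ``Target`` is a space-separated list of integer
class indices.
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .evaluation import ThresholdVector
from .pipeline import DedupRecord, FoldAssignment
from .synthetic import CHANNEL_NAMES, MultiLabelSample

__all__ = [
    "write_hpa_layout",
    "read_hpa_layout",
    "read_label_csv",
    "write_fold_csv",
    "write_dedup_report",
    "write_predictions_csv",
    "read_predictions_csv",
    "write_thresholds_csv",
    "read_thresholds_csv",
    "write_submission_csv",
]


def write_hpa_layout(
    samples: list[MultiLabelSample], directory: str | Path, image_format: str = "png"
) -> Path:
    """Write samples in challenge layout; returns the dataset directory."""
    if image_format not in ("png", "tif"):
        raise ValueError("image_format must be 'png' or 'tif'")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in samples:
        for name, chan in zip(CHANNEL_NAMES, sample.channels):
            path = directory / f"{sample.id}_{name}.{image_format}"
            if image_format == "png":
                iio.imwrite(path, chan.astype(np.uint8))
            else:
                tifffile.imwrite(path, chan.astype(np.uint8))
        rows.append((sample.id, " ".join(str(i) for i in sample.label_indices)))
    with open(directory / "train.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Id", "Target"])
        writer.writerows(rows)
    return directory


def read_label_csv(path: str | Path, n_classes: int = 28) -> tuple[list[str], np.ndarray]:
    """Read an ``Id,Target`` label file into ids + (N, C) binary matrix."""
    df = pd.read_csv(path, dtype={"Id": str, "Target": str})
    if not {"Id", "Target"} <= set(df.columns):
        raise ValueError("label CSV must have columns Id,Target")
    ids = df["Id"].tolist()
    labels = np.zeros((len(ids), n_classes), dtype=np.int8)
    for i, target in enumerate(df["Target"]):
        for tok in str(target).split():
            labels[i, int(tok)] = 1
    return ids, labels


def read_hpa_layout(directory: str | Path, n_classes: int = 28) -> list[MultiLabelSample]:
    """Load a challenge-layout directory back into samples (id order of
    train.csv); accepts PNG or TIFF channel files."""
    directory = Path(directory)
    ids, labels = read_label_csv(directory / "train.csv", n_classes=n_classes)
    samples = []
    for sid, row in zip(ids, labels):
        chans = []
        for name in CHANNEL_NAMES:
            for ext in ("png", "tif", "tiff"):
                path = directory / f"{sid}_{name}.{ext}"
                if path.exists():
                    img = tifffile.imread(path) if ext != "png" else iio.imread(path)
                    chans.append(np.asarray(img))
                    break
            else:
                raise FileNotFoundError(f"missing channel file for {sid}_{name}")
        samples.append(MultiLabelSample(id=sid, channels=np.stack(chans), labels=row))
    return samples


def write_fold_csv(ids: list[str], assignment: FoldAssignment, path: str | Path) -> None:
    pd.DataFrame({"Id": ids, "fold": assignment.fold_of_sample}).to_csv(path, index=False)


def write_dedup_report(records: list[DedupRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.removed_id, r.kept_id, r.hamming) for r in records],
        columns=["removed_id", "kept_id", "hamming"],
    ).to_csv(path, index=False)


def write_predictions_csv(ids: list[str], probs: np.ndarray, path: str | Path) -> None:
    """Prediction matrix as ``Id`` plus one probability column per class."""
    probs = np.asarray(probs, dtype=float)
    cols = {f"class_{c}": probs[:, c] for c in range(probs.shape[1])}
    pd.DataFrame({"Id": ids, **cols}).to_csv(path, index=False)


def read_predictions_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, dtype={"Id": str})
    class_cols = [c for c in df.columns if c.startswith("class_")]
    class_cols.sort(key=lambda c: int(c.split("_")[1]))
    return df["Id"].tolist(), df[class_cols].to_numpy(dtype=float)


def write_thresholds_csv(thresholds: ThresholdVector, path: str | Path) -> None:
    pd.DataFrame(
        {
            "class_index": np.arange(len(thresholds.thresholds)),
            "threshold": thresholds.thresholds,
        }
    ).to_csv(path, index=False)


def read_thresholds_csv(path: str | Path) -> ThresholdVector:
    df = pd.read_csv(path).sort_values("class_index")
    return ThresholdVector(df["threshold"].to_numpy(dtype=float))


def write_submission_csv(ids: list[str], predictions: np.ndarray, path: str | Path) -> None:
    """Challenge submission: ``Id,Predicted`` with space-separated class
    indices (empty string when no class passes its threshold)."""
    predictions = np.asarray(predictions).astype(bool)
    rows = [
        (sid, " ".join(str(c) for c in np.flatnonzero(row)))
        for sid, row in zip(ids, predictions)
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Id", "Predicted"])
        writer.writerows(rows)
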