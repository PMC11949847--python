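"""File I/O: recordings as CSV, images as PNG, datasets via a manifest.

Recording CSV dialect: header ``time,<sensor_1>,...,<sensor_n>`` using the
instrument sensor names, one row per timepoint. The manifest CSV lists
``sample_id, grade, recording_path, image_path`` relative to its own
directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .simulate import EnoseRecording, ImageSample, SyntheticConfig


def write_recording_csv(recording: EnoseRecording, path) -> None:
    df = pd.DataFrame({"time": recording.times})
    for i, name in enumerate(recording.sensor_names):
        df[name] = recording.voltages[i]
    df.to_csv(path, index=False)


def read_recording_csv(
    path, phase_boundaries=(200.0, 240.0, 300.0), grade: str = "unknown"
) -> EnoseRecording:
    df = pd.read_csv(path)
    names = tuple(c for c in df.columns if c != "time")
    return EnoseRecording(
        times=df["time"].to_numpy(),
        voltages=df[list(names)].to_numpy().T,
        sensor_names=names,
        phase_boundaries=tuple(phase_boundaries),
        grade=grade,
    )


def write_image_png(image: ImageSample, path) -> None:
    iio.imwrite(path, (np.clip(image.pixels, 0, 1) * 255).round().astype(np.uint8))


def read_image(path, grade: str = "unknown", product: str = "capsule") -> ImageSample:
    arr = iio.imread(path).astype(float) / 255.0
    return ImageSample(pixels=arr[..., :3], grade=grade, product=product)


def write_dataset(
    config: SyntheticConfig,
    recordings: list[EnoseRecording],
    images: list[ImageSample],
    labels: list[str],
    out_dir,
) -> Path:
    """Persist a simulated dataset; returns the manifest path."""
    out = Path(out_dir)
    (out / "recordings").mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (rec, img, grade) in enumerate(zip(recordings, images, labels)):
        sid = f"sample_{i:03d}"
        rpath = f"recordings/{sid}.csv"
        ipath = f"images/{sid}.png"
        write_recording_csv(rec, out / rpath)
        write_image_png(img, out / ipath)
        rows.append({"sample_id": sid, "grade": grade,
                     "recording_path": rpath, "image_path": ipath})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path, product: str = "capsule"):
    """Load a dataset written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    recordings, images, labels = [], [], []
    for _, row in df.iterrows():
        recordings.append(
            read_recording_csv(base / row["recording_path"], grade=row["grade"])
        )
        images.append(
            read_image(base / row["image_path"], grade=row["grade"],
                       product=product)
        )
        labels.append(row["grade"])
    return recordings, images, labels


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict()
    return str(x)
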