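"""Readers and writers for the on-disk formats used across the package.

Images are 8-bit RGB PNG; instance label maps are single-channel 16-bit PNG
(TIFF accepted on read); point annotations are CSV with header
``image_id,instance_id,row,col``; configs and manifests are YAML.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "PointPromptSet", "read_instance_map", "write_instance_map",
    "read_image", "write_image", "read_points_csv", "write_points_csv",
]


@dataclass
class PointPromptSet:
    """One point annotation per nucleus instance.

    ``coords`` is (K, 2) int in (row, col); ``instance_ids`` is (K,) int and
    pairs each point with its instance label.
    """

    coords: np.ndarray
    instance_ids: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        self.instance_ids = np.asarray(self.instance_ids, dtype=np.int64).reshape(-1)
        if len(self.coords) != len(self.instance_ids):
            raise ValueError("coords and instance_ids length mismatch")

    def __len__(self) -> int:
        return len(self.coords)


def read_image(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    return img[..., :3]


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def read_instance_map(path: str | Path) -> np.ndarray:
    """Read a 16-bit single-channel label image; ids preserved verbatim."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: instance maps must be single-channel, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: instance maps must be integer-typed, got {arr.dtype}")
    return arr.astype(np.int32)


def write_instance_map(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("instance ids must fit in uint16")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, labels.astype(np.uint16))
    else:
        iio.imwrite(path, labels.astype(np.uint16))


def write_points_csv(path: str | Path,
                     rows: list[tuple[str, int, int, int]]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "instance_id", "row", "col"])
        w.writerows(rows)


def read_points_csv(path: str | Path) -> dict[str, PointPromptSet]:
    """Parse a point-annotation CSV, grouped by image.

    Raises on a malformed row (naming the line) or a duplicate instance_id
    within an image.
    """
    groups: dict[str, list[tuple[int, int, int]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["image_id", "instance_id", "row", "col"]:
            raise ValueError(f"{path}: expected header image_id,instance_id,row,col")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                image_id, iid, r, c = row[0], int(row[1]), int(row[2]), int(row[3])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {row!r}") from exc
            groups.setdefault(image_id, []).append((iid, r, c))
    out = {}
    for image_id, pts in groups.items():
        ids = [p[0] for p in pts]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{path}: duplicate instance_id within image {image_id!r}")
        out[image_id] = PointPromptSet(
            coords=np.array([(r, c) for _, r, c in pts], dtype=np.int64).reshape(-1, 2),
            instance_ids=np.array(ids, dtype=np.int64),
        )
    return out
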