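"""Synthetic H&E-like nuclei patches with ground truth and point annotations.

Generates small RGB tissue patches containing clustered, elongated and
overlapping elliptical nuclei rendered darker than the background, together
with a flat instance label map (later-drawn nucleus wins contested pixels),
per-nucleus centroid coordinates and one point annotation per nucleus that
may be jittered uniformly within a disc of configurable radius — the "Shift"
protocol used to study robustness to imprecise clicks.

All coordinates are (row, col), 0-based, pixel-center convention.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .io import PointPromptSet, write_image, write_instance_map, write_points_csv

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "SynthSample", "generate_sample", "jitter_prompts", "make_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic patch generator.

    ``radius_range`` is the equivalent circular radius in pixels; an ellipse
    with axis ratio e drawn from ``elongation_range`` gets semi-axes
    (r*sqrt(e), r/sqrt(e)) so elongation preserves area. ``cluster_fraction``
    is the proportion of nuclei deliberately placed adjacent to (possibly
    overlapping) an earlier nucleus. ``point_shift_max`` is the annotation
    jitter radius in pixels (0 = clicks exactly at centroids, 8 = "Shift 8").
    """

    image_size: tuple[int, int] = (128, 128)
    n_nuclei_range: tuple[int, int] = (10, 14)
    radius_range: tuple[float, float] = (4.0, 9.0)
    elongation_range: tuple[float, float] = (1.0, 4.0)
    cluster_fraction: float = 0.3
    texture_noise_sd: float = 8.0
    stain_palette: tuple[tuple[int, int, int], tuple[int, int, int]] = (
        (96, 64, 150),    # nuclear chromatin (hematoxylin-like)
        (228, 180, 200),  # background stroma (eosin-like)
    )
    boundary_wobble: float = 0.10
    point_shift_max: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.radius_range[0] < 2:
            raise ValueError("minimum nucleus radius must be >= 2 px")
        if not (0 <= self.cluster_fraction <= 1):
            raise ValueError("cluster_fraction must lie in [0, 1]")
        if self.elongation_range[0] < 1:
            raise ValueError("elongation (axis ratio) must be >= 1")
        if self.point_shift_max < 0:
            raise ValueError("point_shift_max must be >= 0")

    def hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class SynthSample:
    """One synthetic patch: image, instance ground truth and annotations."""

    image: np.ndarray               # (H, W, 3) uint8
    instances: np.ndarray           # (H, W) int32, 0 = background
    centers: np.ndarray             # (K, 2) int, centroid cell per instance
    prompts: PointPromptSet         # one (possibly jittered) point per instance
    image_id: str = "sample"

    @property
    def n_instances(self) -> int:
        return len(self.centers)


def _render_nucleus(label_map, center, r_eq, elong, theta, wobble, rng):
    """Paint one elliptical nucleus (with harmonic boundary wobble) onto the
    label map, overwriting whatever was there (later instance wins)."""
    H, W = label_map.shape
    a = r_eq * np.sqrt(elong)   # semi-major
    b = r_eq / np.sqrt(elong)   # semi-minor
    pad = int(np.ceil(a * (1 + wobble) + 2))
    r0, r1 = max(0, int(center[0]) - pad), min(H, int(center[0]) + pad + 1)
    c0, c1 = max(0, int(center[1]) - pad), min(W, int(center[1]) + pad + 1)
    if r0 >= r1 or c0 >= c1:
        return 0
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy, dx = rr - center[0], cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dy + st * dx) / a
    v = (-st * dy + ct * dx) / b
    radial = np.sqrt(u * u + v * v)
    if wobble > 0:
        ang = np.arctan2(v, u)
        k = rng.integers(2, 5)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.3, 1.0) * wobble
        boundary = 1.0 + amp * np.sin(k * ang + phase)
    else:
        boundary = 1.0
    inside = radial <= boundary
    return inside, (slice(r0, r1), slice(c0, c1))


def generate_sample(config: SynthConfig, index: int = 0) -> SynthSample:
    """Render one synthetic patch.

    Deterministic in (config, index). Nuclei whose placement cannot be
    found within the retry bound, or which end up fully occluded by
    later-drawn neighbours, are dropped (with a logged warning), so the
    sample may carry fewer nuclei than drawn from ``n_nuclei_range``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 977, index)))
    H, W = config.image_size
    lo, hi = config.n_nuclei_range
    n_target = int(rng.integers(lo, hi + 1)) if hi > lo else lo

    label = np.zeros((H, W), dtype=np.int32)

    def radius_along(shape, ang):
        """Boundary distance of an ellipse from its center along ``ang``."""
        _, r_eq, elong, theta = shape
        a, b = r_eq * np.sqrt(elong), r_eq / np.sqrt(elong)
        phi = ang - theta
        return a * b / np.hypot(b * np.cos(phi), a * np.sin(phi))

    shapes = []
    margin = config.radius_range[0]
    for _ in range(n_target):
        r_eq = rng.uniform(*config.radius_range)
        elong = rng.uniform(*config.elongation_range)
        theta = rng.uniform(0, np.pi)
        clustered = shapes and rng.random() < config.cluster_fraction
        cand_shape = (None, r_eq, elong, theta)

        def too_close(cand, others, factor):
            for sh in others:
                d2 = (cand[0] - sh[0][0]) ** 2 + (cand[1] - sh[0][1]) ** 2
                # radius_along's angle convention: cos -> row, sin -> col
                join = np.arctan2(cand[1] - sh[0][1], cand[0] - sh[0][0])
                reach = radius_along(sh, join) + radius_along(cand_shape, join + np.pi)
                if d2 < (factor * reach) ** 2:
                    return True
            return False

        center = None
        for _attempt in range(50):
            if clustered:
                anchor = shapes[rng.integers(len(shapes))]
                ang = rng.uniform(0, 2 * np.pi)
                # tangent to mildly overlapping along the joining direction,
                # as in flat benchmark label maps where adjacent nuclei touch
                # but rarely occlude each other
                gap = rng.uniform(0.85, 1.15) * (
                    radius_along(anchor, ang) + radius_along(cand_shape, ang + np.pi))
                cand = (anchor[0][0] + gap * np.cos(ang), anchor[0][1] + gap * np.sin(ang))
            else:
                cand = (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin))
            if not (margin <= cand[0] < H - margin and margin <= cand[1] < W - margin):
                continue
            # mild overlap with the cluster anchor is intended; deep incidental
            # overlap with any other existing nucleus is not
            others = [sh for sh in shapes if not (clustered and sh is anchor)] \
                if clustered else shapes
            if too_close(cand, others, 0.8 if clustered else 0.9):
                continue
            center = cand
            break
        if center is None:
            logger.warning("placement failed after bounded retries; dropping a nucleus")
            continue
        shapes.append((center, r_eq, elong, theta))

    for k, (center, r_eq, elong, theta) in enumerate(shapes, start=1):
        res = _render_nucleus(label, center, r_eq, elong, theta, config.boundary_wobble, rng)
        if res == 0:
            continue
        inside, window = res
        label[window][inside] = k

    # drop fully occluded instances, relabel contiguously
    survivors = [k for k in range(1, len(shapes) + 1) if np.any(label == k)]
    if len(survivors) < len(shapes):
        logger.warning("%d nuclei fully occluded; dropped", len(shapes) - len(survivors))
    relabel = np.zeros(len(shapes) + 1, dtype=np.int32)
    for new_id, old_id in enumerate(survivors, start=1):
        relabel[old_id] = new_id
    label = relabel[label]

    centers = np.zeros((len(survivors), 2), dtype=np.int64)
    for new_id in range(1, len(survivors) + 1):
        rr, cc = np.nonzero(label == new_id)
        centers[new_id - 1] = (int(np.round(rr.mean())), int(np.round(cc.mean())))

    fg_rgb = np.array(config.stain_palette[0], dtype=np.float64)
    bg_rgb = np.array(config.stain_palette[1], dtype=np.float64)
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = bg_rgb
    fg = label > 0
    # per-nucleus brightness jitter gives mild texture variation between cells
    gain = rng.uniform(0.85, 1.15, size=len(survivors) + 1)
    gain[0] = 1.0
    img[fg] = fg_rgb * gain[label[fg], None]
    img += rng.normal(0.0, config.texture_noise_sd, size=img.shape)
    from scipy.ndimage import gaussian_filter
    img = gaussian_filter(img, sigma=(0.6, 0.6, 0.0))
    img = np.clip(img, 0, 255).astype(np.uint8)

    prompt_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 431, index)))
    base = PointPromptSet(coords=centers.copy(),
                          instance_ids=np.arange(1, len(survivors) + 1))
    prompts = jitter_prompts(base, config.point_shift_max, prompt_rng,
                             image_size=(H, W))
    return SynthSample(image=img, instances=label, centers=centers,
                       prompts=prompts, image_id=f"img_{index:04d}")


def jitter_prompts(prompts: PointPromptSet, shift_max: float,
                   rng: np.random.Generator | int,
                   image_size: tuple[int, int] | None = None) -> PointPromptSet:
    """Displace each point by an integer offset uniform on the disc of radius
    ``shift_max`` (rejection sampling on the integer disc), clipped to image
    bounds. ``shift_max=0`` is the identity."""
    if shift_max < 0:
        raise ValueError("shift_max must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    coords = prompts.coords.copy()
    if shift_max > 0:
        s = int(np.floor(shift_max))
        for i in range(len(coords)):
            while True:
                off = rng.integers(-s, s + 1, size=2)
                if off[0] ** 2 + off[1] ** 2 <= shift_max ** 2:
                    break
            coords[i] += off
    if image_size is not None:
        coords[:, 0] = np.clip(coords[:, 0], 0, image_size[0] - 1)
        coords[:, 1] = np.clip(coords[:, 1], 0, image_size[1] - 1)
    return PointPromptSet(coords=coords, instance_ids=prompts.instance_ids.copy())


def make_dataset(config: SynthConfig, n_images: int, out_dir: str | Path | None = None,
                 overwrite: bool = False) -> tuple[list[SynthSample], dict]:
    """Generate ``n_images`` samples; optionally persist them.

    Layout under ``out_dir``: images/{id}.png (8-bit RGB),
    labels/{id}.png (16-bit instance maps), points.csv, manifest.yaml.
    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.
    """
    samples = [generate_sample(config, i) for i in range(n_images)]
    manifest = {
        "n_images": n_images,
        "config": asdict(config),
        "config_hash": config.hash(),
        "image_ids": [s.image_id for s in samples],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
            raise FileExistsError(f"{out_dir} is not empty; pass overwrite=True")
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "labels").mkdir(parents=True, exist_ok=True)
        rows = []
        for s in samples:
            write_image(out_dir / "images" / f"{s.image_id}.png", s.image)
            write_instance_map(out_dir / "labels" / f"{s.image_id}.png", s.instances)
            for iid, (r, c) in zip(s.prompts.instance_ids, s.prompts.coords):
                rows.append((s.image_id, int(iid), int(r), int(c)))
        write_points_csv(out_dir / "points.csv", rows)
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return samples, manifest
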