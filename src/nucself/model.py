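"""Two-branch surrogate segmentation network.

This module provides, at desk scale, the architectural contract of a
foundation-model segmenter adapted to histology with parameter-efficient
fine-tuning:

* a **frozen base encoder** ``E_base`` (small strided CNN, overall stride 8)
  producing domain-agnostic features ``z_base``;
* an **adapter-augmented encoder** ``E_adapt`` sharing the frozen weights,
  plus per-stage residual bottleneck adapters whose last layer is
  zero-initialized, so ``E_adapt == E_base`` before any update and only the
  adapters ever receive gradients;
* a **prompt-conditioned mask decoder** producing one soft instance mask per
  point prompt; prompts are injected through a fixed sinusoidal positional
  embedding placed at the prompt's feature cell plus a distance-to-prompt
  channel (the prompt encoding itself is non-trainable);
* a **prompt-free dual-head nuclei decoder** predicting a foreground
  probability map B' (sigmoid) and a 2-channel center-offset field D'
  (linear) at image resolution;
* a **projection head** (2-layer MLP, ReLU) with a single learnable,
  L2-normalized **prototype** for instance-aware contrastive learning.

The frozen branch's zero-shot competence is emulated by briefly
pre-training the mask decoder on a handful of fully masked synthetic images
(`pretrain_base`), after which the base encoder and mask decoder are frozen
for the whole weakly supervised run. A backbone-free classical provider
(`classical_base_masks`) is available as an alternative source of base
masks.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import autograd.numpy as anp
import numpy as np
import yaml

from . import nn
from .io import PointPromptSet

__all__ = ["ModelConfig", "FeatureMap", "SurrogateModel", "classical_base_masks"]


@dataclass(frozen=True)
class ModelConfig:
    image_size: tuple[int, int] = (128, 128)
    stem_dim: int = 8
    stage_dims: tuple[int, int, int] = (12, 16, 24)
    feature_stride: int = 8
    trunk_dim: int = 16
    proj_dim: int = 64
    # confidence calibration of the mask branch: foundation-model masks are
    # near-binary, and the entropy-based ignore gate (H > 0.3 keeps only
    # p > ~0.95) presumes that; an unsaturated surrogate would see its whole
    # foreground filtered out
    mask_logit_gain: float = 4.0
    init_seed: int = 0

    @property
    def feature_dim(self) -> int:
        return self.stage_dims[-1]

    def hash(self) -> str:
        return hashlib.sha1(yaml.safe_dump(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class FeatureMap:
    """Encoder output: stride-8 features plus the intermediate pyramid
    (stride 1, 2, 4) used by the decoders as skip connections for
    boundary-level detail."""

    values: np.ndarray           # (feature_dim, H/stride, W/stride)
    stem: np.ndarray             # (stem_dim, H, W)
    skips: tuple = ()            # ((d1, H/2, W/2), (d2, H/4, W/4))
    image: np.ndarray | None = None  # (3, H, W) normalized input
    stride: int = 8


def _sin_embed(coord: float, period: float) -> tuple[float, float]:
    ang = 2.0 * np.pi * coord / period
    return np.sin(ang), np.cos(ang)


class SurrogateModel:
    """Holds two parameter pytrees: ``frozen`` (base encoder + mask decoder
    + fine-bias head) and ``trainable`` (adapters, nuclei decoder,
    projection head, prototype)."""

    def __init__(self, config: ModelConfig = ModelConfig()):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence((config.init_seed, 5150)))
        c = config
        dims = (c.stem_dim,) + c.stage_dims
        enc = {
            "stem": nn.conv_init(rng, c.stem_dim, 3, 3),
            "downs": [nn.conv_init(rng, dims[i + 1], dims[i], 3) for i in range(3)],
        }
        maskdec = {
            "trunk": nn.conv_init(rng, c.trunk_dim, c.feature_dim, 3),
            "mix": nn.conv_init(rng, 16, c.trunk_dim + 5, 1),
            "conv": nn.conv_init(rng, 8, 16, 3),
            "head": nn.conv_init(rng, 1, 8, 1),
            "head_b": np.zeros(1, dtype=np.float32),
            "fine": nn.conv_init(rng, 1, c.stem_dim, 1, scale=0.3),
            # radial prior around the prompt: logit += a - b * dist_px
            "radial": np.array([1.5, 0.35], dtype=np.float32),
        }
        self.frozen = {"enc": enc, "maskdec": maskdec}

        adapters = []
        for d in dims:
            mid = max(2, d // 2)
            adapters.append({
                "down": nn.conv_init(rng, mid, d, 1),
                "up": nn.conv_init(rng, d, mid, 1, zero=True),  # identity at init
            })
        # the two heads share the upsampling trunk but mix stem features
        # separately at full resolution, so the strongly weighted offset
        # regression cannot distort the foreground head's features
        # each scale also sees the downsampled image: the surrogate encoder
        # is random-frozen, so its embeddings are far less informative than
        # a pretrained foundation encoder's would be, and the decoder needs
        # direct access to intensity detail for boundary-accurate offsets
        d1, d2 = c.stage_dims[0], c.stage_dims[1]
        nucdec = {
            "c0": nn.conv_init(rng, 16, c.feature_dim, 3),
            "c1": nn.conv_init(rng, 12, 16 + d2 + 3, 3),
            "c2": nn.conv_init(rng, 8, 12 + d1 + 3, 3),
            "mix_b": nn.conv_init(rng, 8, 8 + c.stem_dim + 3, 1),
            "head_b_w": nn.conv_init(rng, 1, 8, 1),
            "head_b_bias": np.zeros(1, dtype=np.float32),
            "mix_d": nn.conv_init(rng, 10, 8 + 3, 3),
            "head_d_w": nn.conv_init(rng, 2, 10, 1),
            "head_d_bias": np.zeros(2, dtype=np.float32),
        }
        proj = {
            "w1": nn.dense_init(rng, c.feature_dim, c.proj_dim),
            "b1": np.zeros(c.proj_dim, dtype=np.float32),
            "w2": nn.dense_init(rng, c.proj_dim, c.proj_dim),
            "b2": np.zeros(c.proj_dim, dtype=np.float32),
        }
        proto = rng.standard_normal(c.proj_dim).astype(np.float32)
        proto /= np.linalg.norm(proto)
        self.trainable = {"adapters": adapters, "nucdec": nucdec,
                          "proj": proj, "prototype": proto}

    # ---------------- encoders ----------------

    def _check_image(self, image: np.ndarray) -> np.ndarray:
        if image.shape[:2] != self.config.image_size:
            raise ValueError(
                f"image size {image.shape[:2]} != configured {self.config.image_size}")
        x = np.asarray(image, dtype=np.float32) / 255.0 - 0.5
        return np.moveaxis(x, -1, 0)  # (3, H, W)

    def _encode(self, image, adapters, frozen):
        x = self._check_image(image)
        h = nn.relu(nn.conv2d(x, frozen["enc"]["stem"], stride=1))
        if adapters is not None:
            h = h + nn.conv2d(nn.relu(nn.conv2d(h, adapters[0]["down"])), adapters[0]["up"])
        stem = h
        skips = []
        for i, W in enumerate(frozen["enc"]["downs"]):
            h = nn.relu(nn.conv2d(h, W, stride=2))
            if adapters is not None:
                a = adapters[i + 1]
                h = h + nn.conv2d(nn.relu(nn.conv2d(h, a["down"])), a["up"])
            if i < 2:
                skips.append(h)
        return FeatureMap(values=h, stem=stem, skips=tuple(skips), image=x,
                          stride=self.config.feature_stride)

    def encode_base(self, image) -> FeatureMap:
        """Frozen domain-agnostic features z_base."""
        return self._encode(image, None, self.frozen)

    def encode_adapt(self, image, trainable=None, frozen=None) -> FeatureMap:
        """Adapter-augmented features z_adapt. Pass ``trainable`` explicitly
        inside an autograd-traced loss so gradients reach the adapters."""
        t = self.trainable if trainable is None else trainable
        f = self.frozen if frozen is None else frozen
        return self._encode(image, t["adapters"], f)

    # ---------------- decoders ----------------

    def _prompt_channels(self, prompts: PointPromptSet):
        """Fixed (non-trainable) conditioning: 4 sinusoidal-position channels
        written at the prompt's feature cell + 1 normalized distance channel."""
        c = self.config
        H, W = c.image_size
        h, w = H // c.feature_stride, W // c.feature_stride
        K = len(prompts)
        cond = np.zeros((K, 5, h, w), dtype=np.float32)
        rr, cc = np.mgrid[0:h, 0:w]
        for k, (pr, pc) in enumerate(prompts.coords):
            if not (0 <= pr < H and 0 <= pc < W):
                raise ValueError(f"prompt ({pr},{pc}) outside image {H}x{W}")
            fr, fc = pr / c.feature_stride, pc / c.feature_stride
            sr, cr_ = _sin_embed(pr, H)
            sc, cc_ = _sin_embed(pc, W)
            ir, ic = min(h - 1, int(round(fr))), min(w - 1, int(round(fc)))
            cond[k, 0, ir, ic] = sr
            cond[k, 1, ir, ic] = cr_
            cond[k, 2, ir, ic] = sc
            cond[k, 3, ir, ic] = cc_
            cond[k, 4] = np.sqrt((rr - fr) ** 2 + (cc - fc) ** 2) / max(h, w)
        return cond

    def decode_masks(self, features: FeatureMap, prompts: PointPromptSet,
                     frozen=None):
        """One soft mask in [0,1] per prompt: (K, H, W).

        Per-prompt coarse logits at feature resolution are bilinearly
        upsampled and refined by a shared full-resolution bias map computed
        from the stem features; decoder weights are frozen after
        pre-training.
        """
        if len(prompts) < 1:
            raise ValueError("decode_masks requires at least one prompt")
        f = self.frozen if frozen is None else frozen
        md = f["maskdec"]
        H, W = self.config.image_size
        trunk = nn.relu(nn.conv2d(features.values, md["trunk"]))
        cond = self._prompt_channels(prompts)
        K = cond.shape[0]
        trunk_k = anp.repeat(trunk[None], K, axis=0)
        x = anp.concatenate([trunk_k, cond], axis=1)
        x = nn.relu(nn.conv2d(x, md["mix"]))
        x = nn.relu(nn.conv2d(x, md["conv"]))
        coarse = nn.conv2d(x, md["head"], md["head_b"])[:, 0]       # (K, h, w)
        fine = nn.conv2d(features.stem, md["fine"])[0]              # (H, W)
        rr, cc = np.mgrid[0:H, 0:W]
        dist = np.sqrt(
            (rr[None] - prompts.coords[:, 0, None, None]) ** 2
            + (cc[None] - prompts.coords[:, 1, None, None]) ** 2
        ).astype(np.float32)                                        # (K, H, W)
        radial = md["radial"][0] - md["radial"][1] * dist
        logits = nn.upsample_bilinear(coarse, (H, W)) + fine[None] + radial
        return nn.sigmoid(self.config.mask_logit_gain * logits)

    def decode_nuclei(self, features: FeatureMap, trainable=None):
        """Prompt-free dual head: (B', D') with B' in [0,1] at (H, W) and D'
        linear at (2, H, W)."""
        t = self.trainable if trainable is None else trainable
        nd = t["nucdec"]
        H, W = self.config.image_size
        skip1, skip2 = features.skips  # stride 2 and stride 4
        img = features.image
        img2 = nn.upsample_bilinear(img, (H // 2, W // 2))
        img4 = nn.upsample_bilinear(img, (H // 4, W // 4))
        h = nn.relu(nn.conv2d(features.values, nd["c0"]))
        h = nn.upsample_bilinear(h, (H // 4, W // 4))
        h = nn.relu(nn.conv2d(anp.concatenate([h, skip2, img4], axis=0), nd["c1"]))
        h = nn.upsample_bilinear(h, (H // 2, W // 2))
        h = nn.relu(nn.conv2d(anp.concatenate([h, skip1, img2], axis=0), nd["c2"]))
        h = nn.upsample_bilinear(h, (H, W))
        hb = nn.relu(nn.conv2d(anp.concatenate([h, features.stem, img], axis=0),
                               nd["mix_b"]))
        B = nn.sigmoid(nn.conv2d(hb, nd["head_b_w"], nd["head_b_bias"])[0])
        hd = nn.relu(nn.conv2d(anp.concatenate([h, img], axis=0), nd["mix_d"]))
        D = nn.conv2d(hd, nd["head_d_w"], nd["head_d_bias"])
        return B, D

    def project_points(self, features: FeatureMap, coords, trainable=None):
        """L2-normalized d-vectors of the projected features at image-space
        (row, col) coords: (N, d). Gradients flow into the adapters through
        the bilinearly sampled features."""
        t = self.trainable if trainable is None else trainable
        coords = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
        H, W = self.config.image_size
        if np.any(coords < 0) or np.any(coords[:, 0] > H - 1) or np.any(coords[:, 1] > W - 1):
            raise ValueError("projection coords outside image bounds")
        feat_coords = coords / self.config.feature_stride
        v = nn.bilinear_sample(features.values, feat_coords)
        p = t["proj"]
        hdn = nn.relu(nn.linear(v, p["w1"], p["b1"]))
        return nn.l2_normalize(nn.linear(hdn, p["w2"], p["b2"]), axis=-1)

    def prototype(self, trainable=None):
        t = self.trainable if trainable is None else trainable
        return nn.l2_normalize(t["prototype"], axis=-1)

    # ---------------- base-mask pre-training ----------------

    def pretrain_base(self, samples, epochs: int = 25, lr: float = 3e-3,
                      seed: int = 0) -> None:
        """Emulate the zero-shot competence of a frozen foundation segmenter:
        briefly fit the mask decoder (only) on a handful of fully masked
        images, then freeze it. Deliberately short so base masks remain
        imperfect, the way zero-shot masks on out-of-domain tissue are."""
        from autograd import grad

        feats = [self.encode_base(s.image) for s in samples]
        targets = []
        for s in samples:
            tg = np.stack([(s.instances == iid).astype(np.float32)
                           for iid in s.prompts.instance_ids])
            targets.append(tg)

        def loss_fn(maskdec, feat, prompts, target):
            frozen = {"enc": self.frozen["enc"], "maskdec": maskdec}
            m = self.decode_masks(feat, prompts, frozen=frozen)
            mc = anp.clip(m, 1e-7, 1 - 1e-7)
            bce = -anp.mean(target * anp.log(mc) + (1 - target) * anp.log(1 - mc))
            # soft-IoU balances the ~3% foreground so masks do not collapse
            # to the background-everywhere solution
            inter = anp.sum(m * target, axis=(1, 2))
            union = anp.sum(m, axis=(1, 2)) + target.sum(axis=(1, 2)) - inter
            iou = anp.mean(1.0 - (inter + 1e-7) / (union + 1e-7))
            return bce + iou

        g = grad(loss_fn)
        params = self.frozen["maskdec"]
        opt = nn.AdamW(params, lr=lr)
        order = np.arange(len(samples))
        rng = np.random.default_rng(seed)
        for _ep in range(epochs):
            rng.shuffle(order)
            for i in order:
                grads = g(params, feats[i], samples[i].prompts, targets[i])
                params = opt.step(params, grads)
        self.frozen["maskdec"] = params

    # ---------------- persistence ----------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        flat = nn.tree_flatten_values({"frozen": self.frozen, "trainable": self.trainable})
        meta = yaml.safe_dump({"format": "nucself-checkpoint-v1",
                               "config": asdict(self.config),
                               "config_hash": self.config.hash()})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **flat)

    @classmethod
    def load(cls, path: str | Path) -> "SurrogateModel":
        data = np.load(Path(path))
        meta = yaml.safe_load(bytes(data["__meta__"]).decode())
        if meta.get("format") != "nucself-checkpoint-v1":
            raise ValueError("unrecognized checkpoint format")
        cfg = meta["config"]
        cfg["image_size"] = tuple(cfg["image_size"])
        cfg["stage_dims"] = tuple(cfg["stage_dims"])
        model = cls(ModelConfig(**cfg))

        def fill(tree, prefix):
            if isinstance(tree, dict):
                return {k: fill(v, f"{prefix}{k}.") for k, v in tree.items()}
            if isinstance(tree, list):
                return [fill(v, f"{prefix}{i}.") for i, v in enumerate(tree)]
            return data[prefix[:-1]]

        model.frozen = fill(model.frozen, "frozen.")
        model.trainable = fill(model.trainable, "trainable.")
        return model

    def frozen_checksum(self) -> str:
        flat = nn.tree_flatten_values(self.frozen)
        h = hashlib.sha1()
        for k in sorted(flat):
            h.update(k.encode())
            h.update(np.ascontiguousarray(flat[k]).tobytes())
        return h.hexdigest()


def classical_base_masks(image: np.ndarray, prompts: PointPromptSet,
                         max_radius: float = 24.0,
                         smooth_sigma: float = 1.0) -> np.ndarray:
    """Backbone-free base-mask provider: per prompt, the dark connected
    region containing the point (Otsu threshold on a local window), limited
    to ``max_radius``, returned as a softened probability mask (K, H, W)."""
    from scipy import ndimage
    from skimage.filters import threshold_otsu

    gray = np.asarray(image, dtype=np.float64).mean(axis=-1)
    H, W = gray.shape
    out = np.zeros((len(prompts), H, W), dtype=np.float32)
    rr, cc = np.mgrid[0:H, 0:W]
    for k, (pr, pc) in enumerate(prompts.coords):
        r0, r1 = max(0, pr - 32), min(H, pr + 33)
        c0, c1 = max(0, pc - 32), min(W, pc + 33)
        win = gray[r0:r1, c0:c1]
        try:
            th = threshold_otsu(win)
        except ValueError:
            continue
        dark = gray < th
        dark &= (rr - pr) ** 2 + (cc - pc) ** 2 <= max_radius ** 2
        lab, _ = ndimage.label(dark)
        if lab[pr, pc] == 0:
            # prompt fell on a bright pixel (jitter); take the nearest dark blob
            continue
        hard = (lab == lab[pr, pc]).astype(np.float32)
        soft = ndimage.gaussian_filter(hard, smooth_sigma)
        out[k] = np.clip(0.05 + 0.9 * soft, 0.0, 1.0)
    return out
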