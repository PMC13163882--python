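"""Training objectives, all ignore-mask aware.

Four terms enter the total objective:

* ``L_P`` — per-instance BCE + soft-IoU between the adapted prompt-guided
  masks and the prompt-stage pseudo-label;
* ``L_B`` — the same BCE + soft-IoU on the prompt-free foreground map
  against the instance-stage binary target;
* ``L_D`` — L1 regression of the 2-channel center-offset field;
* ``L_C`` — instance-aware InfoNCE: prompt-anchored embeddings are pulled
  toward a single learnable prototype and pushed from hard-negative
  background embeddings (background pixels the foreground head scores
  > 0.7), up to 100 negatives per batch.

Every term excludes ignore pixels; ternary targets use the conventions of
:mod:`nucself.pseudolabel` (FG=1, BG=0, IGNORE=-1). Total:
``lambda_P*L_P + lambda_B*L_B + lambda_D*L_D + lambda_C*L_C`` with default
weights (1, 1, 5, 1) and temperature 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from .pseudolabel import BG, IGNORE, PseudoLabel

logger = logging.getLogger(__name__)

EPS = 1e-7  # probability clipping inside logs

__all__ = [
    "LossWeights", "prompt_loss", "binary_loss", "distance_loss",
    "mine_hard_negatives", "contrastive_loss", "total_loss",
]


@dataclass(frozen=True)
class LossWeights:
    lambda_P: float = 1.0
    lambda_B: float = 1.0
    lambda_D: float = 5.0
    lambda_C: float = 1.0
    tau: float = 0.1
    hard_neg_thresh: float = 0.7
    max_hard_negs: int = 100

    def __post_init__(self):
        if min(self.lambda_P, self.lambda_B, self.lambda_D, self.lambda_C) < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.tau <= 0:
            raise ValueError("temperature must be positive")


def _masked_bce_iou(pred, target, valid):
    """BCE + soft-IoU over valid pixels.

    BCE averages -[y log p + (1-y) log(1-p)] over valid pixels (p clipped to
    [eps, 1-eps]); the soft-IoU loss is 1 - sum(p*y) / (sum p + sum y -
    sum(p*y)), eps-stabilized so a perfect {0,1} match (including the
    all-background one) scores exactly 0.
    """
    v = valid.astype(np.float32)
    n = v.sum()
    if n == 0:
        return 0.0
    y = target.astype(np.float32)
    p_log = anp.clip(pred, EPS, 1 - EPS)
    bce = -anp.sum(v * (y * anp.log(p_log) + (1 - y) * anp.log(1 - p_log))) / n
    inter = anp.sum(v * pred * y)
    union = anp.sum(v * pred) + anp.sum(v * y) - inter
    iou = (inter + EPS) / (union + EPS)
    return bce + (1.0 - iou)


def prompt_loss(m_adapt, S_P: PseudoLabel, instance_ids=None):
    """L_P: mean over instances of masked BCE + soft-IoU between each
    adapted mask and that instance's binary target from S_P. Instances with
    zero valid (non-ignored) pixels are excluded from the mean; if all are
    excluded the loss is 0 (latent-space supervision takes over)."""
    K = m_adapt.shape[0]
    if K < 1:
        raise ValueError("prompt_loss requires at least one instance")
    if instance_ids is None:
        instance_ids = np.arange(1, K + 1)
    valid = S_P.valid
    if valid.sum() == 0:
        logger.warning("all pixels ignored in S_P; L_P = 0")
        return 0.0
    terms = [
        _masked_bce_iou(m_adapt[k], S_P.target_for_instance(int(instance_ids[k])), valid)
        for k in range(K)
    ]
    return sum(terms) / K


def binary_loss(B_prime, B_target):
    """L_B: masked BCE + soft-IoU on the foreground probability map against
    a ternary target."""
    valid = B_target != IGNORE
    if valid.sum() == 0:
        logger.warning("no valid pixels for binary loss; L_B = 0")
        return 0.0
    return _masked_bce_iou(B_prime, (B_target == 1), valid)


def distance_loss(D_prime, D_target, valid):
    """L_D: mean absolute error over valid pixels and both channels."""
    v = valid.astype(np.float32)
    n = v.sum()
    if n == 0:
        logger.warning("no valid pixels for distance loss; L_D = 0")
        return 0.0
    return anp.sum(v[None] * anp.abs(D_prime - D_target)) / (2.0 * n)


def mine_hard_negatives(B_prime: np.ndarray, label: np.ndarray | PseudoLabel,
                        rng: np.random.Generator,
                        thresh: float = 0.7, max_negs: int = 100) -> np.ndarray:
    """Coordinates of up to ``max_negs`` background-labeled pixels with
    foreground probability above ``thresh`` (uniform subsample without
    replacement, deterministic under a fixed rng). Shape (N, 2)."""
    if isinstance(label, PseudoLabel):
        label = label.label
    cand = np.argwhere((np.asarray(B_prime) > thresh) & (label == BG))
    if len(cand) > max_negs:
        idx = rng.choice(len(cand), size=max_negs, replace=False)
        cand = cand[np.sort(idx)]
    return cand


def contrastive_loss(anchors, prototype, negatives, tau: float = 0.1):
    """L_C: InfoNCE with a single positive prototype shared by all anchors
    and a shared pool of negatives.

    anchors: (K, d) unit vectors; prototype: (d,) unit vector; negatives:
    (N, d) unit vectors (N may be 0, in which case the loss is exactly 0).
    """
    K = anchors.shape[0] if hasattr(anchors, "shape") else len(anchors)
    if K == 0:
        logger.warning("no anchors; L_C = 0")
        return 0.0
    s_pos = anp.dot(anchors, prototype) / tau                      # (K,)
    if negatives is None or negatives.shape[0] == 0:
        return 0.0 * anp.sum(s_pos)  # keeps the graph connected; value 0
    s_neg = anp.dot(anchors, anp.transpose(negatives)) / tau       # (K, N)
    z = anp.concatenate([s_pos[:, None], s_neg], axis=1)
    m = anp.max(z, axis=1)
    lse = m + anp.log(anp.sum(anp.exp(z - m[:, None]), axis=1))
    return anp.mean(lse - s_pos)


def total_loss(L_P, L_B, L_D, L_C, weights: LossWeights = LossWeights()):
    """Weighted multi-task objective."""
    return (weights.lambda_P * L_P + weights.lambda_B * L_B
            + weights.lambda_D * L_D + weights.lambda_C * L_C)
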