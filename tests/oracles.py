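"""Independent brute-force evaluators used to cross-check the vectorized
implementations. Everything here is written as literal per-pixel / per-set
loops over the stated decision rules, deliberately sharing no code with the
package."""

import itertools
import math

import numpy as np


def brute_refinement(m_u, B_prime):
    """Per-pixel evaluation of the ignore-mask and consensus logic.

    Returns dict with H, F, M_p, A_fg, A_bg, I_base, M_I computed pixel by
    pixel from the printed inequalities.
    """
    K, H, W = m_u.shape
    out = {k: np.zeros((H, W)) for k in ("H", "F")}
    for k in ("M_p", "A_fg", "A_bg", "I_base", "M_I"):
        out[k] = np.zeros((H, W), dtype=bool)
    for i in range(H):
        for j in range(W):
            probs = [m_u[k, i, j] for k in range(K)]
            p = max(probs)
            h = 0.0
            for q in (p, 1.0 - p):
                if q > 0.0:
                    h -= q * math.log(q)
            f = sum(1 for q in probs if q > 0.5)
            b = B_prime[i, j]
            out["H"][i, j] = h
            out["F"][i, j] = f
            out["M_p"][i, j] = (h > 0.3) or (f >= 2)
            out["A_fg"][i, j] = (p > 0.5) and (b > 0.7) and (f < 2)
            out["A_bg"][i, j] = (p < 0.2) and (b < 0.3)
            out["I_base"][i, j] = (h > 0.3) or ((p > 0.5) != (b > 0.5))
            in_union = out["I_base"][i, j] or (f >= 2)
            in_consensus = out["A_fg"][i, j] or out["A_bg"][i, j]
            out["M_I"][i, j] = in_union and not in_consensus
    return out


def brute_dice(pred, gt):
    p = np.asarray(pred, dtype=bool)
    g = np.asarray(gt, dtype=bool)
    inter = 0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            inter += int(p[i, j] and g[i, j])
    denom = int(p.sum()) + int(g.sum())
    return 1.0 if denom == 0 else 2.0 * inter / denom


def brute_aji(pred, gt):
    """Greedy best-IoU matching with used-prediction exclusion, computed by
    materializing every mask pair."""
    gt_ids = sorted(int(g) for g in np.unique(gt) if g > 0)
    pred_ids = sorted(int(p) for p in np.unique(pred) if p > 0)
    if not gt_ids and not pred_ids:
        return 1.0
    if not gt_ids or not pred_ids:
        return 0.0
    used = set()
    I = U = 0
    for g in gt_ids:
        gm = gt == g
        best_iou, best_p = 0.0, None
        for p in pred_ids:
            if p in used:
                continue
            pm = pred == p
            inter = int(np.sum(gm & pm))
            if inter == 0:
                continue
            iou = inter / int(np.sum(gm | pm))
            if iou > best_iou:  # strict: ties keep the lowest id
                best_iou, best_p = iou, p
        if best_p is None:
            U += int(gm.sum())
        else:
            pm = pred == best_p
            I += int(np.sum(gm & pm))
            U += int(np.sum(gm | pm))
            used.add(best_p)
    for p in pred_ids:
        if p not in used:
            U += int(np.sum(pred == p))
    return I / U


def brute_prompt_label(m_u, M_p):
    """Literal per-pixel assembly of the prompt-stage ternary label."""
    K, H, W = m_u.shape
    label = np.full((H, W), -1, dtype=np.int8)
    assign = np.zeros((H, W), dtype=np.int32)
    for i in range(H):
        for j in range(W):
            if M_p[i, j]:
                continue
            probs = [m_u[k, i, j] for k in range(K)]
            p = max(probs)
            if p > 0.5:
                label[i, j] = 1
                assign[i, j] = probs.index(p) + 1
            elif p < 0.5:
                label[i, j] = 0
    return label, assign


def brute_contrastive(anchors, proto, negatives, tau):
    """Literal evaluation of the InfoNCE ratio, one anchor at a time."""
    total = 0.0
    for q in anchors:
        num = math.exp(float(np.dot(q, proto)) / tau)
        den = num
        for n in negatives:
            den += math.exp(float(np.dot(q, n)) / tau)
        total += -math.log(num / den)
    return total / len(anchors)
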