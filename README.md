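# nucself

Weakly supervised nuclei instance segmentation from point annotations,
with self-refining pseudo-labels.

Pixel-accurate nuclei masks are the scarcest resource in computational
pathology: a single H&E patch can hold hundreds of nuclei, and instance
metrics punish every merged or missed cell. `nucself` trains an instance
segmenter from the cheapest practical annotation — **one point click per
nucleus** — by letting the model refine its own training targets instead of
freezing them at the noisy initial guess.

The method couples three mechanisms:

* **Self-evolving EMA pseudo-labels.** A frozen base branch provides
  initial per-instance masks `m_base`; a branch with trainable adapters
  produces `m_adapt`. Targets are built from the blend
  `m_u = alpha_t * m_base + (1 - alpha_t) * m_adapt` with `alpha_t =
  max(0, 1 - t/T)`, shifting trust from the stable zero-shot masks to the
  domain-adapted ones as training proceeds.
* **Hierarchical consensus filtering.** Per-pixel ternary labels
  (foreground / background / **ignore**) exclude uncertain pixels — high
  binary entropy (`H > 0.3`), multi-instance claims (`F >= 2`), or
  disagreement between the prompt-guided and prompt-free branches — and
  then *recover* pixels on which both branches confidently agree
  (`A_fg`, `A_bg`), so the prompt-free decoder trains on a denser signal
  than conservative filtering alone would leave.
* **Instance-aware contrastive learning.** Embeddings sampled at the point
  prompts are pulled toward a single learnable prototype and pushed from
  hard negatives (background pixels scored > 0.7 foreground), an InfoNCE
  with temperature 0.1 that supplies gradient even where every dense label
  has been filtered out.

Inference needs no prompts: a dual-head decoder predicts a foreground map
`B'` and a center-offset field `D'`; seeds (low `|D'|` inside foreground)
grow by marker-based watershed on `-B'`. Evaluation reports Dice and the
Aggregated Jaccard Index (AJI).

Everything runs on one CPU with a small numpy/autograd surrogate backbone
that preserves the frozen-encoder + adapters contract, and a synthetic
H&E-like benchmark (clustered, elongated, overlapping nuclei with per-
nucleus point annotations, optionally jittered 0–8 px) generated by the
package itself — no downloads, no GPU. See `docs/methods.md` for the model
and all design choices.

## Worked example

```python
import numpy as np
from nucself import SynthConfig, generate_sample, fit, TrainConfig, predict, evaluate

# 20 synthetic 128 px patches, ~12 nuclei each, one point per nucleus
train = [generate_sample(SynthConfig(seed=100), i) for i in range(20)]
test  = [generate_sample(SynthConfig(seed=777), i) for i in range(5)]

model, history = fit(train, TrainConfig(total_epochs=15, mode="full", seed=0))
report = evaluate([predict(model, s.image) for s in test],
                  [s.instances for s in test])
print(f"Dice={report.dice:.3f}  AJI={report.aji:.3f}")
print(history[["epoch", "alpha_t", "frac_Mp", "frac_MI"]].tail(3).to_string(index=False))
```

Output from this exact script:

```
Dice=0.937  AJI=0.451
 epoch  alpha_t  frac_Mp  frac_MI
    12 0.200000 0.039978 0.035312
    13 0.133333 0.039011 0.034851
    14 0.066667 0.038086 0.034515
```

`fit` never reads the ground-truth instance maps — only images and prompts;
`evaluate` alone touches ground truth. The last columns show the
self-refinement at work: the instance-stage ignore fraction (`frac_MI`)
ends *below* the conservative prompt-stage one (`frac_Mp`) because the
cross-branch consensus recovers pixels that entropy and overlap filtering
had discarded. At the full benchmark scale (100 training images, 3 seeds)
the self-refining mode reaches mean Dice ≈ 0.93 / AJI ≈ 0.55 and
consistently leads the static-pseudo-label baseline.

A command-line interface covers the same pipeline end to end:

```bash
nucself simulate --out data --n-images 20 --seed 0
nucself train    --data data --out run --mode full --seed 0
nucself infer    --checkpoint run/checkpoint.npz --images data/images --out pred
nucself evaluate --pred pred --gt data/labels --out report.json
nucself refine-labels --mu mu.npy --bprime b.npy --out refined   # one-shot filtering
```

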