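# Methods

`nucself` trains a nuclei instance segmenter for tissue-image patches from
the weakest practical supervision — one point click per nucleus — by letting
the model refine its own training targets. This note documents the model,
the surrogate architecture, the synthetic benchmark, and the numerical and
design choices a maintainer would want to know about.

## The training problem

Given an RGB patch `I` and point prompts `P = {p_1..p_K}` (one per
nucleus), no pixel-accurate masks are available. Supervision is
manufactured in three coupled stages:

**Self-evolving EMA labels.** Two encoders share frozen weights: the base
encoder `E_base` and an adapter-augmented copy `E_adapt` in which only small
zero-initialized residual bottlenecks train. A frozen prompt-conditioned
mask decoder turns either embedding into per-instance soft masks: `m_base`
(cached once; the "zero-shot" masks) and `m_adapt` (evolving). The labeling
prediction is the convex blend

    m_u = alpha_t * m_base + (1 - alpha_t) * m_adapt,

with `alpha_t = max(0, 1 - t/T)` decaying linearly over the run (constant,
exponential `gamma^(10 t/T)` and step-wise hold-then-switch schedules are
implemented for comparison). Early training leans on the stable but noisy
frozen masks; late training trusts the adapted ones.

**Ternary labels with ignore masks.** Per-pixel targets take three values
(foreground / background / ignore); ignored pixels are excluded from every
loss term. The prompt-stage label `S_P` ignores pixels with high entropy or
multi-instance claims:

    M_p(j) = [H(j) > 0.3] or [F(j) >= 2],

where `H(j)` is the binary entropy (natural log) of `p(j) = max_k m_u,k(j)`
and `F(j)` counts instances with `m_u,k(j) > 0.5`. The instance-stage label
`S_I` starts from the stricter set `I_base` (high entropy or disagreement
between the prompt-guided foreground claim `max m_u > 0.5` and the
prompt-free one `B' > 0.5`) but *recovers* pixels on which both branches
confidently agree:

    A_fg = {max m_u > 0.5 and B' > 0.7 and F < 2}
    A_bg = {max m_u < 0.2 and B' < 0.3}
    M_I  = (I_base ∪ {F >= 2}) \ (A_fg ∪ A_bg).

All thresholds and inequality directions are implemented exactly as stated
above and exposed in the `pseudolabel` module; the entropy sum is read as
the two-outcome (foreground vs not) entropy of the per-pixel maximum, the
only bounded reading against which a 0.3 gate is meaningful (max ln 2 ≈
0.693, and the gate passes only p > 0.947 or p < 0.053).

**Losses.** Four ignore-aware terms, weighted 1/1/5/1 with temperature 0.1:
per-instance BCE + soft-IoU between `m_adapt` and `S_P` (`L_P`); the same
form between the prompt-free foreground map `B'` and `S_I`'s binary map
(`L_B`); L1 regression of the 2-channel offset field `D'` (`L_D`),
supervised on foreground pixels only — offsets are undefined elsewhere; and
a prompt-anchored InfoNCE (`L_C`): embeddings sampled at the prompt
coordinates are pulled toward one learnable L2-normalized prototype and
pushed from up to 100 hard negatives — background-labeled pixels the
foreground head scores above 0.7. With no hard negatives the contrastive
ratio is exactly 1 and `L_C = 0`; the term only engages when the model makes
confident background mistakes.

One AdamW optimizer updates adapters, nuclei decoder, projection head and
prototype jointly each step (batch 1), with cosine-annealed learning rate
(period 20 epochs). Pseudo-labels are rebuilt once per epoch from the
cached base masks and the most recent detached model outputs.

## Inference and metrics

Inference is prompt-free: `B'` is thresholded at 0.5; seeds are connected
components (4-adjacency, minimum 3 px) of foreground pixels whose regressed
offset magnitude is below 0.3; a marker-based watershed on `-B'` restricted
to the foreground assigns every foreground pixel to a seed; instances under
10 px are dropped. 4-adjacency for seeds matters: regressed offset fields
interpolate smoothly across the unsupervised interface between touching
nuclei, and 8-adjacency would let one-pixel diagonal low-magnitude bridges
merge the two markers.

Evaluation reports macro Dice on binarized foreground and the Aggregated
Jaccard Index: each ground-truth instance greedily matches the unused
prediction of highest IoU (ties to the lowest id); matched intersections
and unions accumulate, unmatched areas on either side inflate the
denominator. Both metrics are cross-checked in the test suite against
literal per-definition reimplementations.

## Offset-target normalization

The offset target points from each pixel to its instance centroid with a
*relative* magnitude `d / min(r_max, 2.5 * inradius)` (clipped to [-1, 1]).
The inradius clip is deliberate: with the plain max-radius normalization an
axis-ratio-4 nucleus has relative magnitude `1/4 < 0.3` along its entire
minor-axis boundary, so the inference seed region touches the boundary and
merges with a side-by-side neighbour's. The clip keeps the sub-0.3 region
strictly interior for any elongation while leaving it at least ~0.75 of the
inradius wide, comfortably above the 3-px seed minimum. The plain form
(`max_radius`) and a fixed 16-px scale remain available in
`instance_offset_field`. Instances under 3 px have no meaningful centroid
and are excluded from offset supervision with a warning.

## Surrogate backbone

Everything runs on a small CNN stack (numpy + autograd, ~40k parameters)
that preserves the architectural *contract* of a foundation-model segmenter
without its weights:

* frozen randomly initialized encoder: stride-1 stem then three stride-2
  convolutions (overall stride 8, 24 feature channels), intermediate
  stages exposed as skip connections;
* adapters: per-stage residual bottlenecks, final layer zero-initialized so
  `E_adapt == E_base` before the first update; the only trainable encoder
  parameters;
* mask decoder: shared trunk on the stride-8 features; per prompt, a fixed
  sinusoidal positional embedding written at the prompt's feature cell plus
  a distance-to-prompt channel condition a small head whose coarse logits
  are bilinearly upsampled and refined by a shared full-resolution bias map
  and a trainable radial prior; logits pass a fixed gain of 4 before the
  sigmoid, because the 0.3 entropy gate presumes near-binary mask
  confidence (real foundation-model masks are effectively thresholded
  logits);
* nuclei decoder: upsampling trunk with skip connections that also sees
  the bilinearly downsampled image at each scale — the random frozen
  encoder's embeddings carry much less information than a pretrained
  foundation encoder's, and the offset head needs direct intensity detail;
  the foreground and offset heads mix features separately at full
  resolution so the strongly weighted offset regression cannot suppress
  the foreground features;
* projection head: 2-layer MLP (ReLU, 64-d) over bilinearly sampled
  embeddings, L2-normalized, with one learnable prototype.

**Zero-shot emulation.** The frozen branch's competence comes from briefly
pre-training the mask decoder (40 epochs, 14 images, AdamW 3e-3, BCE +
soft-IoU) on fully masked synthetic images drawn from a *shifted* appearance
domain: grayer stain, larger and rounder nuclei, sparse clustering. On the
benchmark domain these base masks reach instance IoU ≈ 0.55–0.65 with
systematic failures on elongated and clustered nuclei — competent but
noisy, which is precisely the regime self-evolving labels address. Without
the shift the static labels are nearly perfect and the static-label
baseline is indistinguishable from the full method. A backbone-free
classical provider (local Otsu + flood fill from the prompt) is available
as an alternative base-mask source.

**Learning rates.** The configured rate (1e-4) is a fine-tuning rate and
applies to the adapters; the from-scratch heads (nuclei decoder, projection,
prototype) train at 20x that rate on the same cosine schedule — at 1e-4
they cannot converge within the desk-scale budget.

**Warm-up.** The cross-branch conflict term in `I_base` only admits
foreground supervision where the prompt-free head already predicts
foreground, so a freshly initialized head can never bootstrap: it would see
background-only targets forever. For the first 5 epochs the instance label
therefore uses the prompt-style ignore mask (entropy + overlap only);
hierarchical consensus filtering takes over once `B'` is calibrated. This
cold-start problem does not arise for a decoder stack inheriting
foundation-model competence.

## Synthetic benchmark

The generator renders H&E-like patches: elliptical nuclei (equivalent
radius 4–9 px, axis ratio up to 4, harmonic boundary wobble) rendered
darker than an eosin-like background with Gaussian texture noise and mild
blur. A configurable fraction (default 0.3) of nuclei is placed tangent to
slightly overlapping an anchor nucleus along the joining direction
(directional ellipse radii, 0.85–1.15 of the touching distance), with a
guard against deep incidental occlusion by non-anchor nuclei — flattened
benchmark label maps have touching, not occluded, instances. Overlaps
resolve to the later-drawn instance. Point annotations sit at the rounded
instance centroid, optionally jittered uniformly on the integer disc of
radius 0–8 px (rejection sampling), the "Shift 0"/"Shift 8" protocol.

Default study conditions: 100 training / 30 held-out test patches of
128x128 px, ~12 nuclei each, Shift 0, 15 training epochs. The held-out set
is fixed across runs; the training set, initialization and all stochastic
training choices derive from one run seed fanned out through independent
`SeedSequence` streams, so runs are bit-reproducible.

What the generator does *not* emulate: real stain physics and
scanner/batch variation, texture inside nuclei and stroma, nucleoli and
chromatin structure, out-of-focus regions, mitotic figures, and true
transparent overlap of nuclei in thick sections. Passing the synthetic
benchmark shows the training mechanics work as designed — labels refine,
ignored regions shrink, instances separate — not that the surrogate would
match reported real-data scores.

## Numerical choices

* Probabilities are clipped to [1e-7, 1 - 1e-7] inside logs; the soft-IoU
  ratio is eps-stabilized so a perfect {0,1} match scores exactly 0 even
  with an empty target.
* Ties in the instance-assignment argmax go to the lowest instance index;
  the watershed runs on a fixed priority field with scan-ordered markers,
  so the pixel partition is order-independent.
* An instance whose prompt-stage target has no valid pixels contributes 0
  to `L_P` and is excluded from its mean; with no valid pixels at all the
  corresponding loss is 0 with a warning (the contrastive term still
  provides gradient).
* Convolutions are single autograd primitives with hand-written
  vector-Jacobian products (shift-and-slice accumulation); bilinear
  resampling is two precomputed interpolation matrices, making the whole
  network differentiable at useful CPU speed in float32.
* Checkpoints are .npz archives of the flattened parameter tree plus a
  YAML header with the architecture config and its hash.

## Known limitations

* The surrogate's absolute scores are not comparable to foundation-model
  results on real benchmarks; only the *orderings* (self-refining above
  static labels; recovered ignore fractions below prompt-stage ones) and
  the mechanism-level invariants are meaningful.
* Offset fields are unsupervised on ignored interface pixels, so touching
  instances can still merge when the regressed magnitude stays below the
  seed threshold along the whole shared boundary; the 4-adjacent seed rule
  and inradius-clipped normalization mitigate but do not eliminate this.
* The contrastive term is silent (exactly zero) whenever no
  background-labeled pixel exceeds 0.7 foreground probability; on clean
  synthetic data this is most of the time, so its desk-scale effect is
  small.
* Augmentation (flip / rotate / scale / crop) is implemented and tested but
  disabled in the default desk-scale protocol; with 15 epochs on abundant
  synthetic data it costs more than it helps.
* `batch_size` is fixed at 1 (the training protocol this implements);
  larger batches are not supported.
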