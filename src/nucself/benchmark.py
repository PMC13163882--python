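"""The default synthetic benchmark: datasets, training runs and headline
numbers.

Desk-scale study conditions: 100 training and 30 test patches of 128x128 px
with ~12 nuclei each (clustered, elongated, overlapping), precise point
annotations ("Shift 0"), 15 training epochs with the surrogate backbone.
The test set is fixed across runs so seeds differ only in training data,
initialization and stochastic training choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .infer import EvalReport, evaluate, extract_instances, render_oracle_maps
from .synthetic import SynthConfig, generate_sample
from .train import TrainConfig, fit, predict

N_TRAIN = 100
N_TEST = 30
TEST_DATA_SEED = 777

__all__ = ["BenchmarkResult", "make_benchmark_data", "run_benchmark",
           "oracle_upper_bound"]


@dataclass
class BenchmarkResult:
    mode: str
    seed: int
    report: EvalReport
    history: "object"  # pandas DataFrame of per-epoch training metrics


def make_benchmark_data(seed: int, n_train: int = N_TRAIN, n_test: int = N_TEST,
                        image_size: int = 128, point_shift: float = 0.0):
    """Training set varies with ``seed``; test set is the fixed benchmark."""
    train_cfg = SynthConfig(image_size=(image_size, image_size),
                            point_shift_max=point_shift, seed=1000 + seed)
    test_cfg = SynthConfig(image_size=(image_size, image_size),
                           seed=TEST_DATA_SEED)
    train = [generate_sample(train_cfg, i) for i in range(n_train)]
    test = [generate_sample(test_cfg, i) for i in range(n_test)]
    return train, test


def run_benchmark(mode: str, seed: int, total_epochs: int = 15,
                  n_train: int = N_TRAIN, n_test: int = N_TEST,
                  point_shift: float = 0.0) -> BenchmarkResult:
    """Train one model under the stated conditions and evaluate it on the
    fixed test set (ground truth is read only here, for scoring)."""
    train, test = make_benchmark_data(seed, n_train=n_train, n_test=n_test,
                                      point_shift=point_shift)
    cfg = TrainConfig(total_epochs=total_epochs, mode=mode, seed=seed)
    model, history = fit(train, cfg)
    preds = [predict(model, s.image) for s in test]
    report = evaluate(preds, [s.instances for s in test],
                      image_ids=[s.image_id for s in test])
    return BenchmarkResult(mode=mode, seed=seed, report=report, history=history)


def oracle_upper_bound(n_images: int = 20, seed: int = 0) -> EvalReport:
    """Feed the instance extractor ideal dual-head maps rendered from
    ground truth: the post-processing ceiling, no learning involved."""
    cfg = SynthConfig(seed=seed)
    samples = [generate_sample(cfg, i) for i in range(n_images)]
    preds, gts, ids = [], [], []
    for s in samples:
        B, D = render_oracle_maps(s.instances)
        preds.append(extract_instances(B, D))
        gts.append(s.instances)
        ids.append(s.image_id)
    return evaluate(preds, gts, image_ids=ids)
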