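"""Training pipeline for the beam-weight scorer.

Labels come from coverage-optimized plans: each candidate beam of a solved
plan yields one example (feature tensor, ground-truth MU w_g, plan coverage
c_p). Unweighted beams vastly outnumber weighted ones (imbalance ratio w_b =
#unweighted / #weighted, around 19 at full scale), so unweighted examples are
subsampled before training; by default each is kept with probability 1/w_b,
which restores an approximately balanced class mix. Training runs 15 epochs
of Adam (beta1 0.9, beta2 0.999, eps 1e-7) with the learning rate stepped
from 1e-3 to 1e-5 by a factor of 10 every 5 epochs, under the
coverage-weighted piecewise loss. Cross-validation folds are stratified so
the distribution of PTV volumes is similar across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .loss import DESIRED_COVERAGE, loss, loss_gradient
from .nnet import BeamScorer, SmallConvNet


@dataclass
class TrainingExample:
    feature: np.ndarray       # (7, H, W)
    w_g: float                # ground-truth beam weight, MU in [0, 300]
    c_p: float                # coverage of the plan that produced w_g
    phantom_id: int = 0
    ptv_volume_cm3: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_g <= 300.0):
            raise ValueError("w_g must lie in [0, 300] MU")
        if not (0.0 < self.c_p <= 1.0):
            raise ValueError("c_p must lie in (0, 1]")


def measure_imbalance(examples: list[TrainingExample]) -> float:
    """w_b = #unweighted / #weighted, measured from the data."""
    n_w = sum(1 for e in examples if e.w_g > 0)
    if n_w == 0:
        raise ValueError("no weighted examples")
    return (len(examples) - n_w) / n_w


def subsample_training(
    examples: list[TrainingExample],
    w_b: float | None = None,
    seed: int | np.random.Generator = 0,
    mode: str = "keep",
) -> list[TrainingExample]:
    """Rebalance by random subsampling of unweighted (w_g = 0) examples.

    mode="keep" (default): keep each unweighted example with probability
    1/w_b, which yields an approximately 1:1 class mix. mode="drop" is the
    literal alternative reading — drop with probability 1/w_b (keep with
    1 - 1/w_b), which barely rebalances. Weighted examples are always kept.
    """
    if w_b is None:
        # balanced or weighted-heavy data needs no subsampling
        w_b = max(measure_imbalance(examples), 1.0)
    if w_b < 1:
        raise ValueError("w_b must be >= 1")
    if not any(e.w_g > 0 for e in examples):
        raise ValueError("no weighted examples")
    if mode not in ("keep", "drop"):
        raise ValueError("mode must be 'keep' or 'drop'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_keep = 1.0 / w_b if mode == "keep" else 1.0 - 1.0 / w_b
    out = []
    for e in examples:
        if e.w_g > 0 or rng.random() < p_keep:
            out.append(e)
    return out


def stratified_folds(examples: list[TrainingExample], folds: int) -> list[np.ndarray]:
    """Fold index arrays; phantoms dealt round-robin in PTV-volume order so the
    PTV-size distribution is similar in every fold (all examples of a phantom
    stay together)."""
    by_phantom: dict[int, list[int]] = {}
    vol: dict[int, float] = {}
    for i, e in enumerate(examples):
        by_phantom.setdefault(e.phantom_id, []).append(i)
        vol[e.phantom_id] = e.ptv_volume_cm3
    order = sorted(by_phantom, key=lambda p: (vol[p], p))
    assignment = [[] for _ in range(folds)]
    # serpentine dealing in volume order balances the fold means
    for k, pid in enumerate(order):
        cycle, pos = divmod(k, folds)
        fold = pos if cycle % 2 == 0 else folds - 1 - pos
        assignment[fold].extend(by_phantom[pid])
    return [np.sort(np.array(a, dtype=int)) for a in assignment]


def learning_rate(epoch: int, lr0: float = 1e-3) -> float:
    """Step schedule: 1e-3 for epochs 0-4, 1e-4 for 5-9, 1e-5 for 10-14."""
    return lr0 * 10.0 ** (-(epoch // 5))


@dataclass
class FoldResult:
    scorer: BeamScorer
    val_index: np.ndarray
    history: list = field(default_factory=list)   # (epoch, mean training loss)


def _fit(
    examples: list[TrainingExample],
    epochs: int,
    batch_size: int,
    seed: int,
    lr0: float,
    c_des: float,
    widths: tuple,
    feature_config: dict | None,
) -> tuple[BeamScorer, list]:
    if len(examples) < batch_size:
        raise ValueError("fewer training examples than the batch size")
    X = np.stack([e.feature for e in examples]).astype(np.float32)
    y = np.array([e.w_g for e in examples])
    c = np.array([e.c_p for e in examples])
    mean = X.mean(axis=(0, 2, 3))
    std = np.maximum(X.std(axis=(0, 2, 3)), 1e-6)
    Xn = (X - mean[None, :, None, None]) / std[None, :, None, None]

    net = SmallConvNet(c_in=X.shape[1], widths=widths, seed=seed)
    out_scale = BeamScorer.W_MAX  # net regresses w/300; gradients chain through
    rng = np.random.default_rng(seed)
    history = []
    n = len(examples)
    for epoch in range(epochs):
        lr = learning_rate(epoch, lr0)
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            pred = net.forward(Xn[idx], train=True) * out_scale
            losses.append(float(np.mean(loss(pred, y[idx], c[idx], c_des))))
            grad = loss_gradient(pred, y[idx], c[idx], c_des) * out_scale / len(idx)
            net.backward(grad)
            net.adam_step(lr)
        history.append((epoch, float(np.mean(losses))))
    scorer = BeamScorer(net, mean, std, feature_config, seed, output_scale=out_scale)
    return scorer, history


def train(
    examples: list[TrainingExample],
    folds: int = 3,
    epochs: int = 15,
    batch_size: int = 32,
    seed: int = 0,
    lr0: float = 1e-3,
    c_des: float = DESIRED_COVERAGE,
    widths: tuple = (16, 32, 64),
    subsample: bool = True,
    subsample_mode: str = "keep",
    feature_config: dict | None = None,
) -> list[FoldResult]:
    """Train one scorer per cross-validation fold (folds=1: single scorer on all).

    Each fold trains on the other folds' examples after imbalance subsampling;
    ``val_index`` holds the held-out example indices (empty for folds=1).
    """
    if folds < 1:
        raise ValueError("folds must be >= 1")
    if folds == 1:
        fold_indices = [np.array([], dtype=int)]
        train_sets = [list(range(len(examples)))]
    else:
        n_phantoms = len({e.phantom_id for e in examples})
        if n_phantoms < 2 * folds:
            raise ValueError("need at least 2 phantoms per fold")
        fold_indices = stratified_folds(examples, folds)
        train_sets = [
            np.concatenate([fold_indices[j] for j in range(folds) if j != k])
            for k in range(folds)
        ]
    results = []
    for k, tr in enumerate(train_sets):
        subset = [examples[i] for i in tr]
        if subsample:
            subset = subsample_training(subset, seed=seed + 1000 * k, mode=subsample_mode)
        scorer, history = _fit(
            subset, epochs, batch_size, seed + k, lr0, c_des, widths, feature_config
        )
        results.append(FoldResult(scorer, fold_indices[k], history))
    return results
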