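"""Single-convolutional-layer sequence classifier.

Architecture: conv(5-channel one-hot input, n_filters, width L, valid
padding) -> ReLU -> non-overlapping max-pool -> dropout -> dense ->
ReLU -> dense(2) -> softmax, trained with binary cross-entropy. The
network is small enough that forward and backward passes are plain
BLAS matrix products, so the whole stack lives here in numpy; the
first-layer kernels are retrievable as 5 x L ``KernelMatrix`` objects
for downstream motif interpretation.

Training splits follow the published protocol: 20% of genes held out as
test data, 4000 of the remaining genes as a validation set per
cross-validation fold (scaled down proportionally for small datasets),
the rest for training, fivefold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .core import KernelMatrix

logger = logging.getLogger(__name__)

DEFAULT_GRIDS = {
    "filters": (8, 16, 24, 32, 40, 48, 64),
    "widths": (8, 12, 14, 16, 18, 22),
    "pools": (5, 10, 15, 20, 25),
}

# validation genes per fold relative to the post-test pool (4000/16000)
_VAL_POOL_RATIO = 0.25


@dataclass
class ModelConfig:
    n_filters: int = 24
    kernel_width: int = 14
    pool_width: int = 10
    dropout_rate: float = 0.5
    dense_width: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_width < 1:
            raise ValueError("pool_width must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


class ConvNet:
    """The classifier; class index 1 is the expressed class."""

    def __init__(self, cfg: ModelConfig, window_length: int):
        if cfg.kernel_width > window_length:
            raise ValueError(
                f"kernel width {cfg.kernel_width} exceeds window length "
                f"{window_length}"
            )
        self.cfg = cfg
        self.window_length = window_length
        self.conv_out = window_length - cfg.kernel_width + 1
        self.n_blocks = self.conv_out // cfg.pool_width
        if self.n_blocks < 1:
            raise ValueError("pool_width larger than the convolution output")
        rng = np.random.default_rng(cfg.seed)
        L, F, D = cfg.kernel_width, cfg.n_filters, cfg.dense_width
        flat_dim = self.n_blocks * F

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(
                np.float32
            )

        # output layer starts near zero and hidden biases slightly
        # positive: with all-positive pooled features a cold-started
        # softmax collapses the dense ReLU layer onto the constant
        # predictor, cutting every gradient path to the kernels
        self.params = {
            "Wc": he((L * 5, F), L * 5),
            "bc": np.zeros(F, dtype=np.float32),
            "W1": he((flat_dim, D), flat_dim),
            "b1": np.full(D, 0.1, dtype=np.float32),
            "W2": 0.01 * he((D, 2), D),
            "b2": np.zeros(2, dtype=np.float32),
        }

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # ------------------------------------------------------------ forward

    def _conv_windows(self, X: np.ndarray) -> np.ndarray:
        L = self.cfg.kernel_width
        win = sliding_window_view(X, (L, 5), axis=(1, 2))
        return np.ascontiguousarray(win).reshape(X.shape[0], self.conv_out, L * 5)

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict:
        """Full forward pass; returns a cache of intermediates."""
        p = self.params
        n = X.shape[0]
        F, pw = self.cfg.n_filters, self.cfg.pool_width
        flat_windows = self._conv_windows(X.astype(np.float32, copy=False))
        zc = flat_windows @ p["Wc"] + p["bc"]  # (n, conv_out, F)
        ac = np.maximum(zc, 0.0)
        trimmed = ac[:, : self.n_blocks * pw].reshape(n, self.n_blocks, pw, F)
        pool_arg = trimmed.argmax(axis=2)
        pooled = np.take_along_axis(trimmed, pool_arg[:, :, None], axis=2)[
            :, :, 0
        ]
        if train and self.cfg.dropout_rate > 0:
            keep = 1.0 - self.cfg.dropout_rate
            mask = (rng.random(pooled.shape) < keep).astype(np.float32) / keep
            dropped = pooled * mask
        else:
            mask = None
            dropped = pooled
        flat = dropped.reshape(n, -1)
        z1 = flat @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ p["W2"] + p["b2"]
        z2s = z2 - z2.max(axis=1, keepdims=True)
        ez = np.exp(z2s)
        probs = ez / ez.sum(axis=1, keepdims=True)
        return {
            "flat_windows": flat_windows,
            "zc": zc,
            "pool_arg": pool_arg,
            "mask": mask,
            "flat": flat,
            "z1": z1,
            "a1": a1,
            "z2": z2,
            "probs": probs,
        }

    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for i in range(0, X.shape[0], batch):
            out.append(self.forward(X[i : i + batch])["probs"])
        return np.concatenate(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # ----------------------------------------------------------- backward

    def _backward(self, X: np.ndarray, y: np.ndarray, cache: dict) -> dict:
        p = self.params
        n = X.shape[0]
        F, pw = self.cfg.n_filters, self.cfg.pool_width
        dz2 = cache["probs"].copy()
        dz2[np.arange(n), y] -= 1.0
        dz2 /= n
        grads = {
            "W2": cache["a1"].T @ dz2,
            "b2": dz2.sum(axis=0),
        }
        da1 = dz2 @ p["W2"].T
        dz1 = da1 * (cache["z1"] > 0)
        grads["W1"] = cache["flat"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dflat = dz1 @ p["W1"].T
        ddropped = dflat.reshape(n, self.n_blocks, F)
        if cache["mask"] is not None:
            dpooled = ddropped * cache["mask"]
        else:
            dpooled = ddropped
        dac = np.zeros((n, self.n_blocks, pw, F), dtype=np.float32)
        np.put_along_axis(dac, cache["pool_arg"][:, :, None], dpooled[:, :, None], axis=2)
        dac_full = np.zeros((n, self.conv_out, F), dtype=np.float32)
        dac_full[:, : self.n_blocks * pw] = dac.reshape(
            n, self.n_blocks * pw, F
        )
        dzc = dac_full * (cache["zc"] > 0)
        fw = cache["flat_windows"]
        grads["Wc"] = fw.reshape(-1, fw.shape[2]).T @ dzc.reshape(-1, F)
        grads["bc"] = dzc.sum(axis=(0, 1))
        return grads

    # ------------------------------------------------------------ kernels

    def kernels(self, stage: str = "", fold: int = -1) -> list[KernelMatrix]:
        """First-layer kernels as 5 x L matrices (channel order A,T,C,G,N)."""
        L, F = self.cfg.kernel_width, self.cfg.n_filters
        W = self.params["Wc"].reshape(L, 5, F)
        return [
            KernelMatrix(W[:, :, f].T, stage=stage, fold=fold, kernel_index=f)
            for f in range(F)
        ]


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))


def train(
    model: ConvNet,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    lr: float = 1e-3,
    batch_size: int = 64,
    max_epochs: int = 50,
    patience: int = 5,
    seed: int = 0,
) -> dict:
    """Adam + early stopping on validation accuracy; restores best weights."""
    rng = np.random.default_rng(seed)
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_acc, best_params, best_epoch = -1.0, None, -1
    history = []
    n = X_train.shape[0]
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            cache = model.forward(X_train[idx], train=True, rng=rng)
            grads = model._backward(X_train[idx], y_train[idx], cache)
            step += 1
            for k, g in grads.items():
                g = g.astype(np.float32)
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                model.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        val_acc = float(np.mean(model.predict(X_val) == y_val))
        history.append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_epoch = epoch
            best_params = {k: p.copy() for k, p in model.params.items()}
        elif epoch - best_epoch >= patience:
            break
    if best_params is not None:
        model.params = best_params
    return {"val_accuracy": best_acc, "epochs": len(history), "history": history}


# ------------------------------------------------------------- splitting


@dataclass
class Splits:
    test_idx: np.ndarray
    folds: list  # list of (train_idx, val_idx)
    n_val: int


def _stratified_take(
    idx: np.ndarray, y: np.ndarray, n_take: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministically draw n_take items from idx, stratified on y[idx]."""
    taken = []
    classes = np.unique(y[idx])
    fracs = {c: np.mean(y[idx] == c) for c in classes}
    for c in classes:
        pool_c = idx[y[idx] == c]
        k = int(round(n_take * fracs[c]))
        perm = rng.permutation(pool_c)
        taken.append(perm[:k])
    taken = np.concatenate(taken)
    rest = np.setdiff1d(idx, taken)
    return np.sort(taken), rest


def split_train(
    y: np.ndarray,
    test_frac: float = 0.2,
    n_val: int = 4000,
    k: int = 5,
    seed: int = 0,
) -> Splits:
    """Test/validation/training partitions for fivefold cross-validation.

    Stratified on label and deterministic under the seed. If the
    post-test pool is too small to spare ``n_val`` genes, the validation
    size is scaled down to a quarter of the pool (the published ratio)
    with a logged warning.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to build stratified splits")
    rng = np.random.default_rng(seed)
    all_idx = np.arange(len(y))
    n_test = int(round(test_frac * len(y)))
    test_idx, pool = _stratified_take(all_idx, y, n_test, rng)
    n_val_eff = n_val
    if n_val > int(_VAL_POOL_RATIO * len(pool)):
        n_val_eff = int(_VAL_POOL_RATIO * len(pool))
        logger.warning(
            "validation size %d too large for pool of %d; scaled to %d",
            n_val,
            len(pool),
            n_val_eff,
        )
    folds = []
    for f in range(k):
        fold_rng = np.random.default_rng(np.random.SeedSequence((seed, f)))
        val_idx, train_idx = _stratified_take(pool, y, n_val_eff, fold_rng)
        folds.append((train_idx, val_idx))
    return Splits(test_idx=test_idx, folds=folds, n_val=n_val_eff)


# ------------------------------------------------------------ evaluation


@dataclass
class EvalResult:
    accuracy: float
    auroc: float | None
    roc: tuple  # (fpr, tpr)
    confusion: dict
    true_positives: list


def auroc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    """AUROC as the normalized Mann-Whitney rank statistic (midrank ties)."""
    ranks = rankdata(scores)
    n1 = int(np.sum(y == 1))
    n0 = len(y) - n1
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(
    model: ConvNet,
    X: np.ndarray,
    y: np.ndarray,
    gene_ids: list[str] | None = None,
) -> EvalResult:
    """Accuracy, ROC, AUROC and the true-positive gene list.

    True positives are genes whose true label is expressed and that the
    model predicts expressed — the interpretation set. AUROC uses the
    predicted expressed-class probability; with a one-class test set it
    is flagged undefined (None).
    """
    if len(y) == 0:
        raise ValueError("empty test set")
    probs = model.predict_proba(X)
    scores = probs[:, 1]
    pred = probs.argmax(axis=1)
    accuracy = float(np.mean(pred == y))
    confusion = {
        "tp": int(np.sum((pred == 1) & (y == 1))),
        "fp": int(np.sum((pred == 1) & (y == 0))),
        "fn": int(np.sum((pred == 0) & (y == 1))),
        "tn": int(np.sum((pred == 0) & (y == 0))),
    }
    if len(np.unique(y)) < 2:
        auroc, roc = None, (np.array([]), np.array([]))
    else:
        auroc = auroc_rank(scores, y)
        fpr, tpr, _ = roc_curve(y, scores)
        roc = (fpr, tpr)
    tp_mask = (pred == 1) & (y == 1)
    if gene_ids is not None:
        true_positives = [g for g, m in zip(gene_ids, tp_mask) if m]
    else:
        true_positives = list(np.flatnonzero(tp_mask))
    return EvalResult(accuracy, auroc, roc, confusion, true_positives)


# ---------------------------------------------------------- CV and grid


@dataclass
class CvResult:
    config: ModelConfig
    fold_results: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f["accuracy"] for f in self.fold_results]))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    cfg: ModelConfig,
    splits: Splits,
    keep_models: bool = True,
    **train_kwargs,
) -> CvResult:
    """Train one model per fold; fold accuracy/AUROC on the fold's
    validation set."""
    result = CvResult(config=cfg)
    for f, (train_idx, val_idx) in enumerate(splits.folds):
        model = ConvNet(
            ModelConfig(**{**cfg.__dict__, "seed": cfg.seed + f}),
            X.shape[1],
        )
        info = train(
            model,
            X[train_idx],
            y[train_idx],
            X[val_idx],
            y[val_idx],
            seed=cfg.seed + 1000 + f,
            **train_kwargs,
        )
        ev = evaluate(model, X[val_idx], y[val_idx])
        result.fold_results.append(
            {
                "fold": f,
                "model": model if keep_models else None,
                "accuracy": ev.accuracy,
                "auroc": ev.auroc,
                "roc": ev.roc,
                "confusion": ev.confusion,
                "epochs": info["epochs"],
            }
        )
    return result


def enumerate_grid(grids: dict | None = None) -> list[ModelConfig]:
    """Every (filters, width, pool) combination, in grid order."""
    grids = grids or DEFAULT_GRIDS
    return [
        ModelConfig(n_filters=f, kernel_width=w, pool_width=p)
        for f, w, p in itertools.product(
            grids["filters"], grids["widths"], grids["pools"]
        )
    ]


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grids: dict | None = None,
    splits: Splits | None = None,
    seed: int = 0,
    **train_kwargs,
) -> tuple[list[dict], ModelConfig]:
    """Evaluate every grid cell by mean fivefold-CV accuracy.

    Returns the per-cell result table and the argmax configuration;
    ties are broken by fewer trainable parameters, then lower grid
    index. Cells whose training fails are recorded with the error and
    excluded from selection.
    """
    configs = enumerate_grid(grids)
    if splits is None:
        splits = split_train(y, seed=seed)
    table = []
    for idx, cfg in enumerate(configs):
        cfg.seed = seed
        row = {"index": idx, "config": cfg}
        try:
            cv = cross_validate(X, y, cfg, splits, keep_models=False, **train_kwargs)
            row["mean_accuracy"] = cv.mean_accuracy
            row["n_parameters"] = ConvNet(cfg, X.shape[1]).n_parameters
        except Exception as exc:  # recorded per-cell, search continues
            row["error"] = str(exc)
            row["mean_accuracy"] = None
        table.append(row)
    scored = [r for r in table if r.get("mean_accuracy") is not None]
    if not scored:
        raise RuntimeError("every grid cell failed")
    best = min(
        scored,
        key=lambda r: (-r["mean_accuracy"], r["n_parameters"], r["index"]),
    )
    return table, best["config"]
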