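"""Training: orthogonal initialization, Lookahead optimization, data splits.

Weights are initialized orthogonally: each parameter, flattened to a 2-D
(output x fan-in) matrix, gets orthonormal columns (or rows when fan-in
exceeds fan-out) from the QR decomposition of a Gaussian draw; biases start
at exactly zero. Optimization uses an adaptive-moment inner rule wrapped in
Lookahead: fast weights take k inner steps, slow weights move a fraction
alpha toward them, and the fast weights are reset to the new slow weights.

Data handling follows an 8:1:1 train/validation/test split per cell line;
multiple training subsets are merged and reshuffled before training. Model
selection and early stopping use the validation Spearman correlation of the
validly-edited head, which is also the hyperparameter-search objective.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import autodiff as ad
from .autodiff import Tensor
from .network import HEAD_NAMES, PrimeNet

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "SplitSpec", "Adam", "Lookahead", "orthogonal_init",
           "split_dataset", "merge_and_shuffle", "train", "tune_hyperparameters"]


def orthogonal_init(model: PrimeNet, seed: int) -> PrimeNet:
    """Re-initialize every weight orthogonally and every bias to exact zero."""
    rng = np.random.default_rng(seed)
    for name, t in model.params.items():
        if name.endswith(".b"):
            t.data = np.zeros_like(t.data)
            continue
        shape = t.data.shape
        rows, cols = shape[0], int(np.prod(shape[1:]))
        a = rng.standard_normal((max(rows, cols), min(rows, cols)))
        q, r = np.linalg.qr(a)
        q = q * np.sign(np.diag(r))  # make the factorization unique
        w = q if rows >= cols else q.T
        t.data = w.reshape(shape).astype(ad.DTYPE)
    return model


class Adam:
    """Adaptive-moment estimation over a named-parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = {k: np.zeros_like(t.data, dtype=np.float64) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data, dtype=np.float64) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.data.dtype
            )


class Lookahead:
    """Slow/fast weight wrapper around any inner optimizer.

    After every ``k`` inner steps the slow weights phi move a fraction
    ``alpha`` toward the fast weights theta, and theta is reset to phi.
    """

    def __init__(self, params: dict[str, Tensor], inner, k: int = 5,
                 alpha: float = 0.5):
        if not (0.0 < alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        if k < 1:
            raise ValueError("k must be >= 1")
        self.params = params
        self.inner = inner
        self.k, self.alpha = k, alpha
        self.slow = {name: t.data.copy() for name, t in params.items()}
        self.inner_steps = 0
        self.outer_iteration = 0

    def step(self) -> None:
        self.inner.step()
        self.inner_steps += 1
        if self.inner_steps % self.k == 0:
            self._outer_update()

    def _outer_update(self) -> None:
        for name, t in self.params.items():
            self.slow[name] = self.slow[name] + self.alpha * (
                t.data.astype(self.slow[name].dtype) - self.slow[name]
            )
            t.data = self.slow[name].astype(t.data.dtype)
        self.outer_iteration += 1

    def finish_epoch(self) -> None:
        """Close a shortened final cycle when the epoch ran out of batches."""
        if self.inner_steps % self.k != 0:
            logger.info("lookahead: shortened final cycle (%d of %d inner steps)",
                        self.inner_steps % self.k, self.k)
            self._outer_update()
            self.inner_steps = 0


@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple = (8, 1, 1)
    seed: int = 0


def split_dataset(items: list, spec: SplitSpec = SplitSpec()):
    """Seeded shuffle then contiguous 8:1:1 cut (floor train/val, rest test)."""
    n = len(items)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    total = sum(spec.ratios)
    n_train = math.floor(n * spec.ratios[0] / total)
    n_val = math.floor(n * spec.ratios[1] / total)
    order = np.random.default_rng(spec.seed).permutation(n)
    pick = lambda idx: [items[i] for i in idx]
    return (pick(order[:n_train]), pick(order[n_train:n_train + n_val]),
            pick(order[n_train + n_val:]))


def merge_and_shuffle(train_sets: list[list], seed: int) -> list:
    merged = [item for subset in train_sets for item in subset]
    order = np.random.default_rng(seed).permutation(len(merged))
    return [merged[i] for i in order]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 50
    early_stop_patience: int = 10
    seed: int = 0
    lookahead_enabled: bool = True
    lookahead_k: int = 5
    lookahead_alpha: float = 0.5

    def manifest(self) -> dict:
        return dict(self.__dict__)


def _mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(target)
    return (diff * diff).mean()


def _valid_head_spearman(model: PrimeNet, X: np.ndarray, y: np.ndarray) -> float:
    pred = model.predict(X)
    rho = stats.spearmanr(pred[:, 0], y[:, 0]).statistic
    return float(rho) if np.isfinite(rho) else float("-inf")


def train(model: PrimeNet, train_data, val_data, config: TrainConfig):
    """Fit the model; returns (model, history).

    ``train_data``/``val_data`` are (X, y) with X (N,128,8,2) and y (N,3) in
    percent. The model is orthogonally initialized, optimized with Adam (in
    Lookahead when enabled) under a mean-squared-error loss averaged over the
    three heads, and restored to the epoch with the best validation Spearman
    of the validly-edited head. History rows carry per-epoch train loss and
    per-head validation Spearman.
    """
    Xtr, ytr = train_data
    Xval, yval = val_data
    Xtr = np.asarray(Xtr, ad.DTYPE)
    ytr = np.asarray(ytr, ad.DTYPE)
    orthogonal_init(model, config.seed)
    inner = Adam(model.params, lr=config.learning_rate)
    opt = (
        Lookahead(model.params, inner, k=config.lookahead_k,
                  alpha=config.lookahead_alpha)
        if config.lookahead_enabled
        else inner
    )
    rng = np.random.default_rng(config.seed + 1)
    n = len(Xtr)
    history: list[dict] = []
    best = {"score": float("-inf"), "state": model.state(), "epoch": -1}
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            model.zero_grad()
            pred = model.forward(Xtr[idx])
            loss = _mse_loss(pred, ytr[idx])
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; aborting. "
                    f"last finite losses: {losses[-5:]}"
                )
            loss.backward()
            opt.step()
            losses.append(lval)
        if isinstance(opt, Lookahead):
            opt.finish_epoch()
        preds = model.predict(Xval)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        for h, name in enumerate(HEAD_NAMES):
            rho = stats.spearmanr(preds[:, h], yval[:, h]).statistic
            row[f"val_spearman_{name}"] = float(rho) if np.isfinite(rho) else np.nan
        history.append(row)
        score = row["val_spearman_valid"]
        logger.info("epoch %d loss %.3f val_spearman_valid %.4f",
                    epoch, row["train_loss"], score)
        if np.isfinite(score) and score > best["score"]:
            best = {"score": score, "state": model.state(), "epoch": epoch}
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                logger.info("early stop at epoch %d (best epoch %d)",
                            epoch, best["epoch"])
                break
    model.load_state(best["state"])
    return model, history


def tune_hyperparameters(space: dict, n_trials: int, seed: int, data,
                         train_config: TrainConfig | None = None,
                         model_seed: int = 0):
    """Random search maximizing validation Spearman of the validly-edited head.

    ``space`` maps ModelConfig/TrainConfig field names to either a list of
    choices or a (low, high) tuple sampled log-uniformly for floats. Returns
    (best_config_dict, trials) with every trial logged as {params, score}.
    """
    from .network import ModelConfig

    if n_trials < 1:
        raise ValueError("need at least one trial")
    (Xtr, ytr), (Xval, yval) = data
    rng = np.random.default_rng(seed)
    base_tc = train_config or TrainConfig()
    trials = []
    model_fields = set(ModelConfig.__dataclass_fields__)
    train_fields = set(TrainConfig.__dataclass_fields__)
    for _ in range(n_trials):
        sampled = {}
        for key, choices in space.items():
            if isinstance(choices, tuple) and len(choices) == 2 and all(
                isinstance(c, float) for c in choices
            ):
                lo, hi = np.log(choices[0]), np.log(choices[1])
                sampled[key] = float(np.exp(rng.uniform(lo, hi)))
            else:
                sampled[key] = choices[int(rng.integers(len(choices)))]
        mc = ModelConfig(**{k: v for k, v in sampled.items() if k in model_fields})
        tc_kwargs = {**base_tc.manifest(),
                     **{k: v for k, v in sampled.items() if k in train_fields}}
        tc = TrainConfig(**tc_kwargs)
        model = PrimeNet(mc, seed=model_seed)
        model, _ = train(model, (Xtr, ytr), (Xval, yval), tc)
        score = _valid_head_spearman(model, Xval, yval)
        trials.append({"params": sampled, "score": score})
    best = max(trials, key=lambda t: t["score"])
    return best["params"], trials
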