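"""Fine-tuning with ROGI-initialized prompt-weight selection.

The pre-trained model is adapted to a labeled task by learning (i) a
*prompt distribution* — a point on the 3-simplex, parameterized by k-1 free
logits through a softmax — that linearly combines the channel representations
into a composite representation, and (ii) a linear task head, while the
prompt-guided aggregation module stays frozen (it is treated as a
task-independent pooling layer; its parameters are bit-identical before and
after fine-tuning).

Prompt weights are initialized to the candidate whose composite representation
has the *lowest roughness index* on the training set (smoothest
structure-property landscape).  Candidates come from an exhaustive 0.1-step
simplex grid when the budget covers it, or from a small Gaussian-process
expected-improvement loop over the free logits for smaller budgets; budget 0
means uniform weights.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel
from scipy.stats import norm

from .autodiff import Adam, Tensor, cross_entropy
from .chem_graph import MoleculeRecord
from .encoder import BatchedGraphs, CHANNELS, encode_nodes, glorot, prompt_aggregate
from .pretrain import Checkpoint, Model, PretrainData
from .qspr_probe import rogi

N_CHANNELS = len(CHANNELS)  # channel order convention: [MCD, SCD, CP]


@dataclass
class PromptWeights:
    """A point on the probability simplex over the three channels."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (N_CHANNELS,):
            raise ValueError(f"expected {N_CHANNELS} weights")
        if (w < -1e-12).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must lie on the probability simplex")
        self.weights = np.clip(w, 0.0, 1.0)

    @classmethod
    def uniform(cls) -> "PromptWeights":
        return cls(np.full(N_CHANNELS, 1.0 / N_CHANNELS))

    def logits(self) -> np.ndarray:
        """k-1 free logits whose softmax (with a fixed 0 appended) gives the
        weights; zero-weight channels are clamped for finiteness."""
        w = np.clip(self.weights, 1e-8, 1.0)
        log_w = np.log(w)
        return log_w[:-1] - log_w[-1]


def weights_from_logits(free_logits: np.ndarray) -> np.ndarray:
    z = np.concatenate([np.asarray(free_logits, dtype=np.float64), [0.0]])
    e = np.exp(z - z.max())
    return e / e.sum()


@dataclass
class FinetuneConfig:
    task: str = "regression"            # "regression" | "classification"
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    rogi_init_budget: int = 0           # candidate evaluations; 0 = uniform init
    snapshot_epochs: Tuple[int, ...] = (0, 10, 20, 50, 100)

    def __post_init__(self):
        if self.task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")
        if self.rogi_init_budget < 0:
            raise ValueError("rogi_init_budget must be >= 0")


# --------------------------------------------------------------------------
# Composite representation and ROGI-based initialization
# --------------------------------------------------------------------------

def composite_representation(channel_reprs: Sequence[np.ndarray],
                             weights: PromptWeights) -> np.ndarray:
    """Simplex-weighted linear combination of the channel representations."""
    reprs = [np.asarray(r, dtype=np.float64) for r in channel_reprs]
    if len({r.shape for r in reprs}) != 1:
        raise ValueError("channel representations must share a shape")
    return sum(w * r for w, r in zip(weights.weights, reprs))


def simplex_grid(step: float = 0.1) -> np.ndarray:
    """All points of the 3-simplex with coordinates in multiples of `step`."""
    m = int(round(1.0 / step))
    pts = [
        (i / m, j / m, (m - i - j) / m)
        for i in range(m + 1)
        for j in range(m + 1 - i)
    ]
    return np.array(pts)


GRID_FALLBACK = simplex_grid(0.1)  # 66 candidates


def init_prompt_weights_rogi(
    channel_reprs: Sequence[np.ndarray],
    labels: Sequence[float],
    budget: int,
    seed: int = 0,
) -> PromptWeights:
    """Prompt weights minimizing training-set ROGI over evaluated candidates.

    budget 0 returns uniform weights; budget >= 66 evaluates the exhaustive
    0.1-step simplex grid (plus the uniform point); smaller budgets run a
    GP-based expected-improvement search over the two free logits.  Constant
    labels make ROGI degenerate (0 everywhere) and return uniform weights.
    """
    if budget == 0:
        return PromptWeights.uniform()
    y = np.asarray(labels, dtype=np.float64)
    if y.max() == y.min():
        warnings.warn("constant labels: ROGI is degenerate; using uniform weights",
                      stacklevel=2)
        return PromptWeights.uniform()

    def objective(w: np.ndarray) -> float:
        comp = composite_representation(channel_reprs, PromptWeights(w))
        return rogi(comp, y)[0]

    if budget >= len(GRID_FALLBACK):
        candidates = np.vstack([GRID_FALLBACK, PromptWeights.uniform().weights])
        scores = np.array([objective(w) for w in candidates])
        return PromptWeights(candidates[int(np.argmin(scores))])

    # GP expected-improvement over the 2 free logits
    rng = np.random.default_rng(seed)
    bound = 4.0
    n_init = min(max(3, budget // 3), budget)
    X = list(rng.uniform(-bound, bound, size=(n_init, N_CHANNELS - 1)))
    scores = [objective(weights_from_logits(x)) for x in X]
    kernel = ConstantKernel(1.0) * RBF(length_scale=2.0)
    while len(X) < budget:
        # fixed kernel hyperparameters: cheap, deterministic, adequate for a
        # 2-dimensional search space with a handful of evaluations
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      optimizer=None, random_state=seed, alpha=1e-8)
        gp.fit(np.array(X), np.array(scores))
        cand = rng.uniform(-bound, bound, size=(256, N_CHANNELS - 1))
        mu, sd = gp.predict(cand, return_std=True)
        best = min(scores)
        sd = np.maximum(sd, 1e-12)
        z = (best - mu) / sd
        ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
        x_next = cand[int(np.argmax(ei))]
        X.append(x_next)
        scores.append(objective(weights_from_logits(x_next)))
    return PromptWeights(weights_from_logits(X[int(np.argmin(scores))]))


# --------------------------------------------------------------------------
# Splits
# --------------------------------------------------------------------------

def random_split(n: int, val_fraction: float = 0.1, test_fraction: float = 0.1,
                 seed: int = 0):
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(round(val_fraction * n))
    n_test = int(round(test_fraction * n))
    return order[n_val + n_test:], order[:n_val], order[n_val:n_val + n_test]


def scaffold_split(records: Sequence[MoleculeRecord], val_fraction: float = 0.1,
                   test_fraction: float = 0.1):
    """Deterministic scaffold split: whole scaffold groups (largest first) are
    assigned to train until the ratio is met, then validation, then test."""
    groups = defaultdict(list)
    for i, rec in enumerate(records):
        groups[rec.scaffold_smiles].append(i)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), g[0]))
    n = len(records)
    n_train = n - int(round(val_fraction * n)) - int(round(test_fraction * n))
    n_val = int(round(val_fraction * n))
    train, val, test = [], [], []
    for g in ordered:
        if len(train) < n_train:
            train.extend(g)
        elif len(val) < n_val:
            val.extend(g)
        else:
            test.extend(g)
    return np.array(train), np.array(val), np.array(test)


# --------------------------------------------------------------------------
# Fine-tuning
# --------------------------------------------------------------------------

@dataclass
class FinetuneResult:
    model: Model
    prompt_weights: PromptWeights
    metric_log: List[dict]
    snapshots: Dict[int, np.ndarray]    # epoch -> composite representations
    aggregation_before: Dict[str, np.ndarray]
    aggregation_after: Dict[str, np.ndarray]


def _channel_graph_reprs(model: Model, graphs, idx) -> List[Tensor]:
    batch = BatchedGraphs([graphs[i] for i in idx])
    h = encode_nodes(batch, model.encoder)
    return [
        prompt_aggregate(h, batch.graph_ids, batch.n_graphs, ch, model.aggregation).graph_repr
        for ch in CHANNELS
    ]


def _composite_tensor(channel_reprs: List[Tensor], w: Tensor) -> Tensor:
    comp = channel_reprs[0] * w.gather([0])
    for c in range(1, N_CHANNELS):
        comp = comp + channel_reprs[c] * w.gather([c])
    return comp


def r_squared(pred: np.ndarray, y: np.ndarray) -> float:
    ss_res = float(((pred - y) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0


def finetune(
    checkpoint: Checkpoint,
    data: PretrainData,
    labels: Sequence[float],
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: FinetuneConfig,
) -> FinetuneResult:
    """Fine-tune the pre-trained model on a labeled task.

    The encoder, the prompt logits and the task head are optimized; the
    aggregation module is frozen.  Composite-representation snapshots over the
    whole molecule set are stored at the configured epochs for probing.
    """
    y = np.asarray(labels, dtype=np.float64)
    model = checkpoint.model
    model.aggregation.set_trainable(False)
    agg_before = {k: v.data.copy() for k, v in model.aggregation.tensors.items()}

    rng = np.random.default_rng(config.seed)

    # ROGI-based prompt-weight initialization on the training set
    from .pretrain import channel_representations
    train_reprs = channel_representations(data, model, indices=train_idx)
    init_w = init_prompt_weights_rogi(
        [train_reprs[ch] for ch in CHANNELS], y[train_idx],
        budget=config.rogi_init_budget, seed=config.seed,
    )

    hidden = model.config.hidden_dim
    out_dim = 2 if config.task == "classification" else 1
    head_rng = np.random.default_rng(config.seed + 3)
    prompt_logits = Tensor(init_w.logits(), requires_grad=True)
    head_w = glorot(head_rng, hidden, out_dim)
    head_b = Tensor(np.zeros(out_dim), requires_grad=True)

    params = {f"enc.{k}": v for k, v in model.encoder.tensors.items()}
    params.update({"prompt_logits": prompt_logits, "head_w": head_w, "head_b": head_b})
    optimizer = Adam(params, lr=config.learning_rate)

    def current_weights() -> np.ndarray:
        return weights_from_logits(prompt_logits.data)

    def full_logits() -> Tensor:
        padded = prompt_logits.reshape(1, N_CHANNELS - 1)
        # append the fixed 0 logit via a constant-embedding matmul
        pad = Tensor(np.hstack([np.eye(N_CHANNELS - 1),
                                np.zeros((N_CHANNELS - 1, 1))]))
        return (padded @ pad).softmax(axis=-1).reshape(N_CHANNELS)

    def predict(idx: np.ndarray) -> np.ndarray:
        reprs = _channel_graph_reprs(model, data.graphs, idx)
        comp = _composite_tensor(reprs, full_logits())
        out = comp @ head_w + head_b
        if config.task == "classification":
            return out.softmax(axis=-1).data[:, 1]
        return out.data[:, 0]

    def snapshot() -> np.ndarray:
        all_idx = np.arange(len(data.graphs))
        reprs = _channel_graph_reprs(model, data.graphs, all_idx)
        return _composite_tensor(reprs, full_logits()).data.copy()

    metric_log: List[dict] = []
    snapshots: Dict[int, np.ndarray] = {}

    def log_epoch(epoch: int, train_loss: float) -> None:
        w = current_weights()
        if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise AssertionError("prompt weights left the simplex")
        pred = predict(val_idx)
        metric = (
            r_squared(pred, y[val_idx])
            if config.task == "regression"
            else float(((pred > 0.5) == (y[val_idx] > 0.5)).mean())
        )
        metric_log.append(
            {"epoch": epoch, "train_loss": train_loss,
             "val_metric": metric, "prompt_weights": w.tolist()}
        )
        if epoch in config.snapshot_epochs:
            snapshots[epoch] = snapshot()

    log_epoch(0, float("nan"))
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) == 0:
                continue
            reprs = _channel_graph_reprs(model, data.graphs, idx)
            comp = _composite_tensor(reprs, full_logits())
            out = comp @ head_w + head_b
            if config.task == "regression":
                diff = out.reshape(len(idx)) - Tensor(y[idx])
                loss = (diff * diff).mean()
            else:
                loss = cross_entropy(out, y[idx].astype(int))
            optimizer.zero_grad()
            loss.backward()
            # freeze contract: no gradient may reach the aggregation module
            for p in model.aggregation.tensors.values():
                if p.grad is not None:
                    raise AssertionError("gradient leaked into frozen aggregation")
            optimizer.step()
            losses.append(float(loss.data))
        log_epoch(epoch, float(np.mean(losses)) if losses else float("nan"))

    agg_after = {k: v.data.copy() for k, v in model.aggregation.tensors.items()}
    return FinetuneResult(
        model=model,
        prompt_weights=PromptWeights(current_weights()),
        metric_log=metric_log,
        snapshots=snapshots,
        aggregation_before=agg_before,
        aggregation_after=agg_after,
    )
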