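"""Two-branch affinity regressor and its training loop.

A drug GLCN and a protein GLCN each produce a pooled graph-level vector;
the two are concatenated and passed through two fully connected layers
(LeakyReLU after the first, dropout after each) and a final linear unit
to yield the predicted affinity.  The training objective is

    L_total = L_dta + lambda * L_GL

with L_dta the batch mean squared error and L_GL the summed per-layer
graph-learning regularizers of both branches, averaged over the
mini-batch.  Optimization is mini-batch Adam with linear learning-rate
warmup followed by a 20% decay every 40 epochs.

Graphs of different sizes are padded into batches with validity masks;
masked execution reproduces per-graph execution to tight tolerance.
Large batches are internally processed in fixed-size micro-chunks purely
to bound the memory of the pairwise N x N x d intermediates — gradient
accumulation over chunks is mathematically identical to one large batch.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .autodiff import Tensor, concatenate
from .chem_graph import ATOM_FEATURE_DIM, MoleculeGraph
from .data import AffinityDataset, load_entity_graphs
from .glcn import GLCNParams, GLConfig, glcn_forward, global_pool, glorot, init_glcn_params
from .metrics import mse as _mse_metric
from .protein_graph import RESIDUE_FEATURE_DIM, ProteinGraph

__all__ = [
    "ModelConfig",
    "HeadParams",
    "DTAParams",
    "TrainState",
    "init_params",
    "pad_graphs",
    "forward_batch",
    "forward",
    "total_loss",
    "lr_at_epoch",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """All hyperparameters of the regressor and its training schedule."""

    drug_glcn: GLConfig = field(default_factory=GLConfig)
    protein_glcn: GLConfig = field(default_factory=GLConfig)
    fc_dims: tuple[int, int] = (1024, 512)
    dropout: float = 0.2
    lambda_gl: float = 1.0
    lr: float = 0.0005
    warmup_epochs: int = 10
    decay_factor: float = 0.8
    decay_every: int = 40
    batch_size: int = 128
    epochs: int = 1000
    seed: int = 0
    micro_batch: int = 16
    val_fraction: float = 0.1
    leaky_slope: float = 0.01

    def __post_init__(self):
        if isinstance(self.drug_glcn, dict):
            self.drug_glcn = GLConfig(**self.drug_glcn)
        if isinstance(self.protein_glcn, dict):
            self.protein_glcn = GLConfig(**self.protein_glcn)
        self.fc_dims = tuple(self.fc_dims)
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.lambda_gl < 0 or self.lr <= 0:
            raise ValueError("lambda_gl must be >= 0 and lr > 0")
        if self.drug_glcn.d_model != self.protein_glcn.d_model:
            raise ValueError("both branches must share d_model for concatenation")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class HeadParams:
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor
    W_out: Tensor
    b_out: Tensor

    def named(self, prefix: str = "head") -> dict[str, Tensor]:
        return {
            f"{prefix}.W1": self.W1,
            f"{prefix}.b1": self.b1,
            f"{prefix}.W2": self.W2,
            f"{prefix}.b2": self.b2,
            f"{prefix}.W_out": self.W_out,
            f"{prefix}.b_out": self.b_out,
        }


@dataclass
class DTAParams:
    drug: GLCNParams
    protein: GLCNParams
    head: HeadParams

    def named(self) -> dict[str, Tensor]:
        out = self.drug.named("drug")
        out.update(self.protein.named("protein"))
        out.update(self.head.named())
        return out


def init_params(config: ModelConfig, rng: np.random.Generator | None = None) -> DTAParams:
    """Seed-controlled Glorot-style initialization of every parameter group."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d = config.drug_glcn.d_model
    h1, h2 = config.fc_dims
    head = HeadParams(
        W1=glorot(rng, 2 * d, h1, (2 * d, h1)),
        b1=Tensor(np.zeros(h1), requires_grad=True),
        W2=glorot(rng, h1, h2, (h1, h2)),
        b2=Tensor(np.zeros(h2), requires_grad=True),
        W_out=glorot(rng, h2, 1, (h2, 1)),
        b_out=Tensor(np.zeros(1), requires_grad=True),
    )
    return DTAParams(
        drug=init_glcn_params(ATOM_FEATURE_DIM, config.drug_glcn, rng),
        protein=init_glcn_params(RESIDUE_FEATURE_DIM, config.protein_glcn, rng),
        head=head,
    )


# ---------------------------------------------------------------------------
# forward pass


def pad_graphs(feature_list: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-size node-feature matrices into (B, N_max, F) + mask."""
    n_max = max(f.shape[0] for f in feature_list)
    width = feature_list[0].shape[1]
    X = np.zeros((len(feature_list), n_max, width))
    mask = np.zeros((len(feature_list), n_max))
    for i, f in enumerate(feature_list):
        X[i, : f.shape[0]] = f
        mask[i, : f.shape[0]] = 1.0
    return X, mask


def _dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if p <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)


def forward_batch(
    mols: list[MoleculeGraph],
    prots: list[ProteinGraph],
    params: DTAParams,
    config: ModelConfig,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[Tensor, Tensor]:
    """Predict affinities for aligned drug/protein graph lists.

    Returns the (B,) prediction tensor and the (B,) per-pair
    graph-learning loss (drug branch + protein branch, summed over
    layers).  Dropout is active only when ``dropout_rng`` is supplied.
    """
    if len(mols) != len(prots) or not mols:
        raise ValueError("need equal, nonzero numbers of drug and protein graphs")
    Xd, mask_d = pad_graphs([m.node_features for m in mols])
    Xp, mask_p = pad_graphs([p.node_features for p in prots])

    Vd, gl_d = glcn_forward(Xd, params.drug, config.drug_glcn, mask=mask_d)
    Vp, gl_p = glcn_forward(Xp, params.protein, config.protein_glcn, mask=mask_p)
    zd = global_pool(Vd, config.drug_glcn.pool, mask=mask_d)
    zp = global_pool(Vp, config.protein_glcn.pool, mask=mask_p)
    z = concatenate([zd, zp], axis=-1)  # (B, 2 d_model)

    h = (z @ params.head.W1 + params.head.b1).leaky_relu(config.leaky_slope)
    h = _dropout(h, config.dropout, dropout_rng)
    h = h @ params.head.W2 + params.head.b2
    h = _dropout(h, config.dropout, dropout_rng)
    pred = (h @ params.head.W_out + params.head.b_out).reshape(len(mols))
    return pred, gl_d + gl_p


def forward(
    mol: MoleculeGraph,
    prot: ProteinGraph,
    params: DTAParams,
    config: ModelConfig,
) -> tuple[float, float]:
    """Single-pair convenience wrapper (evaluation mode, no dropout)."""
    pred, gl = forward_batch([mol], [prot], params, config)
    return float(pred.data[0]), float(gl.data[0])


def total_loss(predictions, targets, gl_loss, lambda_gl: float) -> Tensor:
    """Joint objective: batch MSE plus ``lambda_gl`` times the GL loss."""
    predictions = predictions if isinstance(predictions, Tensor) else Tensor(predictions)
    targets = np.asarray(targets, dtype=np.float64).ravel()
    if targets.size == 0:
        raise ValueError("empty batch")
    if predictions.shape != targets.shape:
        raise ValueError(
            f"prediction shape {predictions.shape} != target shape {targets.shape}"
        )
    gl = gl_loss if isinstance(gl_loss, Tensor) else Tensor(gl_loss)
    return (predictions - Tensor(targets)).square().mean() + lambda_gl * gl


def lr_at_epoch(epoch: int, config: ModelConfig) -> float:
    """Linear warmup to ``config.lr``, then 20% decay every 40 epochs."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if config.warmup_epochs > 0 and epoch < config.warmup_epochs:
        return config.lr * (epoch + 1) / config.warmup_epochs
    steps = (epoch - config.warmup_epochs) // config.decay_every
    return config.lr * config.decay_factor**steps


# ---------------------------------------------------------------------------
# optimization


class Adam:
    """Adam with per-parameter first/second moment estimates."""

    def __init__(self, params: dict[str, Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


@dataclass
class TrainState:
    """Everything needed to resume or apply a trained model."""

    params: DTAParams
    config: ModelConfig
    adam_m: dict[str, np.ndarray]
    adam_v: dict[str, np.ndarray]
    adam_t: int
    epoch: int
    best_val_mse: float
    best_params: dict[str, np.ndarray]
    rng_state: dict


def _record_graphs(dataset, indices, mol_cache, prot_cache):
    mols = [mol_cache[dataset.records[i].drug_id] for i in indices]
    prots = [prot_cache[dataset.records[i].protein_id] for i in indices]
    y = np.array([dataset.records[i].affinity for i in indices])
    return mols, prots, y


def _batch_loss_and_grads(
    dataset, indices, mol_cache, prot_cache, params, config, dropout_rng
):
    """Accumulate gradients of L_total over one batch via micro-chunks.

    The chunked sum equals the full-batch loss exactly: each chunk
    contributes sum(residual^2)/B + lambda * sum(gl)/B.
    """
    b_total = len(indices)
    chunk = max(1, config.micro_batch)
    # group similar-size proteins per chunk to cut padding waste; the
    # chunk gradients are summed, so ordering inside the batch is inert
    indices = sorted(indices, key=lambda i: len(prot_cache[dataset.records[i].protein_id].sequence))
    loss_value = 0.0
    se_sum = 0.0
    for start in range(0, b_total, chunk):
        sub = indices[start : start + chunk]
        mols, prots, y = _record_graphs(dataset, sub, mol_cache, prot_cache)
        pred, gl = forward_batch(mols, prots, params, config, dropout_rng)
        resid = pred - Tensor(y)
        piece = (resid.square().sum() + config.lambda_gl * gl.sum()) * (1.0 / b_total)
        piece.backward()
        loss_value += piece.item()
        se_sum += float((resid.data**2).sum())
    return loss_value, se_sum / b_total


def _eval_mse(dataset, indices, mol_cache, prot_cache, params, config) -> float:
    preds = _predict_indices(dataset, indices, mol_cache, prot_cache, params, config)
    y = np.array([dataset.records[i].affinity for i in indices])
    return _mse_metric(y, preds)


def _predict_indices(dataset, indices, mol_cache, prot_cache, params, config):
    chunk = max(1, config.micro_batch)
    out = np.empty(len(indices))
    for start in range(0, len(indices), chunk):
        sub = indices[start : start + chunk]
        mols, prots, _ = _record_graphs(dataset, sub, mol_cache, prot_cache)
        pred, _ = forward_batch(mols, prots, params, config)
        out[start : start + len(sub)] = pred.data
    return out


def train(
    dataset: AffinityDataset,
    config: ModelConfig,
    train_indices: list[int] | None = None,
    val_indices: list[int] | None = None,
    log_every: int = 0,
) -> tuple[TrainState, list[dict]]:
    """Mini-batch Adam training of the joint objective.

    When index lists are not supplied, a ``val_fraction`` split is drawn
    from ``config.seed``; pass explicit fold indices to use a benchmark's
    fold scheme instead.  Shuffling, dropout and initialization are all
    driven by ``config.seed``, so a fixed seed reproduces the loss
    trajectory exactly.  Returns the final state (with the
    best-validation parameter snapshot) and the per-epoch history.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    if train_indices is None:
        order = rng.permutation(len(dataset))
        n_val = int(round(config.val_fraction * len(dataset)))
        val_indices = [int(i) for i in order[:n_val]]
        train_indices = [int(i) for i in order[n_val:]]
    elif val_indices is None:
        val_indices = []
    if not train_indices:
        raise ValueError("no training records after the split")
    if set(train_indices) & set(val_indices):
        raise ValueError("train/validation splits overlap")

    mol_cache, prot_cache = load_entity_graphs(dataset)
    params = init_params(config, rng)
    named = params.named()
    adam = Adam(named)
    history: list[dict] = []
    best_val = np.inf
    best_params = {k: p.data.copy() for k, p in named.items()}

    train_idx = np.asarray(train_indices)
    for epoch in range(config.epochs):
        lr = lr_at_epoch(epoch, config)
        perm = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        epoch_se = 0.0
        n_batches = 0
        for start in range(0, len(train_idx), config.batch_size):
            batch = train_idx[perm[start : start + config.batch_size]]
            adam.zero_grad()
            dropout_rng = rng if config.dropout > 0 else None
            loss_value, batch_mse = _batch_loss_and_grads(
                dataset, batch, mol_cache, prot_cache, params, config, dropout_rng
            )
            if not np.isfinite(loss_value):
                raise RuntimeError(
                    f"non-finite loss {loss_value} at epoch {epoch}, "
                    f"batch starting at record position {start}"
                )
            adam.step(lr)
            epoch_loss += loss_value
            epoch_se += batch_mse * len(batch)
            n_batches += 1

        entry = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": epoch_loss / n_batches,
            "train_mse": epoch_se / len(train_idx),
        }
        if val_indices:
            val_mse = _eval_mse(dataset, val_indices, mol_cache, prot_cache, params, config)
            entry["val_mse"] = val_mse
            if val_mse < best_val:
                best_val = val_mse
                best_params = {k: p.data.copy() for k, p in named.items()}
        history.append(entry)
        if log_every and epoch % log_every == 0:
            print(
                f"epoch {epoch:4d}  lr {lr:.2e}  loss {entry['train_loss']:.4f}"
                + (f"  val_mse {entry.get('val_mse', float('nan')):.4f}" if val_indices else "")
            )

    if not val_indices:
        best_params = {k: p.data.copy() for k, p in named.items()}
        best_val = history[-1]["train_mse"]
    state = TrainState(
        params=params,
        config=config,
        adam_m=adam.m,
        adam_v=adam.v,
        adam_t=adam.t,
        epoch=config.epochs,
        best_val_mse=float(best_val),
        best_params=best_params,
        rng_state=rng.bit_generator.state,
    )
    return state, history


def predict(
    dataset: AffinityDataset,
    state: TrainState,
    indices: list[int] | None = None,
    use_best: bool = False,
) -> np.ndarray:
    """Evaluation-mode predictions aligned to the dataset's record order."""
    if indices is None:
        indices = list(range(len(dataset)))
    mol_cache, prot_cache = load_entity_graphs(dataset)
    params = state.params
    if use_best:
        params = _params_from_arrays(state.config, state.best_params)
    return _predict_indices(dataset, indices, mol_cache, prot_cache, params, state.config)


# ---------------------------------------------------------------------------
# checkpointing


def _params_from_arrays(config: ModelConfig, arrays: dict[str, np.ndarray]) -> DTAParams:
    params = init_params(config, np.random.default_rng(0))
    named = params.named()
    if set(named) != set(arrays):
        raise ValueError("checkpoint parameter names do not match the config")
    for k, tensor in named.items():
        tensor.data = np.array(arrays[k], dtype=np.float64)
    return params


def save_checkpoint(state: TrainState, path) -> None:
    """Serialize parameters, optimizer moments, config and RNG state."""
    arrays: dict[str, np.ndarray] = {}
    for k, p in state.params.named().items():
        arrays[f"param/{k}"] = p.data
    for k, m in state.adam_m.items():
        arrays[f"adam_m/{k}"] = m
    for k, v in state.adam_v.items():
        arrays[f"adam_v/{k}"] = v
    for k, b in state.best_params.items():
        arrays[f"best/{k}"] = b
    meta = {
        "config": state.config.to_dict(),
        "adam_t": state.adam_t,
        "epoch": state.epoch,
        "best_val_mse": state.best_val_mse,
        "rng_state": state.rng_state,
    }
    buf = io.BytesIO()
    np.savez(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_checkpoint(path) -> TrainState:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        config = ModelConfig.from_dict(meta["config"])
        params_arrays = {
            k[len("param/") :]: npz[k] for k in npz.files if k.startswith("param/")
        }
        params = _params_from_arrays(config, params_arrays)
        adam_m = {k[len("adam_m/") :]: np.array(npz[k]) for k in npz.files if k.startswith("adam_m/")}
        adam_v = {k[len("adam_v/") :]: np.array(npz[k]) for k in npz.files if k.startswith("adam_v/")}
        best = {k[len("best/") :]: np.array(npz[k]) for k in npz.files if k.startswith("best/")}
    return TrainState(
        params=params,
        config=config,
        adam_m=adam_m,
        adam_v=adam_v,
        adam_t=int(meta["adam_t"]),
        epoch=int(meta["epoch"]),
        best_val_mse=float(meta["best_val_mse"]),
        best_params=best,
        rng_state=meta["rng_state"],
    )
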