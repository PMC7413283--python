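"""The zero-inflated denoising convolutional autoencoder (ZI-DCAE).

A ten-layer 1-D convolutional autoencoder imputes a zeroed-out interval in a
720-minute activity record.  Input values are min-max normalized by a global
training-set maximum, each position inside the missing interval is replaced
by the token 0.5, and the network is trained to reconstruct the normalized
uncorrupted record under an RMSE loss computed over the whole record.  Batch
normalization and tanh follow every layer except the last, which applies a
clamped tanh max(0, tanh(x)): the output lives in [0, 1] and negative
pre-activations collapse onto an exact point mass at zero, mimicking the
zero inflation of real activity counts by construction.

Training corrupts each record with a fresh random interval every epoch
(denoising-autoencoder convention) and early-stops on the partial RMSE of a
validation set whose corruption is fixed by seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from . import nn
from .geometry import INPUT_LENGTH, ArchitectureSpec, build_architecture
from .metrics import partial_rmse
from .records import ActivityRecord, MissingMask, RecordSet, corrupt_set

MASK_TOKEN = 0.5


@dataclass
class TrainConfig:
    max_epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stop_patience: int = 30
    rng_seed: int = 0
    train_scale_max: float | None = None   # learned from training data when None
    corruption_length: int = 30

    def __post_init__(self) -> None:
        if min(self.max_epochs, self.batch_size, self.early_stop_patience) < 1:
            raise ValueError("epochs, batch size and patience must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.train_scale_max is not None and self.train_scale_max <= 0:
            raise ValueError("scale must be positive")


def clamped_tanh(x):
    """max(0, tanh(x)) — the zero-inflating output activation."""
    return np.maximum(np.tanh(x), 0.0)


def prepare_input(values: np.ndarray, flags: np.ndarray | None, scale_max: float) -> np.ndarray:
    """Min-max normalize to [0, 1] and write the 0.5 token into masked cells."""
    if scale_max <= 0:
        raise ValueError("scale_max must be positive")
    values = np.asarray(values, dtype=float)
    out = np.clip(values / scale_max, 0.0, 1.0)
    if flags is not None:
        out = out.copy()
        out[np.asarray(flags, bool)] = MASK_TOKEN
    return out


def rmse_loss(reconstruction: np.ndarray, target: np.ndarray) -> float:
    """Root-mean-square error over every position (imputed and observed)."""
    reconstruction = np.asarray(reconstruction, dtype=float)
    target = np.asarray(target, dtype=float)
    if reconstruction.shape != target.shape:
        raise ValueError("reconstruction and target shapes differ")
    return float(np.sqrt(np.mean((reconstruction - target) ** 2)))


class ZIDCAE:
    """The autoencoder: geometry, weights, and forward/backward passes."""

    def __init__(self, spec: ArchitectureSpec, rng_seed: int = 0):
        self.spec = spec
        self.rng_seed = rng_seed
        rng = np.random.default_rng(rng_seed)
        layers: list[nn.Layer] = []
        cin = 1
        for layer_spec in spec.encoder:
            layers.append(nn.Conv1d(cin, layer_spec.out_channels, layer_spec.filter_size, layer_spec.stride, rng))
            layers.append(nn.BatchNorm1d(layer_spec.out_channels))
            layers.append(nn.Tanh())
            cin = layer_spec.out_channels
        self._n_encoder_layers = len(layers)
        for i, layer_spec in enumerate(spec.decoder):
            last = i == len(spec.decoder) - 1
            layers.append(nn.ConvTranspose1d(cin, layer_spec.out_channels, layer_spec.filter_size, layer_spec.stride, rng))
            if last:
                # no batch norm before the output: it would destroy the
                # exact zero point mass of the clamped tanh
                layers.append(nn.ClampedTanh())
            else:
                layers.append(nn.BatchNorm1d(layer_spec.out_channels))
                layers.append(nn.Tanh())
            cin = layer_spec.out_channels
        self.net = nn.Sequential(layers)
        self.scale_max: float | None = None
        self.trained = False
        self.history: dict[str, list[float]] = {"train_loss": [], "val_partial_rmse": []}

    # -- forward / backward -------------------------------------------------

    def forward(self, prepared: np.ndarray, training: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """(reconstruction in [0,1]^(B,720), latent feature maps (B, 128, k))."""
        x = np.asarray(prepared, dtype=nn.DTYPE)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[-1] != INPUT_LENGTH:
            raise ValueError(f"input length must be {INPUT_LENGTH}")
        h = x[:, None, :]
        for layer in self.net.layers[: self._n_encoder_layers]:
            h = layer.forward(h, training)
        latent = h
        for layer in self.net.layers[self._n_encoder_layers :]:
            h = layer.forward(h, training)
        return h[:, 0, :], latent

    def backward(self, d_reconstruction: np.ndarray) -> None:
        self.net.backward(np.asarray(d_reconstruction, dtype=nn.DTYPE)[:, None, :])

    # -- state --------------------------------------------------------------

    def snapshot(self) -> dict:
        state = {"params": [], "running": []}
        for layer in self.net.layers:
            state["params"].append({k: v.copy() for k, v in layer.params.items()})
            if isinstance(layer, nn.BatchNorm1d):
                state["running"].append((layer.running_mean.copy(), layer.running_var.copy()))
            else:
                state["running"].append(None)
        return state

    def restore(self, state: dict) -> None:
        for layer, params, running in zip(self.net.layers, state["params"], state["running"]):
            for k, v in params.items():
                layer.params[k] = v.copy()
            if running is not None:
                layer.running_mean, layer.running_var = running[0].copy(), running[1].copy()

    def save(self, path) -> None:
        """Single-file checkpoint: weights + geometry + scale + seed."""
        arrays = {}
        for i, layer in enumerate(self.net.layers):
            for k, v in layer.params.items():
                arrays[f"layer{i}:{k}"] = v
            if isinstance(layer, nn.BatchNorm1d):
                arrays[f"layer{i}:running_mean"] = layer.running_mean
                arrays[f"layer{i}:running_var"] = layer.running_var
        meta = {
            "format_version": 1,
            "m": self.spec.m,
            "k": self.spec.k,
            "rng_seed": self.rng_seed,
            "scale_max": self.scale_max,
            "trained": self.trained,
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ZIDCAE":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            model = cls(build_architecture(meta["m"], meta["k"]), meta["rng_seed"])
            for i, layer in enumerate(model.net.layers):
                for k in layer.params:
                    layer.params[k] = data[f"layer{i}:{k}"].copy()
                if isinstance(layer, nn.BatchNorm1d):
                    layer.running_mean = data[f"layer{i}:running_mean"].copy()
                    layer.running_var = data[f"layer{i}:running_var"].copy()
        model.scale_max = meta["scale_max"]
        model.trained = meta["trained"]
        return model


def _fresh_corruption(values: np.ndarray, length: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Zero a random interval per row; returns (corrupted, flags)."""
    m, n = values.shape
    starts = rng.integers(0, n - length + 1, size=m)
    corrupted = values.copy()
    flags = np.zeros((m, n), dtype=bool)
    for i, s in enumerate(starts):
        corrupted[i, s : s + length] = 0.0
        flags[i, s : s + length] = True
    return corrupted, flags


def _validation_partial_rmse(model: ZIDCAE, val_values: np.ndarray, val_corrupted_prepared: np.ndarray, val_flags: np.ndarray, scale: float) -> float:
    recon, _ = model.forward(val_corrupted_prepared, training=False)
    imputed = val_values.copy()
    imputed[val_flags] = (recon * scale)[val_flags]
    diff = (val_values - imputed)[val_flags]
    return float(np.sqrt(np.mean(diff**2)))


def train(
    train_set: RecordSet,
    val_set: RecordSet,
    spec: ArchitectureSpec,
    cfg: TrainConfig,
    verbose: bool = False,
) -> ZIDCAE:
    """Fit the autoencoder by Adam on the whole-record RMSE loss.

    Each epoch re-corrupts every training record with a fresh seeded random
    interval; validation corruption is fixed once by seed and the model with
    the best validation partial RMSE is kept (early stop after
    ``early_stop_patience`` epochs without improvement).
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    x_train = train_set.values_matrix()
    x_val = val_set.values_matrix() if len(val_set) else None
    if x_train.shape[1] != INPUT_LENGTH:
        raise ValueError(f"training records must have length {INPUT_LENGTH}")

    scale = cfg.train_scale_max if cfg.train_scale_max is not None else float(x_train.max())
    if scale <= 0:
        raise ValueError("training data are all zero; cannot set a scale")

    root = np.random.default_rng(cfg.rng_seed)
    init_seed = int(root.integers(0, 2**31 - 1))
    val_seed = int(root.integers(0, 2**31 - 1))
    model = ZIDCAE(spec, rng_seed=init_seed)
    model.scale_max = scale
    optimizer = nn.Adam(model.net.parameters(), lr=cfg.learning_rate)

    target_train = np.clip(x_train / scale, 0.0, 1.0).astype(nn.DTYPE)

    if x_val is not None:
        val_rng = np.random.default_rng(val_seed)
        val_corrupted, val_flags = _fresh_corruption(x_val, cfg.corruption_length, val_rng)
        val_prepared = prepare_input(val_corrupted, val_flags, scale).astype(nn.DTYPE)

    best_state, best_val, since_best = None, np.inf, 0
    m = x_train.shape[0]
    for epoch in range(cfg.max_epochs):
        epoch_rng = np.random.default_rng(int(root.integers(0, 2**31 - 1)))
        corrupted, flags = _fresh_corruption(x_train, cfg.corruption_length, epoch_rng)
        prepared = prepare_input(corrupted, flags, scale).astype(nn.DTYPE)
        order = epoch_rng.permutation(m)
        epoch_losses = []
        for lo in range(0, m, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            recon, _ = model.forward(prepared[idx], training=True)
            diff = recon - target_train[idx]
            loss = float(np.sqrt(np.mean(diff.astype(float) ** 2)))
            if not np.isfinite(loss):
                raise RuntimeError("training diverged: non-finite loss")
            epoch_losses.append(loss)
            if loss > 0:
                grad = diff / (diff.size * loss)
                model.backward(grad)
                optimizer.step()
        model.history["train_loss"].append(float(np.mean(epoch_losses)))

        if x_val is not None:
            val_prmse = _validation_partial_rmse(model, x_val, val_prepared, val_flags, scale)
            model.history["val_partial_rmse"].append(val_prmse)
            if verbose:
                print(f"epoch {epoch}: train rmse {model.history['train_loss'][-1]:.4f}  val partial rmse {val_prmse:.1f}")
            if val_prmse < best_val:
                best_val, best_state, since_best = val_prmse, model.snapshot(), 0
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    break

    if best_state is not None:
        model.restore(best_state)
    model.trained = True
    return model


def impute(
    model: ZIDCAE,
    record: ActivityRecord,
    mask: MissingMask,
    scale_max: float | None = None,
    full_reconstruction: bool = False,
) -> ActivityRecord:
    """Denormalized reconstruction spliced into the record's masked cells."""
    if not model.trained:
        raise ValueError("model is not trained")
    scale = scale_max if scale_max is not None else model.scale_max
    if scale is None or scale <= 0:
        raise ValueError("a positive scale_max is required")
    if len(record) != len(mask):
        raise ValueError("record and mask lengths differ")
    prepared = prepare_input(record.values, mask.flags, scale)
    recon, _ = model.forward(prepared, training=False)
    recon_counts = recon[0].astype(float) * scale
    values = record.values.copy()
    if full_reconstruction:
        values = recon_counts
    else:
        values[mask.flags] = recon_counts[mask.flags]
    return dc_replace(record, values=values)


def impute_set(model: ZIDCAE, record_set: RecordSet, batch_size: int = 256) -> RecordSet:
    """Vectorized imputation of a corrupted record set (masks required)."""
    if record_set.masks is None:
        raise ValueError("record set has no masks")
    if not model.trained:
        raise ValueError("model is not trained")
    x = record_set.values_matrix()
    flags = record_set.mask_matrix()
    prepared = prepare_input(x, flags, model.scale_max)
    out = x.copy()
    for lo in range(0, x.shape[0], batch_size):
        recon, _ = model.forward(prepared[lo : lo + batch_size], training=False)
        block = slice(lo, lo + recon.shape[0])
        counts = recon.astype(float) * model.scale_max
        out[block][flags[block]] = counts[flags[block]]
    records = [dc_replace(r, values=out[i]) for i, r in enumerate(record_set.records)]
    return RecordSet(records, record_set.masks, record_set.split_labels)


# ---------------------------------------------------------------------------
# Hyperparameter grid search
# ---------------------------------------------------------------------------

def select_best(table: pd.DataFrame) -> tuple[int, int]:
    """(m, k) of the row with the lowest mean RMSE in a CV summary table."""
    if len(table) == 0:
        raise ValueError("empty grid")
    row = table.loc[table["mean_rmse"].idxmin()]
    return int(row["m"]), int(row["k"])


def cv_grid_search(
    train_set: RecordSet,
    ms: tuple[int, ...] = (20, 30),
    ks: tuple[int, ...] = (40, 60, 80),
    folds: int = 10,
    cfg: TrainConfig | None = None,
) -> tuple[int, int, pd.DataFrame]:
    """10-fold cross-validated grid search over (m, k).

    Records are partitioned into folds by a seeded permutation; each cell's
    score is the mean, over folds, of the held-out partial RMSE after
    training on the remaining folds.  Returns the argmin cell and the full
    per-fold table.
    """
    cfg = cfg or TrainConfig()
    m_records = len(train_set)
    if m_records < folds:
        raise ValueError("need at least one record per fold")
    if not ms or not ks:
        raise ValueError("empty hyperparameter grid")
    rng = np.random.default_rng(cfg.rng_seed)
    perm = rng.permutation(m_records)
    fold_of = np.empty(m_records, dtype=int)
    for pos, rec_idx in enumerate(perm):
        fold_of[rec_idx] = pos % folds

    rows = []
    for k in ks:
        for m in ms:
            spec = build_architecture(m, k)
            scores = []
            for fold in range(folds):
                tr = train_set.subset(np.flatnonzero(fold_of != fold))
                held = train_set.subset(np.flatnonzero(fold_of == fold))
                model = train(tr, RecordSet([]), spec, cfg)
                corrupted = corrupt_set(held, cfg.corruption_length, cfg.rng_seed + fold)
                imputed = impute_set(model, corrupted)
                scores.append(partial_rmse(held, imputed, corrupted.masks))
            rows.append(
                {"k": k, "m": m, **{f"fold{f}": s for f, s in enumerate(scores)}, "mean_rmse": float(np.mean(scores))}
            )
    table = pd.DataFrame(rows)
    best_m, best_k = select_best(table)
    return best_m, best_k, table
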