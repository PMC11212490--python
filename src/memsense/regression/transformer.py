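"""Attention-based sequence→ΔΔF regressor.

A small transformer encoder — learned token and positional embeddings,
pre-norm self-attention blocks, masked mean pooling and a linear head —
trained with mean-squared-error loss and Adam, with early stopping on a
validation split. The implementation is pure numpy (see ``layers``) and
fully deterministic under a fixed seed.

The default capacity (2 layers, 8 heads, 64-dim embeddings) is sized for
datasets of a few thousand peptides; every knob is a :class:`ModelConfig`
field so larger published-scale settings can be dropped in.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
from pathlib import Path

import numpy as np

from ..data import TrainingExample, split_dataset
from . import layers
from .tokenizer import MAX_LENGTH, PAD, VOCAB_SIZE, tokenize, tokenize_batch

logger = logging.getLogger(__name__)


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters for the regressor."""

    embed_dim: int = 64
    n_heads: int = 8
    n_layers: int = 2
    feedforward_dim: int = 128
    dropout: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 60
    seed: int = 0
    splits: tuple[float, float, float] = (0.8, 0.1, 0.1)
    patience: int = 10
    max_length: int = MAX_LENGTH

    def __post_init__(self) -> None:
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        for name in ("embed_dim", "n_heads", "n_layers", "feedforward_dim",
                     "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class _Network(layers.Module):
    """The encoder network itself (parameters + forward/backward)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        d = config.embed_dim
        self.embed = layers.Parameter(rng.normal(0.0, 0.02, size=(VOCAB_SIZE, d)))
        self.pos = layers.Parameter(rng.normal(0.0, 0.02, size=(config.max_length, d)))
        self.blocks = [
            layers.EncoderLayer(d, config.n_heads, config.feedforward_dim,
                                config.dropout, rng)
            for _ in range(config.n_layers)
        ]
        self.final_norm = layers.LayerNorm(d)
        self.head = layers.Dense(d, 1, rng)
        self._cache: tuple | None = None

    def set_training(self, training: bool, rng: np.random.Generator | None) -> None:
        for block in self.blocks:
            for drop in (block.drop1, block.drop2):
                drop.training = training
                drop.rng = rng

    def forward(self, tokens: np.ndarray) -> np.ndarray:
        mask = tokens != PAD
        T = tokens.shape[1]
        x = self.embed.value[tokens] + self.pos.value[:T]
        for block in self.blocks:
            x = block.forward(x, mask)
        x = self.final_norm.forward(x)
        counts = mask.sum(axis=1, keepdims=True).astype(float)
        pooled = (x * mask[..., None]).sum(axis=1) / counts
        self._cache = (tokens, mask, counts)
        return self.head.forward(pooled)[:, 0]

    def backward(self, grad_y: np.ndarray) -> None:
        tokens, mask, counts = self._cache
        g_pooled = self.head.backward(grad_y[:, None])
        gx = (g_pooled[:, None, :] * mask[..., None]) / counts[..., None]
        gx = self.final_norm.backward(gx)
        for block in reversed(self.blocks):
            gx = block.backward(gx)
        np.add.at(self.embed.grad, tokens, gx)
        self.pos.grad += gx.sum(axis=0)


class TransformerDdgModel:
    """Model object: a dataset plus a configuration, fitted via :meth:`fit`."""

    def __init__(self, examples: list[TrainingExample],
                 config: ModelConfig | None = None):
        if not examples:
            raise ValueError("empty dataset")
        self.examples = examples
        self.config = config or ModelConfig()

    def fit(self, verbose: bool = False) -> "TransformerDdgResults":
        """Train with MSE loss, track train/val loss per epoch, and return
        the results at the best-validation checkpoint."""
        cfg = self.config
        train, val, _ = split_dataset(self.examples, cfg.splits, seed=cfg.seed)
        if not train:
            raise ValueError("training split is empty")
        if not val:  # tiny datasets: validate on the training data
            val = train

        rng = np.random.default_rng(cfg.seed)
        net = _Network(cfg, rng)
        params = net.parameters()
        opt = layers.Adam(params, lr=cfg.learning_rate)

        X_train = tokenize_batch([e.sequence for e in train], cfg.max_length)
        y_train = np.array([e.ddF for e in train])
        X_val = tokenize_batch([e.sequence for e in val], cfg.max_length)
        y_val = np.array([e.ddF for e in val])

        history: list[dict[str, float]] = []
        best_loss = np.inf
        best_state: list[np.ndarray] | None = None
        best_epoch = -1
        since_best = 0

        for epoch in range(cfg.epochs):
            order = rng.permutation(len(train))
            net.set_training(True, rng)
            sq_sum, n_seen = 0.0, 0
            for start in range(0, len(train), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                net.zero_grad()
                pred = net.forward(X_train[idx])
                resid = pred - y_train[idx]
                loss = float(np.mean(resid**2))
                if not np.isfinite(loss):
                    raise DivergenceError(f"non-finite loss at epoch {epoch}")
                net.backward(2.0 * resid / len(idx))
                opt.step()
                sq_sum += loss * len(idx)
                n_seen += len(idx)
            net.set_training(False, None)
            val_loss = float(np.mean((net.forward(X_val) - y_val) ** 2))
            if not np.isfinite(val_loss):
                raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
            train_loss = sq_sum / n_seen
            history.append(
                {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
            )
            if verbose:
                logger.info("epoch %d: train MSE %.4f, val MSE %.4f",
                            epoch, train_loss, val_loss)
            if val_loss < best_loss - 1e-12:
                best_loss, best_epoch, since_best = val_loss, epoch, 0
                best_state = [p.value.copy() for p in params]
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break

        for p, saved in zip(params, best_state):
            p.value[...] = saved
        return TransformerDdgResults(
            config=cfg,
            network=net,
            history=history,
            best_epoch=best_epoch,
            dataset_fingerprint=dataset_fingerprint(self.examples),
        )


@dataclasses.dataclass
class TransformerDdgResults:
    """A trained regressor: prediction, evaluation, persistence."""

    config: ModelConfig
    network: _Network
    history: list[dict[str, float]]
    best_epoch: int
    dataset_fingerprint: str

    def predict(self, sequence: str) -> float:
        """Predicted ΔΔF (kJ/mol); deterministic (inference mode).

        Sequences shorter than the reference length are padded and masked.
        Short peptides sit at the steep end of the length extrapolation, so
        predictions for ≤ 12 residues carry extra uncertainty (logged).
        """
        if len(sequence) <= 12:
            logger.warning(
                "sequence of length %d: short peptides tend toward stronger "
                "apparent binding after length extrapolation; interpret with care",
                len(sequence),
            )
        return self.predict_batch([sequence])[0]

    def predict_batch(self, sequences: list[str]) -> np.ndarray:
        self.network.set_training(False, None)
        tokens = tokenize_batch(sequences, self.config.max_length)
        return self.network.forward(tokens)

    def evaluate_rmse(self, examples: list[TrainingExample]) -> dict[str, float]:
        """Root-mean-square error on a test set, with residual mean and SD."""
        if not examples:
            raise ValueError("empty evaluation set")
        pred = self.predict_batch([e.sequence for e in examples])
        resid = pred - np.array([e.ddF for e in examples])
        return {
            "rmse": float(np.sqrt(np.mean(resid**2))),
            "resid_mean": float(resid.mean()),
            "resid_sd": float(resid.std()),
            "n": len(examples),
        }

    def summary(self) -> str:
        cfg = self.config
        last = self.history[-1]
        best = self.history[self.best_epoch]
        lines = [
            "Transformer sequence regressor",
            f"  layers: {cfg.n_layers}  heads: {cfg.n_heads}  "
            f"embed: {cfg.embed_dim}  ffn: {cfg.feedforward_dim}",
            f"  parameters: {sum(p.value.size for p in self.network.parameters())}",
            f"  epochs run: {len(self.history)} (best: {self.best_epoch})",
            f"  best val RMSE: {np.sqrt(best['val_loss']):.3f} kJ/mol  "
            f"(final train RMSE: {np.sqrt(last['train_loss']):.3f})",
            f"  dataset fingerprint: {self.dataset_fingerprint}",
        ]
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: parameter arrays + embedded config, history and
        dataset fingerprint, in a single .npz file."""
        meta = {
            "config": dataclasses.asdict(self.config),
            "history": self.history,
            "best_epoch": self.best_epoch,
            "dataset_fingerprint": self.dataset_fingerprint,
        }
        arrays = {
            f"param_{i}": p.value for i, p in enumerate(self.network.parameters())
        }
        buf = io.BytesIO()
        np.savez(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "TransformerDdgResults":
        try:
            archive = np.load(Path(path), allow_pickle=False)
        except Exception as exc:
            raise RuntimeError(f"cannot load model checkpoint {path}: {exc}") from exc
        meta = json.loads(bytes(archive["meta"]).decode())
        cfg_dict = meta["config"]
        cfg_dict["splits"] = tuple(cfg_dict["splits"])
        config = ModelConfig(**cfg_dict)
        net = _Network(config, np.random.default_rng(0))
        params = net.parameters()
        for i, p in enumerate(params):
            saved = archive[f"param_{i}"]
            if saved.shape != p.value.shape:
                raise RuntimeError(
                    f"checkpoint parameter {i} has shape {saved.shape}, "
                    f"expected {p.value.shape}"
                )
            p.value[...] = saved
        return cls(
            config=config,
            network=net,
            history=meta["history"],
            best_epoch=meta["best_epoch"],
            dataset_fingerprint=meta["dataset_fingerprint"],
        )


def dataset_fingerprint(examples: list[TrainingExample]) -> str:
    """Order-independent SHA-256 fingerprint of a dataset (first 16 hex)."""
    h = hashlib.sha256()
    for line in sorted(f"{e.sequence}\t{e.ddF:.6f}" for e in examples):
        h.update(line.encode())
        h.update(b"\n")
    return h.hexdigest()[:16]


def evaluate_rmse(predict, examples: list[TrainingExample]) -> dict[str, float]:
    """RMSE of any predictor callable/object over a test set."""
    if not examples:
        raise ValueError("empty evaluation set")
    fn = predict.predict if hasattr(predict, "predict") else predict
    resid = np.array([fn(e.sequence) - e.ddF for e in examples])
    return {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "resid_mean": float(resid.mean()),
        "resid_sd": float(resid.std()),
        "n": len(examples),
    }
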