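"""Training protocol: independent pretraining of the three branches, then
fusion training of the weighted classifier.

Each training run draws 80% of its data for iterative optimisation and keeps
20% for per-epoch validation; the parameters from the epoch with the lowest
validation loss are returned (with early stopping on a patience window). The
loss is plain, unweighted binary cross-entropy and the optimizer is Adam.
All randomness (split, initialisation, shuffling) flows from named substreams
of the single ``TrainConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import nn
from .errors import ConfigurationError, TrainingError
from .models import (
    DomainNet,
    DomainSubmodelConfig,
    MaskPair,
    Model,
    PPINet,
    PPISubmodelConfig,
    SequenceNet,
    SequenceSubmodelConfig,
    WeightedClassifier,
)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 30
    val_fraction: float = 0.2
    patience: int = 10
    weight_decay: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ConfigurationError("val_fraction must lie in (0, 1)")
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ConfigurationError("learning_rate/batch_size/max_epochs must be positive")


@dataclass
class TrainHistory:
    """Per-epoch losses; the checkpoint corresponds to ``best_epoch``."""

    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.val_loss))


def derive_seeds(seed: int, *names: str) -> Dict[str, int]:
    """Named 31-bit sub-seeds deterministically expanded from one run seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        n: int(c.generate_state(1, dtype=np.uint64)[0] % (2**31))
        for n, c in zip(names, children)
    }


def split_train_val(
    n_items: int, val_fraction: float = 0.2, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Disjoint (train_idx, val_idx) covering range(n_items), ~(1-f)/f sized."""
    if n_items < 5:
        raise ConfigurationError(f"need at least 5 items to split, got {n_items}")
    n_val = min(max(1, int(round(n_items * val_fraction))), n_items - 1)
    perm = np.random.default_rng(seed).permutation(n_items)
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def _epoch_loss(model: Model, x: np.ndarray, y: np.ndarray, batch: int = 256) -> float:
    total, count = 0.0, 0
    for i in range(0, len(x), batch):
        z = model.forward_logits(x[i : i + batch])
        yb = y[i : i + batch]
        loss, _ = nn.bce_with_logits(z, yb)
        total += loss * z.size
        count += z.size
    return total / max(count, 1)


def fit(
    model: Model,
    x: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    branch: str = "model",
    split: Tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainHistory:
    """Minibatch-Adam training with 80/20 validation-based model selection.

    Mutates ``model`` in place, leaving it at the best-validation epoch.
    ``split`` fixes the (train, validation) index pair explicitly — used when
    several components must share one validation set; otherwise it is drawn
    from the config seed.
    """
    cfg.validate()
    seeds = derive_seeds(cfg.seed, "split", "init", "shuffle")
    if split is None:
        train_idx, val_idx = split_train_val(len(x), cfg.val_fraction, seeds["split"])
    else:
        train_idx, val_idx = split
    x_tr, y_tr = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate,
                  weight_decay=cfg.weight_decay)
    shuffle_rng = np.random.default_rng(seeds["shuffle"])
    history = TrainHistory()
    best_state, best_val = None, np.inf

    for epoch in range(cfg.max_epochs):
        order = shuffle_rng.permutation(len(x_tr))
        epoch_total, epoch_count = 0.0, 0
        for bstart in range(0, len(order), cfg.batch_size):
            bidx = order[bstart : bstart + cfg.batch_size]
            z = model.forward_logits(x_tr[bidx])
            loss, dz = nn.bce_with_logits(z, y_tr[bidx])
            if not np.isfinite(loss):
                raise TrainingError(
                    f"{branch}: non-finite loss at epoch {epoch}, "
                    f"batch {bstart // cfg.batch_size}"
                )
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            if isinstance(model, WeightedClassifier):
                model.enforce_masks()
            epoch_total += loss * z.size
            epoch_count += z.size
        history.train_loss.append(epoch_total / max(epoch_count, 1))
        val_loss = _epoch_loss(model, x_val, y_val)
        history.val_loss.append(val_loss)
        if val_loss < best_val:
            best_val, best_state = val_loss, model.state_dict()
        if epoch - history.best_epoch >= cfg.patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def build_branch_model(
    branch: str,
    data: np.ndarray,
    n_terms: int,
    seed: int,
    vocab_size: int | None = None,
) -> Model:
    """Construct the branch model whose input shapes match ``data``."""
    rng = np.random.default_rng(seed)
    if branch == "sequence":
        cfg = SequenceSubmodelConfig(input_len=data.shape[1], output_dim=n_terms)
        return SequenceNet(cfg, rng)
    if branch == "ppi":
        return PPINet(PPISubmodelConfig(input_dim=data.shape[1], output_dim=n_terms), rng)
    if branch == "domain":
        vocab = vocab_size if vocab_size is not None else int(data.max()) + 1
        cfg = DomainSubmodelConfig(
            vocab_size=vocab, sentence_len=data.shape[1], output_dim=n_terms
        )
        return DomainNet(cfg, rng)
    raise ConfigurationError(f"unknown branch {branch!r}")


def pretrain_submodel(
    branch: str,
    data: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
    vocab_size: int | None = None,
    split: Tuple[np.ndarray, np.ndarray] | None = None,
) -> Tuple[Model, TrainHistory]:
    """Pretrain one branch against the label vectors with BCE + Adam."""
    seeds = derive_seeds(cfg.seed, f"{branch}.init", f"{branch}.fit")
    model = build_branch_model(branch, data, labels.shape[1], seeds[f"{branch}.init"],
                               vocab_size)
    fit_cfg = TrainConfig(**{**cfg.__dict__, "seed": seeds[f"{branch}.fit"]})
    history = fit(model, data, labels, fit_cfg, branch=branch, split=split)
    return model, history


def train_classifier(
    branch_outputs: Sequence[np.ndarray],
    labels: np.ndarray,
    cfg: TrainConfig,
    masks: MaskPair | None = None,
) -> Tuple[WeightedClassifier, TrainHistory]:
    """Train the weighted classifier on frozen, precomputed branch scores."""
    mats = [np.asarray(m, dtype=np.float32) for m in branch_outputs]
    if len({m.shape for m in mats}) != 1:
        raise ConfigurationError(
            f"branch output shapes differ: {[m.shape for m in mats]}"
        )
    n_terms = mats[0].shape[1]
    seeds = derive_seeds(cfg.seed, "classifier.init", "classifier.fit")
    model = WeightedClassifier(
        n_terms,
        np.random.default_rng(seeds["classifier.init"]),
        masks=masks,
        n_branches=len(mats),
    )
    x = np.concatenate(mats, axis=1)
    fit_cfg = TrainConfig(**{**cfg.__dict__, "seed": seeds["classifier.fit"]})
    history = fit(model, x, labels, fit_cfg, branch="classifier")
    if (np.abs(model.hidden.weight.value * (1 - model.masks.input_mask)) > 0).any():
        raise TrainingError("classifier mask violated after training")
    return model, history


# Cross-validation and the no-domain ablation operate on encoded datasets and
# live with the pipeline plumbing; lazily re-exported here to complete the
# training surface without a circular import.
def __getattr__(name: str):
    if name in ("run_kfold_cv", "run_domain_ablation", "run_pipeline"):
        from . import pipeline

        return getattr(pipeline, name)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
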