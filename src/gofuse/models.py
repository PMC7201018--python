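"""The three feature branches and the mask-constrained weighted classifier.

* ``SequenceNet`` — three 1-D conv stages (out-channels 64/32/16, kernel 16,
  stride 1, same-padding, each followed by ReLU and max-pool k=2/s=2) over the
  trigram-embedding matrix, treating the 100 embedding dimensions as input
  channels; flattened and reduced by a dense layer to one logit per GO term.
* ``DomainNet`` — a trainable lookup table (vocab rows, 128-wide; padding row
  0 frozen at zero) turns the domain sentence into an M x 128 matrix; two conv
  stages (out-channels 128/64, kernel 2, stride 2) treat the M sentence
  positions as input channels and convolve along the embedding axis, then
  dense to T logits.
* ``PPINet`` — a three-layer trapezoidal dense net over the protein's row of
  the thresholded PPI score matrix (input N, hidden intermediate, output T).
* ``WeightedClassifier`` — one tiny classifier per GO term: hidden node j sees
  only the three branch scores for term j (constant binary input mask with row
  sums 3), and output node j sees only hidden node j (identity output mask).

Every head is a sigmoid: training minimises binary cross-entropy, so outputs
must live in (0, 1).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np

from . import nn
from .errors import ConfigurationError, ShapeError

#: Branch order used everywhere a classifier input is assembled.
BRANCHES = ("sequence", "domain", "ppi")


@dataclass(frozen=True)
class MaskPair:
    """Constant binary wiring of the weighted classifier.

    ``input_mask`` has shape (T, B*T) with ones at columns {j, T+j, ...,
    (B-1)T+j} in row j — hidden node j accepts exactly one score per branch.
    ``output_mask`` is the T x T identity.
    """

    input_mask: np.ndarray
    output_mask: np.ndarray

    @property
    def n_branches(self) -> int:
        return int(self.input_mask.sum(axis=1)[0])


def build_classifier_masks(n_terms: int, n_branches: int = 3) -> MaskPair:
    """Masks for ``n_terms`` per-term classifiers over ``n_branches`` branches."""
    if n_terms < 1:
        raise ConfigurationError(f"need at least one GO term, got {n_terms}")
    if n_branches < 1:
        raise ConfigurationError(f"need at least one branch, got {n_branches}")
    input_mask = np.zeros((n_terms, n_branches * n_terms), dtype=np.float32)
    rows = np.arange(n_terms)
    for b in range(n_branches):
        input_mask[rows, b * n_terms + rows] = 1.0
    return MaskPair(input_mask=input_mask, output_mask=np.eye(n_terms, dtype=np.float32))


@dataclass(frozen=True)
class PredictionScores:
    """Per-protein, per-term probabilities in [0, 1], aligned with a term set."""

    protein_ids: Sequence[str]
    terms: Sequence[str]
    matrix: np.ndarray


def term_set_hash(terms: Sequence[str]) -> str:
    """Stable fingerprint of an ordered term list, for checkpoint compatibility."""
    return hashlib.sha256("\n".join(terms).encode()).hexdigest()[:16]


class Model:
    """Shared surface of the four trainable models."""

    net: nn.Sequential

    def parameters(self) -> List[nn.Parameter]:
        return self.net.parameters()

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(self._prepare(x))

    def backward(self, dz: np.ndarray) -> None:
        self.net.backward(dz)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Sigmoid probabilities, computed in minibatches to bound memory."""
        x = np.asarray(x)
        outs = [
            nn.sigmoid(self.forward_logits(x[i : i + batch_size]))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        return x

    def state_dict(self) -> Dict[str, np.ndarray]:
        return nn.state_dict(self.net)

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        nn.load_state_dict(self.net, state)
        if hasattr(self, "enforce_masks"):
            self.enforce_masks()


@dataclass(frozen=True)
class SequenceSubmodelConfig:
    input_len: int = 1498
    in_channels: int = 100
    conv_out_channels: tuple = (64, 32, 16)
    conv_kernel: int = 16
    conv_stride: int = 1
    pool_kernel: int = 2
    output_dim: int = 0
    fc_hidden: int | None = None  # optional extra dense layer before the head


class SequenceNet(Model):
    """CNN over the (length, 100) trigram-embedding matrix."""

    def __init__(self, config: SequenceSubmodelConfig, rng: np.random.Generator):
        if config.output_dim < 1:
            raise ConfigurationError("output_dim must be >= 1")
        self.config = config
        layers: list[nn.Layer] = []
        in_ch, length = config.in_channels, config.input_len
        for out_ch in config.conv_out_channels:
            layers += [
                nn.Conv1d(in_ch, out_ch, config.conv_kernel, config.conv_stride, rng),
                nn.ReLU(),
                nn.MaxPool1d(config.pool_kernel),
            ]
            length = -(-length // config.conv_stride) // config.pool_kernel
            in_ch = out_ch
        if length < 1:
            raise ConfigurationError(
                f"input length {config.input_len} collapses to an empty feature "
                "map after conv/pool stages"
            )
        flat = in_ch * length
        layers.append(nn.Flatten())
        if config.fc_hidden:
            layers += [nn.Linear(flat, config.fc_hidden, rng), nn.ReLU()]
            flat = config.fc_hidden
        layers.append(nn.Linear(flat, config.output_dim, rng))
        self.net = nn.Sequential(*layers)

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        expected = (self.config.input_len, self.config.in_channels)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1:] != expected:
            raise ShapeError(
                f"sequence branch expected (batch, {expected[0]}, {expected[1]}), "
                f"got {x.shape}"
            )
        return x.transpose(0, 2, 1)  # embedding dims become conv channels


@dataclass(frozen=True)
class PPISubmodelConfig:
    input_dim: int = 0
    hidden_dim: int | None = None  # default: geometric mean of input and output
    output_dim: int = 0

    def resolved_hidden(self) -> int:
        if self.hidden_dim is not None:
            h = self.hidden_dim
        else:
            h = int(round(np.sqrt(self.input_dim * self.output_dim)))
        return int(min(max(h, self.output_dim), max(self.input_dim, self.output_dim)))


class PPINet(Model):
    """Three-layer trapezoidal dense net over a PPI score-matrix row."""

    def __init__(self, config: PPISubmodelConfig, rng: np.random.Generator):
        if config.input_dim < 1 or config.output_dim < 1:
            raise ConfigurationError("PPI net needs input_dim and output_dim >= 1")
        self.config = config
        hidden = config.resolved_hidden()
        self.net = nn.Sequential(
            nn.Linear(config.input_dim, hidden, rng),
            nn.ReLU(),
            nn.Linear(hidden, config.output_dim, rng),
        )

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 1:
            x = x[None]
        if x.ndim != 2 or x.shape[1] != self.config.input_dim:
            raise ShapeError(
                f"PPI branch expected (batch, {self.config.input_dim}), got {x.shape}"
            )
        return x


@dataclass(frozen=True)
class DomainSubmodelConfig:
    vocab_size: int = 0          # distinct domains + 1 (padding row)
    sentence_len: int = 0        # M_max: dataset-wide maximum domain count
    embed_dim: int = 128
    conv_out_channels: tuple = (128, 64)
    conv_kernel: int = 2
    conv_stride: int = 2
    pool_kernel: int = 2
    output_dim: int = 0
    freeze_padding: bool = True
    #: True: sentence positions are conv in-channels and the convolution runs
    #: along the embedding axis (in-channels = M_max). False: conventional
    #: orientation with embedding dims as channels.
    channels_are_positions: bool = True


class DomainNet(Model):
    """Lookup table + CNN over the sorted domain sentence."""

    def __init__(self, config: DomainSubmodelConfig, rng: np.random.Generator):
        if config.vocab_size < 1 or config.sentence_len < 1 or config.output_dim < 1:
            raise ConfigurationError(
                "domain net needs vocab_size, sentence_len and output_dim >= 1"
            )
        self.config = config
        self.embedding = nn.Embedding(
            config.vocab_size, config.embed_dim, rng, config.freeze_padding
        )
        if config.channels_are_positions:
            in_ch, length = config.sentence_len, config.embed_dim
        else:
            in_ch, length = config.embed_dim, config.sentence_len
        layers: list[nn.Layer] = [self.embedding]
        for out_ch in config.conv_out_channels:
            layers += [
                nn.Conv1d(in_ch, out_ch, config.conv_kernel, config.conv_stride, rng),
                nn.ReLU(),
                nn.MaxPool1d(config.pool_kernel),
            ]
            length = -(-length // config.conv_stride) // config.pool_kernel
            in_ch = out_ch
        if length < 1:
            raise ConfigurationError(
                "embedding width collapses to an empty feature map after "
                "conv/pool stages"
            )
        flat = in_ch * length
        layers += [nn.Flatten(), nn.Linear(flat, config.output_dim, rng)]
        # embedding output is (batch, M, embed_dim); transpose only if the
        # conventional orientation is requested
        self._transpose_after_embed = not config.channels_are_positions
        self.net = nn.Sequential(*layers)

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        idx = self._prepare(x)
        h = self.embedding.forward(idx)
        if self._transpose_after_embed:
            h = np.ascontiguousarray(h.transpose(0, 2, 1))
        for layer in self.net.layers[1:]:
            h = layer.forward(h)
        return h

    def backward(self, dz: np.ndarray) -> None:
        dy = dz
        for layer in reversed(self.net.layers[1:]):
            dy = layer.backward(dy)
        if self._transpose_after_embed:
            dy = dy.transpose(0, 2, 1)
        self.embedding.backward(dy)

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        idx = np.asarray(x)
        if idx.ndim == 1:
            idx = idx[None]
        if idx.ndim != 2 or idx.shape[1] != self.config.sentence_len:
            raise ShapeError(
                f"domain branch expected (batch, {self.config.sentence_len}) "
                f"integer sentences, got {idx.shape}"
            )
        return idx


class WeightedClassifier(Model):
    """Per-term fusion of the branch probabilities under constant binary masks.

    Input is the concatenation of the branch score vectors (order
    :data:`BRANCHES`, restricted to the branches present); output j depends on
    the position-j scores only.
    """

    def __init__(self, n_terms: int, rng: np.random.Generator,
                 masks: MaskPair | None = None, n_branches: int = 3):
        self.masks = masks or build_classifier_masks(n_terms, n_branches)
        self.n_terms = n_terms
        self.hidden = nn.MaskedLinear(self.masks.input_mask, rng, nonnegative_init=True)
        self.out = nn.MaskedLinear(self.masks.output_mask, rng, nonnegative_init=True)
        self.net = nn.Sequential(self.hidden, nn.ReLU(), self.out)

    def enforce_masks(self) -> None:
        self.hidden.enforce_mask()
        self.out.enforce_mask()

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 1:
            x = x[None]
        expected = self.masks.input_mask.shape[1]
        if x.ndim != 2 or x.shape[1] != expected:
            raise ShapeError(
                f"classifier expected (batch, {expected}) concatenated branch "
                f"scores, got {x.shape}"
            )
        return x

    def forward_branches(self, *branch_scores: np.ndarray) -> np.ndarray:
        """Probability output from per-branch score matrices of shape (B, T)."""
        mats = [np.asarray(s, dtype=np.float32) for s in branch_scores]
        if len({m.shape for m in mats}) != 1:
            raise ShapeError(
                f"branch score shapes differ: {[m.shape for m in mats]}"
            )
        return nn.sigmoid(self.forward_logits(np.concatenate(mats, axis=1)))


def save_checkpoint(model: Model, path: str | Path, manifest: dict) -> None:
    """Persist parameters (.npz) plus a JSON manifest side by side."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def load_checkpoint(model: Model, path: str | Path) -> dict:
    """Load parameters into ``model`` and return the manifest."""
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    manifest_path = path.with_suffix(".json")
    if manifest_path.exists():
        with open(manifest_path) as fh:
            return json.load(fh)
    return {}
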