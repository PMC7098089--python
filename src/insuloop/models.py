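"""The five-model stack for insulator-loop prediction, plus evaluation metrics.

Model kinds
-----------
``cnn_anchor``
    Dilated convolutional network over a one-hot anchor window: a 17x5
    convolution (full channel depth), batch norm, leaky ReLU (slope 0.2),
    dropout 0.3, three parallel dilated 5-kernel convolutions (dilation rates
    1, 3, 7) whose outputs are concatenated, batch norm, leaky ReLU, global
    max pooling, dropout, then dense layers (256, 128) and a sigmoid output.
``rnn_anchor``
    Two stacked bidirectional LSTM layers (64 units each, dropout 0.2 after
    each) over the central window of the anchor (800 of 4000 bases by
    default), a time-distributed linear map, then the same dense head.
``anchor``
    The combined model: the trained CNN and RNN with their dense heads
    stripped, features concatenated into a new dense head (512, 256).
``orientation``
    The anchor architecture with a fresh dense head (256, 128) retrained to
    separate left (negative) from right (positive) anchors; its feature
    trunks start from the anchor model's weights and are fine-tuned.
``loop``
    Consumes a pair of encoded anchors; the anchor and orientation feature
    extractors are applied to each side with shared weights, and their
    features plus the anchor/orientation probabilities feed a new dense head
    (512, 256). Pretrained components are frozen by default.

All widths shrink with ``ModelConfig.scale`` (topology is unchanged), so the
full-size architecture and desk-scale test models share every code path.
Training minimizes binary cross-entropy with RMSprop and keeps the
best-validation-loss parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score

from . import nn
from .seqcore import rc_encoded

logger = logging.getLogger(__name__)

MODEL_KINDS = ("cnn_anchor", "rnn_anchor", "anchor", "orientation", "loop")


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Width parameters are the full-size values; ``scale`` multiplies all of
    them (rounded, minimum 1) for desk-scale models. ``rnn_window`` is the
    number of central bases the recurrent models see.
    """

    anchor_length: int = 4000
    rnn_window: int = 800
    conv1_filters: int = 256
    conv1_kernel: int = 17
    dilated_filters: int = 512
    dilated_kernel: int = 5
    dilation_rates: tuple = (1, 3, 7)
    leaky_slope: float = 0.2
    cnn_dropout: float = 0.3
    rnn_dropout: float = 0.2
    lstm_units: int = 64
    lstm_layers: int = 2
    td_units: int = 1
    dense_cnn_rnn: tuple = (256, 128)
    dense_combined: tuple = (512, 256)
    dense_orientation: tuple = (256, 128)
    scale: float = 1.0
    kmer_init_boost: float = 0.3  # k-mer-detector seeding of conv1 filters
    learning_rate: float = 1e-3
    clip_norm: float = 0.0  # global gradient-norm clip; 0 disables
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 5
    strand_average: bool = False
    fine_tune_orientation: bool = True
    fine_tune_loop_components: bool = False

    def __post_init__(self) -> None:
        if self.rnn_window > self.anchor_length:
            raise ValueError("rnn_window must not exceed anchor_length")
        if not (0 < self.cnn_dropout < 1 and 0 < self.rnn_dropout < 1):
            raise ValueError("dropout rates must lie in (0, 1)")

    def width(self, n: int) -> int:
        return max(1, round(n * self.scale))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        for k in ("dilation_rates", "dense_cnn_rnn", "dense_combined",
                  "dense_orientation"):
            d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# trunk / head constructors
# ---------------------------------------------------------------------------

def _build_cnn_trunk(cfg: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    """First convolution, then three parallel dilated convolutions whose
    outputs are concatenated, batch-normalized, activated, global-max-pooled
    and dropped out.

    Batch norm, leaky ReLU and global max pooling are all per-channel, so
    each dilated branch is normalized/activated/pooled separately and the
    pooled vectors concatenated — element-for-element identical to
    concatenating the full-length feature maps first, but it never
    materializes the triple-width map (a large saving on bandwidth-bound
    hosts)."""
    f1 = cfg.width(cfg.conv1_filters)
    f2 = cfg.width(cfg.dilated_filters)
    branches = [
        nn.Sequential([
            nn.Conv1D(f1, f2, cfg.dilated_kernel, rng, dilation=d, same=True),
            nn.BatchNorm(f2),
            nn.LeakyReLU(cfg.leaky_slope),
            nn.GlobalMaxPool(),
        ])
        for d in cfg.dilation_rates
    ]
    conv1 = nn.Conv1D(5, f1, cfg.conv1_kernel, rng)
    conv1.needs_input_grad = False  # one-hot input needs no gradient
    # seed each first-layer filter as a random k-mer detector on top of the
    # noise init: filters then produce informative max-pool contrasts from
    # the start, which removes the long dead plateau that max pooling
    # otherwise causes on motif tasks (cf. PWM-style initialization in
    # sequence CNNs)
    W = conv1.params["W"].reshape(cfg.conv1_kernel, 5, f1)
    kmer_bases = rng.integers(0, 4, size=(cfg.conv1_kernel, f1))
    boost = np.float32(cfg.kmer_init_boost)
    for j in range(cfg.conv1_kernel):
        W[j, kmer_bases[j], np.arange(f1)] += boost
    return nn.Sequential([
        conv1,
        nn.BatchNorm(f1),
        nn.LeakyReLU(cfg.leaky_slope),
        nn.Dropout(cfg.cnn_dropout),
        nn.ParallelConcat(branches),
        nn.Dropout(cfg.cnn_dropout),
    ])


def _build_rnn_trunk(cfg: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    u = cfg.width(cfg.lstm_units)
    layers: list[nn.Layer] = []
    n_in = 5
    for _ in range(cfg.lstm_layers):
        layers.append(nn.BiLSTM(n_in, u, rng))
        layers.append(nn.Dropout(cfg.rnn_dropout))
        n_in = 2 * u
    layers.append(nn.TimeDistributedDense(n_in, cfg.td_units, rng))
    layers.append(nn.Flatten())
    return nn.Sequential(layers)


def _build_head(in_dim: int, hidden: Sequence[int], slope: float,
                rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    for h in hidden:
        layers.append(nn.Dense(in_dim, h, rng))
        layers.append(nn.LeakyReLU(slope))
        in_dim = h
    layers.append(nn.Dense(in_dim, 1, rng))
    return nn.Sequential(layers)


def _cnn_feat_dim(cfg: ModelConfig) -> int:
    return len(cfg.dilation_rates) * cfg.width(cfg.dilated_filters)


def _rnn_feat_dim(cfg: ModelConfig) -> int:
    return cfg.rnn_window * cfg.td_units


def _central_slice(x: np.ndarray, window: int) -> np.ndarray:
    start = (x.shape[1] - window) // 2
    return x[:, start:start + window, :]


def _cnn_maps_and_features(trunk: nn.Sequential, x: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Inference forward pass capturing the pre-pooling conv feature maps.

    Returns ``(maps, features)``: maps is the channel-concatenation of each
    dilated branch's activations entering global max pooling, features the
    trunk output (the pooled vector)."""
    h = np.asarray(x, dtype=nn.F32)
    maps = None
    for layer in trunk.layers:
        if isinstance(layer, nn.ParallelConcat):
            branch_maps, pooled = [], []
            for br in layer.branches:
                bh = h
                for sub in br.layers:
                    if isinstance(sub, nn.GlobalMaxPool):
                        branch_maps.append(bh)
                    bh = sub.forward(bh, False)
                pooled.append(bh)
            maps = np.concatenate(branch_maps, axis=2)
            h = np.concatenate(pooled, axis=1)
        else:
            h = layer.forward(h, False)
    return maps, h


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class BaseModel:
    """Common predict / save / load machinery for the five model kinds."""

    kind = "base"

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.history: list[dict] = []
        self.roots: dict[str, nn.Layer] = {}

    # -- plumbing -----------------------------------------------------------
    def _finalize(self) -> None:
        for root in self.roots.values():
            nn.set_rng(root, self.rng)

    def trainable_layers(self) -> list[nn.Layer]:
        out = []
        for root in self.roots.values():
            out.extend(l for l in nn.iter_layers(root) if l.params and l.trainable)
        return out

    def architecture(self) -> list[str]:
        """Flat layer-type listing, for topology introspection."""
        out = []
        for name, root in sorted(self.roots.items()):
            out.extend(f"{name}/{type(l).__name__}" for l in nn.iter_layers(root))
        return out

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in nn.named_params(self.roots).items()}

    def set_params(self, flat: dict[str, np.ndarray]) -> None:
        nn.load_params(self.roots, flat)

    # -- prediction ---------------------------------------------------------
    def forward_logits(self, inputs, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dz: np.ndarray) -> None:
        raise NotImplementedError

    def predict_logits(self, inputs, batch_size: int = 512) -> np.ndarray:
        inputs = _as_tuple(inputs)
        n = inputs[0].shape[0]
        out = np.empty(n, dtype=np.float64)
        for i in range(0, n, batch_size):
            chunk = tuple(a[i:i + batch_size] for a in inputs)
            out[i:i + batch_size] = self.forward_logits(chunk).ravel()
        return out

    def predict(self, inputs, batch_size: int = 512) -> np.ndarray:
        """Scores in [0, 1]; optionally averaged over both strands."""
        p = nn.sigmoid(self.predict_logits(inputs, batch_size))
        if self.config.strand_average:
            flipped = tuple(rc_encoded(a) for a in _as_tuple(inputs))
            if self.kind == "loop":  # swapping sides mirrors the loop
                flipped = (flipped[1], flipped[0])
            p = 0.5 * (p + nn.sigmoid(self.predict_logits(flipped, batch_size)))
        return p

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "config.json").write_text(json.dumps(
            {"kind": self.kind, "seed": self.seed,
             "config": json.loads(self.config.to_json())}, indent=1))
        np.savez(path / "params.npz", **nn.named_params(self.roots))
        (path / "architecture.json").write_text(
            json.dumps(self.architecture(), indent=1))
        with open(path / "history.tsv", "w") as fh:
            fh.write("epoch\ttrain_loss\tval_loss\tval_ap\n")
            for row in self.history:
                fh.write(f"{row['epoch']}\t{row['train_loss']:.6f}"
                         f"\t{row['val_loss']:.6f}\t{row['val_ap']:.6f}\n")

    @classmethod
    def load(cls, path: str | Path) -> "BaseModel":
        return load_model(path)

    def _load_state(self, path: Path) -> None:
        with np.load(path / "params.npz") as data:
            self.set_params({k: data[k] for k in data.files})
        hist = (path / "history.tsv").read_text().splitlines()[1:]
        self.history = []
        for line in hist:
            e, tl, vl, ap = line.split("\t")
            self.history.append({"epoch": int(e), "train_loss": float(tl),
                                 "val_loss": float(vl), "val_ap": float(ap)})


def _as_tuple(inputs):
    return inputs if isinstance(inputs, (tuple, list)) else (inputs,)


class CnnAnchorModel(BaseModel):
    kind = "cnn_anchor"

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__(config, seed)
        self.trunk = _build_cnn_trunk(config, self.rng)
        sizes = tuple(config.width(s) for s in config.dense_cnn_rnn)
        self.head = _build_head(_cnn_feat_dim(config), sizes,
                                config.leaky_slope, self.rng)
        self.roots = {"trunk": self.trunk, "head": self.head}
        self._finalize()

    def features(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.trunk.forward(np.asarray(x, dtype=nn.F32), training)

    def forward_logits(self, inputs, training: bool = False) -> np.ndarray:
        (x,) = _as_tuple(inputs)
        return self.head.forward(self.features(x, training), training)

    def backward(self, dz: np.ndarray) -> None:
        self.trunk.backward(self.head.backward(dz))

    def cam_maps_and_weights(self, x: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
        """Final conv feature maps and per-sample class-head weights.

        Returns ``(maps, weights)`` with maps of shape (n, L', C) — the
        activations entering global max pooling — and weights of shape
        (n, C): the gradient of the output logit with respect to the pooled
        feature vector (for a single dense output layer this reduces to the
        classic class-activation-map weights).
        """
        x = np.asarray(x, dtype=nn.F32)
        maps, feats = _cnn_maps_and_features(self.trunk, x)
        self.head.forward(feats, training=False)
        weights = self.head.backward(np.ones((x.shape[0], 1), dtype=nn.F32))
        return maps, weights[:, :maps.shape[-1]]


class RnnAnchorModel(BaseModel):
    kind = "rnn_anchor"

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__(config, seed)
        self.trunk = _build_rnn_trunk(config, self.rng)
        sizes = tuple(config.width(s) for s in config.dense_cnn_rnn)
        self.head = _build_head(_rnn_feat_dim(config), sizes,
                                config.leaky_slope, self.rng)
        self.roots = {"trunk": self.trunk, "head": self.head}
        self._finalize()

    def features(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = _central_slice(np.asarray(x, dtype=nn.F32), self.config.rnn_window)
        return self.trunk.forward(x, training)

    def forward_logits(self, inputs, training: bool = False) -> np.ndarray:
        (x,) = _as_tuple(inputs)
        return self.head.forward(self.features(x, training), training)

    def backward(self, dz: np.ndarray) -> None:
        self.trunk.backward(self.head.backward(dz))


class CombinedAnchorModel(BaseModel):
    """CNN + RNN trunks with heads stripped; features feed a new dense head."""

    kind = "anchor"

    def __init__(self, config: ModelConfig, seed: int = 0,
                 cnn: CnnAnchorModel | None = None,
                 rnn: RnnAnchorModel | None = None,
                 head_sizes: Sequence[int] | None = None,
                 freeze_trunks: bool = True):
        super().__init__(config, seed)
        rng = self.rng
        self.cnn_trunk = _build_cnn_trunk(config, rng)
        self.rnn_trunk = _build_rnn_trunk(config, rng)
        if cnn is not None:
            nn.load_params({"t": self.cnn_trunk},
                           nn.named_params({"t": cnn.trunk}))
        if rnn is not None:
            nn.load_params({"t": self.rnn_trunk},
                           nn.named_params({"t": rnn.trunk}))
        sizes = tuple(config.width(s) for s in
                      (head_sizes or config.dense_combined))
        feat_dim = _cnn_feat_dim(config) + _rnn_feat_dim(config)
        self.head = _build_head(feat_dim, sizes, config.leaky_slope, rng)
        self.freeze_trunks = freeze_trunks
        if freeze_trunks:
            for trunk in (self.cnn_trunk, self.rnn_trunk):
                for layer in nn.iter_layers(trunk):
                    layer.trainable = False
        self.roots = {"cnn_trunk": self.cnn_trunk, "rnn_trunk": self.rnn_trunk,
                      "head": self.head}
        self._finalize()

    def features(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=nn.F32)
        t = training and not self.freeze_trunks
        cfeat = self.cnn_trunk.forward(x, t)
        rfeat = self.rnn_trunk.forward(
            _central_slice(x, self.config.rnn_window), t)
        return np.concatenate([cfeat, rfeat], axis=1)

    def forward_logits(self, inputs, training: bool = False) -> np.ndarray:
        (x,) = _as_tuple(inputs)
        return self.head.forward(self.features(x, training), training)

    def backward(self, dz: np.ndarray) -> None:
        dfeat = self.head.backward(dz)
        if not self.freeze_trunks:
            cdim = _cnn_feat_dim(self.config)
            self.cnn_trunk.backward(dfeat[:, :cdim])
            self.rnn_trunk.backward(dfeat[:, cdim:])

    def cam_maps_and_weights(self, x: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=nn.F32)
        maps, cfeat = _cnn_maps_and_features(self.cnn_trunk, x)
        rfeat = self.rnn_trunk.forward(
            _central_slice(x, self.config.rnn_window), False)
        self.head.forward(np.concatenate([cfeat, rfeat], axis=1),
                          training=False)
        dfeat = self.head.backward(np.ones((x.shape[0], 1), dtype=nn.F32))
        return maps, dfeat[:, :maps.shape[-1]]


class OrientationModel(CombinedAnchorModel):
    """Left-vs-right anchor classifier; right anchors are the positive class."""

    kind = "orientation"

    def __init__(self, config: ModelConfig, seed: int = 0,
                 anchor_model: CombinedAnchorModel | None = None):
        super().__init__(config, seed, head_sizes=config.dense_orientation,
                         freeze_trunks=not config.fine_tune_orientation)
        if anchor_model is not None:
            nn.load_params(
                {"c": self.cnn_trunk, "r": self.rnn_trunk},
                nn.named_params({"c": anchor_model.cnn_trunk,
                                 "r": anchor_model.rnn_trunk}))


class LoopModel(BaseModel):
    """Pair model: shared anchor/orientation feature extractors per side,
    concatenated with the component probabilities, feeding a new dense head."""

    kind = "loop"

    def __init__(self, config: ModelConfig, seed: int = 0,
                 anchor_model: CombinedAnchorModel | None = None,
                 orientation_model: OrientationModel | None = None):
        super().__init__(config, seed)
        if anchor_model is None or orientation_model is None:
            raise ValueError(
                "loop model composition requires trained anchor and "
                "orientation components")
        self.anchor_model = anchor_model
        self.orientation_model = orientation_model
        freeze = not config.fine_tune_loop_components
        self._frozen = freeze
        if freeze:
            for m in (anchor_model, orientation_model):
                for root in m.roots.values():
                    for layer in nn.iter_layers(root):
                        layer.trainable = False
        feat_dim = _cnn_feat_dim(config) + _rnn_feat_dim(config)
        in_dim = 2 * feat_dim + 4  # per-side features + 4 component probs
        sizes = tuple(config.width(s) for s in config.dense_combined)
        dense = _build_head(in_dim, sizes, config.leaky_slope, self.rng)
        # the concatenated input mixes pooled conv features, flattened
        # recurrent features and component probabilities on very different
        # scales; normalizing it keeps the small probability block visible
        self.head = nn.Sequential([nn.BatchNorm(in_dim)] + dense.layers)
        self.roots = {"head": self.head}
        for name, root in anchor_model.roots.items():
            self.roots[f"anchor.{name}"] = root
        for name, root in orientation_model.roots.items():
            self.roots[f"orient.{name}"] = root
        self._finalize()

    def pair_features(self, xl: np.ndarray, xr: np.ndarray) -> np.ndarray:
        """Head input: anchor features of each side plus component scores."""
        parts = []
        for x in (xl, xr):
            feats = self.anchor_model.features(x)
            p_anchor = nn.sigmoid(
                self.anchor_model.head.forward(feats, False)).astype(nn.F32)
            p_orient = nn.sigmoid(
                self.orientation_model.forward_logits((x,))).astype(nn.F32)
            parts.extend([feats, p_anchor, p_orient])
        return np.concatenate(parts, axis=1)

    def forward_logits(self, inputs, training: bool = False) -> np.ndarray:
        xl, xr = _as_tuple(inputs)
        return self.head.forward(self.pair_features(xl, xr), training)

    def backward(self, dz: np.ndarray) -> None:
        self.head.backward(dz)  # components are frozen


def build_model(kind: str, config: ModelConfig, seed: int = 0,
                components: dict | None = None) -> BaseModel:
    """Construct an untrained model of the given kind.

    ``anchor`` accepts pretrained ``cnn``/``rnn`` components, ``orientation``
    a pretrained ``anchor`` component, and ``loop`` requires trained
    ``anchor`` and ``orientation`` components.
    """
    components = components or {}
    if kind == "cnn_anchor":
        return CnnAnchorModel(config, seed)
    if kind == "rnn_anchor":
        return RnnAnchorModel(config, seed)
    if kind == "anchor":
        return CombinedAnchorModel(config, seed, cnn=components.get("cnn"),
                                   rnn=components.get("rnn"),
                                   head_sizes=None)
    if kind == "orientation":
        return OrientationModel(config, seed,
                                anchor_model=components.get("anchor"))
    if kind == "loop":
        return LoopModel(config, seed,
                         anchor_model=components.get("anchor"),
                         orientation_model=components.get("orientation"))
    raise ValueError(f"unknown model kind {kind!r}")


def load_model(path: str | Path) -> BaseModel:
    """Load a saved model directory; predictions are bit-stable across loads."""
    path = Path(path)
    meta = json.loads((path / "config.json").read_text())
    cfg = ModelConfig.from_json(json.dumps(meta["config"]))
    kind, seed = meta["kind"], meta["seed"]
    if kind in ("cnn_anchor", "rnn_anchor"):
        model = build_model(kind, cfg, seed)
    elif kind in ("anchor", "orientation"):
        model = build_model(kind, cfg, seed)
    elif kind == "loop":
        anchor = CombinedAnchorModel(cfg, seed)
        orient = OrientationModel(cfg, seed)
        model = LoopModel(cfg, seed, anchor_model=anchor,
                          orientation_model=orient)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    model._load_state(path)
    return model


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class TrainingDiverged(RuntimeError):
    pass


def train_model(model: BaseModel, train_set, val_set,
                config: ModelConfig | None = None, seed: int = 0) -> BaseModel:
    """Train in place; returns the model holding best-validation-loss weights.

    ``train_set`` / ``val_set`` are ``(inputs, labels)`` with inputs a single
    array (anchor tasks) or an (XL, XR) pair (loop task). History records
    per-epoch training loss, validation loss and validation average
    precision. For models whose feature extractors are frozen, features are
    precomputed once and only the dense head is iterated.
    """
    cfg = config or model.config
    rng = np.random.default_rng(seed)
    model.rng = rng
    for root in model.roots.values():
        nn.set_rng(root, rng)
    opt = nn.RMSprop(lr=cfg.learning_rate, clip_norm=cfg.clip_norm)

    tr_inputs, tr_y = _as_tuple(train_set[0]), np.asarray(train_set[1])
    va_inputs, va_y = _as_tuple(val_set[0]), np.asarray(val_set[1])

    frozen_head = (getattr(model, "_frozen", False)
                   or getattr(model, "freeze_trunks", False))
    if frozen_head:
        tr_feats = _precompute_features(model, tr_inputs)
        va_feats = _precompute_features(model, va_inputs)
        net = model.head
        fwd = lambda idx, training: net.forward(tr_feats[idx], training)
        bwd = net.backward
        val_logits = lambda: _batched(lambda a: net.forward(a, False), va_feats)
    else:
        fwd = lambda idx, training: model.forward_logits(
            tuple(a[idx] for a in tr_inputs), training)
        bwd = model.backward
        val_logits = lambda: model.predict_logits(va_inputs)

    n = tr_y.shape[0]
    best = {"loss": np.inf, "params": model.get_params(), "epoch": -1}
    bad_epochs = 0
    model.history = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            z = fwd(idx, True)
            loss, dz = nn.bce_with_logits(z, tr_y[idx])
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"NaN/inf loss at epoch {epoch}, batch {i // cfg.batch_size}: "
                    f"lr={cfg.learning_rate}, batch_size={cfg.batch_size}")
            bwd(dz)
            opt.step(model.trainable_layers())
            losses.append(loss)
        vz = val_logits()
        val_loss, _ = nn.bce_with_logits(vz, va_y)
        val_ap = average_precision(va_y, nn.sigmoid(vz))
        model.history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                              "val_loss": val_loss, "val_ap": val_ap})
        logger.info("%s epoch %d: train %.4f val %.4f ap %.4f",
                    model.kind, epoch, np.mean(losses), val_loss, val_ap)
        if val_loss < best["loss"]:
            best = {"loss": val_loss, "params": model.get_params(), "epoch": epoch}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    model.set_params(best["params"])
    return model


def _precompute_features(model, inputs, batch_size: int = 256) -> np.ndarray:
    if isinstance(model, LoopModel):
        f = lambda chunk: model.pair_features(*chunk)
    else:
        f = lambda chunk: model.features(chunk[0])
    n = inputs[0].shape[0]
    out = []
    for i in range(0, n, batch_size):
        out.append(f(tuple(a[i:i + batch_size] for a in inputs)))
    return np.concatenate(out, axis=0)


def _batched(f, x, batch_size: int = 4096) -> np.ndarray:
    return np.concatenate([f(x[i:i + batch_size]).ravel()
                           for i in range(0, x.shape[0], batch_size)])


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def average_precision(labels, scores) -> float:
    """Area under the precision-recall curve, approximated by average
    precision: the mean, over positives in score order, of precision at each
    positive, with tied scores treated as a single threshold block.

    For a constant scorer this equals the positive prevalence exactly.
    """
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores).ravel()
    if labels.sum() == 0:
        raise ValueError("average precision undefined without positives")
    return float(average_precision_score(labels, scores))


def equal_pr_threshold(labels, scores) -> float:
    """Score cutoff minimizing |precision - recall|, ties toward higher recall.

    Candidate cutoffs are the observed scores; a sample is called positive
    when its score >= the cutoff.
    """
    labels = np.asarray(labels).ravel().astype(bool)
    scores = np.asarray(scores).ravel()
    if labels.sum() == 0:
        raise ValueError("no positive labels")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    npred = np.arange(1, len(y) + 1)
    # last index of each tied block -> valid (threshold = that score)
    block_end = np.nonzero(np.diff(s, append=-np.inf) != 0)[0]
    precision = tp[block_end] / npred[block_end]
    recall = tp[block_end] / labels.sum()
    gap = np.abs(precision - recall)
    # ties toward higher recall; among equal recalls, the higher threshold
    minimal = np.nonzero(gap == gap.min())[0]
    best = minimal[np.argmax(recall[minimal])]
    return float(s[block_end[best]])
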