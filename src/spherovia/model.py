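"""The deep viability regressor: architecture, training, ensembling.

The default architecture is an 18-layer residual convolutional backbone
(batch normalization, ReLU, global average pooling to a 512-dimensional
latent vector) followed by an MLP regression head with four hidden layers of
width 32, 30% dropout before each hidden layer, and a scalar output.  With
three input channels the default model has ~11.2 million trainable
parameters (the head alone contributes 19,617).

Training minimizes mean squared error on control-normalized viability
labels with Adam (learning rate 1e-4, weight decay 5e-4, batch size 32), a
halve-on-plateau learning-rate schedule (patience 5 epochs), and early
stopping on validation loss (patience 20 epochs, best weights restored).
An ensemble is trained over the cross product of initialization seeds and
train/validation split seeds — three of each by default, nine models — and
prediction reports the per-image ensemble mean and standard deviation.

Alternative backbones (an inverted-residual convolutional net and a
patch-embedding transformer, both scaled down, plus a four-block test net)
share the same contract: a pooled latent vector feeding the same head.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from . import nn

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "ViabilityRegressor",
    "TrainedEnsemble",
    "build_model",
    "chronological_split",
    "train",
    "preprocess_images",
    "BACKBONES",
]

BACKBONES = ("resnet18_like", "efficientnet_small_like", "vit_like", "tiny_test")

# fixed intensity standardization applied identically at train and inference
_INTENSITY_MEAN = 0.5
_INTENSITY_SD = 0.25


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "resnet18_like"
    head_hidden: tuple = (32, 32, 32, 32)
    dropout: float = 0.30
    input_size: int = 224
    channels: int = 3

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def latent_dim(self) -> int:
        return {"resnet18_like": 512, "efficientnet_small_like": 1280,
                "vit_like": 192, "tiny_test": 64}[self.backbone]

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "mse"
    batch_size: int = 32
    learning_rate: float = 1e-4
    weight_decay: float = 5e-4
    lr_plateau_factor: float = 0.5
    lr_plateau_patience: int = 5
    lr_plateau_rel_threshold: float = 1e-4
    early_stop_patience: int = 20
    max_epochs: int = 150
    init_seeds: tuple = (0, 1, 2)
    split_seeds: tuple = (0, 1, 2)
    val_fraction: float = 0.2

    def __post_init__(self):
        if self.loss != "mse":
            raise ValueError("only the mean-squared-error loss is supported")
        if not self.init_seeds or not self.split_seeds:
            raise ValueError("need at least one init seed and one split seed")

    @property
    def n_replicates(self) -> int:
        return len(self.init_seeds) * len(self.split_seeds)


# ---------------------------------------------------------------------------
# architectures

def _basic_block(rng, c_in, c_out, stride):
    main = nn.Sequential(
        nn.Conv2d(c_in, c_out, 3, rng, stride=stride, pad=1, bias=False),
        nn.BatchNorm2d(c_out), nn.ReLU(),
        nn.Conv2d(c_out, c_out, 3, rng, stride=1, pad=1, bias=False),
        nn.BatchNorm2d(c_out),
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = nn.Sequential(
            nn.Conv2d(c_in, c_out, 1, rng, stride=stride, bias=False),
            nn.BatchNorm2d(c_out),
        )
    return nn.Residual(main, shortcut)


def _resnet18_backbone(rng, channels):
    plan = [(64, 64, 1), (64, 64, 1), (64, 128, 2), (128, 128, 1),
            (128, 256, 2), (256, 256, 1), (256, 512, 2), (512, 512, 1)]
    layers = [
        nn.Conv2d(channels, 64, 7, rng, stride=2, pad=3, bias=False),
        nn.BatchNorm2d(64), nn.ReLU(), nn.MaxPool2d(3, 2, pad=1),
    ]
    layers += [_basic_block(rng, *p) for p in plan]
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers)


def _tiny_backbone(rng, channels, widths=(8, 16, 32, 64)):
    layers = []
    c_in = channels
    for c_out in widths:
        layers += [
            nn.Conv2d(c_in, c_out, 3, rng, stride=2, pad=1, bias=False),
            nn.BatchNorm2d(c_out), nn.ReLU(),
        ]
        c_in = c_out
    layers.append(nn.GlobalAvgPool())
    return nn.Sequential(*layers)


def _mbconv(rng, c_in, c_out, stride, expand=4):
    c_mid = c_in * expand
    main = nn.Sequential(
        nn.Conv2d(c_in, c_mid, 1, rng, bias=False),
        nn.BatchNorm2d(c_mid), nn.ReLU(),
        nn.DepthwiseConv2d(c_mid, 3, rng, stride=stride, pad=1),
        nn.BatchNorm2d(c_mid), nn.ReLU(),
        nn.Conv2d(c_mid, c_out, 1, rng, bias=False),
        nn.BatchNorm2d(c_out),
    )
    if stride == 1 and c_in == c_out:
        return nn.Residual(main, post_relu=False)
    return nn.Sequential(main, nn.ReLU())


def _effnet_backbone(rng, channels):
    layers = [
        nn.Conv2d(channels, 24, 3, rng, stride=2, pad=1, bias=False),
        nn.BatchNorm2d(24), nn.ReLU(),
        _mbconv(rng, 24, 32, 2), _mbconv(rng, 32, 32, 1),
        _mbconv(rng, 32, 64, 2), _mbconv(rng, 64, 64, 1),
        _mbconv(rng, 64, 128, 2),
        nn.Conv2d(128, 1280, 1, rng, bias=False),
        nn.BatchNorm2d(1280), nn.ReLU(),
        nn.GlobalAvgPool(),
    ]
    return nn.Sequential(*layers)


def _vit_backbone(rng, channels, input_size, dim=192, depth=4, heads=3,
                  patch=8, dropout_seed=0):
    if input_size % patch:
        raise ValueError("input_size must be divisible by the patch size 8")
    n_tok = (input_size // patch) ** 2
    layers = [
        nn.Conv2d(channels, dim, patch, rng, stride=patch),
        nn.TokensFromImage(),
        nn.AddPositionEmbedding(n_tok, dim, rng),
    ]
    for _ in range(depth):
        attn = nn.Sequential(nn.LayerNorm(dim),
                             nn.MultiHeadSelfAttention(dim, heads, rng))
        mlp = nn.Sequential(nn.LayerNorm(dim), nn.Dense(dim, 4 * dim, rng),
                            nn.GELU(), nn.Dense(4 * dim, dim, rng))
        layers += [nn.Residual(attn, post_relu=False),
                   nn.Residual(mlp, post_relu=False)]
    layers += [nn.LayerNorm(dim), nn.MeanPoolTokens()]
    return nn.Sequential(*layers)


def _make_head(rng, latent_dim, hidden, dropout, seed):
    layers = []
    d = latent_dim
    for i, width in enumerate(hidden):
        layers += [nn.Dropout(dropout, seed=seed * 1000 + i),
                   nn.Dense(d, width, rng), nn.ReLU()]
        d = width
    layers.append(nn.Dense(d, 1, rng))
    return nn.Sequential(*layers)


class ViabilityRegressor:
    """Backbone + MLP head with access to the pooled latent vector."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        ch = config.channels
        if config.backbone == "resnet18_like":
            self.backbone = _resnet18_backbone(rng, ch)
        elif config.backbone == "tiny_test":
            self.backbone = _tiny_backbone(rng, ch)
        elif config.backbone == "efficientnet_small_like":
            self.backbone = _effnet_backbone(rng, ch)
        else:
            self.backbone = _vit_backbone(rng, ch, config.input_size)
        self.head = _make_head(rng, config.latent_dim, config.head_hidden,
                               config.dropout, seed)
        self.config_hash = config.hash()

    # -- introspection ----------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return nn.n_parameters(self.backbone) + nn.n_parameters(self.head)

    @property
    def n_head_parameters(self) -> int:
        return nn.n_parameters(self.head)

    def param_items(self):
        return self.backbone.param_items() + self.head.param_items()

    # -- compute ----------------------------------------------------------
    def forward(self, x, train=False):
        latent = self.backbone.forward(x, train=train)
        return self.head.forward(latent, train=train)[:, 0]

    def backward(self, grad_out):
        g = self.head.backward(grad_out[:, None])
        self.backbone.backward(g)

    def predict(self, x) -> np.ndarray:
        return self.forward(np.asarray(x, dtype=nn.DTYPE), train=False)

    def encode(self, x) -> np.ndarray:
        """Pooled backbone features (the model's latent vectors)."""
        return self.backbone.forward(np.asarray(x, dtype=nn.DTYPE),
                                     train=False)

    # -- persistence -------------------------------------------------------
    def state_arrays(self):
        out = {}
        for i, (lyr, name) in enumerate(self.param_items()):
            out[f"p{i}_{name}"] = lyr.params[name]
        for i, (lyr, name) in enumerate(self.buffer_items()):
            out[f"b{i}_{name}"] = getattr(lyr, name)
        return out

    def save(self, path):
        meta = {"config": asdict(self.config), "seed": self.seed,
                "config_hash": self.config_hash}
        np.savez(path, __meta__=json.dumps(meta, default=list),
                 **self.state_arrays())

    @classmethod
    def load(cls, path):
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"]))
        cfg = meta["config"]
        cfg["head_hidden"] = tuple(cfg["head_hidden"])
        model = cls(ModelConfig(**cfg), seed=meta["seed"])
        for i, (lyr, name) in enumerate(model.param_items()):
            lyr.params[name] = data[f"p{i}_{name}"]
        for i, (lyr, name) in enumerate(model.buffer_items()):
            setattr(lyr, name, data[f"b{i}_{name}"])
        return model

    def buffer_items(self):
        return self.backbone.buffer_items() + self.head.buffer_items()

    def _copy_params(self):
        """Snapshot trainable params AND normalization running stats."""
        params = [lyr.params[name].copy() for lyr, name in self.param_items()]
        bufs = [getattr(lyr, name).copy() for lyr, name in self.buffer_items()]
        return params, bufs

    def _restore_params(self, snapshot):
        params, bufs = snapshot
        for (lyr, name), arr in zip(self.param_items(), params):
            lyr.params[name] = arr.copy()
        for (lyr, name), arr in zip(self.buffer_items(), bufs):
            setattr(lyr, name, arr.copy())


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0):
    """Instantiate an untrained regressor for the given configuration."""
    return ViabilityRegressor(config, seed=seed)


# ---------------------------------------------------------------------------
# data plumbing

def preprocess_images(images, config: ModelConfig) -> np.ndarray:
    """Raw grayscale crops -> (N, C, S, S) standardized network input.

    Each image is resized to the configured input size, intensity-shifted by
    the fixed (mean 0.5, sd 0.25) standardization, and replicated across the
    configured channel count.  The same transform runs at train and
    inference time.
    """
    s = config.input_size
    out = np.empty((len(images), config.channels, s, s), dtype=nn.DTYPE)
    for i, img in enumerate(images):
        img = np.asarray(img, dtype=float)
        if img.ndim != 2:
            raise ValueError("expected 2-D grayscale images")
        if min(img.shape) < 4:
            raise ValueError(f"image {i} smaller than the 4-px crop minimum")
        if img.shape != (s, s):
            img = resize(img, (s, s), anti_aliasing=True, mode="reflect")
        out[i] = (img - _INTENSITY_MEAN) / _INTENSITY_SD
    return out


def chronological_split(df: pd.DataFrame, cutoff, study_order: dict | None = None):
    """Partition manifest rows by study into (train_val, test).

    ``cutoff`` is either an ordering-key value (studies with key < cutoff
    train) or an explicit collection of training study ids.  ``study_order``
    maps study id -> sortable key (e.g. a start date); by default the study
    id itself orders.  The split is by study — no study ever appears on both
    sides.
    """
    studies = df["Study"].astype(str)
    unique = list(dict.fromkeys(studies))
    if isinstance(cutoff, (list, tuple, set, frozenset)):
        train_ids = {str(c) for c in cutoff}
        unknown = train_ids - set(unique)
        if unknown:
            raise ValueError(f"unknown study id(s): {sorted(unknown)}")
    else:
        if study_order is not None:
            missing = [s for s in unique if s not in study_order]
            if missing:
                raise ValueError(f"no ordering key for studies {missing}")
            key = lambda s: study_order[s]
        else:
            key = lambda s: s
        train_ids = {s for s in unique if key(s) < cutoff}
    mask = studies.isin(train_ids).to_numpy()
    if mask.all():
        warnings.warn("all studies fall before the cutoff: empty test set",
                      stacklevel=2)
    train_df, test_df = df[mask].copy(), df[~mask].copy()
    assert not (set(train_df["Study"]) & set(test_df["Study"]))
    return train_df, test_df


# ---------------------------------------------------------------------------
# training

def _mse(pred, y):
    return float(np.mean((pred - y) ** 2))


def _train_single(config, x, y, tc: TrainConfig, init_seed, split_seed,
                  verbose=False):
    n = len(x)
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(tc.val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("empty training set after validation split")

    model = ViabilityRegressor(config, seed=init_seed)
    opt = nn.Adam(model.param_items(), lr=tc.learning_rate,
                  weight_decay=tc.weight_decay)
    batch_rng = np.random.default_rng((init_seed + 1) * 100003 + split_seed)

    history = []
    best_val, best_snapshot, best_epoch = np.inf, None, -1
    plateau_best, plateau_count, stop_count = np.inf, 0, 0
    for epoch in range(tc.max_epochs):
        order = batch_rng.permutation(tr_idx)
        losses = []
        for start in range(0, len(order), tc.batch_size):
            idx = order[start:start + tc.batch_size]
            pred = model.forward(x[idx], train=True)
            diff = pred - y[idx]
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(init_seed={init_seed}, split_seed={split_seed}, "
                    f"lr={opt.lr:g})")
            model.backward(2.0 * diff / len(idx))
            opt.step()
            losses.append(loss)
        val_loss = _mse(model.forward(x[val_idx], train=False), y[val_idx])
        history.append({
            "epoch": epoch, "train_mse": float(np.mean(losses)),
            "val_mse": val_loss, "lr": opt.lr,
            "plateau_counter": plateau_count, "stop_counter": stop_count,
        })
        if verbose:
            print(f"[init {init_seed}/split {split_seed}] epoch {epoch:3d} "
                  f"train {np.mean(losses):.5f} val {val_loss:.5f} lr {opt.lr:g}")
        if val_loss < best_val:
            best_val, best_epoch = val_loss, epoch
            best_snapshot = model._copy_params()
            stop_count = 0
        else:
            stop_count += 1
            if stop_count >= tc.early_stop_patience:
                break
        # halve-on-plateau schedule (relative improvement threshold)
        if val_loss < plateau_best * (1.0 - tc.lr_plateau_rel_threshold):
            plateau_best, plateau_count = val_loss, 0
        else:
            plateau_count += 1
            if plateau_count >= tc.lr_plateau_patience:
                opt.lr *= tc.lr_plateau_factor
                plateau_count = 0
    if best_snapshot is not None:
        model._restore_params(best_snapshot)
    return model, pd.DataFrame(history), best_val, best_epoch, \
        (tr_idx, val_idx)


@dataclass
class TrainedEnsemble:
    """Trained replicates with their histories and seeds."""

    models: list
    histories: list          # one DataFrame per model
    seeds: list              # (init_seed, split_seed) per model
    best_val_mse: list
    config: ModelConfig
    train_config: TrainConfig

    def __post_init__(self):
        if not self.models:
            raise ValueError("ensemble needs at least one model")

    def predict(self, images, preprocessed=False):
        """Per-image ensemble mean and sd of predicted viability."""
        x = images if preprocessed else preprocess_images(images, self.config)
        preds = np.stack([m.predict(x) for m in self.models])
        return preds.mean(axis=0), preds.std(axis=0)

    def predict_per_model(self, images, preprocessed=False):
        x = images if preprocessed else preprocess_images(images, self.config)
        return np.stack([m.predict(x) for m in self.models])

    def encode(self, images, preprocessed=False, model_index=0):
        """Latent vectors from one designated member (the first by default)."""
        x = images if preprocessed else preprocess_images(images, self.config)
        return self.models[model_index].encode(x)

    def history_frame(self) -> pd.DataFrame:
        frames = []
        for (iseed, sseed), h in zip(self.seeds, self.histories):
            h = h.copy()
            h["init_seed"], h["split_seed"] = iseed, sseed
            frames.append(h)
        return pd.concat(frames, ignore_index=True)


def train(config: ModelConfig, images, labels,
          train_config: TrainConfig = TrainConfig(), preprocessed=False,
          verbose=False) -> TrainedEnsemble:
    """Train the full seed-cross ensemble on labeled images.

    ``images`` are raw grayscale crops (or a pre-built (N, C, S, S) tensor
    with ``preprocessed=True``); ``labels`` are control-normalized viability
    values.  One model is trained per (init_seed, split_seed) pair.
    """
    y = np.asarray(labels, dtype=float)
    if y.size == 0:
        raise ValueError("empty training set")
    x = images if preprocessed else preprocess_images(images, config)
    if len(x) != y.size:
        raise ValueError("images and labels length mismatch")
    models, histories, seeds, best_vals = [], [], [], []
    for split_seed in train_config.split_seeds:
        for init_seed in train_config.init_seeds:
            m, h, best_val, _, _ = _train_single(
                config, x, y, train_config, init_seed, split_seed,
                verbose=verbose)
            models.append(m)
            histories.append(h)
            seeds.append((init_seed, split_seed))
            best_vals.append(best_val)
    return TrainedEnsemble(models, histories, seeds, best_vals, config,
                           train_config)
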