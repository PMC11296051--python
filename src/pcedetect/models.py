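"""The two prey-capture detectors: a windowed CNN and a 1D V-Net.

The CNN classifies 8-sample (0.32 s) tri-axial segments as capture /
no-capture: two 1D convolutions (128 filters, kernel 2, ReLU), dropout 0.2,
max-pool 2, a 100-unit dense layer and a 2-class softmax, trained with Adam
on categorical cross-entropy in batches of six segments for 10 epochs.

The V-Net labels every sample of a 128-sample (5.12 s) window: a 1D
encoder–decoder with stride-2 down-convolutions, residual additions within
levels, transposed-convolution upsampling and skip concatenations, ending
in a per-sample 2-class softmax.  It is trained with Adam on the
generalized dice loss using windows drawn by the biased global generator;
the weights of the epoch with the lowest validation loss are retained (for
both models).

At prediction time both detectors run on whole dives — the balancing filter
applies to training data only — and every sample at depth <= 0.4 m is
forced to 0, restricting predictions to periods when the animal is actually
submerged.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .dives import Dive
from .sampling import SamplerConfig, WindowBatch, vnet_global_generator

logger = logging.getLogger(__name__)


@dataclass
class CnnConfig:
    n_conv_layers: int = 2
    filters: int = 128
    kernel: int = 2
    dropout: float = 0.2
    pool_factor: int = 2
    dense_units: int = 100
    n_classes: int = 2
    epochs: int = 10
    batch_size: int = 6
    learning_rate: float = 1e-3
    window: int = 8
    n_channels: int = 3
    keep_best_epoch: bool = True

    def __post_init__(self) -> None:
        post_conv = self.window - self.n_conv_layers * (self.kernel - 1)
        if self.kernel > self.window:
            raise ValueError("kernel larger than the input window")
        if post_conv < 1 or post_conv % self.pool_factor:
            raise ValueError(
                f"post-convolution length {post_conv} is not divisible by "
                f"pool factor {self.pool_factor}")


@dataclass
class VnetConfig:
    input_len: int = 128
    n_channels: int = 3
    encoder_levels: int = 3
    filters_per_level: tuple[int, ...] = (16, 32, 64)
    kernel: int = 5
    n_classes: int = 2
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    keep_best_epoch: bool = True

    def __post_init__(self) -> None:
        if len(self.filters_per_level) != self.encoder_levels:
            raise ValueError("filters_per_level must list one width per level")
        down = 2 ** (self.encoder_levels - 1)
        if self.input_len % down:
            raise ValueError(
                f"input_len {self.input_len} not divisible by "
                f"2^(encoder_levels-1) = {down}")


def config_hash(cfg) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_cnn(cfg: CnnConfig, seed: int = 0) -> nn.Sequential:
    """Untrained windowed CNN over (batch, window, 3) inputs."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 1]))
    layers: list[nn.Layer] = []
    cin = cfg.n_channels
    for i in range(cfg.n_conv_layers):
        layers += [nn.Conv1D(cin, cfg.filters, cfg.kernel, rng=rng,
                             name=f"conv{i}"), nn.ReLU()]
        cin = cfg.filters
    layers += [nn.Dropout(cfg.dropout), nn.MaxPool1D(cfg.pool_factor),
               nn.Flatten()]
    post = (cfg.window - cfg.n_conv_layers * (cfg.kernel - 1)) // cfg.pool_factor
    layers += [nn.Dense(post * cfg.filters, cfg.dense_units, rng=rng,
                        name="dense"), nn.ReLU(),
               nn.Dense(cfg.dense_units, cfg.n_classes, rng=rng, name="out")]
    model = nn.Sequential(layers)
    logger.info("CNN built: %d parameters", n_params(model))
    return model


class VNet(nn.Layer):
    """1D V-Net: residual encoder levels joined by skip connections to a
    symmetric decoder, per-sample 2-class logits."""

    def __init__(self, cfg: VnetConfig, rng: np.random.Generator) -> None:
        f = cfg.filters_per_level
        k = cfg.kernel
        L = cfg.encoder_levels
        self.cfg = cfg
        self.stem = nn.Sequential([
            nn.Conv1D(cfg.n_channels, f[0], k, padding="same", rng=rng,
                      name="stem"), nn.PReLU(f[0], name="stem")])
        self.res: list[nn.Sequential] = []
        self.down: list[nn.Sequential] = []
        for i in range(L):
            blocks: list[nn.Layer] = [
                nn.Conv1D(f[i], f[i], k, padding="same", rng=rng,
                          name=f"res{i}a"), nn.PReLU(f[i], name=f"res{i}a")]
            if i == L - 1:  # deeper residual block at the bottom
                blocks += [nn.Conv1D(f[i], f[i], k, padding="same", rng=rng,
                                     name=f"res{i}b"),
                           nn.PReLU(f[i], name=f"res{i}b")]
            self.res.append(nn.Sequential(blocks))
            if i > 0:
                self.down.append(nn.Sequential([
                    nn.Conv1D(f[i - 1], f[i], 2, stride=2, rng=rng,
                              name=f"down{i}"), nn.PReLU(f[i], name=f"down{i}")]))
        self.up: list[nn.Sequential] = []
        self.mix: list[nn.Sequential] = []
        for i in range(L - 2, -1, -1):
            self.up.append(nn.Sequential([
                nn.ConvTranspose1D(f[i + 1], f[i], rng=rng, name=f"up{i}"),
                nn.PReLU(f[i], name=f"up{i}")]))
            self.mix.append(nn.Sequential([
                nn.Conv1D(2 * f[i], f[i], k, padding="same", rng=rng,
                          name=f"mix{i}"), nn.PReLU(f[i], name=f"mix{i}")]))
        self.head = nn.Conv1D(f[0], cfg.n_classes, 1, rng=rng, name="head")

    def params(self) -> list[nn.Param]:
        ps = self.stem.params()
        for blk in self.res + self.down + self.up + self.mix:
            ps += blk.params()
        return ps + self.head.params()

    def forward(self, x, *, training=False, rng=None):
        L = self.cfg.encoder_levels
        t = self.stem.forward(x, training=training, rng=rng)
        e = t + self.res[0].forward(t, training=training, rng=rng)
        skips = [e]
        for i in range(1, L):
            t = self.down[i - 1].forward(e, training=training, rng=rng)
            e = t + self.res[i].forward(t, training=training, rng=rng)
            if i < L - 1:
                skips.append(e)
        cur = e
        for j, i in enumerate(range(L - 2, -1, -1)):
            u = self.up[j].forward(cur, training=training, rng=rng)
            cat = np.concatenate([u, skips[i]], axis=-1)
            cur = u + self.mix[j].forward(cat, training=training, rng=rng)
        return self.head.forward(cur, training=training, rng=rng)

    def backward(self, gy):
        L = self.cfg.encoder_levels
        f = self.cfg.filters_per_level
        g = self.head.backward(gy)
        gskip: dict[int, np.ndarray] = {}
        # decoder ran for i = L-2 .. 0 (j = 0 .. L-2); undo in reverse
        for j in range(L - 2, -1, -1):
            i = L - 2 - j
            gcat = self.mix[j].backward(g)
            gu = g + gcat[..., :f[i]]
            gskip[i] = gcat[..., f[i]:]
            g = self.up[j].backward(gu)
        # g is now the gradient at the bottom encoder output e_{L-1}
        for i in range(L - 1, 0, -1):
            gt = g + self.res[i].backward(g)
            g = self.down[i - 1].backward(gt)
            g = g + gskip[i - 1]
        gt = g + self.res[0].backward(g)
        return self.stem.backward(gt)


def build_vnet(cfg: VnetConfig, seed: int = 0) -> VNet:
    """Untrained 1D V-Net over (batch, input_len, 3) inputs."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 2]))
    model = VNet(cfg, rng)
    logger.info("V-Net built: %d parameters", n_params(model))
    return model


def n_params(model: nn.Layer) -> int:
    return sum(p.value.size for p in model.params())


@dataclass
class TrainedModel:
    """A trained detector: weights, config, per-epoch history, seed."""

    kind: str  # "cnn" or "vnet"
    model: nn.Layer
    config: CnnConfig | VnetConfig
    history: list[dict] = field(default_factory=list)
    seed: int = 0
    best_epoch: int | None = None

    @property
    def n_params(self) -> int:
        return n_params(self.model)

    @property
    def config_hash(self) -> str:
        return config_hash(self.config)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "weights.npz",
                 **{f"p{i:03d}": p.value for i, p in
                    enumerate(self.model.params())})
        meta = {
            "kind": self.kind,
            "config": asdict(self.config),
            "config_hash": self.config_hash,
            "history": self.history,
            "seed": self.seed,
            "best_epoch": self.best_epoch,
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=2))
        import pandas as pd
        pd.DataFrame(self.history).to_csv(out / "history.csv", index=False)

    @classmethod
    def load(cls, out_dir: str | Path) -> "TrainedModel":
        out = Path(out_dir)
        meta = json.loads((out / "meta.json").read_text())
        if meta["kind"] == "cnn":
            cfg = CnnConfig(**meta["config"])
            model = build_cnn(cfg, meta["seed"])
        else:
            cfg_dict = dict(meta["config"])
            cfg_dict["filters_per_level"] = tuple(cfg_dict["filters_per_level"])
            cfg = VnetConfig(**cfg_dict)
            model = build_vnet(cfg, meta["seed"])
        with np.load(out / "weights.npz") as z:
            for i, p in enumerate(model.params()):
                p.value[...] = z[f"p{i:03d}"]
        return cls(kind=meta["kind"], model=model, config=cfg,
                   history=meta["history"], seed=meta["seed"],
                   best_epoch=meta["best_epoch"])


def _snapshot(model: nn.Layer) -> list[np.ndarray]:
    return [p.value.copy() for p in model.params()]


def _restore(model: nn.Layer, weights: list[np.ndarray]) -> None:
    for p, w in zip(model.params(), weights):
        p.value[...] = w


def _check_two_classes(labels: np.ndarray, what: str) -> None:
    u = np.unique(labels)
    if len(u) < 2:
        raise ValueError(
            f"{what} contains a single class ({u.tolist()}); the loss is "
            "degenerate without both classes")


def _eval_loss_cnn(model: nn.Sequential, data: np.ndarray, labels: np.ndarray,
                   chunk: int = 4096) -> float:
    total, n = 0.0, 0
    for s in range(0, len(data), chunk):
        d = data[s:s + chunk]
        logits = model.forward(d, training=False)
        loss, _ = nn.cross_entropy_with_softmax(logits, nn.one_hot(labels[s:s + chunk]))
        total += loss * len(d)
        n += len(d)
    return total / max(n, 1)


def train_cnn(train: WindowBatch, val: WindowBatch, cfg: CnnConfig,
              seed: int = 0, model: nn.Sequential | None = None) -> TrainedModel:
    """Train the windowed CNN on balanced 8-sample segments.

    Validation loss is evaluated after each epoch; the weights of the
    lowest-validation-loss epoch are retained.  ``epochs=0`` returns the
    initialized weights with an empty history.  Raises if the training
    labels contain a single class.
    """
    if model is None:
        model = build_cnn(cfg, seed)
    if cfg.epochs > 0:
        _check_two_classes(train.labels, "CNN training pool")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 11]))
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    history: list[dict] = []
    best_loss, best_w, best_epoch = np.inf, None, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train))
        losses = []
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            logits = model.forward(train.data[idx], training=True, rng=rng)
            loss, dz = nn.cross_entropy_with_softmax(
                logits, nn.one_hot(train.labels[idx]))
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            losses.append(loss)
        val_loss = _eval_loss_cnn(model, val.data, val.labels)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss})
        if val_loss < best_loss:
            best_loss, best_w, best_epoch = val_loss, _snapshot(model), epoch
    if cfg.keep_best_epoch and best_w is not None:
        _restore(model, best_w)
    return TrainedModel(kind="cnn", model=model, config=cfg, history=history,
                        seed=seed, best_epoch=best_epoch)


def _eval_loss_vnet(model: VNet, batch: WindowBatch, batch_size: int) -> float:
    total, n = 0.0, 0
    for s in range(0, len(batch), batch_size):
        d = batch.data[s:s + batch_size]
        logits = model.forward(d, training=False)
        loss = nn.generalized_dice_loss(
            nn.softmax(logits), nn.one_hot(batch.labels[s:s + batch_size]))
        total += loss * len(d)
        n += len(d)
    return total / max(n, 1)


def train_vnet(train_pool: list[tuple[str, np.ndarray, np.ndarray]],
               val_pool: list[tuple[str, np.ndarray, np.ndarray]],
               cfg: VnetConfig, sampler_cfg: SamplerConfig, seed: int = 0,
               model: VNet | None = None) -> TrainedModel:
    """Train the 1D V-Net with the biased global window generator.

    Each epoch draws ``epoch_windows_train`` fresh windows from the training
    pool; the validation set of ``epoch_windows_val`` windows is drawn once
    and held fixed so per-epoch losses are comparable.  Optimized with Adam
    on the generalized dice loss; the lowest-validation-loss epoch's weights
    are retained.
    """
    if model is None:
        model = build_vnet(cfg, seed)
    if cfg.epochs > 0:
        pooled = np.concatenate([l for _, _, l in train_pool]) \
            if train_pool else np.empty(0)
        _check_two_classes(pooled, "V-Net training pool")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 12]))
    val_rng = np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, 13]))
    val = vnet_global_generator(val_pool, sampler_cfg,
                                sampler_cfg.epoch_windows_val, val_rng) \
        if cfg.epochs > 0 else None
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)
    history: list[dict] = []
    best_loss, best_w, best_epoch = np.inf, None, None
    for epoch in range(cfg.epochs):
        batch = vnet_global_generator(train_pool, sampler_cfg,
                                      sampler_cfg.epoch_windows_train, rng)
        losses = []
        for s in range(0, len(batch), cfg.batch_size):
            d = batch.data[s:s + cfg.batch_size]
            logits = model.forward(d, training=True, rng=rng)
            loss, dz = nn.gdl_with_softmax(
                logits, nn.one_hot(batch.labels[s:s + cfg.batch_size]))
            opt.zero_grad()
            model.backward(dz)
            opt.step()
            losses.append(loss)
        val_loss = _eval_loss_vnet(model, val, cfg.batch_size)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss})
        if val_loss < best_loss:
            best_loss, best_w, best_epoch = val_loss, _snapshot(model), epoch
    if cfg.keep_best_epoch and best_w is not None:
        _restore(model, best_w)
    return TrainedModel(kind="vnet", model=model, config=cfg, history=history,
                        seed=seed, best_epoch=best_epoch)


def _cnn_window_starts(dive: Dive, w: int, step: int) -> list[int]:
    n = dive.n_samples
    if n < w:
        return []
    starts = list(range(dive.start_idx, dive.end_idx - w + 1, step))
    if starts[-1] != dive.end_idx - w:  # cover the dive tail
        starts.append(dive.end_idx - w)
    return starts


def predict_points(trained: TrainedModel, norm_data: np.ndarray,
                   depth: np.ndarray, dives: list[Dive],
                   sampler_cfg: SamplerConfig | None = None,
                   dive_threshold_m: float = 0.4) -> np.ndarray:
    """Per-sample binary capture predictions over one individual's series.

    CNN: 8-sample windows slide at step 4 over each dive; every sample of a
    positively classified window is marked (union over overlapping
    windows).  V-Net: non-overlapping 128-sample windows tile each dive,
    the final partial window is edge-padded and its padded outputs
    discarded; per-sample argmax.  All samples at depth <= 0.4 m are forced
    to zero.  Raises on an untrained model (no recorded history when the
    configured epochs are nonzero).
    """
    cfg = sampler_cfg or SamplerConfig()
    if trained.config.epochs > 0 and not trained.history:
        raise ValueError("model has not been trained")
    pred = np.zeros(len(norm_data), dtype=np.uint8)
    if trained.kind == "cnn":
        w, step = cfg.w_cnn, cfg.cnn_step
        starts = [s for d in dives for s in _cnn_window_starts(d, w, step)]
        if starts:
            windows = np.stack([norm_data[s:s + w] for s in starts])
            for c in range(0, len(windows), 4096):
                logits = trained.model.forward(windows[c:c + 4096],
                                               training=False)
                pos = logits.argmax(axis=-1) == 1
                for s, hit in zip(starts[c:c + 4096], pos):
                    if hit:
                        pred[s:s + w] = 1
    elif trained.kind == "vnet":
        w = trained.config.input_len
        full_starts, partials = [], []
        for d in dives:
            for s in range(d.start_idx, d.end_idx, w):
                if s + w <= d.end_idx:
                    full_starts.append(s)
                elif d.end_idx - s > 0:
                    partials.append((s, d.end_idx - s))
        if full_starts:
            windows = np.stack([norm_data[s:s + w] for s in full_starts])
            for c in range(0, len(windows), 512):
                logits = trained.model.forward(windows[c:c + 512],
                                               training=False)
                lab = (logits.argmax(axis=-1) == 1).astype(np.uint8)
                for s, row in zip(full_starts[c:c + 512], lab):
                    pred[s:s + w] = row
        for s, n in partials:
            seg = norm_data[s:s + n]
            padded = np.pad(seg, ((0, w - n), (0, 0)), mode="edge")
            logits = trained.model.forward(padded[None], training=False)
            lab = (logits[0].argmax(axis=-1) == 1).astype(np.uint8)
            pred[s:s + n] = lab[:n]  # discard outputs on the padding
    else:
        raise ValueError(f"unknown model kind {trained.kind!r}")
    pred[depth <= dive_threshold_m] = 0
    return pred
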