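"""Training protocol, evaluation driver, and sweep harnesses.

The protocol: Adam (lr 1e-4, betas (0.9, 0.999), eps 1e-8, no weight
decay), learning rate multiplied by 0.7 every 10 epochs, at most 100
epochs with early stopping after 15 epochs without validation-loss
improvement.  Each epoch every healthy training image passes through
the copy-paste synthesis hook (probability P) and every training image
through classic augmentation; validation and test images are never
augmented.  The loss is the Focal Tversky Loss; the best-validation
weights are restored at the end.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import (EvaluatedSample, LossConfig, MetricReport, confusion,
                      f_score, focal_tversky_loss, focal_tversky_loss_grad,
                      overall_report, per_class_report)
from .network import (NetworkConfig, SegmentationNet, build_network, predict,
                      small_config)
from .synthesis import SynthesisConfig, classic_augment, synthesize

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    max_epochs: int = 100
    early_stop_patience: int = 15
    lr: float = 1e-4
    betas: tuple = (0.9, 0.999)
    adam_eps: float = 1e-8
    weight_decay: float = 0.0
    lr_step_every: int = 10
    lr_factor: float = 0.7
    batch_size: int = 4
    loss: LossConfig = field(default_factory=LossConfig)
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    channel_mode: str = "rgbnir"
    seed: int = 0

    def __post_init__(self):
        for name in ("max_epochs", "early_stop_patience", "lr", "batch_size",
                     "lr_step_every", "lr_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.channel_mode not in ("rgb", "rgbnir"):
            raise ValueError("channel_mode must be 'rgb' or 'rgbnir'")

    def learning_rate_at(self, epoch: int) -> float:
        """Closed form of the step schedule: lr * factor^(epoch // step)."""
        return self.lr * self.lr_factor ** (epoch // self.lr_step_every)


def phantom_train_config(**overrides) -> TrainConfig:
    """Preset for small phantom images (128x128): larger batches and a
    learning rate scaled up for the few-step-per-epoch regime."""
    base = dict(lr=1e-3, batch_size=16)
    base.update(overrides)
    return TrainConfig(**base)


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_f_score: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)
    stop_epoch: int = -1
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(len(self.train_loss)),
            "train_loss": self.train_loss, "val_loss": self.val_loss,
            "val_f_score": self.val_f_score, "lr": self.learning_rate})


class Adam:
    """Adam optimizer over the network's parameter tensors."""

    def __init__(self, params, cfg: TrainConfig):
        self.params = list(params)
        self.b1, self.b2 = cfg.betas
        self.eps = cfg.adam_eps
        self.wd = cfg.weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.wd:
                g = g + self.wd * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)


def _channels(sample_image, mode):
    return sample_image[:, :, :3] if mode == "rgb" else sample_image


def _to_batch(samples, mode):
    from .nn import Tensor
    imgs = np.stack([_channels(s.image, mode).transpose(2, 0, 1)
                     for s in samples]).astype(np.float32)
    masks = np.stack([s.mask for s in samples]).astype(np.float64)
    return Tensor(imgs), masks


def _batch_loss_and_grad(prob, masks, loss_cfg):
    """Mean per-image FTL over a batch and its gradient w.r.t. prob."""
    n = prob.shape[0]
    total, grad = 0.0, np.zeros_like(prob)
    for i in range(n):
        li, gi = focal_tversky_loss_grad(prob[i, 0], masks[i], loss_cfg)
        total += li
        grad[i, 0] = gi
    return total / n, grad / n


def _epoch_samples(train_set, defective_pool, cfg, rng):
    out = []
    for s in train_set:
        if s.is_healthy and cfg.synthesis.setup_id != 1 and defective_pool:
            s = synthesize(s, defective_pool, cfg.synthesis, rng)
        out.append(classic_augment(s, rng))
    return out


def _validation_loss(net, val_set, cfg):
    from .network import BINARY_THRESHOLD
    losses, fsum = [], 0.0
    for s in val_set:
        prob = predict(net, _ChannelView(s, cfg.channel_mode))
        losses.append(focal_tversky_loss(prob, s.mask, cfg.loss))
        fsum += f_score(confusion((prob >= BINARY_THRESHOLD).astype(np.uint8),
                                  s.mask)).f
    return float(np.mean(losses)), fsum / len(val_set)


class _ChannelView:
    """Adapter presenting a sample in the requested channel mode."""

    def __init__(self, sample, mode):
        self.image = _channels(sample.image, mode)
        self.mask = sample.mask


def train(train_set, val_set, net_cfg: NetworkConfig | None = None,
          cfg: TrainConfig | None = None, defective_pool=None):
    """Run the full training protocol; returns ``(net, TrainHistory)``.

    ``defective_pool`` defaults to the defective samples of the training
    split (no test-defect leakage).  Fully reproducible given
    ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    if not train_set or not val_set:
        raise ValueError("training and validation sets must be non-empty")
    in_ch = 3 if cfg.channel_mode == "rgb" else 4
    net_cfg = net_cfg or small_config(in_channels=in_ch)
    if net_cfg.in_channels != in_ch:
        raise ValueError(
            f"network expects {net_cfg.in_channels} channels but channel "
            f"mode {cfg.channel_mode!r} provides {in_ch}")
    if defective_pool is None:
        defective_pool = [s for s in train_set if not s.is_healthy]
    ss = np.random.SeedSequence(cfg.seed)
    init_seed, aug_seed, shuffle_seed = [int(c.generate_state(1)[0]) % (2**31)
                                         for c in ss.spawn(3)]
    net = build_network(net_cfg, seed=init_seed)
    opt = Adam(net.parameters(), cfg)
    aug_rng = np.random.default_rng(aug_seed)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    history = TrainHistory()
    best_loss, best_state, epochs_since_best = np.inf, None, 0
    for epoch in range(cfg.max_epochs):
        lr = cfg.learning_rate_at(epoch)
        samples = _epoch_samples(train_set, defective_pool, cfg, aug_rng)
        order = shuffle_rng.permutation(len(samples))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [samples[i] for i in order[start:start + cfg.batch_size]]
            x, masks = _to_batch(batch, cfg.channel_mode)
            out = net(x, training=True)
            loss, grad = _batch_loss_and_grad(out.data, masks, cfg.loss)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            net.zero_grad()
            out.backward(grad.astype(np.float32))
            opt.step(lr)
            losses.append(loss)
        val_loss, val_f = _validation_loss(net, val_set, cfg)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val_loss)
        history.val_f_score.append(val_f)
        history.learning_rate.append(lr)
        log.info("epoch %d lr %.2e train %.4f val %.4f f %.3f",
                 epoch, lr, history.train_loss[-1], val_loss, val_f)
        if val_loss < best_loss:  # strict improvement
            best_loss, best_state = val_loss, copy.deepcopy(net.state_dict())
            history.best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= cfg.early_stop_patience:
                break
    history.stop_epoch = epoch
    if best_state is not None:
        net.load_state_dict(best_state)
    return net, history


def evaluate(net: SegmentationNet, test_set, threshold: float = 0.5,
             channel_mode: str = "rgbnir", include_healthy: bool = False
             ) -> MetricReport:
    """Predict every test image at full (padded) resolution and score it."""
    if not test_set:
        raise ValueError("empty test set")
    evaluated = []
    for s in test_set:
        prob = predict(net, _ChannelView(s, channel_mode))
        evaluated.append(EvaluatedSample(
            sample_id=s.sample_id, pred_mask=(prob >= threshold).astype(np.uint8),
            gt_mask=s.mask, defects=s.defects))
    report = overall_report(evaluated, include_healthy=include_healthy)
    defective = [e for e in evaluated if not e.is_healthy]
    if any(e.defects for e in defective):
        report.macro = per_class_report(defective, "macro")
        report.sub = per_class_report(defective, "sub")
    return report


def run_ablation(setups, train_set, val_set, test_set,
                 net_cfg: NetworkConfig | None = None,
                 cfg: TrainConfig | None = None) -> pd.DataFrame:
    """Train one model per synthesis setup on identical splits and seed."""
    if not set(setups) <= set(range(1, 7)):
        raise ValueError("setups must be a subset of 1..6")
    cfg = cfg or phantom_train_config()
    rows = []
    for setup in setups:
        run_cfg = replace(cfg, synthesis=replace(cfg.synthesis, setup_id=setup))
        net, _ = train(train_set, val_set, net_cfg, run_cfg)
        rep = evaluate(net, test_set, channel_mode=cfg.channel_mode)
        mean = rep.overall[rep.overall["aggregation"] == "mean_per_image"].iloc[0]
        rows.append({"setup": setup, "csre": mean["csre"],
                     "f_score": mean["f_score"], "precision": mean["precision"],
                     "recall": mean["recall"]})
    return pd.DataFrame(rows)


def sweep_alpha(alphas, train_set, val_set, test_set,
                net_cfg: NetworkConfig | None = None,
                cfg: TrainConfig | None = None) -> pd.DataFrame:
    """Train one model per FTL alpha; larger alpha penalises false
    negatives more, so recall is expected to trend upward."""
    alphas = list(alphas)
    if not alphas:
        raise ValueError("empty alpha list")
    if not all(0.0 <= a <= 1.0 for a in alphas):
        raise ValueError("alphas must lie in [0,1]")
    cfg = cfg or phantom_train_config()
    rows = []
    for a in alphas:
        run_cfg = replace(cfg, loss=replace(cfg.loss, alpha=a))
        net, _ = train(train_set, val_set, net_cfg, run_cfg)
        rep = evaluate(net, test_set, channel_mode=cfg.channel_mode)
        mean = rep.overall[rep.overall["aggregation"] == "mean_per_image"].iloc[0]
        rows.append({"alpha": a, "f_score": mean["f_score"],
                     "precision": mean["precision"], "recall": mean["recall"]})
    table = pd.DataFrame(rows).sort_values("alpha").reset_index(drop=True)
    if len(table) > 1:
        steps = np.diff(table["recall"].to_numpy())
        # fraction of alpha increments that raise recall (1.0 = monotone)
        table.attrs["recall_nondecreasing_fraction"] = float(
            np.mean(steps >= 0))
    return table
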