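"""Alternating adversarial optimization and the cross-validation harness.

Each step samples a foreground-guaranteed batch of augmented, z-scored
patches, updates the two discriminators (SGD with momentum) on real
(one-hot label) versus generated probability maps at their two resolutions,
then updates the generator (Nadam) on the weighted objective
``lambda1*L_seg4 + lambda2*L_seg3 + gamma1*L_adv1 + gamma2*L_adv2 +
beta_ic*CL``.  The learning rate follows the polynomial decay
``base_lr * (1 - iter/max_iter)^power`` per step, clamped to 0 past the
horizon.

Whole runs are pure functions of (config, dataset, seed): histories and
checkpoints reproduce bit-identically in single-threaded execution.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_volumes import LabelVolume, Volume3D
from .losses import LossWeights, adversarial_loss, one_hot, pool_label_probs, \
    seg_loss, total_loss
from .network import Discriminator, Generator, GeneratorOutputs, init_weights
from .nn import Module, Tensor
from .postprocess import ProbabilityVolume, evaluate_pair, postprocess_volume
from .preprocessing import AugmentParams, augment, crop_patch, sample_batch, \
    zscore_normalize

log = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "TrainHistory", "ModelBundle", "TrainingError",
    "lr_poly", "train_alternating", "crossvalidate", "predict_volume",
    "evaluate_model", "save_checkpoint", "load_checkpoint",
    "SGDMomentum", "Nadam",
]


class TrainingError(RuntimeError):
    """Raised when optimization produces a non-finite loss."""


@dataclass
class TrainConfig:
    """Hyperparameters of the adversarial training run.

    Defaults follow the suggested setting (batch 16, 150 epochs, SGD
    momentum 0.9 for the discriminators, base learning rate 2.5e-4 with
    polynomial decay of power 0.9 over a 500-step horizon, tenfold
    cross-validation); width and patch size are reduced in desk-scale runs.
    """

    batch_size: int = 16
    max_epoch: int = 150
    steps_per_epoch: int | None = None   # default: ceil(n_subjects / batch)
    momentum: float = 0.9
    base_lr: float = 2.5e-4
    power: float = 0.9
    max_iter: int = 500
    folds: int = 10
    seed: int = 0
    gen_width: int = 32
    disc_width: int = 32
    patch_size: tuple = (48, 64, 48)
    min_fg_fraction: float = 1.0 / 3.0
    validate_every: int = 1              # epochs between validations; 0 = off
    weights: LossWeights = field(default_factory=LossWeights)
    augment: AugmentParams = field(default_factory=AugmentParams)

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epoch < 1:
            raise ValueError("max_epoch must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if isinstance(self.weights, dict):
            self.weights = LossWeights(**self.weights)
        if isinstance(self.augment, dict):
            self.augment = AugmentParams(**self.augment)
        self.patch_size = tuple(int(s) for s in self.patch_size)

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """CPU-scale preset: width-4 generator, 16x32x16 patches, batch 4,
        50 steps/epoch for 2 epochs.

        The base learning rate is raised to 5e-3: at this reduced width,
        batch size and step count the adaptive generator update needs a
        larger rate to traverse a comparable distance in parameter space
        than in the full-scale configuration.
        """
        params = dict(batch_size=4, max_epoch=2, steps_per_epoch=50,
                      gen_width=4, disc_width=2, patch_size=(16, 32, 16),
                      base_lr=5e-3, validate_every=0, seed=seed)
        params.update(overrides)
        return cls(**params)


@dataclass
class TrainHistory:
    """Per-step loss components, per-epoch validation metrics, seeds."""

    steps: list = field(default_factory=list)
    epochs: list = field(default_factory=list)
    seed: int = 0

    def assert_finite(self):
        for rec in self.steps:
            for k, v in rec.items():
                if isinstance(v, float) and not math.isfinite(v):
                    raise TrainingError(f"non-finite {k} in history")


@dataclass
class ModelBundle:
    """Generator plus both discriminators and their config."""

    generator: Generator
    d1: Discriminator
    d2: Discriminator
    config: TrainConfig


def lr_poly(it: int, cfg: TrainConfig) -> float:
    """Polynomial decay ``base_lr * (1 - it/max_iter)^power``, clamped."""
    if it < 0:
        raise ValueError("iteration index must be >= 0")
    if it > cfg.max_iter:
        log.warning("iteration %d past max_iter %d: lr clamped to 0",
                    it, cfg.max_iter)
        return 0.0
    return cfg.base_lr * (1.0 - it / cfg.max_iter) ** cfg.power


class SGDMomentum:
    """Classic momentum SGD (used for the discriminators)."""

    def __init__(self, params, momentum: float = 0.9):
        self.params = list(params)
        self.momentum = momentum
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float):
        for p, b in zip(self.params, self.buf):
            if p.grad is None:
                continue
            b *= self.momentum
            b += p.grad
            p.data -= lr * b

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Nadam:
    """Adaptive-moment optimizer with Nesterov momentum (generator)."""

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = (b1 * m / (1 - b1 ** (self.t + 1))
                     + (1 - b1) * g / (1 - b1 ** self.t))
            v_hat = v / (1 - b2 ** self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _component_value(name: str, value) -> float:
    x = float(value.data) if isinstance(value, Tensor) else float(value)
    if not math.isfinite(x):
        raise TrainingError(f"non-finite loss component {name!r}: {x}")
    return x


def build_models(cfg: TrainConfig) -> ModelBundle:
    """Construct and He-initialize the three networks from (cfg, seed)."""
    gen = init_weights(Generator(base_width=cfg.gen_width),
                       np.random.default_rng([cfg.seed, 0]))
    d1 = init_weights(Discriminator(3, cfg.disc_width, name="D1"),
                      np.random.default_rng([cfg.seed, 1]))
    d2 = init_weights(Discriminator(3, cfg.disc_width, name="D2"),
                      np.random.default_rng([cfg.seed, 2]))
    return ModelBundle(generator=gen, d1=d1, d2=d2, config=cfg)


def train_alternating(dataset, cfg: TrainConfig, val_dataset=None,
                      bundle: ModelBundle | None = None
                      ) -> tuple[ModelBundle, TrainHistory]:
    """Run the alternating D1/D2-then-G optimization.

    ``dataset`` (and optional ``val_dataset``) are sequences of
    ``(Volume3D, LabelVolume)`` pairs.  Returns the trained bundle and the
    full history; aborts with :class:`TrainingError` naming the offending
    component if any loss turns non-finite.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    bundle = bundle or build_models(cfg)
    gen, d1, d2 = bundle.generator, bundle.d1, bundle.d2
    w = cfg.weights
    rng = np.random.default_rng([cfg.seed, 3])
    opt_g = Nadam(gen.parameters())
    opt_d1 = SGDMomentum(d1.parameters(), cfg.momentum)
    opt_d2 = SGDMomentum(d2.parameters(), cfg.momentum)
    steps_per_epoch = cfg.steps_per_epoch or max(
        1, math.ceil(len(dataset) / cfg.batch_size))
    history = TrainHistory(seed=cfg.seed)
    it = 0
    for epoch in range(cfg.max_epoch):
        gen.train()
        for _ in range(steps_per_epoch):
            lr = lr_poly(min(it, cfg.max_iter), cfg)
            batch = sample_batch(dataset, cfg.batch_size,
                                 cfg.min_fg_fraction, rng,
                                 patch_size=cfg.patch_size)
            patches = [augment(p, cfg.augment, rng) for p in batch.patches]
            x = np.stack([zscore_normalize(p.image) for p in patches])[:, None]
            y = np.stack([p.label for p in patches])
            onehot0 = one_hot(y)
            onehot1 = pool_label_probs(onehot0)

            out: GeneratorOutputs = gen(Tensor(x))

            # --- discriminator updates (generator frozen: detached maps) ---
            d_losses = {}
            for name, disc, opt, real, fake in (
                    ("d1", d1, opt_d1, onehot0, out.p_t4.data),
                    ("d2", d2, opt_d2, onehot1, out.p_t3.data)):
                d_real = disc(Tensor(real))
                d_fake = disc(Tensor(fake))
                value = adversarial_loss(d_real, d_fake, "discriminator")
                loss_d = -value  # discriminator maximizes the value
                opt.zero_grad()
                loss_d.backward()
                opt.step(lr)
                d_losses[name] = {
                    "value": _component_value(f"adv_{name}", value),
                    "d_real": float(d_real.data.mean()),
                    "d_fake": float(d_fake.data.mean()),
                }

            # --- generator update (discriminators frozen: grads discarded) ---
            seg4 = seg_loss(out.p_t4, y, w)
            seg3 = seg_loss(out.p_t3, onehot1, w)
            adv1 = adversarial_loss(0.5, d1(out.p_t4), "generator")
            adv2 = adversarial_loss(0.5, d2(out.p_t3), "generator")
            loss_g = total_loss(seg4, seg3, adv1, adv2, out.cl, w)
            opt_g.zero_grad()
            opt_d1.zero_grad()
            opt_d2.zero_grad()
            loss_g.backward()
            opt_g.step(lr)
            opt_d1.zero_grad()  # discard generator-step gradients on D
            opt_d2.zero_grad()

            history.steps.append({
                "iter": it, "epoch": epoch, "lr": lr,
                "seg4": _component_value("seg4", seg4),
                "seg3": _component_value("seg3", seg3),
                "adv_g1": _component_value("adv_g1", adv1),
                "adv_g2": _component_value("adv_g2", adv2),
                "cl": _component_value("cl", out.cl),
                "total": _component_value("total", loss_g),
                "adv_d1": d_losses["d1"]["value"],
                "adv_d2": d_losses["d2"]["value"],
                "d1_real": d_losses["d1"]["d_real"],
                "d1_fake": d_losses["d1"]["d_fake"],
                "d2_real": d_losses["d2"]["d_real"],
                "d2_fake": d_losses["d2"]["d_fake"],
            })
            it += 1
        epoch_rec = {"epoch": epoch}
        if val_dataset and cfg.validate_every \
                and (epoch + 1) % cfg.validate_every == 0:
            metrics = evaluate_model(gen, val_dataset)
            epoch_rec.update({f"val_{k}": v for k, v in metrics.items()})
        history.epochs.append(epoch_rec)
    history.assert_finite()
    return bundle, history


def _pad_to_divisible(n: int, div: int = 16) -> int:
    return ((n + div - 1) // div) * div


def predict_volume(gen: Generator, v: Volume3D,
                   patch_size: tuple | None = None) -> ProbabilityVolume:
    """Class probabilities for a whole volume (evaluation mode).

    The z-scored volume is zero-padded to the next multiple of 16 per axis
    (or to an explicit covering ``patch_size``), passed through the
    generator once, and the full-resolution probability map is cropped back
    to the source grid.
    """
    if patch_size is None:
        patch_size = tuple(_pad_to_divisible(n) for n in v.shape)
    if any(p < n for p, n in zip(patch_size, v.shape)):
        raise ValueError(
            f"patch {patch_size} does not cover volume {v.shape}")
    normed = Volume3D(zscore_normalize(v.values), spacing=v.spacing,
                      affine=v.affine)
    dummy = LabelVolume(np.zeros(v.shape, dtype=np.int16))
    patch = crop_patch(normed, dummy, patch_size,
                       tuple(s // 2 for s in v.shape))
    gen.eval()
    out = gen(Tensor(patch.image[None, None]))
    probs = out.p_t4.data[0]
    # crop back: the patch window start was center - size//2
    starts = [s // 2 - p // 2 for s, p in zip(v.shape, patch_size)]
    sl = tuple(slice(-st, -st + n) for st, n in zip(starts, v.shape))
    probs = probs[(slice(None),) + sl]
    probs = np.clip(probs, 0.0, 1.0)
    probs /= probs.sum(axis=0, keepdims=True)
    return ProbabilityVolume(probs=probs)


def evaluate_model(gen: Generator, subjects, patch_size=None,
                   apply_postprocess: bool = True) -> dict:
    """Mean DSC/PPV/SEN (averaged over classes) across subjects."""
    per_subject = []
    for vol, lab in subjects:
        probs = predict_volume(gen, vol, patch_size)
        if apply_postprocess:
            pred = postprocess_volume(probs)
        else:
            from .postprocess import voxel_decision
            pred = LabelVolume(voxel_decision(probs.p_ant, probs.p_pos,
                                              probs.p_bac))
        per_subject.append(evaluate_pair(pred, lab).average)
    return {k: float(np.mean([m[k] for m in per_subject]))
            for k in ("dsc", "ppv", "sen")}


def crossvalidate(dataset, cfg: TrainConfig, runner=None) -> dict:
    """K-fold cross-validation with disjoint exhaustive folds.

    ``runner(train_subjects, val_subjects, cfg, fold_index)`` returns a
    metrics dict for one fold (default: full adversarial training plus
    evaluation).  Each round records the mean and standard deviation over
    its validation subjects; the pooled result is the mean and standard
    deviation of the per-fold means.
    """
    n = len(dataset)
    if cfg.folds > n:
        raise ValueError(f"folds ({cfg.folds}) exceed dataset size ({n})")
    if runner is None:
        def runner(train_subjects, val_subjects, cfg, fold_index):
            fold_cfg = TrainConfig(**{**asdict(cfg),
                                      "seed": cfg.seed + fold_index})
            bundle, _ = train_alternating(train_subjects, fold_cfg)
            return evaluate_model(bundle.generator, val_subjects)
    perm = np.random.default_rng([cfg.seed, 99]).permutation(n)
    folds = [sorted(perm[i::cfg.folds].tolist()) for i in range(cfg.folds)]
    per_fold = []
    for k, val_idx in enumerate(folds):
        val_set = set(val_idx)
        train_subjects = [dataset[i] for i in range(n) if i not in val_set]
        val_subjects = [dataset[i] for i in val_idx]
        metrics = runner(train_subjects, val_subjects, cfg, k)
        per_fold.append({"fold": k, "val_indices": val_idx, **metrics})
    keys = [k for k in per_fold[0] if k not in ("fold", "val_indices")]
    pooled = {k: {"mean": float(np.mean([f[k] for f in per_fold])),
                  "sd": float(np.std([f[k] for f in per_fold]))}
              for k in keys}
    return {"folds": folds, "per_fold": per_fold, "pooled": pooled}


# -- checkpointing -------------------------------------------------------------


def save_checkpoint(path, bundle: ModelBundle,
                    rng_state: dict | None = None) -> None:
    """Write all parameters plus a config fingerprint; bit-exact roundtrip."""
    cfg = asdict(bundle.config)
    arrays = {}
    for name, model in (("gen", bundle.generator), ("d1", bundle.d1),
                        ("d2", bundle.d2)):
        for k, v in model.state_dict().items():
            arrays[f"{name}.{k}"] = v
    meta = json.dumps({"config": cfg, "rng_state": rng_state},
                      default=lambda o: o.tolist())
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[ModelBundle, dict]:
    """Restore a :class:`ModelBundle`; returns (bundle, metadata)."""
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg_dict = dict(meta["config"])
    cfg = TrainConfig(**cfg_dict)
    bundle = build_models(cfg)
    for name, model in (("gen", bundle.generator), ("d1", bundle.d1),
                        ("d2", bundle.d2)):
        state = {k[len(name) + 1:]: data[k] for k in data.files
                 if k.startswith(name + ".")}
        model.load_state_dict(state)
    return bundle, meta
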