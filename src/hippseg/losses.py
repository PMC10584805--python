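"""Loss terms: weighted BCE + Dice segmentation loss at two scales,
minimax adversarial values, the Gaussian information-constraint penalty,
and their weighted total.

Every function accepts either plain numpy arrays (returning a float) or
autodiff :class:`~hippseg.nn.Tensor` values (returning a scalar Tensor in
the graph), so the same definitions serve both the oracle tests and the
training loop.

Default weights follow the suggested setting: sigma1=0.6 (BCE), sigma2=0.4
(Dice), lambda1=1 (full-resolution segmentation), lambda2=0.2 (half
resolution), gamma1=0.005 / gamma2=0.002 (adversarial), beta_ic=0.001
(information constraint).  Note these sum to 1.208, not 1; they are used
as given, without renormalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .nn import Tensor

log = logging.getLogger(__name__)

EPS = 1e-7          # probability clipping before logarithms
DICE_SMOOTH = 1e-5
VAR_FLOOR = 1e-8

__all__ = [
    "LossWeights", "weighted_bce", "dice_loss", "seg_loss",
    "adversarial_loss", "info_constraint_loss", "total_loss",
    "one_hot", "pool_label_probs",
]


@dataclass
class LossWeights:
    """Weights of the composite objective (see module docstring)."""

    sigma1: float = 0.6     # BCE weight inside the segmentation loss
    sigma2: float = 0.4     # Dice weight inside the segmentation loss
    lambda1: float = 1.0    # full-resolution segmentation loss
    lambda2: float = 0.2    # half-resolution segmentation loss
    gamma1: float = 0.005   # adversarial loss, full-resolution discriminator
    gamma2: float = 0.002   # adversarial loss, half-resolution discriminator
    beta_ic: float = 0.001  # information-constraint penalty
    beta_bce: float = 0.7   # positive-class weight inside the BCE

    def __post_init__(self):
        for name in ("sigma1", "sigma2", "lambda1", "lambda2",
                     "gamma1", "gamma2", "beta_ic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.beta_bce < 1.0:
            raise ValueError(f"beta_bce must be in (0,1), got {self.beta_bce}")
        s = self.lambda1 + self.lambda2 + self.gamma1 + self.gamma2
        if not math.isclose(s, 1.0, abs_tol=1e-9):
            log.info("objective weights lambda1+lambda2+gamma1+gamma2 = %.3f "
                     "(not normalized to 1; used as configured)", s)


def _as_pair(pred, label):
    """Wrap operands; report whether graph mode is requested."""
    graph = isinstance(pred, Tensor) or isinstance(label, Tensor)
    p = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, float))
    l = label if isinstance(label, Tensor) else Tensor(np.asarray(label, float))
    if p.shape != l.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs label {l.shape}")
    return p, l, graph


def _ret(t: Tensor, graph: bool):
    return t if graph else float(t.data)


def one_hot(label: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Integer class grid -> indicator stack.

    (D,H,W) becomes (C,D,H,W); (N,D,H,W) becomes (N,C,D,H,W).
    """
    label = np.asarray(label)
    axis = 0 if label.ndim == 3 else 1
    return np.stack([(label == c).astype(np.float64)
                     for c in range(n_classes)], axis=axis)


def pool_label_probs(onehot: np.ndarray, factor: int = 2) -> np.ndarray:
    """Average-pool a one-hot stack (N,C,D,H,W) to a coarser soft label.

    Used to build the half-resolution target: block-averaging indicator
    channels yields per-voxel class fractions that still sum to one, avoiding
    interpolation artifacts in probability space.
    """
    n, c, d, h, w = onehot.shape
    f = factor
    if d % f or h % f or w % f:
        raise ValueError(f"spatial dims {(d, h, w)} not divisible by {f}")
    return onehot.reshape(n, c, d // f, f, h // f, f, w // f, f).mean(
        axis=(3, 5, 7))


def weighted_bce(pred, label, beta_bce: float = 0.7):
    """Class-weighted binary cross-entropy, averaged over voxels.

    Per voxel: ``-beta * L * log p - (1 - beta) * (1 - L) * log(1 - p)``,
    with probabilities clipped to [EPS, 1-EPS].
    """
    p, l, graph = _as_pair(pred, label)
    p = p.clip(EPS, 1.0 - EPS)
    term = -(l * p.log() * beta_bce) - ((1.0 - l) * (1.0 - p).log()
                                        * (1.0 - beta_bce))
    return _ret(term.mean(), graph)


def dice_loss(pred, label):
    """Soft Dice loss ``1 - 2<L,P> / (|L| + |P|)`` with a small smoothing
    constant keeping the perfect and empty cases well-defined."""
    p, l, graph = _as_pair(pred, label)
    inter = (p * l).sum()
    denom = p.sum() + l.sum()
    return _ret(1.0 - (inter * 2.0 + DICE_SMOOTH) / (denom + DICE_SMOOTH),
                graph)


def seg_loss(pred, label, w: LossWeights | None = None):
    """Two-term segmentation loss averaged over the foreground classes.

    ``pred`` is a 3-class probability map (N,3,D,H,W) or (3,D,H,W);
    ``label`` either an integer class grid or a matching soft/one-hot
    stack (for pooled half-resolution targets).  The binary BCE and Dice
    terms are applied one-vs-rest to classes 1 and 2 and averaged, then
    combined as ``sigma1 * BCE + sigma2 * Dice``.
    """
    w = w or LossWeights()
    graph = isinstance(pred, Tensor)
    p = pred if graph else Tensor(np.asarray(pred, float))
    if p.ndim == 4:
        p = p.reshape((1,) + p.shape)
    label = label.data if isinstance(label, Tensor) else np.asarray(label)
    if label.ndim == 3:          # (D,H,W) integer grid
        target = one_hot(label[None])
    elif label.ndim == 4:
        if label.shape[0] == p.shape[0] and label.shape[1:] == p.shape[2:]:
            target = one_hot(label)              # (N,D,H,W) integer grid
        else:
            target = np.asarray(label, float)[None]  # (C,D,H,W) soft stack
    else:
        target = np.asarray(label, float)        # (N,C,D,H,W) soft stack
    if target.shape != p.shape:
        raise ValueError(
            f"resolution mismatch: pred {p.shape} vs target {target.shape}")
    bce_terms, dice_terms = [], []
    for cls in (1, 2):
        sl = (slice(None), cls)
        pc = Tensor._wrap(p.data[sl]) if not graph else _slice_channel(p, cls)
        tc = target[sl]
        bce_terms.append(weighted_bce(pc, Tensor(tc), w.beta_bce))
        dice_terms.append(dice_loss(pc, Tensor(tc)))
    bce = _mean_terms(bce_terms)
    dice = _mean_terms(dice_terms)
    out = bce * w.sigma1 + dice * w.sigma2
    return out if graph else float(out.data)


def _slice_channel(t: Tensor, cls: int) -> Tensor:
    """Differentiable channel selection for (N,C,D,H,W) tensors."""
    data = t.data[:, cls]

    def backward(g):
        full = np.zeros_like(t.data)
        full[:, cls] = g
        return ((t, full),)

    out = Tensor(data)
    if t.requires_grad:
        out.requires_grad = True
        out._prev = (t,)
        out._backward = backward
    return out


def _mean_terms(terms):
    acc = terms[0]
    for t in terms[1:]:
        acc = acc + t
    return acc * (1.0 / len(terms))


def adversarial_loss(d_real, d_fake, role: str):
    """Minimax adversarial value.

    ``role="discriminator"``: ``log d_real + log(1 - d_fake)`` — the value
    the discriminator maximizes (0 at its optimum, 2*ln 0.5 at the 0.5
    equilibrium).  ``role="generator"``: ``log(1 - d_fake)`` — the value the
    generator minimizes.  Inputs are probabilities in (0,1), clipped at EPS.
    """
    graph = isinstance(d_real, Tensor) or isinstance(d_fake, Tensor)
    dr = d_real if isinstance(d_real, Tensor) else Tensor(np.asarray(d_real, float))
    df = d_fake if isinstance(d_fake, Tensor) else Tensor(np.asarray(d_fake, float))
    dr = dr.clip(EPS, 1.0 - EPS)
    df = df.clip(EPS, 1.0 - EPS)
    if role == "discriminator":
        val = dr.log().mean() + (1.0 - df).log().mean()
    elif role == "generator":
        val = (1.0 - df).log().mean()
    else:
        raise ValueError(f"role must be discriminator|generator, got {role!r}")
    return _ret(val, graph)


def info_constraint_loss(constrained):
    """Gaussian divergence of the constrained features from N(0,1).

    Per channel c with empirical mean mu_c and variance s2_c (over batch and
    space): ``KL_c = (mu_c^2 + s2_c - 1 - ln s2_c) / 2``; the loss is the
    channel mean, clamped at 0 from below.  Channels with (near-)zero
    variance are floored at VAR_FLOOR.
    """
    graph = isinstance(constrained, Tensor)
    f = constrained if graph else Tensor(np.asarray(constrained, float))
    if f.ndim < 2:
        raise ValueError("need (channels, samples...) with >= 2 values/channel")
    c_axis = 0 if f.ndim in (2, 4) else 1  # (C,...) or (N,C,D,H,W)
    axes = tuple(a for a in range(f.ndim) if a != c_axis)
    n_per = int(np.prod([f.shape[a] for a in axes]))
    if n_per < 2:
        raise ValueError("need >= 2 values per channel")
    mu = f.mean(axis=axes, keepdims=True)
    var = ((f - mu) ** 2).mean(axis=axes, keepdims=True)
    if np.any(var.data < VAR_FLOOR):
        log.warning("info constraint: flooring %d near-zero channel variances",
                    int(np.sum(var.data < VAR_FLOOR)))
        var = var.clip(VAR_FLOOR, np.inf)
    kl = (mu ** 2 + var - 1.0 - var.log()) * 0.5
    out = kl.mean().clip(0.0, np.inf)
    return _ret(out, graph)


def total_loss(seg4, seg3, adv1, adv2, ic, w: LossWeights | None = None):
    """The weighted objective
    ``lambda1*seg4 + lambda2*seg3 + gamma1*adv1 + gamma2*adv2 + beta_ic*ic``.
    """
    w = w or LossWeights()
    parts = [seg4, seg3, adv1, adv2, ic]
    graph = any(isinstance(x, Tensor) for x in parts)
    coefs = [w.lambda1, w.lambda2, w.gamma1, w.gamma2, w.beta_ic]
    acc = None
    for coef, part in zip(coefs, parts):
        term = (part if isinstance(part, Tensor)
                else Tensor(np.asarray(part, float))) * coef
        acc = term if acc is None else acc + term
    return acc if graph else float(acc.data)
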