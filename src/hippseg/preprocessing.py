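"""Patch extraction, normalization, bias-field correction and augmentation.

The training pipeline crops fixed-size 3D patches (default 48x64x48, every
dimension divisible by 2^4 so four pooling stages divide evenly), z-score
normalizes them, and augments with mirroring / small rotations / intensity
shifts.  Batches guarantee that at least a configurable fraction (default
1/3) of patches contain foreground, enforced as ``ceil(batch_size/3)`` via
rejection resampling of background-only crops.

Bias-field correction estimates a smooth multiplicative intensity field with
the N4 algorithm (SimpleITK) guided by a tissue mask — Otsu by default, with
mean-binary / iterative / Sauvola / Niblack alternatives for comparison — or
with a dependency-light log-domain polynomial fit (``method="polyfit"``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_niblack, threshold_otsu, threshold_sauvola

from .io_volumes import LabelVolume, Volume3D

log = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = (48, 64, 48)
POOLING_DIVISOR = 16  # 2^4: four halvings in the encoder

__all__ = [
    "Patch", "Batch", "AugmentParams", "AugmentRecord", "SamplingError",
    "zscore_normalize", "crop_patch", "sample_batch", "threshold_mask",
    "global_threshold", "iterative_threshold", "correct_bias_field",
    "augment", "draw_augment_record", "apply_augment_record",
]


class SamplingError(RuntimeError):
    """Raised when the batch foreground guarantee cannot be met."""


@dataclass
class Patch:
    """A fixed-size crop of (image, label) plus provenance.

    ``pad_mask`` is True where the crop window fell outside the source
    volume and was zero-filled.
    """

    image: np.ndarray
    label: np.ndarray
    source_id: int | str = 0
    center: tuple[int, int, int] = (0, 0, 0)
    pad_mask: np.ndarray = None

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.label = np.asarray(self.label, dtype=np.int16)
        if self.image.shape != self.label.shape:
            raise ValueError(
                f"patch image {self.image.shape} and label "
                f"{self.label.shape} shapes differ")
        _check_divisible(self.image.shape)
        bad = np.setdiff1d(np.unique(self.label), (0, 1, 2))
        if bad.size:
            raise ValueError(f"patch label values outside vocabulary: {bad}")
        if self.pad_mask is None:
            self.pad_mask = np.zeros(self.image.shape, dtype=bool)

    @property
    def has_foreground(self) -> bool:
        return bool((self.label > 0).any())


@dataclass
class Batch:
    """An ordered set of patches with a declared foreground guarantee."""

    patches: list
    min_fg_fraction: float = 1.0 / 3.0

    def __post_init__(self):
        need = math.ceil(self.min_fg_fraction * len(self.patches))
        have = sum(p.has_foreground for p in self.patches)
        if have < need:
            raise ValueError(
                f"batch violates foreground guarantee: {have} < {need}")

    def __len__(self):
        return len(self.patches)

    def images(self) -> np.ndarray:
        """Stack patch images as (N, 1, W, H, D)."""
        return np.stack([p.image for p in self.patches])[:, None]

    def labels(self) -> np.ndarray:
        return np.stack([p.label for p in self.patches])


@dataclass
class AugmentParams:
    """Randomized augmentation settings.

    A patch is selected for augmentation with probability ``select_p``;
    selected patches get an independent mirror flip per axis
    (``mirror_p`` each), one rotation about a random axis with angle uniform
    in ``[-rot_deg, +rot_deg]`` degrees, and an additive intensity shift
    uniform in ``[-intensity_frac * sigma/2, +intensity_frac * sigma/2]``
    where sigma is the patch standard deviation.
    """

    select_p: float = 0.95
    mirror_p: float = 0.5
    rot_deg: float = 15.0
    intensity_frac: float = 0.1

    def __post_init__(self):
        for name in ("select_p", "mirror_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.rot_deg < 0:
            raise ValueError("rot_deg must be >= 0 (range symmetric about 0)")


@dataclass
class AugmentRecord:
    """A concrete draw of augmentation decisions (reproducible transform)."""

    applied: bool
    mirror: tuple[bool, bool, bool]
    rot_axis: int
    angle: float
    intensity_u: float  # in [-1, 1]; shift = u * intensity_frac * sigma / 2


def _check_divisible(shape) -> None:
    for dim in shape:
        if dim % POOLING_DIVISOR:
            raise ValueError(
                f"patch dimension {dim} not divisible by 2^4 "
                f"({POOLING_DIVISOR}); shape {tuple(shape)}")


def zscore_normalize(image: np.ndarray) -> np.ndarray:
    """Standardize to zero mean, unit variance; constant input maps to 0."""
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("cannot normalize non-finite image")
    sigma = image.std()
    if sigma == 0:
        log.warning("z-score of constant patch: returning zeros")
        return np.zeros_like(image)
    return (image - image.mean()) / sigma


def crop_patch(v: Volume3D, l: LabelVolume, size=DEFAULT_PATCH_SIZE,
               center=None) -> Patch:
    """Crop a ``size`` window centred at ``center`` (voxel coordinates).

    Half-open windows: start = center - size//2, covering
    ``[start, start+size)``; regions outside the source volume are
    zero-filled and flagged in ``pad_mask``.  Each size dimension must be
    divisible by 2^4.
    """
    size = tuple(int(s) for s in size)
    _check_divisible(size)
    if v.shape != l.shape:
        raise ValueError(f"image {v.shape} and label {l.shape} shapes differ")
    if center is None:
        center = tuple(s // 2 for s in v.shape)
    center = tuple(int(c) for c in center)
    for c, n in zip(center, v.shape):
        if not 0 <= c < n:
            raise ValueError(f"center {center} outside volume {v.shape}")

    image = np.zeros(size, dtype=np.float64)
    label = np.zeros(size, dtype=np.int16)
    pad_mask = np.ones(size, dtype=bool)
    src_lo, src_hi, dst_lo, dst_hi = [], [], [], []
    for c, s, n in zip(center, size, v.shape):
        start = c - s // 2
        a, b = max(start, 0), min(start + s, n)
        src_lo.append(a)
        src_hi.append(b)
        dst_lo.append(a - start)
        dst_hi.append(b - start)
    src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    dst = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))
    if all(sl.start < sl.stop for sl in src):
        image[dst] = v.values[src]
        label[dst] = l.values[src]
        pad_mask[dst] = False
    return Patch(image=image, label=label, center=center, pad_mask=pad_mask)


def sample_batch(dataset, batch_size: int, min_fg_fraction: float = 1.0 / 3.0,
                 rng: np.random.Generator | None = None,
                 patch_size=DEFAULT_PATCH_SIZE, max_rounds: int = 50) -> Batch:
    """Draw a batch of random crops with the foreground guarantee.

    ``dataset`` is a sequence of ``(Volume3D, LabelVolume)`` pairs.  Crop
    centres are uniform over each chosen subject's voxels; background-only
    crops beyond the allowed quota are resampled (bounded rounds) with
    centres redrawn at random foreground voxels.
    """
    if batch_size < 1:
        raise ValueError(f"batch_size must be >= 1, got {batch_size}")
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng() if rng is None else rng
    fg_subjects = [i for i, (_, lab) in enumerate(dataset)
                   if (lab.values > 0).any()]
    if not fg_subjects:
        raise SamplingError(
            "no subject contains foreground; cannot satisfy the batch "
            "foreground guarantee")

    def random_crop():
        i = int(rng.integers(len(dataset)))
        vol, lab = dataset[i]
        center = tuple(int(rng.integers(n)) for n in vol.shape)
        p = crop_patch(vol, lab, patch_size, center)
        p.source_id = i
        return p

    patches = [random_crop() for _ in range(batch_size)]
    need = math.ceil(min_fg_fraction * batch_size)
    for _ in range(max_rounds):
        have = sum(p.has_foreground for p in patches)
        if have >= need:
            break
        # replace one background-only crop with a foreground-centred one
        j = next(k for k, p in enumerate(patches) if not p.has_foreground)
        i = int(rng.choice(fg_subjects))
        vol, lab = dataset[i]
        fg = np.argwhere(lab.values > 0)
        center = tuple(int(x) for x in fg[int(rng.integers(len(fg)))])
        p = crop_patch(vol, lab, patch_size, center)
        p.source_id = i
        patches[j] = p
    else:
        raise SamplingError(
            f"foreground guarantee unmet after {max_rounds} rounds")
    return Batch(patches=patches, min_fg_fraction=min_fg_fraction)


# -- threshold masks -----------------------------------------------------------


def global_threshold(values: np.ndarray, method: str, nbins: int = 256) -> float:
    """Scalar threshold for the global methods (mean-binary, iterative, otsu)."""
    values = np.asarray(values, dtype=np.float64)
    if method == "mean-binary":
        return float(values.mean())
    if method == "iterative":
        return iterative_threshold(values)
    if method == "otsu":
        return float(threshold_otsu(values, nbins=nbins))
    raise ValueError(f"not a global threshold method: {method}")


def iterative_threshold(values: np.ndarray, tol: float = 1e-8,
                        max_iter: int = 500) -> float:
    """Mean-update thresholding: t <- mean of the two class means, iterated
    until the threshold is constant."""
    values = np.asarray(values, dtype=np.float64)
    t = float(values.mean())
    for _ in range(max_iter):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            break
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) <= tol:
            return float(t_new)
        t = t_new
    return float(t)


def threshold_mask(v: Volume3D | np.ndarray, method: str = "otsu",
                   window=(16, 16, 16)) -> np.ndarray:
    """Binary tissue mask via one of five thresholding strategies.

    Global: ``mean-binary`` (threshold = mean intensity), ``iterative``
    (mean-update rule iterated to a fixed point), ``otsu`` (maximizes
    between-class variance over the intensity histogram).  Local, with a
    ``window`` neighbourhood (default 16x16x16): ``sauvola`` and ``niblack``.
    """
    values = v.values if isinstance(v, Volume3D) else np.asarray(v, float)
    if values.std() == 0:
        log.warning("constant image: threshold mask is all background")
        return np.zeros(values.shape, dtype=bool)
    if method in ("mean-binary", "iterative", "otsu"):
        return values > global_threshold(values, method)
    window = tuple(int(w) for w in window)
    if any(w < 1 for w in window):
        raise ValueError(f"local window must be positive, got {window}")
    # skimage wants odd window sizes
    window = tuple(w if w % 2 else w + 1 for w in window)
    if method == "sauvola":
        return values > threshold_sauvola(values, window_size=window)
    if method == "niblack":
        return values > threshold_niblack(values, window_size=window)
    raise ValueError(
        f"unknown threshold method {method!r}; expected one of "
        "mean-binary, iterative, sauvola, niblack, otsu")


# -- bias-field correction -----------------------------------------------------


def correct_bias_field(v: Volume3D, mask: np.ndarray, method: str = "n4",
                       poly_order: int = 2) -> tuple[Volume3D, Volume3D]:
    """Estimate and remove a smooth multiplicative bias field.

    ``method="n4"`` runs the N4 algorithm (SimpleITK) with ``mask`` as its
    foreground mask; ``method="polyfit"`` fits a low-order polynomial to log
    intensities within the mask.  Returns ``(corrected, bias)`` with
    ``corrected * bias == v`` exactly (the bias is strictly positive).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != v.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {v.shape}")
    if not mask.any():
        raise ValueError("empty mask: nothing to correct against")
    if method == "n4":
        bias = _n4_bias(v.values, mask)
    elif method == "polyfit":
        bias = _polyfit_bias(v.values, mask, poly_order)
    else:
        raise ValueError(f"unknown bias correction method: {method}")
    corrected = Volume3D(v.values / bias, spacing=v.spacing, affine=v.affine)
    return corrected, Volume3D(bias, spacing=v.spacing, affine=v.affine)


def _n4_bias(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(values.T, dtype=np.float32))
    msk = sitk.GetImageFromArray(np.ascontiguousarray(mask.T.astype(np.uint8)))
    corrector = sitk.N4BiasFieldCorrectionImageFilter()
    corrector.Execute(img, msk)
    log_bias = sitk.GetArrayFromImage(
        corrector.GetLogBiasFieldAsImage(img)).T.astype(np.float64)
    # a multiplicative field is identifiable only up to a scalar: pin its
    # geometric mean to 1 within the mask so corrected keeps the input scale
    log_bias -= log_bias[mask].mean()
    return np.exp(log_bias)


def _polyfit_bias(values: np.ndarray, mask: np.ndarray,
                  order: int) -> np.ndarray:
    """Least-squares polynomial fit to log intensities within the mask.

    The fitted log field is centred (mean 0 over the mask) so the bias has
    geometric mean 1 there and the corrected image keeps its scale.
    """
    from .synthetic import polynomial_monomials, _normalized_coords

    eps = max(1e-6, 1e-6 * float(np.abs(values).max()))
    logv = np.log(np.clip(values, eps, None))
    gx, gy, gz = _normalized_coords(values.shape)
    monos = [(0, 0, 0)] + polynomial_monomials(order)
    design = np.stack([(gx**i * gy**j * gz**k)[mask]
                       for i, j, k in monos], axis=1)
    coef, *_ = np.linalg.lstsq(design, logv[mask], rcond=None)
    log_field = np.zeros(values.shape)
    for c, (i, j, k) in zip(coef, monos):
        log_field += c * gx**i * gy**j * gz**k
    log_field -= log_field[mask].mean()
    return np.exp(log_field)


# -- augmentation --------------------------------------------------------------


def draw_augment_record(params: AugmentParams,
                        rng: np.random.Generator) -> AugmentRecord:
    """Draw one set of augmentation decisions (fixed draw order)."""
    applied = bool(rng.random() < params.select_p)
    mirror = tuple(bool(rng.random() < params.mirror_p) for _ in range(3))
    rot_axis = int(rng.integers(3))
    angle = float(rng.uniform(-params.rot_deg, params.rot_deg))
    intensity_u = float(rng.uniform(-1.0, 1.0))
    return AugmentRecord(applied=applied, mirror=mirror, rot_axis=rot_axis,
                         angle=angle, intensity_u=intensity_u)


_ROT_PLANES = {0: (1, 2), 1: (0, 2), 2: (0, 1)}  # rotation about W, H, D axes


def apply_augment_record(p: Patch, params: AugmentParams,
                         rec: AugmentRecord) -> Patch:
    """Apply a drawn transform: identical geometry for image and label,
    trilinear interpolation for the image, nearest-neighbour for the label,
    intensity shift on the image only."""
    if not rec.applied:
        return Patch(image=p.image.copy(), label=p.label.copy(),
                     source_id=p.source_id, center=p.center,
                     pad_mask=p.pad_mask.copy())
    image, label = p.image, p.label.astype(np.float64)
    pad = p.pad_mask.astype(np.float64)
    flips = tuple(ax for ax, m in enumerate(rec.mirror) if m)
    if flips:
        image = np.flip(image, axis=flips)
        label = np.flip(label, axis=flips)
        pad = np.flip(pad, axis=flips)
    if rec.angle != 0.0:
        plane = _ROT_PLANES[rec.rot_axis]
        image = ndimage.rotate(image, rec.angle, axes=plane, reshape=False,
                               order=1, mode="constant", cval=0.0)
        label = ndimage.rotate(label, rec.angle, axes=plane, reshape=False,
                               order=0, mode="constant", cval=0.0)
        pad = ndimage.rotate(pad, rec.angle, axes=plane, reshape=False,
                             order=0, mode="constant", cval=1.0)
    sigma = image.std()
    image = image + rec.intensity_u * params.intensity_frac * sigma / 2.0
    return Patch(image=np.ascontiguousarray(image),
                 label=np.ascontiguousarray(np.rint(label)).astype(np.int16),
                 source_id=p.source_id, center=p.center,
                 pad_mask=np.ascontiguousarray(pad) > 0.5)


def augment(p: Patch, params: AugmentParams,
            rng: np.random.Generator) -> Patch:
    """Randomly augment a patch (select -> mirror -> rotate -> intensity)."""
    return apply_augment_record(p, params, draw_augment_record(params, rng))
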