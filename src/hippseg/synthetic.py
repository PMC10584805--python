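"""Seeded synthetic hippocampus-like subjects for testing the pipeline.

Each subject is a small 3D scalar volume plus a paired label grid containing
two adjacent ellipsoidal "lobes": anterior (label 1) and posterior (label 2),
touching across a shared plane — the adjacency that the voxel decision rule,
connected-component filter and metrics all exercise.  Images are built as
class-dependent mean intensity + additive noise, multiplied by a smooth
positive bias field (exponential of a low-order polynomial in normalized
coordinates), emulating the intensity inhomogeneity that bias-field
correction removes.

Per-axis volume extents default to the ranges observed in the MSD
Task04_Hippocampus training scans: W in [31, 43], H in [40, 59], D in
[24, 47] voxels at 1.0 mm isotropic spacing.

Everything is a pure function of (spec, seed): subject ``i`` of a dataset is
reproducible in isolation from ``(seed, i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_volumes import LabelVolume, Volume3D

__all__ = [
    "SyntheticSpec", "GenerationError", "generate_subject",
    "generate_dataset", "apply_bias_field", "polynomial_monomials",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class GenerationError(RuntimeError):
    """Raised when a subject cannot be built under the given spec."""


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic subject generator.

    ``contrast`` maps class -> mean intensity in arbitrary MR-like units;
    ``contrast_jitter`` is the relative per-subject spread of those means
    (variable tissue contrast across scans).  ``bias_amplitude`` bounds the
    log-bias polynomial coefficients, ``bias_order`` its degree (<= 3).
    """

    extents: dict = field(default_factory=lambda: {
        "W": (31, 43), "H": (40, 59), "D": (24, 47)})
    contrast: dict = field(default_factory=lambda: {0: 100.0, 1: 160.0, 2: 140.0})
    contrast_jitter: float = 0.08
    noise_sd: float = 10.0
    noise_kind: str = "gaussian"          # or "rician"
    bias_amplitude: float = 0.15
    bias_order: int = 2
    lobe_scale: float = 1.0               # multiplies the default lobe radii
    seed: int = 0

    def __post_init__(self):
        for axis, (lo, hi) in self.extents.items():
            if hi < lo:
                raise ValueError(f"empty extent range for {axis}: {(lo, hi)}")
            if lo < 8:
                raise ValueError(f"extent minimum for {axis} must be >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bias_amplitude < 0:
            raise ValueError("bias_amplitude must be >= 0")
        if not 0 <= self.bias_order <= 3:
            raise ValueError("bias_order must be in [0, 3]")
        if self.noise_kind not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise_kind: {self.noise_kind}")


def polynomial_monomials(order: int) -> list[tuple[int, int, int]]:
    """Exponent triples (i, j, k) with 1 <= i+j+k <= order, sorted."""
    return sorted(
        (i, j, k)
        for i in range(order + 1)
        for j in range(order + 1)
        for k in range(order + 1)
        if 1 <= i + j + k <= order
    )


def _normalized_coords(shape):
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def apply_bias_field(v: Volume3D, coefficients,
                     order: int | None = None) -> tuple[Volume3D, Volume3D]:
    """Multiply ``v`` by ``exp(polynomial)`` of normalized coordinates.

    ``coefficients`` is a flat array paired with
    :func:`polynomial_monomials(order)`; the constant term is omitted so the
    log-bias is centred near 0.  Returns ``(biased, bias)`` with
    ``biased = v * bias`` elementwise; the bias is strictly positive for any
    finite coefficients by construction.
    """
    coefficients = np.asarray(coefficients, dtype=np.float64)
    if not np.all(np.isfinite(coefficients)):
        raise ValueError("bias coefficients must be finite")
    if order is None:
        for cand in (1, 2, 3):
            if len(polynomial_monomials(cand)) == coefficients.size:
                order = cand
                break
        else:
            raise ValueError(
                f"cannot infer polynomial order from {coefficients.size} "
                "coefficients; pass order explicitly")
    monos = polynomial_monomials(order)
    if coefficients.size != len(monos):
        raise ValueError(
            f"order {order} needs {len(monos)} coefficients, "
            f"got {coefficients.size}")
    gx, gy, gz = _normalized_coords(v.shape)
    logb = np.zeros(v.shape)
    for c, (i, j, k) in zip(coefficients, monos):
        logb += c * gx**i * gy**j * gz**k
    bias = np.exp(logb)
    biased = Volume3D(v.values * bias, spacing=v.spacing, affine=v.affine)
    return biased, Volume3D(bias, spacing=v.spacing, affine=v.affine)


def _place_lobes(shape, rng, lobe_scale: float) -> np.ndarray:
    """Two touching ellipsoids along the H axis; label 1 then 2."""
    W, H, D = shape
    # radii sized so the pooled foreground stays a few percent of the volume
    ax1 = max(2, int(round(0.14 * W * lobe_scale)))
    by1 = max(3, int(round(0.14 * H * lobe_scale)))
    cz1 = max(2, int(round(0.14 * D * lobe_scale)))
    ax2 = max(2, int(round(0.13 * W * lobe_scale)))
    by2 = max(3, int(round(0.17 * H * lobe_scale)))
    cz2 = max(2, int(round(0.13 * D * lobe_scale)))
    if 2 * (by1 + by2) + 2 >= H or 2 * max(ax1, ax2) + 2 >= W \
            or 2 * max(cz1, cz2) + 2 >= D:
        raise GenerationError(
            f"extents {shape} too small for lobes with radii "
            f"{(ax1, by1, cz1)} and {(ax2, by2, cz2)}")
    cx = W // 2 + int(rng.integers(-2, 3))
    cz = D // 2 + int(rng.integers(-2, 3))
    # touching plane near mid-H; centers overlap by one voxel along H so the
    # voxelized lobes share faces (26-adjacency guaranteed)
    y0 = H // 2 + int(rng.integers(-2, 3))
    cy1 = y0 - by1 + 1
    cy2 = y0 + by2
    cx = int(np.clip(cx, max(ax1, ax2) + 1, W - 2 - max(ax1, ax2)))
    cz = int(np.clip(cz, max(cz1, cz2) + 1, D - 2 - max(cz1, cz2)))
    if cy1 - by1 < 0 or cy2 + by2 >= H:
        raise GenerationError(f"lobes do not fit along H in extents {shape}")
    X, Y, Z = np.meshgrid(np.arange(W), np.arange(H), np.arange(D),
                          indexing="ij")
    in1 = (((X - cx) / ax1) ** 2 + ((Y - cy1) / by1) ** 2
           + ((Z - cz) / cz1) ** 2) <= 1.0
    in2 = (((X - cx) / ax2) ** 2 + ((Y - cy2) / by2) ** 2
           + ((Z - cz) / cz2) ** 2) <= 1.0
    label = np.zeros(shape, dtype=np.int16)
    label[in1] = 1
    label[in2 & ~in1] = 2
    return label


def _check_lobes(label: np.ndarray) -> None:
    for cls in (1, 2):
        mask = label == cls
        if not mask.any():
            raise GenerationError(f"class {cls} is empty")
        _, n = ndimage.label(mask, structure=_STRUCT26)
        if n != 1:
            raise GenerationError(f"class {cls} split into {n} components")
    # the two lobes must touch under 26-connectivity
    dil = ndimage.binary_dilation(label == 1, structure=_STRUCT26)
    if not np.any(dil & (label == 2)):
        raise GenerationError("lobes are not adjacent")


def generate_subject(spec: SyntheticSpec,
                     rng: np.random.Generator) -> tuple[Volume3D, LabelVolume]:
    """Draw one synthetic subject (image, label) from ``spec``."""
    shape = tuple(
        int(rng.integers(lo, hi + 1))
        for lo, hi in (spec.extents["W"], spec.extents["H"], spec.extents["D"]))
    label = _place_lobes(shape, rng, spec.lobe_scale)
    _check_lobes(label)

    means = {
        cls: mu * (1.0 + spec.contrast_jitter * float(rng.uniform(-1, 1)))
        for cls, mu in spec.contrast.items()
    }
    image = np.zeros(shape, dtype=np.float64)
    for cls, mu in means.items():
        image[label == cls] = mu

    if spec.noise_sd > 0:
        if spec.noise_kind == "rician":
            n1 = rng.normal(0.0, spec.noise_sd, shape)
            n2 = rng.normal(0.0, spec.noise_sd, shape)
            image = np.sqrt((image + n1) ** 2 + n2 ** 2)
        else:
            image = image + rng.normal(0.0, spec.noise_sd, shape)

    vol = Volume3D(image)
    if spec.bias_amplitude > 0 and spec.bias_order > 0:
        n_terms = len(polynomial_monomials(spec.bias_order))
        coeffs = rng.uniform(-spec.bias_amplitude, spec.bias_amplitude, n_terms)
        vol, _ = apply_bias_field(vol, coeffs, order=spec.bias_order)
    return vol, LabelVolume(label)


def generate_dataset(spec: SyntheticSpec, n: int,
                     seed: int | None = None) -> list[tuple[Volume3D, LabelVolume]]:
    """Generate ``n`` subjects; subject ``i`` depends only on (seed, i)."""
    if n < 1:
        raise ValueError(f"dataset size must be >= 1, got {n}")
    if seed is None:
        seed = spec.seed
    return [generate_subject(spec, np.random.default_rng([seed, i]))
            for i in range(n)]
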