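"""NIfTI volume and label I/O with geometry preservation.

In-memory convention: arrays are indexed ``(x, y, z) = (W, H, D)`` with
0-based voxel indices; axis reordering, if any, happens only at the I/O
boundary (nibabel returns data in this order for the datasets we target).
Label volumes use the vocabulary ``{0: background, 1: anterior, 2: posterior}``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

LABEL_VOCAB = (0, 1, 2)
BACKGROUND, ANTERIOR, POSTERIOR = LABEL_VOCAB


class VolumeFormatError(ValueError):
    """Raised for unreadable files or invalid voxel payloads."""


@dataclass
class Volume3D:
    """A 3D scalar grid with voxel spacing and an opaque affine geometry."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D grid, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise VolumeFormatError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class LabelVolume:
    """An integer class grid over {0 background, 1 anterior, 2 posterior}."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D label grid, got ndim={self.values.ndim}")
        bad = np.setdiff1d(np.unique(self.values), LABEL_VOCAB)
        if bad.size:
            raise VolumeFormatError(
                f"label values outside vocabulary {LABEL_VOCAB}: {bad.tolist()}")
        self.values = self.values.astype(np.int16)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def foreground_mask(self) -> np.ndarray:
        return self.values > 0


def _load_nifti(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"not a readable NIfTI file: {path}") from exc
    return img


def read_volume(path, nan_policy: str = "error") -> Volume3D:
    """Read a scalar NIfTI volume.

    ``nan_policy`` controls corrupt voxels: ``"error"`` (default) rejects
    NaN/inf payloads, ``"zero"`` replaces them with 0 and logs a warning.
    """
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if not np.all(np.isfinite(data)):
        if nan_policy == "zero":
            n_bad = int(np.sum(~np.isfinite(data)))
            log.warning("replacing %d non-finite voxels with 0 in %s",
                        n_bad, path)
            data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
        else:
            raise VolumeFormatError(
                f"volume {path} contains non-finite voxels "
                "(pass nan_policy='zero' to sanitize)")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(values=data, spacing=spacing, affine=img.affine)


def read_label_volume(path) -> LabelVolume:
    """Read an integer label NIfTI; rejects values outside {0, 1, 2}."""
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6, equal_nan=False):
        raise VolumeFormatError(f"label volume {path} has non-integer voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(values=rounded.astype(np.int16), spacing=spacing,
                       affine=img.affine)


def write_volume(v: Volume3D | LabelVolume, path) -> None:
    """Write a volume or label grid as NIfTI-1, preserving geometry.

    Labels are stored with an integer dtype, scalar volumes as float64 so
    that bias-corrected intensities round-trip to full precision.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(v, LabelVolume):
        data = v.values.astype(np.int16)
    else:
        data = v.values.astype(np.float64)
    img = nib.Nifti1Image(data, v.affine)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # nibabel pixdim chatter
        img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def find_msd_pairs(root) -> list[tuple[Path, Path]]:
    """Locate (image, label) NIfTI pairs in an MSD-style layout.

    Expects ``imagesTr/`` and ``labelsTr/`` subdirectories with matching
    file stems; hidden files (``.``-prefixed) are ignored.
    """
    root = Path(root)
    images = root / "imagesTr"
    labels = root / "labelsTr"
    if not images.is_dir() or not labels.is_dir():
        raise FileNotFoundError(
            f"expected imagesTr/ and labelsTr/ under {root}")
    pairs = []
    for img_path in sorted(images.iterdir()):
        if img_path.name.startswith(".") or not img_path.name.endswith(
                (".nii", ".nii.gz")):
            continue
        lbl_path = labels / img_path.name
        if not lbl_path.exists():
            raise FileNotFoundError(f"no label for image {img_path.name}")
        pairs.append((img_path, lbl_path))
    return pairs
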