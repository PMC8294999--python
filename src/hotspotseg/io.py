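"""Reading and writing images, masks, probability maps and cohort manifests.

Grayscale slices are accepted as PNG (8/16-bit), DICOM or NIfTI and are
min-max rescaled to [0, 1] per slice (MRI has no absolute intensity
scale); the original range is returned as metadata.  Masks round-trip
exactly as 8-bit PNG {0, 255} or NIfTI {0, 1}; probability maps are
written as 16-bit PNG (scaled by 65535) or NIfTI float.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import dataclass

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pydicom

from .exceptions import ConfigurationError
from .phantom import PhantomCase

logger = logging.getLogger(__name__)

_NIFTI_EXTS = (".nii", ".nii.gz")


def _is_nifti(path: str) -> bool:
    return path.endswith(_NIFTI_EXTS)


def _squeeze_2d(arr: np.ndarray, path: str) -> np.ndarray:
    arr = np.squeeze(np.asarray(arr))
    if arr.ndim != 2:
        raise ConfigurationError(
            f"{path}: expected a single 2-D slice, got shape {arr.shape}"
        )
    return arr


def read_image(path: str) -> tuple[np.ndarray, dict]:
    """Load a grayscale slice and rescale it to [0, 1].

    Returns ``(image, meta)`` with the original intensity range in
    ``meta``.  A constant image degenerates to all zeros (warning logged).
    """
    if not os.path.exists(path):
        raise ConfigurationError(f"image file not found: {path}")
    try:
        if _is_nifti(path):
            arr = np.asanyarray(nib.load(path).dataobj)
        elif path.lower().endswith(".dcm"):
            arr = pydicom.dcmread(path).pixel_array
        else:
            arr = iio.imread(path)
    except ConfigurationError:
        raise
    except Exception as exc:  # corrupt / unknown format
        raise ConfigurationError(f"cannot read image {path}: {exc}") from exc
    arr = _squeeze_2d(arr, path).astype(float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        image = (arr - lo) / (hi - lo)
    else:
        logger.warning("constant image %s: rescaling degenerates, using zeros", path)
        image = np.zeros_like(arr)
    return image, {"path": path, "original_min": lo, "original_max": hi}


def write_image(image: np.ndarray, path: str) -> None:
    """Write a [0, 1] float image as 16-bit PNG or NIfTI float."""
    image = np.asarray(image, dtype=float)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(image.astype(np.float32), np.eye(4)), path)
    else:
        iio.imwrite(path, np.round(image * 65535).astype(np.uint16))


write_probability_map = write_image  # same quantization conventions


def read_probability_map(path: str) -> np.ndarray:
    if _is_nifti(path):
        arr = _squeeze_2d(np.asanyarray(nib.load(path).dataobj), path)
        return arr.astype(float)
    arr = _squeeze_2d(iio.imread(path), path)
    return arr.astype(float) / 65535.0


def write_mask(mask: np.ndarray, path: str) -> None:
    """Write a binary mask as PNG {0, 255} or NIfTI {0, 1}."""
    mask = np.asarray(mask, dtype=bool)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), path)
    else:
        iio.imwrite(path, (mask * 255).astype(np.uint8))


def read_mask(path: str) -> np.ndarray:
    if not os.path.exists(path):
        raise ConfigurationError(f"mask file not found: {path}")
    if _is_nifti(path):
        arr = _squeeze_2d(np.asanyarray(nib.load(path).dataobj), path)
        return arr > 0
    return _squeeze_2d(iio.imread(path), path) > 127


# ---------------------------------------------------------------------------
# cohort manifests


@dataclass
class ManifestRow:
    case_id: str
    image_path: str
    mask_path: str
    gold_label: str
    seed: int


def save_cohort(
    cases: list[PhantomCase], out_dir: str, fmt: str = "png"
) -> str:
    """Write cohort images/masks plus a CSV manifest; returns manifest path."""
    if fmt not in ("png", "nii.gz"):
        raise ConfigurationError(f"unsupported cohort format {fmt!r}")
    os.makedirs(out_dir, exist_ok=True)
    manifest = os.path.join(out_dir, "manifest.csv")
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "image_path", "mask_path", "gold_label", "seed"])
        for i, case in enumerate(cases):
            case_id = f"case_{i:04d}"
            img = os.path.join(out_dir, f"{case_id}_image.{fmt}")
            msk = os.path.join(out_dir, f"{case_id}_mask.{fmt}")
            write_image(case.image, img)
            write_mask(case.mask, msk)
            writer.writerow([case_id, img, msk, case.gold_label, case.seed])
    return manifest


def load_manifest(path: str) -> list[ManifestRow]:
    if not os.path.exists(path):
        raise ConfigurationError(f"manifest not found: {path}")
    rows: list[ManifestRow] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                ManifestRow(
                    case_id=rec["case_id"],
                    image_path=rec["image_path"],
                    mask_path=rec["mask_path"],
                    gold_label=rec["gold_label"],
                    seed=int(rec["seed"]),
                )
            )
    return rows
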