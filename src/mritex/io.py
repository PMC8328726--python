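"""Reading and writing images, masks and cohort manifests.

Supported formats: NIfTI (via nibabel), single-frame grayscale DICOM
(via pydicom), 8/16-bit PNG (via imageio) and raw ``.npy`` arrays.
Intensities are returned as floating point; PNG values are scaled by the
bit-depth maximum so an 8-bit 255 and a 16-bit 65535 both map to 1.0.
NIfTI and ``.npy`` store floats directly and round-trip losslessly.
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .errors import ImageIOError, ShapeMismatchError
from .phantoms import PhantomSample

__all__ = [
    "load_image",
    "load_mask",
    "save_image",
    "save_mask",
    "write_cohort",
    "read_cohort",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "NIFTI"
    if name.endswith((".dcm", ".dicom")):
        return "DICOM"
    if name.endswith(".png"):
        return "PNG"
    if name.endswith(".npy"):
        return "ARRAY"
    raise ImageIOError(f"cannot infer image format from {path.name!r}")


def load_image(path, format: Optional[str] = None) -> np.ndarray:
    """Load an intensity image as a float array.

    2-D inputs give a 2-D array; 3-D NIfTI volumes are returned
    slice-indexed, shape (n_slices, H, W).
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    fmt = (format or _detect_format(path)).upper()
    try:
        if fmt == "NIFTI":
            data = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
            if data.ndim == 3:
                data = np.moveaxis(data, -1, 0)
            elif data.ndim != 2:
                raise ImageIOError(f"unsupported NIfTI dimensionality {data.ndim}")
            return data
        if fmt == "DICOM":
            import pydicom

            ds = pydicom.dcmread(str(path))
            arr = ds.pixel_array.astype(np.float64)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            return arr * slope + intercept
        if fmt == "PNG":
            arr = iio.imread(path)
            if arr.ndim == 3:  # collapse RGB(A) to luminance-free grayscale check
                if arr.shape[2] in (3, 4) and np.ptp(arr[..., :3], axis=2).max() == 0:
                    arr = arr[..., 0]
                else:
                    raise ImageIOError(f"{path.name}: colour PNG is not a grayscale image")
            if arr.dtype == np.uint8:
                return arr.astype(np.float64) / 255.0
            if arr.dtype == np.uint16:
                return arr.astype(np.float64) / 65535.0
            raise ImageIOError(f"{path.name}: unsupported PNG bit depth {arr.dtype}")
        if fmt == "ARRAY":
            return np.load(path).astype(np.float64)
    except ImageIOError:
        raise
    except Exception as exc:  # unreadable / malformed file
        raise ImageIOError(f"failed to read {path}: {exc}") from exc
    raise ImageIOError(f"unknown format {fmt!r}")


def load_mask(path, format: Optional[str] = None, image: Optional[np.ndarray] = None) -> np.ndarray:
    """Load a binary mask (nonzero = inside ROI); optionally check pairing."""
    arr = load_image(path, format=format)
    mask = arr != 0
    if image is not None and mask.shape != image.shape:
        raise ShapeMismatchError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    return mask


def save_image(path, image: np.ndarray) -> None:
    """Write an intensity image; format chosen by extension.

    PNG output is quantized to 16-bit (intensities assumed in [0, 1]);
    NIfTI/.npy preserve the float values exactly.
    """
    path = Path(path)
    fmt = _detect_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "NIFTI":
        nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float64), np.eye(4)), str(path))
    elif fmt == "PNG":
        arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
        iio.imwrite(path, np.round(arr * 65535.0).astype(np.uint16))
    elif fmt == "ARRAY":
        np.save(path, np.asarray(image))
    else:
        raise ImageIOError(f"writing format {fmt} is not supported")


def save_mask(path, mask: np.ndarray) -> None:
    path = Path(path)
    fmt = _detect_format(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    m = np.asarray(mask).astype(np.uint8)
    if fmt == "NIFTI":
        nib.save(nib.Nifti1Image(m, np.eye(4)), str(path))
    elif fmt == "PNG":
        iio.imwrite(path, (m * 255).astype(np.uint8))
    elif fmt == "ARRAY":
        np.save(path, m.astype(bool))
    else:
        raise ImageIOError(f"writing format {fmt} is not supported")


def write_cohort(samples: Sequence[PhantomSample], out_dir, fmt: str = "nii") -> Path:
    """Write a phantom cohort as image/mask pairs plus a CSV manifest.

    The manifest has columns sample_id, image, mask, label, seed; paths
    are relative to ``out_dir``.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"nii": ".nii.gz", "png": ".png", "npy": ".npy"}[fmt]
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "image", "mask", "label", "seed"])
        for i, s in enumerate(samples):
            sid = f"sample_{i:04d}"
            img_name, mask_name = f"{sid}_image{ext}", f"{sid}_mask{ext}"
            save_image(out_dir / img_name, s.image)
            save_mask(out_dir / mask_name, s.lesion_mask)
            writer.writerow([sid, img_name, mask_name, s.label, s.spec.seed])
    return manifest


def read_cohort(manifest_path) -> Tuple[List[np.ndarray], List[np.ndarray], List[str]]:
    """Load images, masks and labels listed in a cohort manifest CSV."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    images, masks, labels = [], [], []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            img = load_image(base / row["image"])
            masks.append(load_mask(base / row["mask"], image=img))
            images.append(img)
            labels.append(row["label"])
    return images, masks, labels
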