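"""Reading and writing of images, instance label masks and manifests.

Images are 8-bit RGB PNG/TIFF, normalised to [0, 1] float32 on read and
written back bit-exactly as uint8.  Instance masks are single-channel
16-bit rasters with 0 = background and consecutive positive labels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .synth import AnnotationSet

__all__ = ["read_image", "write_image", "read_labels", "write_labels"]

log = logging.getLogger(__name__)

_TIFF = {".tif", ".tiff"}


def read_image(path) -> np.ndarray:
    """Read an RGB image as float32 in [0, 1].

    8-bit data divides by 255 (bit-exact round trip with
    :func:`write_image`); 16-bit data is scaled by 65535 with a logged
    notice.  Non-RGB input is rejected.
    """
    path = Path(path)
    if path.suffix.lower() in _TIFF:
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            if im.mode != "RGB":
                raise ValueError(
                    f"{path.name}: expected an RGB image, got mode {im.mode!r}"
                )
            arr = np.asarray(im)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"{path.name}: expected 3 colour channels, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        return (arr / 255.0).astype(np.float32)
    if arr.dtype == np.uint16:
        log.info("%s: 16-bit input scaled to [0,1] by 65535", path.name)
        return (arr / 65535.0).astype(np.float32)
    raise ValueError(f"{path.name}: unsupported dtype {arr.dtype}")


def write_image(path, image: np.ndarray) -> None:
    """Write a float [0,1] RGB image as 8-bit PNG or TIFF."""
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    u8 = np.round(arr * 255.0).astype(np.uint8)
    if path.suffix.lower() in _TIFF:
        tifffile.imwrite(path, u8)
    else:
        Image.fromarray(u8, mode="RGB").save(path)


def read_labels(path, complete: bool = False) -> AnnotationSet:
    """Read a single-channel instance mask into an :class:`AnnotationSet`.

    Negative or floating-point labels are rejected; non-consecutive labels
    are relabelled consecutively with the mapping logged.
    """
    path = Path(path)
    if path.suffix.lower() in _TIFF:
        arr = tifffile.imread(path)
    else:
        with Image.open(path) as im:
            arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a single-channel mask")
    if np.issubdtype(arr.dtype, np.floating):
        raise ValueError(f"{path.name}: floating-point labels are not allowed")
    arr = arr.astype(np.int64)
    if arr.min() < 0:
        raise ValueError(f"{path.name}: negative labels are not allowed")
    present = np.unique(arr)
    present = present[present > 0]
    expected = np.arange(1, len(present) + 1)
    if not np.array_equal(present, expected):
        mapping = {int(old): int(new) for old, new in zip(present, expected)}
        log.info("%s: relabelled non-consecutive instances: %s", path.name, mapping)
        out = np.zeros_like(arr)
        for old, new in mapping.items():
            out[arr == old] = new
        arr = out
    return AnnotationSet(labels=arr.astype(np.int32), complete=complete,
                         source_image_id=path.stem)


def write_labels(path, annotations: AnnotationSet | np.ndarray) -> None:
    """Write an instance mask as a 16-bit single-channel PNG or TIFF."""
    path = Path(path)
    labels = annotations.labels if isinstance(annotations, AnnotationSet) else annotations
    if labels.max(initial=0) > 65535:
        raise ValueError("more than 65535 instances cannot be stored in 16 bits")
    u16 = labels.astype(np.uint16)
    if path.suffix.lower() in _TIFF:
        tifffile.imwrite(path, u16)
    else:
        Image.fromarray(u16).save(path)
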