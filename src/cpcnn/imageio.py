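"""Image reading/writing and the three-level resolution pyramid.

Clinical sagittal knee MR slices arrive at heterogeneous resolutions with
uninformative background at the left/right margins; preprocessing crops
each image to a 2:1 width:height window and resamples it to the three
working resolutions (nominal 640x320, 1280x640, 2560x1280) consumed by
the primary, secondary and tertiary network tiers.

Grayscale images are float32 in [0, 1] with (row, column) = (y, x)
indexing, origin top-left. Readers cover PNG/TIFF (Pillow / tifffile)
and optionally single-frame DICOM when pydicom is importable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

__all__ = [
    "PyramidImage",
    "load_image",
    "build_pyramid",
    "save_png",
    "read_manifest",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class PyramidImage:
    """One case as three co-registered resolutions of the same scene."""

    low: np.ndarray  # (H, W), float32 in [0, 1]
    mid: np.ndarray  # (2H, 2W)
    high: np.ndarray  # (4H, 4W)
    case_id: str = ""

    def __post_init__(self):
        h, w = self.low.shape
        if self.mid.shape != (2 * h, 2 * w) or self.high.shape != (4 * h, 4 * w):
            raise ValueError(
                "pyramid levels must scale 1x/2x/4x: got "
                f"{self.low.shape}, {self.mid.shape}, {self.high.shape}"
            )

    @property
    def base_size(self) -> tuple[int, int]:
        """(width, height) of the lowest level."""
        return (self.low.shape[1], self.low.shape[0])

    def levels(self):
        return {"low": self.low, "mid": self.mid, "high": self.high}


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Scale an image array to float32 [0, 1] based on its dtype."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float32) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float32) / 65535.0
    if arr.dtype.kind in "iu":
        info = np.iinfo(arr.dtype)
        return (arr.astype(np.float64) - min(info.min, 0)) / float(info.max - min(info.min, 0))
    arr = arr.astype(np.float32)
    top = float(arr.max()) if arr.size else 1.0
    if top > 1.0:
        arr = arr / top
    return np.clip(arr, 0.0, 1.0).astype(np.float32)


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[:, :, :3] @ _LUMA
    raise IOError(f"unsupported image shape {arr.shape}")


def load_image(path) -> np.ndarray:
    """Read a grayscale image as float32 [0, 1].

    PNG/TIFF via Pillow/tifffile; ``.dcm`` via pydicom when available.
    RGB inputs are converted to luminance (ITU-R 601 weights).
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"image not found: {p}")
    if p.stat().st_size == 0:
        raise IOError(f"empty image file: {p}")
    suffix = p.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise IOError(f"DICOM support requires pydicom (reading {p})") from exc
        ds = pydicom.dcmread(p)
        arr = ds.pixel_array.astype(np.float32)
        # MR pixel data rarely spans its storage dtype: scale by data range
        lo, hi = float(arr.min()), float(arr.max())
        arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(p)
    else:
        try:
            with Image.open(p) as im:
                arr = np.asarray(im)
        except Exception as exc:
            raise IOError(f"cannot read image {p}: {exc}") from exc
    gray = _to_grayscale(_normalize(np.asarray(arr)))
    return np.asarray(gray, dtype=np.float32)


def _center_crop_2to1(image: np.ndarray) -> np.ndarray:
    """Crop the longer relative dimension so width = 2 x height."""
    h, w = image.shape
    if w >= 2 * h:
        target_w = 2 * h
        x0 = (w - target_w) // 2
        return image[:, x0:x0 + target_w]
    target_h = w // 2
    y0 = (h - target_h) // 2
    return image[y0:y0 + target_h, :]


def build_pyramid(image: np.ndarray, base_size: tuple[int, int] = (640, 320),
                  case_id: str = "") -> PyramidImage:
    """Center-crop to 2:1 and resample to the three pyramid levels.

    ``base_size`` is (width, height) of the lowest level; the other levels
    are 2x and 4x. Sources below a level's resolution are upsampled —
    scanner resolutions are heterogeneous and must never fail.
    """
    w, h = int(base_size[0]), int(base_size[1])
    if w != 2 * h:
        raise ValueError(f"base_size must be 2:1 (width = 2 x height), got {base_size}")
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2 or image.size == 0:
        raise ValueError(f"expected a nonempty 2-D grayscale image, got shape {image.shape}")
    cropped = _center_crop_2to1(image)
    levels = []
    for scale in (1, 2, 4):
        th, tw = h * scale, w * scale
        if cropped.shape == (th, tw):
            levels.append(cropped.astype(np.float32))
            continue
        down = cropped.shape[0] > th
        lvl = _sk_resize(cropped, (th, tw), order=1, mode="edge",
                         anti_aliasing=down, preserve_range=True)
        levels.append(np.clip(lvl, 0.0, 1.0).astype(np.float32))
    return PyramidImage(low=levels[0], mid=levels[1], high=levels[2],
                        case_id=case_id)


def save_png(path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float32), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8), mode="L").save(path)


def read_manifest(manifest_path):
    """Read a dataset manifest CSV written by :func:`phantoms.write_dataset`.

    Returns a list of dict rows with absolute paths resolved against the
    manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    rows = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            entry = dict(row)
            entry["label"] = int(row["label"])
            for key in ("low", "mid", "high", "mask"):
                if row.get(key):
                    entry[key] = str(base / row[key])
            rows.append(entry)
    return rows
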