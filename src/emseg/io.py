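"""Reading and writing images, masks and tissue maps.

8-bit grayscale PNG/TIFF round-trips go through imageio; NIfTI volumes are
read with nibabel and reduced to an axial slice.  Tissue maps are written
as indexed-color PNGs with a fixed palette so runs are visually comparable.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

from .labels import BG, SKULL, CSF, GM, WM

__all__ = ["read_grayscale", "write_grayscale", "read_nifti_slice",
           "write_mask", "write_tissue_map", "TISSUE_COLORS"]

# fixed color table: BG black, SKULL white, CSF blue, GM green, WM red
TISSUE_COLORS = {
    BG: (0, 0, 0),
    SKULL: (255, 255, 255),
    CSF: (60, 100, 230),
    GM: (90, 200, 90),
    WM: (230, 80, 70),
}


def read_grayscale(path) -> np.ndarray:
    """Load an image file as a 2-D uint8 grid (RGB inputs are averaged)."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def write_grayscale(path, image) -> None:
    iio.imwrite(path, np.clip(np.rint(np.asarray(image)), 0, 255).astype(np.uint8))


def read_nifti_slice(path, index: int = None, axis: int = 2) -> np.ndarray:
    """Extract one slice of a NIfTI volume, rescaled to uint8.

    ``index`` defaults to the middle slice along ``axis``.
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if index is None:
        index = vol.shape[axis] // 2
    sl = np.take(vol, index, axis=axis).astype(float)
    lo, hi = sl.min(), sl.max()
    if hi > lo:
        sl = (sl - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(sl), 0, 255).astype(np.uint8)


def write_mask(path, mask) -> None:
    """Save a boolean mask as a 0/255 PNG."""
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_tissue_map(path, tissue_map) -> None:
    """Save a tissue/label map as an RGB PNG with the fixed color table."""
    tm = np.asarray(tissue_map)
    rgb = np.zeros(tm.shape + (3,), dtype=np.uint8)
    for code, color in TISSUE_COLORS.items():
        rgb[tm == code] = color
    iio.imwrite(path, rgb)
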