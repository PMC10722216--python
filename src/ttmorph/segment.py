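"""T-tubule mask production and ingestion.

Masks are an explicit interchange point: the reference workflow exports
binary t-tubule masks from an interactively trained pixel classifier, and
:func:`load_mask` ingests such exports.  :func:`baseline_segment`
provides a deterministic classical segmenter (top-hat background
subtraction, Gaussian smoothing, Otsu threshold within the cell, small
object removal, peripheral-rim and nucleus-void exclusion) so the
pipeline runs end to end without any external classifier.  Downstream
morphometry is agnostic to where the mask came from.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import disk, erosion, remove_small_objects, white_tophat

from .types import CellImage, TubuleMask

__all__ = ["SegmentParams", "load_mask", "save_mask", "baseline_segment"]


@dataclass
class SegmentParams:
    """Baseline segmenter settings.

    expected_tubule_width_px : nominal tubule width; the top-hat radius is
        three times this value so tubules survive background subtraction.
    rim_px : peripheral rim of the cell mask excluded from the tubule mask
        (the surface sarcolemma is not a t-tubule).
    nucleus_sigma_px / nucleus_frac / nucleus_min_area_px : the nucleus is
        detected as a large connected intensity void, i.e. a region of the
        heavily smoothed WGA image below ``nucleus_frac`` of the in-cell
        median.
    """

    expected_tubule_width_px: int = 3
    smoothing_sigma_px: float = 1.0
    min_size_px: int = 9
    min_class_separation: float = 4.0
    rim_px: int = 3
    nucleus_sigma_px: float = 8.0
    nucleus_frac: float = 0.5
    nucleus_min_area_px: int = 400


def load_mask(path: str | Path, cell: CellImage) -> TubuleMask:
    """Read an exported binary tubule mask and align it to a cell.

    Any nonzero pixel counts as tubule; the result is intersected with the
    cell mask.  An all-background mask is allowed (border-zone cells can
    be nearly tubule-free) and only sets ``empty_warning``.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        raw = tifffile.imread(path)
    else:
        raw = iio.imread(path)
    raw = np.asarray(raw)
    if raw.ndim == 3 and raw.shape[2] in (3, 4):  # flatten RGB(A) exports
        raw = raw[..., :3].max(axis=2)
    if raw.shape != cell.shape:
        raise ValueError(
            f"mask {path.name} has shape {raw.shape}, cell is {cell.shape}"
        )
    return TubuleMask.from_cell(raw > 0, cell, provenance="external_file")


def save_mask(path: str | Path, mask: TubuleMask) -> None:
    """Write a mask as an 8-bit 0/255 single-channel image (TIFF or PNG)."""
    path = Path(path)
    img = (mask.mask.astype(np.uint8)) * 255
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)


def _nucleus_void(cell: CellImage, params: SegmentParams) -> np.ndarray:
    """Large low-intensity connected region inside the cell (the nucleus)."""
    smooth = gaussian(cell.tubule_channel, sigma=params.nucleus_sigma_px)
    inside = cell.cell_mask
    med = np.median(smooth[inside])
    if med <= 0:
        return np.zeros(cell.shape, dtype=bool)
    dark = inside & (smooth < params.nucleus_frac * med)
    labels, n = ndi.label(dark)
    void = np.zeros(cell.shape, dtype=bool)
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() >= params.nucleus_min_area_px:
            void |= comp
    return void


def baseline_segment(
    cell: CellImage, params: SegmentParams | None = None
) -> TubuleMask:
    """Deterministic classical t-tubule segmentation of the WGA channel."""
    params = params or SegmentParams()
    if not cell.cell_mask.any():
        raise ValueError("empty cell mask")

    img = cell.tubule_channel.astype(float)
    radius = max(3 * params.expected_tubule_width_px // 2, 2)
    flat = white_tophat(img, footprint=disk(radius))
    smooth = gaussian(flat, sigma=params.smoothing_sigma_px)

    inside_vals = smooth[cell.cell_mask]
    if np.ptp(inside_vals) <= 0:
        mask = np.zeros(cell.shape, dtype=bool)
    else:
        # Otsu splits any histogram, structure or not.  Guard with the
        # class-separation effect size: splitting a unimodal noise
        # distribution yields (mu1 - mu0) of roughly 2.5 background SDs,
        # while genuine tubule signal separates by far more.
        thr = threshold_otsu(inside_vals)
        v0 = inside_vals[inside_vals <= thr]
        v1 = inside_vals[inside_vals > thr]
        sep = (v1.mean() - v0.mean()) / max(v0.std(), 1e-12)
        if sep < params.min_class_separation:
            mask = np.zeros(cell.shape, dtype=bool)
        else:
            mask = (smooth > thr) & cell.cell_mask
            mask = remove_small_objects(mask, max_size=params.min_size_px - 1)

    if params.rim_px > 0:
        interior = erosion(cell.cell_mask, disk(params.rim_px))
        mask &= interior
    mask &= ~_nucleus_void(cell, params)

    return TubuleMask.from_cell(mask, cell, provenance="baseline_segmenter")
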