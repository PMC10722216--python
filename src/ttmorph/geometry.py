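"""Cell preparation: long-axis estimation, rotation to vertical, and QC.

Analysis of tubule angles requires every myocyte to be oriented the same
way, so each cell is rotated (bilinear interpolation) until its
longitudinal centre of mass is vertical, then cropped to its bounding box
plus a margin.  Cells showing curvature, inconsistent labelling, edge
contact or low contrast are excluded by a deterministic, threshold-based
analogue of the usual manual exclusion criteria.

Conventions: row-major arrays with origin top-left; angles are measured
counter-clockwise from the vertical image axis and lie in (-90, 90].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .types import CellImage, QCReport

__all__ = [
    "GeometryParams",
    "estimate_long_axis",
    "rotate_to_vertical",
    "prepare_cell",
    "qc_filter",
]


@dataclass
class GeometryParams:
    """Thresholds for cell preparation and quality control.

    contrast_min : minimum robust contrast (p99 - p1)/p99 of the in-mask
        WGA intensity.
    rectangularity_min : minimum ratio of mask area to its bounding-box
        area after rotation; curved (banana-shaped) cells fall below it.
    band_cv_max : maximum coefficient of variation of per-sarcomere-band
        mean intensity; patchy labelling exceeds it.
    crop_margin_px : margin kept around the mask bounding box after
        rotation.
    """

    contrast_min: float = 0.2
    rectangularity_min: float = 0.75
    band_cv_max: float = 0.6
    crop_margin_px: int = 10
    band_period_um: float = 1.9


def estimate_long_axis(cell_mask: np.ndarray) -> tuple[float, bool]:
    """Angle of the mask's principal axis from the vertical image axis.

    The major eigenvector of the second central moments of the foreground
    coordinates defines the long axis.  Returns ``(angle_deg, degenerate)``
    with the angle in (-90, 90], counter-clockwise positive; a mask with
    equal eigenvalues (no preferred axis) returns 0 with the degeneracy
    flag set.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    coords = np.argwhere(cell_mask)
    if coords.shape[0] == 0:
        raise ValueError("empty mask: cannot estimate a long axis")
    if np.unique(coords, axis=0).shape[0] < 2:
        raise ValueError("mask needs at least two distinct foreground pixels")

    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if np.isclose(evals[0], evals[1], rtol=1e-6, atol=1e-9):
        return 0.0, True  # isotropic: tie broken toward no rotation
    vr, vc = evecs[:, 1]
    # CCW-positive as the image is displayed (origin top-left), matching
    # the rotation convention used by rotate_to_vertical.
    angle = np.degrees(np.arctan2(vc, vr))
    angle = (angle + 90.0) % 180.0 - 90.0
    if angle == -90.0:
        angle = 90.0
    return float(angle), False


def _rotate_channel(img: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    return _sk_rotate(
        img.astype(float), angle_deg, resize=True, order=order,
        preserve_range=True, mode="constant", cval=0.0,
    )


def rotate_to_vertical(
    cell: CellImage,
    angle_deg: float,
    margin_px: int = 10,
    extra_mask: np.ndarray | None = None,
):
    """Rotate all channels and the mask by ``-angle_deg`` and crop.

    Bilinear interpolation is used for the intensity channels and for the
    mask, which is re-binarised at 0.5.  The output is cropped to the
    rotated mask's bounding box plus ``margin_px`` (clamped at the frame).

    An ``extra_mask`` (e.g. a tubule mask aligned to the input) is carried
    through the identical transform; the return value is then the pair
    ``(cell, extra_mask)``.
    """
    # skimage.rotate(angle) turns the content counter-clockwise on screen;
    # undoing a CCW-positive axis angle therefore passes -angle.
    rot = lambda im, order: _rotate_channel(im, -angle_deg, order)
    mask = rot(cell.cell_mask.astype(float), 1) > 0.5
    if not mask.any():
        raise ValueError("rotation produced an empty cell mask")
    tub = np.clip(rot(cell.tubule_channel, 1), 0, None)
    ryr = np.clip(rot(cell.ryr_channel, 1), 0, None)

    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0 = max(rows[0] - margin_px, 0)
    r1 = min(rows[-1] + margin_px + 1, mask.shape[0])
    c0 = max(cols[0] - margin_px, 0)
    c1 = min(cols[-1] + margin_px + 1, mask.shape[1])
    sl = (slice(r0, r1), slice(c0, c1))
    out = CellImage(
        tubule_channel=tub[sl],
        ryr_channel=ryr[sl],
        cell_mask=mask[sl],
        pixel_size_nm=cell.pixel_size_nm,
        cell_id=cell.cell_id,
        animal_id=cell.animal_id,
        group_label=cell.group_label,
        region_label=cell.region_label,
    )
    if extra_mask is None:
        return out
    extra = rot(np.asarray(extra_mask, dtype=float), 1) > 0.5
    return out, extra[sl]


def prepare_cell(
    cell: CellImage,
    params: GeometryParams | None = None,
    extra_mask: np.ndarray | None = None,
):
    """Estimate the long axis and rotate the cell to vertical.

    Returns ``(rotated_cell, angle)``, or ``(rotated_cell, rotated_mask,
    angle)`` when an extra mask rides along through the same transform.
    """
    params = params or GeometryParams()
    angle, _ = estimate_long_axis(cell.cell_mask)
    res = rotate_to_vertical(
        cell, angle, margin_px=params.crop_margin_px, extra_mask=extra_mask
    )
    if extra_mask is None:
        return res, angle
    return res[0], res[1], angle


def _robust_contrast(values: np.ndarray) -> float:
    p1, p99 = np.percentile(values, [1, 99])
    if p99 <= 0:
        return 0.0
    return float((p99 - p1) / p99)


def _rectangularity(mask: np.ndarray) -> float:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    box = (rows[-1] - rows[0] + 1) * (cols[-1] - cols[0] + 1)
    return float(mask.sum() / box)


def _band_cv(cell: CellImage, period_um: float) -> float:
    """CV of per-sarcomere-band mean WGA intensity down the cell."""
    period_px = max(int(round(period_um / cell.pixel_size_um)), 2)
    rows = np.flatnonzero(cell.cell_mask.any(axis=1))
    means = []
    for start in range(rows[0], rows[-1] + 1 - period_px // 2, period_px):
        band = slice(start, min(start + period_px, rows[-1] + 1))
        m = cell.cell_mask[band]
        if m.sum() < 10:
            continue
        means.append(cell.tubule_channel[band][m].mean())
    if len(means) < 3:
        return 0.0
    means = np.asarray(means)
    if means.mean() <= 0:
        return np.inf
    return float(means.std() / means.mean())


def qc_filter(cell: CellImage, params: GeometryParams | None = None) -> QCReport:
    """Deterministic pass/fail quality control on a rotated cell.

    Checks, in order: edge contact (mask touches the crop frame, implying
    the cell touched the source field border), low contrast, curvature
    (low rectangularity of the vertically aligned mask), and inconsistent
    labelling (high CV of sarcomere-band mean intensity).
    """
    params = params or GeometryParams()
    mask = cell.cell_mask
    reasons: list[str] = []
    details: dict[str, float] = {}

    touches = (
        mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    if touches:
        reasons.append("touches_edge")

    contrast = _robust_contrast(cell.tubule_channel[mask]) if mask.any() else 0.0
    details["contrast"] = contrast
    if contrast < params.contrast_min:
        reasons.append("low_contrast")

    if mask.any():
        rect = _rectangularity(mask)
        details["rectangularity"] = rect
        if rect < params.rectangularity_min:
            reasons.append("curved")

        cv = _band_cv(cell, params.band_period_um)
        details["band_cv"] = cv
        if cv > params.band_cv_max:
            reasons.append("inconsistent_labelling")

    return QCReport(cell_id=cell.cell_id, reasons=reasons, details=details)
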