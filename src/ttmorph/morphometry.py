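"""Per-cell t-tubule morphometry from the binary mask.

Four outcomes are computed on a vertically aligned cell:

* area % — tubule-mask pixels over myocyte-mask pixels x 100;
* length % — pixels of the one-pixel-wide skeleton over myocyte area x 100
  (a length density; skeleton length is the pixel count, no diagonal
  correction, so length % <= area % holds exactly);
* transverse % — share of skeleton pixels whose local chord orientation
  falls in the transverse band, 60-130 degrees from the longitudinal
  (vertical) axis, inclusive at both ends;
* thickness ratio — mask area / skeleton length, a mean tubule width
  proxy in pixels.

Local orientation uses an along-branch chord: for each skeleton pixel the
angle of the segment joining the pixels reached by walking half a window
in each direction along the branch (shorter at ends and branch points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize

from .types import CellImage, PowerResult, Skeleton, TubuleMask, CellMetrics

__all__ = [
    "MorphometryParams",
    "area_fraction",
    "skeletonize",
    "length_density",
    "local_orientation",
    "transverse_fraction",
    "thickness_ratio",
    "compute_cell_metrics",
]

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class MorphometryParams:
    orientation_window_px: int = 7
    transverse_band_deg: tuple = (60.0, 130.0)
    diagonal_correction: bool = False  # sqrt(2) weighting of diagonal steps


def area_fraction(mask: TubuleMask, cell_mask: np.ndarray) -> float:
    """Percent area of the tubule mask over the myocyte area."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    n_cell = int(cell_mask.sum())
    if n_cell == 0:
        raise ValueError("empty cell mask")
    return 100.0 * mask.area_px / n_cell


def _chord_angle(p0: tuple, p1: tuple) -> float:
    """Angle of the chord p0->p1 from vertical, folded into [0, 180)."""
    dr = p1[0] - p0[0]
    dc = p1[1] - p0[1]
    return math.degrees(math.atan2(dc, dr)) % 180.0


def _build_adjacency(pixels: np.ndarray) -> list:
    index = {tuple(p): i for i, p in enumerate(pixels)}
    adj: list[list[int]] = [[] for _ in range(len(pixels))]
    for i, (r, c) in enumerate(pixels):
        for dr, dc in _NEIGHBOURS:
            j = index.get((r + dr, c + dc))
            if j is not None:
                adj[i].append(j)
    return adj


def local_orientation(pixels: np.ndarray, window: int = 7) -> np.ndarray:
    """Per-pixel chord orientation along the skeleton, degrees in [0, 180).

    Each pixel's orientation is the angle of the chord joining the two
    farthest-apart pixels among those reachable within ``window // 2``
    steps along the skeleton (geodesic ball).  On a simple branch this is
    the chord between the pixels half a window away in each direction
    (shorter near ends); at a branch point the deepest-reaching arms win,
    so the orientation follows the longest incident branches.  Ties are
    broken toward the smaller angle; isolated pixels are assigned 0.
    """
    pixels = np.asarray(pixels, dtype=int).reshape(-1, 2)
    n = len(pixels)
    if n == 0:
        return np.empty(0, dtype=float)
    half = max(window // 2, 1)
    adj = _build_adjacency(pixels)
    out = np.zeros(n, dtype=float)
    pts = [tuple(p) for p in pixels]
    for i in range(n):
        depth = {i: 0}
        frontier = [i]
        for d in range(1, half + 1):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in depth:
                        depth[v] = d
                        nxt.append(v)
            frontier = nxt
            if not frontier:
                break
        max_d = max(depth.values())
        if max_d == 0:
            out[i] = 0.0
            continue
        # candidate chord endpoints: the centre plus all deepest pixels
        cands = [i] + [j for j, d in depth.items() if d == max_d]
        best = None  # (-squared length, angle)
        for a in range(len(cands)):
            pa = pts[cands[a]]
            for b in range(a + 1, len(cands)):
                pb = pts[cands[b]]
                d2 = (pa[0] - pb[0]) ** 2 + (pa[1] - pb[1]) ** 2
                key = (-d2, _chord_angle(pa, pb))
                if best is None or key < best:
                    best = key
        out[i] = best[1]
    return out


def skeletonize(mask: TubuleMask, window: int = 7) -> Skeleton:
    """Topology-preserving thinning of the tubule mask to unit width.

    Isolated single pixels survive as length-1 elements.  Local chord
    orientations are attached to every skeleton pixel.
    """
    sk_mask = _sk_skeletonize(mask.mask)
    pixels = np.argwhere(sk_mask)
    orients = local_orientation(pixels, window=window)
    return Skeleton(pixels=pixels, orientations_deg=orients, mask=sk_mask)


def skeleton_length(sk: Skeleton, diagonal_correction: bool = False) -> float:
    """Skeleton length in pixels.

    Default is the plain pixel count (keeps length % <= area % exact).
    With ``diagonal_correction`` each diagonal link adds sqrt(2) - 1 to
    approximate geodesic length, for sensitivity analysis.
    """
    if not diagonal_correction or sk.length_px == 0:
        return float(sk.length_px)
    index = {tuple(p) for p in sk.pixels}
    n_diag = 0
    for r, c in sk.pixels:
        # count each diagonal edge once via two of the four diagonals
        if (r + 1, c + 1) in index:
            n_diag += 1
        if (r + 1, c - 1) in index:
            n_diag += 1
    return sk.length_px + (math.sqrt(2.0) - 1.0) * n_diag


def length_density(
    sk: Skeleton, cell_mask: np.ndarray, diagonal_correction: bool = False
) -> float:
    """Skeleton length normalised by cell area, in percent."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    n_cell = int(cell_mask.sum())
    if n_cell == 0:
        raise ValueError("empty cell mask")
    return 100.0 * skeleton_length(sk, diagonal_correction) / n_cell


def transverse_fraction(
    orientations_deg: np.ndarray, band: tuple = (60.0, 130.0)
) -> float | None:
    """Percent of skeleton pixels oriented within the transverse band.

    The band is inclusive at both ends; an empty skeleton yields ``None``
    (missing), never 0.
    """
    lo, hi = band
    if not (0.0 <= lo < hi <= 180.0):
        raise ValueError(f"invalid orientation band {band}")
    orientations_deg = np.asarray(orientations_deg, dtype=float)
    if orientations_deg.size == 0:
        return None
    inside = (orientations_deg >= lo) & (orientations_deg <= hi)
    return 100.0 * float(inside.sum()) / orientations_deg.size


def thickness_ratio(mask: TubuleMask, sk: Skeleton) -> float | None:
    """Mask area / skeleton length: mean tubule width in pixels.

    Missing (``None``) when the skeleton is empty.
    """
    if sk.length_px == 0:
        return None
    return mask.area_px / sk.length_px


def compute_cell_metrics(
    cell: CellImage,
    mask: TubuleMask,
    t_result: PowerResult | None = None,
    r_result: PowerResult | None = None,
    params: MorphometryParams | None = None,
) -> CellMetrics:
    """Assemble the per-cell outcome row from mask, skeleton and spectra."""
    params = params or MorphometryParams()
    sk = skeletonize(mask, window=params.orientation_window_px)
    return CellMetrics(
        cell_id=cell.cell_id,
        animal_id=cell.animal_id,
        group=cell.group_label,
        region=cell.region_label,
        area_pct=area_fraction(mask, cell.cell_mask),
        length_pct=length_density(
            sk, cell.cell_mask, diagonal_correction=params.diagonal_correction
        ),
        transverse_pct=transverse_fraction(
            sk.orientations_deg, band=params.transverse_band_deg
        ),
        thickness_ratio=thickness_ratio(mask, sk),
        t_power_au=t_result.power_au if t_result else np.nan,
        r_power_au=r_result.power_au if r_result else np.nan,
        t_peak_freq=t_result.peak_freq_per_um if t_result else np.nan,
        r_peak_freq=r_result.peak_freq_per_um if r_result else np.nan,
        t_fit_ok=t_result.fit_ok if t_result else False,
        r_fit_ok=r_result.fit_ok if r_result else False,
    )
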