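"""Core data containers shared across the pipeline.

The unit of analysis is a single cardiomyocyte crop (:class:`CellImage`):
a two-channel confocal image (WGA membrane/t-tubule labelling and RyR
immunolabelling) together with a binary cell mask and the pixel size.
Downstream stages attach a binary t-tubule mask (:class:`TubuleMask`),
a one-pixel-wide centerline (:class:`Skeleton`) and the per-cell outcome
metrics (:class:`CellMetrics`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Optional

import numpy as np

__all__ = [
    "CellImage",
    "QCReport",
    "TubuleMask",
    "Skeleton",
    "PowerResult",
    "CellMetrics",
]

QC_REASONS = ("curved", "inconsistent_labelling", "touches_edge", "low_contrast")

MASK_PROVENANCES = ("external_file", "baseline_segmenter", "simulator_truth")


@dataclass
class CellImage:
    """A single-cell two-channel confocal crop.

    Parameters
    ----------
    tubule_channel :
        WGA (membrane / t-tubule) intensity image, non-negative.
    ryr_channel :
        RyR immunolabelling intensity image, same shape.
    cell_mask :
        Boolean mask of the myocyte area, same shape.
    pixel_size_nm :
        Lateral pixel size in nanometres (85 nm for the reference
        acquisition settings).
    """

    tubule_channel: np.ndarray
    ryr_channel: np.ndarray
    cell_mask: np.ndarray
    pixel_size_nm: float = 85.0
    cell_id: str = "cell"
    animal_id: str = "animal"
    group_label: str = "group"
    region_label: str = "region"

    def __post_init__(self) -> None:
        self.tubule_channel = np.asarray(self.tubule_channel, dtype=float)
        self.ryr_channel = np.asarray(self.ryr_channel, dtype=float)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        if not (
            self.tubule_channel.shape
            == self.ryr_channel.shape
            == self.cell_mask.shape
        ):
            raise ValueError(
                "channel/mask shapes differ: "
                f"tubule {self.tubule_channel.shape}, "
                f"ryr {self.ryr_channel.shape}, mask {self.cell_mask.shape}"
            )
        if self.tubule_channel.ndim != 2:
            raise ValueError("CellImage holds single 2-D confocal planes")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if np.any(self.tubule_channel < 0) or np.any(self.ryr_channel < 0):
            raise ValueError("intensity channels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_mask.shape

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    def labels(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "animal_id": self.animal_id,
            "group": self.group_label,
            "region": self.region_label,
        }


@dataclass
class QCReport:
    """Outcome of the per-cell quality-control filter.

    ``passed`` is true exactly when ``reasons`` is empty; reasons are drawn
    from ``{curved, inconsistent_labelling, touches_edge, low_contrast}``.
    """

    cell_id: str
    reasons: list = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.reasons) - set(QC_REASONS)
        if bad:
            raise ValueError(f"unknown QC reasons: {sorted(bad)}")

    @property
    def passed(self) -> bool:
        return len(self.reasons) == 0


@dataclass
class TubuleMask:
    """Binary t-tubule mask aligned to a :class:`CellImage`.

    The foreground is always restricted to the parent cell mask; the
    constructor enforces the intersection.  ``provenance`` records whether
    the mask came from an external segmentation export, the built-in
    baseline segmenter, or the simulator's ground truth.
    """

    mask: np.ndarray
    provenance: str = "external_file"
    empty_warning: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.provenance not in MASK_PROVENANCES:
            raise ValueError(
                f"provenance must be one of {MASK_PROVENANCES}, got {self.provenance!r}"
            )

    @classmethod
    def from_cell(
        cls, mask: np.ndarray, cell: "CellImage", provenance: str
    ) -> "TubuleMask":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != cell.shape:
            raise ValueError(
                f"tubule mask shape {mask.shape} != cell shape {cell.shape}"
            )
        clipped = mask & cell.cell_mask
        return cls(
            mask=clipped,
            provenance=provenance,
            empty_warning=not clipped.any(),
        )

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class Skeleton:
    """One-pixel-wide centerline of a tubule mask with local orientations.

    ``pixels`` is an (N, 2) array of (row, col) coordinates;
    ``orientations_deg`` gives, per pixel, the local chord angle measured
    from the vertical (longitudinal) axis, folded into [0, 180).
    """

    pixels: np.ndarray
    orientations_deg: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)
        self.orientations_deg = np.asarray(self.orientations_deg, dtype=float)
        if len(self.pixels) != len(self.orientations_deg):
            raise ValueError("one orientation per skeleton pixel required")

    @property
    def length_px(self) -> int:
        return len(self.pixels)


@dataclass
class PowerResult:
    """First-harmonic regularity score from the spatial power spectrum.

    ``power_au`` is the fitted Gaussian peak height above the linear
    baseline, in dB of the normalised power spectrum.  ``fit_ok`` is false
    when the fit failed or found no positive peak, in which case
    ``power_au`` is 0 and the cell is flagged rather than dropped.
    """

    power_au: float
    peak_freq_per_um: float
    fit_ok: bool
    profile: np.ndarray
    freqs_per_um: np.ndarray
    peak_linear: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.power_au):
            raise ValueError("power_au must be finite")


@dataclass
class CellMetrics:
    """The six per-cell outcomes with study-design labels."""

    cell_id: str
    animal_id: str
    group: str
    region: str
    area_pct: float
    length_pct: float
    transverse_pct: Optional[float]
    thickness_ratio: Optional[float]
    t_power_au: float
    r_power_au: float
    t_peak_freq: float = np.nan
    r_peak_freq: float = np.nan
    t_fit_ok: bool = True
    r_fit_ok: bool = True

    def as_row(self) -> dict:
        return asdict(self)

    @staticmethod
    def columns() -> list:
        return [f.name for f in fields(CellMetrics)]
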