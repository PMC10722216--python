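"""Imaging-geometry sanity checks: lateral resolution and Nyquist sampling.

Confocal t-tubule imaging resolves structures down to roughly the Rayleigh
criterion 0.61 lambda / NA; with a 618 nm peak-emission fluorophore and a
1.4 NA objective this is about 270 nm, so an 85 nm pixel comfortably
satisfies Nyquist sampling (pixel <= resolution / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["OpticsSpec", "rayleigh_resolution", "nyquist_check"]

# Alternative lateral-resolution prefactors for confocal variants.
RESOLUTION_FACTORS = {"rayleigh": 0.61, "confocal": 0.51, "fwhm": 0.37}


@dataclass(frozen=True)
class OpticsSpec:
    """Acquisition optics: emission wavelength (nm), NA, pixel size (nm)."""

    emission_wavelength_nm: float = 618.0
    numerical_aperture: float = 1.4
    pixel_size_nm: float = 85.0

    def __post_init__(self) -> None:
        if self.emission_wavelength_nm <= 0:
            raise ValueError("emission wavelength must be positive")
        if not 0 < self.numerical_aperture <= 1.7:
            raise ValueError("numerical aperture must be in (0, 1.7]")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")


def rayleigh_resolution(spec: OpticsSpec, factor: str = "rayleigh") -> float:
    """Lateral optical resolution in nm (default Rayleigh, 0.61 lambda/NA)."""
    try:
        k = RESOLUTION_FACTORS[factor]
    except KeyError:
        raise ValueError(
            f"unknown resolution factor {factor!r}; "
            f"choose from {sorted(RESOLUTION_FACTORS)}"
        ) from None
    return k * spec.emission_wavelength_nm / spec.numerical_aperture


def nyquist_check(spec: OpticsSpec, factor: str = "rayleigh") -> tuple[bool, float]:
    """Whether the pixel size satisfies Nyquist sampling.

    Returns ``(passed, limiting_pixel_nm)`` where the limiting pixel size
    is half the lateral resolution; the boundary is inclusive.
    """
    limit = rayleigh_resolution(spec, factor=factor) / 2.0
    return spec.pixel_size_nm <= limit, limit
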