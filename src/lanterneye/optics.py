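"""Optical sensitivity of a camera-type fish eye.

Two standard photon-catch quantities are computed per photoreceptor:

* extended-source sensitivity (downwelling spacelight), in um^2 sr:

      S = (pi/4)^2 * (d / F)^2 * (1 - exp(-k l))

  where d is rod diameter (um), l outer-segment length (um), k the pigment
  absorption coefficient (um^-1) and F the F-number of the eye.  Under
  Matthiessen's ratio (focal length = 2.55 x lens radius) F = 1.275 for any
  fish eye, so S is independent of eye size.

* point-source sensitivity (a bioluminescent flash of E photons at range r),
  in photons absorbed:

      N = E * (A^2 / (16 r^2)) * exp(-alpha r) * (1 - exp(-k l))

  with lens diameter A and range r in metres and alpha the seawater
  attenuation coefficient (m^-1).  N scales with A^2: bigger eyes catch more
  flash photons.

The lens diameter stands in for the pupil aperture; aphakic gaps and tapeta,
which enlarge the effective aperture or path length in real eyes, are not
modelled.  S is a per-receptor quantity: true scene sensitivity is set by
the pool of rods converging on one ganglion cell (see
``summation_ratio``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EyeGeometry",
    "RodGeometry",
    "OpticalConstants",
    "SensitivityResult",
    "matthiessen_focal_length",
    "sensitivity_extended",
    "sensitivity_point",
    "linear_to_areal_density",
    "summation_ratio",
    "add_sensitivity_columns",
]

#: Matthiessen's ratio: focal length ~ 2.55 x lens radius in fish eyes
MATTHIESSEN_RATIO = 2.55


@dataclass(frozen=True)
class EyeGeometry:
    """Lens diameter A (mm), focal length f (mm) and F-number F = f/A."""

    lens_diameter: float
    focal_length: float
    f_number: float

    @classmethod
    def from_lens(cls, lens_diameter: float) -> "EyeGeometry":
        f, F = matthiessen_focal_length(lens_diameter)
        return cls(lens_diameter=lens_diameter, focal_length=f, f_number=F)


@dataclass(frozen=True)
class RodGeometry:
    """Rod dimensions in micrometres: diameter d, outer-segment length l,
    and inner-segment (ellipsoid) length."""

    diameter: float
    outer_segment_length: float
    inner_segment_length: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.outer_segment_length < 0 or self.inner_segment_length < 0:
            raise ValueError("rod dimensions must be positive (lengths may be zero)")
        if not (0.5 <= self.diameter <= 5.0):
            warnings.warn(
                f"rod diameter {self.diameter} um is outside the observed 0.5-5 um range",
                stacklevel=2,
            )


@dataclass(frozen=True)
class OpticalConstants:
    """Fixed physical constants of the sensitivity equations.

    k: pigment absorption coefficient, um^-1 (vertebrate average 0.035);
    E: photons per bioluminescent flash (1e10);
    r: source distance, m (1);
    alpha: seawater attenuation coefficient, m^-1 (0.05).
    """

    k: float = 0.035
    E: float = 1e10
    r: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if min(self.k, self.E, self.r, self.alpha) <= 0:
            raise ValueError("all optical constants must be positive")


@dataclass(frozen=True)
class SensitivityResult:
    """S in um^2 sr (extended source), N in photons (point source)."""

    S: float
    N: float


def matthiessen_focal_length(lens_diameter: float) -> tuple[float, float]:
    """Focal length and F-number from the lens diameter via Matthiessen's ratio.

    f = 2.55 x (A/2) = 1.275 A, so F = f/A = 1.275 regardless of lens size.
    """
    if lens_diameter <= 0:
        raise ValueError("lens diameter must be positive")
    f = MATTHIESSEN_RATIO * lens_diameter / 2.0
    return f, f / lens_diameter


def sensitivity_extended(
    rod: RodGeometry, constants: OpticalConstants = OpticalConstants(), f_number: float = 1.275
) -> float:
    """Extended-source (downwelling light) sensitivity, um^2 sr.

    S = (pi/4)^2 (d/F)^2 (1 - e^{-k l}); independent of lens size at fixed F.
    """
    if f_number <= 0:
        raise ValueError("F-number must be positive")
    absorb = 1.0 - math.exp(-constants.k * rod.outer_segment_length)
    return (math.pi / 4.0) ** 2 * (rod.diameter / f_number) ** 2 * absorb


def sensitivity_point(
    eye: EyeGeometry, rod: RodGeometry, constants: OpticalConstants = OpticalConstants()
) -> float:
    """Point-source (bioluminescent flash) sensitivity: photons absorbed.

    N = E (A^2 / 16 r^2) e^{-alpha r} (1 - e^{-k l}) with A, r in metres.
    """
    if constants.r <= 0:
        raise ValueError("source distance must be positive")
    if eye.lens_diameter < 0:
        raise ValueError("lens diameter must be non-negative")
    A_m = eye.lens_diameter / 1000.0  # mm -> m
    geom = A_m**2 / (16.0 * constants.r**2)
    absorb = 1.0 - math.exp(-constants.k * rod.outer_segment_length)
    return constants.E * geom * math.exp(-constants.alpha * constants.r) * absorb


def sensitivity(
    lens_diameter_mm: float,
    rod: RodGeometry,
    constants: OpticalConstants = OpticalConstants(),
) -> SensitivityResult:
    """Convenience wrapper computing both S and N for one eye."""
    eye = EyeGeometry.from_lens(lens_diameter_mm)
    return SensitivityResult(
        S=sensitivity_extended(rod, constants, eye.f_number),
        N=sensitivity_point(eye, rod, constants),
    )


def linear_to_areal_density(linear: float, packing: str = "square") -> float:
    """Convert a linear count (cells/mm along a section) to areal density.

    square packing -> linear^2; hexagonal -> (2/sqrt(3)) linear^2 (rods in
    wholemounts sit in a hexagonal array, 15.47% denser than square).
    """
    if linear <= 0:
        raise ValueError("linear density must be positive")
    if packing == "square":
        return linear**2
    if packing == "hexagonal":
        return (2.0 / math.sqrt(3.0)) * linear**2
    raise ValueError(f"unknown packing {packing!r}")


def summation_ratio(rod_density: float, ganglion_density: float) -> float:
    """Rod-to-ganglion-cell convergence ratio (rods pooling per ganglion cell)."""
    if rod_density <= 0 or ganglion_density <= 0:
        raise ValueError("densities must be positive")
    return rod_density / ganglion_density


def add_sensitivity_columns(
    traits: pd.DataFrame,
    constants: OpticalConstants = OpticalConstants(),
    lens_col: str = "lens_diameter_mm",
    rod_d_col: str = "rod_diameter_um",
    os_col: str = "os_length_um",
) -> pd.DataFrame:
    """Append S (um^2 sr) and N (photons) columns to a species trait table."""
    for col in (lens_col, rod_d_col, os_col):
        if col not in traits.columns:
            raise ValueError(f"trait table missing column {col!r}")
    out = traits.copy()
    S = []
    N = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # range warning handled per-row upstream
        for _, row in traits.iterrows():
            rod = RodGeometry(
                diameter=float(row[rod_d_col]), outer_segment_length=float(row[os_col])
            )
            res = sensitivity(float(row[lens_col]), rod, constants)
            S.append(res.S)
            N.append(res.N)
    out["S_um2_sr"] = S
    out["N_photons"] = N
    return out
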