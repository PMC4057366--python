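"""Optical-fractionator stereology for retinal wholemounts.

A flattened retina is treated as a single section (section sampling fraction
ssf = 1) with the photoreceptors in one layer (thickness sampling fraction
tsf = 1).  Rods are counted in small frames placed on a systematic grid with
a uniform random start, and the total rod number is estimated as

    N_total = sum(Q_i) * (1/ssf) * (1/asf) * (1/tsf)

where asf, the area sampling fraction, is the frame-to-grid area ratio.
Precision is summarised by the Schaeffer coefficient of error (CE), with
CE < 0.1 the conventional acceptability threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "SamplingDesign",
    "WholemountSample",
    "FractionatorEstimate",
    "area_sampling_fraction",
    "scheaffer_ce",
    "fractionator_total",
]

#: conversion from a um x um frame area to mm^2
_UM2_TO_MM2 = 1e-6


@dataclass(frozen=True)
class SamplingDesign:
    """Counting-frame and sampling-grid geometry, all lengths in micrometres.

    ``ssf`` and ``tsf`` default to 1: the wholemount is a single section and
    the rods form a single layer, so only the area fraction subsamples.
    """

    frame_w: float
    frame_h: float
    grid_dx: float
    grid_dy: float
    ssf: float = 1.0
    tsf: float = 1.0

    def __post_init__(self) -> None:
        for name in ("frame_w", "frame_h", "grid_dx", "grid_dy", "ssf", "tsf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.frame_w > self.grid_dx or self.frame_h > self.grid_dy:
            raise ValueError(
                "counting frame must fit inside one grid cell "
                f"(frame {self.frame_w}x{self.frame_h}, grid {self.grid_dx}x{self.grid_dy})"
            )

    @property
    def frame_area_mm2(self) -> float:
        return self.frame_w * self.frame_h * _UM2_TO_MM2

    @property
    def grid_area_mm2(self) -> float:
        return self.grid_dx * self.grid_dy * _UM2_TO_MM2


def area_sampling_fraction(design: SamplingDesign) -> float:
    """Frame area divided by grid-cell area (asf), unitless.

    For the published designs 1/asf is an exact integer (e.g. a 10x10 um
    frame on a 320x320 um grid gives asf = 1/1024), so the fractionator
    total on integer counts is exact integer arithmetic.
    """
    return (design.frame_w * design.frame_h) / (design.grid_dx * design.grid_dy)


def _inverse_asf_exact(design: SamplingDesign) -> Fraction:
    """1/asf as an exact rational when the geometry is integral."""
    num = Fraction(design.grid_dx).limit_denominator(10**6) * Fraction(
        design.grid_dy
    ).limit_denominator(10**6)
    den = Fraction(design.frame_w).limit_denominator(10**6) * Fraction(
        design.frame_h
    ).limit_denominator(10**6)
    return num / den


@dataclass
class WholemountSample:
    """Systematic sampling record: site coordinates (mm), per-site rod counts,
    the design used, and the wholemount outline."""

    sites: np.ndarray  # (n, 2) float, mm
    counts: np.ndarray  # (n,) non-negative int
    design: SamplingDesign
    outline: Polygon

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=float).reshape(-1, 2)
        self.counts = np.asarray(self.counts)
        if self.sites.shape[0] != self.counts.shape[0]:
            raise ValueError("sites and counts length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integers")
        self.counts = np.round(self.counts).astype(np.int64)

    @property
    def n_sites(self) -> int:
        return int(self.counts.shape[0])

    @property
    def site_densities(self) -> np.ndarray:
        """Per-site rod density in rods per mm^2."""
        return self.counts / self.design.frame_area_mm2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site_x_mm": self.sites[:, 0], "site_y_mm": self.sites[:, 1], "count": self.counts}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, design: SamplingDesign, outline: Polygon
    ) -> "WholemountSample":
        required = {"site_x_mm", "site_y_mm", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        return cls(
            sites=df[["site_x_mm", "site_y_mm"]].to_numpy(float),
            counts=df["count"].to_numpy(),
            design=design,
            outline=outline,
        )


@dataclass(frozen=True)
class FractionatorEstimate:
    """Fractionator summary for one wholemount, mirroring the usual report:
    total rod number, mean and peak site density (rods/mm^2), Schaeffer CE."""

    total: float
    mean_density: float
    peak_density: float
    peak_density_rounded: float  # nearest 10x10^3 mm^-2, the printed granularity
    ce: float
    n_sites: int

    def to_row(self) -> dict:
        return {
            "total_cells": self.total,
            "mean_density_per_mm2": self.mean_density,
            "peak_density_per_mm2": self.peak_density,
            "peak_density_per_mm2_rounded": self.peak_density_rounded,
            "schaeffer_ce": self.ce,
            "n_sites": self.n_sites,
        }


def scheaffer_ce(counts: Sequence[int]) -> float:
    """Schaeffer coefficient of error of the total-count estimate.

    CE = sqrt(s^2 / n) / qbar, with qbar the mean per-site count and s^2 the
    sample variance (n-1 denominator): the relative standard error of the
    mean count under simple random sampling.  Values below 0.1 are treated
    as acceptable precision.
    """
    q = np.asarray(counts, dtype=float)
    if q.ndim != 1 or q.size < 2:
        raise ValueError("need at least two site counts")
    qbar = q.mean()
    if qbar == 0:
        raise ValueError("CE undefined: all site counts are zero")
    s2 = q.var(ddof=1)
    return math.sqrt(s2 / q.size) / qbar


def fractionator_total(sample: WholemountSample) -> FractionatorEstimate:
    """Estimate total rod number and density summaries from a wholemount sample.

    The total is exact integer arithmetic whenever 1/asf is integral (true of
    all published frame/grid pairs).  Mean density is the unweighted mean of
    per-site densities; peak density is the maximum site density, also
    reported rounded to the nearest 10 x 10^3 mm^-2.
    """
    if sample.n_sites < 2:
        raise ValueError("fractionator estimate requires at least two sites")
    design = sample.design
    q_sum = int(sample.counts.sum())
    inv_asf = _inverse_asf_exact(design)
    total_frac = q_sum * inv_asf / (
        Fraction(design.ssf).limit_denominator(10**6)
        * Fraction(design.tsf).limit_denominator(10**6)
    )
    total = float(total_frac) if total_frac.denominator != 1 else int(total_frac)

    dens = sample.site_densities
    mean_density = float(dens.mean())
    peak_density = float(dens.max())
    peak_rounded = float(np.round(peak_density / 10_000.0) * 10_000.0)
    # CE is undefined for an all-zero record; the estimate itself (0) is still valid
    ce = scheaffer_ce(sample.counts) if q_sum > 0 else float("nan")
    return FractionatorEstimate(
        total=total,
        mean_density=mean_density,
        peak_density=peak_density,
        peak_density_rounded=peak_rounded,
        ce=ce,
        n_sites=sample.n_sites,
    )


def estimates_table(samples: dict[str, WholemountSample]) -> pd.DataFrame:
    """One-row-per-retina summary table (label, densities, total, CE)."""
    rows = []
    for label, sample in samples.items():
        row = {"retina": label}
        row.update(fractionator_total(sample).to_row())
        rows.append(row)
    return pd.DataFrame(rows)
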