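"""Synthetic retinal wholemounts with known ground truth.

Real wholemounts are flattened discs with radial relief cuts, carrying a
smooth rod-density field with a single specialisation: an *arch* (a partial
annulus of high density), a *ring* (full annulus), a *streak* (elongated
band) or none (uniform).  This module builds such fields analytically so the
true total rod count is known, and simulates the systematic counting process
that a stereology workstation performs on them: a grid with uniform random
start, a small counting frame per grid cell, Poisson-distributed rod counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

from .stereology import SamplingDesign, WholemountSample

__all__ = [
    "SpecializationSpec",
    "TrueRetina",
    "slit_disc_outline",
    "build_true_retina",
    "sample_wholemount",
    "subsample_region",
]

SpecializationKind = Literal["uniform", "arch", "ring", "streak"]


@dataclass(frozen=True)
class SpecializationSpec:
    """Geometry and amplitude of one high-density specialisation.

    The density profile is a Gaussian fall-off in distance ``s`` from the
    specialisation locus:

        density(p) = background + (peak - background) * exp(-s^2 / (2 width^2))

    ``radius_mm`` is the radius of the arch/ring locus, or the axis length of
    a streak; ``arc_span`` (degrees) is the angular extent of an arch, or the
    orientation span is unused for rings; ``angle_deg`` orients the arch
    midpoint / streak axis.
    """

    kind: SpecializationKind
    background_density: float  # rods / mm^2
    peak_density: float  # rods / mm^2
    center: tuple[float, float] = (0.0, 0.0)
    radius_mm: float = 1.0
    width_mm: float = 0.5
    arc_span: float = 180.0
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.background_density <= 0:
            raise ValueError("background_density must be > 0")
        if self.peak_density < self.background_density:
            raise ValueError("peak_density must be >= background_density")
        if self.width_mm <= 0:
            raise ValueError("width_mm must be > 0")
        if not (0 < self.arc_span <= 360):
            raise ValueError("arc_span must be in (0, 360] degrees")
        if self.kind not in ("uniform", "arch", "ring", "streak"):
            raise ValueError(f"unknown specialisation kind {self.kind!r}")


def _locus_geometry(spec: SpecializationSpec):
    """Shapely geometry of the specialisation locus (None for uniform)."""
    cx, cy = spec.center
    if spec.kind == "uniform":
        return None
    if spec.kind == "ring":
        return Point(cx, cy).buffer(spec.radius_mm, quad_segs=256).exterior
    if spec.kind == "arch":
        half = math.radians(spec.arc_span) / 2.0
        mid = math.radians(spec.angle_deg)
        theta = np.linspace(mid - half, mid + half, 257)
        pts = np.column_stack(
            [cx + spec.radius_mm * np.cos(theta), cy + spec.radius_mm * np.sin(theta)]
        )
        return LineString(pts)
    # streak: straight segment of length radius_mm centred on `center`
    ang = math.radians(spec.angle_deg)
    dx = 0.5 * spec.radius_mm * math.cos(ang)
    dy = 0.5 * spec.radius_mm * math.sin(ang)
    return LineString([(cx - dx, cy - dy), (cx + dx, cy + dy)])


@dataclass
class TrueRetina:
    """Ground-truth retina: outline polygon (mm), evaluable density field
    (rods/mm^2), and the exact expected total rod count."""

    outline: Polygon
    density: Callable[[np.ndarray, np.ndarray], np.ndarray]
    true_total: float
    spec: SpecializationSpec | None = None

    @property
    def area_mm2(self) -> float:
        return self.outline.area


def slit_disc_outline(
    radius_mm: float = 2.5,
    n_slits: int = 4,
    slit_depth_frac: float = 0.55,
    slit_width_deg: float = 8.0,
) -> Polygon:
    """Disc with radial slits removed: the shape of a flattened wholemount.

    Relief cuts let the hemispherical retina flatten; each cut removes a thin
    wedge reaching ``slit_depth_frac`` of the radius inward from the rim.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    disc = Point(0.0, 0.0).buffer(radius_mm, quad_segs=128)
    half_w = math.radians(slit_width_deg) / 2.0
    for i in range(n_slits):
        ang = 2 * math.pi * i / n_slits + math.pi / n_slits
        inner = radius_mm * (1.0 - slit_depth_frac)
        r_out = radius_mm * 1.01
        wedge = Polygon(
            [
                (inner * math.cos(ang), inner * math.sin(ang)),
                (r_out * math.cos(ang - half_w), r_out * math.sin(ang - half_w)),
                (r_out * math.cos(ang + half_w), r_out * math.sin(ang + half_w)),
            ]
        )
        disc = disc.difference(wedge)
    return disc


def build_true_retina(
    spec: SpecializationSpec, outline: Polygon, integration_cells: int = 400
) -> TrueRetina:
    """Attach a specialisation density field to an outline and integrate it.

    The true total is the numerical integral of the field over the outline,
    computed on a fine interior raster (cell-count along the longer bounding
    box axis given by ``integration_cells``) rescaled by the exact polygon
    area, which is exact for a uniform field and accurate to quadrature
    tolerance otherwise.
    """
    if not outline.is_valid or outline.area <= 0:
        raise ValueError("outline must be a simple polygon with positive area")
    locus = _locus_geometry(spec)
    bg = spec.background_density
    amp = spec.peak_density - spec.background_density
    two_w2 = 2.0 * spec.width_mm**2

    def density(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if locus is None or amp == 0:
            return np.full(np.broadcast(x, y).shape, float(bg))
        pts = shapely.points(np.column_stack([np.ravel(x), np.ravel(y)]))
        s = shapely.distance(pts, locus)
        vals = bg + amp * np.exp(-(s**2) / two_w2)
        return vals.reshape(np.broadcast(x, y).shape)

    true_total = _integrate_over_polygon(density, outline, integration_cells)
    return TrueRetina(outline=outline, density=density, true_total=true_total, spec=spec)


def _integrate_over_polygon(
    density: Callable, outline: Polygon, n_cells: int
) -> float:
    minx, miny, maxx, maxy = outline.bounds
    span = max(maxx - minx, maxy - miny)
    h = span / n_cells
    xs = np.arange(minx + h / 2, maxx, h)
    ys = np.arange(miny + h / 2, maxy, h)
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(outline, gx.ravel(), gy.ravel())
    if not inside.any():
        raise ValueError("degenerate outline: no interior integration points")
    vals = density(gx.ravel()[inside], gy.ravel()[inside])
    # mean interior density times exact polygon area: removes the raster's
    # area-discretisation error, leaving only the field-sampling error
    return float(vals.mean() * outline.area)


def sample_wholemount(
    retina: TrueRetina,
    design: SamplingDesign,
    seed: int | np.random.Generator,
    overdispersion: float = 1.0,
) -> WholemountSample:
    """Simulate systematic random sampling of a wholemount.

    A grid with steps (grid_dx, grid_dy) um is laid down with a uniform
    random start offset in [0, step)^2; sites whose frame centre falls inside
    the outline are kept; each site's rod count is Poisson with mean
    density(site) x frame area.  ``overdispersion`` > 1 switches to a
    negative-binomial count with the same mean and variance inflated by that
    factor.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    step_x = design.grid_dx / 1000.0  # um -> mm
    step_y = design.grid_dy / 1000.0
    minx, miny, maxx, maxy = retina.outline.bounds
    off_x = rng.uniform(0.0, step_x)
    off_y = rng.uniform(0.0, step_y)
    xs = np.arange(minx - step_x + off_x, maxx + step_x, step_x)
    ys = np.arange(miny - step_y + off_y, maxy + step_y, step_y)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = shapely.contains_xy(retina.outline, pts[:, 0], pts[:, 1])
    sites = pts[inside]
    if sites.shape[0] == 0:
        raise ValueError("sampling design places no sites inside the outline")
    mu = retina.density(sites[:, 0], sites[:, 1]) * design.frame_area_mm2
    if overdispersion < 1.0:
        raise ValueError("overdispersion must be >= 1")
    if overdispersion == 1.0:
        counts = rng.poisson(mu)
    else:
        # NB with variance = overdispersion * mu
        r = mu / (overdispersion - 1.0)
        p = 1.0 / overdispersion
        counts = rng.negative_binomial(r, p)
    return WholemountSample(sites=sites, counts=counts, design=design, outline=retina.outline)


def subsample_region(
    retina: TrueRetina,
    region: Polygon,
    finer_design: SamplingDesign,
    seed: int | np.random.Generator,
) -> WholemountSample:
    """Re-sample a sub-region (e.g. the high-density area) at a finer grid.

    Used when a coarse grid undershoots the true peak density; the finer
    sample's peak estimate moves toward the field maximum.
    """
    if not region.within(retina.outline.buffer(1e-9)):
        raise ValueError("sub-sampling region must lie within the retina outline")
    sub = TrueRetina(
        outline=region, density=retina.density, true_total=float("nan"), spec=retina.spec
    )
    sample = sample_wholemount(sub, finer_design, seed)
    return sample
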