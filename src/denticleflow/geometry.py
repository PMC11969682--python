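"""Parametric 2D denticle-row profiles, flow domains, and solid masks.

A "profile" is a simple closed polygon describing a row of tooth-like
denticles sitting on a thin baseline slab, the 2D cross-section of the
denticulated hook of a pteraspidiform oral plate.  Rostrally facing
denticles point their cusps upstream (toward -x); the caudal (null-model)
orientation is the mirror image.  Profiles are rasterized to boolean
solid masks on uniform or graded rectilinear grids for the flow solver.

Coordinate convention: x increases downstream, y = 0 is the domain floor,
all lengths in meters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Polygon

log = logging.getLogger(__name__)

ROSTRAL = "rostral"
CAUDAL = "caudal"

# Empirical-to-idealized model-length ratio (0.00235 m / 0.0025 m).
EMPIRICAL_LENGTH_RATIO = 0.94


class ParameterError(ValueError):
    """Invalid geometric parameters."""


class DomainError(ValueError):
    """Invalid computational-domain request."""


class ResolutionError(ValueError):
    """Grid spacing too coarse to resolve the denticles."""


@dataclass(frozen=True)
class DenticleParams:
    """Dimensions of an idealized denticle row.

    Defaults reproduce a ~20-denticle, 2.5 mm row of ~110 µm denticles with
    recurved cusps whose overhang closes the inter-denticle spaces into
    flask-shaped cavities.
    """

    n_denticles: int = 20
    pitch: float = 1.25e-4
    denticle_length: float = 1.10e-4
    denticle_height: float = 5.5e-5
    tip_overhang: float = 0.3
    baseline_thickness: float = 2.0e-5
    orientation: str = ROSTRAL
    perturbation_cv: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_denticles < 2:
            raise ParameterError("need at least 2 denticles")
        for name in ("pitch", "denticle_length", "denticle_height",
                     "baseline_thickness"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.denticle_length >= self.pitch:
            raise ParameterError("denticle base width must be < pitch")
        if not 0.0 <= self.tip_overhang < 1.0:
            raise ParameterError("tip_overhang must be in [0, 1)")
        if self.perturbation_cv < 0:
            raise ParameterError("perturbation_cv must be >= 0")
        if self.orientation not in (ROSTRAL, CAUDAL):
            raise ParameterError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class DenticleProfile:
    """Simple closed polygon of a denticle row (baseline included).

    ``vertices`` is an (n, 2) float array, counter-clockwise, not repeating
    the first vertex.  min y is 0 (the baseline sits on the domain floor).
    """

    vertices: np.ndarray
    model_length_L: float
    orientation: str
    provenance: str = "idealized"
    denticle_height: float = 5.5e-5
    baseline_thickness: float = 2.0e-5
    n_denticles: int = 0
    apex_x: np.ndarray = field(default_factory=lambda: np.empty(0))

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon().area

    @property
    def max_height(self) -> float:
        return float(self.vertices[:, 1].max())

    def validate(self) -> None:
        poly = self.polygon()
        if not poly.is_simple or not poly.is_valid:
            raise ParameterError("profile polygon is self-intersecting")
        ymin = float(self.vertices[:, 1].min())
        if abs(ymin) > 1e-12:
            raise ParameterError(f"profile min y is {ymin}, expected 0")
        ext = float(self.vertices[:, 0].max() - self.vertices[:, 0].min())
        if not math.isclose(ext, self.model_length_L, rel_tol=1e-9):
            raise ParameterError("model_length_L does not match x extent")


@dataclass(frozen=True)
class FlowDomain:
    """Rectangular computational domain around one profile.

    Margins follow the published sizing rule: at least 3 model lengths of
    clear water upstream and at least 20 downstream (a scaled-down mode may
    relax the downstream factor), with the height at least 20 times the
    baseline-sample midline height V1.
    """

    upstream_margin: float
    downstream_margin: float
    height: float
    total_length: float
    baseline_midline_height_V1: float


def _canonicalize(verts: np.ndarray) -> np.ndarray:
    """CCW orientation, starting from the lexicographically smallest vertex."""
    nxt = np.roll(verts, -1, axis=0)
    area2 = float((verts[:, 0] * nxt[:, 1] - nxt[:, 0] * verts[:, 1]).sum())
    if area2 < 0:
        verts = verts[::-1]
    start = np.lexsort((verts[:, 1], verts[:, 0]))[0]
    return np.roll(verts, -start, axis=0)


def _build_row(n: int, pitch: float, bases: np.ndarray, heights: np.ndarray,
               overhangs: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Vertex walk for a rostral row with per-denticle dimensions.

    Denticle i's upstream base corner sits at x_i = (pitch - b0) + o0*b0 + i*pitch
    (b0, o0 nominal values), so the foremost cusp never overhangs x = 0.
    Returns (vertices, apex x positions, baseline length).
    """
    b0, o0 = bases.mean(), (overhangs * bases).mean()
    x_front0 = (pitch - b0) + o0
    centers = x_front0 + b0 / 2 + pitch * np.arange(n)
    fronts = centers - bases / 2
    backs = centers + bases / 2
    apexes = fronts - overhangs * bases
    Lb = max(backs[-1], pitch * n + o0)

    pts: list[tuple[float, float]] = [(0.0, 0.0), (Lb, 0.0), (Lb, t)]
    for i in range(n - 1, -1, -1):
        pts.append((backs[i], t))
        pts.append((apexes[i], t + heights[i]))
        pts.append((fronts[i], t))
    pts.append((0.0, t))
    verts = np.array(pts, float)
    return verts, apexes, Lb


def make_idealized_profile(params: DenticleParams) -> DenticleProfile:
    """Row of identical asymmetric denticles on a flat baseline.

    The steep face (optionally overhanging, producing a recurved cusp and
    flask-shaped inter-denticle spaces) faces the cusp direction; rostral
    cusps point upstream (-x).
    """
    params.validate()
    n = params.n_denticles
    bases = np.full(n, params.denticle_length)
    heights = np.full(n, params.denticle_height)
    overhangs = np.full(n, params.tip_overhang)
    verts, apexes, _ = _build_row(n, params.pitch, bases, heights, overhangs,
                                  params.baseline_thickness)
    verts = _canonicalize(verts)
    L = float(verts[:, 0].max() - verts[:, 0].min())
    prof = DenticleProfile(
        vertices=verts, model_length_L=L, orientation=ROSTRAL,
        provenance="idealized", denticle_height=params.denticle_height,
        baseline_thickness=params.baseline_thickness, n_denticles=n,
        apex_x=apexes)
    prof.validate()
    if params.orientation == CAUDAL:
        prof = mirror_profile(prof)
    return prof


def make_empirical_profile(params: DenticleParams,
                           length_target: float | None = None) -> DenticleProfile:
    """Seeded shape-perturbed row emulating section-position variation.

    Per-denticle height, base width, and overhang are multiplied by
    independent lognormal factors with coefficient of variation
    ``perturbation_cv`` (mean 1).  x-dimensions are rescaled so the total
    length targets ``length_target`` (default 0.94 x the idealized length,
    the ratio of the two published model lengths).  Same seed, same profile.
    """
    params.validate()
    if params.perturbation_cv <= 0:
        prof = make_idealized_profile(params)
        return replace(prof, provenance="empirical_synthetic")

    n = params.n_denticles
    if length_target is None:
        length_target = EMPIRICAL_LENGTH_RATIO * params.n_denticles * params.pitch
    scale_x = length_target / (params.n_denticles * params.pitch)
    pitch = params.pitch * scale_x
    b_nom = params.denticle_length * scale_x
    t = params.baseline_thickness

    rng = np.random.default_rng(params.seed)
    sigma = math.sqrt(math.log(1.0 + params.perturbation_cv ** 2))
    factors = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=(3, n))

    shrink = 1.0
    for attempt in range(12):
        f = 1.0 + (factors - 1.0) * shrink
        f = np.clip(f, 0.35, 2.5)
        heights = params.denticle_height * f[0]
        bases = np.minimum(b_nom * f[1], 0.95 * pitch)
        overhangs = np.clip(params.tip_overhang * f[2], 0.0, 0.9)
        verts, apexes, _ = _build_row(n, pitch, bases, heights, overhangs, t)
        if Polygon(verts).is_simple and Polygon(verts).is_valid:
            break
        shrink *= 0.5
        log.warning("empirical profile self-intersected; clipping perturbation "
                    "factors (attempt %d)", attempt + 1)
    else:
        raise ParameterError("could not build a simple empirical profile")

    verts = _canonicalize(verts)
    L = float(verts[:, 0].max() - verts[:, 0].min())
    prof = DenticleProfile(
        vertices=verts, model_length_L=L, orientation=ROSTRAL,
        provenance="empirical_synthetic", denticle_height=params.denticle_height,
        baseline_thickness=t, n_denticles=n, apex_x=apexes)
    prof.validate()
    if params.orientation == CAUDAL:
        prof = mirror_profile(prof)
    return prof


def mirror_profile(profile: DenticleProfile) -> DenticleProfile:
    """Reflect about the profile midline and flip the orientation tag.

    Caudally facing models are, by construction, mirror images of the
    rostrally facing ones; mirroring is an involution and preserves area.
    """
    xmin = profile.vertices[:, 0].min()
    xmax = profile.vertices[:, 0].max()
    verts = profile.vertices.copy()
    verts[:, 0] = (xmin + xmax) - verts[:, 0]
    verts = _canonicalize(verts[::-1])
    flipped = CAUDAL if profile.orientation == ROSTRAL else ROSTRAL
    apex = np.sort((xmin + xmax) - profile.apex_x)
    return replace(profile, vertices=verts, orientation=flipped, apex_x=apex)


def build_domain(profile: DenticleProfile, height: float = 0.01,
                 upstream_factor: float = 3.0,
                 downstream_factor: float = 20.0) -> FlowDomain:
    """Domain with ``upstream_factor``*L upstream and ``downstream_factor``*L
    downstream of the model; default height 0.01 m, recording V1 = height/20."""
    if height <= profile.max_height:
        raise DomainError(
            f"domain height {height} must exceed profile height "
            f"{profile.max_height}")
    if upstream_factor < 3.0 or downstream_factor < 3.0:
        raise DomainError("margins below 3 model lengths are not supported")
    L = profile.model_length_L
    up, down = upstream_factor * L, downstream_factor * L
    return FlowDomain(upstream_margin=up, downstream_margin=down,
                      height=height, total_length=up + L + down,
                      baseline_midline_height_V1=height / 20.0)


@dataclass
class MaskGrid:
    """Rectilinear grid with a boolean solid mask (True = solid cell).

    ``spacing_h`` is the fine (near-body) spacing; ``dx``/``dy`` hold the
    per-cell spacings, identical to ``spacing_h`` on uniform grids.
    """

    spacing_h: float
    nx: int
    ny: int
    solid: np.ndarray
    origin: tuple[float, float]
    dx: np.ndarray
    dy: np.ndarray

    @property
    def xf(self) -> np.ndarray:
        """x cell-face coordinates, length nx+1."""
        return self.origin[0] + np.concatenate(([0.0], np.cumsum(self.dx)))

    @property
    def yf(self) -> np.ndarray:
        return self.origin[1] + np.concatenate(([0.0], np.cumsum(self.dy)))

    @property
    def xc(self) -> np.ndarray:
        f = self.xf
        return 0.5 * (f[:-1] + f[1:])

    @property
    def yc(self) -> np.ndarray:
        f = self.yf
        return 0.5 * (f[:-1] + f[1:])

    @property
    def uniform(self) -> bool:
        return (np.allclose(self.dx, self.dx[0]) and
                np.allclose(self.dy, self.dy[0]) and
                np.isclose(self.dx[0], self.dy[0]))

    def cell_areas(self) -> np.ndarray:
        return np.outer(self.dx, self.dy)

    def solid_area(self) -> float:
        return float((self.cell_areas() * self.solid).sum())


def _check_resolution(profile: DenticleProfile, spacing_h: float) -> None:
    hgt = profile.denticle_height
    if spacing_h > hgt / 2:
        raise ResolutionError(
            f"spacing {spacing_h} leaves fewer than 2 cells across a "
            f"{hgt}-tall denticle")
    if spacing_h > hgt / 4:
        log.warning("spacing %g resolves a denticle with < 4 cells; results "
                    "will be rough", spacing_h)


def _fill_solid(profile: DenticleProfile, x_offset: float,
                xc: np.ndarray, yc: np.ndarray) -> np.ndarray:
    poly = shapely.transform(profile.polygon(),
                             lambda a: a + np.array([x_offset, 0.0]))
    solid = np.zeros((len(xc), len(yc)), dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    isel = np.flatnonzero((xc >= minx) & (xc <= maxx))
    jsel = np.flatnonzero((yc >= miny) & (yc <= maxy))
    if isel.size == 0 or jsel.size == 0:
        return solid
    X, Y = np.meshgrid(xc[isel], yc[jsel], indexing="ij")
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    solid[np.ix_(isel, jsel)] = inside
    return solid


def rasterize(profile: DenticleProfile, domain: FlowDomain,
              spacing_h: float) -> MaskGrid:
    """Uniform-grid cell-center point-in-polygon rasterization.

    The profile is placed with its leading edge at the end of the upstream
    margin.  The rasterized solid area converges to the exact polygon area
    as h -> 0, with error bounded by h times the polygon perimeter.
    """
    _check_resolution(profile, spacing_h)
    nx = int(round(domain.total_length / spacing_h))
    ny = int(round(domain.height / spacing_h))
    dx = np.full(nx, spacing_h)
    dy = np.full(ny, spacing_h)
    xc = (np.arange(nx) + 0.5) * spacing_h
    yc = (np.arange(ny) + 0.5) * spacing_h
    x_off = domain.upstream_margin - profile.vertices[:, 0].min()
    solid = _fill_solid(profile, x_off, xc, yc)
    if not solid.any():
        raise ResolutionError("rasterization produced an empty solid mask")
    return MaskGrid(spacing_h=spacing_h, nx=nx, ny=ny, solid=solid,
                    origin=(0.0, 0.0), dx=dx, dy=dy)


def _graded_axis(fine_start: float, fine_end: float, total: float,
                 h: float, growth: float, max_cell: float) -> np.ndarray:
    """Cell spacings along one axis: uniform h on [fine_start, fine_end],
    geometrically growing toward 0 and toward ``total`` (capped), with the
    outermost cell of each coarse block stretched to close the interval."""

    def coarse(length: float) -> list[float]:
        out: list[float] = []
        d = h
        while sum(out) < length:
            d = min(d * growth, max_cell)
            out.append(d)
        out[-1] -= sum(out) - length  # close exactly
        if out[-1] < 0.25 * h and len(out) > 1:
            out[-2] += out[-1]
            out.pop()
        return out

    n_fine = max(1, int(round((fine_end - fine_start) / h)))
    # snap the fine window to a whole number of cells so the axis closes
    # on the domain boundary exactly
    fine_end = min(total, fine_start + n_fine * h)
    n_fine = int(round((fine_end - fine_start) / h))
    left = coarse(fine_start)[::-1] if fine_start > 1e-15 else []
    right = coarse(total - fine_end) if total - fine_end > 1e-15 else []
    spac = left + [h] * n_fine + right
    spac[-1] += total - sum(spac)
    return np.array(spac, float)


def rasterize_graded(profile: DenticleProfile, domain: FlowDomain,
                     spacing_h: float, growth: float = 1.12,
                     max_cell: float = 2.5e-4, pad: float = 2.0e-4,
                     y_fine_pad: float = 1.0e-4) -> MaskGrid:
    """Graded-grid rasterization: uniform ``spacing_h`` in a window around
    the model (padded by ``pad`` in x, ``y_fine_pad`` above the profile),
    geometric coarsening to ``max_cell`` in the far field.  Mirrors the
    published meshing strategy of a fine refinement region near the body
    inside a coarser domain mesh."""
    _check_resolution(profile, spacing_h)
    L = profile.model_length_L
    x0 = max(0.0, domain.upstream_margin - pad)
    x1 = min(domain.total_length, domain.upstream_margin + L + pad)
    dx = _graded_axis(x0, x1, domain.total_length, spacing_h, growth, max_cell)
    y1 = min(domain.height, profile.max_height + y_fine_pad)
    dy = _graded_axis(0.0, y1, domain.height, spacing_h, growth, max_cell)
    xf = np.concatenate(([0.0], np.cumsum(dx)))
    yf = np.concatenate(([0.0], np.cumsum(dy)))
    xc = 0.5 * (xf[:-1] + xf[1:])
    yc = 0.5 * (yf[:-1] + yf[1:])
    x_off = domain.upstream_margin - profile.vertices[:, 0].min()
    solid = _fill_solid(profile, x_off, xc, yc)
    if not solid.any():
        raise ResolutionError("rasterization produced an empty solid mask")
    return MaskGrid(spacing_h=spacing_h, nx=len(dx), ny=len(dy), solid=solid,
                    origin=(0.0, 0.0), dx=dx, dy=dy)
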