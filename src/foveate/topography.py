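"""Topographic maps of retinal ganglion-cell density and fovea geometry.

Counting-frame samples are interpolated onto a regular grid masked to the
wholemount outline; the fovea is located as the density peak; its position
is expressed in normalized Cartesian coordinates relative to the retinal
center, with negative x temporal, positive x nasal, positive y dorsal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import (
    LinearNDInterpolator,
    NearestNDInterpolator,
    RegularGridInterpolator,
)
from scipy.spatial import QhullError
from shapely.geometry import Point, Polygon
from skimage import measure
from sklearn.base import BaseEstimator


def circle_outline(radius: float, center=(0.0, 0.0), n_vertices: int = 256) -> Polygon:
    """Polygonal approximation of a circular wholemount outline."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )
    return Polygon(pts)


@dataclass
class DensityField:
    """Gridded ganglion-cell density surface masked to the retina outline.

    Attributes
    ----------
    grid : ndarray, shape (ny, nx)
        Densities in cells/mm^2; NaN outside the outline.
    origin : tuple of float
        (x, y) of grid[0, 0] in mm.
    step : float
        Grid spacing in mm (equal in x and y).
    outline : shapely Polygon
        Wholemount outline in mm.
    """

    grid: np.ndarray
    origin: tuple[float, float]
    step: float
    outline: Polygon

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if not self.outline.is_valid or not self.outline.is_simple:
            raise ValueError("outline polygon must be simple (non-self-intersecting)")
        unmasked = self.grid[np.isfinite(self.grid)]
        if unmasked.size and unmasked.min() < 0:
            raise ValueError("density values must be >= 0")

    @property
    def x_coords(self) -> np.ndarray:
        return self.origin[0] + self.step * np.arange(self.grid.shape[1])

    @property
    def y_coords(self) -> np.ndarray:
        return self.origin[1] + self.step * np.arange(self.grid.shape[0])

    def _interpolators(self):
        if not hasattr(self, "_lin"):
            self._lin = RegularGridInterpolator(
                (self.y_coords, self.x_coords),
                self.grid,
                method="linear",
                bounds_error=False,
                fill_value=np.nan,
            )
            mask = np.isfinite(self.grid)
            yy, xx = np.nonzero(mask)
            self._near = NearestNDInterpolator(
                np.column_stack([self.y_coords[yy], self.x_coords[xx]]),
                self.grid[mask],
            )
        return self._lin, self._near

    def value_at(self, x, y):
        """Bilinear density at points (mm); nearest-cell fallback inside the
        outline where bilinear interpolation touches masked cells."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        lin, near = self._interpolators()
        pts = np.column_stack([y, x])
        vals = lin(pts)
        bad = ~np.isfinite(vals)
        if bad.any():
            inside = np.array(
                [self.outline.buffer(1e-9).contains(Point(px, py))
                 for px, py in zip(x[bad], y[bad])]
            )
            fix = np.where(bad)[0][inside]
            if fix.size:
                vals[fix] = near(pts[fix])
        return vals if vals.size > 1 else float(vals[0])

    def disk_mean(self, x: float, y: float, radius: float) -> float:
        """Mean density over grid cells within ``radius`` of (x, y).

        Emulates recording an averaged cell density in a small neighborhood
        of a sampling point; masked cells are excluded.  Falls back to the
        interpolated point value when no cell center lies in the disk.
        """
        xs, ys = self.x_coords, self.y_coords
        reach = radius * (1 + 1e-9)
        ix = np.nonzero(np.abs(xs - x) <= reach)[0]
        iy = np.nonzero(np.abs(ys - y) <= reach)[0]
        if ix.size and iy.size:
            sub = self.grid[np.ix_(iy, ix)]
            dx = xs[ix][None, :] - x
            dy = ys[iy][:, None] - y
            # tolerant boundary test so cells exactly one step away are
            # included regardless of floating-point scale
            in_disk = (dx**2 + dy**2 <= radius**2 * (1 + 1e-9)) & np.isfinite(sub)
            if in_disk.any():
                return float(sub[in_disk].mean())
        return float(self.value_at(x, y))

    @property
    def range(self) -> tuple[float, float]:
        vals = self.grid[np.isfinite(self.grid)]
        return float(vals.min()), float(vals.max())

    def to_csv(self, grid_path, header_path=None):
        """Export the dense grid as CSV, plus a JSON header (origin, step)."""
        np.savetxt(grid_path, self.grid, delimiter=",")
        if header_path is not None:
            import json

            with open(header_path, "w") as fh:
                json.dump(
                    {
                        "origin": list(self.origin),
                        "step": self.step,
                        "shape": list(self.grid.shape),
                        "outline": list(self.outline.exterior.coords),
                    },
                    fh,
                )


class TopographicMap(BaseEstimator):
    """Interpolate counting-frame densities onto a masked regular grid.

    Sklearn-style estimator: ``fit`` consumes a set of counting frames and
    an outline, ``predict`` evaluates the fitted density surface at
    arbitrary points.  Site densities are computed as count / frame area;
    the default method interpolates linearly on a Delaunay triangulation of
    the sites (exact at the sites) with nearest-neighbor extrapolation out
    to the outline; negative interpolants are clipped to zero.

    Parameters
    ----------
    grid_step : float
        Grid spacing in mm.
    method : {"linear", "nearest"}
        Interpolation between sites.

    Attributes
    ----------
    field_ : DensityField
        The fitted gridded density surface.
    site_densities_ : ndarray
        count/area densities (cells/mm^2) at the fitted sites.
    """

    def __init__(self, grid_step: float = 0.1, method: str = "linear"):
        self.grid_step = grid_step
        self.method = method

    def fit(self, frames, outline: Polygon):
        sites = np.asarray(frames.sites, dtype=float)
        if sites.shape[0] < 4:
            raise ValueError("need at least 4 counting frames")
        dens = np.asarray(frames.densities, dtype=float)
        if np.all(frames.counts == 0):
            warnings.warn(
                "all counting-frame counts are zero; map is a flat zero field"
            )
        if self.method == "nearest":
            interp = NearestNDInterpolator(sites, dens)
            near = interp
        elif self.method == "linear":
            try:
                interp = LinearNDInterpolator(sites, dens)
            except QhullError as err:
                raise ValueError(
                    "counting-frame sites are degenerate (collinear); cannot "
                    "triangulate a topographic map"
                ) from err
            if interp.tri.simplices.size == 0:  # pragma: no cover
                raise ValueError("counting-frame sites are degenerate")
            near = NearestNDInterpolator(sites, dens)
        else:
            raise ValueError(f"unknown interpolation method {self.method!r}")

        minx, miny, maxx, maxy = outline.bounds
        xs = np.arange(minx, maxx + self.grid_step / 2, self.grid_step)
        ys = np.arange(miny, maxy + self.grid_step / 2, self.grid_step)
        xx, yy = np.meshgrid(xs, ys)
        vals = interp(xx, yy)
        if self.method == "linear":
            hole = ~np.isfinite(vals)
            if hole.any():
                vals[hole] = near(xx[hole], yy[hole])
        vals = np.clip(vals, 0.0, None)
        inside = _points_in_polygon(outline, xx, yy)
        vals[~inside] = np.nan
        self.site_densities_ = dens
        self._interp, self._near = interp, near
        self.field_ = DensityField(
            grid=vals, origin=(xs[0], ys[0]), step=self.grid_step, outline=outline
        )
        return self

    def predict(self, X):
        """Density at points (mm) from the site interpolant (exact at the
        fitted sites for the default linear method)."""
        X = np.asarray(X, dtype=float).reshape(-1, 2)
        vals = np.atleast_1d(np.asarray(self._interp(X[:, 0], X[:, 1]), dtype=float))
        hole = ~np.isfinite(vals)
        if hole.any():
            vals[hole] = self._near(X[hole, 0], X[hole, 1])
        return np.clip(vals, 0.0, None)


def _points_in_polygon(poly: Polygon, xx, yy):
    """Vectorized point-in-polygon test via matplotlib's path code."""
    from matplotlib.path import Path as MplPath

    path = MplPath(np.asarray(poly.exterior.coords))
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    return path.contains_points(pts, radius=1e-9).reshape(xx.shape)


def build_topographic_map(
    frames, outline: Polygon, grid_step: float = 0.1, method: str = "linear"
) -> DensityField:
    """Functional wrapper: counting frames + outline -> DensityField."""
    return TopographicMap(grid_step=grid_step, method=method).fit(frames, outline).field_


def isodensity_contours(field: DensityField, levels) -> dict:
    """Marching-squares isodensity contours of the masked grid.

    Parameters
    ----------
    levels : sequence of float
        Strictly increasing density levels.  A level above the field's
        maximum yields an empty contour list; a level below the minimum
        encloses the entire retina, so the outline itself is returned as
        the contour.  Neither is an error.

    Returns
    -------
    dict mapping level -> list of (n, 2) polyline arrays in mm coordinates.
    """
    levels = list(levels)
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly increasing")
    lo, hi = field.range
    out = {}
    for lev in levels:
        if lev > hi:
            out[lev] = []
            continue
        if lev < lo:
            out[lev] = [np.asarray(field.outline.exterior.coords)]
            continue
        polylines = measure.find_contours(field.grid, lev)
        out[lev] = [
            np.column_stack(
                [
                    field.origin[0] + c[:, 1] * field.step,
                    field.origin[1] + c[:, 0] * field.step,
                ]
            )
            for c in polylines
        ]
    return out


def locate_fovea(
    field: DensityField, smooth_mm: float = 0.0
) -> tuple[float, float]:
    """Locate the fovea as the global density maximum of the map (mm).

    Ties (a plateau of equal maximal cells) are broken by returning the
    centroid of the largest maximal-density connected region.  A flat
    field has no unique fovea and is rejected.

    Parameters
    ----------
    smooth_mm : float
        If > 0, the peak is sought on a disk-mean-smoothed copy of the
        grid (disk radius in mm).  On maps interpolated from noisy
        counting frames the raw argmax rides on single-site noise;
        smoothing at roughly the site spacing makes the located peak
        track the underlying density summit instead.
    """
    grid = field.grid
    if smooth_mm > 0:
        from scipy import ndimage

        r = max(int(round(smooth_mm / field.step)), 1)
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        disk = (xx**2 + yy**2 <= r**2).astype(float)
        finite = np.isfinite(grid)
        num = ndimage.convolve(
            np.where(finite, grid, 0.0), disk, mode="constant"
        )
        den = ndimage.convolve(finite.astype(float), disk, mode="constant")
        with np.errstate(invalid="ignore"):
            grid = np.where(finite, num / den, np.nan)
        field = DensityField(
            grid=grid, origin=field.origin, step=field.step,
            outline=field.outline,
        )
    lo, hi = field.range
    if hi - lo <= 1e-12 * max(hi, 1.0):
        raise ValueError("no unique fovea: density field is flat")
    at_max = np.isfinite(field.grid) & (field.grid >= hi * (1 - 1e-12))
    labels = measure.label(at_max, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    region = labels == sizes.argmax()
    iy, ix = np.nonzero(region)
    return (
        float(field.origin[0] + ix.mean() * field.step),
        float(field.origin[1] + iy.mean() * field.step),
    )


@dataclass(frozen=True)
class FoveaPosition:
    """Normalized fovea coordinates relative to the retinal center.

    Negative x is temporal, positive x nasal; positive y dorsal, negative
    y ventral — the convention under which the average avian fovea sits
    dorso-temporally (x < 0, y > 0).  Both coordinates are dimensionless
    fractions of the equal-area circle radius of the outline.
    """

    x: float
    y: float
    species: str = ""
    eye_side: str = "right"

    def __post_init__(self):
        if self.x**2 + self.y**2 >= 1.0:
            raise ValueError(
                f"normalized fovea position ({self.x:.3f}, {self.y:.3f}) "
                "falls outside the unit disk"
            )


def normalize_fovea_position(
    fovea_mm: tuple[float, float],
    outline: Polygon,
    eye_side: str = "right",
) -> FoveaPosition:
    """Express a fovea position relative to the retinal center.

    The retinal center is the outline centroid and the normalization
    radius the radius of the circle with the outline's area; the fovea
    offset from the center is divided by that radius.  For left eyes the
    horizontal axis is mirrored so temporal is negative for both sides —
    right and left eyes of one bird then map to identical coordinates.
    """
    if eye_side not in ("left", "right"):
        raise ValueError("eye_side must be 'left' or 'right'")
    pt = Point(fovea_mm)
    if not outline.buffer(1e-9).contains(pt):
        raise ValueError(f"fovea {fovea_mm} lies outside the retina outline")
    c = outline.centroid
    radius = np.sqrt(outline.area / np.pi)
    x = (fovea_mm[0] - c.x) / radius
    y = (fovea_mm[1] - c.y) / radius
    if eye_side == "left":
        x = -x
    return FoveaPosition(x=x, y=y, eye_side=eye_side)


def t_confidence_interval(mean: float, se: float, n: int, alpha: float = 0.05):
    """Two-sided t-based confidence interval from a mean, SE, and n."""
    tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1)
    return mean - tcrit * se, mean + tcrit * se


@dataclass(frozen=True)
class PositionSummary:
    """Across-species summary of one normalized fovea coordinate axis."""

    mean: float
    se: float
    ci_low: float
    ci_high: float
    n: int


def mean_position_with_ci(positions, alpha: float = 0.05) -> dict:
    """Species-mean fovea position with t-based confidence intervals.

    Parameters
    ----------
    positions : list of FoveaPosition
        One species-averaged position per species; duplicate species
        labels are rejected.
    alpha : float
        1 - confidence level (0.05 for 95% CIs).

    Returns
    -------
    dict with keys ``"x"`` and ``"y"`` mapping to PositionSummary.
    """
    if len(positions) < 2:
        raise ValueError("need at least 2 species")
    labels = [p.species for p in positions]
    if any(labels) and len(set(labels)) != len(labels):
        dupes = sorted({s for s in labels if labels.count(s) > 1})
        raise ValueError(f"duplicate species labels: {dupes}")
    n = len(positions)
    out = {}
    for axis in ("x", "y"):
        vals = np.array([getattr(p, axis) for p in positions], dtype=float)
        mean = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(n)
        lo, hi = t_confidence_interval(mean, se, n, alpha)
        out[axis] = PositionSummary(
            mean=float(mean), se=float(se), ci_low=float(lo), ci_high=float(hi), n=n
        )
    return out
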