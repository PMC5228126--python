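"""Periphery-to-fovea transects and density-gradient slopes.

A transect runs along one of the four retinal axes (nasal, temporal,
dorsal, ventral) from the retinal margin to the fovea.  Density is sampled
at equally spaced points (averaged over a small disk around each point),
distance is normalized so 0 is the margin and 1 the fovea, density is
expressed in 10^3 cells/mm^2, and the slope of the ordinary least-squares
trend line is the proxy for how pronounced the periphery-to-fovea density
increase is.  With these units the normalized slope is independent of
retina size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .topography import DensityField

AXES = ("nasal", "temporal", "dorsal", "ventral")
# Ray directions on the map plane (+x nasal, +y dorsal).
_AXIS_DIRECTIONS = {
    "nasal": (1.0, 0.0),
    "temporal": (-1.0, 0.0),
    "dorsal": (0.0, 1.0),
    "ventral": (0.0, -1.0),
}


@dataclass(frozen=True)
class Transect:
    """One straight margin-to-fovea segment along a retinal axis."""

    axis: str
    margin_xy: tuple[float, float]
    fovea_xy: tuple[float, float]

    @property
    def length(self) -> float:
        return float(np.hypot(
            self.fovea_xy[0] - self.margin_xy[0],
            self.fovea_xy[1] - self.margin_xy[1],
        ))


@dataclass
class TransectProfile:
    """Density samples along one transect.

    ``distances`` are normalized (0 = margin, 1 = fovea) and strictly
    increasing; ``densities`` are in 10^3 cells/mm^2.
    """

    axis: str
    distances: np.ndarray
    densities: np.ndarray

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.distances.size < 3:
            raise ValueError("a transect profile needs at least 3 samples")
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be strictly increasing")
        if self.distances[0] < 0 or self.distances[-1] > 1:
            raise ValueError("distances must lie in [0, 1]")
        if np.any(self.densities < 0):
            raise ValueError("densities must be >= 0")


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS trend-line fit of density on normalized transect distance.

    ``slope`` is in 10^3 cells/mm^2 per unit normalized distance — the
    retinal-configuration proxy: larger means a more pronounced
    periphery-to-fovea density increase.
    """

    axis: str
    slope: float
    intercept: float
    r2: float
    species: str = ""
    flat: bool = False


def lay_transects(field: DensityField, fovea_mm: tuple[float, float]) -> dict:
    """Cast the four axis rays from the fovea to the outline.

    Returns a dict axis -> Transect whose margin endpoint is the
    intersection of the axis ray with the outline; every transect passes
    through the fovea (horizontal rays give nasal/temporal, vertical rays
    dorsal/ventral).
    """
    fx, fy = fovea_mm
    pt = Point(fx, fy)
    if not field.outline.contains(pt):
        raise ValueError(
            "fovea must lie strictly inside the retina outline to anchor "
            "transects"
        )
    minx, miny, maxx, maxy = field.outline.bounds
    reach = 2 * max(maxx - minx, maxy - miny)
    out = {}
    for axis, (ux, uy) in _AXIS_DIRECTIONS.items():
        far = (fx + reach * ux, fy + reach * uy)
        hit = LineString([(fx, fy), far]).intersection(field.outline.exterior)
        if hit.is_empty:
            raise ValueError(f"{axis} ray does not reach the outline")
        pts = [hit] if hit.geom_type == "Point" else list(hit.geoms)
        margin = max(pts, key=lambda p: (p.x - fx) * ux + (p.y - fy) * uy)
        out[axis] = Transect(
            axis=axis, margin_xy=(margin.x, margin.y), fovea_xy=(fx, fy)
        )
    return out


def sample_transect(
    field: DensityField, transect: Transect, n_points: int = 10
) -> TransectProfile:
    """Sample density at equally spaced points from margin to fovea.

    The recorded density at each point is the field value averaged over a
    disk of radius one grid step around the point; points falling in
    masked regions are dropped with a warning.  Densities are converted to
    10^3 cells/mm^2 and distances normalized to [0, 1].
    """
    if n_points < 3:
        raise ValueError("need n_points >= 3")
    t = np.linspace(0.0, 1.0, n_points)
    mx, my = transect.margin_xy
    fx, fy = transect.fovea_xy
    xs = mx + t * (fx - mx)
    ys = my + t * (fy - my)
    dens = np.array(
        [field.disk_mean(x, y, radius=field.step) for x, y in zip(xs, ys)]
    )
    keep = np.isfinite(dens)
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} of {n_points} transect samples fell in masked "
            f"regions on the {transect.axis} axis and were dropped"
        )
    if keep.sum() < 3:
        raise ValueError(
            f"fewer than 3 valid samples survive on the {transect.axis} transect"
        )
    return TransectProfile(
        axis=transect.axis, distances=t[keep], densities=dens[keep] / 1000.0
    )


def fit_gradient_slope(profile: TransectProfile, species: str = "") -> SlopeEstimate:
    """OLS fit of density (10^3 cells/mm^2) on normalized distance."""
    x, y = profile.distances, profile.densities
    if np.ptp(x) == 0:
        raise ValueError("zero variance in transect distances")
    xc = x - x.mean()
    slope = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    intercept = float(y.mean() - slope * x.mean())
    ss_tot = float(np.dot(y - y.mean(), y - y.mean()))
    flat = ss_tot == 0.0
    if flat:
        r2 = 0.0
    else:
        resid = y - (intercept + slope * x)
        r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot
    return SlopeEstimate(
        axis=profile.axis,
        slope=slope,
        intercept=intercept,
        r2=max(0.0, min(1.0, r2)),
        species=species,
        flat=flat,
    )


def overall_slope(estimates) -> SlopeEstimate:
    """Arithmetic mean of the four per-axis slopes ("overall" proxy)."""
    by_axis = {e.axis: e for e in estimates}
    missing = [a for a in AXES if a not in by_axis]
    if missing:
        raise ValueError(f"missing axis slope estimates: {missing}")
    if len(estimates) != 4:
        raise ValueError("expected exactly one estimate per axis")
    species = {e.species for e in estimates}
    return SlopeEstimate(
        axis="overall",
        slope=float(np.mean([by_axis[a].slope for a in AXES])),
        intercept=float(np.mean([by_axis[a].intercept for a in AXES])),
        r2=float(np.mean([by_axis[a].r2 for a in AXES])),
        species=species.pop() if len(species) == 1 else "",
    )


def slopes_for_field(
    field: DensityField,
    fovea_mm: tuple[float, float],
    n_points: int = 10,
    species: str = "",
) -> dict:
    """Convenience: all four axis slopes plus the overall mean for one map."""
    transects = lay_transects(field, fovea_mm)
    ests = [
        fit_gradient_slope(sample_transect(field, transects[a], n_points), species)
        for a in AXES
    ]
    out = {e.axis: e for e in ests}
    out["overall"] = overall_slope(ests)
    return out


def slope_table(per_species_slopes: dict) -> pd.DataFrame:
    """Species x {axes + overall} slope DataFrame from nested dicts."""
    rows = {
        sp: {axis: est.slope for axis, est in slopes.items()}
        for sp, slopes in per_species_slopes.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")[list(AXES) + ["overall"]]
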