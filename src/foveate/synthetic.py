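"""Synthetic wholemount retinas, counting-frame samples, trees, and traits.

Every downstream stage of the package (topographic maps, fovea geometry,
transect slopes, PGLS) is exercised against data generated here with known
ground truth: a circular wholemount carrying a single off-center foveal
density peak, stereology-style counting-frame samples with Poisson noise,
and species traits evolved on a phylogeny under Brownian motion with
Pagel's lambda structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import dendropy
from shapely.geometry import Point

from .topography import DensityField, circle_outline

AXES = ("nasal", "temporal", "dorsal", "ventral")


@dataclass(frozen=True)
class RetinaSpec:
    """Parameters of one synthetic single-foveate wholemount.

    The density surface rises from ``base_density`` at the retinal margin to
    ``peak_density`` at the fovea.  Along the ray from the fovea to the
    margin through any point, the normalized fovea-to-margin distance
    ``d`` in [0, 1] maps to density ``base + (peak - base) * (1 - d)**s``,
    with the shape exponent ``s`` taken from the quadrant (nasal, temporal,
    dorsal, or ventral, split by the two meridians through the fovea)
    containing the point.  ``s = 1`` gives a linear (smooth) fall-off;
    larger ``s`` concentrates high density near the fovea (steep pattern).

    Parameters
    ----------
    radius : float
        Wholemount radius in mm.
    fovea_xy : tuple of float
        Fovea position normalized by the radius; each component in (-1, 1)
        and strictly inside the unit disk.  Positive x is nasal, positive y
        dorsal.
    base_density, peak_density : float
        Ganglion-cell densities (cells/mm^2) at the margin and the fovea.
    quadrant_steepness : dict
        Shape exponent per axis, keys ``nasal/temporal/dorsal/ventral``,
        all > 0.
    noise_cv : float
        Coefficient of variation of multiplicative lognormal noise applied
        to the density surface (0 = noiseless).
    seed : int
        RNG seed for the noise draw.
    """

    radius: float = 6.0
    fovea_xy: tuple[float, float] = (-0.145, 0.057)
    base_density: float = 500.0
    peak_density: float = 4000.0
    quadrant_steepness: dict = dc_field(
        default_factory=lambda: {a: 1.0 for a in AXES}
    )
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if not (0 < self.base_density <= self.peak_density):
            raise ValueError(
                "require peak_density >= base_density > 0, got "
                f"base={self.base_density}, peak={self.peak_density}"
            )
        fx, fy = self.fovea_xy
        if fx * fx + fy * fy >= 1.0:
            raise ValueError(
                f"fovea_xy {self.fovea_xy} lies outside the unit disk: the "
                "fovea must be strictly inside the retina"
            )
        missing = [a for a in AXES if a not in self.quadrant_steepness]
        if missing:
            raise ValueError(f"quadrant_steepness missing axes: {missing}")
        if any(self.quadrant_steepness[a] <= 0 for a in AXES):
            raise ValueError("quadrant_steepness exponents must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @property
    def fovea_mm(self) -> tuple[float, float]:
        return (self.fovea_xy[0] * self.radius, self.fovea_xy[1] * self.radius)


def _quadrant_steepness_array(spec: RetinaSpec, dx, dy):
    """Shape exponent at each point, by the quadrant relative to the fovea.

    Quadrants are delimited by the two diagonal meridians through the
    fovea: points with |dx| >= |dy| belong to the horizontal (nasal or
    temporal) quadrants, the rest to the vertical (dorsal or ventral) ones.
    """
    s = np.empty(np.broadcast(dx, dy).shape, dtype=float)
    horiz = np.abs(dx) >= np.abs(dy)
    s[horiz & (dx >= 0)] = spec.quadrant_steepness["nasal"]
    s[horiz & (dx < 0)] = spec.quadrant_steepness["temporal"]
    s[~horiz & (dy > 0)] = spec.quadrant_steepness["dorsal"]
    s[~horiz & (dy <= 0)] = spec.quadrant_steepness["ventral"]
    return s


def density_at(spec: RetinaSpec, x, y):
    """Noiseless ground-truth density (cells/mm^2) at points (x, y) in mm.

    Points outside the retina return NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fx, fy = spec.fovea_mm
    dx, dy = x - fx, y - fy
    r = np.hypot(dx, dy)
    # Distance from the fovea to the circular margin along each ray:
    # solve |f + t*u| = R for t >= 0 with unit direction u.
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, dx / r, 1.0)
        uy = np.where(r > 0, dy / r, 0.0)
    b = fx * ux + fy * uy
    t_max = -b + np.sqrt(b * b + (spec.radius**2 - (fx * fx + fy * fy)))
    d_norm = np.clip(r / t_max, 0.0, 1.0)
    s = _quadrant_steepness_array(spec, dx, dy)
    dens = spec.base_density + (spec.peak_density - spec.base_density) * (
        1.0 - d_norm
    ) ** s
    inside = np.hypot(x, y) <= spec.radius * (1 + 1e-12)
    return np.where(inside, dens, np.nan)


def generate_density_field(spec: RetinaSpec, grid_step: float) -> DensityField:
    """Evaluate the synthetic density surface on a regular grid.

    Parameters
    ----------
    spec : RetinaSpec
    grid_step : float
        Grid spacing in mm; must resolve the retina (< radius / 10).

    Returns
    -------
    DensityField
        Grid masked (NaN) outside the circular outline.  If
        ``spec.noise_cv > 0``, multiplicative lognormal noise with that CV
        (unit mean) has been applied to the surface.
    """
    if grid_step >= spec.radius / 10:
        raise ValueError(
            f"grid_step {grid_step} too coarse for radius {spec.radius}; "
            "need grid_step < radius/10"
        )
    n = int(np.floor(spec.radius / grid_step))
    coords = np.arange(-n, n + 1) * grid_step
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    grid = density_at(spec, xx, yy)
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma2 = np.log1p(spec.noise_cv**2)
        noise = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), size=grid.shape)
        grid = grid * noise
    outline = circle_outline(spec.radius, center=(0.0, 0.0))
    return DensityField(
        grid=grid, origin=(coords[0], coords[0]), step=grid_step, outline=outline
    )


@dataclass
class CountingFrameSet:
    """Stereology-style counting-frame samples across one wholemount.

    Attributes
    ----------
    sites : ndarray, shape (n, 2)
        Site coordinates in mm on the wholemount plane.
    frame_side : float
        Side length of the square counting frame in micrometers.
    counts : ndarray of int
        Ganglion cells counted at each site, summed over its frames.
    frames_per_site : int
        Number of counting frames pooled per site; the density estimate at
        a site is count / (frames_per_site x frame area), the usual
        stereological pooling that keeps the tally per site large enough
        for a stable estimate.
    """

    sites: np.ndarray
    frame_side: float
    counts: np.ndarray
    frames_per_site: int = 1

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=float).reshape(-1, 2)
        self.counts = np.asarray(self.counts)
        if self.frame_side <= 0:
            raise ValueError("frame_side must be > 0")
        if self.frames_per_site < 1:
            raise ValueError("frames_per_site must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def frame_area_mm2(self) -> float:
        """Single-frame area in mm^2 (side is given in µm)."""
        return (self.frame_side / 1000.0) ** 2

    @property
    def sampled_area_mm2(self) -> float:
        """Total counted area per site in mm^2."""
        return self.frame_area_mm2 * self.frames_per_site

    @property
    def densities(self) -> np.ndarray:
        """Empirical density estimate count/area (cells/mm^2) per site."""
        return self.counts / self.sampled_area_mm2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_mm": self.sites[:, 0],
                "y_mm": self.sites[:, 1],
                "frame_side_um": self.frame_side,
                "frames_per_site": self.frames_per_site,
                "count": self.counts,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountingFrameSet":
        side = float(df["frame_side_um"].iloc[0])
        fps = int(df["frames_per_site"].iloc[0]) if "frames_per_site" in df else 1
        return cls(
            sites=df[["x_mm", "y_mm"]].to_numpy(),
            frame_side=side,
            counts=df["count"].to_numpy(),
            frames_per_site=fps,
        )


def sample_counting_frames(
    field: DensityField,
    n_sites: int,
    frame_side: float = 50.0,
    seed: int | None = 0,
    layout: str = "uniform",
    frames_per_site: int = 1,
) -> CountingFrameSet:
    """Draw counting sites inside the outline and Poisson cell counts.

    Each site's count is Poisson with mean ``local density x counted
    area``, the stereological sampling model: a frame of side 50 µm covers
    0.0025 mm^2, so density 4000 cells/mm^2 yields 10 cells per frame in
    expectation; pooling several frames per site scales the mean (and the
    counted area) accordingly.

    Parameters
    ----------
    field : DensityField
    n_sites : int
        Number of sites (>= 4).
    frame_side : float
        Frame side length in µm (default 50).
    seed : int or None
        RNG seed; fixed seed gives an identical CountingFrameSet.
    layout : {"uniform", "lattice"}
        Uniform-random sites, or a regular lattice clipped to the outline
        (the lattice is sized to yield at least ``n_sites`` sites).
    frames_per_site : int
        Counting frames pooled at each site (default 1).
    """
    if n_sites < 4:
        raise ValueError("need n_sites >= 4")
    if frame_side <= 0:
        raise ValueError("frame_side must be > 0")
    minx, miny, maxx, maxy = field.outline.bounds
    extent = min(maxx - minx, maxy - miny)
    if frame_side / 1000.0 > extent:
        raise ValueError(
            f"counting frame side {frame_side} um exceeds the retina extent "
            f"({extent:.3f} mm)"
        )
    rng = np.random.default_rng(seed)
    if layout == "uniform":
        sites = []
        while len(sites) < n_sites:
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if field.outline.contains(Point(x, y)):
                sites.append((x, y))
        sites = np.array(sites)
    elif layout == "lattice":
        k = int(np.ceil(np.sqrt(n_sites)))
        while True:
            xs = np.linspace(minx, maxx, k + 2)[1:-1]
            ys = np.linspace(miny, maxy, k + 2)[1:-1]
            xx, yy = np.meshgrid(xs, ys)
            pts = np.column_stack([xx.ravel(), yy.ravel()])
            keep = np.array(
                [field.outline.contains(Point(x, y)) for x, y in pts]
            )
            if keep.sum() >= n_sites:
                sites = pts[keep]
                break
            k += 1
    else:
        raise ValueError(f"unknown layout {layout!r}")
    dens = field.value_at(sites[:, 0], sites[:, 1])
    dens = np.nan_to_num(dens, nan=0.0)
    area = (frame_side / 1000.0) ** 2 * frames_per_site
    counts = rng.poisson(np.clip(dens, 0, None) * area)
    return CountingFrameSet(
        sites=sites, frame_side=frame_side, counts=counts,
        frames_per_site=frames_per_site,
    )


# ---------------------------------------------------------------------------
# Phylogenies and trait evolution


def random_tree(n_tips: int, seed: int | None = 0) -> dendropy.Tree:
    """Random ultrametric coalescent-style tree with ``n_tips`` labelled tips.

    Lineages are merged pairwise at random with exponential waiting times
    (rate scaled by the number of open lineages), then node depths are
    normalized so the root-to-tip depth is 1.  Tips are labelled
    ``sp01 ... spNN``.
    """
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_tips):
        taxon = taxa.new_taxon(label=f"sp{i + 1:02d}")
        node = dendropy.Node(taxon=taxon)
        node.age = 0.0
        nodes.append(node)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.age = t
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = parent.age - a.age
        b.edge.length = parent.age - b.age
        nodes = [nd for m, nd in enumerate(nodes) if m not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    scale = 1.0 / root.age
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    tree.seed_node.edge.length = None
    return tree


def balanced_tree(depth: int, branch_length: float = 1.0) -> dendropy.Tree:
    """Fully balanced binary ultrametric tree with 2**depth tips."""
    taxa = dendropy.TaxonNamespace()
    counter = [0]

    def build(level):
        node = dendropy.Node()
        if level == 0:
            counter[0] += 1
            node.taxon = taxa.new_taxon(label=f"sp{counter[0]:03d}")
        else:
            for _ in range(2):
                child = build(level - 1)
                child.edge.length = branch_length
                node.add_child(child)
        return node

    root = build(depth)
    return dendropy.Tree(taxon_namespace=taxa, seed_node=root)


def star_tree(n_tips: int, depth: float = 1.0) -> dendropy.Tree:
    """Star phylogeny: all tips attach directly to the root at equal depth."""
    taxa = dendropy.TaxonNamespace()
    root = dendropy.Node()
    for i in range(n_tips):
        node = dendropy.Node(taxon=taxa.new_taxon(label=f"sp{i + 1:02d}"))
        node.edge.length = depth
        root.add_child(node)
    return dendropy.Tree(taxon_namespace=taxa, seed_node=root)


@dataclass(frozen=True)
class TraitSimSpec:
    """Specification of trait evolution for PGLS simulations.

    The response is ``y = beta0 + beta1 * x + eps`` with
    ``eps ~ MVN(0, sigma2 * V(lambda_true))``, where V is the Brownian
    shared-path-length matrix of the tree and lambda scales its
    off-diagonal entries (Pagel's lambda).
    """

    tree: dendropy.Tree
    beta0: float = 0.0
    beta1: float = 1.0
    lambda_true: float = 1.0
    sigma2: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.lambda_true <= 1.0):
            raise ValueError("lambda_true must be in [0, 1]")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        labels = [t.label for t in self.tree.taxon_namespace]
        if len(labels) != len(set(labels)):
            raise ValueError("tree tip labels must be unique")


def simulate_traits_on_tree(
    spec: TraitSimSpec, predictor: "pd.Series | dict"
) -> pd.DataFrame:
    """Simulate a species trait from a predictor with phylogenetic error.

    Parameters
    ----------
    spec : TraitSimSpec
    predictor : Series or dict
        Predictor value per species, keyed by tip label; must cover every
        tip of the tree.

    Returns
    -------
    DataFrame indexed by species with columns ``predictor`` and ``trait``.
    """
    from .pgls import bm_vcv, lambda_transform

    predictor = pd.Series(predictor, dtype=float)
    tips = [t.label for t in spec.tree.taxon_namespace]
    missing = sorted(set(tips) - set(predictor.index))
    if missing:
        raise ValueError(f"predictor missing species present in tree: {missing}")
    predictor = predictor.loc[tips]
    n = len(tips)
    mean = spec.beta0 + spec.beta1 * predictor.to_numpy()
    if spec.sigma2 == 0:
        y = mean
    else:
        V = lambda_transform(bm_vcv(spec.tree, tips), spec.lambda_true)
        L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
        rng = np.random.default_rng(spec.seed)
        y = mean + np.sqrt(spec.sigma2) * (L @ rng.standard_normal(n))
    return pd.DataFrame(
        {"predictor": predictor.to_numpy(), "trait": y}, index=pd.Index(tips, name="species")
    )
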