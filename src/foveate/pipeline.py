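"""End-to-end study orchestration.

Simulate-or-load counting frames per retina -> topographic maps -> fovea
geometry -> transect slopes -> species averaging -> regional comparison ->
the PGLS battery: {log head movement rate, degree of eye movement} against
{overall + four axis} slopes, eye movement against log head rate, and the
size-independence check of overall slope against log eye axial length
(twelve comparative regressions in all).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field, asdict

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon

from . import __version__
from .synthetic import (
    AXES,
    CountingFrameSet,
    RetinaSpec,
    TraitSimSpec,
    random_tree,
    sample_counting_frames,
    simulate_traits_on_tree,
)
from .topography import (
    build_topographic_map,
    locate_fovea,
    mean_position_with_ci,
    normalize_fovea_position,
    FoveaPosition,
)
from .gradients import slopes_for_field, slope_table
from .regional import region_glm
from .pgls import PGLSRegression, parse_newick, write_newick, log_transform_rate


@dataclass
class StudyConfig:
    """Configuration of one full study run (documented key-value schema).

    mode "simulate" generates every input from the seed; mode "load" reads
    frames.csv / outlines.csv / traits.csv / tree.nwk from ``data_dir``.
    """

    mode: str = "simulate"
    data_dir: str | None = None
    out_dir: str = "study_out"
    seed: int = 0
    # spatial stage
    grid_step: float = 0.1
    n_transect_points: int = 10
    n_sites: int = 200
    frame_side: float = 50.0
    frames_per_site: int = 25
    site_layout: str = "uniform"
    # simulated community
    n_species: int = 29
    retinas_per_species: tuple[int, int] = (2, 5)
    radius: float = 6.0
    base_density: float = 500.0
    peak_density: float = 4000.0
    steepness_range: tuple[float, float] = (0.4, 1.3)
    noise_cv: float = 0.05
    fovea_mean_xy: tuple[float, float] = (-0.145, 0.057)
    fovea_sd: float = 0.05
    # simulated traits
    lambda_true: float = 1.0
    beta_head: float = 0.5
    beta0_head: float = 2.0
    sigma2_head: float = 0.09
    beta_eye: float = 5.0
    beta0_eye: float = 0.0
    sigma2_eye: float = 9.0
    # inference
    lambda_mode: str = "ml"
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("retinas_per_species", "steepness_range", "fovea_mean_xy"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def true_overall_slope(spec_or_s, base: float = 500.0, peak: float = 4000.0):
    """Analytic OLS slope of the planted power-law profile.

    Along a transect with normalized distance t (0 margin, 1 fovea) the
    planted density is base + (peak - base) * t**s, whose least-squares
    linear slope over t in [0, 1] is (peak - base) * 6 s / ((s+1)(s+2)),
    in the same density units.  Used as the ground-truth predictor when
    generating traits, so trait generation never depends on the measured
    maps.
    """
    s = np.asarray(spec_or_s, dtype=float)
    return (peak - base) / 1000.0 * 6.0 * s / ((s + 1.0) * (s + 2.0))


@dataclass
class RetinaMeasurement:
    species: str
    retina_id: str
    eye_side: str
    fovea: FoveaPosition
    slopes: dict  # axis -> SlopeEstimate


def measure_retina(
    frames: CountingFrameSet,
    outline: Polygon,
    species: str,
    retina_id: str,
    eye_side: str = "right",
    grid_step: float = 0.1,
    n_transect_points: int = 10,
) -> RetinaMeasurement:
    """Map one retina: interpolate, find the fovea, fit the four slopes.

    The fovea is located on a smoothed copy of the map (disk radius equal
    to the mean counting-site spacing) so the peak tracks the density
    summit rather than single-site Poisson noise.
    """
    field = build_topographic_map(frames, outline, grid_step=grid_step)
    site_spacing = float(np.sqrt(outline.area / len(frames.counts)))
    fovea_mm = locate_fovea(field, smooth_mm=site_spacing)
    fovea = normalize_fovea_position(fovea_mm, outline, eye_side)
    fovea = FoveaPosition(
        x=fovea.x, y=fovea.y, species=species, eye_side=eye_side
    )
    slopes = slopes_for_field(
        field, fovea_mm, n_points=n_transect_points, species=species
    )
    return RetinaMeasurement(
        species=species, retina_id=retina_id, eye_side=eye_side,
        fovea=fovea, slopes=slopes,
    )


def species_average(measurements: list[RetinaMeasurement]) -> tuple[dict, list]:
    """Average per-retina slopes and fovea positions within species.

    Returns (slopes_by_species, positions): each species contributes one
    averaged slope per axis (axes missing from every retina of a species
    are flagged as missing with a warning) and one averaged fovea
    position.  Averaging is a plain arithmetic mean, so it is invariant to
    retina order.
    """
    by_species: dict[str, list[RetinaMeasurement]] = {}
    for m in measurements:
        by_species.setdefault(m.species, []).append(m)
    slopes_out: dict[str, dict] = {}
    positions = []
    for sp, ms in by_species.items():
        axis_means = {}
        for axis in list(AXES) + ["overall"]:
            vals = [m.slopes[axis].slope for m in ms if axis in m.slopes]
            if not vals:
                warnings.warn(f"species {sp}: axis {axis} missing in all retinas")
                axis_means[axis] = np.nan
            else:
                axis_means[axis] = float(np.mean(vals))
        slopes_out[sp] = axis_means
        positions.append(
            FoveaPosition(
                x=float(np.mean([m.fovea.x for m in ms])),
                y=float(np.mean([m.fovea.y for m in ms])),
                species=sp,
            )
        )
    return slopes_out, positions


def simulate_study_inputs(config: StudyConfig, rng=None):
    """Generate the full synthetic study: tree, retinas, frames, traits.

    Per species a latent steepness exponent is drawn uniformly from
    ``steepness_range`` (shared by all four quadrants up to small
    per-retina lognormal jitter), retinas receive jittered fovea
    positions, and counting frames with Poisson noise are sampled from
    each retina's density field.  Behavioral traits are linear in the
    species' analytic ground-truth overall slope plus Brownian-motion
    phylogenetic error with Pagel's lambda structure.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    tree = random_tree(config.n_species, seed=int(rng.integers(2**31)))
    species = sorted({leaf.taxon.label for leaf in tree.leaf_node_iter()})
    steep = pd.Series(
        rng.uniform(*config.steepness_range, size=len(species)), index=species
    )
    retinas = []
    lo, hi = config.retinas_per_species
    for sp in species:
        n_ret = int(rng.integers(lo, hi + 1))
        for r in range(n_ret):
            s_jit = float(steep[sp] * rng.lognormal(0.0, 0.05))
            fx = config.fovea_mean_xy[0] + rng.normal(0, config.fovea_sd)
            fy = config.fovea_mean_xy[1] + rng.normal(0, config.fovea_sd)
            spec = RetinaSpec(
                radius=config.radius,
                fovea_xy=(fx, fy),
                base_density=config.base_density,
                peak_density=config.peak_density,
                quadrant_steepness={a: s_jit for a in AXES},
                noise_cv=config.noise_cv,
                seed=int(rng.integers(2**31)),
            )
            retinas.append((sp, f"{sp}_r{r + 1}", spec))
    slope_true = true_overall_slope(
        steep.to_numpy(), config.base_density, config.peak_density
    )
    slope_true = pd.Series(slope_true, index=species)
    head = simulate_traits_on_tree(
        TraitSimSpec(
            tree=tree, beta0=config.beta0_head, beta1=config.beta_head,
            lambda_true=config.lambda_true, sigma2=config.sigma2_head,
            seed=int(rng.integers(2**31)),
        ),
        slope_true,
    )["trait"]
    eye = simulate_traits_on_tree(
        TraitSimSpec(
            tree=tree, beta0=config.beta0_eye, beta1=config.beta_eye,
            lambda_true=config.lambda_true, sigma2=config.sigma2_eye,
            seed=int(rng.integers(2**31)),
        ),
        slope_true,
    )["trait"]
    traits = pd.DataFrame(
        {
            "head_rate": np.exp(head),  # modeled on the log scale
            "eye_movement": np.clip(eye, 0.5, None),
            "axial_length": np.exp(rng.normal(np.log(12.0), 0.2, len(species))),
        },
        index=pd.Index(species, name="species"),
    )
    return tree, retinas, traits, steep


def pgls_battery(
    slopes: pd.DataFrame, traits: pd.DataFrame, tree, lambda_mode="ml"
) -> dict:
    """The twelve comparative regressions of the study design."""
    lam = lambda_mode if lambda_mode == "ml" else float(lambda_mode)
    common = [sp for sp in slopes.index if sp in traits.index]
    slopes = slopes.loc[common]
    traits = traits.loc[common]
    log_head = pd.Series(
        log_transform_rate(traits["head_rate"].to_numpy()), index=traits.index
    )
    fits = {}
    for axis in ["overall", *AXES]:
        X = slopes[[axis]].rename(columns={axis: f"slope_{axis}"})
        fits[f"head_rate~slope_{axis}"] = PGLSRegression(tree=tree, lam=lam).fit(
            X, log_head
        )
        fits[f"eye_movement~slope_{axis}"] = PGLSRegression(tree=tree, lam=lam).fit(
            X, traits["eye_movement"]
        )
    fits["eye_movement~log_head_rate"] = PGLSRegression(tree=tree, lam=lam).fit(
        log_head.to_frame("log_head_rate"), traits["eye_movement"]
    )
    log_axial = pd.Series(
        np.log(traits["axial_length"].to_numpy()), index=traits.index
    )
    fits["overall_slope~log_axial_length"] = PGLSRegression(tree=tree, lam=lam).fit(
        log_axial.to_frame("log_axial_length"), slopes["overall"]
    )
    return fits


def _fit_to_dict(fit) -> dict:
    return {
        "coefficients": {k: float(v) for k, v in fit.coefficients.items()},
        "lambda": float(fit.lambda_hat),
        "sigma2": float(fit.sigma2_hat),
        "F": float(fit.F),
        "df": list(fit.df),
        "df_label": fit.df_label,
        "p": float(fit.p),
        "r2": float(fit.r2),
        "r2_adj": float(fit.r2_adj),
        "loglik": float(fit.loglik),
        "n": int(fit.n),
    }


def load_study_inputs(data_dir):
    """Read frames.csv, outlines.csv, traits.csv, tree.nwk from a directory."""
    from pathlib import Path

    d = Path(data_dir)
    for name in ("frames.csv", "outlines.csv", "traits.csv", "tree.nwk"):
        if not (d / name).exists():
            raise FileNotFoundError(f"load mode requires {d / name}")
    frames = pd.read_csv(d / "frames.csv")
    outlines = pd.read_csv(d / "outlines.csv")
    traits = pd.read_csv(d / "traits.csv").set_index("species")
    tree = parse_newick((d / "tree.nwk").read_text())
    retinas = []
    for rid, grp in frames.groupby("retina_id", sort=True):
        overt = outlines[outlines["retina_id"] == rid]
        if overt.empty:
            raise ValueError(f"no outline for retina {rid}")
        outline = Polygon(overt[["x_mm", "y_mm"]].to_numpy())
        fs = CountingFrameSet.from_frame(grp)
        retinas.append(
            (
                str(grp["species"].iloc[0]),
                str(rid),
                str(grp["eye_side"].iloc[0]) if "eye_side" in grp else "right",
                fs,
                outline,
            )
        )
    return tree, retinas, traits


def run_study(config: StudyConfig) -> dict:
    """Execute the full pipeline and write all artifacts to ``out_dir``.

    Returns the study report dict; writes the per-species slope table, the
    fovea position summary, the regional comparison, the PGLS battery
    (with a standardized-residual outlier screen), and a manifest.
    """
    from pathlib import Path

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.mode == "simulate":
        tree, retina_specs, traits, steep = simulate_study_inputs(config)
        measurements = []
        for sp, rid, rspec in retina_specs:
            from .synthetic import generate_density_field

            field = generate_density_field(rspec, grid_step=config.grid_step)
            frames = sample_counting_frames(
                field,
                n_sites=config.n_sites,
                frame_side=config.frame_side,
                seed=rspec.seed + 1,
                layout=config.site_layout,
                frames_per_site=config.frames_per_site,
            )
            measurements.append(
                measure_retina(
                    frames, field.outline, sp, rid,
                    grid_step=config.grid_step,
                    n_transect_points=config.n_transect_points,
                )
            )
        (out / "tree.nwk").write_text(write_newick(tree) + "\n")
    elif config.mode == "load":
        tree, retinas, traits = load_study_inputs(config.data_dir)
        measurements = [
            measure_retina(
                frames, outline, sp, rid, eye_side,
                grid_step=config.grid_step,
                n_transect_points=config.n_transect_points,
            )
            for sp, rid, eye_side, frames, outline in retinas
        ]
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    tree_tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    orphans = sorted(set(traits.index) - tree_tips)
    if orphans:
        raise ValueError(f"species in traits but absent from tree: {orphans}")

    slopes_by_sp, positions = species_average(measurements)
    slopes = slope_table(
        {sp: {a: _S(v) for a, v in d.items()} for sp, d in slopes_by_sp.items()}
    )
    slopes.index.name = "species"
    slopes.to_csv(out / "slopes.csv")

    fovea_summary = mean_position_with_ci(positions, alpha=config.alpha)
    fovea_dict = {
        axis: asdict(summary) for axis, summary in fovea_summary.items()
    }
    positions_df = pd.DataFrame(
        {"species": [p.species for p in positions],
         "x": [p.x for p in positions], "y": [p.y for p in positions]}
    ).set_index("species")
    positions_df.to_csv(out / "fovea_positions.csv")

    region = region_glm(slopes)
    models = pgls_battery(slopes, traits, tree, lambda_mode=config.lambda_mode)

    # outlier screen: standardized residuals beyond +-3 are flagged but not
    # removed (screening replicates the study's check, removal would not)
    pgls_dict = {}
    for name, model in models.items():
        entry = _fit_to_dict(model.to_fit())
        z = model.resid_standardized_
        entry["outliers"] = sorted(z.index[np.abs(z) > 3.0])
        pgls_dict[name] = entry
    report = {
        "fovea_summary": fovea_dict,
        "region_comparison": region.to_dict(),
        "pgls": pgls_dict,
        "n_species": int(len(slopes)),
        "n_retinas": int(len(measurements)),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: _jsonable(v) for k, v in asdict(config).items()},
        "artifacts": sorted(
            p.name for p in out.iterdir() if p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    return v


class _S:
    """Tiny adapter giving species_average output the SlopeEstimate surface."""

    def __init__(self, slope):
        self.slope = slope
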