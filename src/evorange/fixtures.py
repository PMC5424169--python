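"""Synthetic landscapes, climate scenarios and pseudo-niche-model output.

Everything the simulator consumes can be generated here so the full
pipeline runs without external data. The generated system emulates a
small alpine block: an elevation ramp drives a temperature gradient
(lapse rate), precipitation rises with elevation, and carbonate bedrock
forms smooth patches. A synthetic species occupies an upper-elevation
niche (alpine endemics sit near the top of their massifs, so warming
immediately contracts the statically suitable area); warming scenarios
shift the thermal optimum upslope at a constant per-decade rate between
2010 and 2090.

All outputs are pure functions of ``(spec, seed)``: the same spec and
seed give byte-identical rasters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .demography import SpeciesParams
from .landscape import ANCHOR_YEARS, ClimateScenario, Landscape, write_ascii_grid
from .niche import suitability_from_environment

__all__ = [
    "FixtureSpec",
    "NicheParams",
    "SEVERITIES",
    "MICRO_SPECIES",
    "make_landscape",
    "make_scenario",
    "make_niche",
    "make_predictions",
    "suitability_maps",
    "write_input_directory",
]

#: per-decade (temperature °C, precipitation mm) trends by scenario severity
SEVERITIES: dict[str, tuple[float, float]] = {
    "none": (0.0, 0.0),
    "mild": (0.1875, 0.0),
    "moderate": (0.34375, -5.0),
    "severe": (0.5, -10.0),
}


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study system.

    Defaults describe a 32 × 32 grid of 250 m cells (64 km²) spanning an
    800 m elevation ramp; temperature falls along the ramp with a
    6.5 °C/km lapse rate. The niche centre sits at 75% of the ramp so
    that warming pushes the suitable band towards (and past) the upper
    grid edge.
    """

    grid_shape: tuple[int, int] = (32, 32)
    cell_size: float = 250.0
    elevation_range_m: float = 800.0
    elevation_noise_m: float = 30.0
    temp_base: float = 8.0            # °C at the foot of the ramp
    lapse_rate: float = 6.5           # °C per km of elevation
    temp_noise: float = 0.2           # °C, cell-level
    precip_base: float = 1000.0       # mm at the foot of the ramp
    precip_elev_gain: float = 300.0   # mm across the full ramp
    precip_noise: float = 80.0        # mm, smoothed field
    carbonate_smooth_cells: float = 2.0
    niche_elevation_fraction: float = 0.75
    niche_temp_width: float = 1.2     # squared-°C niche width (variance-like)
    niche_precip_width: float = 62500.0  # (250 mm)²
    niche_carb_width: float = 900.0   # (30 %)²
    niche_carb_centre: float = 75.0   # % carbonate preferred
    seed: int = 0


@dataclass
class NicheParams:
    """Centre and width of the synthetic species' niche (raw units)."""

    centre: np.ndarray  # (temperature, precipitation, carbonate)
    width: np.ndarray


#: synthetic focal species for desk-scale studies (K scaled down)
MICRO_SPECIES = SpeciesParams(
    name="micro", s_a=0.9, fecundity=15.0, germination_rate=0.3,
    seed_survival=0.3, clonal_rate=0.2, max_seed_age=1, K_max=300,
    dispersal_m=0.35, dispersal_mean_m=300.0)


def _rng(spec: FixtureSpec, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def make_landscape(spec: FixtureSpec) -> Landscape:
    """Elevation-ramp landscape with temperature, precipitation and
    carbonate layers."""
    rng = _rng(spec, 1)
    R, C = spec.grid_shape
    rows = np.arange(R, dtype=float)[:, None]
    elevation = (rows / max(R - 1, 1)) * spec.elevation_range_m \
        + rng.normal(0.0, spec.elevation_noise_m, size=(R, C))
    temperature = (spec.temp_base - spec.lapse_rate * elevation / 1000.0
                   + rng.normal(0.0, spec.temp_noise, size=(R, C)))
    precip_smooth = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, size=(R, C)), sigma=2.0, mode="nearest")
    precip_smooth *= spec.precip_noise / max(precip_smooth.std(), 1e-12)
    precipitation = (spec.precip_base
                     + spec.precip_elev_gain * elevation / spec.elevation_range_m
                     + precip_smooth)
    carb_field = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, size=(R, C)), sigma=spec.carbonate_smooth_cells,
        mode="nearest")
    carb_field /= max(carb_field.std(), 1e-12)
    carbonate = 100.0 / (1.0 + np.exp(-2.0 * carb_field))
    return Landscape(carbonate, temperature, precipitation,
                     cell_size=spec.cell_size)


def make_scenario(spec: FixtureSpec, landscape: Landscape,
                  severity: str = "moderate") -> ClimateScenario:
    """Decadal warming trajectory 2010–2090 of the given severity.

    Warming is spatially uniform and linear per decade; precipitation
    follows its (possibly zero) per-decade trend. Climate stays constant
    after 2090 by construction of the optimum interpolation.
    """
    if severity not in SEVERITIES:
        raise ValueError(f"severity must be one of {sorted(SEVERITIES)}")
    dT, dP = SEVERITIES[severity]
    decades = np.arange(len(ANCHOR_YEARS), dtype=float)
    temp = landscape.temperature[None] + (dT * decades)[:, None, None]
    precip = landscape.precipitation[None] + (dP * decades)[:, None, None]
    return ClimateScenario(severity, temp, precip)


def make_niche(spec: FixtureSpec, landscape: Landscape) -> NicheParams:
    """Niche centre/width of the synthetic species in raw units.

    The thermal and precipitation centres are taken at the spec's niche
    elevation on the noise-free ramp; the carbonate centre is fixed.
    """
    elev = spec.niche_elevation_fraction * spec.elevation_range_m
    centre = np.array([
        spec.temp_base - spec.lapse_rate * elev / 1000.0,
        spec.precip_base + spec.precip_elev_gain * elev / spec.elevation_range_m,
        spec.niche_carb_centre,
    ])
    width = np.array([spec.niche_temp_width, spec.niche_precip_width,
                      spec.niche_carb_width])
    return NicheParams(centre, width)


def _env_stack(landscape: Landscape) -> np.ndarray:
    return np.stack([landscape.temperature, landscape.precipitation,
                     landscape.carbonate], axis=-1)


def make_predictions(spec: FixtureSpec, landscape: Landscape,
                     niche_params: NicheParams,
                     displacements: tuple[float, ...] = (0.1, 0.25, 0.5, 2.0),
                     noise: float = 0.05,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-niche-model probability maps plus the truth presence mask.

    The truth mask is the suitability (logistic in niche distance) of the
    2010 environment thresholded at 0.5. Each pseudo-model predicts the
    suitability of a niche whose centre is displaced by the given number
    of niche widths in a random direction, plus mild additive
    noise — larger displacement, lower skill. The default displacements
    yield a skill spread whose weakest model falls below the 0.3 TSS
    discard line.
    """
    rng = _rng(spec, 2)
    env = _env_stack(landscape)
    truth_p = suitability_from_environment(env, niche_params.centre,
                                           niche_params.width)
    truth = truth_p >= 0.5
    preds = []
    for disp in displacements:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        centre = niche_params.centre + disp * direction * np.sqrt(niche_params.width)
        p = suitability_from_environment(env, centre, niche_params.width)
        if noise > 0:
            p = p + rng.normal(0.0, noise, size=p.shape)
        preds.append(np.clip(p, 0.0, 1.0))
    return np.stack(preds), truth


def suitability_maps(spec: FixtureSpec, landscape: Landscape,
                     scenario: ClimateScenario, niche_params: NicheParams,
                     years: tuple[int, ...] | None = None,
                     ) -> dict[int, np.ndarray]:
    """Projected suitability per record year (stand-in for niche-model
    projections under the forcing climate)."""
    from .landscape import theta_field
    if years is None:
        years = tuple(range(2000, 2091, 10))
    return {int(y): suitability_from_environment(
        theta_field(landscape, scenario, float(y)),
        niche_params.centre, niche_params.width) for y in years}


def write_input_directory(spec: FixtureSpec, out_dir: str | Path,
                          severity: str = "moderate") -> Path:
    """Write a ready-to-run input directory of plain-text rasters.

    Layout: ``carbonate.asc``, ``temperature_<year>.asc`` and
    ``precipitation_<year>.asc`` per anchor decade, per-model suitability
    maps, the truth presence mask and an ensemble-ready file list.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    land = make_landscape(spec)
    scen = make_scenario(spec, land, severity)
    niche_params = make_niche(spec, land)
    preds, truth = make_predictions(spec, land, niche_params)
    cs = spec.cell_size
    write_ascii_grid(out / "carbonate.asc", land.carbonate, cs)
    for i, year in enumerate(ANCHOR_YEARS):
        write_ascii_grid(out / f"temperature_{year}.asc", scen.temperature[i], cs)
        write_ascii_grid(out / f"precipitation_{year}.asc", scen.precipitation[i], cs)
    for j, p in enumerate(preds):
        write_ascii_grid(out / f"model_{j}_probability.asc", p, cs)
    write_ascii_grid(out / "truth_presence.asc", truth.astype(float), cs)
    return out
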