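"""Year-loop engine: event scheduling, burn-in, climate-scenario runs.

Every simulated year executes, in this fixed order:

1. mating and seed production
2. seed dispersal
3. aging of adults and pre-adults
4. seed germination and survival in the seedbank
5. clonal reproduction
6. seedling competition (density-dependent regulation)
7. census (statistics recorded before selection)
8. seedling viability selection
9. ceiling regulation (burn-in phase only)

Simulations run in two phases. The *burn-in* holds the climate at its
initial (2010) state and applies a ceiling regulation — capacity 0 in
cells predicted unoccupied by the niche model, a large value (default
8,000) elsewhere — until the populations reach demographic and
mutation–selection–migration equilibrium; the state is then snapshotted.
The *scenario* phase restarts from the snapshot and simulates years
2000–2150 with decadal climate forcing between 2010 and 2090 (constant
afterwards), recording per-cell statistics every 10 years.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genetics, niche
from .demography import Patch, Pool, SeedCohort, SpeciesParams, reproduce_clonal, \
    reproduce_sexual, age_and_survive, seedbank_step
from .genetics import GeneticParams, N_TRAITS
from .landscape import ClimateScenario, EnvScaler, Landscape, disperse_seeds, \
    theta_field
from .regulation import SelectionRegime, calibrate_kc, ceiling_regulate_counts, \
    competition_survival, viability_survival

__all__ = [
    "EVENT_ORDER",
    "SimConfig",
    "Simulation",
    "build_simulation",
    "run_year",
    "burn_in",
    "run_scenario",
    "save_snapshot",
    "load_snapshot",
]

EVENT_ORDER = (
    "mating", "dispersal", "aging", "germination", "clonal_reproduction",
    "competition", "census", "selection",
)

#: founder standing variation: rounds of the standard mutation operator
FOUNDER_MUTATION_ROUNDS = 100


@dataclass
class SimConfig:
    """Run-level knobs (species/genetics live in their own param objects)."""

    vs_multiplier: float = 1.0          # V_s = multiplier * V_SENM
    burn_in_years: int = 5000
    burn_in_ceiling: int = 8000
    record_interval: int = 10
    start_year: int = 2000
    end_year: int = 2150
    n_replicates: int = 10
    init_adults: int | None = None      # default: K_max // 2
    single_genotype: bool = False       # no-evolution baseline mode
    count_pre_adults: bool = True       # include pre-adults in competition N
    occupancy_stage: str = "established"  # or "adults"
    explosion_factor: int = 10          # burn-in guard

    def __post_init__(self) -> None:
        if self.vs_multiplier <= 0:
            raise ValueError("vs_multiplier must be > 0")
        if self.record_interval < 1:
            raise ValueError("record_interval must be >= 1")
        if self.occupancy_stage not in ("established", "adults"):
            raise ValueError("occupancy_stage must be 'established' or 'adults'")


@dataclass
class Simulation:
    """Mutable simulation state for one grid."""

    landscape: Landscape
    scenario: ClimateScenario
    scaler: EnvScaler
    species: SpeciesParams        # k_c calibrated
    gparams: GeneticParams        # V_E calibrated
    regime: SelectionRegime       # V_s in standardized units
    config: SimConfig
    presence0: np.ndarray         # initial predicted-occupied mask
    patches: dict[tuple[int, int], Patch] = field(default_factory=dict)
    grid_id: str = "grid0"
    event_log: list[str] | None = None

    def theta_std(self, year: float) -> np.ndarray:
        """Standardized optimum field at ``year``; shape (R, C, T)."""
        return self.scaler.transform(theta_field(self.landscape, self.scenario,
                                                 year))

    def patch(self, cell: tuple[int, int]) -> Patch:
        p = self.patches.get(cell)
        if p is None:
            p = Patch.empty(self.gparams.L, N_TRAITS)
            self.patches[cell] = p
        return p

    def prune(self) -> None:
        dead = [c for c, p in self.patches.items()
                if p.n_established == 0 and p.n_bank == 0]
        for c in dead:
            del self.patches[c]

    def occupancy_mask(self) -> np.ndarray:
        mask = np.zeros(self.landscape.shape, dtype=bool)
        for (r, c), p in self.patches.items():
            n = p.adults.n if self.config.occupancy_stage == "adults" \
                else p.adults.n + p.pre1.n + p.pre2.n + p.seedlings.n
            if n > 0:
                mask[r, c] = True
        return mask

    def total_established(self) -> int:
        return sum(p.n_established for p in self.patches.values())


def _founder_population(n: int, optimum_std: np.ndarray, gp: GeneticParams,
                        rng: np.random.Generator,
                        rounds: int = FOUNDER_MUTATION_ROUNDS) -> np.ndarray:
    return genetics.founder_genomes(n, optimum_std, gp, rng, rounds=rounds)


def calibrate_VE_from_founders(gp: GeneticParams, rng: np.random.Generator,
                               n: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Environmental variances hitting the target heritability for the
    founder standing variation. Returns ``(V_E, realized founder V_G)``."""
    genomes = _founder_population(n, np.zeros(N_TRAITS), gp, rng)
    V_G = genetics.genotypic_value(genomes).var(axis=0, ddof=1)
    return genetics.calibrate_VE(V_G, gp.h2_target), V_G


def build_simulation(landscape: Landscape, scenario: ClimateScenario,
                     presence: np.ndarray, species: SpeciesParams,
                     gparams: GeneticParams, config: SimConfig,
                     rng: np.random.Generator,
                     grid_id: str = "grid0") -> Simulation:
    """Assemble and initialize a simulation for one grid.

    Standardizes the environment, anchors the selection variances to the
    niche widths over ``presence`` (V_s = multiplier · V_SENM; variables
    with zero niche width are released from selection), calibrates the
    competitive weight against the species' nominal adult capacity and
    the environmental variances against the heritability target, and
    founds locally adapted populations in every predicted-occupied cell.
    """
    presence = np.asarray(presence, dtype=bool)
    if presence.shape != landscape.shape:
        raise ValueError("presence mask must match the landscape grid")
    scaler = EnvScaler.fit(landscape, scenario)
    env0 = scaler.transform(theta_field(landscape, scenario, 2010.0))
    summary = niche.niche_summary(env0, presence)
    V_s = summary.V_SENM * config.vs_multiplier
    # a variable constant across occupied cells carries no niche
    # information: selection on it is effectively released
    V_s = np.where(summary.usable, V_s, 1e9)
    regime = SelectionRegime(V_s)
    sp = species if species.k_c is not None else species.with_kc(
        calibrate_kc(species))

    gp = gparams
    V_E, _ = calibrate_VE_from_founders(gp, rng)
    gp = GeneticParams(L=gp.L, mu=0.0 if config.single_genotype else gp.mu,
                       v=gp.v, V_E=V_E, h2_target=gp.h2_target)

    sim = Simulation(landscape, scenario, scaler, sp, gp, regime, config,
                     presence, grid_id=grid_id)
    n0 = config.init_adults if config.init_adults is not None \
        else max(10, sp.K_max // 2)
    if config.single_genotype:
        g_star = niche.global_genotype(env0, presence)
    for cell in zip(*np.nonzero(presence)):
        cell = (int(cell[0]), int(cell[1]))
        if config.single_genotype:
            genomes = np.broadcast_to(
                g_star / (2 * gp.L), (n0, gp.L, 2, N_TRAITS)).copy()
        else:
            genomes = _founder_population(n0, env0[cell], gp, rng)
        patch = sim.patch(cell)
        patch.adults = Pool.from_genomes(genomes, gp.V_E, rng)
    return sim


def run_year(sim: Simulation, year: float, mode: str,
             rng: np.random.Generator,
             recorder: list[dict] | None = None,
             suitability: np.ndarray | None = None) -> None:
    """Execute one full yearly cycle in the canonical event order."""
    if mode not in ("burn_in", "scenario"):
        raise ValueError("mode must be 'burn_in' or 'scenario'")
    sp, gp, cfg = sim.species, sim.gparams, sim.config
    theta = sim.theta_std(2010.0 if mode == "burn_in" else year)
    log = sim.event_log
    cells = list(sim.patches.keys())

    # 1. mating and seed production
    fresh: dict[tuple[int, int], np.ndarray] = {}
    origins_r, origins_c, seed_stacks = [], [], []
    for cell in cells:
        seeds = reproduce_sexual(sim.patches[cell], sp, gp, rng)
        if seeds.shape[0]:
            seed_stacks.append(seeds)
            origins_r.append(np.full(seeds.shape[0], cell[0], dtype=np.int64))
            origins_c.append(np.full(seeds.shape[0], cell[1], dtype=np.int64))
    if log is not None:
        log.append("mating")

    # 2. seed dispersal (absorbing boundary)
    if seed_stacks:
        all_seeds = np.concatenate(seed_stacks)
        rows = np.concatenate(origins_r)
        cols = np.concatenate(origins_c)
        rows, cols, lost = disperse_seeds(
            rows, cols, sim.landscape.shape, sim.landscape.cell_size,
            sp.dispersal_m, sp.dispersal_mean_m, rng)
        keep = ~lost
        rows, cols, all_seeds = rows[keep], cols[keep], all_seeds[keep]
        order = np.lexsort((cols, rows))
        rows, cols, all_seeds = rows[order], cols[order], all_seeds[order]
        bounds = np.nonzero(np.diff(rows) | np.diff(cols))[0] + 1
        for chunk, r0, c0 in zip(
                np.split(all_seeds, bounds),
                rows[np.r_[0, bounds]] if rows.size else [],
                cols[np.r_[0, bounds]] if cols.size else []):
            fresh[(int(r0), int(c0))] = chunk
    if log is not None:
        log.append("dispersal")

    # 3. aging of adults and pre-adults
    for cell in cells:
        age_and_survive(sim.patches[cell], sp, rng)
    if log is not None:
        log.append("aging")

    # 4. germination and seedbank survival; fresh seeds enter afterwards
    for cell in sorted(set(cells) | set(fresh)):
        patch = sim.patch(cell)
        germinants, patch.bank = seedbank_step(patch.bank, sp, rng, L=gp.L)
        if germinants.shape[0]:
            patch.seedlings = Pool.concat([
                patch.seedlings, Pool.from_genomes(germinants, gp.V_E, rng)])
        if cell in fresh:
            patch.bank.append(SeedCohort(0, fresh[cell]))
    if log is not None:
        log.append("germination")

    # 5. clonal reproduction
    for cell, patch in sim.patches.items():
        clones = reproduce_clonal(patch, sp, gp, rng,
                                  mutation=not cfg.single_genotype)
        if clones.shape[0]:
            patch.seedlings = Pool.concat([
                patch.seedlings, Pool.from_genomes(clones, gp.V_E, rng)])
    if log is not None:
        log.append("clonal_reproduction")

    # 6. seedling competition against established plants
    for patch in sim.patches.values():
        if patch.seedlings.n == 0:
            continue
        n_comp = patch.adults.n + (patch.pre1.n + patch.pre2.n
                                   if cfg.count_pre_adults else 0)
        p = competition_survival(n_comp, sp.k_c)
        patch.seedlings = patch.seedlings.subset(
            rng.random(patch.seedlings.n) < p)
    if log is not None:
        log.append("competition")

    # 7. census (before selection)
    if recorder is not None:
        _record(sim, year, theta, recorder, suitability)
    if log is not None:
        log.append("census")

    # 8. seedling viability selection
    for cell, patch in sim.patches.items():
        if patch.seedlings.n == 0:
            continue
        w = viability_survival(patch.seedlings.phenotypes, theta[cell],
                               sim.regime.V_s)
        patch.seedlings = patch.seedlings.subset(rng.random(patch.seedlings.n) < w)
    if log is not None:
        log.append("selection")

    # 9. ceiling regulation (burn-in only)
    if mode == "burn_in":
        _apply_ceiling(sim, rng)
    sim.prune()


def _apply_ceiling(sim: Simulation, rng: np.random.Generator) -> None:
    K = sim.config.burn_in_ceiling
    guard = sim.config.explosion_factor * K
    for cell in list(sim.patches):
        patch = sim.patches[cell]
        if not sim.presence0[cell]:
            sim.patches[cell] = Patch.empty(sim.gparams.L, N_TRAITS)
            continue
        n = patch.n_established
        if n > guard:
            raise RuntimeError(
                f"demographic explosion in patch {cell}: {n} > {guard}")
        kept = ceiling_regulate_counts(n, K, rng)
        if kept is None:
            continue
        pools = [patch.seedlings, patch.pre1, patch.pre2, patch.adults]
        sizes = np.cumsum([0] + [p.n for p in pools])
        new_pools = []
        for p, lo, hi in zip(pools, sizes[:-1], sizes[1:]):
            local = kept[(kept >= lo) & (kept < hi)] - lo
            new_pools.append(p.subset(np.sort(local)))
        patch.seedlings, patch.pre1, patch.pre2, patch.adults = new_pools


def _trait_stats(pool_values: np.ndarray, prefix: str) -> dict[str, float]:
    out: dict[str, float] = {}
    n = pool_values.shape[0]
    mean = pool_values.mean(axis=0) if n else np.full(N_TRAITS, np.nan)
    var = pool_values.var(axis=0, ddof=1) if n > 1 else np.full(N_TRAITS, np.nan)
    for k in range(N_TRAITS):
        out[f"{prefix}_mean_{k}"] = float(mean[k])
        out[f"{prefix}_var_{k}"] = float(var[k])
    return out


def _record(sim: Simulation, year: float, theta: np.ndarray,
            recorder: list[dict],
            suitability: np.ndarray | None) -> None:
    for cell, patch in sorted(sim.patches.items()):
        established = [patch.adults, patch.pre1, patch.pre2, patch.seedlings]
        n_est = sum(p.n for p in established)
        if n_est == 0 and patch.n_bank == 0:
            continue
        row: dict = {"year": int(year), "grid": sim.grid_id,
                     "row": cell[0], "col": cell[1]}
        row.update(patch.stage_counts())
        if n_est:
            pool = Pool.concat(established)
            row.update(_trait_stats(pool.genotypes, "genotype"))
            row.update(_trait_stats(pool.phenotypes, "phenotype"))
        else:
            row.update(_trait_stats(np.zeros((0, N_TRAITS)), "genotype"))
            row.update(_trait_stats(np.zeros((0, N_TRAITS)), "phenotype"))
        if patch.seedlings.n:
            w = viability_survival(patch.seedlings.phenotypes, theta[cell],
                                   sim.regime.V_s)
            row["adaptive_survival"] = float(np.mean(w))
        else:
            row["adaptive_survival"] = np.nan
        row["suitability"] = (float(suitability[cell])
                              if suitability is not None else np.nan)
        row["occupied"] = bool(
            patch.adults.n if sim.config.occupancy_stage == "adults" else n_est)
        recorder.append(row)


def burn_in(sim: Simulation, rng: np.random.Generator,
            years: int | None = None, snapshot_dir: str | Path | None = None,
            ) -> dict:
    """Run the burn-in phase; returns equilibrium diagnostics.

    Climate is frozen at its initial state and the ceiling regulation is
    active. Diagnostics include the regression slope of total adult
    numbers over the last 10% of years (should be ~0 at equilibrium).
    """
    years = int(years if years is not None else sim.config.burn_in_years)
    tail = max(10, years // 10)
    adult_series = np.zeros(years)
    for t in range(years):
        run_year(sim, 2010.0, "burn_in", rng)
        adult_series[t] = sum(p.adults.n for p in sim.patches.values())
        if sim.total_established() == 0:
            raise RuntimeError(
                f"global extinction during burn-in at year {t + 1} "
                f"(adults trajectory tail: {adult_series[max(0, t - 5):t + 1]})")
    x = np.arange(tail, dtype=float)
    y = adult_series[-tail:]
    slope = float(np.polyfit(x, y, 1)[0]) if tail > 1 else 0.0
    diagnostics = {
        "years": years,
        "final_adults": float(adult_series[-1]),
        "mean_adults_tail": float(y.mean()),
        "tail_slope_per_year": slope,
        "relative_tail_slope": slope * tail / max(y.mean(), 1e-9),
        "occupied_cells": int(sim.occupancy_mask().sum()),
    }
    if snapshot_dir is not None:
        save_snapshot(sim, snapshot_dir)
    return diagnostics


def run_scenario(sim: Simulation, rng: np.random.Generator,
                 suitability_maps: dict[int, np.ndarray] | None = None,
                 ) -> pd.DataFrame:
    """Simulate the climate-forcing phase and return the record table.

    Years run from ``config.start_year`` to ``config.end_year``; records
    are written at ``record_interval``-year anchors (2000, 2010, …).
    ``suitability_maps`` optionally provides a per-record-year map whose
    values are stored alongside the census.
    """
    cfg = sim.config
    rows: list[dict] = []
    for year in range(cfg.start_year, cfg.end_year + 1):
        record = (year - cfg.start_year) % cfg.record_interval == 0
        suit = None
        if suitability_maps is not None and record:
            suit = suitability_maps.get(min(year, 2090))
        run_year(sim, float(year), "scenario", rng,
                 recorder=rows if record else None, suitability=suit)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# snapshots

_STAGES = ("adults", "pre1", "pre2", "seedlings")


def save_snapshot(sim: Simulation, path: str | Path) -> None:
    """Serialize the population state to a directory of .npy files.

    Deterministic bytes: saving, loading and saving again produces
    identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cells = sorted(sim.patches.keys())
    for stage in _STAGES:
        genomes, phen, where = [], [], []
        for cell in cells:
            pool: Pool = getattr(sim.patches[cell], stage)
            if pool.n:
                genomes.append(pool.genomes)
                phen.append(pool.phenotypes)
                where.append(np.tile(cell, (pool.n, 1)))
        L = sim.gparams.L
        np.save(path / f"{stage}_genomes.npy",
                np.concatenate(genomes) if genomes else np.zeros((0, L, 2, N_TRAITS)))
        np.save(path / f"{stage}_phenotypes.npy",
                np.concatenate(phen) if phen else np.zeros((0, N_TRAITS)))
        np.save(path / f"{stage}_cells.npy",
                np.concatenate(where) if where else np.zeros((0, 2), dtype=np.int64))
    b_gen, b_cell, b_age = [], [], []
    for cell in cells:
        # canonical order: cohorts by age, so a save/load/save round trip
        # is byte-stable
        for cohort in sorted(sim.patches[cell].bank, key=lambda c: c.age):
            if cohort.n:
                b_gen.append(cohort.genomes)
                b_cell.append(np.tile(cell, (cohort.n, 1)))
                b_age.append(np.full(cohort.n, cohort.age, dtype=np.int64))
    L = sim.gparams.L
    np.save(path / "bank_genomes.npy",
            np.concatenate(b_gen) if b_gen else np.zeros((0, L, 2, N_TRAITS)))
    np.save(path / "bank_cells.npy",
            np.concatenate(b_cell) if b_cell else np.zeros((0, 2), dtype=np.int64))
    np.save(path / "bank_ages.npy",
            np.concatenate(b_age) if b_age else np.zeros(0, dtype=np.int64))
    meta = {
        "V_E": sim.gparams.V_E.tolist(),
        "V_s": sim.regime.V_s.tolist(),
        "k_c": sim.species.k_c,
        "grid_id": sim.grid_id,
        "L": sim.gparams.L,
    }
    (path / "meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1))


def load_snapshot(sim: Simulation, path: str | Path) -> None:
    """Restore population state saved by :func:`save_snapshot` into
    ``sim`` (which must have been built with the same landscape/params)."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta["L"] != sim.gparams.L:
        raise ValueError("snapshot locus count does not match simulation")
    sim.patches.clear()
    for stage in _STAGES:
        genomes = np.load(path / f"{stage}_genomes.npy")
        phen = np.load(path / f"{stage}_phenotypes.npy")
        cells = np.load(path / f"{stage}_cells.npy")
        for cell in np.unique(cells, axis=0) if cells.size else []:
            m = (cells == cell).all(axis=1)
            pool = Pool(genomes[m], genetics.genotypic_value(genomes[m]),
                        phen[m])
            setattr(sim.patch((int(cell[0]), int(cell[1]))), stage, pool)
    b_gen = np.load(path / "bank_genomes.npy")
    b_cells = np.load(path / "bank_cells.npy")
    b_ages = np.load(path / "bank_ages.npy")
    if b_cells.size:
        for cell in np.unique(b_cells, axis=0):
            m = (b_cells == cell).all(axis=1)
            patch = sim.patch((int(cell[0]), int(cell[1])))
            for age in np.unique(b_ages[m]):
                ma = m & (b_ages == age)
                patch.bank.append(SeedCohort(int(age), b_gen[ma]))
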