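"""Structured text configuration.

One YAML file drives a study. Sections map onto the parameter objects:
``species`` (preset name plus optional overrides), ``genetics``
(:class:`~evorange.genetics.GeneticParams` fields), ``selection``,
``fixture`` (:class:`~evorange.fixtures.FixtureSpec` fields),
``scenario`` and ``sim`` (:class:`~evorange.engine.SimConfig` fields
plus the master seed and replicate count). Unknown keys anywhere are
errors — silent typos in simulation configs are how wrong science
happens.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .demography import SPECIES_PRESETS, SpeciesParams
from .engine import SimConfig
from .fixtures import SEVERITIES, FixtureSpec
from .genetics import GeneticParams

__all__ = ["StudyConfig", "load_config"]


@dataclass
class StudyConfig:
    """Fully resolved configuration for one study."""

    species: SpeciesParams
    genetics: GeneticParams
    sim: SimConfig
    fixture: FixtureSpec
    severity: str = "moderate"
    seed: int = 1
    n_replicates: int = 3


def _build(cls, section: dict, label: str, **extra):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise KeyError(f"unknown keys in '{label}' section: {sorted(unknown)}")
    kwargs = dict(section)
    for key, value in kwargs.items():
        if isinstance(value, list):
            kwargs[key] = tuple(value)
    kwargs.update(extra)
    return cls(**kwargs)


def load_config(path: str | Path) -> StudyConfig:
    """Parse and validate a study configuration file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known_sections = {"species", "species_overrides", "genetics", "selection",
                      "fixture", "scenario", "sim"}
    unknown = set(raw) - known_sections
    if unknown:
        raise KeyError(f"unknown top-level sections: {sorted(unknown)}")

    preset = raw.get("species", "campanula")
    if preset not in SPECIES_PRESETS:
        raise KeyError(f"unknown species preset '{preset}' "
                       f"(available: {sorted(SPECIES_PRESETS)})")
    overrides = raw.get("species_overrides", {}) or {}
    species = _build(SpeciesParams,
                     {**dataclasses.asdict(SPECIES_PRESETS[preset]), **overrides},
                     "species_overrides")

    genetics_params = _build(GeneticParams, raw.get("genetics", {}) or {},
                             "genetics")

    selection = dict(raw.get("selection", {}) or {})
    vs_multiplier = selection.pop("vs_multiplier", 1.0)
    if selection:
        raise KeyError(f"unknown keys in 'selection' section: {sorted(selection)}")

    scenario = dict(raw.get("scenario", {}) or {})
    severity = scenario.pop("severity", "moderate")
    if severity not in SEVERITIES:
        raise KeyError(f"unknown scenario severity '{severity}'")
    if scenario:
        raise KeyError(f"unknown keys in 'scenario' section: {sorted(scenario)}")

    fixture = _build(FixtureSpec, raw.get("fixture", {}) or {}, "fixture")

    sim_section = dict(raw.get("sim", {}) or {})
    seed = int(sim_section.pop("seed", 1))
    n_replicates = int(sim_section.pop("n_replicates", 3))
    sim = _build(SimConfig, sim_section, "sim", vs_multiplier=vs_multiplier)

    return StudyConfig(species=species, genetics=genetics_params, sim=sim,
                       fixture=fixture, severity=severity, seed=seed,
                       n_replicates=n_replicates)
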