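"""Derived statistics over record tables.

The engine's scenario phase emits one row per occupied cell per record
year (stage counts, per-trait genotype/phenotype moments, mean seedling
adaptive survival, site suitability, occupancy flag). The functions here
reduce that table to the summary series used for reporting: occupancy
change relative to 2010, mean adaptive seedling survival, within-site
population size, age-structure frequencies, suitability of
occupied/unoccupied/colonized/extinct site classes, and rates of
environmental change in Haldanes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "occupancy_series",
    "occupancy_change",
    "adaptive_seedling_survival",
    "mean_adult_count",
    "age_structure",
    "suitability_classes",
    "haldane_rate",
    "occupied_cells",
]


def _occupied(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["occupied"]]


def occupied_cells(records: pd.DataFrame, year: int) -> set[tuple[int, int]]:
    """Set of (row, col) cells occupied at ``year``'s census."""
    sub = _occupied(records)
    sub = sub[sub["year"] == year]
    return set(zip(sub["row"].astype(int), sub["col"].astype(int)))


def occupancy_series(records: pd.DataFrame) -> pd.Series:
    """Number of occupied cells per record year."""
    return _occupied(records).groupby("year").size().rename("occupied")


def occupancy_change(records: pd.DataFrame, baseline_year: int = 2010
                     ) -> pd.Series:
    """Relative change in occupancy: (occupied(t) − occupied(2010)) /
    occupied(2010). Years with no occupied cell count as zero occupancy
    (change −1)."""
    occ = occupancy_series(records)
    years = sorted(records["year"].unique())
    occ = occ.reindex(years, fill_value=0)
    if baseline_year not in occ.index or occ.loc[baseline_year] == 0:
        raise ValueError(f"no occupancy recorded at baseline year {baseline_year}")
    base = occ.loc[baseline_year]
    return ((occ - base) / base).rename("occupancy_change")


def adaptive_seedling_survival(records: pd.DataFrame) -> pd.Series:
    """Mean seedling adaptive survival per year.

    Averages the per-cell mean survival weighted by seedling numbers,
    i.e. the plain mean over seedlings; competition with adults does not
    enter (the value is the Gaussian viability itself, recorded at the
    pre-selection census). Years without seedlings give NaN.
    """
    sub = records.dropna(subset=["adaptive_survival"])
    sub = sub[sub["n_seedling"] > 0]

    def _mean(g: pd.DataFrame) -> float:
        w = g["n_seedling"].to_numpy(dtype=float)
        return float(np.average(g["adaptive_survival"], weights=w))

    out = sub.groupby("year").apply(_mean, include_groups=False)
    years = sorted(records["year"].unique())
    return out.reindex(years).rename("adaptive_survival")


def mean_adult_count(records: pd.DataFrame) -> pd.Series:
    """Mean number of adults per occupied site, per year."""
    sub = _occupied(records)
    return sub.groupby("year")["n_adult"].mean().rename("adults_per_site")


def age_structure(records: pd.DataFrame) -> pd.DataFrame:
    """Frequencies of seedlings, pre-adults and adults among established
    plants, per year (seeds in the bank excluded)."""
    cols = ["n_seedling", "n_pre_adult", "n_adult"]
    tot = records.groupby("year")[cols].sum()
    denom = tot.sum(axis=1)
    out = tot.div(denom, axis=0)
    out.columns = ["seedling", "pre_adult", "adult"]
    return out


def suitability_classes(records: pd.DataFrame,
                        suitability_maps: dict[int, np.ndarray],
                        baseline_year: int = 2010) -> pd.DataFrame:
    """Mean site suitability (probability × 1,000) in four site classes.

    Classes per year: currently occupied, currently unoccupied,
    colonized since ``baseline_year`` and extinct since
    ``baseline_year``. After 2090 the 2090 suitability map is used
    (climate constant afterwards). Empty classes give NaN.
    """
    base = occupied_cells(records, baseline_year)
    if not base:
        raise ValueError(f"no occupancy recorded at {baseline_year}")
    years = sorted(records["year"].unique())
    rows = []
    for year in years:
        grid = suitability_maps.get(min(int(year), 2090))
        if grid is None:
            raise KeyError(f"no suitability map for year {year}")
        grid = np.asarray(grid, dtype=float)
        occ = occupied_cells(records, year)
        all_cells = {(r, c) for r in range(grid.shape[0])
                     for c in range(grid.shape[1])}
        classes = {
            "occupied": occ,
            "unoccupied": all_cells - occ,
            "colonized": occ - base,
            "extinct": base - occ,
        }
        row: dict = {"year": year}
        for name, cells in classes.items():
            if cells:
                vals = [grid[c] for c in sorted(cells)]
                row[name] = 1000.0 * float(np.mean(vals))
            else:
                row[name] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("year")


def haldane_rate(theta_series: np.ndarray, phenotypic_sd: float,
                 window: int = 1) -> float:
    """Rate of environmental change in Haldanes.

    Per-year change of the optimum over ``window`` years divided by the
    within-population phenotypic standard deviation of the trait.
    """
    theta_series = np.asarray(theta_series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1 year")
    if theta_series.shape[0] < window + 1:
        raise ValueError("theta series shorter than the window")
    if phenotypic_sd <= 0:
        raise ValueError("phenotypic standard deviation must be > 0")
    return float((theta_series[window] - theta_series[0]) / window
                 / phenotypic_sd)
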