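"""Density regulation and viability selection on seedlings.

Seedlings face two consecutive mortality filters each year:

1. *Competition* against established plants, with Beverton–Holt survival
   ``p = 1 / (1 + k_c · n_established)`` where ``k_c`` is the competitive
   weight of an established individual. Seedlings mostly compete against
   adults already holding favourable microsites, so seedling density
   itself does not enter the denominator.
2. *Gaussian stabilizing viability selection* on the three quantitative
   traits, ``p = exp(−½ (z−θ)' W⁻¹ (z−θ))`` with diagonal ``W`` (no
   correlated selection); the diagonal entries ``V_s,k`` are anchored to
   the niche width ``V_SENM`` of the corresponding environmental
   variable, so smaller ``V_s`` means stronger selection.

``k_c`` is calibrated so the deterministic single-patch equilibrium of a
perfectly adapted population matches a species' nominal maximum adult
number; realized simulated populations sit below that because of
migration and mutation loads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .demography import SpeciesParams, deterministic_equilibrium
from .genetics import N_TRAITS

__all__ = [
    "SelectionRegime",
    "competition_survival",
    "viability_survival",
    "expected_survival_at_optimum",
    "calibrate_kc",
    "ceiling_regulate_counts",
]

#: selection-variance multipliers explored in the sensitivity grid
VS_MULTIPLIERS = (1.0, 0.5, 0.33)


@dataclass
class SelectionRegime:
    """Diagonal stabilizing-selection regime.

    ``V_s`` holds one selection variance per trait, usually a multiple
    (1, 0.5 or 0.33) of the niche width ``V_SENM`` extracted from the
    static niche model.
    """

    V_s: np.ndarray = field(default_factory=lambda: np.ones(N_TRAITS))

    def __post_init__(self) -> None:
        self.V_s = np.asarray(self.V_s, dtype=float)
        if np.any(self.V_s <= 0):
            raise ValueError("selection variances V_s must be > 0")

    @classmethod
    def from_niche_width(cls, V_SENM: np.ndarray,
                         multiplier: float = 1.0) -> "SelectionRegime":
        return cls(np.asarray(V_SENM, dtype=float) * multiplier)


def competition_survival(n_established: float | np.ndarray,
                         k_c: float) -> float | np.ndarray:
    """Beverton–Holt seedling survival ``1 / (1 + k_c · n_established)``."""
    n = np.asarray(n_established, dtype=float)
    if np.any(n < 0) or k_c < 0:
        raise ValueError("n_established and k_c must be non-negative")
    out = 1.0 / (1.0 + k_c * n)
    return float(out) if out.ndim == 0 else out


def viability_survival(z: np.ndarray, theta: np.ndarray,
                       V_s: np.ndarray) -> float | np.ndarray:
    """Gaussian survival ``exp(−½ Σ_k (z_k − θ_k)² / V_s,k)``.

    Vectorised over a leading individual axis of ``z``.
    """
    V_s = np.asarray(V_s, dtype=float)
    if np.any(V_s <= 0):
        raise ValueError("selection variances V_s must be > 0")
    z = np.asarray(z, dtype=float)
    theta = np.asarray(theta, dtype=float)
    dev = z - theta
    out = np.exp(-0.5 * np.sum(dev * dev / V_s, axis=-1))
    return float(out) if out.ndim == 0 else out


def expected_survival_at_optimum(V_s: np.ndarray, V_P: np.ndarray) -> float:
    """Mean viability of a population centred on its optimum.

    For Gaussian phenotypic spread ``V_P,k`` per trait the expectation of
    ``exp(−z²/2V_s)`` is ``√(V_s / (V_s + V_P))``; the traits multiply.
    """
    V_s = np.asarray(V_s, dtype=float)
    V_P = np.asarray(V_P, dtype=float)
    return float(np.prod(np.sqrt(V_s / (V_s + V_P))))


def calibrate_kc(sp: SpeciesParams, target_K: int | None = None) -> float:
    """Competitive weight giving a deterministic adult equilibrium of
    ``target_K`` (defaults to the species preset ``K_max``) in a single
    perfectly adapted patch without selection mortality.

    Root-finds on ``log10 k_c``; the equilibrium is monotonically
    decreasing in ``k_c``. Raises if the life history cannot grow at
    zero density.
    """
    K = int(target_K if target_K is not None else sp.K_max)
    if K <= 0:
        raise ValueError("target_K must be > 0")

    def gap(log_kc: float) -> float:
        eq = deterministic_equilibrium(sp, 10.0 ** log_kc)
        return eq["adults"] - K

    lo, hi = -8.0, 4.0
    if gap(lo) < 0:
        raise ValueError("target_K unreachable even without competition")
    kc_log = optimize.brentq(gap, lo, hi, xtol=1e-10)
    return 10.0 ** kc_log


def ceiling_regulate_counts(n_established: int, K_ceiling: int,
                            rng: np.random.Generator) -> np.ndarray | None:
    """Indices of established individuals retained under a hard ceiling.

    Returns ``None`` when no truncation is needed; an empty index array
    when ``K_ceiling`` is 0 (site predicted unoccupied: patch emptied);
    otherwise a uniform random subset of size ``K_ceiling``.
    """
    if K_ceiling < 0:
        raise ValueError("K_ceiling must be >= 0")
    if K_ceiling == 0:
        return np.zeros(0, dtype=np.int64)
    if n_established <= K_ceiling:
        return None
    return rng.choice(n_established, size=K_ceiling, replace=False)
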