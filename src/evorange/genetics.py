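"""Diploid multilocus pleiotropic genetics.

Each individual carries ``L`` unlinked, additive diploid loci. Every allele
is a length-``T`` vector of real effects, one per quantitative trait
(``T = 3`` by default: one trait per environmental variable). Mutation
follows a continuum-of-alleles model: a mutation adds a draw from an
isotropic ``T``-dimensional Gaussian, ``N(0, v·I)``, to the existing
allelic effect vector, so allelic values random-walk rather than being
resampled. The genotypic value of a trait is the plain sum of its 2L
allelic effects; the phenotype adds an independent Gaussian environmental
deviation per trait.

All operations are vectorised over a leading population axis: a single
genome is an array of shape ``(L, 2, T)``, a population is
``(N, L, 2, T)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "N_TRAITS",
    "GeneticParams",
    "new_genomes",
    "mutate",
    "inherit",
    "genotypic_value",
    "express_phenotype",
    "calibrate_VE",
    "estimate_heritability",
    "founder_genomes",
    "genomes_to_table",
    "genomes_from_table",
]

#: number of quantitative traits (one per environmental variable)
N_TRAITS = 3


def _default_VE() -> np.ndarray:
    return np.zeros(N_TRAITS)


@dataclass
class GeneticParams:
    """Constants of the genetic architecture.

    Parameters
    ----------
    L:
        Number of unlinked additive diploid loci (default 10).
    mu:
        Per-allele mutation probability per genome-copying event.
    v:
        Variance of each trait component of a mutational effect
        (isotropic, no mutational correlation). Default 0.05.
    V_E:
        Per-trait environmental variance added on top of the genotypic
        value when a phenotype is expressed. Calibrated so that the
        average founding heritability hits ``h2_target``.
    h2_target:
        Narrow-sense heritability aimed for at initialisation (~0.3).
    """

    L: int = 10
    mu: float = 0.001
    v: float = 0.05
    V_E: np.ndarray = field(default_factory=_default_VE)
    h2_target: float = 0.3

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mutation rate mu must lie in [0, 1]")
        if self.v < 0:
            raise ValueError("mutational variance v must be >= 0")
        self.V_E = np.asarray(self.V_E, dtype=float)
        if self.V_E.shape != (N_TRAITS,):
            raise ValueError(f"V_E must have shape ({N_TRAITS},)")
        if np.any(self.V_E < 0):
            raise ValueError("environmental variances must be >= 0")

    @property
    def mutational_variance(self) -> float:
        """Per-trait mutational variance injected per patch per
        generation, ``2·L·mu·v``."""
        return 2.0 * self.L * self.mu * self.v


def new_genomes(n: int, L: int = 10, T: int = N_TRAITS) -> np.ndarray:
    """Allocate ``n`` all-zero genomes of shape ``(n, L, 2, T)``."""
    return np.zeros((n, L, 2, T))


def _check_genomes(genomes: np.ndarray) -> np.ndarray:
    g = np.asarray(genomes, dtype=float)
    if g.ndim < 3 or g.shape[-2] != 2:
        raise ValueError(
            "genomes must have shape (..., L, 2, T); got %r" % (g.shape,)
        )
    return g


def mutate(genomes: np.ndarray, params: GeneticParams, rng: np.random.Generator,
           rate: float | None = None) -> np.ndarray:
    """Mutate every allele independently with probability ``params.mu``.

    Each mutating allele receives an additive effect vector drawn from
    ``N(0, v·I_T)`` (continuum of alleles). Returns a new array; the
    input is not modified. ``rate`` overrides ``params.mu`` (used for
    founder jittering).
    """
    g = _check_genomes(genomes)
    mu = params.mu if rate is None else rate
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    if params.v < 0:
        raise ValueError("mutational variance v must be >= 0")
    out = g.copy()
    if mu == 0.0 or out.size == 0:
        return out
    hit = rng.random(out.shape[:-1]) < mu  # one Bernoulli per allele copy
    n_hit = int(hit.sum())
    if n_hit:
        out[hit] += rng.normal(0.0, np.sqrt(params.v), size=(n_hit, out.shape[-1]))
    return out


def inherit(mothers: np.ndarray, fathers: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Mendelian transmission with free recombination.

    At every locus the offspring receives one of the mother's two
    homologous alleles (uniformly) and one of the father's. Accepts
    matched stacks of parental genomes ``(N, L, 2, T)`` and returns the
    ``N`` offspring genomes.
    """
    m = _check_genomes(mothers)
    f = _check_genomes(fathers)
    if m.shape != f.shape:
        raise ValueError("maternal and paternal genome stacks must match")
    single = m.ndim == 3
    if single:
        m = m[None]
        f = f[None]
    n, L, _, T = m.shape
    out = np.empty((n, L, 2, T))
    pick_m = rng.integers(0, 2, size=(n, L))
    pick_f = rng.integers(0, 2, size=(n, L))
    ix_n = np.arange(n)[:, None]
    ix_l = np.arange(L)[None, :]
    out[:, :, 0, :] = m[ix_n, ix_l, pick_m, :]
    out[:, :, 1, :] = f[ix_n, ix_l, pick_f, :]
    return out[0] if single else out


def genotypic_value(genomes: np.ndarray) -> np.ndarray:
    """Per-trait sum of all 2L allelic effects (fully additive)."""
    g = _check_genomes(genomes)
    return g.sum(axis=(-3, -2))


def express_phenotype(g: np.ndarray, V_E: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Phenotype = genotypic value + independent ``N(0, V_E,k)`` noise."""
    g = np.asarray(g, dtype=float)
    V_E = np.asarray(V_E, dtype=float)
    if np.any(V_E < 0):
        raise ValueError("environmental variances must be >= 0")
    return g + rng.normal(0.0, np.sqrt(V_E), size=g.shape)


def calibrate_VE(V_G: np.ndarray, h2_target: float) -> np.ndarray:
    """Environmental variances giving heritability ``h2_target`` per trait.

    Solves ``V_G / (V_G + V_E) = h2`` for ``V_E``:
    ``V_E = V_G · (1 − h2) / h2``.
    """
    if not 0.0 < h2_target < 1.0:
        raise ValueError("h2_target must lie strictly in (0, 1)")
    V_G = np.asarray(V_G, dtype=float)
    if np.any(V_G <= 0):
        raise ValueError("genetic variances must be > 0 to calibrate V_E")
    return V_G * (1.0 - h2_target) / h2_target


def estimate_heritability(genotypes: np.ndarray,
                          phenotypes: np.ndarray) -> np.ndarray:
    """Narrow-sense h² per trait: sample V_G over sample V_P."""
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    Z = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    if G.shape != Z.shape or G.shape[0] < 2:
        raise ValueError("need matched genotype/phenotype arrays of >= 2 individuals")
    V_P = Z.var(axis=0, ddof=1)
    if np.any(V_P == 0):
        raise ZeroDivisionError("phenotypic variance is zero for some trait")
    return G.var(axis=0, ddof=1) / V_P


def founder_genomes(n: int, optimum: np.ndarray, params: GeneticParams,
                    rng: np.random.Generator, rounds: int = 100) -> np.ndarray:
    """Locally adapted founders with standing variation.

    All 2L alleles start at ``optimum / (2L)`` per trait, so the
    genotypic value equals the local environmental optimum; ``rounds``
    applications of the standard mutation operator then build standing
    variation (expected per-trait genetic variance ≈ ``rounds·2·L·mu·v``,
    which for the default rates sits near the mutation–selection-balance
    variance, keeping the heritability calibration valid through time).
    """
    optimum = np.asarray(optimum, dtype=float)
    g = np.broadcast_to(
        optimum / (2 * params.L), (n, params.L, 2, optimum.shape[-1])
    ).copy()
    for _ in range(rounds):
        g = mutate(g, params, rng)
    return g


def genomes_to_table(genomes: np.ndarray) -> pd.DataFrame:
    """Flatten a genome stack to one row per (individual, locus, copy)."""
    g = _check_genomes(genomes)
    if g.ndim == 3:
        g = g[None]
    n, L, _, T = g.shape
    idx = pd.MultiIndex.from_product(
        [range(n), range(L), range(2)], names=["individual", "locus", "copy"]
    )
    cols = [f"trait_{k}" for k in range(T)]
    return pd.DataFrame(g.reshape(n * L * 2, T), index=idx, columns=cols).reset_index()


def genomes_from_table(table: pd.DataFrame) -> np.ndarray:
    """Inverse of :func:`genomes_to_table`."""
    trait_cols = [c for c in table.columns if c.startswith("trait_")]
    T = len(trait_cols)
    tab = table.sort_values(["individual", "locus", "copy"])
    n = tab["individual"].nunique()
    L = tab["locus"].nunique()
    return tab[trait_cols].to_numpy().reshape(n, L, 2, T)
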