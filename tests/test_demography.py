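"""Stage-structured life cycle: reproduction, aging, seedbank, clonality,
and agreement of the stochastic demography with deterministic oracles."""

import numpy as np
import pytest

from evorange import demography
from evorange.demography import Patch, Pool, SeedCohort, SPECIES_PRESETS, \
    SpeciesParams, age_and_survive, deterministic_equilibrium, \
    effective_germination_rate, reproduce_clonal, reproduce_sexual, \
    seedbank_step, simulate_patch_counts
from evorange.genetics import GeneticParams, genotypic_value


def _patch_with_adults(n, rng, L=10, value=0.0):
    genomes = np.full((n, L, 2, 3), value / (2 * L))
    patch = Patch.empty(L)
    patch.adults = Pool.from_genomes(genomes, np.zeros(3), rng)
    return patch


def test_no_adults_no_seeds(rng):
    sp = SPECIES_PRESETS["campanula"]
    seeds = reproduce_sexual(Patch.empty(10), sp, GeneticParams(), rng)
    assert seeds.shape[0] == 0


def test_single_adult_poisson_fecundity(rng):
    sp = SpeciesParams(fecundity=8.0)
    gp = GeneticParams(mu=0.0)
    counts = [reproduce_sexual(_patch_with_adults(1, rng), sp, gp, rng).shape[0]
              for _ in range(400)]
    assert np.mean(counts) == pytest.approx(8.0, rel=0.08)


def test_offspring_alleles_follow_mendelian_expectation(rng):
    """Two homozygous parents with distinct alleles: offspring allele
    frequencies match the enumeration expectation (1/2 each)."""
    sp = SpeciesParams(fecundity=50.0)
    gp = GeneticParams(mu=0.0)
    patch = Patch.empty(10)
    g = np.zeros((2, 10, 2, 3))
    g[0] = 1.0 / 20  # parent A: genotypic value 1 per trait
    patch.adults = Pool.from_genomes(g, np.zeros(3), rng)
    seeds = reproduce_sexual(patch, sp, gp, rng)
    # every allele is one of the two parental values
    assert set(np.round(np.unique(seeds), 6)) <= {0.0, 0.05}
    freq_A = (seeds[:, :, :, 0] > 0).mean()
    assert freq_A == pytest.approx(0.5, abs=0.06)


def test_adults_immortal_at_full_survival(rng):
    sp = SpeciesParams(s_a=1.0)
    patch = _patch_with_adults(137, rng)
    age_and_survive(patch, sp, rng)
    assert patch.adults.n == 137


def test_two_pre_adult_years_before_adulthood(rng):
    """A seedling cohort passes exactly two pre-adult censuses and joins
    the reproductive adults in its third year after germination."""
    sp = SpeciesParams(s_a=1.0)
    patch = Patch.empty(10)
    patch.seedlings = Pool.from_genomes(np.zeros((20, 10, 2, 3)),
                                        np.zeros(3), np.random.default_rng(0))
    stages = []
    for _ in range(3):
        age_and_survive(patch, sp, np.random.default_rng(0))
        stages.append((patch.seedlings.n, patch.pre1.n, patch.pre2.n,
                       patch.adults.n))
    assert stages[0] == (0, 20, 0, 0)   # first pre-adult year
    assert stages[1] == (0, 0, 20, 0)   # second pre-adult year
    assert stages[2] == (0, 0, 0, 20)   # reproductive adults


def test_adult_life_expectancy_is_geometric(rng):
    """Mean adult lifespan at s_a = 0.9 is 1/(1-s_a) = 10 years."""
    sp = SpeciesParams(s_a=0.9)
    patch = _patch_with_adults(4000, rng)
    alive, lifespans, year = patch.adults.n, [], 0
    while patch.adults.n:
        year += 1
        before = patch.adults.n
        age_and_survive(patch, sp, rng)
        lifespans += [year] * (before - patch.adults.n)
    assert np.mean(lifespans) == pytest.approx(10.0, rel=0.08)


def test_full_germination_empties_bank(rng):
    sp = SpeciesParams(germination_rate=1.0, max_seed_age=5)
    bank = [SeedCohort(0, np.ones((40, 10, 2, 3))),
            SeedCohort(2, np.ones((15, 10, 2, 3)))]
    germ, bank = seedbank_step(bank, sp, rng)
    assert germ.shape[0] == 55
    assert bank == []


def test_seedbank_max_age_primula(rng):
    """With germination disabled, a cohort persists in the bank to age 7
    and no further (Primula-type longevity)."""
    sp = SpeciesParams(germination_rate=0.0, seed_survival=1.0, max_seed_age=7)
    bank = [SeedCohort(0, np.zeros((10, 10, 2, 3)))]
    seen = []
    for _ in range(10):
        germ, bank = seedbank_step(bank, sp, rng)
        assert germ.shape[0] == 0
        seen += [c.age for c in bank]
    assert max(seen) == 7
    assert bank == []  # discarded after exceeding max age


def test_no_seedbank_species_seeds_do_not_persist(rng):
    """Campanula-type seeds (max age 1) germinate exactly one year after
    production or die; none persist past their second bank step."""
    sp = SPECIES_PRESETS["campanula"]
    bank = [SeedCohort(0, np.zeros((500, 10, 2, 3)))]
    germ1, bank = seedbank_step(bank, sp, rng)
    assert germ1.shape[0] > 0  # first opportunity, one year after seed set
    germ2, bank = seedbank_step(bank, sp, rng)
    assert germ2.shape[0] == 0
    assert bank == []


def test_seedbank_bookkeeping_conserved(rng):
    """Germinated + surviving + dead + discarded seeds add up to the
    previous bank exactly."""
    sp = SpeciesParams(germination_rate=0.4, seed_survival=1.0, max_seed_age=5)
    bank = [SeedCohort(a, np.zeros((100, 10, 2, 3))) for a in range(5)]
    total_before = sum(c.n for c in bank)
    discarded = sum(c.n for c in bank if c.age + 1 > sp.max_seed_age)
    germ, bank_after = seedbank_step(bank, sp, rng)
    # seed_survival=1: non-germinating survivors all remain
    assert germ.shape[0] + sum(c.n for c in bank_after) + discarded \
        == total_before


def test_clonal_reproduction(rng):
    sp = SpeciesParams(clonal_rate=0.0)
    gp = GeneticParams(mu=0.0)
    patch = _patch_with_adults(50, rng)
    assert reproduce_clonal(patch, sp, gp, rng).shape[0] == 0
    sp = SpeciesParams(clonal_rate=2.0)
    clones = reproduce_clonal(patch, sp, gp, rng)
    assert clones.shape[0] == pytest.approx(100, rel=0.3)
    # with mutation off, clones are genetic copies of their parents
    np.testing.assert_allclose(
        genotypic_value(clones),
        np.tile(patch.adults.genotypes[0], (clones.shape[0], 1)), atol=1e-12)


def test_effective_germination_rate_matches_enumeration():
    sp = SpeciesParams(germination_rate=0.25, seed_survival=0.4, max_seed_age=5)
    g, s = 0.25, 0.4
    brute = sum(g * ((1 - g) * s) ** (a - 1) for a in range(1, 6))
    assert effective_germination_rate(sp) == pytest.approx(brute, rel=1e-12)


def test_infeasible_life_history_signalled():
    sp = SpeciesParams(fecundity=0.05, germination_rate=0.1, clonal_rate=0.0,
                       s_a=0.7)
    with pytest.raises(ValueError, match="infeasible"):
        deterministic_equilibrium(sp, 0.1)


def test_stochastic_equilibrium_matches_deterministic_recursion(rng):
    """Single-patch stochastic adult numbers fluctuate around the
    deterministic fixed point (large-K preset)."""
    sp = SPECIES_PRESETS["festuca"]
    k_c = 0.0038
    eq = deterministic_equilibrium(sp, k_c)
    res = simulate_patch_counts(sp, k_c, 500, rng)
    mean_adults = res["adults"][-200:].mean()
    assert mean_adults == pytest.approx(eq["adults"], rel=0.05)


def _hand_projection_matrix(sp: SpeciesParams, c: float, w: float) -> np.ndarray:
    """Yearly projection for state [b0, b1, S_sel, P1, P2, N] of a
    max_seed_age=1 species at frozen competition survival c, written out
    entry by entry (independent of the package's recursion code)."""
    g, ss, f, r, sa = (sp.germination_rate, sp.seed_survival, sp.fecundity,
                       sp.clonal_rate, sp.s_a)
    M = np.zeros((6, 6))
    M[0, 5] = f                       # fresh seeds from adults
    M[1, 0] = (1 - g) * ss            # bank survivors age 0 -> 1
    # seedlings: germination of age-0 cohort + clonal from post-aging
    # established (N' = sa N + sa P2, P1' = S_sel, P2' = sa P1)
    M[2, 0] = w * c * g
    M[2, 2] = w * c * r               # clonal from P1' = S_sel
    M[2, 3] = w * c * r * sa          # from P2' = sa P1
    M[2, 4] = w * c * r * sa          # from N' part sa P2
    M[2, 5] = w * c * r * sa          # from N' part sa N
    M[3, 2] = 1.0                     # S_sel -> P1
    M[4, 3] = sa                      # P1 -> P2
    M[5, 4] = sa                      # P2 -> N
    M[5, 5] = sa                      # adult survival
    return M


def test_stable_age_structure_matches_leading_eigenvector(rng):
    """Census stage frequencies converge to the stable structure given by
    the leading eigenvector of the hand-built stage projection matrix."""
    sp = SPECIES_PRESETS["festuca"]
    k_c, w = 0.0038, 1.0
    res = simulate_patch_counts(sp, k_c, 600, rng)
    tail = {k: res[k][-300:].mean() for k in res}
    n_est = tail["adults"] + tail["pre1"] + tail["pre2"]
    c = 1.0 / (1.0 + k_c * n_est)
    M = _hand_projection_matrix(sp, c, w)
    vals, vecs = np.linalg.eig(M)
    lead = np.argmax(vals.real)
    assert vals[lead].real == pytest.approx(1.0, abs=0.02)  # at equilibrium
    v = np.abs(vecs[:, lead].real)
    # census seedlings are pre-selection: S_census = S_sel / w
    stages = np.array([v[2] / w, v[3], v[4], v[5]])
    stages /= stages.sum()
    observed = np.array([tail["seedlings"], tail["pre1"], tail["pre2"],
                         tail["adults"]])
    observed /= observed.sum()
    np.testing.assert_allclose(observed, stages, atol=0.02)


def test_age_structure_ordering_under_selection_load(rng):
    """With realistic seedling selection mortality the stable structure is
    dominated by adults, then seedlings, then pre-adults."""
    sp = SPECIES_PRESETS["campanula"]
    k_c = 0.0984
    res = simulate_patch_counts(sp, k_c, 500, rng, selection_survival=0.3)
    adults = res["adults"][-200:].mean()
    seedlings = res["seedlings"][-200:].mean()
    pre = (res["pre1"] + res["pre2"])[-200:].mean()
    assert adults > seedlings > pre


def test_stage_flow_no_stage_skipping(rng):
    """Next year's first-year pre-adults are exactly this year's
    post-selection seedlings: nobody skips a stage."""
    sp = SPECIES_PRESETS["campanula"]
    res = simulate_patch_counts(sp, 0.0984, 200, rng, selection_survival=0.5)
    # pre1 counts lag post-selection seedlings; with selection_survival
    # applied binomially we can only bound: pre1(t+1) <= seedlings(t)
    assert np.all(res["pre1"][1:] <= res["seedlings"][:-1])
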