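"""Genetic architecture: continuum-of-alleles mutation, Mendelian
transmission, additive genotype-phenotype map, heritability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evorange import genetics
from evorange.genetics import GeneticParams, calibrate_VE, estimate_heritability, \
    express_phenotype, genotypic_value, inherit, mutate


def test_zero_mutation_rate_is_identity(rng):
    gp = GeneticParams(mu=0.0)
    g = rng.normal(size=(50, 10, 2, 3))
    out = mutate(g, gp, rng)
    np.testing.assert_array_equal(out, g)


def test_negative_mutational_variance_rejected():
    with pytest.raises(ValueError):
        GeneticParams(v=-0.1)


def test_mutational_effects_isotropic(rng):
    """Mutation effects have per-trait variance v = 0.05 and no
    cross-trait correlation."""
    gp = GeneticParams()
    g = np.zeros((60000, 1, 2, 3))  # 120k alleles
    eff = mutate(g, gp, rng, rate=1.0).reshape(-1, 3)
    var = eff.var(axis=0, ddof=1)
    se = gp.v * np.sqrt(2.0 / (eff.shape[0] - 1))
    assert np.all(np.abs(var - gp.v) < 3 * se)
    cov = np.cov(eff.T)
    off = cov[~np.eye(3, dtype=bool)]
    assert np.all(np.abs(off) < 0.003)


def test_per_patch_mutational_variance_is_2Lmuv(rng):
    """Per-generation genotypic variance injected by mutation matches the
    closed form 2·L·mu·v (Monte-Carlo vs printed formula)."""
    gp = GeneticParams(mu=0.01)
    g = np.zeros((50000, gp.L, 2, 3))
    increments = genotypic_value(mutate(g, gp, rng))
    var = increments.var(axis=0, ddof=1)
    expected = gp.mutational_variance
    assert expected == pytest.approx(2 * 10 * 0.01 * 0.05)
    # variance of a compound Bernoulli-normal sum; 3 MC standard errors
    assert np.all(np.abs(var - expected) < 0.1 * expected)


def test_inherit_identical_homozygous_parents(rng):
    allele = np.array([0.2, 0.0, -0.1])
    parent = np.tile(allele, (10, 2, 1))
    child = inherit(parent, parent, rng)
    np.testing.assert_array_equal(child, parent)


def test_inherit_mendelian_transmission(rng):
    """A heterozygous locus transmits each allele at frequency 1/2."""
    mother = np.zeros((10000, 1, 2, 3))
    mother[:, 0, 0, 0] = 1.0  # heterozygote 1/0
    father = np.zeros_like(mother)
    child = inherit(mother, father, rng)
    freq = child[:, 0, 0, 0].mean()
    assert freq == pytest.approx(0.5, abs=0.02)


def test_inherit_free_recombination_gamete_types(rng):
    """A double heterozygote produces all four gamete types at 1/4
    (brute-force expectation for unlinked loci)."""
    n = 20000
    mother = np.zeros((n, 2, 2, 3))
    mother[:, :, 0, 0] = 1.0  # allele "1" on copy 0 at both loci
    father = np.zeros_like(mother)
    child = inherit(mother, father, rng)
    maternal = child[:, :, 0, 0]  # 1 if copy-0 allele transmitted
    types, counts = np.unique(maternal, axis=0, return_counts=True)
    assert len(types) == 4
    np.testing.assert_allclose(counts / n, 0.25, atol=0.02)


def test_inherit_mismatched_loci_rejected(rng):
    with pytest.raises(ValueError):
        inherit(np.zeros((5, 10, 2, 3)), np.zeros((5, 8, 2, 3)), rng)


def test_genotypic_value_examples(rng):
    assert np.array_equal(genotypic_value(np.zeros((10, 2, 3))), np.zeros(3))
    g = np.zeros((10, 2, 3))
    g[3, 1] = [0.2, 0.0, -0.1]
    np.testing.assert_allclose(genotypic_value(g), [0.2, 0.0, -0.1])


def test_genotypic_value_matches_naive_double_loop(rng):
    g = rng.normal(size=(4, 10, 2, 3))
    fast = genotypic_value(g)
    slow = np.zeros((4, 3))
    for i in range(4):
        for l in range(10):
            for c in range(2):
                slow[i] += g[i, l, c]
    np.testing.assert_allclose(fast, slow, rtol=1e-12)


@settings(derandomize=True, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_genotypic_value_permutation_invariant(seed):
    r = np.random.default_rng(seed)
    g = r.normal(size=(10, 2, 3))
    base = genotypic_value(g)
    perm = r.permutation(10)
    np.testing.assert_allclose(genotypic_value(g[perm]), base, rtol=1e-12)
    np.testing.assert_allclose(genotypic_value(g[:, ::-1]), base, rtol=1e-12)


def test_express_phenotype_zero_VE_identity(rng):
    g = rng.normal(size=(100, 3))
    np.testing.assert_array_equal(express_phenotype(g, np.zeros(3), rng), g)


def test_express_phenotype_variance_and_independence(rng):
    V_E = np.array([0.5, 1.0, 2.0])
    g = np.zeros((100000, 3))
    dev = express_phenotype(g, V_E, rng)
    np.testing.assert_allclose(dev.var(axis=0, ddof=1), V_E, rtol=0.05)
    cov = np.cov(dev.T)
    assert np.all(np.abs(cov[~np.eye(3, dtype=bool)]) < 0.03)


def test_calibrate_VE_algebra():
    np.testing.assert_allclose(calibrate_VE(np.ones(3), 0.5), np.ones(3))
    np.testing.assert_allclose(calibrate_VE(np.full(3, 0.3), 0.3),
                               np.full(3, 0.7), rtol=1e-12)
    with pytest.raises(ValueError):
        calibrate_VE(np.ones(3), 1.0)
    with pytest.raises(ValueError):
        calibrate_VE(np.zeros(3), 0.3)


def test_heritability_roundtrip(rng):
    """Phenotypes built with the calibrated V_E recover the target h2."""
    g = rng.normal(0.0, 1.0, size=(50000, 3))
    V_G = g.var(axis=0, ddof=1)
    V_E = calibrate_VE(V_G, 0.3)
    z = express_phenotype(g, V_E, rng)
    h2 = estimate_heritability(g, z)
    np.testing.assert_allclose(h2, 0.3, atol=0.01)


def test_estimate_heritability_limits(rng):
    g = rng.normal(size=(500, 3))
    assert np.allclose(estimate_heritability(g, g), 1.0)
    same = np.zeros((500, 3))
    z = express_phenotype(same, np.ones(3), rng)
    assert np.allclose(estimate_heritability(same, z), 0.0)
    with pytest.raises(ZeroDivisionError):
        estimate_heritability(same, same)


def test_neutral_heterozygosity_decay(rng):
    """With selection off and constant N, expected heterozygosity of a
    biallelic marker decays as (1 - 1/(2N))^t (Wright-Fisher oracle)."""
    N, T, reps = 30, 25, 400
    pop = np.zeros((reps * N, 1, 2, 3))
    pop[:, 0, 0, 0] = 1.0  # every individual heterozygous: H0 = 0.5
    for _ in range(T):
        mothers = (rng.integers(0, N, size=reps * N)
                   + np.repeat(np.arange(reps) * N, N))
        fathers = (rng.integers(0, N, size=reps * N)
                   + np.repeat(np.arange(reps) * N, N))
        pop = inherit(pop[mothers], pop[fathers], rng)
    alleles = pop[:, 0, :, 0].reshape(reps, 2 * N)
    p = alleles.mean(axis=1)
    H = 2 * p * (1 - p)
    expected = 0.5 * (1 - 1 / (2 * N)) ** T
    se = H.std(ddof=1) / np.sqrt(reps)
    assert abs(H.mean() - expected) < 3 * se + 1e-9


def test_genome_table_roundtrip(rng):
    g = rng.normal(size=(7, 5, 2, 3))
    table = genetics.genomes_to_table(g)
    assert len(table) == 7 * 5 * 2
    back = genetics.genomes_from_table(table)
    np.testing.assert_allclose(back, g, rtol=1e-12)
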