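"""Pleiotropic mutation and heritability calibration.

Draws mutational effect vectors from the continuum-of-alleles operator,
verifies their per-trait variance and the per-patch variance input
2·L·mu·v, then calibrates environmental variances so a founder
population hits the target heritability.
"""

import numpy as np

from evorange import genetics
from evorange.engine import _founder_population, calibrate_VE_from_founders
from evorange.genetics import GeneticParams

rng = np.random.default_rng(1)
gp = GeneticParams(mu=0.01)

effects = genetics.mutate(np.zeros((50000, 1, 2, 3)), gp, rng,
                          rate=1.0).reshape(-1, 3)
print("per-trait mutational effect variance:",
      np.round(effects.var(axis=0, ddof=1), 4))
print("  (each mutation adds N(0, v) per trait; v =", gp.v, ")")

increments = genetics.genotypic_value(
    genetics.mutate(np.zeros((50000, gp.L, 2, 3)), gp, rng))
print("per-generation genotypic variance injected:",
      np.round(increments.var(axis=0, ddof=1), 5),
      "~ 2*L*mu*v =", gp.mutational_variance)

gp = GeneticParams(mu=0.001)
V_E, V_G = calibrate_VE_from_founders(gp, rng, n=3000)
genomes = _founder_population(5000, np.zeros(3), gp, rng)
g = genetics.genotypic_value(genomes)
z = genetics.express_phenotype(g, V_E, rng)
print("founder V_G:", np.round(V_G, 4), "-> calibrated V_E:", np.round(V_E, 4))
print("realized narrow-sense h2 per trait:",
      np.round(genetics.estimate_heritability(g, z), 3),
      "(target", gp.h2_target, ")")
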