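"""Multi-environment BLUPs, variance components and heritability.

Phenotypes follow y = mu + sum(a_q x_q) + ge + e over 6 environments x
2 replicates; the variance decomposition yields entry-mean broad-sense
heritability and shrunken line values for QTL mapping.
"""

from dhqtl import ObservationModel, SimConfig
from dhqtl.pheno import (
    blup_table,
    fit_variance_components,
    heritability,
    trait_correlations,
)
from dhqtl.simulate import QtlEffect, QtlSpec, simulate_population

spec = QtlSpec(
    qtls=[QtlEffect("LA1", 1, 40.0, 2.0), QtlEffect("LA2", 1, 40.0, 2.0),
          QtlEffect("LA2", 2, 70.0, 1.5), QtlEffect("TBA", 2, 30.0, 2.5)],
    mu={"LA1": 32.0, "LA2": 31.0, "TBA": 32.3},
    sigma2_ge=1.0, sigma2_e=4.0, n_env=6, n_rep=2, binary_locus=None)

config = SimConfig.small(n_chrom=2, n_snps=300, n_lines=571, seed=3)
_, pheno, _ = simulate_population(config, ObservationModel(), spec)

for trait in ["LA1", "LA2", "TBA"]:
    vc = fit_variance_components(pheno, trait)
    print(f"{trait}: s2_g={vc.sigma2_g:5.2f} s2_ge={vc.sigma2_ge:5.2f} "
          f"s2_e={vc.sigma2_e:5.2f}  H2={heritability(vc):.3f}")

blups = blup_table(pheno)
print("\ntrait correlations of BLUPs (LA1/LA2 share a QTL, TBA does not):")
print(trait_correlations(blups).round(3).to_string())
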