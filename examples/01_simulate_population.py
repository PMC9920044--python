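"""Simulate a small doubled-haploid population with known ground truth.

Each DH line carries one meiosis worth of crossovers (Poisson process on
the genetic map, no interference) and is observed through a sparse,
error-prone genotyping model.
"""

from dhqtl import ObservationModel, SimConfig
from dhqtl.simulate import simulate_population

config = SimConfig.small(n_chrom=2, n_snps=1000, n_lines=200, seed=1)
obs = ObservationModel(missing_rate=0.3, error_rate=0.02, het_rate=0.02)
matrix, _, truth = simulate_population(config, obs)

missing = (matrix.calls == -1).mean()
het = (matrix.calls == 2).mean()
print(f"lines x markers : {matrix.n_lines} x {matrix.n_markers}")
print(f"missing fraction: {missing:.3f} (target 0.30)")
print(f"het-call fraction among observed: {het / (1 - missing):.3f}")
print(f"true crossovers : {len(truth.crossovers)} "
      f"({len(truth.crossovers) / matrix.n_lines:.2f} per line; "
      "2 chromosomes x 1 Morgan each -> expect ~2)")
print(truth.crossovers.head().to_string(index=False))
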