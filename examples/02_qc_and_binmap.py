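"""Quality control and sliding-window genotype correction.

QC removes low-depth calls, distorted markers and heterozygous
lines/markers; the bin-map stage then votes 15-SNP windows, resolves
recombination breakpoints, and projects clean block genotypes back
onto the markers.
"""

import numpy as np

from dhqtl import ObservationModel, SimConfig, run_binmap, run_qc
from dhqtl.simulate import simulate_population

config = SimConfig.small(n_chrom=2, n_snps=1000, n_lines=200, seed=1)
obs = ObservationModel(missing_rate=0.3, error_rate=0.02, het_rate=0.02)
matrix, _, truth = simulate_population(config, obs)

filtered, report = run_qc(matrix)
print(f"QC: {report.cells_set_missing_depth} low-depth calls masked, "
      f"{report.snps_removed_segregation} distorted SNPs removed, "
      f"{report.surviving_lines} lines x {report.surviving_snps} SNPs kept")

corrected, blocks, breakpoints = run_binmap(filtered)
acc = (corrected.calls == truth.true_calls).mean()
print(f"binmap: {len(blocks)} blocks, {len(breakpoints)} breakpoints")
print(f"marker-level agreement with simulated truth: {acc:.4f}")

# how close do detected breakpoints land to the true crossovers?
errs = []
for (line, chrom), sub in truth.crossovers.groupby(["line", "chrom"]):
    det = breakpoints[(breakpoints.line == line)
                      & (breakpoints.chrom == chrom)]["pos_bp"].to_numpy()
    for xo in sub["pos_bp"]:
        if len(det):
            errs.append(np.min(np.abs(det - xo)))
print(f"median breakpoint localization error: {np.median(errs) / 1e3:.0f} kb")
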