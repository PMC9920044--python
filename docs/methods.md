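# Methods

This note documents the models, rules and numerical choices behind each
stage of `dhqtl`, the parameters that matter, and what the synthetic
population generator does and does not emulate.

## The population and its simulator

A doubled-haploid (DH) line is fully homozygous and carries the
recombination of exactly one meiosis. The generator
(`dhqtl.simulate`) draws, per chromosome of genetic length *L* cM, a
crossover count from Poisson(*L*/100) with positions i.i.d. uniform on
the cM scale — a no-interference model, deliberately consistent with
the Haldane mapping function used in map estimation and in the
conditional genotype probabilities of the scan stage. Physical
positions come from linear interpolation of the marker cM↔bp map;
marker bp positions are uniform within the chromosome with cM
proportional to bp (constant per-chromosome recombination rate).

Defaults mirror the maize study design the package is patterned on:
10 chromosomes with genetic lengths summing to 833.94 cM, per-
chromosome marker counts summing to 26,917, and 571 lines.
`SimConfig.small()` provides reduced configurations for tests and
examples.

**Observation model.** Each line×marker cell is missing with
`missing_rate` (default 0.30); an observed cell is recorded
heterozygous with `het_rate` (0.02), otherwise flipped to the other
parent with `error_rate` (0.02), otherwise correct. Per-cell read
depth for observed calls is 1 + Poisson(9) (mean 10) — shallow
transcriptome genotyping has no published per-SNP coverage law, so a
shifted Poisson was chosen once as a reasonable stand-in; it leaves a
~2% tail under the depth-5 QC cut so the filter is exercised. True
heterozygosity is absent by construction (DH lines); heterozygous
calls are observation noise. An optional contaminant-line flag raises
a line's het rate (emulating failed genome doubling) to exercise the
line-level het filter.

**Phenotypes.** For line *i*, environment *j*, replicate *k*:

    y_ijk = mu + sum_q a_q x_iq + (ge)_ij + e_ijk ,  x in {+1, −1}

with (ge) ~ N(0, σ²_ge) per line×environment and e ~ N(0, σ²_ε) per
observation; defaults are 6 environments × 2 replicates. A designated
locus determines a fully penetrant binary trait (the cob-color
analog; the study treats that trait as monogenic). The
`study_qtl_spec()` architecture places the packaged table's 42
QTL at their printed cM positions with their printed additive effects
and sets per-trait variance components so the implied entry-mean
heritability approximates the study-scale values (leaf angles ~0.93,
tassel-branch angle ~0.85, flag-leaf angle ~0.71), splitting the
non-genetic variance evenly between G×E and residual. Because linked
QTL covary, the realized genetic variance differs somewhat from the
independence-based target; tests score realized heritability
empirically rather than assuming it.

**What the simulator does not emulate:** read-level sequencing,
segregation distortion of biological origin, interference
(chiasma obligate or otherwise), residual true heterozygosity,
epistasis, dominance (meaningless in DH), spatial field trends, and
trait-correlated error. Passing recovery tests therefore demonstrate
correctness of the algorithms under the stated noise model, not
robustness to every artifact of real data.

## Quality control

Filter order is depth → segregation → marker-het → line-het, mirroring
the narrative order of the source protocol; both het orders are
available and logged. The segregation rule is read as a conjunction —
discard iff major:minor > 2 AND χ²(1 df vs 1:1) p < 1e-7 — the
conservative literal reading; at n ≈ 436 the two conditions nearly
coincide. Het fractions use non-missing calls as denominator (a rate
of observed calls, not of all markers). Markers with fewer than two
informative calls are degenerate and dropped. All filters are
idempotent.

## Sliding-window genotype calling

Windows of 15 *sequenced* SNPs are tiled per line per chromosome
(windows never span chromosomes; the terminal window may be short and
is voted on its member fraction). A window is homozygous A (B) when
the A (B) fraction strictly exceeds 11/15; 11/15 exactly is
heterozygous. "Sliding window" protocols of this kind are
operationally tiled — the run-length rules (merging adjacent windows,
counting het runs in windows) only make sense on a tiling; an
overlapping step-1 mode exists in `call_windows(step=1)` for
sensitivity analysis but the block pipeline consumes tiled windows.

Heterozygous runs of ≤ 6 windows flanked by homozygous windows are
crossover signatures: the run is split at its midpoint (odd runs give
the left half the extra window), each half joining its flank; equal
flanks absorb the run without a breakpoint; runs at chromosome ends
join their single flank. Longer het runs remain heterozygous blocks.

Two refinements beyond the window-resolution rules:

* **Boundary refinement.** The window vote localizes a crossover only
  to window granularity. For each pair of directly adjacent
  homozygous blocks with different genotypes, the raw calls within
  two windows of the boundary are re-scanned and the split minimizing
  call mismatches (het calls neutral; ties resolve to the middle of
  the optimal range, preserving the midpoint convention under
  perfectly ambiguous data) is adopted. With noise-free input this
  recovers the exact transition SNP.
* **Double-crossover recovery.** A true double crossover whose inner
  segment is shorter than one window never outvotes its window. Runs
  of ≥ 5 consecutive sequenced opposite-parent calls inside a
  homozygous block are split out at SNP resolution (five consecutive
  2%-probability errors occur at rate 3×10⁻⁹); the small-block rules
  below still decide whether the segment is trusted.

Cleaning rules: runs of ≥ 3 consecutive sub-300 kb blocks with
alternating genotypes collapse into one heterozygous block (the
operationalization of "frequently transient genotypes", which the
source protocol does not quantify; thresholds configurable);
homozygous blocks with < 5 SNPs or < 300 kb become missing (the false
double-crossover guard); heterozygous blocks with < 15 SNPs or < 1 Mb
become missing; adjacent same-genotype blocks re-merge.

Breakpoints are reported at the physical midpoint between the last
SNP of one homozygous block and the first SNP of the next when their
genotypes differ; pairs separated by a missing/het gap are emitted at
the gap midpoint with an `uncertain` flag. Projection back to markers
assigns each marker the genotype of its block, with inter-block
boundaries at the midpoint convention above, terminal blocks extended
to the chromosome ends.

**Fidelity bound.** The rules *deliberately* erase true segments
below their thresholds, so "round-trip identity under zero noise"
holds exactly on markers lying in true parental segments with ≥ 5
markers and ≥ 300 kb span — in practice > 99.9% of cells at test
scales — and cannot hold on smaller segments by design. Tests assert
identity on that marker set. Under the reference noise setting (30%
missing, 2% error, 2% het, 2,000 SNPs and 200 lines per chromosome),
≥ 95% of true crossovers are matched by a detected breakpoint within
one window's physical span (≈ window_size/(1−missing) marker
spacings), with essentially no false detections.

## Genetic map

Marker order is physical (the markers anchor to a reference
assembly); no de-novo ordering is attempted. The DH counting
estimator r̂ = recombinant/informative is applied to adjacent markers
(het and missing calls uninformative); r̂ ≥ 0.5 (likely mis-ordered
markers) is clipped below 0.5 and flagged, as are pairs with no
informative line (distance 0). Kosambi is the package default (the
common choice for maize maps); Haldane is the simulator-consistent
option used in recovery tests, where the estimated total length of a
fully observed 400-line chromosome falls within 10% of truth. The
mapping function used is recorded in the map metadata; both invert
analytically (round-trip error < 1e-12).

## BLUPs and heritability

The trial model is y = μ + env + g + (ge) + ε with environment fixed
and genotype and G×E random — the standard plant-breeding model for
entry-mean line values; the replicate effect is absorbed into the
residual (no rep term appears in the source protocol; configurable).
Balanced designs are solved in closed form from expected mean
squares (E[MS_G] = σ²ε + Rσ²ge + ERσ²g, E[MS_GE] = σ²ε + Rσ²ge,
E[MS_e] = σ²ε); unbalanced designs fall back to REML via a linear
mixed model (statsmodels MixedLM) with the same effect structure, and
the two routes agree on balanced data in tests. Negative estimates
truncate to zero with a flag; a single environment forces σ²ge = 0
with a flag.

Entry-mean heritability is H² = σ²g/(σ²g + σ²ge/E + σ²ε/(ER)).
BLUPs shrink environment-adjusted line-mean deviations by
λ_i = σ²g/(σ²g + σ²ge/E_i + σ²ε/n_i), using each line's own
environment count E_i and observation count n_i — exactly the
balanced formula when the design is complete, and a per-line
approximation to the mixed-model equations otherwise (lines absent
from a trait get NaN). BLUPs are centered (sum ≈ 0) and never exceed
the raw deviation in magnitude.

## QTL scanning

Conditional P(genotype = A) at each grid position (1 cM default step)
comes from the flanking informative markers under Haldane:
P = f_L f_R / (f_L f_R + (1−f_L)(1−f_R)) with f = 1−r or r by flank
state; one-sided at chromosome ends; 0.5 with no informative marker.
Scans regress the phenotype on x = 2P − 1 (Haley–Knott), an
approximation to the full interval-mapping mixture likelihood that is
standard for DH populations with entry-mean phenotypes;
LOD = (n/2) log₁₀(RSS₀/RSS₁). The binary trait is scanned with the
same linear model on 0/1 coding.

Composite interval mapping forward-selects k = 3 background
covariates (grid positions, by greedy RSS reduction) and drops
covariates within 10 cM of the test position from both the null and
full model of that position; k and the window are configurable —
the source protocol names the method without parameters, and these
defaults follow common practice. k = 0 reduces exactly to interval
mapping.

Genome-wide thresholds come from permuting the phenotype across lines
(1000 permutations, α = 0.05 by default; fewer than 20 permutations
is an error), keeping the genome-wide max LOD per permutation and
taking the empirical 95th percentile. The permutation scan is fully
vectorized for the single-regressor case. Calibration: across 100
null phenotypes each tested against its own 200-permutation
threshold, the rejection rate is 0.05 ± 0.03.

Support intervals use the 1.5-LOD drop: the contiguous run around the
peak with LOD ≥ peak − 1.5, extended one grid step beyond on each
side where available (flanking-marker convention), clipped at
chromosome ends. Additive effect a is the regression coefficient on
x (half the homozygous-class mean difference); PVE = 100(1 −
RSS₁/RSS₀) from the single-position model. Peak calling accepts
local maxima above threshold, greedily from the highest; two maxima
on a chromosome are distinct QTL only when separated by a dip of
more than 1.5 LOD below the lower peak or by more than 20 cM — some
such rule is needed to report multiple QTL per chromosome, and this
one is the package's choice (both constants configurable). Grid
positions carry interpolated bp, so peaks and interval bounds are
reported in both cM and Mb.

## Overlap analysis

Two QTL of different traits overlap when they share a chromosome and
their closed physical-coordinate support intervals intersect
(max of left bounds ≤ min of right bounds); a cM mode and an open
convention are available. Counts are pairwise (not clique-based);
each QTL contributes its PVE once per trait pair, summed per side.

The packaged 42-QTL study table additionally carries the original
curated overlap annotation, and `find_overlaps(criterion="annotation")`
summarizes that column directly. This matters because the published
overlap matrix is *not* recoverable from the printed interval bounds
under any mechanical rule: the table contains interval pairs that
intersect in both Mb and cM but were not counted as overlapping, and
one counted pair whose Mb intervals are disjoint (meeting only at a
single cM boundary point). The packaged-table worked examples
therefore use the annotation criterion — the derivation the published
summary actually reflects — while de-novo QTL tables from the
pipeline use the interval criterion.

The segregation check is a Pearson χ² goodness-of-fit of class counts
against an expected ratio (classes − 1 df). Candidate-gene proximity
is 0 when a QTL peak falls inside the gene span, else the distance to
the nearer gene edge, with a flag for genes intersecting the support
interval; BED input is converted from 0-based half-open and GFF3 from
1-based inclusive to internal 1-based inclusive coordinates.

## Numerical and testing choices

Determinism: every stochastic routine takes a NumPy `Generator` or an
integer seed; identical configuration and seed reproduce outputs
bit-for-bit, and the pipeline stamps a config hash into every output.
Recombination fractions are clipped to [0, 0.4999999] before mapping-
function transforms; zero-variance phenotypes give LOD 0; perfect
fits (RSS₁ = 0) report +inf with a flag; degenerate single-class
genotypes at a peak raise an error rather than return silent zeros.

Test problem sizes are chosen to exercise each property at the
smallest scale where the signal is unambiguous: breakpoint recovery
uses two chromosomes of 2,000 SNPs × 200 lines; interval-coverage and
binary-localization benchmarks use 30 seeded replicates of 400- and
311-line single-trait populations on fully observed genotypes (so map
estimation error does not confound scan calibration); the variance-
component benchmark uses the full 571 × 6 × 2 design. The acceptance
script re-runs all of these from a single command-line seed.

## Known limitations

* Marker order is taken from the assembly; mis-assemblies appear as
  inflated adjacent recombination (flagged, not repaired).
* The CIM covariate count is fixed per scan, not chosen by
  information criteria.
* BLUPs for unbalanced designs use per-line shrinkage rather than the
  full mixed-model equations; with severe unbalancedness the two can
  diverge.
* The binary trait is analyzed by linear regression on 0/1 coding;
  a logistic or nonparametric scan would be more principled near
  fixation.
* Overlap conclusions depend on the interval convention; the package
  pins the convention in output metadata rather than claiming one is
  canonical.
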