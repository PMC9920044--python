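"""Synthetic doubled-haploid (DH) populations with known ground truth.

A DH line carries the product of a single meiosis, doubled to full
homozygosity: each chromosome is a mosaic of parent-A and parent-B
segments separated by crossovers.  This module simulates

* parental marker maps on a maize-like genome (10 chromosomes, marker
  density and genetic lengths patterned on a high-density DH map),
* DH genomes via a no-interference (Poisson) crossover process, so the
  crossover count on a chromosome of genetic length *L* Morgans is
  Poisson(*L*) and positions are uniform on the cM scale — consistent
  with the Haldane mapping function used downstream,
* a sparse, error-prone genotyping observation model emulating shallow
  transcriptome-based genotyping (missing calls, allele flips, spurious
  heterozygous calls, per-cell read depth),
* multi-environment replicated phenotypes with an additive QTL model
  plus genotype-by-environment and residual noise, and one fully
  penetrant single-locus binary trait (a cob-color analog).

Every run returns a :class:`TruthSet` holding the realized crossovers
and QTL genotypes, so downstream stages (QC, bin-map construction, map
estimation, QTL scans) can be scored against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import A, B, HET, MISSING, SnpCallMatrix

# Maize-like defaults: B73-scale physical lengths (bp) and genetic
# lengths / marker counts patterned on a dense DH linkage map.
MAIZE_CHROM_BP = [
    307_000_000, 244_000_000, 236_000_000, 247_000_000, 224_000_000,
    174_000_000, 182_000_000, 181_000_000, 160_000_000, 151_000_000,
]
MAIZE_CHROM_CM = [114.39, 110.28, 86.10, 74.45, 89.08,
                  71.68, 85.96, 74.29, 67.94, 59.77]
MAIZE_CHROM_NSNP = [4529, 3276, 2954, 2661, 3730, 1864, 1500, 2644, 1986, 1773]

ANGLE_TRAITS = ("LA1", "LA2", "LA3", "FLA", "TBA")
#: DH-population trait means (degrees) used as intercepts by default
DEFAULT_TRAIT_MEANS = {"LA1": 32.0, "LA2": 31.0, "LA3": 32.5,
                       "FLA": 35.2, "TBA": 32.3}


@dataclass
class SimConfig:
    """Population-scale parameters of a simulated DH study."""

    n_chrom: int = 10
    chrom_len_bp: list[int] = field(default_factory=lambda: list(MAIZE_CHROM_BP))
    chrom_len_cm: list[float] = field(default_factory=lambda: list(MAIZE_CHROM_CM))
    n_snps: list[int] = field(default_factory=lambda: list(MAIZE_CHROM_NSNP))
    n_lines: int = 571
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chrom < 1 or self.n_lines < 1:
            raise ValueError("counts must be >= 1")
        for name in ("chrom_len_bp", "chrom_len_cm", "n_snps"):
            v = getattr(self, name)
            if np.isscalar(v):
                v = [v] * self.n_chrom
                setattr(self, name, list(v))
            if len(v) != self.n_chrom:
                raise ValueError(f"{name} must have n_chrom={self.n_chrom} entries")
        if any(x <= 0 for x in self.chrom_len_bp):
            raise ValueError("physical lengths must be > 0")
        if any(x < 0 for x in self.chrom_len_cm):
            raise ValueError("genetic lengths must be >= 0")
        if any(n < 1 for n in self.n_snps):
            raise ValueError("n_snps must be >= 1 per chromosome")

    @classmethod
    def small(cls, n_chrom=2, n_snps=500, n_lines=100, seed=0,
              chrom_len_bp=200_000_000, chrom_len_cm=100.0) -> "SimConfig":
        """A reduced configuration convenient for tests and examples."""
        return cls(
            n_chrom=n_chrom,
            chrom_len_bp=[chrom_len_bp] * n_chrom,
            chrom_len_cm=[chrom_len_cm] * n_chrom,
            n_snps=[n_snps] * n_chrom,
            n_lines=n_lines,
            seed=seed,
        )


def default_depth_law(rng: np.random.Generator, size) -> np.ndarray:
    """Per-cell read depth for observed calls: 1 + Poisson(9), mean 10.

    Shallow transcriptome genotyping yields highly variable coverage; a
    shifted Poisson keeps every *observed* call at depth >= 1 while
    leaving a small tail below the depth-5 QC cut.
    """
    return 1 + rng.poisson(9.0, size=size)


@dataclass
class ObservationModel:
    """Noise model mapping true DH genotypes to observed calls.

    Each cell is missing with ``missing_rate``; an observed cell is
    recorded heterozygous with ``het_rate``, else flipped to the other
    parent with ``error_rate``, else equals the true genotype.  DH lines
    are homozygous by construction, so heterozygous calls are pure
    observation noise (or contamination, see ``contaminant_lines`` in
    :func:`observe_genotypes`).
    """

    missing_rate: float = 0.3
    error_rate: float = 0.02
    het_rate: float = 0.02
    depth_law = staticmethod(default_depth_law)

    def __post_init__(self) -> None:
        for name in ("missing_rate", "error_rate", "het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QtlEffect:
    """One additive QTL: ``trait`` gains ``additive`` degrees per A allele."""

    trait: str
    chrom: int
    pos_cm: float
    additive: float


@dataclass
class QtlSpec:
    """Trait architecture: QTL effects plus variance components and design.

    The phenotype model for line *i*, environment *j*, replicate *k* is

        y_ijk = mu + sum_q a_q x_iq + (ge)_ij + e_ijk

    with x in {+1, -1} (A/B at the QTL), (ge) ~ N(0, s2_ge) drawn once
    per line x environment, and e ~ N(0, s2_e) per observation.
    """

    qtls: list[QtlEffect]
    mu: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    sigma2_ge: dict | float = 1.0
    sigma2_e: dict | float = 4.0
    n_env: int = 6
    n_rep: int = 2
    binary_locus: tuple | None = (1, 33.0)  # (chrom, cM): cob-color analog

    def traits(self) -> list[str]:
        seen: dict[str, None] = {}
        for q in self.qtls:
            seen.setdefault(q.trait, None)
        return list(seen)

    def _per_trait(self, value, trait) -> float:
        return value[trait] if isinstance(value, dict) else float(value)

    def sigma2_ge_of(self, trait) -> float:
        return self._per_trait(self.sigma2_ge, trait)

    def sigma2_e_of(self, trait) -> float:
        return self._per_trait(self.sigma2_e, trait)


@dataclass
class DHGenome:
    """One DH line: per-chromosome parental segments on the cM scale.

    ``segments[chrom]`` is an ordered list of ``(start_cm, end_cm,
    parent)`` tuples (parent 0 = A, 1 = B) tiling [0, L] with adjacent
    segments from alternating parents.
    """

    segments: dict

    def crossovers_cm(self, chrom) -> list[float]:
        segs = self.segments[chrom]
        return [seg[1] for seg in segs[:-1]]

    def genotype_at(self, chrom, pos_cm: float) -> int:
        for start, end, parent in self.segments[chrom]:
            if start <= pos_cm <= end:
                return parent
        raise ValueError(f"position {pos_cm} cM outside chromosome {chrom}")


@dataclass
class TruthSet:
    """Ground truth emitted with every simulation for recovery scoring."""

    genomes: list[DHGenome]
    crossovers: pd.DataFrame  # line, chrom, pos_cm, pos_bp
    qtl_spec: QtlSpec | None = None
    qtl_genotypes: pd.DataFrame | None = None  # lines x QTL, +1/-1
    binary_trait: pd.Series | None = None
    true_calls: np.ndarray | None = None  # n_lines x n_markers, codes A/B

    def to_json(self, path) -> None:
        payload = {
            "crossovers": self.crossovers.to_dict(orient="list"),
            "qtls": None
            if self.qtl_spec is None
            else [vars(q) for q in self.qtl_spec.qtls],
            "binary_trait": None
            if self.binary_trait is None
            else self.binary_trait.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ----------------------------------------------------------------------
# parental map
# ----------------------------------------------------------------------

def make_parental_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw biallelic parent-informative markers along each chromosome.

    Marker bp positions are uniform within the chromosome; cM positions
    follow by linear bp->cM scaling (a constant per-chromosome
    recombination rate).  Returns a table with columns
    ``marker, chrom, bp, cm``.
    """
    frames = []
    for c in range(config.n_chrom):
        chrom = c + 1
        n = config.n_snps[c]
        L = config.chrom_len_bp[c]
        if n > L:
            raise ValueError("more SNPs than base pairs on chromosome")
        bp = np.unique((rng.random(n) * L).astype(np.int64) + 1)
        while len(bp) < n:  # collisions are rare for n << L
            extra = (rng.random(n - len(bp)) * L).astype(np.int64) + 1
            bp = np.unique(np.concatenate([bp, extra]))
        bp = np.sort(bp)
        cm = bp / config.chrom_len_bp[c] * config.chrom_len_cm[c]
        frames.append(pd.DataFrame({
            "marker": [f"M{chrom}_{i + 1}" for i in range(n)],
            "chrom": chrom, "bp": bp, "cm": cm,
        }))
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# meiosis
# ----------------------------------------------------------------------

def simulate_dh_genome(chrom_len_cm, rng: np.random.Generator) -> DHGenome:
    """Simulate one DH genome by a no-interference crossover process.

    Parameters
    ----------
    chrom_len_cm
        Mapping chromosome -> genetic length in cM (or a sequence, taken
        as chromosomes 1..n).
    rng
        NumPy generator; the crossover count per chromosome is
        Poisson(L/100) and positions are iid uniform on [0, L].
    """
    if not isinstance(chrom_len_cm, dict):
        chrom_len_cm = {i + 1: L for i, L in enumerate(chrom_len_cm)}
    segments = {}
    for chrom, L in chrom_len_cm.items():
        start_parent = int(rng.integers(2))
        if L <= 0:
            segments[chrom] = [(0.0, 0.0, start_parent)]
            continue
        n_xo = rng.poisson(L / 100.0)
        cuts = np.sort(rng.uniform(0.0, L, size=n_xo))
        bounds = np.concatenate([[0.0], cuts, [L]])
        segs = []
        parent = start_parent
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            segs.append((float(lo), float(hi), parent))
            parent = 1 - parent
        segments[chrom] = segs
    return DHGenome(segments=segments)


def genome_to_calls(genome: DHGenome, parental_map: pd.DataFrame) -> np.ndarray:
    """True genotype code (A=0 / B=1) at every marker of the map."""
    out = np.empty(len(parental_map), dtype=np.int8)
    for chrom, sub in parental_map.groupby("chrom", sort=False):
        segs = genome.segments[chrom]
        bounds = np.array([s[1] for s in segs])
        parents = np.array([s[2] for s in segs], dtype=np.int8)
        idx = np.searchsorted(bounds, sub["cm"].to_numpy(), side="left")
        idx = np.minimum(idx, len(segs) - 1)
        out[sub.index] = parents[idx]
    return out


def interpolate_bp(parental_map: pd.DataFrame, chrom, pos_cm) -> np.ndarray:
    """Physical position(s) for cM position(s) by linear marker interpolation."""
    sub = parental_map[parental_map["chrom"] == chrom]
    return np.interp(np.atleast_1d(pos_cm), sub["cm"].to_numpy(),
                     sub["bp"].to_numpy())


def simulate_genomes(config: SimConfig, parental_map: pd.DataFrame,
                     rng: np.random.Generator) -> tuple[list[DHGenome], pd.DataFrame]:
    """Simulate all DH genomes; also return the crossover truth table."""
    lengths = {c + 1: config.chrom_len_cm[c] for c in range(config.n_chrom)}
    genomes, rows = [], []
    for i in range(config.n_lines):
        g = simulate_dh_genome(lengths, rng)
        genomes.append(g)
        for chrom in lengths:
            for xo in g.crossovers_cm(chrom):
                rows.append((f"DH{i + 1:04d}", chrom, xo,
                             float(interpolate_bp(parental_map, chrom, xo)[0])))
    crossovers = pd.DataFrame(rows, columns=["line", "chrom", "pos_cm", "pos_bp"])
    return genomes, crossovers


# ----------------------------------------------------------------------
# observation model
# ----------------------------------------------------------------------

def observe_genotypes(
    genomes: list[DHGenome],
    parental_map: pd.DataFrame,
    obs_model: ObservationModel,
    rng: np.random.Generator,
    contaminant_lines=(),
    contaminant_het: float = 0.4,
) -> tuple[SnpCallMatrix, np.ndarray]:
    """Apply the sparse noisy observation model to true DH genotypes.

    ``contaminant_lines`` (row indices) emulate failed genome doubling:
    their observed het rate is raised to ``contaminant_het`` so the
    line-level heterozygosity filter has something to catch.

    Returns the observed :class:`SnpCallMatrix` (with depth layer) and
    the true call matrix (codes A/B) for scoring.
    """
    n_lines, n_markers = len(genomes), len(parental_map)
    true_calls = np.vstack([genome_to_calls(g, parental_map) for g in genomes])

    calls = true_calls.copy()
    missing = rng.random((n_lines, n_markers)) < obs_model.missing_rate
    u = rng.random((n_lines, n_markers))
    het_rate = np.full((n_lines, 1), obs_model.het_rate)
    for i in contaminant_lines:
        het_rate[i, 0] = contaminant_het
    is_het = u < het_rate
    is_err = (~is_het) & (u < het_rate + obs_model.error_rate)
    calls[is_het] = HET
    calls[is_err] = 1 - true_calls[is_err]  # flip A<->B
    calls[missing] = MISSING

    depth = np.zeros((n_lines, n_markers), dtype=np.int32)
    observed = ~missing
    depth[observed] = obs_model.depth_law(rng, int(observed.sum()))

    matrix = SnpCallMatrix(
        lines=[f"DH{i + 1:04d}" for i in range(n_lines)],
        markers=parental_map[["marker", "chrom", "bp", "cm"]].copy(),
        calls=calls,
        depth=depth,
    )
    return matrix, true_calls


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

def simulate_phenotypes(
    genomes: list[DHGenome],
    qtl_spec: QtlSpec,
    rng: np.random.Generator,
    line_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate the tidy multi-environment phenotype table.

    Returns
    -------
    pheno : DataFrame
        Columns ``line, env, rep, trait, value`` for every quantitative
        trait in the spec.
    binary : Series
        Per-line binary Mendelian trait (1 = parent-A allele at the
        designated locus, 0 otherwise); empty if no locus configured.
    qtl_geno : DataFrame
        Lines x QTL matrix of realized +1/-1 genotypes (truth).
    """
    n = len(genomes)
    if line_ids is None:
        line_ids = [f"DH{i + 1:04d}" for i in range(n)]

    qtl_cols = {}
    for qi, q in enumerate(qtl_spec.qtls):
        x = np.array([1 if g.genotype_at(q.chrom, q.pos_cm) == 0 else -1
                      for g in genomes])
        qtl_cols[f"q{qi}_{q.trait}_c{q.chrom}@{q.pos_cm:g}"] = x
    qtl_geno = pd.DataFrame(qtl_cols, index=line_ids)

    E, R = qtl_spec.n_env, qtl_spec.n_rep
    frames = []
    for trait in qtl_spec.traits():
        genetic = np.zeros(n)
        for qi, q in enumerate(qtl_spec.qtls):
            if q.trait == trait:
                genetic += q.additive * qtl_geno.iloc[:, qi].to_numpy()
        mu = qtl_spec.mu.get(trait, 0.0) if isinstance(qtl_spec.mu, dict) \
            else float(qtl_spec.mu)
        ge = rng.normal(0.0, np.sqrt(qtl_spec.sigma2_ge_of(trait)), size=(n, E))
        eps = rng.normal(0.0, np.sqrt(qtl_spec.sigma2_e_of(trait)), size=(n, E, R))
        y = mu + genetic[:, None, None] + ge[:, :, None] + eps
        idx = pd.MultiIndex.from_product(
            [line_ids, range(1, E + 1), range(1, R + 1)],
            names=["line", "env", "rep"])
        frames.append(pd.DataFrame({"trait": trait, "value": y.ravel()},
                                   index=idx).reset_index())
    pheno = pd.concat(frames, ignore_index=True)

    if qtl_spec.binary_locus is not None:
        chrom, pos = qtl_spec.binary_locus
        vals = [1 if g.genotype_at(chrom, pos) == 0 else 0 for g in genomes]
        binary = pd.Series(vals, index=line_ids, name="cob_color")
    else:
        binary = pd.Series(dtype=int, name="cob_color")
    return pheno, binary, qtl_geno


# ----------------------------------------------------------------------
# one-call convenience
# ----------------------------------------------------------------------

def simulate_population(
    config: SimConfig,
    obs_model: ObservationModel | None = None,
    qtl_spec: QtlSpec | None = None,
    contaminant_lines=(),
):
    """Simulate map, genomes, observations and phenotypes in one call.

    Returns ``(matrix, pheno, truth)`` where ``matrix`` is the observed
    noisy :class:`SnpCallMatrix`, ``pheno`` the tidy phenotype table
    (``None`` if no QTL spec), and ``truth`` the :class:`TruthSet`.
    """
    rng = np.random.default_rng(config.seed)
    obs_model = obs_model or ObservationModel()
    pmap = make_parental_map(config, rng)
    genomes, crossovers = simulate_genomes(config, pmap, rng)
    matrix, true_calls = observe_genotypes(
        genomes, pmap, obs_model, rng, contaminant_lines=contaminant_lines)

    pheno = binary = qtl_geno = None
    if qtl_spec is not None:
        pheno, binary, qtl_geno = simulate_phenotypes(
            genomes, qtl_spec, rng, line_ids=matrix.lines)
    truth = TruthSet(
        genomes=genomes, crossovers=crossovers, qtl_spec=qtl_spec,
        qtl_genotypes=qtl_geno, binary_trait=binary, true_calls=true_calls)
    return matrix, pheno, truth


def study_qtl_spec(n_env: int = 6, n_rep: int = 2,
                        heritability: dict | None = None,
                        ge_share: float = 0.5) -> QtlSpec:
    """QTL architecture patterned on the packaged 42-QTL maize table.

    Each packaged QTL contributes its printed additive effect (degrees)
    at its printed peak cM position; variance components are then set so
    the entry-mean broad-sense heritability of each trait approximately
    matches the study-scale values (LA1/LA2/LA3 ~0.93, TBA ~0.85,
    FLA ~0.71), splitting the non-genetic variance between GxE and
    residual by ``ge_share``.  Linkage among QTL makes the realized
    genetic variance differ somewhat from the independence-based target;
    tests score realized heritability empirically.
    """
    from .fixtures import load_table2

    t2 = load_table2()
    heritability = heritability or {"LA1": 0.934, "LA2": 0.934, "LA3": 0.934,
                                    "TBA": 0.845, "FLA": 0.710}
    qtls = [QtlEffect(trait=r.trait, chrom=int(r.chrom),
                      pos_cm=float(r.peak_cm), additive=float(r.add))
            for r in t2.itertuples()]
    s2ge, s2e = {}, {}
    for trait, sub in t2.groupby("trait"):
        s2g = float((sub["add"] ** 2).sum())  # independence approximation
        h2 = heritability[trait]
        extra = s2g / h2 - s2g  # = s2_ge/E + s2_e/(E R)
        s2ge[trait] = n_env * extra * ge_share
        s2e[trait] = n_env * n_rep * extra * (1.0 - ge_share)
    return QtlSpec(qtls=qtls, sigma2_ge=s2ge, sigma2_e=s2e,
                   n_env=n_env, n_rep=n_rep, binary_locus=(1, 33.0))
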