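"""End-to-end pipeline: simulate -> QC -> binmap -> map -> BLUP -> scan -> overlap.

Every stage parameter defaults to the source study's published setting
(15-SNP windows with the >11/15 homozygosity rule, het runs of at most
6 windows, 5-SNP/300-kb and 15-SNP/1-Mb block rules, depth >= 5,
segregation p < 1e-7 at ratio > 2, 15% het cuts, 1000 permutations at
alpha 0.05, 1.5-LOD drop).  The full configuration is serialized into
every output for provenance, and a fixed seed makes runs byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binmap as _binmap
from . import genmap as _genmap
from . import overlap as _overlap
from . import pheno as _pheno
from . import qc as _qc
from . import scan as _scan
from . import simulate as _sim

log = logging.getLogger("dhqtl")


@dataclass
class PipelineConfig:
    # simulation scale
    n_chrom: int = 10
    n_snps_per_chrom: int | None = None  # None: maize-like per-chromosome counts
    n_lines: int = 571
    seed: int = 1
    # observation model
    missing_rate: float = 0.3
    error_rate: float = 0.02
    het_rate: float = 0.02
    # QC
    min_depth: int = 5
    seg_alpha: float = 1e-7
    seg_ratio: float = 2.0
    max_het: float = 0.15
    # binmap
    window_size: int = 15
    hom_threshold: float = 11 / 15
    max_het_run: int = 6
    min_block_snps: int = 5
    min_block_kb: float = 300.0
    min_het_snps: int = 15
    min_het_mb: float = 1.0
    # map
    mapping_function: str = "haldane"
    # scan
    method: str = "cim"
    step_cm: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    n_covariates: int = 3
    window_cm: float = 10.0
    lod_drop: float = 1.5
    # stage toggles
    skip_simulate: bool = False
    genotype_csv: str | None = None
    phenotype_csv: str | None = None

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def binmap_params(self) -> _binmap.BinmapParams:
        return _binmap.BinmapParams(
            window_size=self.window_size, hom_threshold=self.hom_threshold,
            max_het_run=self.max_het_run, min_block_snps=self.min_block_snps,
            min_block_bp=int(self.min_block_kb * 1e3),
            min_het_snps=self.min_het_snps,
            min_het_bp=int(self.min_het_mb * 1e6))


def _write_with_provenance(df: pd.DataFrame, path: Path, cfg_hash: str,
                           sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"# dhqtl config_hash={cfg_hash}\n")
        df.to_csv(fh, sep=sep, index=False)


def run_pipeline(config: PipelineConfig, outdir, qtl_spec=None) -> dict:
    """Execute all stages and write the artifact bundle to ``outdir``.

    Returns a dict of the in-memory results (matrices, map, BLUPs, QTL
    table, overlap summary, QC report).  ``qtl_spec`` defaults to a
    trait architecture patterned on the packaged study table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format=f"%(levelname)s [run {cfg_hash}] %(message)s")
    config.to_yaml(outdir / "config.yaml")

    # --- stage 1: inputs -------------------------------------------------
    if config.skip_simulate:
        if not config.genotype_csv:
            raise ValueError("skip_simulate requires genotype_csv")
        matrix = _sim.SnpCallMatrix.read_csv(config.genotype_csv)
        pheno = (pd.read_csv(config.phenotype_csv)
                 if config.phenotype_csv else None)
        truth = None
    else:
        if config.n_snps_per_chrom is None:
            sim_cfg = _sim.SimConfig(n_lines=config.n_lines, seed=config.seed)
            sim_cfg.n_chrom = config.n_chrom
            sim_cfg.chrom_len_bp = sim_cfg.chrom_len_bp[:config.n_chrom]
            sim_cfg.chrom_len_cm = sim_cfg.chrom_len_cm[:config.n_chrom]
            sim_cfg.n_snps = sim_cfg.n_snps[:config.n_chrom]
        else:
            sim_cfg = _sim.SimConfig.small(
                n_chrom=config.n_chrom, n_snps=config.n_snps_per_chrom,
                n_lines=config.n_lines, seed=config.seed)
        obs = _sim.ObservationModel(missing_rate=config.missing_rate,
                                    error_rate=config.error_rate,
                                    het_rate=config.het_rate)
        if qtl_spec is None:
            qtl_spec = _sim.study_qtl_spec()
            # default architecture trimmed to the simulated chromosomes
            qtl_spec.qtls = [q for q in qtl_spec.qtls
                             if q.chrom <= sim_cfg.n_chrom]
            if (qtl_spec.binary_locus is not None
                    and qtl_spec.binary_locus[0] > sim_cfg.n_chrom):
                qtl_spec.binary_locus = None
        for q in qtl_spec.qtls:
            if q.chrom > sim_cfg.n_chrom:
                raise ValueError(
                    f"QTL on chromosome {q.chrom} outside simulated genome")
        matrix, pheno, truth = _sim.simulate_population(
            sim_cfg, obs, qtl_spec)
        matrix.write_csv(outdir / "genotypes_raw.csv")
        pheno.to_csv(outdir / "phenotypes.csv", index=False)
        truth.to_json(outdir / "truth.json")
    log.info("input: %d lines x %d SNPs", matrix.n_lines, matrix.n_markers)

    # --- stage 2: QC -----------------------------------------------------
    filtered, report = _qc.run_qc(
        matrix, min_depth=config.min_depth, seg_alpha=config.seg_alpha,
        seg_ratio=config.seg_ratio, max_het=config.max_het)
    with open(outdir / "qc_report.json", "w") as fh:
        json.dump({"config_hash": cfg_hash, **report.to_dict()}, fh, indent=1)
    log.info("QC: %d lines x %d SNPs survive", filtered.n_lines,
             filtered.n_markers)

    # --- stage 3: binmap -------------------------------------------------
    corrected, blocks, breakpoints = _binmap.run_binmap(
        filtered, config.binmap_params())
    _write_with_provenance(blocks, outdir / "blocks.tsv", cfg_hash)
    _write_with_provenance(breakpoints, outdir / "breakpoints.tsv", cfg_hash)
    corrected.write_csv(outdir / "genotypes_corrected.csv")

    # --- stage 4: genetic map -------------------------------------------
    gmap = _genmap.build_map(corrected, function=config.mapping_function)
    _write_with_provenance(gmap.markers, outdir / "genetic_map.tsv", cfg_hash)
    _write_with_provenance(_genmap.map_summary(gmap),
                           outdir / "map_summary.tsv", cfg_hash)
    log.info("map: %.2f cM total", gmap.total_cm())

    # --- stage 5: BLUPs --------------------------------------------------
    results: dict = {"matrix": matrix, "filtered": filtered,
                     "corrected": corrected, "map": gmap, "blocks": blocks,
                     "breakpoints": breakpoints, "qc_report": report,
                     "truth": truth}
    if pheno is None:
        return results
    traits = list(pheno["trait"].unique())
    components = {t: _pheno.fit_variance_components(pheno, t) for t in traits}
    blups = pd.concat(
        [_pheno.compute_blups(pheno, t, components[t]) for t in traits], axis=1)
    blups.to_csv(outdir / "blups.csv")
    h2 = {t: _pheno.heritability(components[t]) for t in traits}
    with open(outdir / "variance_components.json", "w") as fh:
        json.dump({t: {**{k: v for k, v in vars(components[t]).items()
                          if not isinstance(v, list)},
                       "H2": h2[t]} for t in traits}, fh, indent=1)
    _write_with_provenance(_pheno.trait_correlations(blups).reset_index(),
                           outdir / "trait_correlations.tsv", cfg_hash)

    # --- stage 6: QTL scans ----------------------------------------------
    grid = _scan.genotype_probs(gmap.markers, corrected,
                                step_cm=config.step_cm)
    all_records = []
    curves = {}
    for trait in traits:
        y = blups[trait].reindex(corrected.lines)
        perm = _scan.permutation_threshold(
            grid, y, n_perm=config.n_perm, alpha=config.alpha,
            seed=config.seed, method="im")
        if config.method == "cim":
            curve = _scan.scan_cim(grid, y, trait=trait,
                                   n_covariates=config.n_covariates,
                                   window_cm=config.window_cm)
        else:
            curve = _scan.scan_im(grid, y, trait=trait)
        recs = _scan.detect_qtls(curve, perm.threshold, grid, y,
                                 markers=gmap.markers, drop=config.lod_drop)
        curves[trait] = (curve, perm)
        all_records.extend(recs)
        log.info("%s: threshold %.2f, %d QTL", trait, perm.threshold,
                 len(recs))
    qtl_table = _scan.records_to_table(all_records)
    qtl_table.insert(0, "qtl", [
        f"q{r.trait}_{r.chrom}_{i}" for i, r in enumerate(all_records)])
    _write_with_provenance(qtl_table, outdir / "qtl_table.tsv", cfg_hash)
    lod_frames = []
    for trait, (curve, perm) in curves.items():
        df = curve.positions.copy()
        df.insert(0, "trait", trait)
        df["lod"] = curve.lod
        df["threshold"] = perm.threshold
        lod_frames.append(df)
    _write_with_provenance(pd.concat(lod_frames, ignore_index=True),
                           outdir / "lod_curves.tsv", cfg_hash)

    # --- stage 7: overlap ------------------------------------------------
    if len(qtl_table) and qtl_table["trait"].nunique() > 1:
        summary = _overlap.find_overlaps(qtl_table, criterion="interval")
        _write_with_provenance(summary.counts.reset_index(),
                               outdir / "overlap_counts.tsv", cfg_hash)
        _write_with_provenance(summary.pve.reset_index(),
                               outdir / "overlap_pve.tsv", cfg_hash)
        results["overlap"] = summary
    results.update({"pheno": pheno, "blups": blups, "components": components,
                    "heritability": h2, "qtl_table": qtl_table,
                    "curves": curves})
    return results
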