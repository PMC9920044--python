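"""SNP- and line-level quality control for DH genotype matrices.

Four filters, applied in the order depth -> segregation -> SNP
heterozygosity -> line heterozygosity:

1. *Depth*: calls backed by fewer than ``min_depth`` reads (default 5)
   are set missing.
2. *Segregation distortion*: in a biparental DH population every marker
   should segregate 1:1.  A marker is discarded when its A:B ratio
   exceeds ``max_ratio`` (default 2) AND a 1-df Pearson chi-square test
   against 1:1 rejects at ``alpha`` (default 1e-7).
3. *SNP heterozygosity*: DH lines are homozygous, so markers whose
   heterozygous-call fraction (over non-missing calls) exceeds
   ``max_het`` (default 15%) are treated as unreliable and discarded.
4. *Line heterozygosity*: lines above the same 15% threshold are
   removed (failed genome doubling or sample contamination).

Each filter is idempotent; :class:`QcReport` records what was removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .matrix import A, B, HET, MISSING, SnpCallMatrix


@dataclass
class QcReport:
    """Per-rule removal counts and the surviving matrix dimensions."""

    input_lines: int = 0
    input_snps: int = 0
    cells_set_missing_depth: int = 0
    snps_removed_segregation: int = 0
    snps_removed_het: int = 0
    lines_removed_het: int = 0
    surviving_lines: int = 0
    surviving_snps: int = 0
    warnings: list[str] = field(default_factory=list)
    filter_order: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(vars(self))


def depth_filter(matrix: SnpCallMatrix, min_depth: int = 5,
                 report: QcReport | None = None) -> SnpCallMatrix:
    """Set calls with read depth below ``min_depth`` to missing.

    The boundary is inclusive: depth == ``min_depth`` is retained.  A
    matrix without a depth layer is returned unchanged with a warning.
    """
    out = matrix.copy()
    if out.depth is None:
        if report is not None:
            report.warnings.append("depth_filter: no depth layer; no-op")
        return out
    low = (out.depth < min_depth) & (out.calls != MISSING)
    out.calls[low] = MISSING
    if report is not None:
        report.cells_set_missing_depth += int(low.sum())
    return out


def _allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return (calls == A).sum(axis=0), (calls == B).sum(axis=0)


def segregation_filter(matrix: SnpCallMatrix, alpha: float = 1e-7,
                       max_ratio: float = 2.0,
                       report: QcReport | None = None) -> SnpCallMatrix:
    """Discard markers with segregation distorted beyond ``max_ratio``:1.

    Heterozygous and missing calls are excluded from the allele counts.
    A marker is removed iff the chi-square (1 df) p-value against 1:1 is
    below ``alpha`` AND the major:minor allele ratio exceeds
    ``max_ratio``.  Markers with fewer than 2 informative calls are
    degenerate and removed.
    """
    na, nb = _allele_counts(matrix.calls)
    n = na + nb
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(n > 0, (na - nb) ** 2 / np.maximum(n, 1), 0.0)
        minor = np.minimum(na, nb)
        ratio = np.where(minor > 0, np.maximum(na, nb) / np.maximum(minor, 1),
                         np.inf)
    pval = stats.chi2.sf(chi2, df=1)
    distorted = (pval < alpha) & (ratio > max_ratio)
    degenerate = n < 2
    drop = distorted | degenerate
    if report is not None:
        report.snps_removed_segregation += int(drop.sum())
    return matrix.subset(marker_mask=~drop)


def het_filter(matrix: SnpCallMatrix, max_het: float = 0.15,
               order: str = "snps_then_lines",
               report: QcReport | None = None) -> SnpCallMatrix:
    """Remove markers, then lines, whose het fraction exceeds ``max_het``.

    Fractions are computed over non-missing calls; entities with no
    calls at all have het fraction 0.  ``order`` may be
    ``"snps_then_lines"`` (default) or ``"lines_then_snps"``.
    """

    def het_frac(calls, axis):
        h = (calls == HET).sum(axis=axis)
        nm = (calls != MISSING).sum(axis=axis)
        return np.where(nm > 0, h / np.maximum(nm, 1), 0.0)

    out = matrix
    steps = (["snp", "line"] if order == "snps_then_lines" else ["line", "snp"])
    for step in steps:
        if step == "snp":
            keep = het_frac(out.calls, axis=0) <= max_het
            if report is not None:
                report.snps_removed_het += int((~keep).sum())
            out = out.subset(marker_mask=keep)
        else:
            keep = het_frac(out.calls, axis=1) <= max_het
            if report is not None:
                report.lines_removed_het += int((~keep).sum())
            out = out.subset(line_mask=keep)
    return out


def run_qc(matrix: SnpCallMatrix, min_depth: int = 5, seg_alpha: float = 1e-7,
           seg_ratio: float = 2.0, max_het: float = 0.15,
           het_order: str = "snps_then_lines") -> tuple[SnpCallMatrix, QcReport]:
    """Apply the full QC chain and return the filtered matrix + report."""
    report = QcReport(input_lines=matrix.n_lines, input_snps=matrix.n_markers)
    report.filter_order = ["depth", "segregation", f"het({het_order})"]
    out = depth_filter(matrix, min_depth=min_depth, report=report)
    out = segregation_filter(out, alpha=seg_alpha, max_ratio=seg_ratio,
                             report=report)
    out = het_filter(out, max_het=max_het, order=het_order, report=report)
    report.surviving_lines = out.n_lines
    report.surviving_snps = out.n_markers
    return out, report
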