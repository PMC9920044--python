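"""Genetic-map estimation from corrected DH genotypes.

Markers are kept in physical (bp) order — the map anchors to a
reference assembly — and adjacent-marker recombination fractions are
estimated by the standard DH counting estimator: among lines genotyped
at both markers, r-hat = recombinant / informative.  Recombination
fractions convert to map distances through the Haldane
(d = -50 ln(1-2r), no interference) or Kosambi
(d = 25 ln((1+2r)/(1-2r)), partial interference) mapping function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import A, B, SnpCallMatrix


@dataclass
class RfEstimate:
    chrom: object
    left_index: int
    right_index: int
    informative: int
    recombinant: int
    rf: float
    flagged: bool = False


@dataclass
class GeneticMap:
    """Ordered markers with cumulative cM positions per chromosome."""

    markers: pd.DataFrame  # marker, chrom, bp, cm
    mapping_function: str = "kosambi"
    flags: list[str] = field(default_factory=list)

    def chrom_lengths(self) -> pd.Series:
        return self.markers.groupby("chrom", sort=False)["cm"].max()

    def total_cm(self) -> float:
        return float(self.chrom_lengths().sum())

    def write_tsv(self, path) -> None:
        self.markers.to_csv(path, sep="\t", index=False)


MAX_RF = 0.4999999


def estimate_rf(matrix: SnpCallMatrix) -> list[RfEstimate]:
    """Adjacent-marker recombination fractions from a DH call matrix.

    Heterozygous and missing calls are uninformative.  A pair with no
    informative line gets r-hat = 0 and a flag; estimates at or above
    0.5 (likely mis-ordered markers) are clipped just below 0.5 and
    flagged.
    """
    out: list[RfEstimate] = []
    calls = matrix.calls
    for chrom in matrix.chroms:
        cols = matrix.chrom_indices(chrom)
        sub = calls[:, cols]
        informative = (sub[:, :-1] != -1) & (sub[:, :-1] != 2) \
            & (sub[:, 1:] != -1) & (sub[:, 1:] != 2)
        recomb = informative & (sub[:, :-1] != sub[:, 1:])
        n_inf = informative.sum(axis=0)
        n_rec = recomb.sum(axis=0)
        for k in range(len(cols) - 1):
            if n_inf[k] == 0:
                out.append(RfEstimate(chrom, int(cols[k]), int(cols[k + 1]),
                                      0, 0, 0.0, flagged=True))
                continue
            r = n_rec[k] / n_inf[k]
            flagged = r >= 0.5
            out.append(RfEstimate(chrom, int(cols[k]), int(cols[k + 1]),
                                  int(n_inf[k]), int(n_rec[k]),
                                  float(min(r, MAX_RF)), flagged=flagged))
    return out


def rf_to_cm(r, function: str = "kosambi"):
    """Map distance (cM) for recombination fraction(s) ``r`` in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    if function == "haldane":
        d = -50.0 * np.log1p(-2.0 * r)
    elif function == "kosambi":
        d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    else:
        raise ValueError(f"unknown mapping function {function!r}")
    return float(d) if d.ndim == 0 else d


def cm_to_rf(d, function: str = "kosambi"):
    """Inverse of :func:`rf_to_cm`."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    if function == "haldane":
        r = 0.5 * (1.0 - np.exp(-d / 50.0))
    elif function == "kosambi":
        r = 0.5 * np.tanh(d / 50.0)
    else:
        raise ValueError(f"unknown mapping function {function!r}")
    return float(r) if r.ndim == 0 else r


def build_map(matrix: SnpCallMatrix, function: str = "kosambi") -> GeneticMap:
    """Estimate the genetic map of a corrected DH matrix.

    Marker order is the physical order; each chromosome starts at 0 cM
    and adjacent-marker distances accumulate.
    """
    estimates = estimate_rf(matrix)
    by_pair = {(e.left_index, e.right_index): e for e in estimates}
    flags = [f"pair {e.left_index}-{e.right_index} flagged (inf={e.informative})"
             for e in estimates if e.flagged]
    markers = matrix.markers.copy()
    cm = np.zeros(len(markers))
    for chrom in matrix.chroms:
        cols = matrix.chrom_indices(chrom)
        acc = 0.0
        for k in range(1, len(cols)):
            e = by_pair[(int(cols[k - 1]), int(cols[k]))]
            acc += rf_to_cm(e.rf, function) if e.informative else 0.0
            cm[cols[k]] = acc
    markers["cm"] = cm
    if "marker" not in markers.columns:
        markers.insert(0, "marker", matrix.marker_names())
    return GeneticMap(markers=markers[["marker", "chrom", "bp", "cm"]],
                      mapping_function=function, flags=flags)


def map_summary(gmap: GeneticMap) -> pd.DataFrame:
    """Per-chromosome map profile with a totals row.

    Columns: marker count, mean and max adjacent physical gap (Mb),
    genetic length (cM), mean and max adjacent genetic gap (cM).  The
    totals row sums counts and lengths; its mean/max gaps aggregate
    over all adjacent pairs genome-wide.
    """
    rows = []
    all_dbp, all_dcm = [], []
    for chrom, sub in gmap.markers.groupby("chrom", sort=False):
        dbp = np.diff(sub["bp"].to_numpy()) / 1e6
        dcm = np.diff(sub["cm"].to_numpy())
        all_dbp.append(dbp)
        all_dcm.append(dcm)
        rows.append({
            "chrom": chrom, "n_snps": len(sub),
            "mean_mb": dbp.mean() if len(dbp) else 0.0,
            "max_mb": dbp.max() if len(dbp) else 0.0,
            "length_cm": float(sub["cm"].max()),
            "mean_cm": dcm.mean() if len(dcm) else 0.0,
            "max_cm": dcm.max() if len(dcm) else 0.0,
        })
    dbp = np.concatenate(all_dbp) if all_dbp else np.array([])
    dcm = np.concatenate(all_dcm) if all_dcm else np.array([])
    rows.append({
        "chrom": "Total", "n_snps": len(gmap.markers),
        "mean_mb": dbp.mean() if len(dbp) else 0.0,
        "max_mb": dbp.max() if len(dbp) else 0.0,
        "length_cm": float(sum(r["length_cm"] for r in rows)),
        "mean_cm": dcm.mean() if len(dcm) else 0.0,
        "max_cm": dcm.max() if len(dcm) else 0.0,
    })
    return pd.DataFrame(rows)


def summarize_profile(profile: pd.DataFrame) -> dict:
    """Totals of a per-chromosome map-profile table (no totals row)."""
    return {
        "n_snps": int(profile["n_snps"].sum()),
        "length_cm": float(profile["length_cm"].sum()),
    }
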