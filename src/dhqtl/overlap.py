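"""Cross-trait QTL overlap, Mendelian segregation checks, gene proximity.

Two QTL of different traits "overlap" when they map to the same region;
pairwise overlap counts and the phenotypic variance the overlapping QTL
explain on each trait's side summarize how far two traits share genetic
control.  Two criteria are supported:

* ``criterion="interval"`` — same chromosome and closed physical (Mb)
  support intervals intersect (``max(lefts) <= min(rights)``); the
  mechanical rule for de-novo QTL tables.  A cM mode is available.
* ``criterion="annotation"`` — use a curated ``overlaps`` column naming
  the partner QTL, as in the packaged study table.  Published overlap
  summaries are often curated this way and are not always recoverable
  from interval bounds alone (the packaged table includes interval
  pairs that intersect but were not counted, and one counted pair whose
  Mb intervals only meet on the cM scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OverlapSummary:
    """Pairwise overlap counts and per-side summed PVE.

    ``counts`` is symmetric; ``pve.loc[t1, t2]`` is the summed PVE of
    the *t1*-side QTL overlapping trait *t2* (not symmetric).
    ``pairs`` lists the contributing QTL pairs.
    """

    counts: pd.DataFrame
    pve: pd.DataFrame
    pairs: pd.DataFrame  # trait_a, qtl_a, trait_b, qtl_b


def _interval_pairs(table: pd.DataFrame, scale: str, closed: bool
                    ) -> list[tuple[int, int]]:
    left, right = f"left_{scale}", f"right_{scale}"
    pairs = []
    for i in range(len(table)):
        for j in range(i + 1, len(table)):
            a, b = table.iloc[i], table.iloc[j]
            if a["trait"] == b["trait"] or a["chrom"] != b["chrom"]:
                continue
            lo = max(a[left], b[left])
            hi = min(a[right], b[right])
            if (lo <= hi) if closed else (lo < hi):
                pairs.append((i, j))
    return pairs


def _annotation_pairs(table: pd.DataFrame) -> list[tuple[int, int]]:
    if "overlaps" not in table.columns:
        raise ValueError("annotation criterion needs an 'overlaps' column")
    index_of = {q: i for i, q in enumerate(table["qtl"])}
    pairs = set()
    for i, row in table.iterrows():
        if pd.isna(row["overlaps"]):
            continue
        for partner in str(row["overlaps"]).split(","):
            partner = partner.strip()
            if not partner:
                continue
            j = index_of.get(partner)
            if j is None:
                raise ValueError(f"unknown partner QTL {partner!r}")
            pairs.add((min(i, j), max(i, j)))
    return sorted(pairs)


def find_overlaps(table: pd.DataFrame, criterion: str = "interval",
                  scale: str = "mb", closed: bool = True) -> OverlapSummary:
    """Pairwise cross-trait overlap summary of a QTL table.

    ``table`` needs ``qtl (or an index), trait, chrom, left_mb,
    right_mb, pve`` columns (``left_cm/right_cm`` for ``scale="cm"``);
    rows with missing bounds are excluded with a warning flag in the
    output.  Each QTL contributes its PVE at most once per trait pair.
    """
    table = table.reset_index(drop=True)
    if "qtl" not in table.columns:
        table = table.assign(qtl=[f"Q{i}" for i in range(len(table))])
    if criterion == "interval":
        bounds = [f"left_{scale}", f"right_{scale}"]
        ok = table[bounds].notna().all(axis=1)
        table = table[ok].reset_index(drop=True)
        pairs = _interval_pairs(table, scale, closed)
    elif criterion == "annotation":
        pairs = _annotation_pairs(table)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    traits = list(pd.unique(table["trait"]))
    counts = pd.DataFrame(0, index=traits, columns=traits)
    pve = pd.DataFrame(0.0, index=traits, columns=traits)
    seen_side = set()  # (qtl_index, partner_trait): PVE counted once per pair
    rows = []
    for i, j in pairs:
        ta, tb = table.loc[i, "trait"], table.loc[j, "trait"]
        counts.loc[ta, tb] += 1
        counts.loc[tb, ta] += 1
        if (i, tb) not in seen_side:
            pve.loc[ta, tb] += float(table.loc[i, "pve"])
            seen_side.add((i, tb))
        if (j, ta) not in seen_side:
            pve.loc[tb, ta] += float(table.loc[j, "pve"])
            seen_side.add((j, ta))
        rows.append((ta, table.loc[i, "qtl"], tb, table.loc[j, "qtl"]))
    pairs_df = pd.DataFrame(rows, columns=["trait_a", "qtl_a",
                                           "trait_b", "qtl_b"])
    np.fill_diagonal(counts.values, 0)
    return OverlapSummary(counts=counts, pve=pve, pairs=pairs_df)


def per_trait_pve(table: pd.DataFrame) -> pd.Series:
    """Total PVE (%) summed over each trait's QTL."""
    return table.groupby("trait")["pve"].sum()


def chi_square_gof(counts, expected_ratio=(1, 1)) -> tuple[float, float]:
    """Pearson chi-square goodness of fit of class counts to a ratio.

    Returns (chi2, p) with classes-1 degrees of freedom; used for the
    single-gene Mendelian segregation check (e.g. red:white cob counts
    against 1:1 in a DH population).
    """
    counts = np.asarray(counts, float)
    if counts.sum() == 0:
        raise ValueError("all counts are zero")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    ratio = np.asarray(expected_ratio, float)
    if np.any(ratio <= 0) or len(ratio) != len(counts):
        raise ValueError("expected ratio must be positive, one per class")
    expected = counts.sum() * ratio / ratio.sum()
    chi2, p = stats.chisquare(counts, expected)
    return float(chi2), float(p)


def candidate_proximity(qtl_table: pd.DataFrame, genes: pd.DataFrame
                        ) -> pd.DataFrame:
    """Distance from each QTL peak to each candidate gene.

    ``genes`` needs ``gene, chrom, start_bp, end_bp`` (1-based
    inclusive).  Distance is 0 when the peak lies within the gene span,
    else the bp gap to the nearer gene edge; ``inside_interval`` flags
    genes intersecting the QTL's physical support interval.  Genes on
    other chromosomes are skipped.
    """
    rows = []
    for _, q in qtl_table.iterrows():
        peak_bp = q["peak_mb"] * 1e6
        for _, g in genes.iterrows():
            if g["chrom"] != q["chrom"]:
                continue
            if g["start_bp"] <= peak_bp <= g["end_bp"]:
                dist = 0.0
            else:
                dist = min(abs(peak_bp - g["start_bp"]),
                           abs(peak_bp - g["end_bp"]))
            inside = (g["start_bp"] <= q["right_mb"] * 1e6
                      and g["end_bp"] >= q["left_mb"] * 1e6)
            rows.append((g["gene"], q.get("qtl", q.get("trait")), q["trait"],
                         dist, bool(inside)))
    return pd.DataFrame(rows, columns=["gene", "qtl", "trait",
                                       "distance_bp", "inside_interval"])


def read_gene_annotations(path, fmt: str = "auto") -> pd.DataFrame:
    """Read gene spans from BED (0-based half-open) or GFF3 (1-based).

    Returns a table with ``gene, chrom, start_bp, end_bp`` in 1-based
    inclusive coordinates.
    """
    path = str(path)
    if fmt == "auto":
        fmt = "gff3" if path.endswith((".gff", ".gff3")) else "bed"
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if fmt == "bed":
                chrom, start, end = f[0], int(f[1]) + 1, int(f[2])
                name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
            else:  # gff3
                if len(f) < 9:
                    continue
                chrom, start, end = f[0], int(f[3]), int(f[4])
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                name = attrs.get("ID", attrs.get("Name", f"{chrom}:{start}-{end}"))
            try:
                chrom = int(chrom)
            except ValueError:
                pass
            rows.append((name, chrom, start, end))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start_bp", "end_bp"])
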