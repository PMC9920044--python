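"""Genotype call matrices for biparental doubled-haploid populations.

A :class:`SnpCallMatrix` holds the per-line, per-marker observed allele
calls of a DH population genotyped against its two parents.  Calls are
stored as a compact ``int8`` array with one code per state:

====== =====================================
code   meaning
====== =====================================
``0``  homozygous for the parent-A allele
``1``  homozygous for the parent-B allele
``2``  heterozygous call
``-1`` missing (no call)
====== =====================================

An optional ``depth`` layer carries per-cell read depth, which the QC
stage uses for its minimum-coverage filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

A = np.int8(0)
B = np.int8(1)
HET = np.int8(2)
MISSING = np.int8(-1)

#: text representation used in CSV round-trips
CODE_TO_CHAR = {0: "A", 1: "B", 2: "H", -1: "NA"}
CHAR_TO_CODE = {"A": 0, "B": 1, "H": 2, "NA": -1, "": -1}


def _check_markers(markers: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "bp"}
    if not required.issubset(markers.columns):
        raise ValueError(f"marker table needs columns {sorted(required)}")
    for _, sub in markers.groupby("chrom", sort=False):
        if not sub["bp"].is_monotonic_increasing:
            raise ValueError("markers must be sorted by bp within chromosome")
    return markers.reset_index(drop=True)


@dataclass
class SnpCallMatrix:
    """Observed genotype calls (lines x markers) with optional depth layer.

    Parameters
    ----------
    lines
        Line identifiers, one per row of ``calls``.
    markers
        Marker table with at least ``chrom`` and ``bp`` columns (optionally
        ``cm`` and ``marker``), sorted by (chrom, bp).
    calls
        ``int8`` array of shape (n_lines, n_markers) using the codes above.
    depth
        Optional nonnegative integer read depth per cell, same shape.
    """

    lines: list[str]
    markers: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.markers = _check_markers(self.markers)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.lines)}, {len(self.markers)})"
            )
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
            if self.depth.shape != self.calls.shape:
                raise ValueError("depth layer shape mismatch")
            if (self.depth < 0).any():
                raise ValueError("depth must be nonnegative")

    # ------------------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chroms(self) -> list:
        return list(pd.unique(self.markers["chrom"]))

    def chrom_indices(self, chrom) -> np.ndarray:
        """Column indices of the markers on one chromosome."""
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())

    def copy(self) -> "SnpCallMatrix":
        return SnpCallMatrix(
            lines=list(self.lines),
            markers=self.markers.copy(),
            calls=self.calls.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            meta=dict(self.meta),
        )

    def subset(self, line_mask=None, marker_mask=None) -> "SnpCallMatrix":
        """Return a new matrix restricted to the selected lines/markers."""
        lm = np.ones(self.n_lines, bool) if line_mask is None else np.asarray(line_mask)
        mm = (
            np.ones(self.n_markers, bool)
            if marker_mask is None
            else np.asarray(marker_mask)
        )
        return SnpCallMatrix(
            lines=[l for l, keep in zip(self.lines, lm) if keep],
            markers=self.markers.loc[mm].reset_index(drop=True),
            calls=self.calls[np.ix_(lm, mm)],
            depth=None if self.depth is None else self.depth[np.ix_(lm, mm)],
            meta=dict(self.meta),
        )

    # ------------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        """Calls as a lines x markers DataFrame of A/B/H/NA strings."""
        names = self.marker_names()
        chars = np.array(["NA", "A", "B", "H"])  # index by code+1
        data = chars[self.calls.astype(int) + 1]
        return pd.DataFrame(data, index=list(self.lines), columns=names)

    def marker_names(self) -> list[str]:
        if "marker" in self.markers.columns:
            return [str(m) for m in self.markers["marker"]]
        return [
            f"M{c}_{i}"
            for c, i in zip(self.markers["chrom"], range(1, self.n_markers + 1))
        ]

    def write_csv(self, path) -> None:
        """Write calls (and marker metadata header rows) to CSV."""
        df = self.to_dataframe()
        header = pd.DataFrame(
            [self.markers["chrom"].tolist(), self.markers["bp"].tolist()],
            index=["#chrom", "#bp"],
            columns=df.columns,
        )
        pd.concat([header, df]).to_csv(path, index_label="line")

    @classmethod
    def read_csv(cls, path) -> "SnpCallMatrix":
        raw = pd.read_csv(path, index_col=0, dtype=str)
        chrom = raw.loc["#chrom"]
        bp = raw.loc["#bp"].astype(np.int64)
        body = raw.drop(index=["#chrom", "#bp"])
        markers = pd.DataFrame(
            {"marker": raw.columns, "chrom": chrom.values, "bp": bp.values}
        )
        # chromosome labels may be ints; keep them comparable after round-trip
        try:
            markers["chrom"] = markers["chrom"].astype(int)
        except (TypeError, ValueError):
            pass
        calls = (
            body.fillna("NA").map(lambda s: CHAR_TO_CODE[str(s)]).to_numpy(np.int8)
        )
        return cls(lines=list(body.index), markers=markers, calls=calls)
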