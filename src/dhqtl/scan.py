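"""Interval mapping and composite interval mapping for DH populations.

Genotype probabilities at a grid of positions are computed from the
flanking informative markers under the Haldane model (no interference,
matching a Poisson crossover process).  At a grid point with flanking
recombination fractions r1, r2 and flank states (gL, gR),

    P(A | gL, gR) = fL fR / (fL fR + (1-fL)(1-fR)),

where fL = 1-r1 if gL = A else r1, and fR likewise.  Scans use
Haley-Knott regression of the phenotype on the genotype expectation
x = 2 P(A) - 1, with

    LOD = (n/2) log10(RSS0 / RSS1).

Composite interval mapping adds forward-selected background covariates
and drops those within ``window_cm`` of the test position.  Genome-wide
significance comes from permutation of the phenotype vector; support
intervals use the 1.5-LOD drop rule with a one-step flanking extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import A, B, SnpCallMatrix


@dataclass
class ProbGrid:
    """P(genotype = A) per line at each evaluation position."""

    positions: pd.DataFrame  # chrom, cm, bp
    p_a: np.ndarray  # n_lines x n_positions
    lines: list[str]

    @property
    def x(self) -> np.ndarray:
        """Haley-Knott regressor 2 P(A) - 1 in [-1, 1]."""
        return 2.0 * self.p_a - 1.0

    def subset_lines(self, mask) -> "ProbGrid":
        mask = np.asarray(mask)
        return ProbGrid(self.positions, self.p_a[mask],
                        [l for l, m in zip(self.lines, mask) if m])


@dataclass
class LodCurve:
    trait: str
    positions: pd.DataFrame  # chrom, cm, bp
    lod: np.ndarray
    method: str = "im"
    covariates: list[int] = field(default_factory=list)  # position indices
    active_covariates: list | None = None  # per-position covariate lists (cim)
    flags: list[str] = field(default_factory=list)


@dataclass
class PermutationResult:
    n_perm: int
    alpha: float
    null_max_lod: np.ndarray
    threshold: float
    seed: int | None = None


@dataclass
class QtlRecord:
    trait: str
    chrom: object
    peak_marker: str
    peak_cm: float
    peak_mb: float
    lod: float
    left_cm: float
    right_cm: float
    left_mb: float
    right_mb: float
    pve: float
    add: float


def _haldane_r(d_cm: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cm, float) / 50.0))


def genotype_probs(markers: pd.DataFrame, matrix: SnpCallMatrix,
                   step_cm: float = 1.0,
                   at_markers: bool = False) -> ProbGrid:
    """Conditional P(A) at grid positions from flanking informative markers.

    ``markers`` must carry ``chrom, bp, cm`` for every column of
    ``matrix`` (e.g. a :class:`~dhqtl.genmap.GeneticMap` table).
    Heterozygous and missing calls are uninformative; a line with no
    informative marker on a chromosome gets probability 0.5 there.
    With ``at_markers=True`` the evaluation positions are the marker
    positions themselves (used for CIM covariates).
    """
    pos_frames = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        cm = sub["cm"].to_numpy()
        if at_markers:
            grid_cm = cm
            grid_bp = sub["bp"].to_numpy().astype(float)
        else:
            L = cm.max()
            grid_cm = np.arange(0.0, L + step_cm / 2, step_cm)
            grid_cm[-1] = min(grid_cm[-1], L)
            grid_bp = np.interp(grid_cm, cm, sub["bp"].to_numpy().astype(float))
        pos_frames.append(pd.DataFrame(
            {"chrom": chrom, "cm": grid_cm, "bp": grid_bp}))
    positions = pd.concat(pos_frames, ignore_index=True)

    n_lines = matrix.n_lines
    p_a = np.full((n_lines, len(positions)), 0.5)
    col_of_chrom = {c: matrix.chrom_indices(c) for c in matrix.chroms}
    for chrom, pos_sub in positions.groupby("chrom", sort=False):
        cols = col_of_chrom[chrom]
        m_cm = markers["cm"].to_numpy()[cols]
        grid = pos_sub["cm"].to_numpy()
        out_idx = pos_sub.index.to_numpy()
        for li in range(n_lines):
            calls = matrix.calls[li, cols]
            inf = (calls == A) | (calls == B)
            if not inf.any():
                continue
            mpos = m_cm[inf]
            mg = calls[inf]  # 0 = A, 1 = B
            idx = np.searchsorted(mpos, grid)
            left = np.clip(idx - 1, 0, len(mpos) - 1)
            right = np.clip(idx, 0, len(mpos) - 1)
            has_left = idx > 0
            has_right = idx < len(mpos)
            r1 = _haldane_r(np.abs(grid - mpos[left]))
            r2 = _haldane_r(np.abs(mpos[right] - grid))
            f_l = np.where(mg[left] == A, 1.0 - r1, r1)
            f_r = np.where(mg[right] == A, 1.0 - r2, r2)
            f_l = np.where(has_left, f_l, 0.5)
            f_r = np.where(has_right, f_r, 0.5)
            num = f_l * f_r
            den = num + (1.0 - f_l) * (1.0 - f_r)
            p_a[li, out_idx] = num / den
    return ProbGrid(positions=positions, p_a=p_a, lines=list(matrix.lines))


# ----------------------------------------------------------------------
# scanning
# ----------------------------------------------------------------------

def _clean_y(grid: ProbGrid, phenotype) -> tuple[ProbGrid, np.ndarray]:
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(grid.lines).to_numpy(float)
    else:
        y = np.asarray(phenotype, float)
        if len(y) != len(grid.lines):
            raise ValueError("phenotype length != number of lines")
    keep = np.isfinite(y)
    return (grid.subset_lines(keep), y[keep]) if not keep.all() else (grid, y)


def _im_lod(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Vectorized single-regressor Haley-Knott LOD over all positions."""
    n = len(y)
    yc = y - y.mean()
    s0 = float(yc @ yc)
    flags = []
    if s0 == 0.0:
        return np.zeros(x.shape[1]), flags
    xc = x - x.mean(axis=0)
    sxx = (xc ** 2).sum(axis=0)
    sxy = xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = s0 - np.where(sxx > 0, sxy ** 2 / np.where(sxx > 0, sxx, 1.0), 0.0)
    rss1 = np.maximum(rss1, 0.0)
    lod = np.full(x.shape[1], np.inf)
    ok = rss1 > 0
    lod[ok] = (n / 2.0) * np.log10(s0 / rss1[ok])
    if not ok.all():
        flags.append("zero residual variance at some positions (LOD = inf)")
    return lod, flags


def scan_im(grid: ProbGrid, phenotype, trait: str = "trait") -> LodCurve:
    """Single-QTL interval-mapping scan (Haley-Knott regression)."""
    g, y = _clean_y(grid, phenotype)
    lod, flags = _im_lod(g.x, y)
    return LodCurve(trait=trait, positions=grid.positions.copy(), lod=lod,
                    method="im", flags=flags)


def _forward_select(x: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    """Forward selection of ``k`` covariate positions by RSS reduction."""
    n, p = x.shape
    resid_y = y - y.mean()
    rx = x - x.mean(axis=0)
    chosen: list[int] = []
    for _ in range(min(k, p)):
        sxx = (rx ** 2).sum(axis=0)
        sxy = rx.T @ resid_y
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(sxx > 1e-12, sxy ** 2 / np.where(sxx > 0, sxx, 1), 0.0)
        gain[chosen] = -np.inf
        j = int(np.argmax(gain))
        if gain[j] <= 0:
            break
        chosen.append(j)
        # residualize y and remaining X on the chosen column
        xj = rx[:, j].copy()
        denom = xj @ xj
        resid_y = resid_y - (xj @ resid_y) / denom * xj
        rx = rx - np.outer(xj, (xj @ rx) / denom)
    return chosen


def _ols_rss(Xd: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    r = y - Xd @ beta
    return float(r @ r)


def scan_cim(grid: ProbGrid, phenotype, trait: str = "trait",
             n_covariates: int = 3, window_cm: float = 10.0) -> LodCurve:
    """Composite interval mapping scan.

    Background covariates are forward-selected among the grid positions
    (k = ``n_covariates``); at each test position, covariates within
    ``window_cm`` on the same chromosome are excluded from both the
    null and the full model.  With ``n_covariates=0`` the scan reduces
    exactly to :func:`scan_im`.
    """
    g, y = _clean_y(grid, phenotype)
    if n_covariates == 0:
        curve = scan_im(grid, phenotype, trait=trait)
        curve.method = "cim"
        curve.active_covariates = [[] for _ in range(len(curve.lod))]
        return curve
    x = g.x
    n, p = x.shape
    flags: list[str] = []
    if n_covariates > p:
        flags.append(f"covariates reduced from {n_covariates} to {p}")
        n_covariates = p
    chosen = _forward_select(x, y, n_covariates)
    pos = grid.positions
    chrom = pos["chrom"].to_numpy()
    cm = pos["cm"].to_numpy()

    lod = np.zeros(p)
    active_lists = []
    ones = np.ones((n, 1))
    for j in range(p):
        active = [c for c in chosen
                  if not (chrom[c] == chrom[j] and abs(cm[c] - cm[j]) <= window_cm)]
        active_lists.append(active)
        x_cov = x[:, active] if active else np.empty((n, 0))
        rss0 = _ols_rss(np.hstack([ones, x_cov]), y)
        rss1 = _ols_rss(np.hstack([ones, x_cov, x[:, [j]]]), y)
        if rss1 <= 0:
            lod[j] = np.inf
            flags.append(f"zero residual variance at position {j}")
        else:
            lod[j] = (n / 2.0) * np.log10(rss0 / rss1)
    return LodCurve(trait=trait, positions=pos.copy(), lod=lod, method="cim",
                    covariates=chosen, active_covariates=active_lists,
                    flags=flags)


# ----------------------------------------------------------------------
# permutation threshold
# ----------------------------------------------------------------------

def permutation_threshold(grid: ProbGrid, phenotype, n_perm: int = 1000,
                          alpha: float = 0.05, seed: int | None = None,
                          method: str = "im", **scan_kw) -> PermutationResult:
    """Genome-wide LOD threshold from phenotype permutations.

    The phenotype vector is shuffled across lines ``n_perm`` times
    (genotypes intact), the genome-wide maximum LOD recorded per
    permutation, and the threshold taken as the empirical (1 - alpha)
    quantile of that null sample.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a meaningful quantile")
    g, y = _clean_y(grid, phenotype)
    rng = np.random.default_rng(seed)
    if method == "im":
        # vectorized: all permutations at once
        Y = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
        x = g.x
        n = len(y)
        Yc = Y - Y.mean(axis=0)
        s0 = (Yc ** 2).sum(axis=0)  # per permutation
        xc = x - x.mean(axis=0)
        sxx = (xc ** 2).sum(axis=0)
        sxy = xc.T @ Yc  # positions x perms
        with np.errstate(divide="ignore", invalid="ignore"):
            rss1 = s0[None, :] - np.where(
                sxx[:, None] > 0, sxy ** 2 / np.where(sxx[:, None] > 0,
                                                      sxx[:, None], 1.0), 0.0)
        rss1 = np.maximum(rss1, 1e-300)
        lod = (n / 2.0) * np.log10(s0[None, :] / rss1)
        null_max = lod.max(axis=0)
    elif method == "cim":
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            curve = scan_cim(g, rng.permutation(y), **scan_kw)
            null_max[i] = float(np.max(curve.lod))
    else:
        raise ValueError(f"unknown scan method {method!r}")
    threshold = float(np.quantile(null_max, 1.0 - alpha))
    return PermutationResult(n_perm=n_perm, alpha=alpha,
                             null_max_lod=null_max, threshold=threshold,
                             seed=seed)


# ----------------------------------------------------------------------
# peaks, intervals, effects
# ----------------------------------------------------------------------

def lod_support_interval(curve: LodCurve, peak_index: int,
                         drop: float = 1.5) -> tuple[int, int]:
    """1.5-LOD support interval around a peak, as position indices.

    The core is the contiguous run around the peak with
    LOD >= peak - drop (restricted to the peak's chromosome), extended
    one grid position beyond on each side where available.
    """
    chrom = curve.positions["chrom"].to_numpy()
    lod = curve.lod
    target = lod[peak_index] - drop
    same = np.flatnonzero(chrom == chrom[peak_index])
    lo_bound, hi_bound = same.min(), same.max()
    left = peak_index
    while left - 1 >= lo_bound and lod[left - 1] >= target:
        left -= 1
    right = peak_index
    while right + 1 <= hi_bound and lod[right + 1] >= target:
        right += 1
    # flanking convention: one step beyond when available
    left = max(left - 1, lo_bound)
    right = min(right + 1, hi_bound)
    return int(left), int(right)


def qtl_effects(grid: ProbGrid, phenotype, peak_index: int
                ) -> tuple[float, float]:
    """Additive effect and PVE of the single-QTL model at one position.

    The additive effect is the regression coefficient on x = 2P(A) - 1
    (half the difference between the genotype-class means); PVE is
    100 (1 - RSS1/RSS0).
    """
    g, y = _clean_y(grid, phenotype)
    x = g.x[:, peak_index]
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("degenerate genotype at peak (single class)")
    yc = y - y.mean()
    a = float(xc @ yc) / sxx
    s0 = float(yc @ yc)
    rss1 = s0 - (float(xc @ yc) ** 2) / sxx
    pve = 0.0 if s0 == 0 else 100.0 * (1.0 - rss1 / s0)
    return a, pve


def _local_maxima(lod: np.ndarray, idx: np.ndarray) -> list[int]:
    out = []
    for k, j in enumerate(idx):
        left_ok = k == 0 or idx[k - 1] != j - 1 or lod[j] >= lod[j - 1]
        right_ok = k == len(idx) - 1 or idx[k + 1] != j + 1 or lod[j] > lod[j + 1]
        if left_ok and right_ok:
            out.append(int(j))
    return out


def detect_qtls(curve: LodCurve, threshold: float, grid: ProbGrid,
                phenotype, markers: pd.DataFrame | None = None,
                drop: float = 1.5, min_sep_cm: float = 20.0
                ) -> list[QtlRecord]:
    """Call QTL peaks above a threshold and fill their records.

    Local maxima with LOD >= ``threshold`` are candidate peaks; two
    maxima on one chromosome are distinct QTL only when separated by a
    dip below (lower peak LOD - ``drop``) or by more than
    ``min_sep_cm``.  Each record carries the 1.5-LOD support interval,
    additive effect, PVE, and the nearest marker (when ``markers`` with
    ``marker, chrom, cm, bp`` columns are supplied).
    """
    pos = curve.positions
    chrom = pos["chrom"].to_numpy()
    cm = pos["cm"].to_numpy()
    lod = curve.lod
    records: list[QtlRecord] = []
    accepted: list[int] = []
    above = np.flatnonzero(lod >= threshold)
    if len(above) == 0:
        return records
    peaks = _local_maxima(lod, above)
    for j in sorted(peaks, key=lambda j: -lod[j]):
        distinct = True
        for a in accepted:
            if chrom[a] != chrom[j]:
                continue
            lo, hi = sorted((a, j))
            dip = lod[lo:hi + 1].min()
            if dip < lod[j] - drop or abs(cm[a] - cm[j]) > min_sep_cm:
                continue
            distinct = False
            break
        if distinct:
            accepted.append(j)
    for j in sorted(accepted):
        li, ri = lod_support_interval(curve, j, drop=drop)
        a, pve = qtl_effects(grid, phenotype, j)
        name = ""
        if markers is not None:
            msub = markers[markers["chrom"] == chrom[j]]
            nearest = (msub["cm"] - cm[j]).abs().idxmin()
            name = str(msub.loc[nearest, "marker"])
        records.append(QtlRecord(
            trait=curve.trait, chrom=chrom[j], peak_marker=name,
            peak_cm=float(cm[j]), peak_mb=float(pos["bp"].iloc[j] / 1e6),
            lod=float(lod[j]), left_cm=float(cm[li]), right_cm=float(cm[ri]),
            left_mb=float(pos["bp"].iloc[li] / 1e6),
            right_mb=float(pos["bp"].iloc[ri] / 1e6),
            pve=float(pve), add=float(a)))
    return records


def records_to_table(records: list[QtlRecord]) -> pd.DataFrame:
    """QTL records as a DataFrame mirroring the study's summary columns."""
    cols = ["trait", "chrom", "peak_marker", "peak_cm", "peak_mb", "lod",
            "left_cm", "right_cm", "left_mb", "right_mb", "pve", "add"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=cols)
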