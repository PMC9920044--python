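"""Sliding-window genotype calling and recombination-breakpoint resolution.

Low-coverage genotyping of a DH line yields sparse, error-prone
per-SNP calls.  Because a DH chromosome is a mosaic of long parental
segments, calls can be cleaned by voting in windows of consecutive
sequenced SNPs:

1. Windows of ``window_size`` (default 15) sequenced SNPs are tiled
   along each chromosome.  A window is called homozygous A (or B) when
   the fraction of A (or B) calls among its sites strictly exceeds
   ``hom_threshold`` (default 11/15); otherwise it is heterozygous (H).
2. A genuine crossover appears as a short run of H windows between two
   homozygous blocks.  Maximal H runs of at most ``max_het_run``
   (default 6) windows flanked by homozygous windows are split at their
   midpoint, each half joining its flanking genotype; a breakpoint is
   recorded at the physical midpoint between the two halves.  Longer H
   runs are left as heterozygous blocks.
3. Consecutive same-genotype windows merge into blocks.  Runs of three
   or more short (< ``transient_span_bp``) blocks with alternating
   genotypes collapse into one heterozygous block; homozygous blocks
   with fewer than ``min_block_snps`` SNPs or spanning less than
   ``min_block_bp`` are set missing (guards against false double
   crossovers), and heterozygous blocks with fewer than
   ``min_het_snps`` SNPs or spanning less than ``min_het_bp`` are set
   missing.
4. Block genotypes are projected back onto the SNP markers, giving a
   corrected genotype matrix for map construction and QTL scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import A, B, HET, MISSING, SnpCallMatrix


@dataclass
class BinmapParams:
    window_size: int = 15
    hom_threshold: float = 11 / 15
    max_het_run: int = 6
    min_block_snps: int = 5
    min_block_bp: int = 300_000
    min_het_snps: int = 15
    min_het_bp: int = 1_000_000
    transient_run: int = 3
    transient_span_bp: int = 300_000
    refine: bool = True  # SNP-level boundary refinement after the window vote
    dxo_min_snps: int = 5  # consecutive opposite calls that resurrect a segment


@dataclass
class WindowCall:
    """One window of sequenced SNPs with its voted genotype."""

    index: int
    snp_indices: np.ndarray  # marker indices (within chromosome)
    genotype: int
    first_bp: int
    last_bp: int

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


@dataclass
class Block:
    """A run of windows sharing one genotype in one line/chromosome."""

    genotype: int
    first_snp: int  # first/last sequenced marker index (within chromosome)
    last_snp: int
    n_snps: int
    first_bp: int
    last_bp: int

    @property
    def span_bp(self) -> int:
        return self.last_bp - self.first_bp


@dataclass
class BreakpointRecord:
    left_genotype: int
    right_genotype: int
    pos_bp: float
    uncertain: bool = False  # flanks separated by a missing/het gap


def call_windows(calls: np.ndarray, bp: np.ndarray,
                 window_size: int = 15, hom_threshold: float = 11 / 15,
                 step: int | None = None) -> list[WindowCall]:
    """Vote window genotypes over the sequenced SNPs of one chromosome.

    ``calls`` and ``bp`` are per-marker arrays for a single line and
    chromosome; missing calls are skipped when filling windows.  By
    default windows tile the sequenced SNPs (step = window size); a
    smaller ``step`` gives overlapping windows for sensitivity analysis
    (the block pipeline itself consumes tiled windows).
    """
    step = window_size if step is None else step
    seq = np.flatnonzero(calls != MISSING)
    windows: list[WindowCall] = []
    if len(seq) == 0:
        return windows
    starts = range(0, len(seq), step)
    for wi, s in enumerate(starts):
        members = seq[s:s + window_size]
        if len(members) == 0:
            break
        sub = calls[members]
        size = len(sub)
        frac_a = (sub == A).sum() / size
        frac_b = (sub == B).sum() / size
        if frac_a > hom_threshold:
            g = int(A)
        elif frac_b > hom_threshold:
            g = int(B)
        else:
            g = int(HET)
        windows.append(WindowCall(index=wi, snp_indices=members, genotype=g,
                                  first_bp=int(bp[members[0]]),
                                  last_bp=int(bp[members[-1]])))
        if len(members) < window_size and step == window_size:
            break  # short terminal window
    return windows


def _split_het_runs(genos: list[int], max_het_run: int) -> list[int]:
    """Reassign short H runs to their flanking homozygous genotypes.

    Runs of <= ``max_het_run`` H windows flanked on both sides by
    homozygous windows are split at the midpoint (odd runs put the
    extra window on the left half); runs at a chromosome end take the
    genotype of their single flank; longer runs stay H.
    """
    out = list(genos)
    n = len(out)
    i = 0
    while i < n:
        if out[i] != HET:
            i += 1
            continue
        j = i
        while j < n and out[j] == HET:
            j += 1
        run = j - i
        left = out[i - 1] if i > 0 else None
        right = out[j] if j < n else None
        if left is not None and right is not None:
            if run <= max_het_run:
                n_left = (run + 1) // 2  # extra window goes left
                for k in range(i, i + n_left):
                    out[k] = left
                for k in range(i + n_left, j):
                    out[k] = right
        elif left is not None:
            for k in range(i, j):
                out[k] = left
        elif right is not None:
            for k in range(i, j):
                out[k] = right
        # both None: chromosome entirely H; leave as is
        i = j
    return out


def _merge_windows(windows: list[WindowCall], genos: list[int]) -> list[Block]:
    blocks: list[Block] = []
    for w, g in zip(windows, genos):
        if blocks and blocks[-1].genotype == g:
            b = blocks[-1]
            b.last_snp = int(w.snp_indices[-1])
            b.n_snps += w.n_snps
            b.last_bp = w.last_bp
        else:
            blocks.append(Block(genotype=int(g),
                                first_snp=int(w.snp_indices[0]),
                                last_snp=int(w.snp_indices[-1]),
                                n_snps=w.n_snps,
                                first_bp=w.first_bp, last_bp=w.last_bp))
    return blocks


def resolve_breakpoints(windows: list[WindowCall], max_het_run: int = 6
                        ) -> tuple[list[Block], list[BreakpointRecord]]:
    """Split short H runs, merge windows into blocks, emit breakpoints.

    Breakpoints are recorded at the physical midpoint between the last
    SNP of each homozygous block and the first SNP of the next,
    whenever the two blocks carry different parental genotypes.
    """
    if not windows:
        return [], []
    genos = _split_het_runs([w.genotype for w in windows], max_het_run)
    blocks = _merge_windows(windows, genos)
    return blocks, blocks_to_breakpoints(blocks)


def blocks_to_breakpoints(blocks: list[Block]) -> list[BreakpointRecord]:
    """Breakpoints implied by a block sequence.

    Consecutive homozygous blocks with different parental genotypes
    yield a breakpoint at the midpoint of the physical gap between
    them; intervening missing or heterozygous blocks make the
    breakpoint position uncertain (flagged) but it is still emitted at
    the midpoint of the whole gap.
    """
    bps: list[BreakpointRecord] = []
    hom_idx = [i for i, b in enumerate(blocks) if b.genotype in (A, B)]
    for i, j in zip(hom_idx[:-1], hom_idx[1:]):
        left, right = blocks[i], blocks[j]
        if left.genotype != right.genotype:
            mid = 0.5 * (left.last_bp + right.first_bp)
            bps.append(BreakpointRecord(
                left_genotype=int(left.genotype),
                right_genotype=int(right.genotype),
                pos_bp=float(mid), uncertain=j != i + 1))
    return bps


def refine_block_boundaries(blocks: list[Block], calls: np.ndarray,
                            bp: np.ndarray, window_size: int = 15
                            ) -> list[Block]:
    """Sharpen A|B block boundaries to SNP resolution using raw calls.

    The window vote localizes a crossover only to window granularity.
    For each pair of directly adjacent homozygous blocks with different
    genotypes, the sequenced SNPs within two windows of the boundary
    are re-examined and the split point minimizing call mismatches
    (left calls against the left genotype, right calls against the
    right genotype; heterozygous calls are neutral) is chosen; ties
    resolve to the middle of the optimal range.  With noise-free input
    this recovers the exact transition SNP, making block projection an
    exact round trip.
    """
    blocks = [replace(b) for b in blocks]
    span = 2 * window_size
    for left, right in zip(blocks[:-1], blocks[1:]):
        if left.genotype not in (A, B) or right.genotype not in (A, B):
            continue
        if left.genotype == right.genotype:
            continue
        lseq = np.flatnonzero(calls[left.first_snp:left.last_snp + 1] != MISSING)
        lseq += left.first_snp
        rseq = np.flatnonzero(calls[right.first_snp:right.last_snp + 1] != MISSING)
        rseq += right.first_snp
        ltail = lseq[-span:]
        rhead = rseq[:span]
        if len(lseq) <= len(ltail) or len(rseq) <= len(rhead):
            # keep at least one SNP outside the search region per block
            ltail = lseq[1:] if len(lseq) > 1 else lseq[:0]
            rhead = rseq[:-1] if len(rseq) > 1 else rseq[:0]
        region = np.concatenate([ltail, rhead]).astype(int)
        if len(region) == 0:
            continue
        c = calls[region]
        # mismatch(k): region[:k] scored against left genotype, rest against right
        wrong_left = np.concatenate([[0], np.cumsum(c == right.genotype)])
        wrong_right = np.concatenate([[0], np.cumsum((c == left.genotype)[::-1])])[::-1]
        cost = wrong_left + wrong_right
        best = np.flatnonzero(cost == cost.min())
        k = int(best[len(best) // 2])
        n_left_region = k
        # rebuild extents: left block keeps SNPs before region plus k of it
        left_keep = np.concatenate([lseq[:len(lseq) - len(ltail)], region[:k]])
        right_keep = np.concatenate([region[k:], rseq[len(rhead):]])
        if len(left_keep) == 0 or len(right_keep) == 0:
            continue  # degenerate split; keep window-level boundary
        left.last_snp = int(left_keep[-1])
        left.n_snps = len(left_keep)
        left.last_bp = int(bp[left.last_snp])
        right.first_snp = int(right_keep[0])
        right.n_snps = len(right_keep)
        right.first_bp = int(bp[right.first_snp])
    return blocks


def recover_double_crossovers(blocks: list[Block], calls: np.ndarray,
                              bp: np.ndarray, min_snps: int = 5
                              ) -> list[Block]:
    """Resurrect short opposite-parent segments hidden by the window vote.

    A double crossover whose inner segment is shorter than one window
    never outvotes its window and is silently absorbed into the
    surrounding block.  Runs of at least ``min_snps`` consecutive
    sequenced calls of the opposite parent inside a homozygous block
    are split out as their own block at SNP resolution (a run of
    errors that long is vanishingly unlikely at realistic error rates);
    the small-block missing rules downstream still decide whether the
    resurrected segment is trusted.
    """
    out: list[Block] = []
    for blk in blocks:
        if blk.genotype not in (A, B):
            out.append(replace(blk))
            continue
        other = B if blk.genotype == A else A
        seq = np.flatnonzero(calls[blk.first_snp:blk.last_snp + 1] != MISSING)
        seq += blk.first_snp
        is_other = calls[seq] == other
        # maximal runs of consecutive opposite calls (in sequenced space)
        runs = []
        start = None
        for k, flag in enumerate(is_other):
            if flag and start is None:
                start = k
            elif not flag and start is not None:
                if k - start >= min_snps:
                    runs.append((start, k))
                start = None
        if start is not None and len(is_other) - start >= min_snps:
            runs.append((start, len(is_other)))
        if not runs:
            out.append(replace(blk))
            continue
        cursor = 0
        for s, e in runs:
            if s > cursor:
                left_idx = seq[cursor:s]
                out.append(Block(genotype=int(blk.genotype),
                                 first_snp=int(left_idx[0]),
                                 last_snp=int(left_idx[-1]),
                                 n_snps=len(left_idx),
                                 first_bp=int(bp[left_idx[0]]),
                                 last_bp=int(bp[left_idx[-1]])))
            mid_idx = seq[s:e]
            out.append(Block(genotype=int(other),
                             first_snp=int(mid_idx[0]),
                             last_snp=int(mid_idx[-1]),
                             n_snps=len(mid_idx),
                             first_bp=int(bp[mid_idx[0]]),
                             last_bp=int(bp[mid_idx[-1]])))
            cursor = e
        if cursor < len(seq):
            tail_idx = seq[cursor:]
            out.append(Block(genotype=int(blk.genotype),
                             first_snp=int(tail_idx[0]),
                             last_snp=int(tail_idx[-1]),
                             n_snps=len(tail_idx),
                             first_bp=int(bp[tail_idx[0]]),
                             last_bp=int(bp[tail_idx[-1]])))
    return out


def _collapse_transient(blocks: list[Block], params: BinmapParams) -> list[Block]:
    """Collapse runs of >=3 short alternating blocks into one H block."""
    out: list[Block] = []
    i = 0
    n = len(blocks)
    while i < n:
        j = i
        # grow a run of short blocks with strictly alternating genotypes
        while (j < n and blocks[j].span_bp < params.transient_span_bp
               and (j == i or blocks[j].genotype != blocks[j - 1].genotype)):
            j += 1
        if j - i >= params.transient_run:
            merged = replace(blocks[i])
            merged.genotype = int(HET)
            merged.last_snp = blocks[j - 1].last_snp
            merged.n_snps = sum(b.n_snps for b in blocks[i:j])
            merged.last_bp = blocks[j - 1].last_bp
            out.append(merged)
            i = j
        else:
            out.append(blocks[i])
            i += 1
    return out


def _remerge(blocks: list[Block]) -> list[Block]:
    out: list[Block] = []
    for b in blocks:
        if out and out[-1].genotype == b.genotype:
            prev = out[-1]
            prev.last_snp = b.last_snp
            prev.n_snps += b.n_snps
            prev.last_bp = b.last_bp
        else:
            out.append(replace(b))
    return out


def apply_missing_rules(blocks: list[Block],
                        params: BinmapParams | None = None) -> list[Block]:
    """Apply the small-block and het-block missing rules, then re-merge.

    Homozygous blocks with fewer than ``min_block_snps`` sequenced SNPs
    or spanning less than ``min_block_bp`` become missing (false double
    crossover guard); heterozygous blocks with fewer than
    ``min_het_snps`` SNPs or less than ``min_het_bp`` become missing.
    Short alternating-genotype block runs are first collapsed into a
    heterozygous block.
    """
    params = params or BinmapParams()
    blocks = _collapse_transient([replace(b) for b in blocks], params)
    for b in blocks:
        if b.genotype in (A, B):
            if b.n_snps < params.min_block_snps or b.span_bp < params.min_block_bp:
                b.genotype = int(MISSING)
        elif b.genotype == HET:
            if b.n_snps < params.min_het_snps or b.span_bp < params.min_het_bp:
                b.genotype = int(MISSING)
    return _remerge(blocks)


def project_to_snps(blocks: list[Block], bp: np.ndarray) -> np.ndarray:
    """Write block genotypes back onto the marker grid of one chromosome.

    Markers inside a block's physical extent take its genotype; markers
    between two blocks are assigned by the midpoint of the gap (the
    breakpoint convention), so a single A|B boundary projects as a step
    function.  Markers beyond the outermost blocks take the terminal
    block's genotype.  With no blocks at all, every marker is missing.
    """
    out = np.full(len(bp), MISSING, dtype=np.int8)
    if not blocks:
        return out
    # boundaries midway between adjacent blocks
    edges = [-np.inf]
    for leftb, rightb in zip(blocks[:-1], blocks[1:]):
        edges.append(0.5 * (leftb.last_bp + rightb.first_bp))
    edges.append(np.inf)
    for b, lo, hi in zip(blocks, edges[:-1], edges[1:]):
        sel = (bp > lo) & (bp <= hi)
        out[sel] = b.genotype
    return out


def run_binmap(matrix: SnpCallMatrix, params: BinmapParams | None = None
               ) -> tuple[SnpCallMatrix, pd.DataFrame, pd.DataFrame]:
    """Run the full window -> block -> projection pipeline on a matrix.

    Returns ``(corrected, blocks, breakpoints)`` where ``corrected`` is
    a :class:`SnpCallMatrix` of cleaned per-marker genotypes, and the
    two DataFrames tabulate every block and breakpoint per line and
    chromosome (breakpoint positions in bp).
    """
    params = params or BinmapParams()
    corrected = np.full_like(matrix.calls, MISSING)
    block_rows, bp_rows = [], []
    geno_char = {0: "A", 1: "B", 2: "H", -1: "NA"}
    for chrom in matrix.chroms:
        cols = matrix.chrom_indices(chrom)
        bp = matrix.markers["bp"].to_numpy()[cols]
        for li, line in enumerate(matrix.lines):
            calls = matrix.calls[li, cols]
            windows = call_windows(calls, bp, window_size=params.window_size,
                                   hom_threshold=params.hom_threshold)
            blocks, _ = resolve_breakpoints(windows, params.max_het_run)
            if params.refine:
                blocks = refine_block_boundaries(blocks, calls, bp,
                                                 params.window_size)
                blocks = recover_double_crossovers(blocks, calls, bp,
                                                   params.dxo_min_snps)
            blocks = apply_missing_rules(blocks, params)
            corrected[li, cols] = project_to_snps(blocks, bp)
            for b in blocks:
                block_rows.append((line, chrom, geno_char[b.genotype],
                                   b.first_snp, b.last_snp, b.n_snps,
                                   b.first_bp, b.last_bp, b.span_bp))
            for rec in blocks_to_breakpoints(blocks):
                bp_rows.append((line, chrom, geno_char[rec.left_genotype],
                                geno_char[rec.right_genotype], rec.pos_bp,
                                rec.uncertain))
    corrected_matrix = SnpCallMatrix(
        lines=list(matrix.lines), markers=matrix.markers.copy(),
        calls=corrected, meta={**matrix.meta, "binmap": vars(params)})
    blocks_df = pd.DataFrame(block_rows, columns=[
        "line", "chrom", "genotype", "first_snp", "last_snp", "n_snps",
        "first_bp", "last_bp", "span_bp"])
    breakpoints_df = pd.DataFrame(bp_rows, columns=[
        "line", "chrom", "left", "right", "pos_bp", "uncertain"])
    return corrected_matrix, blocks_df, breakpoints_df


def infer_blocks(calls: np.ndarray, bp: np.ndarray,
                 params: BinmapParams | None = None
                 ) -> tuple[list[Block], list[BreakpointRecord]]:
    """Window, resolve and clean one line/chromosome in a single call."""
    params = params or BinmapParams()
    windows = call_windows(calls, bp, window_size=params.window_size,
                           hom_threshold=params.hom_threshold)
    blocks, _ = resolve_breakpoints(windows, params.max_het_run)
    if params.refine:
        blocks = refine_block_boundaries(blocks, calls, bp, params.window_size)
        blocks = recover_double_crossovers(blocks, calls, bp,
                                           params.dxo_min_snps)
    blocks = apply_missing_rules(blocks, params)
    return blocks, blocks_to_breakpoints(blocks)
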