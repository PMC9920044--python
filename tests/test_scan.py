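import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from dhqtl import scan as S
from dhqtl.matrix import A, B, MISSING, SnpCallMatrix
from dhqtl.simulate import (
    SimConfig,
    genome_to_calls,
    make_parental_map,
    simulate_genomes,
)


def prob_grid_from_x(x):
    """ProbGrid for a single position from a +-1 genotype vector."""
    x = np.asarray(x, float)
    return S.ProbGrid(
        positions=pd.DataFrame({"chrom": [1], "cm": [0.0], "bp": [100.0]}),
        p_a=((x + 1) / 2).reshape(-1, 1),
        lines=[f"L{i}" for i in range(len(x))])


def sim_grid(n_lines=400, n_snps=100, n_chrom=1, seed=0, step_cm=1.0):
    rng = np.random.default_rng(seed)
    cfg = SimConfig.small(n_chrom=n_chrom, n_snps=n_snps, n_lines=n_lines,
                          seed=seed)
    pmap = make_parental_map(cfg, rng)
    genomes, _ = simulate_genomes(cfg, pmap, rng)
    calls = np.vstack([genome_to_calls(g, pmap) for g in genomes])
    matrix = SnpCallMatrix(lines=[f"L{i}" for i in range(n_lines)],
                           markers=pmap, calls=calls)
    grid = S.genotype_probs(pmap, matrix, step_cm=step_cm)
    return grid, genomes, rng


class TestGenotypeProbs:
    def test_observed_marker_probability_is_certain(self):
        markers = pd.DataFrame({"marker": ["m1", "m2"], "chrom": [1, 1],
                                "bp": [1_000_000, 21_000_000],
                                "cm": [0.0, 20.0]})
        mat = SnpCallMatrix(lines=["L1"], markers=markers,
                            calls=np.array([[A, B]], dtype=np.int8))
        grid = S.genotype_probs(markers, mat, step_cm=20.0)
        assert grid.p_a[0, 0] == pytest.approx(1.0)
        assert grid.p_a[0, -1] == pytest.approx(0.0)

    def test_midpoint_closed_form_flanks_aa(self):
        markers = pd.DataFrame({"marker": ["m1", "m2"], "chrom": [1, 1],
                                "bp": [1_000_000, 21_000_000],
                                "cm": [0.0, 20.0]})
        mat = SnpCallMatrix(lines=["L1"], markers=markers,
                            calls=np.array([[A, A]], dtype=np.int8))
        grid = S.genotype_probs(markers, mat, step_cm=10.0)
        r = 0.5 * (1 - np.exp(-10 / 50))
        expected = (1 - r) ** 2 / ((1 - r) ** 2 + r ** 2)
        assert grid.p_a[0, 1] == pytest.approx(expected, abs=1e-12)
        assert grid.p_a[0, 1] == pytest.approx(0.9902, abs=5e-5)

    def test_equidistant_opposite_flanks_half(self):
        markers = pd.DataFrame({"marker": ["m1", "m2"], "chrom": [1, 1],
                                "bp": [1_000_000, 21_000_000],
                                "cm": [0.0, 20.0]})
        mat = SnpCallMatrix(lines=["L1"], markers=markers,
                            calls=np.array([[A, B]], dtype=np.int8))
        grid = S.genotype_probs(markers, mat, step_cm=10.0)
        assert grid.p_a[0, 1] == pytest.approx(0.5)

    def test_uninformative_line_gets_half_everywhere(self):
        markers = pd.DataFrame({"marker": ["m1", "m2"], "chrom": [1, 1],
                                "bp": [1_000_000, 21_000_000],
                                "cm": [0.0, 20.0]})
        mat = SnpCallMatrix(lines=["L1"], markers=markers,
                            calls=np.array([[MISSING, MISSING]],
                                           dtype=np.int8))
        grid = S.genotype_probs(markers, mat, step_cm=5.0)
        assert (grid.p_a[0] == 0.5).all()


class TestScanIm:
    def test_hand_computed_toy_lod(self):
        grid = prob_grid_from_x([1, 1, 1, 1, -1, -1, -1, -1])
        y = np.array([3.0, 2, 3, 2, 1, 0, 1, 0])
        curve = S.scan_im(grid, y)
        assert curve.lod[0] == pytest.approx(4 * np.log10(5), abs=1e-12)

    def test_constant_phenotype_zero_lod(self):
        grid, _, _ = sim_grid(n_lines=50, n_snps=30, seed=1)
        curve = S.scan_im(grid, np.full(50, 7.0))
        assert (curve.lod == 0).all()

    def test_matches_least_squares_oracle(self):
        """HK LOD equals (n/2) log10 RSS ratio from an independent
        per-position least-squares fit, on 50 random instances."""
        rng = np.random.default_rng(2)
        for _ in range(50):
            n, p = rng.integers(10, 40), rng.integers(2, 8)
            pa = rng.random((n, p))
            grid = S.ProbGrid(
                positions=pd.DataFrame({"chrom": 1, "cm": np.arange(p, dtype=float),
                                        "bp": np.arange(p, dtype=float)}),
                p_a=pa, lines=[f"L{i}" for i in range(n)])
            y = rng.normal(size=n)
            curve = S.scan_im(grid, y)
            x = 2 * pa - 1
            for j in range(p):
                X = np.column_stack([np.ones(n), x[:, j]])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                rss1 = ((y - X @ beta) ** 2).sum()
                rss0 = ((y - y.mean()) ** 2).sum()
                expected = (n / 2) * np.log10(rss0 / rss1)
                assert curve.lod[j] == pytest.approx(expected, abs=1e-8)

    def test_affine_phenotype_invariance(self):
        grid, _, _ = sim_grid(n_lines=80, n_snps=40, seed=3)
        y = np.random.default_rng(3).normal(size=80)
        l1 = S.scan_im(grid, y).lod
        l2 = S.scan_im(grid, 3.5 * y - 11.0).lod
        assert np.allclose(l1, l2, atol=1e-10)

    def test_perfect_fit_reported_infinite_with_flag(self):
        grid = prob_grid_from_x([1, 1, -1, -1])
        y = np.array([1.0, 1, -1, -1])
        curve = S.scan_im(grid, y)
        assert np.isinf(curve.lod[0])
        assert curve.flags


class TestScanCim:
    def test_zero_covariates_reduces_to_im(self):
        grid, genomes, rng = sim_grid(n_lines=100, n_snps=50, seed=4)
        y = rng.normal(size=100)
        im = S.scan_im(grid, y)
        cim = S.scan_cim(grid, y, n_covariates=0)
        assert np.allclose(im.lod, cim.lod)

    def test_covariates_inside_window_excluded_per_position(self):
        grid, genomes, rng = sim_grid(n_lines=100, n_snps=50, seed=5)
        x = np.array([1 if g.genotype_at(1, 50.0) == 0 else -1
                      for g in genomes])
        y = 2.0 * x + rng.normal(size=100)
        curve = S.scan_cim(grid, y, n_covariates=2, window_cm=10.0)
        cm = curve.positions["cm"].to_numpy()
        for j, active in enumerate(curve.active_covariates):
            for c in active:
                assert abs(cm[c] - cm[j]) > 10.0

    def test_linked_qtl_resolved_as_two_peaks(self):
        """Two QTL 40 cM apart on one chromosome give two distinct
        CIM peaks above threshold."""
        grid, genomes, rng = sim_grid(n_lines=400, n_snps=120, seed=6)
        x1 = np.array([1 if g.genotype_at(1, 30.0) == 0 else -1
                       for g in genomes])
        x2 = np.array([1 if g.genotype_at(1, 70.0) == 0 else -1
                       for g in genomes])
        y = 1.5 * x1 + 1.5 * x2 + rng.normal(0, 2.0, 400)
        curve = S.scan_cim(grid, y, n_covariates=3, window_cm=10.0)
        recs = S.detect_qtls(curve, 3.0, grid, y)
        cms = sorted(r.peak_cm for r in recs if r.chrom == 1)
        assert len(cms) >= 2
        assert any(abs(c - 30) < 10 for c in cms)
        assert any(abs(c - 70) < 10 for c in cms)

    def test_more_covariates_than_positions_reduced_with_warning(self):
        grid = prob_grid_from_x([1, -1, 1, -1, 1, -1])
        y = np.array([1.0, 2, 3, 4, 5, 6])
        curve = S.scan_cim(grid, y, n_covariates=5)
        assert any("reduced" in f for f in curve.flags)


class TestPermutationThreshold:
    def test_alpha_one_gives_null_minimum(self):
        grid, _, rng = sim_grid(n_lines=60, n_snps=30, seed=7)
        y = rng.normal(size=60)
        perm = S.permutation_threshold(grid, y, n_perm=50, alpha=1.0, seed=1)
        assert perm.threshold == pytest.approx(perm.null_max_lod.min())

    def test_fixed_seed_reproducible(self):
        grid, _, rng = sim_grid(n_lines=60, n_snps=30, seed=8)
        y = rng.normal(size=60)
        t1 = S.permutation_threshold(grid, y, n_perm=50, seed=9).threshold
        t2 = S.permutation_threshold(grid, y, n_perm=50, seed=9).threshold
        assert t1 == t2

    def test_too_few_permutations_rejected(self):
        grid = prob_grid_from_x([1, -1, 1, -1])
        with pytest.raises(ValueError):
            S.permutation_threshold(grid, np.ones(4), n_perm=10)

    def test_threshold_is_empirical_quantile(self):
        grid, _, rng = sim_grid(n_lines=60, n_snps=30, seed=10)
        y = rng.normal(size=60)
        perm = S.permutation_threshold(grid, y, n_perm=100, alpha=0.05,
                                       seed=2)
        assert perm.threshold == pytest.approx(
            np.quantile(perm.null_max_lod, 0.95))


class TestSupportInterval:
    def _curve(self, lods, chrom=None):
        n = len(lods)
        return S.LodCurve(
            trait="t",
            positions=pd.DataFrame({
                "chrom": chrom if chrom is not None else [1] * n,
                "cm": np.arange(n, dtype=float),
                "bp": np.arange(n, dtype=float) * 1e6}),
            lod=np.asarray(lods, float))

    def test_flanking_convention(self):
        left, right = S.lod_support_interval(self._curve([1, 3, 5, 4, 2]), 2)
        assert (left, right) == (1, 4)

    def test_monotone_curve_clipped_at_chromosome_end(self):
        left, right = S.lod_support_interval(self._curve([1, 2, 3, 4, 5]), 4)
        assert right == 4
        assert left == 2  # core {3,4} extended one step

    def test_flat_curve_spans_whole_chromosome(self):
        left, right = S.lod_support_interval(self._curve([3, 3, 3, 3]), 1)
        assert (left, right) == (0, 3)

    def test_interval_confined_to_peak_chromosome(self):
        curve = self._curve([5, 5, 5, 5], chrom=[1, 1, 2, 2])
        left, right = S.lod_support_interval(curve, 2)
        assert (left, right) == (2, 3)


class TestEffects:
    def test_class_means_give_additive_effect(self):
        grid = prob_grid_from_x([1, 1, -1, -1])
        y = np.array([2.5, 2.5, 0.5, 0.5])
        a, pve = S.qtl_effects(grid, y, 0)
        assert a == pytest.approx(1.0)

    def test_toy_dataset_pve(self):
        grid = prob_grid_from_x([1, 1, 1, 1, -1, -1, -1, -1])
        y = np.array([3.0, 2, 3, 2, 1, 0, 1, 0])
        _, pve = S.qtl_effects(grid, y, 0)
        assert pve == pytest.approx(80.0)

    def test_zero_effect_zero_pve(self):
        grid = prob_grid_from_x([1, -1, 1, -1])
        y = np.array([1.0, 1.0, 1.0, 1.0])
        a, pve = S.qtl_effects(grid, y, 0)
        assert a == 0.0 and pve == 0.0

    def test_degenerate_single_class_rejected(self):
        grid = prob_grid_from_x([1, 1, 1, 1])
        with pytest.raises(ValueError):
            S.qtl_effects(grid, np.arange(4.0), 0)


class TestDetectQtls:
    def test_curve_below_threshold_empty(self):
        grid, _, rng = sim_grid(n_lines=60, n_snps=30, seed=11)
        y = rng.normal(size=60)
        curve = S.scan_im(grid, y)
        assert S.detect_qtls(curve, 1e6, grid, y) == []

    def test_single_peak_record_invariants(self):
        grid, genomes, rng = sim_grid(n_lines=300, n_snps=80, seed=12)
        x = np.array([1 if g.genotype_at(1, 50.0) == 0 else -1
                      for g in genomes])
        y = 2.0 * x + rng.normal(size=300)
        curve = S.scan_im(grid, y)
        recs = S.detect_qtls(curve, 3.0, grid, y)
        assert len(recs) >= 1
        r = max(recs, key=lambda r: r.lod)
        assert r.left_cm <= r.peak_cm <= r.right_cm
        assert r.left_mb <= r.peak_mb <= r.right_mb
        assert 0 <= r.pve <= 100
        assert r.lod >= 3.0
        assert abs(r.peak_cm - 50.0) < 10.0
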