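import numpy as np
import pandas as pd
import pytest

from dhqtl.matrix import SnpCallMatrix
from dhqtl.simulate import (
    ObservationModel,
    SimConfig,
    make_parental_map,
    genome_to_calls,
    simulate_genomes,
    simulate_population,
)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def clean_population():
    """Noise-free 2-chromosome population: observed calls equal truth."""
    cfg = SimConfig.small(n_chrom=2, n_snps=500, n_lines=50, seed=5)
    obs = ObservationModel(missing_rate=0.0, error_rate=0.0, het_rate=0.0)
    matrix, _, truth = simulate_population(cfg, obs)
    return matrix, truth


@pytest.fixture(scope="session")
def noisy_population():
    """Moderately sized noisy population shared across tests."""
    cfg = SimConfig.small(n_chrom=2, n_snps=800, n_lines=120, seed=7)
    obs = ObservationModel(missing_rate=0.3, error_rate=0.02, het_rate=0.02)
    matrix, _, truth = simulate_population(cfg, obs)
    return matrix, truth


@pytest.fixture(scope="session")
def true_call_population():
    """400-line single-chromosome population with fully observed truth."""
    rng = np.random.default_rng(99)
    cfg = SimConfig.small(n_chrom=1, n_snps=100, n_lines=400, seed=99)
    pmap = make_parental_map(cfg, rng)
    genomes, crossovers = simulate_genomes(cfg, pmap, rng)
    calls = np.vstack([genome_to_calls(g, pmap) for g in genomes])
    matrix = SnpCallMatrix(lines=[f"L{i}" for i in range(cfg.n_lines)],
                           markers=pmap, calls=calls)
    return matrix, genomes, pmap


def make_matrix(calls, bp=None, chrom=1, depth=None, lines=None):
    """Small helper to build a SnpCallMatrix from a raw call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_lines, n_markers = calls.shape
    if bp is None:
        bp = np.arange(1, n_markers + 1) * 100_000
    markers = pd.DataFrame({
        "marker": [f"M{chrom}_{i + 1}" for i in range(n_markers)],
        "chrom": chrom, "bp": np.asarray(bp),
        "cm": np.asarray(bp) / 1e6})
    return SnpCallMatrix(
        lines=lines or [f"L{i + 1}" for i in range(n_lines)],
        markers=markers, calls=calls, depth=depth)
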