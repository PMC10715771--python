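import numpy as np
import pytest

from copeaks import (
    LociGrid,
    OptimizeParams,
    ScoreParams,
    generate_synthetic_signals,
    score,
)


@pytest.fixture
def small_grid():
    return LociGrid(chrom="chr1", origin=0, L=50, n=3)


@pytest.fixture
def block_matrix():
    """Zero-noise 4-sample matrix with one planted block at loci 3-5."""
    return generate_synthetic_signals(
        n=8, K=4, blocks=[(3, 5, 10.0)], dispersion=0.0, noise=0.0, seed=0
    )


@pytest.fixture
def two_block_fixture():
    """Two enriched blocks separated by a 3-locus gap, zero noise.

    Used to exercise the fragmentation penalty: at gamma=0 the zero-score
    gap is not worth selecting, while any gamma>0 merges the two blocks.
    """
    matrix = generate_synthetic_signals(
        n=60,
        K=6,
        blocks=[(20, 27, 10.0), (31, 38, 10.0)],
        dispersion=0.0,
        noise=0.0,
        seed=0,
    )
    return matrix, score(matrix)


def random_instance(rng, n_range=(4, 12), K_range=(1, 10)):
    """One random small problem: a score vector from a synthetic matrix plus
    random budget/penalty, for oracle cross-checks."""
    n = int(rng.integers(*n_range, endpoint=True))
    K = int(rng.integers(*K_range, endpoint=True))
    values = rng.gamma(shape=1.0, scale=2.0, size=(K, n))
    grid = LociGrid(chrom="chrR", n=n)
    from copeaks import SignalMatrix

    matrix = SignalMatrix(grid=grid, sample_ids=[f"s{k}" for k in range(K)], values=values)
    sv = score(matrix, ScoreParams())
    gamma = float(rng.choice([0.0, 0.5, 1.0, 5.0]))
    b = float(rng.choice([0.1, 0.3, 0.5, 0.7, 0.9]))
    return sv, OptimizeParams(b=b, gamma=gamma)
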