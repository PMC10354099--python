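import numpy as np
import pytest

from tmescreen.enrichment import RankedProfile
from tmescreen.types import ExpressionMatrix


@pytest.fixture
def four_gene_profile() -> RankedProfile:
    """Ranked profile (g1..g4) with scores (4,3,2,1) used in worked examples."""
    return RankedProfile(genes=["g1", "g2", "g3", "g4"], scores=np.array([4.0, 3.0, 2.0, 1.0]))


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    return ExpressionMatrix(
        gene_ids=["A", "B", "C"],
        sample_ids=["s1", "s2"],
        values=np.array([[3.0, 1.0], [1.0, 2.0], [2.0, 2.0]]),
    )


def ssgsea_oracle(ordered_in_set: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Independent cumulative-difference oracle for the single-sample score.

    Walks the ranked list position by position, accumulating the weighted
    in-set fraction minus the uniform out-of-set fraction; no vectorized
    shortcuts shared with the implementation.
    """
    n = len(ordered_in_set)
    n_in = int(ordered_in_set.sum())
    if weights is None:
        weights = np.ones(n)
    total_in = sum(w for w, m in zip(weights, ordered_in_set) if m)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for i in range(n):
        if ordered_in_set[i]:
            cum_in += weights[i]
        else:
            cum_out += 1
        es += cum_in / total_in - cum_out / (n - n_in)
    return es


def gsea_oracle(ordered_in_set: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Independent running-sum enumeration for the two-class score."""
    n = len(ordered_in_set)
    n_in = int(ordered_in_set.sum())
    if weights is None:
        weights = np.ones(n)
    total_in = sum(w for w, m in zip(weights, ordered_in_set) if m)
    best = 0.0
    running = 0.0
    cum_in = 0.0
    cum_out = 0
    for i in range(n):
        if ordered_in_set[i]:
            cum_in += weights[i]
        else:
            cum_out += 1
        running = cum_in / total_in - cum_out / (n - n_in)
        if abs(running) > abs(best):
            best = running
    return best
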