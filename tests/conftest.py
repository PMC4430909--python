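import numpy as np
import pytest


def ward_oracle(S):
    """From-scratch adjacency-constrained Ward reference.

    At every step, recomputes the merge cost of every adjacent block pair
    directly from the dense similarity matrix (2-D prefix sums for the
    block sums) and merges the leftmost minimizer. Independent of the
    incremental implementation under test.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    P = np.zeros((p + 1, p + 1))
    P[1:, 1:] = S.cumsum(axis=0).cumsum(axis=1)

    def bsum(a, b, c, d):
        return P[b, d] - P[a, d] - P[b, c] + P[a, c]

    blocks = [(j, j + 1) for j in range(p)]
    merges = []
    W = [0.0]
    while len(blocks) > 1:
        best = None
        for i in range(len(blocks) - 1):
            (a, b), (c, d) = blocks[i], blocks[i + 1]
            pg, ph = b - a, d - c
            cost = (pg * ph / (pg + ph)) * (
                bsum(a, b, a, b) / pg**2
                + bsum(c, d, c, d) / ph**2
                - 2.0 * bsum(a, b, c, d) / (pg * ph)
            )
            if best is None or cost < best[0]:
                best = (cost, i)
        cost, i = best
        merges.append((blocks[i], blocks[i + 1], cost))
        W.append(W[-1] + cost)
        blocks[i : i + 2] = [(blocks[i][0], blocks[i + 1][1])]
    return merges, np.array(W)


def oracle_partition(S, G):
    """Partition into G blocks implied by the oracle's merge order."""
    p = len(S)
    merges, _ = ward_oracle(S)
    starts = set(range(p))
    for left, right, _ in merges[: p - G]:
        starts.discard(right[0])
    return np.array(sorted(starts))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_similarity():
    def make(p, seed=0):
        r = np.random.default_rng(seed)
        S = r.uniform(0.0, 1.0, (p, p))
        S = (S + S.T) / 2.0
        np.fill_diagonal(S, 1.0)
        return S

    return make
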