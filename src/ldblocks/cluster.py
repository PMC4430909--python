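"""Adjacency-constrained Ward clustering of SNPs on an LD similarity kernel.

The algorithm is Ward's incremental sum-of-squares agglomeration expressed
purely through pairwise similarities (a kernel trick): writing S_gg' for
the sum of similarities s(j, k) = r^2(j, k) over all ordered pairs
(j in g, k in g') -- so S_gg includes self-pairs and a singleton has
S_gg = s(j, j) = 1 -- the within-group dispersion of a partition into G
groups is

    W_G = p - sum_g S_gg / p_g

and merging adjacent groups g, g' increases W by

    d_{g,g'} = (p_g p_g' / (p_g + p_g')) (S_gg/p_g^2 + S_g'g'/p_g'^2
                                          - 2 S_gg'/(p_g p_g')).

Only groups adjacent on the genome may merge, so at most (number of
clusters - 1) candidate merges are live at any time; cross-sums are
maintained additively (S_{(g u g')h} = S_gh + S_g'h) and fresh similarity
values are requested lazily from the provider only when a merge creates a
new neighbor pair. Merge heights need not be monotone across steps: the
adjacency constraint can produce inversions and no ultrametric assumption
is made.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MergeStep",
    "ClusterTree",
    "BlockStructure",
    "DenseSimilarity",
    "ward_constrained",
    "cut",
    "within_dispersion",
]


class DenseSimilarity:
    """Adapter exposing a dense symmetric similarity matrix as a provider."""

    def __init__(self, S):
        S = np.asarray(S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("similarity matrix must be square")
        self.S = S
        self.p = S.shape[0]

    def r2(self, j, k):
        return float(self.S[j, k])

    def r2_pairs(self, js, ks):
        return self.S[np.asarray(js), np.asarray(ks)]

    def sum_block(self, rows, cols):
        return float(self.S[np.ix_(np.asarray(rows), np.asarray(cols))].sum())


@dataclass(frozen=True)
class MergeStep:
    """One agglomeration: merge of two genomically adjacent clusters.

    ``left`` and ``right`` are 0-based half-open column ranges; ``height``
    is the Ward merge cost d_{g,g'}.
    """

    left: tuple[int, int]
    right: tuple[int, int]
    height: float
    step_index: int


@dataclass
class ClusterTree:
    """The p-1 constrained merges plus the dispersion profile.

    ``W_profile[G]`` (index 1..p) is the within-group dispersion of the
    partition into G clusters obtained by cutting after p-G merges;
    W_profile[p] = 0 and W_{G-1} = W_G + height of the (p-G+1)-th merge.
    Index 0 is unused (NaN).
    """

    merges: list[MergeStep]
    W_profile: np.ndarray
    p: int

    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])


@dataclass
class BlockStructure:
    """A partition of the p SNPs into G contiguous blocks in genomic order."""

    starts: np.ndarray  # G block start columns, 0-based, ascending
    p: int

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=int)
        if self.starts[0] != 0 or not (np.diff(self.starts) > 0).all():
            raise ValueError("block starts must begin at 0 and be strictly increasing")
        if self.starts[-1] >= self.p:
            raise ValueError("block start beyond matrix width")

    @property
    def G(self) -> int:
        return len(self.starts)

    @property
    def sizes(self) -> np.ndarray:
        return np.diff(np.append(self.starts, self.p))

    @property
    def ranges(self) -> list[tuple[int, int]]:
        """0-based half-open (start, stop) per block."""
        stops = np.append(self.starts[1:], self.p)
        return list(zip(self.starts.tolist(), stops.tolist()))

    def labels(self) -> np.ndarray:
        """Block index (0-based) per SNP."""
        lab = np.zeros(self.p, dtype=int)
        for g, (a, b) in enumerate(self.ranges):
            lab[a:b] = g
        return lab

    @classmethod
    def from_sizes(cls, sizes) -> "BlockStructure":
        sizes = np.asarray(sizes, dtype=int)
        starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        return cls(starts=starts, p=int(sizes.sum()))


def _merge_cost(pg, ph, Sgg, Shh, Sgh):
    return (pg * ph / (pg + ph)) * (Sgg / pg**2 + Shh / ph**2 - 2.0 * Sgh / (pg * ph))


def ward_constrained(similarity, p: int | None = None) -> ClusterTree:
    """Run the adjacency-constrained Ward agglomeration.

    Parameters
    ----------
    similarity : provider with ``sum_block(rows, cols)`` (and optionally
        ``r2_pairs``), e.g. :class:`~ldblocks.ld.LDProvider`, or a dense
        symmetric similarity matrix.
    p : leaf count; inferred from the provider if omitted.

    Ties between equal minimal merge costs break toward the leftmost
    (smallest starting index) pair, so the result is deterministic.
    """
    if isinstance(similarity, np.ndarray):
        similarity = DenseSimilarity(similarity)
    if p is None:
        p = similarity.p
    if p < 2:
        raise ValueError("clustering requires at least 2 SNPs")

    start = np.arange(p)
    end = np.arange(1, p + 1)  # half-open
    size = np.ones(p, dtype=np.int64)
    nxt = np.arange(1, p + 1)  # p == sentinel "none"
    prv = np.arange(-1, p - 1)
    active = np.ones(p, dtype=bool)
    gen = np.zeros(p, dtype=np.int64)

    # singleton self-sums: s(j, j), which is 1 for an r^2 kernel
    if hasattr(similarity, "r2_pairs"):
        idx = np.arange(p)
        Sgg = np.asarray(similarity.r2_pairs(idx, idx), dtype=float).copy()
        Scross = np.empty(p)
        Scross[: p - 1] = similarity.r2_pairs(idx[:-1], idx[1:])
        Scross[p - 1] = np.nan
    else:
        Sgg = np.array([similarity.sum_block([j], [j]) for j in range(p)])
        Scross = np.array(
            [similarity.sum_block([j], [j + 1]) for j in range(p - 1)] + [np.nan]
        )

    heap: list = []
    for c in range(p - 1):
        d = _merge_cost(1, 1, Sgg[c], Sgg[c + 1], Scross[c])
        heapq.heappush(heap, (d, c, c, 0, 0))

    merges: list[MergeStep] = []
    W = np.full(p + 1, np.nan)
    W[p] = 0.0

    for step in range(1, p):
        while True:
            if not heap:
                raise RuntimeError("candidate heap exhausted before completion")
            d, _, c, gc, gr = heapq.heappop(heap)
            r = nxt[c]
            if active[c] and r < p and active[r] and gen[c] == gc and gen[r] == gr:
                break
        left_range = (int(start[c]), int(end[c]))
        right_range = (int(start[r]), int(end[r]))
        merges.append(MergeStep(left_range, right_range, float(d), step))
        W[p - step] = W[p - step + 1] + d

        # absorb r into c
        Sgg[c] = Sgg[c] + Sgg[r] + 2.0 * Scross[c]
        rr = nxt[r]
        if rr < p:
            # S(c_new, rr) = S(r, rr) + fresh S(old c, rr)
            fresh = similarity.sum_block(
                np.arange(start[c], end[c]), np.arange(start[rr], end[rr])
            )
            Scross[c] = Scross[r] + fresh
        else:
            Scross[c] = np.nan
        l = prv[c]
        if l >= 0:
            # S(l, c_new) = S(l, old c) + fresh S(l, r)
            fresh = similarity.sum_block(
                np.arange(start[l], end[l]), np.arange(start[r], end[r])
            )
            Scross[l] = Scross[l] + fresh
        end[c] = end[r]
        size[c] += size[r]
        active[r] = False
        nxt[c] = rr
        if rr < p:
            prv[rr] = c
        # only c's generation changes: this invalidates the stale (l, c) and
        # (c, rr) entries while keeping (prv(l), l) alive
        gen[c] += 1
        if l >= 0:
            dl = _merge_cost(size[l], size[c], Sgg[l], Sgg[c], Scross[l])
            heapq.heappush(heap, (dl, int(start[l]), int(l), int(gen[l]), int(gen[c])))
        if rr < p:
            dc = _merge_cost(size[c], size[rr], Sgg[c], Sgg[rr], Scross[c])
            heapq.heappush(heap, (dc, int(start[c]), int(c), int(gen[c]), int(gen[rr])))

    return ClusterTree(merges=merges, W_profile=W, p=p)


def cut(tree: ClusterTree, G: int) -> BlockStructure:
    """Partition into G contiguous blocks by undoing the last G-1 merges."""
    if not 1 <= G <= tree.p:
        raise ValueError(f"G must be in [1, {tree.p}], got {G}")
    boundaries = set(range(tree.p))  # candidate block starts
    for m in tree.merges[: tree.p - G]:
        boundaries.discard(m.right[0])
    return BlockStructure(starts=np.array(sorted(boundaries)), p=tree.p)


def within_dispersion(similarity, blocks: BlockStructure) -> float:
    """Direct evaluation of W_G = p - sum_g S_gg / p_g on a partition."""
    if isinstance(similarity, np.ndarray):
        similarity = DenseSimilarity(similarity)
    total = 0.0
    for a, b in blocks.ranges:
        idx = np.arange(a, b)
        total += similarity.sum_block(idx, idx) / (b - a)
    return blocks.p - total
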