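"""Shared helpers: edge indexing, deterministic seeding, union-find on edge lists."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = [
    "mat_to_vec",
    "vec_to_mat",
    "stable_hash",
    "rng_for",
    "component_labels_from_edges",
    "max_component_extent",
    "max_run_length",
]


def mat_to_vec(mat: np.ndarray) -> np.ndarray:
    """Extract the strict upper triangle of (..., n, n) as a vector (..., n(n-1)/2)."""
    mat = np.asarray(mat)
    n = mat.shape[-1]
    iu, ju = np.triu_indices(n, k=1)
    return mat[..., iu, ju]


def vec_to_mat(vec: np.ndarray, n: int, diag: float = 0.0) -> np.ndarray:
    """Inverse of :func:`mat_to_vec`: build symmetric matrices with a constant diagonal."""
    vec = np.asarray(vec, dtype=float)
    iu, ju = np.triu_indices(n, k=1)
    out = np.zeros(vec.shape[:-1] + (n, n), dtype=float)
    out[..., iu, ju] = vec
    out[..., ju, iu] = vec
    idx = np.arange(n)
    out[..., idx, idx] = diag
    return out


def stable_hash(*parts) -> int:
    """Platform-independent 32-bit hash of string-able parts (CRC32 chained)."""
    h = 0
    for p in parts:
        h = zlib.crc32(str(p).encode("utf8"), h)
    return h & 0xFFFFFFFF


def rng_for(seed: int, *parts) -> np.random.Generator:
    """Deterministic generator keyed by a master seed plus arbitrary labels.

    Derivation goes through ``SeedSequence([seed, crc32(parts...)])`` so the
    stream depends only on the labels, not on call order.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [stable_hash(p) for p in parts]
    return np.random.default_rng(np.random.SeedSequence(entropy))


class _DSU:
    __slots__ = ("parent",)

    def __init__(self):
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        parent = self.parent
        root = x
        while parent.setdefault(root, root) != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller root wins
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def component_labels_from_edges(i_idx, j_idx) -> dict[int, int]:
    """Map each node appearing in the edge list to its component root (smallest member)."""
    dsu = _DSU()
    for a, b in zip(i_idx, j_idx):
        dsu.union(int(a), int(b))
    return {x: dsu.find(x) for x in dsu.parent}


def max_component_extent(i_idx, j_idx) -> int:
    """Largest connected-component edge count ("extent") of an edge list; 0 if empty."""
    if len(i_idx) == 0:
        return 0
    roots = component_labels_from_edges(i_idx, j_idx)
    counts: dict[int, int] = {}
    for a, b in zip(i_idx, j_idx):
        r = roots[int(a)]
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values())


def max_run_length(mask: np.ndarray) -> np.ndarray:
    """Length of the longest run of True along the last axis (vectorized)."""
    mask = np.atleast_2d(np.asarray(mask, dtype=bool))
    c = np.cumsum(mask, axis=-1)
    # value of the cumulative count at the most recent False, carried forward
    floor = np.maximum.accumulate(np.where(mask, 0, c), axis=-1)
    return (c - floor).max(axis=-1)
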