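"""Multi-level random decomposition of a point cloud.

The downsampling layer splits a cloud of ``M`` points into ``L`` pairwise
disjoint index subsets whose union is the whole cloud.  Subsets are drawn by
a seeded uniform random permutation cut into ``L`` near-equal contiguous
chunks, so each subset is an unbiased random sample of the cloud and the two
set identities (disjointness, complete coverage) hold exactly.  Because the
subsets are exchangeable random samples, their second-order structure
(covariance of coordinates) matches the full cloud's in expectation — the
"similar overall scheme" requirement that lets one network weight set serve
every level.

Indices inside each subset are kept in ascending order so downstream
neighbor searches have a canonical, permutation-stable ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pointcloud_io import LabeledCloud

__all__ = ["Partition", "decompose", "gather"]


@dataclass
class Partition:
    """L disjoint index subsets covering ``{0..M-1}`` (ascending inside each)."""

    subsets: list[np.ndarray]
    n_points: int
    seed: int

    @property
    def L(self) -> int:
        return len(self.subsets)

    def level_of_point(self) -> np.ndarray:
        """Length-M array mapping each point index to its level (0-based)."""
        lev = np.empty(self.n_points, dtype=np.int64)
        for l, idx in enumerate(self.subsets):
            lev[idx] = l
        return lev


def decompose(cloud_or_m, L: int, seed: int) -> Partition:
    """Randomly partition ``M`` points into ``L`` size-balanced subsets.

    Accepts either a :class:`LabeledCloud` or an integer point count.
    Subset sizes differ by at most one; the ``M mod L`` remainder points go
    to the first subsets.  The same seed always yields the same partition.
    """
    m = cloud_or_m.n_points if isinstance(cloud_or_m, LabeledCloud) else int(cloud_or_m)
    if L < 1:
        raise ValueError("L must be >= 1")
    if m < L:
        raise ValueError(f"cannot decompose M={m} points into L={L} subsets")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    base, rem = divmod(m, L)
    sizes = [base + (1 if l < rem else 0) for l in range(L)]
    subsets = []
    start = 0
    for size in sizes:
        subsets.append(np.sort(perm[start:start + size]))
        start += size
    return Partition(subsets, m, seed)


def gather(cloud: LabeledCloud, partition: Partition, l: int) -> LabeledCloud:
    """Extract subset ``l`` (0-based) as its own cloud, in canonical order."""
    if not 0 <= l < partition.L:
        raise IndexError(f"level {l} out of range for L={partition.L}")
    idx = partition.subsets[l]
    return LabeledCloud(cloud.coords[idx], cloud.labels[idx], f"{cloud.id}/level{l}")
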