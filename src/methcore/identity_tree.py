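"""Core-composition tree relating samples by shared methyl-CpG arrangement.

Each sample is summarized as the set of CpG labels belonging to its maximal
significant cores; pairwise dissimilarity is the Jaccard distance between
those label sets, and samples are clustered by UPGMA (average linkage),
which yields an ultrametric tree serialized as newick. Samples with the same
core composition end up as siblings at distance zero, so the tree groups
cell types / brain areas by core identity.

UPGMA merges are made deterministic by always merging, among tied minimal
pairs, the pair whose (lexicographically sorted) leaf-name tuples compare
lowest; input sample order therefore never changes the topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_discovery import Core

__all__ = [
    "SampleCoreProfile",
    "DistanceMatrix",
    "jaccard_distance",
    "profile_from_cores",
    "distance_matrix",
    "build_tree",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleCoreProfile:
    """The union of CpG labels across one sample's maximal significant cores."""

    sample_id: str
    core_labels: frozenset[int]


@dataclass
class DistanceMatrix:
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("distances must lie in [0, 1]")


def jaccard_distance(a: SampleCoreProfile, b: SampleCoreProfile) -> float:
    """1 - |A n B| / |A u B| on core label sets; 0 for identical, 1 for disjoint."""
    if not a.core_labels and not b.core_labels:
        raise ValueError(
            f"no cores to compare between {a.sample_id!r} and {b.sample_id!r}"
        )
    inter = len(a.core_labels & b.core_labels)
    union = len(a.core_labels | b.core_labels)
    return 1.0 - inter / union


def profile_from_cores(sample_id: str, cores: Iterable[Core]) -> SampleCoreProfile:
    """Union of labels across a sample's (maximal, significant) cores."""
    labels: set[int] = set()
    for c in cores:
        if c.significant:
            labels |= set(c.cpg_labels)
    if not labels:
        logger.warning("sample %s has no significant cores: empty profile", sample_id)
    return SampleCoreProfile(sample_id=sample_id, core_labels=frozenset(labels))


def distance_matrix(profiles: Sequence[SampleCoreProfile]) -> DistanceMatrix:
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jaccard_distance(profiles[i], profiles[j])
    return DistanceMatrix(tuple(p.sample_id for p in profiles), d)


def build_tree(dmat: DistanceMatrix, method: str = "upgma") -> str:
    """UPGMA tree over the distance matrix, returned as a newick string.

    Branch lengths place each merge at half the average inter-cluster
    distance (cluster height), so the tree is ultrametric. Tied minimal
    pairs are broken by lexicographic comparison of the clusters' sorted
    leaf-name tuples, making the output canonical under input reordering.
    """
    if method != "upgma":
        raise ValueError(f"unknown method {method!r}")
    n = len(dmat.sample_ids)
    if n < 2:
        raise ValueError("need at least 2 samples")

    # active clusters: key tuple of sorted leaf names -> (newick, height, size)
    clusters: dict[tuple[str, ...], tuple[str, float, int]] = {
        (name,): (name, 0.0, 1) for name in dmat.sample_ids
    }
    dist: dict[frozenset[tuple[str, ...]], float] = {}
    keys = sorted(clusters)
    name_to_idx = {name: i for i, name in enumerate(dmat.sample_ids)}
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            dist[frozenset((a, b))] = dmat.values[name_to_idx[a[0]], name_to_idx[b[0]]]

    while len(clusters) > 1:
        best: tuple[tuple[str, ...], tuple[str, ...]] | None = None
        best_d = np.inf
        for a, b in ((a, b) for i, a in enumerate(sorted(clusters))
                     for b in sorted(clusters)[i + 1 :]):
            d = dist[frozenset((a, b))]
            if d < best_d - 1e-12 or (
                abs(d - best_d) <= 1e-12 and (best is None or (a, b) < best)
            ):
                best_d, best = d, (a, b)
        assert best is not None
        a, b = best
        nwk_a, h_a, s_a = clusters.pop(a)
        nwk_b, h_b, s_b = clusters.pop(b)
        height = best_d / 2.0
        merged_key = tuple(sorted(a + b))
        merged_nwk = (
            f"({nwk_a}:{height - h_a:.10g},{nwk_b}:{height - h_b:.10g})"
        )
        # UPGMA: distance to the merge is the size-weighted average
        for other in clusters:
            d_new = (
                s_a * dist.pop(frozenset((a, other)))
                + s_b * dist.pop(frozenset((b, other)))
            ) / (s_a + s_b)
            dist[frozenset((merged_key, other))] = d_new
        dist.pop(frozenset((a, b)))
        clusters[merged_key] = (merged_nwk, height, s_a + s_b)

    (nwk, _, _), = clusters.values()
    return nwk + ";"
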