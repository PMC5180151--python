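"""MOTU delimitation by objective clustering at a p-distance threshold.

Two sequences share a MOTU iff they are connected by a chain of pairwise
uncorrected distances at or below the threshold (single linkage /
connected components). This is the only linkage under which the MOTU
count is provably non-increasing in the threshold, which the
``threshold_scan`` stability check relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from edna._seqtools import (
    UndefinedDistanceError,
    encode,
    identity_overlap,
    p_dist,
)

__all__ = [
    "p_distance", "distance_matrix", "objective_cluster", "threshold_scan",
    "MotuPartition", "ObjectiveClusterer",
]


def p_distance(a: str, b: str) -> float:
    """Uncorrected pairwise distance.

    Equal-length inputs are compared positionally with pairwise deletion
    (positions holding a gap or N in either sequence are excluded);
    unequal lengths are globally aligned first and end-gap columns are
    excluded. Raises :class:`UndefinedDistanceError` when no position is
    comparable.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return p_dist(a.replace("-", "N"), b.replace("-", "N")) \
        if len(a) == len(b) else p_dist(a, b)


def distance_matrix(seqs: list[str]) -> np.ndarray:
    """All-pairs p-distance matrix; undefined pairs are set to 1.0 + eps
    (always above any threshold) and reported via a warning."""
    n = len(seqs)
    lens = {len(s) for s in seqs}
    out = np.zeros((n, n))
    if len(lens) == 1:
        enc = encode([s.replace("-", "N") for s in seqs])
        step = max(1, 2**24 // (enc.size + 1))
        for i in range(0, n, step):
            block = enc[i : i + step]
            comp = (block[:, None, :] > 0) & (enc[None, :, :] > 0)
            mism = (block[:, None, :] != enc[None, :, :]) & comp
            ncomp = comp.sum(axis=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[i : i + step] = np.where(
                    ncomp > 0, mism.sum(axis=2) / np.maximum(ncomp, 1), 1.0 + 1e-9
                )
        if (out > 1.0).any():
            warnings.warn("undefined p-distances treated as above-threshold")
        np.fill_diagonal(out, 0.0)
        return out
    undefined = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = p_distance(seqs[i], seqs[j])
            except UndefinedDistanceError:
                d = 1.0 + 1e-9
                undefined += 1
            out[i, j] = out[j, i] = d
    if undefined:
        warnings.warn(f"{undefined} undefined p-distances treated as above-threshold")
    return out


@dataclass
class MotuPartition:
    """Assignment of sequences to MOTUs with canonical ids.

    MOTU ids are assigned after sorting clusters by (descending total read
    count, representative sequence), making the partition invariant to
    input order. The representative of a cluster is its highest-count
    member, ties broken by lexicographically smallest sequence.
    """

    labels: dict[str, str]           # sequence -> motu id
    representatives: dict[str, str]  # motu id -> representative sequence

    @property
    def n_motus(self) -> int:
        return len(self.representatives)

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {m: [] for m in self.representatives}
        for seq, m in self.labels.items():
            out[m].append(seq)
        return out


def objective_cluster(
    seqs: list[str],
    threshold: float = 0.03,
    counts: dict[str, float] | None = None,
    dist: np.ndarray | None = None,
) -> MotuPartition:
    """Cluster sequences into MOTUs at an uncorrected p-distance threshold.

    ``counts`` (total read count per sequence) drives representative
    selection; absent counts default to 1. A precomputed ``dist`` matrix
    may be supplied to avoid recomputation across thresholds.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    uniq = sorted(set(seqs))
    if dist is None:
        dist = distance_matrix(uniq)
    elif dist.shape != (len(uniq), len(uniq)):
        raise ValueError("distance matrix shape does not match unique sequences")
    adj = csr_matrix(dist <= threshold)
    n_comp, comp = connected_components(adj, directed=False)
    counts = counts or {}
    clusters: dict[int, list[str]] = {}
    for seq, c in zip(uniq, comp):
        clusters.setdefault(int(c), []).append(seq)
    reps = {}
    for c, members in clusters.items():
        reps[c] = min(members, key=lambda s: (-counts.get(s, 1.0), s))
    order = sorted(
        clusters,
        key=lambda c: (-sum(counts.get(s, 1.0) for s in clusters[c]), reps[c]),
    )
    width = max(4, len(str(n_comp)))
    motu_ids = {c: f"MOTU_{i + 1:0{width}d}" for i, c in enumerate(order)}
    labels = {seq: motu_ids[int(c)] for seq, c in zip(uniq, comp)}
    representatives = {motu_ids[c]: reps[c] for c in clusters}
    return MotuPartition(labels=labels, representatives=representatives)


def threshold_scan(
    seqs: list[str],
    thresholds: list[float],
    counts: dict[str, float] | None = None,
) -> dict[float, int]:
    """MOTU count at each threshold (ascending); counts are non-increasing."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    uniq = sorted(set(seqs))
    dist = distance_matrix(uniq)
    return {
        t: objective_cluster(uniq, t, counts=counts, dist=dist).n_motus
        for t in thresholds
    }


class ObjectiveClusterer:
    """Scikit-learn-style wrapper around :func:`objective_cluster`.

    Parameters
    ----------
    threshold : float
        p-distance cut for single-linkage chaining (default 0.03).

    Attributes (after ``fit``)
    --------------------------
    labels_ : ndarray of str, MOTU id per input sequence (input order)
    partition_ : MotuPartition
    """

    def __init__(self, threshold: float = 0.03):
        self.threshold = threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold}

    def set_params(self, **params) -> "ObjectiveClusterer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, X: list[str], y=None, counts: dict[str, float] | None = None):
        self.partition_ = objective_cluster(list(X), self.threshold, counts=counts)
        self.labels_ = np.array([self.partition_.labels[s] for s in X])
        return self

    def fit_predict(self, X: list[str], y=None) -> np.ndarray:
        return self.fit(X).labels_
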