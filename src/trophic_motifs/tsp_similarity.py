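"""Comparing triad significance profiles and clustering webs into families.

Profiles are compared by Pearson's correlation coefficient r over the 13
components, converted to the Euclidean metric d = sqrt(2 (1 - r)), and
clustered by UPGMA (average linkage).  Cutting the dendrogram at a
threshold distance d_c yields "motif families" — groups of webs with
mutually similar over/under-representation patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "SimilarityMatrix",
    "Dendrogram",
    "pearson_r",
    "tsp_distance",
    "similarity_matrix",
    "upgma",
    "family_partition",
    "model_vs_empirical_r",
]

_N_TRIADS = 13
_R_TOL = 1e-9


def pearson_r(profile_a: Sequence[float], profile_b: Sequence[float]) -> float:
    """Pearson correlation between two 13-component significance profiles.

    Uses the sample mean and the (n-1)-normalized standard deviation;
    either way the normalizations cancel and r lies in [-1, 1].  A
    constant profile has zero variance and no defined correlation.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != (_N_TRIADS,) or b.shape != (_N_TRIADS,):
        raise ValueError(f"profiles must have length {_N_TRIADS}")
    da = a - a.mean()
    db = b - b.mean()
    na = float(np.sqrt((da * da).sum()))
    nb = float(np.sqrt((db * db).sum()))
    if na == 0.0:
        raise ValueError("first profile is constant; correlation undefined")
    if nb == 0.0:
        raise ValueError("second profile is constant; correlation undefined")
    r = float((da * db).sum() / (na * nb))
    return float(np.clip(r, -1.0, 1.0))


def tsp_distance(r: float) -> float:
    """Convert a correlation to the metric distance d = sqrt(2 (1 - r))."""
    if not -1.0 - _R_TOL <= r <= 1.0 + _R_TOL:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    r = min(1.0, max(-1.0, r))
    return float(np.sqrt(2.0 * (1.0 - r)))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise profile correlations and the derived distance matrix."""

    labels: tuple[str, ...]
    r_matrix: np.ndarray
    d_matrix: np.ndarray


def similarity_matrix(profiles: dict[str, Sequence[float]]) -> SimilarityMatrix:
    """All pairwise correlations/distances between named profiles."""
    labels = tuple(profiles)
    k = len(labels)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r[i, j] = r[j, i] = pearson_r(profiles[labels[i]], profiles[labels[j]])
    d = np.sqrt(2.0 * (1.0 - np.clip(r, -1.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return SimilarityMatrix(labels=labels, r_matrix=r, d_matrix=d)


@dataclass(frozen=True)
class Dendrogram:
    """UPGMA merge tree over a set of labelled items.

    ``linkage`` is a scipy linkage matrix; rows record (child, child,
    merge height, size) with non-decreasing heights.
    """

    labels: tuple[str, ...]
    linkage: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, d_c: float) -> list[set[str]]:
        """Partition items into clusters whose internal merges are below d_c."""
        if d_c <= 0:
            return [{lab} for lab in self.labels]
        assignment = hierarchy.fcluster(self.linkage, t=d_c, criterion="distance")
        clusters: dict[int, set[str]] = {}
        for lab, c in zip(self.labels, assignment):
            clusters.setdefault(int(c), set()).add(lab)
        return list(clusters.values())

    def to_newick(self) -> str:
        """Plain-text (Newick) rendering of the merge tree with branch heights."""
        n = len(self.labels)
        nodes: dict[int, tuple[str, float]] = {
            i: (lab, 0.0) for i, lab in enumerate(self.labels)
        }
        for row, (a, b, h, _) in enumerate(self.linkage):
            sa, ha = nodes.pop(int(a))
            sb, hb = nodes.pop(int(b))
            rep = f"({sa}:{h / 2 - ha / 2:.6g},{sb}:{h / 2 - hb / 2:.6g})"
            nodes[n + row] = (rep, h)
        (rep, _), = nodes.values()
        return rep + ";"


def upgma(d_matrix: np.ndarray, labels: Sequence[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) hierarchical clustering of a distance matrix.

    Ties between merge candidates are broken deterministically by lowest
    cluster index (scipy's behaviour for equal heights).
    """
    d = np.asarray(d_matrix, dtype=float)
    k = d.shape[0]
    if d.shape != (k, k):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (d < 0).any():
        raise ValueError("distances must be nonnegative")
    if labels is None:
        labels = [str(i) for i in range(k)]
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(labels=tuple(labels), linkage=z)


def family_partition(dendrogram: Dendrogram, d_c: float) -> list[set[str]]:
    """Cut a dendrogram at threshold d_c into motif families."""
    if d_c <= 0:
        raise ValueError("d_c must be positive")
    return dendrogram.cut(d_c)


def model_vs_empirical_r(
    empirical_z: Sequence[float],
    model_zs: Sequence[Sequence[float]],
    *,
    average_normalized: bool = False,
) -> float:
    """Correlation between an empirical profile and a model ensemble.

    The model ensemble's z vectors are averaged component-wise first,
    then correlated with the empirical z vector.  With
    ``average_normalized=True`` each model profile is unit-normalized
    before averaging (the "average TSP" reading) — both conventions give
    near-identical r in practice.
    """
    zs = np.asarray(model_zs, dtype=float)
    if zs.ndim != 2 or zs.shape[1] != _N_TRIADS or zs.shape[0] < 2:
        raise ValueError("need an ensemble of >= 2 model profiles of length 13")
    if average_normalized:
        norms = np.linalg.norm(zs, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        zs = zs / norms
    return pearson_r(empirical_z, zs.mean(axis=0))
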