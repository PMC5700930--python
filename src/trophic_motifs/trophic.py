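"""Trophic levels and the trophic incoherence parameter q.

The trophic level of a species is one plus the mean trophic level of its
prey; basal species (no prey) sit at level 1.  Writing ``A`` for the
prey->predator adjacency matrix and ``k_j`` for the in-degree of
predator ``j``,

    s_j = 1 + (1/k_j) * sum_i A[i, j] * s_i .

Each link carries a trophic distance ``x_ij = s_j - s_i``.  Summing the
defining equation over predators shows the distances always average to
exactly 1, so their spread is captured by a single number,

    q = sqrt(<x^2> - 1),

the *trophic incoherence parameter*.  q = 0 iff every consumer feeds
exactly one level below itself (a perfectly layered web); large q means
pervasive cross-level feeding (omnivory).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .foodweb_io import FoodWeb, validate_trophic_preconditions

__all__ = ["TrophicProfile", "TrophicValidityError", "trophic_levels", "incoherence"]

#: radicand within this of zero is treated as exactly zero (perfectly
#: coherent webs accumulate ~1e-16 noise in the linear solve)
_RADICAND_TOL = 1e-12

# above this many unknowns the reduced system is solved sparsely
_SPARSE_CUTOFF = 400


class TrophicValidityError(ValueError):
    """The web violates a precondition for assigning trophic levels."""


@dataclass(frozen=True)
class TrophicProfile:
    """Trophic levels, per-link trophic distances and the incoherence q."""

    levels: Mapping[str, float]
    distances: np.ndarray
    q: float

    @property
    def mean_distance(self) -> float:
        return float(np.mean(self.distances))


def _require_valid(web: FoodWeb) -> None:
    report = validate_trophic_preconditions(web)
    if not report.is_valid:
        raise TrophicValidityError(
            "trophic levels undefined: " + "; ".join(report.reasons)
        )


def levels_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Solve the trophic-level linear system on a dense adjacency matrix.

    Assumes the web is trophic-valid; callers on untrusted input should
    validate first.  The (N-B)x(N-B) reduced system over non-basal nodes
    is solved by direct LU factorization (dense for small webs, sparse
    above ``_SPARSE_CUTOFF`` unknowns) — the defining equation is exact,
    not an iteration to be truncated.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    k_in = a.sum(axis=0)
    basal = k_in == 0
    s = np.ones(n)
    nb = np.flatnonzero(~basal)
    if nb.size == 0:
        return s
    inv_k = 1.0 / k_in[nb]
    # rows/cols of the reduced system follow the non-basal node order
    coupling = a[np.ix_(nb, nb)].T * inv_k[:, None]
    rhs = 1.0 + a[np.ix_(np.flatnonzero(basal), nb)].sum(axis=0) * inv_k
    if nb.size > _SPARSE_CUTOFF:
        m = sp.eye(nb.size, format="csc") - sp.csc_matrix(coupling)
        sol = spla.spsolve(m, rhs)
    else:
        sol = np.linalg.solve(np.eye(nb.size) - coupling, rhs)
    s[nb] = sol
    return s


def q_from_adjacency(a: np.ndarray) -> float:
    """Incoherence parameter from a dense adjacency matrix (assumed valid)."""
    s = levels_from_adjacency(a)
    ii, jj = np.nonzero(a)
    if ii.size == 0:
        raise TrophicValidityError("q undefined for a web with no links")
    x = s[jj] - s[ii]
    radicand = float(np.mean(x * x) - 1.0)
    if radicand < 0.0:
        if radicand < -_RADICAND_TOL:
            raise FloatingPointError(f"negative radicand {radicand} beyond tolerance")
        radicand = 0.0
    elif radicand < _RADICAND_TOL:
        radicand = 0.0
    return float(np.sqrt(radicand))


def trophic_levels(web: FoodWeb) -> dict[str, float]:
    """Per-species trophic levels (basal species pinned at 1).

    Raises
    ------
    TrophicValidityError
        If the web has no basal species or has species unreachable from
        every basal species.
    """
    _require_valid(web)
    s = levels_from_adjacency(web.adjacency)
    return {node: float(s[i]) for i, node in enumerate(web.nodes)}


def incoherence(web: FoodWeb) -> TrophicProfile:
    """Trophic profile of a web: levels, link distances, and q.

    q is the standard deviation of the trophic-distance distribution
    (whose mean is identically 1), computed in population form over the
    L links; a radicand within floating tolerance of zero is clipped so
    perfectly layered webs report q = 0 exactly.
    """
    _require_valid(web)
    if web.n_links == 0:
        raise TrophicValidityError("q undefined for a web with no links")
    s = levels_from_adjacency(web.adjacency)
    idx = web.index
    pairs = sorted(web.edges)
    x = np.array([s[idx[v]] - s[idx[u]] for u, v in pairs])
    radicand = float(np.mean(x * x) - 1.0)
    if abs(radicand) < _RADICAND_TOL:
        radicand = 0.0
    if radicand < 0.0:
        raise FloatingPointError(f"negative radicand {radicand} beyond tolerance")
    levels = {node: float(s[i]) for i, node in enumerate(web.nodes)}
    return TrophicProfile(levels=levels, distances=x, q=float(np.sqrt(radicand)))
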