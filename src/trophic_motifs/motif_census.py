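"""Triad census, degree-preserving randomization and significance profiles.

There are 13 isomorphism classes of connected three-node directed
graphs.  Five contain only single links: S1 (three-species chain), S2
(the feed-forward loop, i.e. omnivory), S3 (directed cycle), S4 (one
predator with two prey — apparent competition) and S5 (two predators
sharing a prey — direct competition).  The remaining eight, D1–D8,
contain at least one mutual-predation dyad; they are ordered here by
increasing number of single links alongside the dyads (D1/D2: dyad plus
one incoming / outgoing link; D3–D5: dyad plus two single links, in
"down", "up", cyclic arrangement; D6: two dyads; D7: two dyads plus a
single link; D8: all three dyads).

The significance of each class in a web is measured against a
configuration-model null: an ensemble of graphs with the same in- and
out-degree sequence obtained by Markov-chain double-edge swaps.  The
z-score of class k is

    z_k = (N_k - <N_k>_rand) / sigma_rand,

and the 13-vector of z-scores, normalized to unit Euclidean length, is
the (normalized) triad significance profile.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .foodweb_io import FoodWeb

logger = logging.getLogger(__name__)

__all__ = [
    "TRIAD_LABELS",
    "TriadCensus",
    "NullEnsembleStats",
    "TSP",
    "classify_triad",
    "census",
    "randomize",
    "tsp",
]

TRIAD_LABELS: tuple[str, ...] = (
    "S1", "S2", "S3", "S4", "S5",
    "D1", "D2", "D3", "D4", "D5", "D6", "D7", "D8",
)

# ----------------------------------------------------------------------
# classification: 6-bit dyad code -> class index
# ----------------------------------------------------------------------
# A labelled 3-node digraph on nodes (0, 1, 2) is encoded in 6 bits:
# bit b(3*p + ...) — we use pair slots (0,1), (0,2), (1,2), two bits per
# slot: low bit = forward edge (lower -> higher node), high bit = reverse.

_PAIRS = ((0, 1), (0, 2), (1, 2))


def _encode(edges: Iterable[tuple[int, int]]) -> int:
    code = 0
    es = set(edges)
    for slot, (a, b) in enumerate(_PAIRS):
        if (a, b) in es:
            code |= 1 << (2 * slot)
        if (b, a) in es:
            code |= 1 << (2 * slot + 1)
    return code


def _decode(code: int) -> set[tuple[int, int]]:
    edges = set()
    for slot, (a, b) in enumerate(_PAIRS):
        if code & (1 << (2 * slot)):
            edges.add((a, b))
        if code & (1 << (2 * slot + 1)):
            edges.add((b, a))
    return edges


def _canonical(code: int) -> int:
    edges = _decode(code)
    best = 64
    for perm in itertools.permutations(range(3)):
        c = _encode((perm[u], perm[v]) for u, v in edges)
        best = min(best, c)
    return best


# representatives of the 13 classes, in profile order
_REPRESENTATIVES: dict[str, tuple[tuple[int, int], ...]] = {
    "S1": ((0, 1), (1, 2)),                      # chain
    "S2": ((0, 1), (1, 2), (0, 2)),              # feed-forward loop / omnivory
    "S3": ((0, 1), (1, 2), (2, 0)),              # cycle
    "S4": ((0, 2), (1, 2)),                      # apparent competition (shared predator)
    "S5": ((2, 0), (2, 1)),                      # direct competition (shared prey)
    "D1": ((0, 1), (1, 0), (2, 0)),              # dyad + incoming single link
    "D2": ((0, 1), (1, 0), (0, 2)),              # dyad + outgoing single link
    "D3": ((0, 1), (1, 0), (2, 0), (2, 1)),      # dyad + two incoming
    "D4": ((0, 1), (1, 0), (0, 2), (1, 2)),      # dyad + two outgoing
    "D5": ((0, 1), (1, 0), (2, 0), (1, 2)),      # dyad + through-flow
    "D6": ((0, 1), (1, 0), (0, 2), (2, 0)),      # two dyads
    "D7": ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2)),  # two dyads + single
    "D8": ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)),  # all mutual
}


def _connected(code: int) -> bool:
    # three nodes are weakly connected iff >= 2 of the 3 dyad slots are occupied
    occupied = sum(1 for slot in range(3) if code & (3 << (2 * slot)))
    return occupied >= 2


@lru_cache(maxsize=1)
def _code_table() -> np.ndarray:
    """Map each of the 64 labelled 3-node digraphs to a class index (-1 = disconnected)."""
    canon_to_idx = {
        _canonical(_encode(edges)): i
        for i, (label, edges) in enumerate(_REPRESENTATIVES.items())
    }
    assert len(canon_to_idx) == 13, "representatives must cover 13 distinct classes"
    table = np.full(64, -1, dtype=np.int64)
    for code in range(64):
        if _connected(code):
            table[code] = canon_to_idx[_canonical(code)]
    return table


def classify_triad(graph) -> str:
    """Classify a 3-node directed graph into one of the 13 connected triad
    classes, or ``"disconnected"``.

    ``graph`` may be a :class:`FoodWeb`, a networkx DiGraph, or an
    iterable of edges over exactly three nodes.
    """
    if isinstance(graph, FoodWeb):
        nodes, edges = list(graph.nodes), list(graph.edges)
    elif hasattr(graph, "edges") and hasattr(graph, "nodes"):
        nodes, edges = list(graph.nodes()), list(graph.edges())
    else:
        edges = [(u, v) for u, v in graph]
        nodes = sorted({n for e in edges for n in e})
    if len(nodes) != 3:
        raise ValueError(f"expected exactly 3 nodes, got {len(nodes)}")
    order = {n: i for i, n in enumerate(nodes)}
    code = _encode((order[u], order[v]) for u, v in edges if u != v)
    idx = int(_code_table()[code])
    return "disconnected" if idx < 0 else TRIAD_LABELS[idx]


# ----------------------------------------------------------------------
# census
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TriadCensus:
    """Counts of connected induced 3-node subgraphs by class."""

    counts: np.ndarray  # length 13, int64, ordered per TRIAD_LABELS

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (13,) or (c < 0).any():
            raise ValueError("census must be 13 nonnegative counts")
        object.__setattr__(self, "counts", c)

    def as_dict(self) -> dict[str, int]:
        return {lab: int(c) for lab, c in zip(TRIAD_LABELS, self.counts)}

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@lru_cache(maxsize=4)
def _triple_index(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), 3)),
        dtype=np.int32,
        count=n * (n - 1) * (n - 2) // 2,
    ).reshape(-1, 3)
    return combos[:, 0], combos[:, 1], combos[:, 2]


def _census_adjacency(a: np.ndarray) -> np.ndarray:
    """Vectorized census on a dense boolean adjacency matrix.

    Each unordered node triple is assigned its 6-bit dyad code in one
    shot; a precomputed 64-entry table maps codes to classes.
    """
    n = a.shape[0]
    counts = np.zeros(13, dtype=np.int64)
    if n < 3:
        return counts
    a = a.astype(np.int8, copy=False)
    # pairwise dyad codes: 1 = forward (row->col), 2 = reverse
    p = a + 2 * a.T
    table = _code_table()
    i, j, k = _triple_index(n) if n <= 350 else (None, None, None)
    if i is None:
        # chunked fallback for very large webs
        chunk: list[tuple[int, int, int]] = []
        for triple in itertools.combinations(range(n), 3):
            chunk.append(triple)
            if len(chunk) == 2_000_000:
                counts += _count_chunk(p, table, np.array(chunk, dtype=np.int64))
                chunk = []
        if chunk:
            counts += _count_chunk(p, table, np.array(chunk, dtype=np.int64))
        return counts
    code = p[i, j] + 4 * p[i, k] + 16 * p[j, k]
    cls = table[code]
    counts += np.bincount(cls[cls >= 0], minlength=13).astype(np.int64)
    return counts


def _count_chunk(p: np.ndarray, table: np.ndarray, t: np.ndarray) -> np.ndarray:
    code = p[t[:, 0], t[:, 1]] + 4 * p[t[:, 0], t[:, 2]] + 16 * p[t[:, 1], t[:, 2]]
    cls = table[code]
    return np.bincount(cls[cls >= 0], minlength=13).astype(np.int64)


def census(web: FoodWeb | np.ndarray) -> TriadCensus:
    """Count the connected induced 3-node subgraphs of a web by class.

    Each unordered triple of nodes contributes at most one count — that
    of the induced subgraph's class (the convention used by mfinder).
    """
    a = web.adjacency if isinstance(web, FoodWeb) else np.asarray(web, dtype=bool)
    if a.shape[0] < 3:
        logger.warning("census of a web with fewer than 3 nodes is all zeros")
    return TriadCensus(_census_adjacency(a))


# ----------------------------------------------------------------------
# degree-preserving randomization
# ----------------------------------------------------------------------

def _edge_arrays(web: FoodWeb) -> tuple[np.ndarray, np.ndarray]:
    idx = web.index
    pairs = sorted(web.edges)
    u = np.array([idx[a] for a, _ in pairs], dtype=np.int64)
    v = np.array([idx[b] for _, b in pairs], dtype=np.int64)
    return u, v


def _swap_plain(u, v, n, attempts, rng, forbid_mutual=False):
    """In-place double-edge swaps on edge arrays; returns accepted count."""
    m = len(u)
    eset = set((u * n + v).tolist())
    pick = rng.integers(0, m, size=(attempts, 2))
    accepted = 0
    for e1, e2 in pick:
        if e1 == e2:
            continue
        a, b = u[e1], v[e1]
        c, d = u[e2], v[e2]
        if a == d or c == b:
            continue
        n1 = a * n + d
        n2 = c * n + b
        if n1 in eset or n2 in eset:
            continue
        if forbid_mutual and (d * n + a in eset or b * n + c in eset):
            continue
        eset.discard(a * n + b)
        eset.discard(c * n + d)
        eset.add(n1)
        eset.add(n2)
        v[e1] = d
        v[e2] = b
        accepted += 1
    return accepted


def _swap_mutual_pairs(pu, pv, eset, n, attempts, rng):
    """Swap endpoints between whole mutual dyads, keeping them mutual."""
    m = len(pu)
    if m < 2:
        return 0
    pick = rng.integers(0, m, size=(attempts, 2))
    flip = rng.random(attempts) < 0.5
    accepted = 0
    for t, (e1, e2) in enumerate(pick):
        if e1 == e2:
            continue
        a, b = pu[e1], pv[e1]
        c, d = pu[e2], pv[e2]
        if flip[t]:
            c, d = d, c
        # propose dyads {a, d} and {c, b}
        if a == d or c == b:
            continue
        bad = False
        for x, y in ((a, d), (d, a), (c, b), (b, c)):
            if x * n + y in eset:
                bad = True
                break
        if bad:
            continue
        for x, y in ((a, b), (b, a), (c, d), (d, c)):
            eset.discard(x * n + y)
        for x, y in ((a, d), (d, a), (c, b), (b, c)):
            eset.add(x * n + y)
        pv[e1] = d
        pu[e2], pv[e2] = c, b
        accepted += 1
    return accepted


def randomize(
    web: FoodWeb,
    swaps_per_link: int = 10,
    *,
    mode: str = "plain",
    rng: np.random.Generator | int | None = None,
) -> FoodWeb:
    """Degree-preserving randomization by attempted double-edge swaps.

    ``swaps_per_link * L`` swaps are *attempted*; swaps that would create
    a self-loop or a duplicate edge are rejected.  ``mode="plain"``
    randomizes all links together; ``mode="mutual"`` additionally
    preserves the number of mutual-predation dyads by swapping single
    links and mutual dyads within their own pools (mfinder's stricter
    null).
    """
    if mode not in ("plain", "mutual"):
        raise ValueError(f"unknown randomization mode {mode!r}")
    if web.n_links < 2:
        return web
    rng = np.random.default_rng(rng)
    n = web.n_nodes
    u, v = _edge_arrays(web)
    attempts = int(swaps_per_link) * len(u)
    if mode == "plain":
        _swap_plain(u, v, n, attempts, rng)
        edges = [(web.nodes[a], web.nodes[b]) for a, b in zip(u, v)]
        return FoodWeb(web.nodes, frozenset(edges))
    # mutual mode: split pools
    eset = set((u * n + v).tolist())
    singles = [(a, b) for a, b in zip(u.tolist(), v.tolist()) if b * n + a not in eset]
    mutual = [
        (a, b) for a, b in zip(u.tolist(), v.tolist()) if b * n + a in eset and a < b
    ]
    n_single = len(singles)
    n_mut_links = 2 * len(mutual)
    total = n_single + n_mut_links
    su = np.array([a for a, _ in singles], dtype=np.int64)
    sv = np.array([b for _, b in singles], dtype=np.int64)
    pu = np.array([a for a, _ in mutual], dtype=np.int64)
    pv = np.array([b for _, b in mutual], dtype=np.int64)
    single_attempts = round(attempts * (n_single / total)) if total else 0
    mutual_attempts = attempts - single_attempts
    if n_single >= 2:
        # maintain eset consistency: swap singles against full edge set
        _swap_singles_in_context(su, sv, eset, n, single_attempts, rng)
    _swap_mutual_pairs(pu, pv, eset, n, mutual_attempts, rng)
    edges = [(web.nodes[a], web.nodes[b]) for a, b in zip(su, sv)]
    for a, b in zip(pu, pv):
        edges.append((web.nodes[a], web.nodes[b]))
        edges.append((web.nodes[b], web.nodes[a]))
    return FoodWeb(web.nodes, frozenset(edges))


def _swap_singles_in_context(u, v, eset, n, attempts, rng):
    """Double-edge swaps on single links that never create a mutual dyad."""
    m = len(u)
    pick = rng.integers(0, m, size=(attempts, 2))
    accepted = 0
    for e1, e2 in pick:
        if e1 == e2:
            continue
        a, b = u[e1], v[e1]
        c, d = u[e2], v[e2]
        if a == d or c == b:
            continue
        n1 = a * n + d
        n2 = c * n + b
        if n1 in eset or n2 in eset:
            continue
        if d * n + a in eset or b * n + c in eset:
            continue
        eset.discard(a * n + b)
        eset.discard(c * n + d)
        eset.add(n1)
        eset.add(n2)
        v[e1] = d
        v[e2] = b
        accepted += 1
    return accepted


# ----------------------------------------------------------------------
# triad significance profile
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class NullEnsembleStats:
    """Per-class mean and sd of triad counts over the randomized ensemble."""

    mean: np.ndarray
    sd: np.ndarray
    ensemble_size: int
    swaps_per_link: int
    mode: str
    seed: int | None

    def __post_init__(self):
        if self.ensemble_size < 2:
            raise ValueError("ensemble size must be at least 2")


@dataclass(frozen=True)
class TSP:
    """Triad significance profile: 13 z-scores and their unit-norm version."""

    z: np.ndarray
    z_hat: np.ndarray
    undefined: bool = False  # True when z is the zero vector

    n: int = field(default=13, init=False)

    def as_dict(self) -> dict[str, float]:
        return {lab: float(x) for lab, x in zip(TRIAD_LABELS, self.z)}


def normalize_profile(z: Sequence[float]) -> TSP:
    """Unit-normalize a 13-vector of z-scores (flagged undefined if all zero)."""
    z = np.asarray(z, dtype=float)
    if z.shape != (13,):
        raise ValueError("a triad significance profile has 13 components")
    norm = float(np.linalg.norm(z))
    if norm == 0.0:
        return TSP(z=z, z_hat=np.zeros(13), undefined=True)
    return TSP(z=z, z_hat=z / norm, undefined=False)


def tsp(
    web: FoodWeb,
    ensemble_size: int = 1000,
    swaps_per_link: int = 10,
    seed: int | None = None,
    *,
    mode: str = "plain",
) -> tuple[TriadCensus, NullEnsembleStats, TSP]:
    """Triad significance profile of a web against a configuration-model null.

    Each null sample is an independent swap chain started from the
    original web (avoids autocorrelation between samples).  Classes with
    zero null variance get z = 0 by policy: such triads are identically
    distributed under the null and carry no significance signal.
    """
    if ensemble_size < 2:
        raise ValueError("ensemble_size must be >= 2")
    if web.n_nodes < 3 or web.n_links < 2:
        raise ValueError("TSP requires at least 3 nodes and 2 links")
    rng = np.random.default_rng(seed)
    observed = census(web)
    samples = np.empty((ensemble_size, 13), dtype=np.int64)
    for s in range(ensemble_size):
        rand_web = randomize(web, swaps_per_link, mode=mode, rng=rng)
        samples[s] = census(rand_web).counts
    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1)
    z = np.zeros(13)
    ok = sd > 0
    z[ok] = (observed.counts[ok] - mean[ok]) / sd[ok]
    if not ok.all():
        logger.debug("null sd = 0 for classes %s; z set to 0",
                     [TRIAD_LABELS[i] for i in np.flatnonzero(~ok)])
    stats = NullEnsembleStats(
        mean=mean, sd=sd, ensemble_size=ensemble_size,
        swaps_per_link=swaps_per_link, mode=mode, seed=seed,
    )
    return observed, stats, normalize_profile(z)
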