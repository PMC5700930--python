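"""Reading, writing and validating directed food webs.

A food web is a directed graph whose links point from prey to predator
(resource to consumer).  Species with no prey — zero in-degree — are
*basal* (autotrophs).  The on-disk format is a plain-text edge list:
one ``prey predator`` pair per line, ``#`` comments, and an optional
``#nodes:`` header that preserves isolated species across round-trips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FoodWeb",
    "TrophicValidation",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency_csv",
    "basal_nodes",
    "validate_trophic_preconditions",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


@dataclass(frozen=True)
class FoodWeb:
    """An immutable directed food web.

    Parameters
    ----------
    nodes
        Species labels in canonical (lexicographic) order.
    edges
        Set of ``(prey, predator)`` pairs.  Self-loops and duplicates are
        rejected; use :meth:`from_edges` to canonicalize raw input.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise ValueError("a food web needs at least one species")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node labels must be unique")
        if tuple(sorted(self.nodes)) != self.nodes:
            raise ValueError("nodes must be in canonical (sorted) order; use FoodWeb.from_edges")
        nodeset = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u!r}->{v!r} not allowed")
            if u not in nodeset or v not in nodeset:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] | None = None,
    ) -> "FoodWeb":
        """Build a canonical web, dropping self-loops and duplicate links.

        Self-loops (cannibalism) are removed because the trophic-level
        linear system is ill-posed with them; removals are logged.
        """
        edge_list = [(str(u), str(v)) for u, v in edges]
        loops = [(u, v) for u, v in edge_list if u == v]
        if loops:
            logger.warning("dropping %d self-loop(s): %s", len(loops), sorted(set(loops)))
        kept = [(u, v) for u, v in edge_list if u != v]
        uniq = set(kept)
        dups = len(kept) - len(uniq)
        if dups:
            logger.warning("collapsing %d duplicate edge(s)", dups)
        node_set = {n for e in uniq for n in e}
        if nodes is not None:
            extra = set(map(str, nodes))
            node_set |= extra
        return cls(tuple(sorted(node_set)), frozenset(uniq))

    @classmethod
    def from_adjacency(cls, a: np.ndarray, labels: Iterable[str] | None = None) -> "FoodWeb":
        """Build a web from a dense 0/1 adjacency matrix ``a[i, j] = prey i -> predator j``."""
        a = np.asarray(a)
        n = a.shape[0]
        if a.shape != (n, n):
            raise ValueError("adjacency matrix must be square")
        if labels is None:
            width = max(3, len(str(n - 1)))
            labels = [f"n{i:0{width}d}" for i in range(n)]
        labels = [str(x) for x in labels]
        ii, jj = np.nonzero(a)
        return cls.from_edges(
            [(labels[i], labels[j]) for i, j in zip(ii, jj)], nodes=labels
        )

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    @cached_property
    def index(self) -> Mapping[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        """N — number of species."""
        return len(self.nodes)

    @property
    def n_links(self) -> int:
        """L — number of trophic links."""
        return len(self.edges)

    @cached_property
    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency matrix A with A[i, j] = 1 for link i -> j."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        idx = self.index
        for u, v in self.edges:
            a[idx[u], idx[v]] = True
        return a

    @cached_property
    def in_degree(self) -> Mapping[str, int]:
        deg = dict.fromkeys(self.nodes, 0)
        for _, v in self.edges:
            deg[v] += 1
        return deg

    @cached_property
    def out_degree(self) -> Mapping[str, int]:
        deg = dict.fromkeys(self.nodes, 0)
        for u, _ in self.edges:
            deg[u] += 1
        return deg

    @cached_property
    def basal(self) -> frozenset[str]:
        """Species with zero in-degree."""
        return frozenset(n for n in self.nodes if self.in_degree[n] == 0)

    @property
    def n_basal(self) -> int:
        """B — number of basal species."""
        return len(self.basal)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def relabel(self, mapping: Mapping[str, str]) -> "FoodWeb":
        return FoodWeb.from_edges(
            [(mapping[u], mapping[v]) for u, v in self.edges],
            nodes=[mapping[n] for n in self.nodes],
        )


# ----------------------------------------------------------------------
# plain-text edge lists
# ----------------------------------------------------------------------

def read_edge_list(path: str | Path, *, swap_columns: bool = False) -> FoodWeb:
    """Read a ``prey predator`` edge list.

    ``swap_columns=True`` flips the two columns for datasets that list
    predator first.  ``#nodes: a b c`` headers declare species without
    links (otherwise isolated species cannot be represented).
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    declared: list[str] = []
    n_lines = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("nodes:"):
                    declared.extend(body[len("nodes:"):].split())
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 'prey predator', got {line!r}"
                )
            u, v = tokens
            if swap_columns:
                u, v = v, u
            edges.append((u, v))
            n_lines += 1
    if not edges and not declared:
        raise EdgeListParseError(f"{path}: no edges or node declarations found")
    return FoodWeb.from_edges(edges, nodes=declared or None)


def write_edge_list(web: FoodWeb, path: str | Path) -> None:
    """Write a web so that ``read_edge_list(write_edge_list(web)) == web``.

    A ``#nodes:`` header is emitted when the web has isolated species,
    since those cannot be recovered from the links alone.
    """
    path = Path(path)
    linked = {n for e in web.edges for n in e}
    with path.open("w", encoding="utf-8") as fh:
        if linked != set(web.nodes):
            fh.write("#nodes: " + " ".join(web.nodes) + "\n")
        for u, v in sorted(web.edges):
            fh.write(f"{u} {v}\n")


def read_adjacency_csv(path: str | Path) -> FoodWeb:
    """Read a dense adjacency matrix CSV (row = prey label, column = predator label)."""
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    df.columns = df.columns.map(str)
    df.index = df.index.map(str)
    if list(df.index) != list(df.columns):
        raise ValueError("adjacency CSV must have identical row and column labels")
    return FoodWeb.from_adjacency(df.to_numpy() != 0, labels=list(df.index))


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TrophicValidation:
    """Report on whether trophic levels are well defined for a web.

    A web is trophic-valid iff it has at least one basal species and
    every species is reachable from some basal species along directed
    (prey -> predator) paths.
    """

    has_basal: bool
    unreachable: frozenset[str]

    @property
    def is_valid(self) -> bool:
        return self.has_basal and not self.unreachable

    @property
    def reasons(self) -> tuple[str, ...]:
        out = []
        if not self.has_basal:
            out.append("no basal node (every species has at least one prey)")
        if self.unreachable:
            out.append(
                "nodes unreachable from any basal node: "
                + ", ".join(sorted(self.unreachable))
            )
        return tuple(out)


def basal_nodes(web: FoodWeb) -> frozenset[str]:
    """Species with in-degree zero (no prey)."""
    return web.basal


def validate_trophic_preconditions(web: FoodWeb) -> TrophicValidation:
    """Check the two conditions under which the trophic-level system is solvable."""
    basal = web.basal
    if not basal:
        return TrophicValidation(has_basal=False, unreachable=frozenset(web.nodes))
    succ: dict[str, list[str]] = {n: [] for n in web.nodes}
    for u, v in web.edges:
        succ[u].append(v)
    seen = set(basal)
    frontier = list(basal)
    while frontier:
        nxt = []
        for u in frontier:
            for v in succ[u]:
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
    return TrophicValidation(
        has_basal=True, unreachable=frozenset(set(web.nodes) - seen)
    )
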