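"""Synthetic food webs with known analytic properties.

These generators provide test inputs whose trophic properties are known
in closed form: perfectly layered webs (q = 0 by construction), small
named toys (the omnivory triangle with q = sqrt(1/6), the diamond with
q = 0, the 3-cycle which has no basal species and so no trophic levels),
and random trophic-valid DAGs with exact (N, B, L).
"""

from __future__ import annotations

import numpy as np

from .foodweb_io import FoodWeb

__all__ = ["make_layered", "make_toy", "make_random_dag", "TOY_KINDS"]

TOY_KINDS = ("chain3", "omnivory-triangle", "diamond", "cycle3")


def _label(i: int) -> str:
    return f"n{i:03d}"


def make_layered(
    levels: int,
    width: int,
    extra_links: int = 0,
    seed: int | None = None,
    *,
    skip_link: bool = False,
) -> FoodWeb:
    """A perfectly layered web: ``levels`` layers of ``width`` species.

    Each non-basal species eats one species in the layer directly below;
    ``extra_links`` additional adjacent-layer links are added at random.
    All links span exactly one level, so q = 0.  With ``skip_link=True``
    one level-skipping link is added (requires >= 3 levels), breaking
    coherence: q > 0.
    """
    if levels < 2 or width < 1:
        raise ValueError("need levels >= 2 and width >= 1")
    rng = np.random.default_rng(seed)
    layer = [[lv * width + w for w in range(width)] for lv in range(levels)]
    edges: set[tuple[int, int]] = set()
    for lv in range(1, levels):
        for j in layer[lv]:
            i = int(rng.choice(layer[lv - 1]))
            edges.add((i, j))
    candidates = [
        (i, j)
        for lv in range(1, levels)
        for i in layer[lv - 1]
        for j in layer[lv]
        if (i, j) not in edges
    ]
    if extra_links > len(candidates):
        raise ValueError("extra_links exceeds available adjacent-layer pairs")
    for k in rng.choice(len(candidates), size=extra_links, replace=False) if extra_links else []:
        edges.add(candidates[int(k)])
    if skip_link:
        if levels < 3:
            raise ValueError("a level-skipping link needs >= 3 levels")
        edges.add((layer[0][0], layer[2][0]))
    return FoodWeb.from_edges(
        [(_label(i), _label(j)) for i, j in edges],
        nodes=[_label(i) for i in range(levels * width)],
    )


def make_toy(kind: str) -> FoodWeb:
    """Named fixed webs: chain3, omnivory-triangle (q = sqrt(1/6)),
    diamond (q = 0), cycle3 (trophic-invalid — no basal species)."""
    if kind == "chain3":
        edges = [("a", "b"), ("b", "c")]
    elif kind == "omnivory-triangle":
        edges = [("b", "m"), ("b", "t"), ("m", "t")]
    elif kind == "diamond":
        edges = [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")]
    elif kind == "cycle3":
        edges = [("a", "b"), ("b", "c"), ("c", "a")]
    else:
        raise ValueError(f"unknown toy web {kind!r}; choose from {TOY_KINDS}")
    return FoodWeb.from_edges(edges)


def make_random_dag(N: int, B: int, L: int, seed: int | None = None) -> FoodWeb:
    """A random trophic-valid DAG with exactly N species, B basal, L links.

    Nodes are ordered; each non-basal node takes one prey among earlier
    nodes (a forest of chains rooted at basal nodes), then the remaining
    links are sampled uniformly among forward pairs that keep basal
    in-degrees zero.
    """
    if not 1 <= B < N:
        raise ValueError("need 1 <= B < N")
    max_links = (N - B) * (N - 1) - (N - B) * (N - B - 1) // 2
    if not N - B <= L <= max_links:
        raise ValueError(f"L must be in [{N - B}, {max_links}] for N={N}, B={B}")
    rng = np.random.default_rng(seed)
    edges: set[tuple[int, int]] = set()
    for j in range(B, N):
        edges.add((int(rng.integers(0, j)), j))
    pool = [
        (i, j)
        for j in range(B, N)
        for i in range(j)
        if (i, j) not in edges
    ]
    extra = L - (N - B)
    for k in rng.choice(len(pool), size=extra, replace=False) if extra else []:
        edges.add(pool[int(k)])
    return FoodWeb.from_edges(
        [(_label(i), _label(j)) for i, j in edges],
        nodes=[_label(i) for i in range(N)],
    )
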