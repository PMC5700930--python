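import itertools

import numpy as np
import pytest

from trophic_motifs import FoodWeb, classify_triad, make_toy
from trophic_motifs.motif_census import TRIAD_LABELS


@pytest.fixture
def chain():
    return make_toy("chain3")


@pytest.fixture
def omnivory():
    return make_toy("omnivory-triangle")


@pytest.fixture
def diamond():
    return make_toy("diamond")


@pytest.fixture
def cycle3():
    return make_toy("cycle3")


def brute_force_census(web: FoodWeb) -> dict[str, int]:
    """Independent census oracle: classify every induced node triple."""
    counts = dict.fromkeys(TRIAD_LABELS, 0)
    for triple in itertools.combinations(web.nodes, 3):
        tset = set(triple)
        sub = [(u, v) for u, v in web.edges if u in tset and v in tset]
        g_nodes = sorted(triple)
        label = classify_triad(_EdgeView(g_nodes, sub))
        if label != "disconnected":
            counts[label] += 1
    return counts


class _EdgeView:
    """Minimal graph-like wrapper so the oracle path stays independent."""

    def __init__(self, nodes, edges):
        self._nodes, self._edges = nodes, edges

    def nodes(self):
        return list(self._nodes)

    def edges(self):
        return list(self._edges)


def random_digraph(n: int, p: float, rng: np.random.Generator) -> FoodWeb:
    """Erdos-Renyi directed graph (mutual dyads allowed, no self-loops)."""
    a = rng.random((n, n)) < p
    np.fill_diagonal(a, False)
    return FoodWeb.from_adjacency(a)
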