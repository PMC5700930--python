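import itertools

import numpy as np
import pytest

from trophic_motifs import FoodWeb, census, classify_triad, randomize, tsp
from trophic_motifs.motif_census import (
    TRIAD_LABELS,
    _code_table,
    _decode,
    _encode,
    normalize_profile,
)

from conftest import brute_force_census, random_digraph


class TestClassifyTriad:
    def test_chain_is_s1(self):
        assert classify_triad([("a", "b"), ("b", "c")]) == "S1"

    def test_feed_forward_is_s2(self):
        assert classify_triad([("a", "b"), ("b", "c"), ("a", "c")]) == "S2"

    def test_cycle_is_s3(self, cycle3):
        assert classify_triad(cycle3) == "S3"

    def test_shared_predator_is_s4(self):
        assert classify_triad([("a", "c"), ("b", "c")]) == "S4"

    def test_shared_prey_is_s5(self):
        assert classify_triad([("c", "a"), ("c", "b")]) == "S5"

    def test_dyad_with_outgoing_link(self):
        # one mutual dyad plus a single link leaving the dyad
        assert classify_triad([("a", "b"), ("b", "a"), ("b", "c")]) == "D2"

    def test_single_edge_is_disconnected(self):
        web = FoodWeb.from_edges([("a", "b")], nodes=["a", "b", "c"])
        assert classify_triad(web) == "disconnected"

    def test_wrong_node_count_is_an_error(self):
        with pytest.raises(ValueError, match="3 nodes"):
            classify_triad([("a", "b")])

    def test_permutation_invariance_over_all_digraphs(self):
        """Every labelled 3-node digraph keeps its class under all 6 relabelings."""
        for code in range(64):
            edges = _decode(code)
            base = classify_triad(_triple([("abc"[u], "abc"[v]) for u, v in edges]))
            for perm in itertools.permutations("abc"):
                relabeled = [(perm[u], perm[v]) for u, v in edges]
                assert classify_triad(_triple(relabeled)) == base

    def test_agrees_with_networkx_triad_types(self):
        """Independent oracle: networkx's 16-type triad classification."""
        import networkx as nx

        nx_name = {
            "021C": "S1", "030T": "S2", "030C": "S3", "021U": "S4", "021D": "S5",
            "111D": "D1", "111U": "D2", "120D": "D3", "120U": "D4", "120C": "D5",
            "201": "D6", "210": "D7", "300": "D8",
        }
        for code in range(64):
            g = nx.DiGraph()
            g.add_nodes_from([0, 1, 2])
            g.add_edges_from(_decode(code))
            expected = nx_name.get(nx.triads.triad_type(g), "disconnected")
            assert classify_triad(g) == expected


class _triple:
    """Graph-like wrapper fixing the node set to {a, b, c}."""

    def __init__(self, edge_list):
        self._edges = list(edge_list)

    def nodes(self):
        return ["a", "b", "c"]

    def edges(self):
        return self._edges


class TestCensus:
    def test_omnivory_triangle(self, omnivory):
        assert census(omnivory).as_dict() == {
            **dict.fromkeys(TRIAD_LABELS, 0), "S2": 1
        }

    def test_diamond(self, diamond):
        counts = census(diamond).as_dict()
        assert counts["S1"] == 2 and counts["S4"] == 1 and counts["S5"] == 1
        assert census(diamond).total == 4

    def test_complete_bidirectional_triangle(self):
        web = FoodWeb.from_edges(
            [(u, v) for u in "abc" for v in "abc" if u != v]
        )
        assert census(web).as_dict()["D8"] == 1
        assert census(web).total == 1

    def test_small_web_all_zero_with_warning(self, caplog):
        web = FoodWeb.from_edges([("a", "b")])
        with caplog.at_level("WARNING"):
            assert census(web).total == 0
        assert "fewer than 3" in caplog.text

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_digraphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        web = random_digraph(n, float(rng.uniform(0.1, 0.5)), rng)
        assert census(web).as_dict() == brute_force_census(web)

    def test_total_counts_connected_triples(self, diamond):
        assert census(diamond).total == sum(brute_force_census(diamond).values())


class TestRandomize:
    def test_chain_is_a_fixed_point(self, chain):
        # the 3-chain is the unique digraph for its degree sequences
        assert randomize(chain, 50, rng=0) == chain

    @pytest.mark.parametrize("mode", ["plain", "mutual"])
    def test_degree_sequences_preserved(self, mode):
        rng = np.random.default_rng(5)
        for _ in range(5):
            web = random_digraph(15, 0.2, rng)
            if web.n_links < 2:
                continue
            shuffled = randomize(web, 10, mode=mode, rng=rng)
            assert shuffled.in_degree == web.in_degree
            assert shuffled.out_degree == web.out_degree

    def test_plain_mode_randomizes(self):
        web = random_digraph(20, 0.2, np.random.default_rng(8))
        assert randomize(web, 10, rng=1) != web

    def test_mutual_mode_preserves_dyad_count(self):
        rng = np.random.default_rng(13)
        web = random_digraph(12, 0.35, rng)

        def mutual_count(w):
            return sum(1 for u, v in w.edges if (v, u) in w.edges) // 2

        assert mutual_count(web) > 0, "fixture should contain mutual dyads"
        shuffled = randomize(web, 10, mode="mutual", rng=rng)
        assert mutual_count(shuffled) == mutual_count(web)

    def test_unknown_mode_rejected(self, chain):
        with pytest.raises(ValueError, match="mode"):
            randomize(chain, 1, mode="bogus")

    def test_reproducible_given_seed(self):
        web = random_digraph(15, 0.25, np.random.default_rng(3))
        assert randomize(web, 10, rng=42) == randomize(web, 10, rng=42)


class TestTSP:
    def test_degenerate_null_gives_zero_profile(self, chain):
        _, stats, profile = tsp(chain, ensemble_size=5, swaps_per_link=5, seed=0)
        assert np.all(stats.sd == 0)
        assert np.all(profile.z == 0)
        assert profile.undefined

    def test_normalization_example(self):
        z = np.zeros(13)
        z[0], z[1] = 3.0, 4.0
        profile = normalize_profile(z)
        assert profile.z_hat[0] == pytest.approx(0.6)
        assert profile.z_hat[1] == pytest.approx(0.8)
        assert np.linalg.norm(profile.z_hat) == pytest.approx(1.0)
        assert not profile.undefined

    def test_profile_has_unit_norm(self):
        web = random_digraph(20, 0.2, np.random.default_rng(17))
        _, _, profile = tsp(web, ensemble_size=30, swaps_per_link=5, seed=1)
        if not profile.undefined:
            assert np.linalg.norm(profile.z_hat) == pytest.approx(1.0)

    def test_small_ensemble_rejected(self, chain):
        with pytest.raises(ValueError, match="ensemble_size"):
            tsp(chain, ensemble_size=1)

    def test_ensemble_size_self_consistency(self):
        """z_S2 from a small null ensemble agrees with a larger one within
        Monte-Carlo error."""
        from trophic_motifs.gppm import GPPMConfig, generate

        web = generate(GPPMConfig(B=3, N=30, L=140, T=0.2, seed=6)).web
        s2 = TRIAD_LABELS.index("S2")
        _, _, small = tsp(web, ensemble_size=100, swaps_per_link=5, seed=1)
        _, _, large = tsp(web, ensemble_size=400, swaps_per_link=5, seed=2)
        # z-scores estimated from finite ensembles: allow a generous MC band
        assert small.z[s2] == pytest.approx(large.z[s2], abs=1.0)
        assert np.sign(small.z[s2]) == np.sign(large.z[s2])


class TestCodeTable:
    def test_thirteen_connected_classes(self):
        table = _code_table()
        assert set(table[table >= 0]) == set(range(13))

    def test_encode_decode_round_trip(self):
        for code in range(64):
            assert _encode(_decode(code)) == code
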