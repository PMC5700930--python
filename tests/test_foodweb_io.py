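import logging

import numpy as np
import pytest

from trophic_motifs import (
    FoodWeb,
    basal_nodes,
    make_random_dag,
    read_adjacency_csv,
    read_edge_list,
    validate_trophic_preconditions,
    write_edge_list,
)
from trophic_motifs.foodweb_io import EdgeListParseError
from trophic_motifs.gppm import GPPMConfig, generate

from conftest import random_digraph


def _write(tmp_path, text, name="web.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadEdgeList:
    def test_two_link_chain(self, tmp_path):
        web = read_edge_list(_write(tmp_path, "a b\nb c\n"))
        assert (web.n_nodes, web.n_basal, web.n_links) == (3, 1, 2)

    def test_duplicates_and_self_loops_dropped_with_warning(self, tmp_path, caplog):
        with caplog.at_level(logging.WARNING, logger="trophic_motifs.foodweb_io"):
            web = read_edge_list(_write(tmp_path, "a b\na b\nb b\n"))
        assert (web.n_nodes, web.n_basal, web.n_links) == (2, 1, 1)
        messages = " ".join(r.message for r in caplog.records)
        assert "duplicate" in messages and "self-loop" in messages

    def test_malformed_line_names_line_number(self, tmp_path):
        with pytest.raises(EdgeListParseError, match=":1:"):
            read_edge_list(_write(tmp_path, "a\n"))

    def test_empty_file_is_an_error(self, tmp_path):
        with pytest.raises(EdgeListParseError):
            read_edge_list(_write(tmp_path, "# just a comment\n"))

    def test_swap_columns_flips_direction(self, tmp_path):
        path = _write(tmp_path, "pred prey\n")
        assert ("pred", "prey") in read_edge_list(path).edges
        assert ("prey", "pred") in read_edge_list(path, swap_columns=True).edges

    def test_nodes_header_preserves_isolated_species(self, tmp_path):
        web = read_edge_list(_write(tmp_path, "#nodes: a b c lonely\na b\nb c\n"))
        assert web.n_nodes == 4 and "lonely" in web.nodes


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_dag_round_trip(self, tmp_path, seed):
        web = make_random_dag(20, 5, 50, seed=seed)
        path = tmp_path / "rt.tsv"
        write_edge_list(web, path)
        assert read_edge_list(path) == web

    def test_gppm_draw_round_trip(self, tmp_path):
        web = generate(GPPMConfig(B=5, N=50, L=200, T=0.4, seed=3)).web
        path = tmp_path / "rt.tsv"
        write_edge_list(web, path)
        assert read_edge_list(path) == web

    def test_isolated_nodes_survive_via_header(self, tmp_path):
        web = FoodWeb.from_edges([("a", "b")], nodes=["a", "b", "iso"])
        path = tmp_path / "rt.tsv"
        write_edge_list(web, path)
        assert "#nodes:" in path.read_text()
        assert read_edge_list(path) == web

    def test_edgeless_web_round_trips(self, tmp_path):
        web = FoodWeb.from_edges([], nodes=["x", "y"])
        path = tmp_path / "rt.tsv"
        write_edge_list(web, path)
        assert read_edge_list(path) == web


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    _labels = st.text(alphabet="abcdefgh", min_size=1, max_size=3)

    @given(st.sets(st.tuples(_labels, _labels), max_size=30))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_round_trip_identity_on_arbitrary_webs(tmp_path_factory, raw_edges):
        """read(write(web)) == web for any canonical web."""
        web = FoodWeb.from_edges(raw_edges, nodes=["z"])  # keep at least one node
        path = tmp_path_factory.mktemp("rt") / "web.tsv"
        write_edge_list(web, path)
        assert read_edge_list(path) == web
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


class TestAdjacencyCsv:
    def test_round_trip_through_csv(self, tmp_path, omnivory):
        import pandas as pd

        a = omnivory.adjacency.astype(int)
        pd.DataFrame(a, index=omnivory.nodes, columns=omnivory.nodes).to_csv(
            tmp_path / "adj.csv"
        )
        assert read_adjacency_csv(tmp_path / "adj.csv") == omnivory

    def test_mismatched_labels_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text(",x,y\na,0,1\nb,0,0\n")
        with pytest.raises(ValueError, match="identical row and column"):
            read_adjacency_csv(tmp_path / "bad.csv")


class TestBasalAndValidation:
    def test_chain_has_one_basal(self, chain):
        assert basal_nodes(chain) == {"a"}

    def test_shared_predator_two_basal(self):
        web = FoodWeb.from_edges([("a", "c"), ("b", "c")])
        assert basal_nodes(web) == {"a", "b"}

    def test_cycle_has_no_basal(self, cycle3):
        assert basal_nodes(cycle3) == frozenset()

    def test_basal_count_matches_degree_tally(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            web = random_digraph(10, 0.25, rng)
            tally = sum(1 for n in web.nodes if web.in_degree[n] == 0)
            assert web.n_basal == len(basal_nodes(web)) == tally

    def test_chain_is_trophic_valid(self, chain):
        assert validate_trophic_preconditions(chain).is_valid

    def test_cycle_invalid_for_lack_of_basal(self, cycle3):
        report = validate_trophic_preconditions(cycle3)
        assert not report.is_valid and not report.has_basal
        assert "no basal" in report.reasons[0]

    def test_unreachable_component_detected(self):
        web = FoodWeb.from_edges([("a", "b"), ("c", "d"), ("d", "c")])
        report = validate_trophic_preconditions(web)
        assert not report.is_valid
        assert report.unreachable == {"c", "d"}


class TestFoodWebInvariants:
    def test_self_loop_rejected_in_constructor(self):
        with pytest.raises(ValueError, match="self-loop"):
            FoodWeb(("a",), frozenset({("a", "a")}))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            FoodWeb(("a", "a"), frozenset())

    def test_canonical_node_order_enforced(self):
        with pytest.raises(ValueError, match="canonical"):
            FoodWeb(("b", "a"), frozenset())

    def test_adjacency_matches_edges(self, diamond):
        a = diamond.adjacency
        idx = diamond.index
        for u, v in diamond.edges:
            assert a[idx[u], idx[v]]
        assert a.sum() == diamond.n_links
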