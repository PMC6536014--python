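import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiscreen import (
    GeneList,
    InteractionNetwork,
    build_network,
    connected_components,
    read_edge_table,
    read_gene_list,
    write_edge_table,
    write_metrics_report,
)
from ppiscreen.errors import (
    ConfigurationError,
    EdgeTableParseError,
    EmptyGeneListError,
)
from ppiscreen.graph_model import NodeMetrics, read_annotations

from conftest import net_from_edges, random_network


# ---------------------------------------------------------------- gene lists


class TestReadGeneList:
    def test_deduplicates_preserving_first_appearance(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("SRC\nEGFR\nSRC\n")
        genes = read_gene_list(p)
        assert genes.symbols == ("SRC", "EGFR")

    def test_skips_comments_and_blanks(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("# header\n\nCDH1\n")
        assert read_gene_list(p).symbols == ("CDH1",)

    def test_case_normalized_to_upper(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("src\nSrc\nEGFR\n")
        assert read_gene_list(p).symbols == ("SRC", "EGFR")

    def test_reads_full_sized_query_list(self, tmp_path):
        symbols = [f"G{i:03d}" for i in range(123)]
        p = tmp_path / "genes.txt"
        p.write_text("\n".join(symbols))
        assert len(read_gene_list(p)) == 123

    def test_empty_after_filtering_raises(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("# only a comment\n\n")
        with pytest.raises(EmptyGeneListError):
            read_gene_list(p)

    def test_genelist_rejects_duplicates_and_empty(self):
        with pytest.raises(ValueError):
            GeneList(symbols=("A", "A"))
        with pytest.raises(ValueError):
            GeneList(symbols=("",))


# ---------------------------------------------------------------- edge table


class TestReadEdgeTable:
    def test_threshold_and_self_loop_rules(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\t900\nB\tC\t350\nA\tA\t950\n")
        net = read_edge_table(p, score_threshold=400)
        assert net.nodes == {"A", "B"}
        assert net.edges() == {("A", "B")}

    def test_reciprocal_duplicates_keep_max_score(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\t500\nB\tA\t700\n")
        net = read_edge_table(p, score_threshold=400)
        assert net.edges() == {("A", "B")}
        assert net.score("A", "B") == 700

    def test_max_collapse_happens_before_thresholding(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\t500\nB\tA\t700\n")
        net = read_edge_table(p, score_threshold=600)
        assert net.edges() == {("A", "B")}

    def test_header_autodetected(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("nodeA\tnodeB\tcombined_score\nA\tB\t800\n")
        assert read_edge_table(p, 0).edges() == {("A", "B")}

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\t800\nA\tB\n")
        with pytest.raises(EdgeTableParseError, match="line 2"):
            read_edge_table(p, 0)

    def test_non_integer_score_after_header_is_error(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\t800\nB\tC\thigh\n")
        with pytest.raises(EdgeTableParseError, match="line 2"):
            read_edge_table(p, 0)

    def test_no_surviving_rows_gives_empty_network(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\t100\n")
        net = read_edge_table(p, score_threshold=900)
        assert net.n_nodes() == 0 and net.n_edges() == 0

    def test_threshold_extremes_match_row_filter_oracle(self, tmp_path):
        rng = random.Random(42)
        rows = [
            (f"G{rng.randrange(20):02d}", f"G{rng.randrange(20):02d}", rng.randrange(1001))
            for _ in range(50)
        ]
        p = tmp_path / "edges.tsv"
        p.write_text("".join(f"{a}\t{b}\t{s}\n" for a, b, s in rows))

        # independent oracle: plain row filtering + dedup on unordered pairs
        def expected_edges(threshold):
            best = {}
            for a, b, s in rows:
                key = tuple(sorted((a, b)))
                best[key] = max(best.get(key, -1), s)
            return {k for k, s in best.items() if s >= threshold and k[0] != k[1]}

        assert read_edge_table(p, 0).edges() == expected_edges(0)
        assert read_edge_table(p, 1000).edges() == expected_edges(1000)

    def test_invalid_threshold_rejected(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\t500\n")
        with pytest.raises(ConfigurationError):
            read_edge_table(p, 1500)


# ------------------------------------------------------------- build_network


class TestBuildNetwork:
    def test_unrecognized_genes_reported(self):
        genes = GeneList.from_iterable(["A", "B", "C"])
        universe = net_from_edges([("A", "B")])
        net, unrec = build_network(genes, universe)
        assert net.nodes == {"A", "B"}
        assert net.edges() == {("A", "B")}
        assert unrec == {"C"}

    def test_recognized_gene_without_edges_stays_isolated(self):
        genes = GeneList.from_iterable(["A"])
        universe = net_from_edges([("B", "C")], extra_nodes=["A"])
        net, unrec = build_network(genes, universe)
        assert net.nodes == {"A"} and net.n_edges() == 0
        assert unrec == set()

    def test_recognized_count_matches_set_intersection(self):
        rng = random.Random(7)
        universe = random_network(rng, 100, 0.05)
        genes = GeneList.from_iterable(
            rng.sample([f"N{i:02d}" for i in range(120)], 40)
        )
        net, unrec = build_network(genes, universe)
        expected = set(genes.symbols) & universe.nodes
        assert net.nodes == expected
        assert unrec == set(genes.symbols) - universe.nodes

    def test_idempotent(self):
        rng = random.Random(11)
        universe = random_network(rng, 30, 0.1)
        genes = GeneList.from_iterable(sorted(universe.nodes)[:20])
        net1, _ = build_network(genes, universe)
        net2, unrec2 = build_network(GeneList.from_iterable(net1.nodes), net1)
        assert net2 == net1
        assert unrec2 == set()


# ----------------------------------------------------------------- components


def _union_find_components(net):
    parent = {v: v for v in net.nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in net.edges():
        parent[find(a)] = find(b)
    groups = {}
    for v in net.nodes:
        groups.setdefault(find(v), set()).add(v)
    return {frozenset(g) for g in groups.values()}


class TestConnectedComponents:
    def test_isolated_nodes_are_singletons(self):
        net = net_from_edges([("A", "B")], extra_nodes=["C"])
        parts = connected_components(net)
        assert set(parts.components) == {frozenset("AB"), frozenset("C")}
        assert parts.main == frozenset("AB")
        assert parts.n_isolated() == 1

    def test_empty_network(self):
        parts = connected_components(InteractionNetwork())
        assert len(parts) == 0

    def test_matches_union_find_oracle(self):
        rng = random.Random(5)
        for trial in range(10):
            net = random_network(rng, 30, 25 / (30 * 29 / 2))
            parts = connected_components(net)
            assert set(parts.components) == _union_find_components(net)
            assert sum(len(c) for c in parts.components) == net.n_nodes()

    def test_main_tie_broken_lexicographically(self):
        net = net_from_edges([("X", "Y"), ("A", "B")])
        parts = connected_components(net)
        assert parts.main == frozenset("AB")


# -------------------------------------------------------------------- report


class TestMetricsReport:
    def test_single_row(self, tmp_path):
        m = NodeMetrics("ABC", 3, 0.0, 1.0, 0, 4)
        out = tmp_path / "report.tsv"
        write_metrics_report([m], "degree", out)
        lines = out.read_text().splitlines()
        assert lines[0] == "R\tname\tdescription\tD\tBC\tCC\tStress"
        assert lines[1] == "1\tABC\t\t3\t0.00\t1.00\t0"

    def test_top_row_formats_like_published_table(self, tmp_path):
        # hand-constructed record mirroring the published top hub-bottleneck
        src = NodeMetrics("SRC", 36, 0.20, 0.58, 9508, 105)
        other = NodeMetrics("EGFR", 35, 0.16, 0.57, 7840, 105)
        out = tmp_path / "report.tsv"
        write_metrics_report([other, src], "degree", out)
        lines = out.read_text().splitlines()
        assert lines[1] == "1\tSRC\t\t36\t0.20\t0.58\t9508"
        assert lines[2].startswith("2\tEGFR\t")

    def test_ties_ordered_alphabetically(self, tmp_path):
        ms = [NodeMetrics(g, 2, 0.0, 1.0, 0, 3) for g in ("B", "A")]
        out = tmp_path / "report.tsv"
        write_metrics_report(ms, "degree", out)
        names = [ln.split("\t")[1] for ln in out.read_text().splitlines()[1:]]
        assert names == ["A", "B"]

    def test_unknown_metric_rejected(self, tmp_path):
        m = NodeMetrics("A", 1, 0.0, 1.0, 0, 2)
        with pytest.raises(ConfigurationError):
            write_metrics_report([m], "pagerank", tmp_path / "r.tsv")

    def test_annotations_fill_description_column(self, tmp_path):
        ann = tmp_path / "ann.tsv"
        ann.write_text("SRC\tproto-oncogene tyrosine kinase\n")
        m = NodeMetrics("SRC", 36, 0.20, 0.58, 9508, 105)
        out = tmp_path / "report.tsv"
        write_metrics_report([m], "degree", out, read_annotations(ann))
        assert "proto-oncogene tyrosine kinase" in out.read_text()


# ------------------------------------------------------------ invariants


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    edges=st.lists(
        st.tuples(st.integers(0, 14), st.integers(0, 14)).filter(lambda e: e[0] != e[1]),
        max_size=40,
    ),
    isolated=st.integers(0, 4),
)
def test_roundtrip_and_degree_sum(tmp_path_factory, edges, isolated):
    """Writing a network (including isolated nodes) to the scored-table
    format and re-reading at threshold 0 reproduces it exactly, and the
    handshake identity sum(degrees) == 2 * n_edges holds."""
    net = InteractionNetwork()
    for a, b in edges:
        net.add_edge(f"G{a:02d}", f"G{b:02d}", 800)
    for i in range(isolated):
        net.add_node(f"ISO{i}")
    assert sum(net.degree(v) for v in net.nodes) == 2 * net.n_edges()

    path = tmp_path_factory.mktemp("rt") / "edges.tsv"
    write_edge_table(net, path)
    back = read_edge_table(path, 0)
    assert back == net
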