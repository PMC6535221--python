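"""Keyword screening, bipartite network construction and Cytoscape exports."""

import networkx as nx
import pandas as pd
import pytest

from lncforge.errors import ConfigurationError
from lncforge.models import EnrichmentRecord, TargetLink, Term, TermAnnotation
from lncforge.network import (
    build_network,
    export,
    export_graphml,
    export_sif,
    hub_table,
    screen_by_keywords,
)


def _rec(term_id, name, significant=True):
    return EnrichmentRecord(term_id, name, "pathway-like", 50, 5, 5, 3,
                            0.6, 0.01, 0.02, significant)


def _ann():
    return TermAnnotation([
        Term("T1", "ovarian steroidogenesis", frozenset({"gA", "gB"})),
        Term("T2", "ribosome", frozenset({"gC"})),
        Term("T3", "oxytocin signaling pathway", frozenset({"gD"})),
    ])


def test_keyword_screen_retains_matching_significant_terms():
    recs = [_rec("T1", "ovarian steroidogenesis"),
            _rec("T2", "ribosome"),
            _rec("T3", "oxytocin signaling pathway", significant=False)]
    retained = screen_by_keywords(recs, _ann(), ["steroid", "oxytocin"])
    assert retained == {"gA", "gB"}  # T3 matches but is not significant


def test_keyword_screen_rejects_blank_keywords():
    with pytest.raises(ConfigurationError):
        screen_by_keywords([], _ann(), ["steroid", " "])
    with pytest.raises(ConfigurationError):
        screen_by_keywords([], _ann(), [])


def test_keyword_screen_no_match_warns_and_returns_empty(caplog):
    with caplog.at_level("WARNING"):
        retained = screen_by_keywords([_rec("T2", "ribosome", significant=False)],
                                      _ann(), ["steroid"])
    assert retained == set()
    assert any("no significant term" in r.message for r in caplog.records)


def _de(calls):
    return pd.DataFrame({"call": pd.Series(calls)})


def test_build_network_basic_counts_and_degree():
    de_lnc = _de({"L1": "up"})
    de_mrna = _de({"gA": "down", "gB": "up", "gC": "up"})
    links = [TargetLink("L1", g, "cis", distance_bp=d)
             for g, d in (("gA", 10), ("gB", 20), ("gC", 30))]
    G = build_network(de_lnc, de_mrna, links, {"gA", "gB", "gC"})
    assert G.number_of_nodes() == 4 and G.number_of_edges() == 3
    assert G.nodes["L1"]["degree"] == 3
    assert G.nodes["L1"]["direction"] == "up"
    assert G.nodes["gA"]["direction"] == "down"
    assert hub_table(G).iloc[0]["node"] == "L1"


def test_build_network_dedups_cis_and_trans_edges():
    de_lnc = _de({"L1": "up"})
    de_mrna = _de({"gA": "up"})
    links = [TargetLink("L1", "gA", "cis", distance_bp=100),
             TargetLink("L1", "gA", "trans", r=0.95)]
    G = build_network(de_lnc, de_mrna, links, {"gA"})
    assert G.number_of_edges() == 1
    e = G.edges["L1", "gA"]
    assert e["mode"] == "cis+trans"
    assert e["distance_bp"] == 100 and e["r"] == pytest.approx(0.95)


def test_build_network_excludes_ns_lncrnas_and_unretained_genes():
    de_lnc = _de({"L1": "ns", "L2": "down"})
    de_mrna = _de({"gA": "up", "gB": "up"})
    links = [TargetLink("L1", "gA", "cis", distance_bp=1),
             TargetLink("L2", "gA", "cis", distance_bp=1),
             TargetLink("L2", "gB", "cis", distance_bp=1)]
    G = build_network(de_lnc, de_mrna, links, {"gA"})
    assert set(G.nodes) == {"L2", "gA"}


def test_bipartite_handshake():
    de_lnc = _de({"L1": "up", "L2": "down"})
    de_mrna = _de({f"g{i}": "up" for i in range(5)})
    links = [TargetLink(l, f"g{i}", "cis", distance_bp=i)
             for l in ("L1", "L2") for i in range(5)]
    G = build_network(de_lnc, de_mrna, links, {f"g{i}" for i in range(5)})
    lnc_deg = sum(d for n, d in G.degree if G.nodes[n]["kind"] == "lncRNA")
    gene_deg = sum(d for n, d in G.degree if G.nodes[n]["kind"] == "mRNA")
    assert lnc_deg == gene_deg == G.number_of_edges()


def test_planted_hub_tops_hub_list(study):
    """L01 is generated with six cis targets; after the full identify+DE+target
    stages it has the highest degree in the follicular network."""
    from lncforge.pipeline import run_pipeline
    import tempfile

    with tempfile.TemporaryDirectory() as d:
        run_pipeline(study.config, d)
        hubs = pd.read_csv(f"{d}/network_follicular_hubs.tsv", sep="\t")
    assert hubs.iloc[0]["node"] == "L01.t1"


def test_sif_export_stable_and_sorted(tmp_path):
    de_lnc = _de({"L2": "up", "L1": "up"})
    de_mrna = _de({"gA": "up", "gB": "down"})
    links = [TargetLink("L2", "gB", "cis", distance_bp=1),
             TargetLink("L1", "gA", "cis", distance_bp=1),
             TargetLink("L1", "gB", "trans", r=0.99)]
    G = build_network(de_lnc, de_mrna, links, {"gA", "gB"})
    p1, p2 = tmp_path / "a.sif", tmp_path / "b.sif"
    export_sif(G, p1)
    export_sif(G, p2)
    assert p1.read_bytes() == p2.read_bytes()
    lines = p1.read_text().splitlines()
    assert lines == sorted(lines)
    assert lines[0].split("\t") == ["L1", "targets", "gA"]


def test_graphml_roundtrip_isomorphic_with_attributes(tmp_path):
    de_lnc = _de({"L1": "up"})
    de_mrna = _de({"gA": "down"})
    links = [TargetLink("L1", "gA", "cis", distance_bp=42)]
    G = build_network(de_lnc, de_mrna, links, {"gA"})
    p = tmp_path / "n.graphml"
    export_graphml(G, p)
    H = nx.read_graphml(p)
    assert nx.is_isomorphic(
        G, H,
        node_match=lambda a, b: (a["kind"], a["direction"]) == (b["kind"], b["direction"]),
        edge_match=lambda a, b: a["mode"] == b["mode"])


def test_empty_network_exports_are_valid(tmp_path):
    G = build_network(_de({}), _de({}), [], set())
    export_graphml(G, tmp_path / "e.graphml")
    assert nx.read_graphml(tmp_path / "e.graphml").number_of_nodes() == 0
    export_sif(G, tmp_path / "e.sif")
    assert (tmp_path / "e.sif").read_text() == ""


def test_export_dispatch_unknown_format(tmp_path):
    G = nx.Graph()
    with pytest.raises(ConfigurationError, match="format"):
        export(G, "dot", tmp_path / "x")
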