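"""Keyword-screened lncRNA-mRNA regulatory network construction and export.

Genes are retained when they are annotated to a significant enrichment term
whose name matches at least one keyword (case-insensitive substring, regex
optional).  Nodes are differentially expressed lncRNAs with at least one
retained target plus the retained target genes; edges are the (deduplicated)
cis/trans target links.  Exports are Cytoscape-loadable: SIF, GraphML and a
TSV edge list, all with stable ordering so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ConfigurationError
from .models import EnrichmentRecord, TargetLink, TermAnnotation

logger = logging.getLogger(__name__)

DEFAULT_KEYWORDS = ("steroid", "oxytocin", "retinol", "foxo", "reproduct",
                    "estrogen", "prolactin")


def screen_by_keywords(enrich_results: list[EnrichmentRecord],
                       annotation: TermAnnotation,
                       keywords=DEFAULT_KEYWORDS,
                       regex: bool = False) -> set[str]:
    """Genes annotated to any *significant* term whose name matches a keyword."""
    keywords = list(keywords)
    if not keywords or any(not str(k).strip() for k in keywords):
        raise ConfigurationError("keywords must be non-empty, non-blank strings")
    retained: set[str] = set()
    matched_terms = []
    for rec in enrich_results:
        if not rec.significant:
            continue
        name = rec.term_name.casefold()
        hit = any(
            re.search(str(k), rec.term_name, flags=re.IGNORECASE) if regex
            else str(k).casefold() in name
            for k in keywords
        )
        if hit:
            matched_terms.append(rec.term_id)
            retained |= set(annotation[rec.term_id].genes)
    if not matched_terms:
        logger.warning("no significant term matched any keyword; empty gene set")
    return retained


def build_network(de_lnc: pd.DataFrame, de_mrna: pd.DataFrame,
                  links: list[TargetLink], retained_genes: set[str]) -> nx.Graph:
    """Bipartite graph of DE lncRNAs vs retained target genes.

    Node attributes: kind (lncRNA/mRNA), direction (up/down from the DE call;
    ns for a retained gene that was not itself DE), degree.  Edge attributes:
    mode ("cis", "trans" or "cis+trans"), distance_bp, r.
    """
    lnc_dir = {fid: c for fid, c in de_lnc["call"].items() if c in ("up", "down")}
    gene_dir: dict[str, str] = {}
    if "call" in de_mrna.columns:
        gene_dir = {fid: c for fid, c in de_mrna["call"].items()}

    merged: dict[tuple[str, str], dict] = {}
    for l in links:
        if l.lncrna_id not in lnc_dir or l.gene_id not in retained_genes:
            continue
        if l.lncrna_id == l.gene_id:
            continue
        key = (l.lncrna_id, l.gene_id)
        e = merged.setdefault(key, {"modes": set(), "distance_bp": None, "r": None})
        e["modes"].add(l.mode)
        if l.mode == "cis":
            e["distance_bp"] = l.distance_bp
        if l.mode == "trans":
            e["r"] = l.r

    G = nx.Graph()
    lnc_nodes = sorted({k[0] for k in merged})
    gene_nodes = sorted({k[1] for k in merged})
    for nid in lnc_nodes:
        G.add_node(nid, kind="lncRNA", direction=lnc_dir[nid], bipartite=0)
    for nid in gene_nodes:
        G.add_node(nid, kind="mRNA", direction=gene_dir.get(nid, "ns"), bipartite=1)
    for (lid, gid) in sorted(merged):
        e = merged[(lid, gid)]
        attrs = {"mode": "+".join(sorted(e["modes"]))}
        if e["distance_bp"] is not None:
            attrs["distance_bp"] = int(e["distance_bp"])
        if e["r"] is not None:
            attrs["r"] = float(e["r"])
        G.add_edge(lid, gid, **attrs)
    for nid in G.nodes:
        G.nodes[nid]["degree"] = G.degree[nid]
    return G


def hub_table(G: nx.Graph) -> pd.DataFrame:
    """Nodes by degree descending, ties broken by id."""
    rows = sorted(
        ({"node": n, "kind": d["kind"], "direction": d["direction"],
          "degree": d["degree"]} for n, d in G.nodes(data=True)),
        key=lambda r: (-r["degree"], r["node"]),
    )
    return pd.DataFrame(rows, columns=["node", "kind", "direction", "degree"])


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_sif(G: nx.Graph, path) -> None:
    lines = []
    for u, v in G.edges():
        lnc, gene = (u, v) if G.nodes[u]["kind"] == "lncRNA" else (v, u)
        lines.append(f"{lnc}\ttargets\t{gene}")
    Path(path).write_text("\n".join(sorted(lines)) + ("\n" if lines else ""))


def export_graphml(G: nx.Graph, path) -> None:
    H = nx.Graph()
    for n in sorted(G.nodes):
        H.add_node(n, **G.nodes[n])
    for u, v in sorted((tuple(sorted(e)) for e in G.edges()), key=lambda e: e):
        H.add_edge(u, v, **G.edges[u, v])
    nx.write_graphml(H, path)


def export_edges_tsv(G: nx.Graph, path) -> None:
    rows = []
    for u, v in G.edges():
        lnc, gene = (u, v) if G.nodes[u]["kind"] == "lncRNA" else (v, u)
        d = G.edges[u, v]
        rows.append({"lncrna_id": lnc, "gene_id": gene, "mode": d.get("mode", ""),
                     "distance_bp": d.get("distance_bp", ""),
                     "r": f"{d['r']:.6f}" if "r" in d else ""})
    rows.sort(key=lambda r: (r["lncrna_id"], r["gene_id"]))
    pd.DataFrame(rows, columns=["lncrna_id", "gene_id", "mode", "distance_bp", "r"]
                 ).to_csv(path, sep="\t", index=False)


def export(G: nx.Graph, fmt: str, path) -> None:
    """Dispatch on format: sif | graphml | tsv."""
    writers = {"sif": export_sif, "graphml": export_graphml, "tsv": export_edges_tsv}
    if fmt not in writers:
        raise ConfigurationError(f"unknown export format {fmt!r}; use sif/graphml/tsv")
    writers[fmt](G, path)
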