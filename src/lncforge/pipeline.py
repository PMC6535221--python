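"""End-to-end pipeline on a synthetic (or on-disk) study.

Stages: generate/load inputs -> lncRNA identification -> FPKM -> per-phase NB
differential expression (lncRNAs at transcript level, mRNAs at gene level) ->
cis + trans target prediction for the DE lncRNAs -> hypergeometric enrichment
of the target genes -> keyword-screened bipartite network with Cytoscape
exports.  All outputs are TSV/SIF/GraphML/JSON with stable ordering and
formatting, so a fixed seed reproduces the run byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path


from . import io as lio
from .diffexpr import de_analysis
from .enrichment import enrich, enrichment_frame
from .expression import aggregate_to_genes, fpkm
from .identify import characterize, identify_lncrnas
from .models import PHASES
from .network import (
    DEFAULT_KEYWORDS,
    build_network,
    export_edges_tsv,
    export_graphml,
    export_sif,
    hub_table,
    screen_by_keywords,
)
from .simulate import SimConfig, simulate_study, write_study
from .targets import cis_targets, links_frame, trans_targets

_FLOAT_FMT = "%.10g"


def run_pipeline(cfg: SimConfig, outdir, keywords=DEFAULT_KEYWORDS,
                 use: str = "pvalue") -> dict:
    """Simulate a study and run every stage, writing all artifacts to *outdir*.

    Returns a summary dict (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(cfg)
    write_study(study, outdir)
    sheet, counts = study.sheet, study.counts

    # --- identification ----------------------------------------------------
    candidates, report = identify_lncrnas(study.transcripts, study.votes)
    lnc_ids = [t.transcript_id for t in candidates]
    mrnas = [t for t in study.transcripts if t.biotype == "known_mRNA"]
    report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    report.venn_frame(study.votes.predictors).to_csv(
        outdir / "venn.tsv", sep="\t", index=False)
    lio.write_gtf(candidates, outdir / "candidates.gtf")

    # --- quantification -----------------------------------------------------
    lengths = lio.feature_lengths(study.transcripts)
    lnc_counts = counts.loc[lnc_ids]
    lnc_expr = fpkm(lnc_counts, lengths)
    gene_counts, gene_lengths = aggregate_to_genes(
        counts.loc[[t.transcript_id for t in mrnas]], mrnas)
    gene_expr = fpkm(gene_counts, gene_lengths)
    lnc_expr.to_csv(outdir / "fpkm_lncrna.tsv", sep="\t", float_format=_FLOAT_FMT)
    gene_expr.to_csv(outdir / "fpkm_mrna.tsv", sep="\t", float_format=_FLOAT_FMT)

    for name, table in characterize(candidates, mrnas, lnc_expr).items():
        table.to_csv(outdir / f"characterize_{name}.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)

    summary: dict = {
        "n_input_transcripts": report.n_input,
        "n_candidate_lncrnas": len(candidates),
        "n_known_mrnas": len(mrnas),
        "rule_rejections": dict(sorted(report.rule_counts.items())),
    }

    # --- per-phase DE, targets, enrichment, network -------------------------
    background = sorted(gene_expr.index[(gene_expr > 0).any(axis=1)])
    for phase in PHASES:
        de_lnc = de_analysis(lnc_counts, sheet, phase, use=use)
        de_gene = de_analysis(gene_counts, sheet, phase, use=use)
        de_lnc.to_csv(outdir / f"de_lncrna_{phase}.tsv", sep="\t",
                      float_format=_FLOAT_FMT)
        de_gene.to_csv(outdir / f"de_mrna_{phase}.tsv", sep="\t",
                       float_format=_FLOAT_FMT)

        de_lnc_ids = sorted(de_lnc.index[de_lnc["call"] != "ns"])
        de_lnc_models = [t for t in candidates if t.transcript_id in set(de_lnc_ids)]
        links = cis_targets(de_lnc_models, mrnas)
        phase_samples = sheet.select(phase=phase)
        if de_lnc_ids:
            links += trans_targets(lnc_expr.loc[de_lnc_ids, phase_samples],
                                   gene_expr[phase_samples])
        links_frame(links).to_csv(outdir / f"targets_{phase}.tsv", sep="\t",
                                  index=False)

        target_genes = sorted({l.gene_id for l in links})
        records = enrich(target_genes, study.terms, background)
        enrichment_frame(records).to_csv(outdir / f"enrichment_{phase}.tsv",
                                         sep="\t", index=False,
                                         float_format=_FLOAT_FMT)

        retained = screen_by_keywords(records, study.terms, keywords)
        G = build_network(de_lnc, de_gene, links, retained)
        export_sif(G, outdir / f"network_{phase}.sif")
        export_graphml(G, outdir / f"network_{phase}.graphml")
        export_edges_tsv(G, outdir / f"network_{phase}_edges.tsv")
        hub_table(G).to_csv(outdir / f"network_{phase}_hubs.tsv", sep="\t",
                            index=False)

        calls_l = de_lnc["call"].value_counts()
        calls_g = de_gene["call"].value_counts()
        summary[phase] = {
            "lncrna_up": int(calls_l.get("up", 0)),
            "lncrna_down": int(calls_l.get("down", 0)),
            "mrna_up": int(calls_g.get("up", 0)),
            "mrna_down": int(calls_g.get("down", 0)),
            "n_target_links": len(links),
            "n_target_genes": len(target_genes),
            "n_significant_terms": sum(r.significant for r in records),
            "network_nodes": G.number_of_nodes(),
            "network_edges": G.number_of_edges(),
        }

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return summary
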