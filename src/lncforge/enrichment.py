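"""Hypergeometric over-representation analysis with BH FDR Q-values.

For a query gene set (DE genes or lncRNA target genes), each term's overlap is
tested against the background with the upper-tail hypergeometric probability

    p = sum_{i=m}^{min(M, n)} C(M, i) C(N-M, n-i) / C(N, n)

where N = background size, M = background genes in the term, n = query genes
in the background and m = query genes in the term.  Q-values are BH step-up
within a namespace; the significance flag uses the raw p <= 0.05 rule (the
Q-value is reported alongside).  The rich factor is m / M, the fraction of a
term's background genes hit by the query.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import EnrichmentRecord, TermAnnotation

logger = logging.getLogger(__name__)


def hypergeom_test(query, term_genes, background) -> EnrichmentRecord | None:
    """Upper-tail hypergeometric test of one term; genes outside the
    background are dropped (logged).  Returns None for an empty background or
    a term with no background genes."""
    bg = set(background)
    q = set(query)
    dropped = len(q - bg)
    if dropped:
        logger.info("%d query genes outside background dropped", dropped)
    q &= bg
    t = set(term_genes) & bg
    N, M, n = len(bg), len(t), len(q)
    if N == 0 or M == 0:
        logger.info("term skipped: empty background or empty term after intersection")
        return None
    m = len(q & t)
    p = float(stats.hypergeom.sf(m - 1, N, M, n))
    p = min(max(p, 0.0), 1.0)
    return EnrichmentRecord(
        term_id="", term_name="", namespace="", N=N, M=M, n=n, m=m,
        rich_factor=m / M, pvalue=p,
    )


def hypergeom_exact(N: int, M: int, n: int, m: int) -> float:
    """Exact integer-arithmetic upper-tail probability (independent oracle)."""
    num = sum(math.comb(M, i) * math.comb(N - M, n - i)
              for i in range(m, min(M, n) + 1))
    return float(Fraction(num, math.comb(N, n)))


def enrich(query, annotation: TermAnnotation, background, alpha: float = 0.05,
           min_query_genes: int = 1) -> list[EnrichmentRecord]:
    """Test every term with at least *min_query_genes* query genes; BH across
    the tested terms; significant iff raw p <= alpha."""
    records: list[EnrichmentRecord] = []
    for term in sorted(annotation, key=lambda t: t.term_id):
        rec = hypergeom_test(query, term.genes, background)
        if rec is None or rec.m < min_query_genes:
            continue
        rec.term_id = term.term_id
        rec.term_name = term.term_name
        rec.namespace = annotation.namespace
        records.append(rec)
    if records:
        pvals = np.array([r.pvalue for r in records])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for r, qv in zip(records, qvals):
            r.qvalue = float(qv)
            r.significant = r.pvalue <= alpha
    records.sort(key=lambda r: (r.pvalue, r.term_id))
    return records


def enrichment_frame(records: list[EnrichmentRecord]):
    import pandas as pd

    return pd.DataFrame([{
        "term_id": r.term_id, "term_name": r.term_name, "namespace": r.namespace,
        "N": r.N, "M": r.M, "n": r.n, "m": r.m,
        "rich_factor": r.rich_factor, "pvalue": r.pvalue, "qvalue": r.qvalue,
        "significant": r.significant,
    } for r in records], columns=["term_id", "term_name", "namespace", "N", "M",
                                  "n", "m", "rich_factor", "pvalue", "qvalue",
                                  "significant"])
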