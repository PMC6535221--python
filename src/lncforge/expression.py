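"""FPKM quantification and expression-matrix utilities.

FPKM(i, j) = 1e9 * k_ij / (N_j * L_i), with k_ij assigned fragments, N_j the
per-sample total (column sum by default, overridable for a library-wide mapped
count) and L_i the feature length in bp.  FPKM is invariant to jointly scaling
a sample's counts and total, and monotone in k at fixed N and L.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .models import SampleSheet, TranscriptModel

logger = logging.getLogger(__name__)


def fpkm(counts: pd.DataFrame, lengths: pd.Series | dict,
         totals: pd.Series | dict | None = None) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments."""
    lengths = pd.Series(lengths, dtype=float)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise DataError(f"missing lengths for features: {list(missing[:5])}...")
    L = lengths.reindex(counts.index)
    if (L <= 0).any():
        raise DataError("feature lengths must be positive")
    if totals is None:
        N = counts.sum(axis=0).astype(float)
    else:
        N = pd.Series(totals, dtype=float).reindex(counts.columns)
        if N.isna().any():
            raise DataError("totals missing for some samples")
    zero = N == 0
    if zero.any():
        logger.warning("samples with zero total fragments: %s; FPKM set to 0",
                       list(N.index[zero]))
        N = N.replace(0, np.nan)
    out = 1e9 * counts.div(N, axis=1).div(L, axis=0)
    return out.fillna(0.0)


def group_means(expr: pd.DataFrame, sheet: SampleSheet,
                group: str | None = None, phase: str | None = None) -> pd.Series:
    """Arithmetic mean expression over the selected samples."""
    samples = sheet.select(group=group, phase=phase)  # raises if empty
    missing = [s for s in samples if s not in expr.columns]
    if missing:
        raise ConfigurationError(f"samples not in expression matrix: {missing}")
    return expr[samples].mean(axis=1)


def aggregate_to_genes(counts: pd.DataFrame, transcripts: list[TranscriptModel]
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Gene-level aggregation: counts summed over isoforms, length = max
    isoform length.  Returns (gene counts, gene lengths)."""
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    length_of: dict[str, int] = {}
    for t in transcripts:
        g = t.gene_id
        length_of[g] = max(length_of.get(g, 0), t.length())
    keep = [tid for tid in counts.index if tid in gene_of]
    grouped = counts.loc[keep].groupby([gene_of[tid] for tid in keep], sort=True).sum()
    grouped.index.name = "gene_id"
    lengths = pd.Series({g: float(length_of[g]) for g in grouped.index}, name="length")
    return grouped, lengths


def log2p1(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1), the default variance-stabilizing transform for correlations."""
    return np.log2(expr + 1.0)
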