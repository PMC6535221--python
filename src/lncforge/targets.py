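"""Cis and trans lncRNA target-gene prediction.

Cis targets are protein-coding genes whose genomic span lies within a fixed
window (default 50 kb, boundary inclusive) of the lncRNA on either side,
strand-ignored; overlapping features have distance 0.  Trans targets are genes
whose expression correlates with the lncRNA at Pearson r >= 0.9 (signed by
default), computed on log2(FPKM + 1).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .expression import log2p1
from .models import TargetLink, TranscriptModel

logger = logging.getLogger(__name__)


def _distance(s1: int, e1: int, s2: int, e2: int) -> int:
    """Nearest-end gap between half-open intervals; 0 when overlapping."""
    return max(s2 - e1, s1 - e2, 0)


def cis_targets(lncrnas: list[TranscriptModel], genes: list[TranscriptModel],
                window: int = 50_000) -> list[TargetLink]:
    """Sorted-sweep window query: link each lncRNA to every same-chromosome
    gene within *window* bp (inclusive)."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[TranscriptModel]]] = {}
    for chrom in sorted({g.chrom for g in genes}):
        sub = sorted((g for g in genes if g.chrom == chrom), key=lambda g: g.start)
        starts = np.array([g.start for g in sub], dtype=np.int64)
        ends = np.array([g.end for g in sub], dtype=np.int64)
        by_chrom[chrom] = (starts, ends, sub)

    links: list[TargetLink] = []
    for lnc in lncrnas:
        entry = by_chrom.get(lnc.chrom)
        if entry is None:
            continue
        starts, ends, sub = entry
        hi = int(np.searchsorted(starts, lnc.end + window, side="right"))
        mask = ends[:hi] >= lnc.start - window
        for j in np.nonzero(mask)[0]:
            g = sub[j]
            if g.transcript_id == lnc.transcript_id:
                continue
            links.append(TargetLink(
                lncrna_id=lnc.transcript_id, gene_id=g.gene_id, mode="cis",
                distance_bp=_distance(lnc.start, lnc.end, g.start, g.end)))
    links.sort(key=lambda l: (l.lncrna_id, l.gene_id))
    return links


def cis_targets_bruteforce(lncrnas: list[TranscriptModel],
                           genes: list[TranscriptModel],
                           window: int = 50_000) -> list[TargetLink]:
    """O(n*m) all-pairs scan; the independent oracle for the sweep."""
    links = []
    for lnc in lncrnas:
        for g in genes:
            if g.chrom != lnc.chrom or g.transcript_id == lnc.transcript_id:
                continue
            d = _distance(lnc.start, lnc.end, g.start, g.end)
            if d <= window:
                links.append(TargetLink(lncrna_id=lnc.transcript_id,
                                        gene_id=g.gene_id, mode="cis",
                                        distance_bp=d))
    links.sort(key=lambda l: (l.lncrna_id, l.gene_id))
    return links


def trans_targets(lnc_expr: pd.DataFrame, gene_expr: pd.DataFrame,
                  r_threshold: float = 0.9, min_samples: int = 4,
                  log_transform: bool = True,
                  absolute: bool = False) -> list[TargetLink]:
    """Pearson-correlation targets over shared samples.

    Constant (zero-variance) expression vectors have undefined correlation and
    yield no links (logged).  With ``absolute=True`` the magnitude |r| is
    compared with the threshold instead of the signed value.
    """
    shared = [s for s in lnc_expr.columns if s in set(gene_expr.columns)]
    if len(shared) < min_samples:
        raise ConfigurationError(
            f"only {len(shared)} shared samples; need >= {min_samples}"
        )
    L = log2p1(lnc_expr[shared]) if log_transform else lnc_expr[shared].astype(float)
    G = log2p1(gene_expr[shared]) if log_transform else gene_expr[shared].astype(float)

    def _standardize(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        x = df.values - df.values.mean(axis=1, keepdims=True)
        norms = np.sqrt((x**2).sum(axis=1))
        ok = norms > 0
        x[ok] /= norms[ok, None]
        return x, ok

    Lx, Lok = _standardize(L)
    Gx, Gok = _standardize(G)
    n_const = int((~Lok).sum() + (~Gok).sum())
    if n_const:
        logger.info("%d constant expression vectors excluded from trans correlation",
                    n_const)
    R = Lx @ Gx.T
    score = np.abs(R) if absolute else R
    links = []
    for i, lid in enumerate(L.index):
        if not Lok[i]:
            continue
        for j in np.nonzero(score[i] >= r_threshold)[0]:
            if not Gok[j]:
                continue
            gid = G.index[j]
            if gid == lid:
                continue
            links.append(TargetLink(lncrna_id=lid, gene_id=gid, mode="trans",
                                    r=float(R[i, j]), n_samples_used=len(shared)))
    links.sort(key=lambda l: (l.lncrna_id, l.gene_id))
    return links


def links_frame(links: list[TargetLink]) -> pd.DataFrame:
    """Tabular view of target links for TSV export."""
    rows = [{
        "lncrna_id": l.lncrna_id, "gene_id": l.gene_id, "mode": l.mode,
        "distance_bp": l.distance_bp if l.distance_bp is not None else "",
        "r": f"{l.r:.6f}" if l.r is not None else "",
    } for l in links]
    return pd.DataFrame(rows, columns=["lncrna_id", "gene_id", "mode",
                                       "distance_bp", "r"])
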