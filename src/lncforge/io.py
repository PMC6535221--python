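"""Readers and writers for every external format the pipeline touches.

GTF (StringTie/gffcompare dialect), TSV count matrix, TSV sample sheet, TSV
coding-potential vote table, TSV coverage matrix and GMT term annotation.
GTF coordinates (1-based inclusive) are converted to internal 0-based
half-open at this boundary and back on write, so an exon written as
``start=101 end=200`` becomes the interval ``[100, 200)`` of width 100.
"""

from __future__ import annotations

from pathlib import Path

import gffutils.feature
import pandas as pd

from .errors import ConfigurationError, DataError, ParseError
from .models import SampleSheet, Term, TermAnnotation, TranscriptModel, VoteTable


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path, sample_id: str | None = None) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Exon features are grouped by ``transcript_id`` and sorted; ``class_code``
    and ``cov`` are taken from the transcript feature when present.  A missing
    ``class_code`` defaults to ``'='`` (known match) and a missing ``cov`` to
    an empty coverage map (0 in all samples).  When *sample_id* is given, a
    ``cov`` attribute populates ``coverage[sample_id]`` (per-sample GTF
    convention); otherwise use :func:`read_coverage` + :func:`attach_coverage`.
    """
    path = Path(path)
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # gffutils raises plain ValueError and friends
                raise ParseError(f"{path}:{lineno}: malformed GTF line: {exc}") from exc
            attrs = feat.attributes
            tid = _attr(attrs, "transcript_id")
            if feat.featuretype == "exon":
                if tid is None:
                    raise ParseError(f"{path}:{lineno}: exon without transcript_id")
                gid = _attr(attrs, "gene_id")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: exon without gene_id")
                rec = meta.setdefault(tid, {"gene_id": gid, "chrom": feat.seqid,
                                            "strand": feat.strand})
                rec.setdefault("gene_id", gid)
                if tid not in exons:
                    order.append(tid)
                # GTF 1-based inclusive -> 0-based half-open
                exons.setdefault(tid, []).append((feat.start - 1, feat.end))
            elif feat.featuretype == "transcript":
                if tid is None:
                    raise ParseError(f"{path}:{lineno}: transcript without transcript_id")
                rec = meta.setdefault(tid, {"gene_id": _attr(attrs, "gene_id"),
                                            "chrom": feat.seqid, "strand": feat.strand})
                if tid not in exons:
                    order.append(tid)
                    exons.setdefault(tid, [])
                code = _attr(attrs, "class_code")
                if code is not None:
                    rec["class_code"] = code
                cov = _attr(attrs, "cov")
                if cov is not None and sample_id is not None:
                    rec["cov"] = float(cov)

    out: list[TranscriptModel] = []
    for tid in order:
        rec = meta[tid]
        ex = sorted(exons.get(tid, []))
        coverage = {}
        if sample_id is not None and "cov" in rec:
            coverage[sample_id] = rec["cov"]
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=rec.get("gene_id") or tid,
            chrom=rec["chrom"],
            strand=rec.get("strand") or ".",
            exons=ex,
            class_code=rec.get("class_code", "="),
            coverage=coverage,
        )
        t.validate()
        out.append(t)
    return out


def _attr(attrs, key: str) -> str | None:
    try:
        vals = attrs[key]
    except KeyError:
        return None
    return vals[0] if vals else None


def write_gtf(transcripts: list[TranscriptModel], path) -> None:
    """Write transcript + exon GTF lines (internal half-open -> 1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; ' \
                    f'class_code "{t.class_code}";'
            fh.write("\t".join([
                t.chrom, "lncforge", "transcript", str(t.start + 1), str(t.end),
                ".", t.strand, ".", attrs,
            ]) + "\n")
            for i, (s, e) in enumerate(t.exons, start=1):
                ex_attrs = attrs + f' exon_number "{i}";'
                fh.write("\t".join([
                    t.chrom, "lncforge", "exon", str(s + 1), str(e),
                    ".", t.strand, ".", ex_attrs,
                ]) + "\n")


# ---------------------------------------------------------------------------
# Coverage matrix (transcript x sample)
# ---------------------------------------------------------------------------

def read_coverage(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise DataError(f"{path}: negative coverage values")
    return df


def write_coverage(transcripts: list[TranscriptModel], path) -> None:
    rows = {t.transcript_id: t.coverage for t in transcripts}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def attach_coverage(transcripts: list[TranscriptModel], coverage: pd.DataFrame) -> None:
    """Populate each transcript's per-sample coverage map from a matrix."""
    for t in transcripts:
        if t.transcript_id in coverage.index:
            t.coverage = {s: float(v) for s, v in coverage.loc[t.transcript_id].items()}


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def read_counts(path, sheet: SampleSheet | None = None) -> pd.DataFrame:
    """Read a feature x sample fragment-count matrix (TSV, header row).

    Counts must be non-negative integers.  When *sheet* is given the column
    sample ids are cross-validated against it.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise DataError(f"{path}: negative counts")
    as_int = df.round().astype("int64")
    if not (df.values == as_int.values).all():
        raise DataError(f"{path}: non-integer counts")
    if sheet is not None:
        unknown = set(df.columns) - set(sheet.sample_ids)
        if unknown:
            raise ConfigurationError(
                f"{path}: samples absent from sample sheet: {sorted(unknown)}"
            )
    return as_int


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Coding-potential votes
# ---------------------------------------------------------------------------

def read_votes(path) -> VoteTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.isna().any().any():
        missing = df.index[df.isna().any(axis=1)].tolist()
        raise DataError(f"{path}: missing predictor votes for transcripts {missing}")
    return VoteTable(df)


def write_votes(votes: VoteTable, path) -> None:
    out = votes.df.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT term annotation
# ---------------------------------------------------------------------------

def read_gmt(path, namespace: str = "pathway-like") -> TermAnnotation:
    """Read GMT: ``term_id <TAB> term_name <TAB> gene1 <TAB> gene2 ...``"""
    terms: list[Term] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs term_id, term_name and >=1 gene"
                )
            terms.append(Term(parts[0], parts[1], frozenset(parts[2:])))
    return TermAnnotation(terms, namespace=namespace)


def write_gmt(annotation: TermAnnotation, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation, key=lambda t: t.term_id):
            fh.write("\t".join([term.term_id, term.term_name, *sorted(term.genes)]) + "\n")


def feature_lengths(transcripts: list[TranscriptModel]) -> pd.Series:
    """Mature length (sum of exon widths) per transcript id."""
    return pd.Series(
        {t.transcript_id: t.length() for t in transcripts}, name="length", dtype=float
    )
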