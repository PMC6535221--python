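"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open throughout the package; GTF I/O converts at
the boundary (GTF is 1-based inclusive).  A transcript's length is the sum of
its exon widths (mature length), not the genomic span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, DataError

GROUPS = ("polytocous", "monotocous")
PHASES = ("follicular", "luteal")

#: class_code -> lncRNA subtype, per the gffcompare vocabulary
CLASS_CODE_SUBTYPE = {"u": "lincRNA", "i": "intronic", "x": "antisense"}

VOTE_LABELS = ("coding", "noncoding")


@dataclass
class TranscriptModel:
    """One assembled transcript: exon structure, class code, coverage, biotype."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str = "."
    exons: list[tuple[int, int]] = field(default_factory=list)
    class_code: str = "="
    coverage: dict[str, float] = field(default_factory=dict)
    biotype: str = "unclassified"
    subtype: str | None = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def length(self) -> int:
        """Mature transcript length: sum of exon widths in bp."""
        return sum(e - s for s, e in self.exons)

    def validate(self) -> None:
        if len(self.class_code) != 1:
            raise DataError(
                f"{self.transcript_id}: class_code must be one character, "
                f"got {self.class_code!r}"
            )
        if not self.exons:
            raise DataError(f"{self.transcript_id}: transcript has no exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise DataError(f"{self.transcript_id}: exon end {e} <= start {s}")
            if prev_end is not None and s < prev_end:
                raise DataError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e
        if any(v < 0 for v in self.coverage.values()):
            raise DataError(f"{self.transcript_id}: negative coverage")


class SampleSheet:
    """Sample metadata: sample_id -> (group, phase).

    Groups are ``polytocous``/``monotocous``; phases ``follicular``/``luteal``.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"sample_id", "group", "phase"}
        if not required.issubset(df.columns):
            raise DataError(f"sample sheet needs columns {sorted(required)}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise DataError(f"duplicate sample ids: {dups}")
        bad_g = set(df["group"]) - set(GROUPS)
        if bad_g:
            raise DataError(f"unknown group labels: {sorted(bad_g)}")
        bad_p = set(df["phase"]) - set(PHASES)
        if bad_p:
            raise DataError(f"unknown phase labels: {sorted(bad_p)}")
        self.df = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def select(self, group: str | None = None, phase: str | None = None) -> list[str]:
        """Sample ids matching the given group and/or phase (order preserved)."""
        mask = pd.Series(True, index=self.df.index)
        if group is not None:
            mask &= self.df["group"] == group
        if phase is not None:
            mask &= self.df["phase"] == phase
        out = self.df.loc[mask, "sample_id"].tolist()
        if not out:
            raise ConfigurationError(
                f"no samples match group={group!r} phase={phase!r}"
            )
        return out

    def condition_of(self, sample_id: str) -> tuple[str, str]:
        row = self.df[self.df["sample_id"] == sample_id]
        if row.empty:
            raise ConfigurationError(f"unknown sample {sample_id!r}")
        return row.iloc[0]["group"], row.iloc[0]["phase"]

    def __len__(self) -> int:
        return len(self.df)


class VoteTable:
    """Coding-potential calls: transcript x predictor -> {coding, noncoding}."""

    def __init__(self, df: pd.DataFrame):
        bad = set(df.values.ravel()) - set(VOTE_LABELS)
        if bad or df.isna().any().any():
            raise DataError(
                f"votes must all be one of {VOTE_LABELS}; offending values: {sorted(map(str, bad))}"
            )
        self.df = df

    @property
    def predictors(self) -> list[str]:
        return list(self.df.columns)

    def votes_for(self, transcript_id: str) -> dict[str, str]:
        if transcript_id not in self.df.index:
            raise DataError(f"no coding-potential votes for transcript {transcript_id!r}")
        return self.df.loc[transcript_id].to_dict()

    def noncoding_predictors(self, transcript_id: str) -> frozenset[str]:
        votes = self.votes_for(transcript_id)
        return frozenset(p for p, v in votes.items() if v == "noncoding")

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.df.index


@dataclass
class Term:
    term_id: str
    term_name: str
    genes: frozenset[str]


class TermAnnotation:
    """term_id -> (name, gene set), with a namespace tag (GO-like or pathway-like)."""

    def __init__(self, terms: list[Term], namespace: str = "pathway-like"):
        seen: dict[str, Term] = {}
        for t in terms:
            if t.term_id in seen:
                raise DataError(f"duplicate term id {t.term_id!r}")
            if not t.genes:
                raise DataError(f"term {t.term_id!r} has an empty gene set")
            seen[t.term_id] = t
        self.terms = seen
        self.namespace = namespace

    def __iter__(self):
        return iter(self.terms.values())

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> Term:
        return self.terms[term_id]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.terms.values():
            out |= t.genes
        return frozenset(out)


@dataclass
class TargetLink:
    """A (lncRNA, gene) regulatory edge, cis (genomic distance) or trans (correlation)."""

    lncrna_id: str
    gene_id: str
    mode: str  # "cis" | "trans"
    distance_bp: int | None = None
    r: float | None = None
    n_samples_used: int | None = None


@dataclass
class EnrichmentRecord:
    """Hypergeometric over-representation result for one term."""

    term_id: str
    term_name: str
    namespace: str
    N: int  # background size
    M: int  # background genes in term
    n: int  # query genes in background
    m: int  # query genes in term
    rich_factor: float
    pvalue: float
    qvalue: float = 1.0
    significant: bool = False
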