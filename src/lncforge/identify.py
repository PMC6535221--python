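"""Candidate lncRNA identification: the four-rule filter cascade.

A transcript is a candidate lncRNA iff it

1. is longer than 200 nt (mature length) with at least 2 exons,
2. has read coverage >= 5 in at least one sample,
3. carries class code ``u``, ``i`` or ``x`` (lincRNA / intronic / antisense
   relative to the reference annotation), and
4. is called noncoding by all coding-potential predictors (consensus
   intersection over, by default, CNCI / CPC / PFAM / CPAT votes).

The four rules are independent predicates, so the candidate set does not
depend on the order in which they are applied; the fixed cascade order only
determines which rule a rejected transcript is attributed to (the first one it
fails).  The report also tallies the per-predictor-subset Venn cells over the
transcripts reaching the consensus step.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .models import CLASS_CODE_SUBTYPE, TranscriptModel, VoteTable

RULE_ORDER = ("too_short", "too_few_exons", "low_coverage", "class_code",
              "coding_potential")


@dataclass
class FilterReport:
    """Per-transcript outcomes plus per-rule and Venn-cell tallies."""

    outcomes: dict[str, str] = field(default_factory=dict)  # tid -> "retained" | rule
    rule_counts: Counter = field(default_factory=Counter)
    venn: dict[frozenset, int] = field(default_factory=dict)  # noncoding-predictor subset -> count
    n_input: int = 0
    n_reaching_consensus: int = 0

    @property
    def n_retained(self) -> int:
        return sum(1 for v in self.outcomes.values() if v == "retained")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"transcript_id": list(self.outcomes),
             "outcome": list(self.outcomes.values())}
        )

    def venn_frame(self, predictors: list[str]) -> pd.DataFrame:
        rows = []
        for r in range(len(predictors) + 1):
            for subset in itertools.combinations(predictors, r):
                key = frozenset(subset)
                rows.append({"noncoding_predictors": "+".join(subset) or "(none)",
                             "count": self.venn.get(key, 0)})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# individual rules (each returns (retained, rejected-with-rule))
# ---------------------------------------------------------------------------

def filter_structure(transcripts: list[TranscriptModel], min_length: int = 200,
                     min_exons: int = 2):
    """Retain transcripts strictly longer than *min_length* nt with at least
    *min_exons* exons.  Length is the sum of exon widths."""
    retained, rejected = [], []
    for t in transcripts:
        if t.length() <= min_length:
            rejected.append((t, "too_short"))
        elif t.n_exons < min_exons:
            rejected.append((t, "too_few_exons"))
        else:
            retained.append(t)
    return retained, rejected


def filter_coverage(transcripts: list[TranscriptModel], min_cov: float = 5.0):
    """Remove transcripts whose coverage is below *min_cov* in EVERY sample."""
    retained, rejected = [], []
    for t in transcripts:
        if not t.coverage:
            raise DataError(f"{t.transcript_id}: empty coverage map")
        if all(v < min_cov for v in t.coverage.values()):
            rejected.append((t, "low_coverage"))
        else:
            retained.append(t)
    return retained, rejected


def filter_class_code(transcripts: list[TranscriptModel],
                      retained_codes: frozenset = frozenset("uix")):
    """Retain u/i/x transcripts and record the lncRNA subtype on them."""
    retained, rejected = [], []
    for t in transcripts:
        if t.class_code in retained_codes:
            t.subtype = CLASS_CODE_SUBTYPE.get(t.class_code)
            retained.append(t)
        else:
            rejected.append((t, "class_code"))
    return retained, rejected


def consensus_noncoding(transcripts: list[TranscriptModel], votes: VoteTable):
    """Candidates are transcripts every predictor calls noncoding.

    Returns ``(candidates, rejected, venn)`` where *venn* maps each subset of
    predictors to the number of transcripts exactly that subset called
    noncoding (16 cells for 4 predictors).
    """
    predictors = frozenset(votes.predictors)
    candidates, rejected = [], []
    venn: dict[frozenset, int] = {}
    for t in transcripts:
        nc = votes.noncoding_predictors(t.transcript_id)  # raises DataError if absent
        venn[nc] = venn.get(nc, 0) + 1
        if nc == predictors:
            t.biotype = "candidate_lncRNA"
            candidates.append(t)
        else:
            rejected.append((t, "coding_potential"))
    return candidates, rejected, venn


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def identify_lncrnas(transcripts: list[TranscriptModel], votes: VoteTable, *,
                     min_length: int = 200, min_exons: int = 2,
                     min_cov: float = 5.0,
                     retained_codes: frozenset = frozenset("uix")
                     ) -> tuple[list[TranscriptModel], FilterReport]:
    """Run the full cascade; every input transcript appears exactly once in
    the report, attributed to the first rule it fails (or retained)."""
    report = FilterReport(n_input=len(transcripts))
    surviving, rej1 = filter_structure(transcripts, min_length, min_exons)
    surviving, rej2 = filter_coverage(surviving, min_cov)
    surviving, rej3 = filter_class_code(surviving, retained_codes)
    report.n_reaching_consensus = len(surviving)
    candidates, rej4, venn = consensus_noncoding(surviving, votes)
    report.venn = venn

    for t, rule in itertools.chain(rej1, rej2, rej3, rej4):
        report.outcomes[t.transcript_id] = rule
        report.rule_counts[rule] += 1
        if t.class_code == "=" and rule == "class_code":
            t.biotype = "known_mRNA"
        else:
            t.biotype = "rejected"
    for t in candidates:
        report.outcomes[t.transcript_id] = "retained"
    return candidates, report


# ---------------------------------------------------------------------------
# descriptive characterization (exon counts, lengths, expression)
# ---------------------------------------------------------------------------

LENGTH_BINS = (0, 200, 400, 600, 800, 1000, 1500, 2000, 3000, 5000, np.inf)


def characterize(candidates: list[TranscriptModel], mrnas: list[TranscriptModel],
                 expr: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    """Summary tables comparing lncRNA candidates with known mRNAs:
    exon-count histogram, mature-length histogram and (when an expression
    matrix is supplied) per-class expression summaries."""
    tables: dict[str, pd.DataFrame] = {}
    rows = []
    for cls, ts in (("lncRNA", candidates), ("mRNA", mrnas)):
        counts = Counter(t.n_exons for t in ts)
        for n_ex in sorted(counts):
            rows.append({"class": cls, "n_exons": n_ex, "count": counts[n_ex]})
    tables["exon_hist"] = pd.DataFrame(rows, columns=["class", "n_exons", "count"])

    rows = []
    for cls, ts in (("lncRNA", candidates), ("mRNA", mrnas)):
        lengths = [t.length() for t in ts]
        if lengths:
            binned = pd.cut(lengths, LENGTH_BINS, right=True)
            for interval, n in binned.value_counts().sort_index().items():
                rows.append({"class": cls, "length_bin": str(interval), "count": int(n)})
    tables["length_hist"] = pd.DataFrame(rows, columns=["class", "length_bin", "count"])

    if expr is not None:
        rows = []
        for cls, ts in (("lncRNA", candidates), ("mRNA", mrnas)):
            ids = [t.transcript_id for t in ts if t.transcript_id in expr.index]
            if ids:
                vals = expr.loc[ids].values.ravel()
                rows.append({"class": cls, "n": len(ids),
                             "median_fpkm": float(np.median(vals)),
                             "mean_fpkm": float(np.mean(vals))})
        tables["expression"] = pd.DataFrame(
            rows, columns=["class", "n", "median_fpkm", "mean_fpkm"])
    return tables
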