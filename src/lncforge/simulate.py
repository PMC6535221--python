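"""Synthetic study generator with planted ground truth.

Emulates a 12-sample uterine RNA-seq design — 3 replicates x 2 prolificacy
groups (polytocous/monotocous) x 2 estrous phases (follicular/luteal) — as a
transcript annotation (GTF), a negative-binomial fragment-count matrix,
per-sample coverage, a 4-predictor coding-potential vote table and a GMT term
annotation.  Every downstream stage has a known answer:

* planted lncRNAs carry class codes u/i/x, >=2 exons and mature length >200 nt;
* each decoy violates exactly one identification rule, so filter attribution
  is testable;
* differential expression is planted as multiplicative fold changes on the
  polytocous samples of one phase;
* cis pairs are placed at an exact nearest-end genomic gap;
* trans pairs share a latent multiplicative factor calibrated so the expected
  expression correlation is at least the requested value.

All randomness derives from ``SimConfig.seed``; the same seed yields
byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError
from .models import (
    SampleSheet,
    Term,
    TermAnnotation,
    TranscriptModel,
    VoteTable,
)
from . import io as lio

PREDICTORS = ("CNCI", "CPC", "PFAM", "CPAT")

#: decoy rule ids, matching the identification module's attribution vocabulary
DECOY_RULES = ("too_short", "too_few_exons", "low_coverage", "class_code", "coding_potential")

REPRO_TERM_NAMES = (
    "ovarian steroidogenesis",
    "retinol metabolism",
    "oxytocin signaling pathway",
    "steroid hormone biosynthesis",
    "FoxO signaling pathway",
)
NEUTRAL_TERM_NAMES = (
    "ribosome biogenesis",
    "spliceosome assembly",
    "DNA replication",
    "oxidative phosphorylation",
    "lysosome",
)

_SQRT3 = math.sqrt(3.0)


@dataclass
class PlantedDE:
    feature_id: str  # transcript id
    phase: str
    log2_effect: float


@dataclass
class CisPair:
    lncrna_id: str  # transcript id
    gene_id: str    # mRNA gene id
    gap_bp: int


@dataclass
class TransPair:
    lncrna_id: str
    gene_id: str
    target_r: float


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 3 replicates per group x phase cell,
    NB dispersion 0.1 (variance mu + 0.1 mu^2), baseline means log2-uniform in
    [2^5, 2^9] fragments, and five decoys (one per identification rule).
    """

    seed: int = 0
    n_chroms: int = 3
    n_mrna: int = 60
    n_lncrna: int = 20
    n_decoys: int = 5
    samples_per_cell: int = 3
    nb_dispersion: float = 0.1
    baseline_mean_log2_range: tuple[float, float] = (5.0, 9.0)
    lncrna_mean_log2_offset: float = -1.5  # lncRNAs expressed below mRNAs
    chrom_length: int = 40_000_000
    spacing_bp: int = 60_000  # > cis window, so only planted pairs sit within 50 kb
    trans_latent_sd: float = 2.0  # sigma of the shared log-latent factor
    planted_de: list[PlantedDE] = field(default_factory=list)
    planted_cis_pairs: list[CisPair] = field(default_factory=list)
    planted_trans_pairs: list[TransPair] = field(default_factory=list)

    def validate(self) -> None:
        if self.samples_per_cell < 1:
            raise GenerationError("samples_per_cell must be >= 1")
        if self.nb_dispersion < 0:
            raise GenerationError("nb_dispersion must be >= 0")
        for p in self.planted_cis_pairs:
            if p.gap_bp > 50_000:
                raise GenerationError(
                    f"cis pair {p.lncrna_id}-{p.gene_id}: gap {p.gap_bp} > 50 kb window"
                )
        for p in self.planted_trans_pairs:
            if not 0 < p.target_r <= 1:
                raise GenerationError("trans target_r must be in (0, 1]")

    @classmethod
    def default(cls, seed: int = 0) -> "SimConfig":
        """The standard study: 20 lncRNAs, 60 mRNA genes, 5 decoys, planted
        DE / cis / trans structure in both phases."""
        de = []
        # follicular-phase effects: cis-pair members + extra DE-only features
        for fid, eff in [
            ("L01.t1", 2.0), ("L02.t1", 2.0), ("L03.t1", -2.0),
            ("L07.t1", 2.0), ("L08.t1", -2.0),
            ("G01.t1", 2.0), ("G02.t1", 2.0), ("G03.t1", -2.0),
            ("G04.t1", 2.0), ("G05.t1", -2.0), ("G06.t1", 2.0),
            ("G07.t1", 2.0), ("G08.t1", -2.0),
        ]:
            de.append(PlantedDE(fid, "follicular", eff))
        for fid, eff in [
            ("L11.t1", 2.0), ("L12.t1", 2.0), ("L13.t1", -2.0), ("L14.t1", -2.0),
            ("G11.t1", 2.0), ("G12.t1", -2.0), ("G13.t1", 2.0), ("G14.t1", -2.0),
        ]:
            de.append(PlantedDE(fid, "luteal", eff))
        cis = [
            # L01 is a planted hub with six cis targets
            CisPair("L01.t1", "G01", 5_000),
            CisPair("L01.t1", "G02", 12_000),
            CisPair("L01.t1", "G03", 20_000),
            CisPair("L01.t1", "G04", 28_000),
            CisPair("L01.t1", "G05", 36_000),
            CisPair("L01.t1", "G06", 44_000),
            CisPair("L02.t1", "G07", 39_000),
            CisPair("L03.t1", "G08", 50_000),  # inclusive window boundary
            CisPair("L11.t1", "G11", 15_000),
            CisPair("L12.t1", "G12", 25_000),
            CisPair("L13.t1", "G13", 10_000),
            CisPair("L14.t1", "G14", 30_000),
        ]
        trans = [
            TransPair("L04.t1", "G21", 0.95),
            TransPair("L05.t1", "G22", 0.95),
            TransPair("L06.t1", "G23", 0.95),
        ]
        return cls(seed=seed, planted_de=de, planted_cis_pairs=cis,
                   planted_trans_pairs=trans)


@dataclass
class GroundTruth:
    """What was planted: the answer key for every pipeline stage."""

    true_lncrna_ids: set[str] = field(default_factory=set)
    decoy_rules: dict[str, str] = field(default_factory=dict)  # transcript -> rule
    de_table: pd.DataFrame | None = None  # transcript_id, gene_id, phase, log2_effect, direction
    cis_table: pd.DataFrame | None = None  # lncrna_id, gene_id, gap_bp
    trans_table: pd.DataFrame | None = None  # lncrna_id, gene_id, target_r


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _rng(stage: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([stage, seed])


def _make_exons(rng, start: int, n_exons: int, widths: tuple[int, int],
                introns: tuple[int, int]) -> list[tuple[int, int]]:
    exons = []
    pos = start
    for i in range(n_exons):
        w = int(rng.integers(widths[0], widths[1] + 1))
        exons.append((pos, pos + w))
        pos += w + int(rng.integers(introns[0], introns[1] + 1))
    return exons


def _lnc_structure(rng, start: int) -> list[tuple[int, int]]:
    return _make_exons(rng, start, int(rng.integers(2, 4)), (150, 500), (200, 1500))


def _mrna_structure(rng, start: int) -> list[tuple[int, int]]:
    return _make_exons(rng, start, int(rng.integers(4, 9)), (120, 300), (300, 2000))


def simulate_annotation(cfg: SimConfig) -> tuple[list[TranscriptModel], GroundTruth]:
    """Generate the transcript annotation with planted lncRNAs, decoys and
    exact-gap cis pairs.  Raises :class:`GenerationError` if a chromosome is
    too short for the requested layout."""
    cfg.validate()
    rng = _rng(1, cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    cursors = {c: 10_000 for c in chroms}
    truth = GroundTruth()

    lnc_ids = [f"L{i + 1:02d}" for i in range(cfg.n_lncrna)]
    gene_ids = [f"G{i + 1:02d}" for i in range(cfg.n_mrna)]
    cis_by_lnc: dict[str, list[CisPair]] = {}
    for p in cfg.planted_cis_pairs:
        cis_by_lnc.setdefault(p.lncrna_id, []).append(p)

    transcripts: dict[str, TranscriptModel] = {}

    def _place(chrom: str, builder, tid: str, gid: str, class_code: str,
               exons: list[tuple[int, int]] | None = None) -> TranscriptModel:
        start = cursors[chrom]
        ex = exons if exons is not None else builder(rng, start)
        if ex[-1][1] > cfg.chrom_length:
            raise GenerationError(
                f"{chrom} too short ({cfg.chrom_length} bp) for requested layout"
            )
        t = TranscriptModel(tid, gid, chrom, "+" if rng.random() < 0.5 else "-",
                            ex, class_code)
        cursors[chrom] = ex[-1][1] + cfg.spacing_bp
        transcripts[tid] = t
        return t

    lnc_codes = ["u", "i", "x"]
    chrom_cycle = 0

    # 1. cis clusters: each planted-hub lncRNA with its genes at exact gaps
    cis_rows = []
    for li, lnc_tid in enumerate(sorted(cis_by_lnc)):
        chrom = chroms[chrom_cycle % len(chroms)]
        chrom_cycle += 1
        gid = lnc_tid.split(".")[0]
        code = lnc_codes[li % 3]
        # leave room upstream for left-side cis genes (window + gene length)
        cursors[chrom] += 120_000
        lnc = _place(chrom, _lnc_structure, lnc_tid, gid, code)
        right_cursor = lnc.end
        left_cursor = lnc.start
        extent_lo, extent_hi = lnc.start, lnc.end
        for k, pair in enumerate(sorted(cis_by_lnc[lnc_tid], key=lambda p: p.gap_bp)):
            gex = _mrna_structure(rng, 0)
            g_len = gex[-1][1]
            if k % 2 == 0:
                g_start = lnc.end + pair.gap_bp
                if g_start < right_cursor:
                    raise GenerationError(
                        f"cis gaps for {lnc_tid} overlap on the right side"
                    )
                exons = [(s + g_start, e + g_start) for s, e in gex]
                right_cursor = exons[-1][1]
            else:
                g_end = lnc.start - pair.gap_bp
                g_start = g_end - g_len
                if g_start < 0 or g_end > left_cursor:
                    raise GenerationError(
                        f"cis gaps for {lnc_tid} overlap on the left side"
                    )
                exons = [(s + g_start, e + g_start) for s, e in gex]
                left_cursor = exons[0][0]
            gene_tid = f"{pair.gene_id}.t1"
            t = TranscriptModel(gene_tid, pair.gene_id, chrom, "+", exons, "=")
            transcripts[gene_tid] = t
            extent_lo = min(extent_lo, exons[0][0])
            extent_hi = max(extent_hi, exons[-1][1])
            cis_rows.append({"lncrna_id": lnc_tid, "gene_id": pair.gene_id,
                             "gap_bp": pair.gap_bp})
        if extent_hi > cfg.chrom_length:
            raise GenerationError(f"{chrom} too short for cis cluster of {lnc_tid}")
        cursors[chrom] = extent_hi + cfg.spacing_bp

    # 2. remaining lncRNAs
    for i, gid in enumerate(lnc_ids):
        tid = f"{gid}.t1"
        if tid in transcripts:
            continue
        chrom = chroms[chrom_cycle % len(chroms)]
        chrom_cycle += 1
        _place(chrom, _lnc_structure, tid, gid, lnc_codes[i % 3])
    truth.true_lncrna_ids = {f"{g}.t1" for g in lnc_ids}

    # 3. remaining mRNA genes
    for gid in gene_ids:
        tid = f"{gid}.t1"
        if tid in transcripts:
            continue
        chrom = chroms[chrom_cycle % len(chroms)]
        chrom_cycle += 1
        _place(chrom, _mrna_structure, tid, gid, "=")

    # 4. decoys, each violating exactly one rule
    for i in range(cfg.n_decoys):
        rule = DECOY_RULES[i % len(DECOY_RULES)]
        gid = f"D{i + 1:02d}"
        tid = f"{gid}.t1"
        chrom = chroms[chrom_cycle % len(chroms)]
        chrom_cycle += 1
        start = cursors[chrom]
        if rule == "too_short":
            exons = [(start, start + 80), (start + 400, start + 490)]  # length 170
            _place(chrom, None, tid, gid, "u", exons=exons)
        elif rule == "too_few_exons":
            exons = [(start, start + 800)]
            _place(chrom, None, tid, gid, "u", exons=exons)
        elif rule == "class_code":
            _place(chrom, _lnc_structure, tid, gid, "j")
        else:  # low_coverage / coding_potential: structurally valid lncRNA
            _place(chrom, _lnc_structure, tid, gid, "u")
        truth.decoy_rules[tid] = rule

    ordered = [transcripts[tid] for tid in sorted(transcripts)]
    for t in ordered:
        t.validate()

    # coverage: everything comfortably expressed except the low-coverage decoy
    sheet = design_sheet(cfg)
    cov_rng = _rng(5, cfg.seed)
    for t in ordered:
        rule = truth.decoy_rules.get(t.transcript_id)
        if rule == "low_coverage":
            t.coverage = {s: float(cov_rng.uniform(0.5, 4.5))
                          for s in sheet.sample_ids}
        else:
            t.coverage = {s: float(cov_rng.uniform(6.0, 60.0))
                          for s in sheet.sample_ids}

    # ground-truth tables
    de_rows = []
    for p in cfg.planted_de:
        if p.feature_id not in transcripts:
            raise GenerationError(f"planted DE feature {p.feature_id!r} not generated")
        de_rows.append({
            "transcript_id": p.feature_id,
            "gene_id": transcripts[p.feature_id].gene_id,
            "phase": p.phase,
            "log2_effect": p.log2_effect,
            "direction": "up" if p.log2_effect > 0 else "down",
        })
    truth.de_table = pd.DataFrame(
        de_rows, columns=["transcript_id", "gene_id", "phase", "log2_effect", "direction"])
    truth.cis_table = pd.DataFrame(cis_rows, columns=["lncrna_id", "gene_id", "gap_bp"])
    trans_rows = []
    for p in cfg.planted_trans_pairs:
        for fid in (p.lncrna_id, f"{p.gene_id}.t1"):
            if fid not in transcripts:
                raise GenerationError(f"planted trans feature {fid!r} not generated")
        trans_rows.append({"lncrna_id": p.lncrna_id, "gene_id": p.gene_id,
                           "target_r": p.target_r})
    truth.trans_table = pd.DataFrame(
        trans_rows, columns=["lncrna_id", "gene_id", "target_r"])
    return ordered, truth


def design_sheet(cfg: SimConfig) -> SampleSheet:
    """The 2-group x 2-phase sample sheet (PF/MF/PL/ML naming)."""
    rows = []
    for phase, pcode in (("follicular", "F"), ("luteal", "L")):
        for group, gcode in (("polytocous", "P"), ("monotocous", "M")):
            for r in range(cfg.samples_per_cell):
                rows.append({"sample_id": f"{gcode}{pcode}{r + 1}",
                             "group": group, "phase": phase})
    return SampleSheet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _latent_factor(rng, sigma: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean-one multiplicative latent factor exp(sigma*z), z ~ U(-sqrt3, sqrt3)."""
    z = rng.uniform(-_SQRT3, _SQRT3, size=n)
    c = math.sinh(sigma * _SQRT3) / (sigma * _SQRT3)  # E[exp(sigma z)]
    return np.exp(sigma * z) / c, z


def _calibrate_rho(target_r: float, sigma: float, alpha: float,
                   mean_lnc: np.ndarray, mean_gene: np.ndarray) -> float:
    """Latent correlation needed so the expected log-expression Pearson r
    meets the target, by a delta-method attenuation correction.

    Log-scale noise variance per feature ~ alpha + E[1/mean]; the latent
    signal variance is sigma^2.  Calibrates to target + 0.4*(1-target) so the
    expected correlation sits above (not at) the requested threshold.
    """
    c = math.sinh(sigma * _SQRT3) / (sigma * _SQRT3)
    e_inv_latent = c * c  # E[1/f] for the mean-one factor
    nu_l = alpha + float(np.mean(e_inv_latent / mean_lnc))
    nu_g = alpha + float(np.mean(e_inv_latent / mean_gene))
    lam = sigma**2 / math.sqrt((sigma**2 + nu_l) * (sigma**2 + nu_g))
    rho_cal = target_r + 0.4 * (1.0 - target_r)
    return min(1.0, rho_cal / lam)


def simulate_counts(cfg: SimConfig, transcripts: list[TranscriptModel],
                    sheet: SampleSheet | None = None) -> pd.DataFrame:
    """NB fragment counts: k_ij ~ NB(mean = s_j * q_i * 2^effect * latent,
    dispersion = cfg.nb_dispersion)."""
    cfg.validate()
    rng = _rng(2, cfg.seed)
    if sheet is None:
        sheet = design_sheet(cfg)
    samples = sheet.sample_ids
    tids = [t.transcript_id for t in transcripts]
    n_feat, n_samp = len(tids), len(samples)
    lo, hi = cfg.baseline_mean_log2_range

    q = 2.0 ** rng.uniform(lo, hi, size=n_feat)
    # lncRNA-like transcripts (u/i/x) are expressed below coding genes
    is_lnc = np.array([t.class_code in ("u", "i", "x") for t in transcripts])
    q[is_lnc] *= 2.0 ** cfg.lncrna_mean_log2_offset
    # trans-pair members sit at the top of the mean range: the correlation
    # signal must dominate shot noise (see docs/methods.md)
    trans_members = {p.lncrna_id for p in cfg.planted_trans_pairs}
    trans_members |= {f"{p.gene_id}.t1" for p in cfg.planted_trans_pairs}
    idx = {tid: i for i, tid in enumerate(tids)}
    for tid in sorted(trans_members):
        if tid in idx:
            q[idx[tid]] = 2.0 ** hi

    s = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_samp))

    effect = np.ones((n_feat, n_samp))
    for p in cfg.planted_de:
        if p.feature_id not in idx:
            raise GenerationError(f"planted DE feature {p.feature_id!r} unknown")
        cols = [j for j, sm in enumerate(samples)
                if sheet.condition_of(sm) == ("polytocous", p.phase)]
        effect[idx[p.feature_id], cols] = 2.0 ** p.log2_effect

    latent = np.ones((n_feat, n_samp))
    sigma = cfg.trans_latent_sd
    for p in cfg.planted_trans_pairs:
        li = idx[p.lncrna_id]
        gi = idx[f"{p.gene_id}.t1"]
        m0_l = s * q[li]
        m0_g = s * q[gi]
        rho = _calibrate_rho(p.target_r, sigma, cfg.nb_dispersion, m0_l, m0_g)
        f_l, z = _latent_factor(rng, sigma, n_samp)
        w = rng.uniform(-_SQRT3, _SQRT3, size=n_samp)
        u = rho * z + math.sqrt(max(0.0, 1.0 - rho**2)) * w
        c = math.sinh(sigma * _SQRT3) / (sigma * _SQRT3)
        latent[li] = f_l
        latent[gi] = np.exp(sigma * u) / c

    mean = q[:, None] * s[None, :] * effect * latent
    alpha = cfg.nb_dispersion
    if alpha == 0:
        counts = rng.poisson(mean)
    else:
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mean)
        counts = rng.negative_binomial(n_param, p_param)
    return pd.DataFrame(counts, index=pd.Index(tids, name="feature_id"),
                        columns=samples)


# ---------------------------------------------------------------------------
# votes and terms
# ---------------------------------------------------------------------------

def simulate_votes(cfg: SimConfig, transcripts: list[TranscriptModel],
                   truth: GroundTruth) -> VoteTable:
    """True lncRNAs get 4/4 noncoding votes; the coding-potential decoy gets
    exactly one coding vote; known mRNAs vote coding everywhere."""
    rows = {}
    for t in transcripts:
        tid = t.transcript_id
        rule = truth.decoy_rules.get(tid)
        if t.class_code == "=" and rule is None:
            rows[tid] = {p: "coding" for p in PREDICTORS}
        elif rule == "coding_potential":
            rows[tid] = {p: ("coding" if p == "CPC" else "noncoding")
                         for p in PREDICTORS}
        else:
            rows[tid] = {p: "noncoding" for p in PREDICTORS}
    df = pd.DataFrame.from_dict(rows, orient="index").loc[
        [t.transcript_id for t in transcripts], list(PREDICTORS)]
    return VoteTable(df)


def simulate_terms(cfg: SimConfig, transcripts: list[TranscriptModel],
                   truth: GroundTruth) -> TermAnnotation:
    """Reproduction-named terms hold the planted per-phase target/DE genes
    (so each phase's enrichment has a strongly stacked term); neutral terms
    hold random other genes."""
    rng = _rng(4, cfg.seed)
    mrna_genes = sorted({t.gene_id for t in transcripts
                         if t.class_code == "=" and
                         t.transcript_id not in truth.decoy_rules})
    mrna_set = set(mrna_genes)

    # per-phase relevant genes: targets of that phase's DE lncRNAs + DE genes
    de = truth.de_table if truth.de_table is not None else pd.DataFrame(
        columns=["transcript_id", "gene_id", "phase"])
    pools: dict[str, set[str]] = {}
    for phase in ("follicular", "luteal"):
        de_phase = de[de["phase"] == phase]
        de_lnc = set(de_phase["transcript_id"]) - {f"{g}.t1" for g in mrna_set}
        pool = {g for g in de_phase["gene_id"] if g in mrna_set}
        for table in (truth.cis_table, truth.trans_table):
            if table is not None:
                pool |= {r.gene_id for r in table.itertuples()
                         if r.lncrna_id in de_lnc and r.gene_id in mrna_set}
        pools[phase] = pool

    planted = pools["follicular"] | pools["luteal"]
    others = [g for g in mrna_genes if g not in planted]

    terms = []
    phase_cycle = ("follicular", "luteal")
    for i, name in enumerate(REPRO_TERM_NAMES):
        pool = pools[phase_cycle[i % 2]]
        pad = list(rng.choice(others, size=min(2, len(others)), replace=False))
        genes = frozenset(sorted(pool) + pad)
        if not genes:
            continue
        terms.append(Term(f"path{i + 1:03d}", name, genes))
    for j, name in enumerate(NEUTRAL_TERM_NAMES):
        genes = frozenset(rng.choice(others, size=min(8, len(others)), replace=False))
        if genes:
            terms.append(Term(f"path{len(REPRO_TERM_NAMES) + j + 1:03d}", name, genes))
    return TermAnnotation(terms, namespace="pathway-like")


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------

@dataclass
class SimStudy:
    config: SimConfig
    transcripts: list[TranscriptModel]
    truth: GroundTruth
    sheet: SampleSheet
    counts: pd.DataFrame
    votes: VoteTable
    terms: TermAnnotation


def simulate_study(cfg: SimConfig) -> SimStudy:
    """Generate annotation, coverage, counts, votes and terms in one pass."""
    transcripts, truth = simulate_annotation(cfg)
    sheet = design_sheet(cfg)
    counts = simulate_counts(cfg, transcripts, sheet)
    votes = simulate_votes(cfg, transcripts, truth)
    terms = simulate_terms(cfg, transcripts, truth)
    return SimStudy(cfg, transcripts, truth, sheet, counts, votes, terms)


def write_study(study: SimStudy, outdir) -> dict[str, Path]:
    """Write all study inputs + the ground-truth answer key to *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.gtf",
        "coverage": outdir / "coverage.tsv",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "votes": outdir / "votes.tsv",
        "terms": outdir / "terms.gmt",
        "truth": outdir / "ground_truth.json",
    }
    lio.write_gtf(study.transcripts, paths["annotation"])
    lio.write_coverage(study.transcripts, paths["coverage"])
    lio.write_counts(study.counts, paths["counts"])
    lio.write_sample_sheet(study.sheet, paths["samples"])
    lio.write_votes(study.votes, paths["votes"])
    lio.write_gmt(study.terms, paths["terms"])
    truth = study.truth
    payload = {
        "true_lncrna_ids": sorted(truth.true_lncrna_ids),
        "decoy_rules": dict(sorted(truth.decoy_rules.items())),
        "de_table": truth.de_table.to_dict(orient="records"),
        "cis_table": truth.cis_table.to_dict(orient="records"),
        "trans_table": truth.trans_table.to_dict(orient="records"),
    }
    paths["truth"].write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return paths
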