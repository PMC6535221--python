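# Methods

This note documents the statistical models, conventions and design choices
behind lncforge, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinates and data model

All genomic intervals are 0-based half-open internally; GTF I/O converts at
the boundary (GTF exon `start=101 end=200` ↔ interval `[100, 200)`, width
100). A transcript's *length* is the sum of its exon widths (mature length),
the standard convention for the >200 nt lncRNA definition — not the genomic
span. Unknown gffcompare class codes are preserved verbatim; they simply fail
the u/i/x retention rule rather than raising an error, since gffcompare emits
about a dozen codes and only three denote lncRNA-compatible loci.

## Candidate lncRNA identification

Four independent predicates: (1) length > 200 nt **and** ≥ 2 exons,
(2) coverage ≥ 5× in at least one sample (a transcript is removed only when it
is below 5 in *every* sample), (3) class code ∈ {u, i, x} (recorded subtype
lincRNA / intronic / antisense), (4) unanimous noncoding votes from all
configured coding-potential predictors. Because the rules are independent,
the candidate set does not depend on application order; the fixed cascade
order (structure → coverage → class code → coding potential) only determines
which rule a rejection is *attributed* to (first failure). The exon rule is
read as ≥ 2 because two-exon lncRNAs are the dominant class in this kind of
data; `min_exons` is a parameter, so the strict "> 2" reading is one flag
away. Whether coverage filtering should precede or follow class-code
screening is immaterial to the final set (tested as a permutation property).

## FPKM

FPKM(i,j) = 10⁹ · k_ij / (N_j · L_i). By default N_j is the column sum of
the supplied count matrix (assigned-fragment convention); a library-wide
mapped-read total can be supplied via `totals`. lncRNAs are quantified at
transcript level; mRNAs at gene level with counts summed over isoforms and
length = the longest isoform. FPKM is invariant to jointly scaling one
sample's counts and total, and monotone in counts at fixed N and L.

## Differential expression

The test is the classic exact conditional NB test of the DESeq lineage,
self-contained:

* **Size factors** — median-of-ratios: s_j = median over features (restricted
  to features positive in every sample) of k_ij / (Π_v k_iv)^(1/m). Size
  factors carry an overall scale freedom: scaling one sample's counts by c
  multiplies its size factor by exactly c *relative to the others* (a common
  factor c^(1/m) moves all of them). Normalized counts and fold changes are
  therefore exactly invariant to per-sample scaling.
* **Dispersion** — per-feature method of moments on normalized counts,
  pooled across the two conditions: α̂ = max(0, (v̂ − μ̂·mean(1/s)) / μ̂²),
  where v̂ pools within-condition sample variances and the μ̂·mean(1/s) term
  removes counting (shot) noise; floored at 10⁻⁸. This estimator is
  consistent (it recovers α = 0.1 within a few percent at 100 replicates) but
  extremely noisy at n = 3, where it is zero by chance for roughly half the
  features; plugging it straight into the test inflates type-I error about
  two-fold. The default therefore applies **maximum sharing**: a parametric
  trend α(μ) = a₀ + a₁/μ is fit across features by trimmed least squares
  (features more than 3 robust SDs above the curve are dropped and the curve
  refit, so a handful of genuinely hyper-variable features — e.g. features
  driven by a shared latent factor — cannot inflate the trend for everything
  else), and each feature uses max(per-feature MoM, trend). Measured on a
  2,000-feature null simulation (α = 0.1, 3 vs 3) this brings empirical
  Pr(p < 0.05) to ≈ 0.03, at or below nominal, while sensitivity for 4×
  effects at n = 3 stays ≥ 0.9. `sharing="per_gene"` disables it.
* **Exact test** — conditioning on the total count of a feature over both
  groups, the two group sums are modelled as NB with means M_A = q̂·Σ_{j∈A}
  s_j (q̂ the pooled normalized mean) and variances V_A = M_A + α̂ q̂² Σ_{j∈A}
  s_j² (the sum of the per-sample NB variances, re-parameterised to an NB for
  the sum; Poisson when V ≤ M). The two-sided p-value is the total
  conditional probability of all splits at most as likely as the observed
  one. Note a property of all conditional exact tests: because the test
  conditions on *raw* totals, individual p-values are only approximately
  invariant to rescaling one sample's counts (DE calls are ≈ 97% concordant
  in simulation), even though all normalized quantities are exactly
  invariant.
* **Calls** — fold change = mean normalized B / mean normalized A (polytocous
  over monotocous), reported as +inf with a flag when group A is all zero and
  as 1 with a flag (p = 1) when both groups are all zero. The rule "fold
  change > 1.5 and p < 0.05" is applied symmetrically (up: FC > 1.5; down:
  FC < 1/1.5). Raw p is the default gate — BH-adjusted values are always
  reported alongside and `use="padj"` switches the gate to FDR < 0.05. BH is
  applied within each feature class (lncRNA / mRNA) and comparison
  separately.

## Target prediction

*Cis*: same chromosome and nearest-end gap ≤ 50,000 bp (inclusive boundary;
overlap = distance 0), strand-ignored since the window is symmetric upstream
and downstream; anchored at transcript boundaries. Implemented as a
sorted-start sweep with a searchsorted cut, and verified set-equal to the
O(n·m) all-pairs scan on random fixtures (a permanent property test —
the two code paths are kept independent).

*Trans*: Pearson r ≥ 0.9 (signed by default; `absolute=True` available)
computed on log2(FPKM+1), which stabilises Pearson on skewed expression; raw
FPKM mode available. Constant vectors have undefined correlation and yield no
link. Within the pipeline the correlation uses the samples of the phase under
comparison (six); a 12-sample mode is a matter of passing the full matrices.

## Enrichment

Upper-tail hypergeometric p = Σ_{i≥m} C(M,i)·C(N−M,n−i)/C(N,n) per term,
with N the background, M the term's background genes, n the query in
background, m the overlap; rich factor = m/M. The background defaults to the
expressed gene set (genes with nonzero FPKM somewhere), not the whole
annotation, to avoid inflating significance. BH Q-values are computed within
a namespace; the significance flag uses the raw p ≤ 0.05 rule with Q reported
alongside. The same plain hypergeometric test serves GO-like and
pathway-like namespaces — no transcript-length-bias (Wallenius) correction is
applied, a deliberate scope decision documented here prominently.

## Network

Genes are retained when annotated to a significant term whose name matches a
keyword (case-insensitive substring; regex optional; defaults cover steroid /
oxytocin / retinol / FoxO / estrogen / prolactin / reproduction). Nodes are
DE lncRNAs with ≥ 1 retained link plus the retained target genes; a gene that
is retained but not itself DE carries direction "ns". Duplicate (lncRNA,
gene) links merge into one edge with mode "cis+trans". Exports (SIF, GraphML,
TSV) insert nodes and edges in sorted order so identical inputs give
byte-identical files.

## Synthetic-study generator

The generator emulates the 12-sample design: 3 replicates × {polytocous,
monotocous} × {follicular, luteal}. Defaults: 20 lncRNAs, 60 mRNA genes,
5 decoys, NB dispersion α = 0.1, baseline means log2-uniform on [2⁵, 2⁹]
fragments with lncRNAs offset −1.5 log2 (lncRNAs are expressed below coding
genes, as observed in uterine RNA-seq), sample size factors log-uniform on
[0.5, 2], coverage uniform on [6, 60]× (the low-coverage decoy on
[0.5, 4.5]×). Counts are k_ij ~ NB(mean = s_j · q_i · 2^effect · latent,
dispersion α).

* **Decoys** violate exactly one identification rule each (length ≤ 200 nt;
  single exon; coverage < 5 everywhere; class code outside u/i/x; one coding
  vote), so rule attribution is testable.
* **DE effects** multiply the polytocous samples of one phase by 2^effect
  (default planted effects ±2 log2). Effects are planted on the cis-pair
  members (both the lncRNA and its gene) so the downstream network is
  non-degenerate.
* **Cis pairs** are placed at an exact nearest-end gap on a shared
  chromosome, alternating sides of the lncRNA; all other features are spaced
  > 50 kb apart so the planted pairs are precisely the in-window pairs.
  Infeasible layouts (chromosome too short, overlapping gap requests) raise a
  generation error.
* **Trans pairs** share a latent multiplicative factor exp(σz) with z uniform
  on [−√3, √3] (unit variance, bounded tails — a Gaussian latent's heavy left
  tail pushes counts into the shot-noise regime where the target correlation
  is unreachable at realistic means) and σ = 2 by default. The latent
  correlation ρ′ between the pair is calibrated by a delta-method attenuation
  correction — log-scale noise variance ≈ α + E[1/mean] per feature — so the
  *expected* expression correlation is at least the requested target
  (calibrated to target + 0.4·(1 − target), i.e. above the threshold, since
  the sample correlation over 12 samples is itself noisy). Trans-pair
  members are assigned baseline means at the top of the configured range for
  the same signal-to-noise reason. Measured recovery of r = 0.95 pairs at
  the 0.9 threshold is ≈ 90% over 100 seeds.
* **Terms**: reproduction-named terms hold each phase's planted target/DE
  genes (plus small random padding); neutral terms hold random other genes.
* **Determinism**: every stage derives its RNG from (stage constant, seed);
  a fixed seed reproduces all output files byte for byte.

## What the synthetic tests do and do not show

The generator matches the DE test's own model (NB with mean–dispersion
parameterisation), so parameter-recovery and error-calibration results are
statements about correct implementation, not about robustness to model
misspecification. Real data features the generator does not emulate: multiple
isoforms per gene, batch effects, correlated features beyond the planted
pairs, length-dependent detection bias (relevant to the enrichment stage),
GC/mappability effects, and outlier samples. Power numbers at n = 3 transfer
only to features with comparable means and dispersions.

## Problem sizes

Default analyses run on the 85-transcript, 12-sample study in ~2 s. The
calibration studies use 2,000-feature null/power simulations, 500-feature
dispersion recovery at 100 replicates per group, 100 random fixtures for the
cis oracle and 100 seeds for trans recovery — sizes chosen so the whole suite
completes in well under a minute while keeping Monte-Carlo error small
relative to the margins asserted.

## Known limitations

* The exact NB test is conservative for very low counts (discreteness), like
  all conditional exact tests.
* The trend-stabilised dispersion can over-dampen a feature whose true
  dispersion sits far below the trend; this costs power only, never type-I
  control.
* Fold changes use no pseudocount; zero-in-one-group features are reported
  with sentinel values and flags rather than smoothed estimates.
* GMT terms are flat gene sets; no GO DAG propagation.
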