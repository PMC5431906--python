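# Methods

This note documents the models implemented in `cgsplice`, the defaults that
matter, what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Coordinates and junctions

Internal coordinates are 0-based half-open; GTF I/O converts to and from the
format's 1-based inclusive convention and the conversion is round-trip
exact. A splice junction is stored as its intron interval `(start, end)`;
"donor" and "acceptor" are the strand-aware 5′ and 3′ ends of that interval.
Gene-level computations that need a single reference transcript (region
labels, exon-skip counts, CG motif regions) use the gene's longest
transcript, with ties broken by transcript id, so results are deterministic
and reproducible from the annotation alone.

## PSI estimation and the Bayes factor

PSI is estimated from junction-spanning reads only: reads supporting the
inclusion isoform's discriminating junctions versus reads supporting the
exclusion isoform's. Because both isoforms of an event are measured at
junctions, isoform lengths cancel and no read-generative model is needed;
with a uniform prior the posterior is Beta(k_inc+1, k_exc+1), reported with
its central 95% credible interval. This is a deliberate simplification of
full generative PSI estimators (no read-length or insert-size corrections);
its calibration is verified directly (mean absolute error ≈ 0.02 and
coverage ≈ 0.95 at ~200 reads/event in the acceptance benchmarks).

Differential splicing is scored with an analytic Bayes factor comparing the
two-ψ model to the shared-ψ model, both under uniform priors. The binomial
coefficients cancel, leaving a ratio of beta functions evaluated with
`betaln`, so the statistic is exact at any count and symmetric under sample
swap. The retention filter is the complement of the study's removal rule:
keep iff BF ≥ 20, |∆ψ| ≥ 0.1, both isoforms have > 0 reads, and each
isoform has ≥ 10 reads in the comparison. The last clause is ambiguous in
prose ("fewer than 10 reads supporting either isoform"); we read it
per-isoform, and `per_isoform=False` switches to the total-count reading.

CG events are quantified with the same machinery. The inclusion (conjoined)
isoform is the junction-adjacent exon of each partner plus any detected
intergenic exons; the exclusion (wild-type) isoform is the donor-adjacent
exon plus up to one following exon of the upstream partner. Retained/
detained introns use the generic exon–intron–exon versus spliced exon–exon
pair.

## CG detection

A CG call requires a junction whose donor lies in one gene and acceptor in
a distinct downstream gene, co-oriented on one chromosome, with neither
gene's span contained in the other's (the encapsulation rule excludes e.g.
intronic miRNAs). Filters mirror a fusion-caller configuration:

- partner expression ≥ 50 reads each, measured as junction reads fully
  assigned to the gene, pooled across the samples of the comparison;
- splice score = 4: donor on an annotated exon 3′ boundary (+1), acceptor
  on an annotated 5′ boundary (+1), intervening sequence starting GT (+1)
  and ending AG (+1), strand-aware;
- exon-boundary flag set (the two boundary points);
- confidence ≥ 0.9. The original caller's learned classifier probability
  has no training corpus here; it is replaced by the transparent rule
  `confidence = (splice_score/4) · min(1, split_reads/5)`, which is 1.0 for
  a canonical boundary junction with ≥ 5 split reads and degrades
  proportionally otherwise.

Exon-skip counts are taken against each partner's longest transcript; the
modal read-through pattern (donor at the second-to-last exon, acceptor at
the second exon) is encoded (1, 1), and a donor at the last exon with an
acceptor at the first is (0, 0). The interrupted index is mean coverage of
the CG-retained portion over the CG-removed portion of a participant
(infinite, flagged, when the removed portion has zero coverage); the
splicing index is wild-type junction-spanning read pairs per CG-supporting
junction read. Events sharing an ordered partner pair collapse to one CG
with an isoform count, since donor/acceptor variation reflects isoforms of
the same conjoined pair.

## Long-read validation

Reads are junction chains with alignment attributes; filtering keeps
aligned proportion ≥ 0.90 and identity ≥ 0.80 (inclusive). A read maps to a
gene when ≥ 3 of its junctions exactly equal the gene's annotated
junctions; reads mapping to exactly two co-oriented, non-encapsulated genes
nominate CG candidates. Validation of a short-read call counts reads
containing a junction exactly equal to the call's donor/acceptor pair. The
phrase "consecutive read exon junctions matching the reported junction
coordinates" admits a looser reading; we implement the strictest one — an
exact coordinate pair, no tolerance — and expose `tolerance_bp` (default 0)
for relaxation. Under this rule a uniform 2-bp jitter must, and does,
reduce validation to zero.

## Dose-response clustering

Profiles (rows over an ordered dose grid, here 0–10 µM in seven steps) are
row-standardized; rows with more than two missing values, or two
consecutive missing values, are dropped and remaining gaps filled by linear
interpolation (edge gaps take the nearest value). The network is signed:
a_ij = ((1+cor_ij)/2)^β, so perfect correlation gives adjacency 1 and
perfect anticorrelation 0. β is chosen over 1–30 by the scale-free topology
fit R² of the binned connectivity distribution: the smallest β whose R²
exceeds 0.8 once the curve's per-step gain drops below 0.01; when the fit
never reaches 0.8 — the expected outcome for a design with a few large
co-response blocks, which is not scale-free — a power above 20 is used (the
first plateau past 20), matching standard guidance for such matrices.

Similarity is the unsigned topological overlap of the signed adjacency;
modules come from average-linkage clustering of 1 − TOM with a static cut
at height 0.99 and a minimum module size of 25. A static cut replaces the
dynamic hybrid tree cut deliberately: it is deterministic, dependency-free,
and adequate for block-structured dose profiles. Modules whose eigen-events
correlate above 0.8 (dissimilarity < 0.2, the common default for module
merging) are merged. The eigen-event is the first right singular vector of
the module's standardized profiles, oriented to correlate positively with
the member average and scaled to unit variance. Members correlating < 0.75
with their module's eigen-event are unassigned; the eigen-event is
re-estimated and the rule re-applied until the membership is stable, so the
published 0.75 rule holds as a hard invariant of the output. Whole modules
falling below the minimum size after filtering are dissolved.

Event-type composition per cluster is tested with a one-tailed
hypergeometric over-representation test, BH-adjusted across types ×
clusters. Cross-dataset concordance uses Huber robust regression slopes
(statsmodels RLM, Huber's T with tuning constant 1.345, MAD scale, IRLS) of
each profile against the dose *rank* (0..k−1) — the 0 µM dose rules out log
scaling, and only the slope sign enters the concordance statistic, which
any monotone re-axis preserves. The test statistic is the proportion of
paired events with equal slope sign (exact zeros excluded from the
denominator; all-tie input is an error); the null permutes the event labels
of one slope vector m times (default 10,000) and p = (b+1)/(m+1), where b
counts shuffles reaching the observed proportion. On ≤ 7 events the
function accepts the exhaustive permutation set and reproduces the
enumerated p exactly. The null-calibration benchmark draws independent
slope vectors of length 2000 — the scale at which shared ∆AS event sets
actually occur — because the proportion statistic is discrete and its
tie-inclusive p is visibly conservative for short vectors (an intrinsic
property of the estimator, not an implementation artifact).

## Motif enrichment and 3′-end signals

A PWM match is a window whose Σ log₂(p_base/bg_base) reaches 80% of the
PWM's maximum achievable score under the same background; scanning is
sense-strand only (RBP motifs act on the transcript), T ≡ U, and windows
containing ambiguous bases never match. Background base frequencies are
estimated from the pooled scanned sequence set, keeping the analysis
self-contained. Motif density is d = m/l.

The seven skipped-exon regions are the upstream constitutive exon, two
upstream-intron halves, the SE, two downstream-intron halves, and the
downstream exon, in transcript orientation. Each flanking intron
contributes at most 600 bp: introns up to the cap are split at the
midpoint; longer introns contribute 300 bp adjacent to each splice site.
(The cap's prose is ambiguous between per-intron and per-half; per-intron
is implemented and configurable.) The four CG regions are the penultimate
and last exons of the upstream partner and the first and second exons of
the downstream partner; the natural background is a random sample of
non-CG genes with ≥ 4 exons.

Group-versus-background density comparisons are Welch t-tests on pooled
ranks (average ranks on ties), two-sided, BH-adjusted across every
(region × motif) cell of one comparison, significant at adjusted p < 0.05.
The effect size is the Kerby simple-difference rank-biserial correlation,
computed from the Mann-Whitney U statistic (effect = 2U/(n₁n₂) − 1 with U
counting group-favorable pairs); it is +1 under complete separation and
verified against the 1 − 2U/(n₁n₂) identity. Family redundancy is resolved
by keeping the representative family member's motif when present, else the
motif significant in the most regions, ties to the lexicographically
smallest id. Motifs significant somewhere are grouped by hierarchically
clustering their signed effect patterns (Euclidean, average linkage) and
cutting at half the maximum co-phenetic distance.

3′-end scanning reports canonical A(A/U)UAAA hexamers within 50 bp upstream
of a poly(A) site, UGUA (CFIm) within 150 bp upstream, and a downstream
element within 50 bp downstream, all in transcript orientation. A DSE is a
window of ≥ 6 nt consisting of uracils with at most three interspersed,
non-adjacent guanines; any qualifying window suffices, which reduces to an
exact 6-mer criterion (every longer qualifying window contains a qualifying
6-mer). Both scanners are tested against brute-force enumeration oracles.

## siRNA screen

Counts are upper-quartile normalized: each library is divided by the 75th
percentile of its nonzero counts (linear interpolation between order
statistics) and multiplied by the mean of those percentiles, a common
reference that makes the transform idempotent. "Detected" means a nonzero
raw count. CGs detected in ≥ 3 control libraries keep a treatment value
only if it exceeds that CG's control mean + 2 sample standard deviations
(computed on normalized values, consistent with normalization preceding
filtering; n−1 denominator); CGs detected in zero controls keep every
positive value; all other CGs are discarded. Retained distinct CGs are
counted per treatment.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *evidence structure* of a dose-response
splicing study: tandem same-strand gene pairs with configurable intergenic
distances and canonical GT..AG intron boundaries written into the sequence;
monotone-up/-down/flat ψ dose curves (default amplitude 0.5 across the
seven-dose grid, Gaussian noise σ = 0.05 by default — a strong but
realistic splicing response with junction-level measurement noise);
Poisson(depth)-binomial junction counts (default depth 50 reads per
junction per sample); a per-dose read-through probability curve rising
steeply past the inhibitor's cellular IC50 (defaults 0 → 0.6 across the
grid, mirroring the several-fold jump seen between adjacent doses at the
response inflection); long reads as exact junction chains with optional
coordinate jitter; and siRNA count tables with Gaussian per-CG baselines
(CV 0.2), per-library size factors, and planted fold shifts.

Read-through *steals* reads from the upstream partner's terminal junction
rather than adding depth, so total terminal-junction depth is conserved —
the study's observation that CGs form at the expense of canonical isoforms,
encoded as a hard constraint. The magnitude of that trade-off is not
quantified in the source; the one-for-one model is this package's
construction and is configurable. Downstream partners are simulated at
half the upstream expression, reflecting the observed asymmetry.

Not emulated: read-level sequencing (no FASTQ, no error model beyond the
long-read attribute fields), fragment-length and positional coverage
biases, multi-isoform genes, overlapping or antisense transcription (tests
construct those cases explicitly), and biological covariation between
events. Passing tests therefore demonstrate correctness of the statistical
machinery under the stated sampling models — not robustness to alignment
artifacts or annotation errors in real libraries.

Motif planting writes non-overlapping consensus copies at uniform random
positions (collisions re-drawn up to a cap, then an error) and mutates
chance occurrences elsewhere in the target interval, so achieved density
equals the requested density exactly and the enrichment benchmarks have a
known effect size.

## Numerical choices and degenerate inputs

- Beta quantiles and `betaln` from scipy; no sampling anywhere in the
  estimators.
- Zero-variance profile rows are an error naming the rows (they cannot be
  standardized); all-missing rows are dropped.
- Overlapping genes get intergenic distance 0 with an overlap flag rather
  than a negative distance.
- Zero removed-portion coverage yields an infinite interrupted index,
  flagged via `math.isinf`; an empty retained portion is an error.
- A CG with zero supporting reads has no splicing index (error), matching
  its definition.
- Sign ties are excluded from the concordance denominator; an all-tie
  input is an error rather than a silent 0/0.
- BH adjustment and hypergeometric tails come from statsmodels/scipy;
  identical-constant enrichment cells short-circuit to p = 1, effect 0.

## Benchmark problem sizes

The acceptance benchmarks run at: 500 events × ~200 reads (PSI
calibration); 20 random count configurations + 1000 null events × 100
reads/side (Bayes factor); 200 gene pairs with 50 planted CGs (detection);
150 events per response class at σ = 0.1 (clustering); 720 exhaustive
permutations and 200 null replicates × 999 shuffles × 2000 events
(concordance); 20 seeds × (100 + 400) events × 7 regions (motif power and
matched-density null); 10,000 random sequences per scanner oracle; 20 gene
pairs (long-read validation); 20 seeds × 50–100 CGs (siRNA screen). These
sizes give stable Monte-Carlo estimates while keeping a full run to about
a minute on one CPU.

## Known limitations

- The junction-only PSI model ignores exon-body reads; events whose
  isoforms differ only in length (no discriminating junction) are out of
  scope, as are events with more than two isoforms.
- The splice-score surrogate and rule-based confidence are transparent
  stand-ins for a trained fusion classifier; they are exact on annotated,
  canonical junctions and deliberately conservative elsewhere.
- The static tree cut can split a sprawling module that a dynamic cut
  would keep whole; for block-structured dose profiles this has no
  practical effect, but very heterogeneous modules may shed members.
- Scale-free fit selection is meaningful only for matrices large and
  diverse enough to have a connectivity distribution; below 50 rows the
  selector refuses to run.
- The permutation p-value is conservative for short, heavily tied slope
  vectors; exhaustive enumeration is available below 8 events.
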