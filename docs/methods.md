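# Methods

This note records the models, conventions and numerical choices behind
`gutcore`, and what the synthetic validation does and does not establish.

## Ingestion conventions

- **OTU QC.** Three independent per-OTU rules: upstream chimera/singleton
  flags (consumed, never computed), a total-read floor (< 10 reads removed —
  the boundary is inclusive on 10), and a presence rule removing OTUs
  detected in fewer than `ceil(0.01 · n_samples)` samples (strictest reading
  of "fewer than 1% of samples"). The singleton flag is kept distinct from
  the read floor even though the floor subsumes it numerically, because
  upstream pipelines report them separately. Filtering is idempotent.
- **Taxonomy.** RDP fixed-rank rows are parsed into (name, rank, confidence)
  triplets. A genus call is accepted iff its confidence is ≥ the threshold —
  inclusive, since a stated "threshold of 50%" names the admitted boundary.
  The threshold is a per-dataset parameter (0.5 for pyrosequenced V3 reads,
  0.8 for V3–V4 MiSeq reads). A missing genus rank is an UNASSIGNED call,
  not an error.
- **Relative abundance.** Genus-unassigned reads are pooled into a residual
  that is excluded from the genus list but included in every sample's
  denominator, so abundances are fractions of *total* filtered reads and
  genus columns sum to ≤ 1. This is configurable in principle but is the
  package default because per-sample totals are the natural normaliser.

## Core identification

Prevalence is the detection fraction (relative abundance > 0) over an
explicit sample subset — by convention the healthy samples — and the core
threshold (default 0.5) is inclusive. Entries are ordered by descending
prevalence, ties by descending mean abundance then name, so output tables
are deterministic. `core_summary` reports both the unweighted mean of the
per-dataset core read fractions and the pooled-read fraction: the two
natural cross-dataset "averages" differ whenever dataset sizes differ, and
neither is privileged.

## Co-abundance groups

Spearman ρ is the Pearson correlation of midranked abundances (zeros tie at
the bottom); p-values use the two-sided t approximation; the family of
k(k−1)/2 upper-triangle tests is adjusted with Benjamini–Yekutieli, which
stays valid under the arbitrary dependence a correlation matrix carries. The
family size m is fixed to the full triangle even when some pairs are
degenerate; a constant genus gets ρ = 0, p = 1 (logged) rather than being
dropped, so the grouping always covers the core set. Edge thresholds are
strict, as printed: |ρ| > 0.5, q < 0.001.

**Grouping rule.** No explicit algorithm is published for delimiting the
groups; connected components over significant positive edges is ruled out
because a significant positive edge can cross two groups. The primary rule
is average-linkage agglomeration on d = 1 − ρ cut at height 0.5 (clusters
whose mean internal ρ ≥ 0.5), with components mode available for sensitivity
analysis. Groups are labelled C1, C2, … by descending size (ties by mean
prevalence), members ordered by descending prevalence.

## Ordination and MANOVA

PCA is mean-centred SVD with no variance scaling — the decomposition implied
by Euclidean distances between abundance profiles. Sign convention: the
largest-magnitude entry of each loading vector is positive. MANOVA is
one-way on the first k score dimensions: Λ = det(W)/det(W+B), Bartlett's
χ² = −(n − 1 − (k+g)/2)·ln Λ on k(g−1) df. k defaults to 2 (matching 2-D
score plots; small cohorts cannot support full-rank MANOVA over all genera)
and is capped at n − g − 1; a singular W reduces k with a logged note. The
choice of k and the use of scores rather than raw abundances are exposed
parameters, since published analyses rarely state them.

## LEfSe-style selection

Stage 1 is a per-genus tie-corrected Kruskal–Wallis test (all-identical
input is defined as H = 0, p = 1); the screen is strict (p < α). Stage 2
scales abundances to parts per million, draws 30 subsamples of ⌊2/3⌋ of each
class (LEfSe's published defaults; both exposed), fits a regularised Fisher
discriminant per subsample, and scores genus i as
log₁₀(1 + |mean_b[(w·share + raw)/2]|), where *raw* is the class-mean
difference and *w·share* its decomposition along the unit discriminant
direction. The log10(1 + x) form maps a null effect to 0. Selection is
strict (score > 2.0). Resampling streams are keyed to each class's member
ids, making scores invariant to row order and class relabeling. Equivalence
with the original LEfSe release is claimed at the level of selection
decisions on planted data, not score-for-score. No subclass/Wilcoxon stage:
the designs handled here have no subclasses.

## Phenotype screen

Spearman ρ per (PC, parameter) pair on pairwise-complete samples (n ≥ 3,
otherwise NA and excluded from the family), Benjamini–Hochberg over the full
k × m batch (BY is reserved for the correlation matrix where dependence is
structural), significant at q < 0.1 strict. k defaults to 10 leading
components since downstream interpretation may reach past PC3.

## Phylogeny

p-distances with pairwise deletion of gap/ambiguity sites (Jukes–Cantor
correction optional); a pair with no comparable site is an error naming the
pair. Neighbor joining is the classic Saitou–Nei agglomeration with the
Studier–Keppler Q criterion, lowest-index tie-breaking, negative branch
estimates clamped to zero with the deficit moved to the sister branch, and
the final trifurcation as the unrooted representation; on additive matrices
it provably recovers the generating topology and metric (tested to 1e−9).
Bootstrap supports are Felsenstein column resampling with bipartition
frequencies mapped onto the point-estimate tree. The multiple alignment is
consumed, not computed.

## Synthetic community model

Per sample s, latent group factors f_s ~ MVN(0, R); per genus i in group
g(i):

log A_is = μ + o_i + λ·f_s[g(i)] + ln2·Σ(matching log₂ effects) + ε_is,
ε ~ N(0, σ²)

then zero-inflation with per-genus probability d_i, per-sample
renormalisation, and multinomial read sampling at fixed depth. Host
parameters are linear readouts of f plus noise. Zeroing happens *before*
renormalisation so dropout controls prevalence independently of
composition. All sub-stage RNG streams are derived from the seed by fixed
offsets, so enlarging the genus set does not reshuffle per-sample draws.

Defaults (the "stated world" of the validation suite):

- **Scale.** 101 samples × 100–120 genera, depth 30,000, five planted blocks
  of sizes 22/6/5/3/1; the cohort fixture arranges 205 samples in three
  pseudo-cohorts with 48/34/19 healthy (101 total) plus two diseased groups.
- **Abundance.** μ = 0, genus offsets N(0, 1) (long-tailed after
  exponentiation). Ungrouped background genera get a +0.75 offset boost so
  the planted core carries roughly half of the reads — matching what healthy
  cohorts show — and, critically, so compositional closure does not cancel
  the shared group factors (with no abundant background, a group's factor
  divides out of its members' relative abundances and within-group
  correlation collapses or turns negative).
- **Prevalence.** Grouped (core) genera: dropout linspace(0, 0.15)
  (prevalence 1.0 → 0.85). Ungrouped: linspace(0.65, 0.95) (0.35 → 0.05).
  Two constraints fix this profile: every planted prevalence must sit ≥ 3
  binomial SE from the 0.5 core threshold at n ≈ 100 for the core set to be
  identifiable, and grouped dropout beyond ~15% is incompatible with the
  within-group rank correlation the blocks are meant to carry (zero-inflated
  Spearman is bounded roughly by the joint-detection probability). Real
  cohorts contain boundary genera — healthy-mouse surveys report core
  members at 50.5% prevalence — and genera that are both rare and strongly
  co-abundant; the generator deliberately does not model either, so a green
  recovery test speaks only to structure away from those boundaries.
- **Coupling.** λ = 2.0 and σ = 0.5, calibrated once so that detectable
  (low-dropout) within-group pairs show Spearman ρ ≈ 0.75–0.85 and planted
  block means sit near the 0.6–0.65 that the 0.5 linkage cut resolves
  cleanly; the between-group factor correlation matrix encodes the target
  ecology (C1–C2 +0.3, C2–C3 −0.4, C1–C4 −0.4, C3–C4 +0.3, C5 uncoupled).
- **Effects.** Differential-abundance fixtures plant effects on *sparse*
  genera (offset −4). This is deliberate: a planted fold-change on an
  abundant genus shifts every other genus through compositional closure,
  making the "null" genera genuinely differentially abundant — at which
  point selecting them is correct behaviour, not a false positive. With
  sparse planted genera the null genera stay null and the Kruskal–Wallis
  screen runs at its nominal level.

## Determinism and outputs

Every stochastic stage takes a seed; the pipeline writes TSV/Newick/JSON
artifacts once, records thresholds in a greppable run log, and emits a
manifest of output SHA-256 hashes — reruns with identical config and inputs
are bit-identical. Synthetic runs add a truth-recovery report (core
Jaccard, grouping ARI, per-contrast selection sensitivity).

## Known limitations

- Plain Spearman, not compositionality-aware association (SparCC etc.); the
  grouping emulates the published workflow, not best current practice.
- The Bartlett χ² MANOVA approximation is asymptotic; cohorts of a few
  dozen samples are near its comfort zone but exact F-approximations are not
  provided.
- The LDA effect size is one reasonable reading of the LEfSe convention;
  scores agree with the original in selection behaviour, not digit-for-digit.
- BIOM support covers v1 (JSON) only, not v2 (HDF5).
- The generator does not model sequencing batch effects, overdispersion
  beyond the multinomial, strain-level structure, or prevalence boundary
  genera (see above).
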