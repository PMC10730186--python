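# Methods

This note documents the models, conventions, numerical choices, and known
limitations of `microleak`. It describes what the code computes, not results;
every number shown by the README or tests is recomputed at run time.

## Data model and units

The root object is a genus-by-sample table of nonnegative integer read
counts. All downstream statistics operate on per-sample **percent** relative
abundances (rows sum to 100), the unit in which genus medians are
conventionally printed and in which the AL index is defined. Operations that
are mathematically scale-free (Bray-Curtis, ANOSIM, Shannon, the AL index)
accept any nonnegative scale.

Rarefaction is a single multivariate-hypergeometric draw per sample to a
common depth (default 35,500 reads; the generator simulates 35,595, the mean
amplicon depth of the emulated study), not an average over draws. Samples
under depth are dropped with a warning, the standard practice. A fixed seed
gives a bit-identical subsample. Good's coverage is C = 1 − F1/N with F1 the
number of singleton taxa.

## Univariate and categorical statistics

- One-way ANOVA, Kruskal–Wallis (tie-corrected), and Spearman correlation
  (mid-ranks, two-sided t approximation) delegate to scipy. Degenerate
  all-identical inputs return statistic 0, p = 1 rather than NaN.
- The 2×2 chi-square carries **no continuity correction**: on the diet leak
  table [[9,6],[10,5]] the uncorrected test gives p = 0.705 while the Yates
  form gives ≈ 1.0; the uncorrected convention is the one under which the
  published comparisons reproduce.
- The two-sided Fisher exact p-value sums hypergeometric point probabilities
  no larger than the observed table's, with 1e-7 relative slack for
  floating-point ties. The Freeman–Halton test generalizes exactly that rule
  to K×2 tables by full enumeration over the fixed margins; enumeration is
  refused (with a suggestion to fall back to Monte-Carlo) when the smaller
  outcome margin exceeds 30. On 2×2 input, Freeman–Halton and Fisher agree
  to numerical precision — the suite verifies this exhaustively for all
  margins ≤ 12.
- Test selection for outcome tables follows the small-cell rule: the exact
  test whenever any cell is < 5, otherwise chi-square.
- Post-hoc procedures: Tukey HSD (scipy's studentized-range implementation),
  Dunn's z-test on pooled mid-ranks with tie correction and Bonferroni
  adjustment, and Duncan's multiple range test. Duncan's is expressed as
  pairwise "p-values" rescaled from studentized-range tail probabilities so
  that comparison to α reproduces the fixed-level multiple-range decision;
  this is documented as approximate — the classical procedure has no native
  p-value. All three feed a compact letter display (split-and-absorb):
  groups sharing a letter are not significantly different at α.
- Classifier metrics treat **leak as the positive class** (sensitivity =
  detected leaks / all leaks). This follows from the cutoff convention
  "index ≥ cutoff predicts absence of leak".

## Diversity and ordination

Shannon uses the natural logarithm (mothur's convention; with ~150–200 OTUs
the emulated study's values near 3.0 are only consistent with ln). Chao1
defaults to the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)); the classic
form is behind a flag and falls back to bias-corrected when F2 = 0. Alpha
diversity is computed on the rarefied table, matching the conventional order
of operations.

PCoA applies Gower double-centering to −½d² and an eigendecomposition;
negative eigenvalues (non-Euclidean input) are reported but contribute no
coordinates, and no Cailliez correction is applied. The goodness-of-fit
`fit_r2` is the squared Pearson correlation between the original
dissimilarities and the inter-point distances over retained axes; it is 1 to
1e-9 for Euclidean-derived input.

ANOSIM uses Clarke's statistic R = (r̄_between − r̄_within)/(n(n−1)/4) on
mid-ranked dissimilarities, so R ∈ [−1, 1]. Significance is
p = (1 + #{permuted R ≥ observed})/(n_permutations + 1) with seeded
permutations (default 999); small designs can request exhaustive enumeration
instead. Bonferroni control across pairwise ANOSIMs is the caller's
responsibility via `bonferroni_alpha`; the module reports raw p-values.

CCA is the classical ter Braak chi-square-weighted constrained ordination:
Q = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2} is regressed onto row-weighted,
standardized constraints and the fitted part is decomposed by SVD. Total
inertia equals the table's chi-square statistic divided by the grand total.
Collinear constraint columns are detected by pivoted QR and dropped with a
warning. The pipeline accepts any numeric covariate table for the
macronutrient constraints.

## Differential abundance

`kw_screen` runs Kruskal–Wallis per taxon and attaches Dunn letters and
median [IQR] summaries for significant taxa. `lefse` is the classic LDA
effect-size formulation for two classes (one-vs-rest for more): a
Kruskal–Wallis filter at α = 0.05, then 30 bootstrap iterations subsampling
2/3 of each class, a linear discriminant per bootstrap, and a per-taxon
effect size averaging the raw between-class mean difference with the
discriminant-projected difference attributed back to the taxon. Effects are
computed on a per-million scale (percent × 10⁴) so the canonical log₁₀
threshold of 4 keeps its standard meaning; the reported score is
log₁₀(1 + |effect|) signed toward the enriched class. The subclass
(Wilcoxon) stage of the original procedure is omitted — this study design
has no subclasses. Constant features are jittered by N(0, 10⁻⁶) within a
bootstrap only to keep the within-class scatter invertible.

## The AL index and CART

The AL index is (Paramuribaculum + Clostridium sensu stricto + Alistipes) /
(Dubosiella + Bacteroides + Akkermansia) on percent abundances; genera
missing from a sample count as zero. Boundary and degenerate conventions:

- index ≥ cutoff (default 0.45) → predict no leak; the boundary itself is
  no-leak, since the cutoff is defined as "predicting the absence of leak";
- denominator 0 with numerator > 0 → flagged degenerate, predicted no-leak
  (absence of all three leak-associated genera is the extreme no-leak
  signal);
- 0/0 → degenerate, prediction undefined.

Evaluation restricts to POD4 samples with known outcome — the timepoint at
which the leak-associated community shift is strongest — and reports a
confusion matrix with leak positive plus per-group median [IQR] index
scores, with leak mice pooled into their own comparison group.

CART grows greedy binary trees maximizing information gain in bits over
(taxon, midpoint-between-sorted-values) candidates; ties break toward the
lower taxon index, then the lower threshold, making training fully
deterministic given the seed. Stopping: max depth 3, minimum leaf size 2
(shallow trees selecting about three taxa), both configurable. The
train/prediction split is a randomized half split **stratified by outcome**
so both halves contain both classes whenever possible. The candidate pool is
the eight leak-associated genera (the six index genera plus *Lachnospiraceae*
spp. and *Parasutterella*). Re-deriving the cutoff by ROC optimization is
intentionally out of scope; 0.45 is taken as given.

## Engraftment (source attribution)

A sink (recipient stool) community is modeled as a mixture over known
sources — donor slurry and recipient baseline — plus an unknown source.
Known-source taxon distributions are fixed Dirichlet-smoothed empirical
profiles (α = 0.001 per taxon); the unknown source has its own Dirichlet
prior (β = 0.01) and is learned; the mixing vector has a uniform Dirichlet
prior. Inference is a **blocked Gibbs sampler**: because reads of one taxon
are exchangeable, each sweep reassigns every taxon's reads jointly with one
multinomial draw, then redraws the unknown-source distribution and the
mixing vector from their Dirichlet conditionals. This targets the same
posterior as a per-read collapsed sweep while vectorizing over reads.
Defaults: 100 burn-in sweeps, 100 retained draws thinned ×10, 10 independent
restarts averaged; sinks deeper than 1,000 reads are subsampled to that
depth before fitting to bound runtime (a documented divergence from
read-level fidelity). Proportions are posterior-mean assignment fractions
and always form a simplex. Per-group, per-timepoint engraftment summaries
delegate the across-timepoint comparison to ANOVA with Tukey post-hoc.

## Synthetic-study generator

The generator defines the study conditions; it is not a tuning dial.

- **Generative family**: Dirichlet-multinomial — proportions drawn from a
  Dirichlet centered on the group's genus median profile, counts multinomial
  at depth 35,595. Concentration defaults to 200, chosen once so simulated
  interquartile ranges are of the same order as the published group IQRs.
- **Profiles**: the five published per-group genus median profiles (pooled
  leak group AL plus LD, WD, LD-wdFMT, WD-ldFMT), each padded with a
  residual taxon to 100%.
- **Design**: 16 mice per treatment group; perioperative deaths 1/1/0/3
  (LD/WD/LD-wdFMT/WD-ldFMT) so survivors number 15/15/16/13; leak outcomes
  6/5/4/0 among survivors. Non-survivors contribute only a baseline sample
  and carry an unknown leak status — they are excluded from every leak
  analysis. These counts make the clinical stage reproduce the published
  contingency tests exactly (chi-square p = 0.705, Fisher p = 0.458 and
  0.0437, Freeman–Halton survival p = 0.380, survival 92%). Note the
  published survival table lists the FMT groups' survivor counts swapped
  relative to the leak tables; the generator follows the leak tables, and
  the survival test is invariant to that row permutation.
- **Leak effect**: multiplicative fold-changes at POD4 only (×2.2
  Bacteroides, ×1.8 Akkermansia, ×0.5 Alistipes, ×0.5 Clostridium s.s.,
  ×0.6 Lachnospiraceae spp., ×0.8 Paramuribaculum), renormalized. The
  `generate_leak_separated_cohort` helper raises these to a configurable
  power (0 = exchangeable null, 1 = default shift).
- **FMT**: post-gavage samples mix convexly, (1−f)·recipient + f·donor,
  with per-timepoint engraftment fractions 33.0/11.8/15.5% (WD slurry into
  LD-fed mice at DOS/POD4/POD7) and 10.6/5.1/9.8% (LD slurry into WD-fed
  mice); the donor profile is the opposite diet's control profile.
- **Body weight** at DOS: N(30.6, 2.6²) g for LD, N(36.4, 4.0²) g for WD.

What the generator does **not** emulate: OTU-level richness (it carries 16
genus-level taxa, so Good's coverage is ≈ 100% rather than ~98.7% and
Chao1/Shannon magnitudes differ from OTU-level values), per-mouse
longitudinal autocorrelation beyond the shared group profile, phylogenetic
structure, and read-level error. Tests passing on synthetic data therefore
validate the statistical machinery and the direction/order of effects, not
OTU-scale diversity values; the published classifier performance figures
(73%/80%/71%) require the deposited sequence data and are checked here only
as a property — sensitivity ≥ 0.7 and specificity ≥ 0.6 at cutoff 0.45 in at
least 90% of seeded replicates.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed, and the pipeline derives
per-stage seeds from one master seed; identical configuration and seed give
byte-identical report bundles (verified by manifest hash). Simulation-based
checks use deliberately modest problem sizes — 100 seeded cohorts for
classifier properties, 500 null simulations at 199 permutations for ANOSIM
calibration, 20 replicates for engraftment recovery, an exhaustive battery
of ≤ 12-sample instances for the CART oracle — sizes at which the Monte
Carlo error is small relative to the tolerances being asserted.

## Known limitations

- Duncan's test is a p-value approximation of a fixed-level procedure (see
  above).
- The Freeman–Halton enumeration is exponential in the number of groups;
  the margin bound of 30 keeps it exact and fast for clinical-scale tables
  but large tables need the chi-square or a Monte-Carlo variant.
- The engraftment sampler's known-source distributions are fixed at their
  smoothed empirical estimates (no resampling of source profiles), so very
  similar donor and baseline profiles widen the posterior on the mixing
  fractions.
- LEfSe here is the two-class, no-subclass variant; multi-class designs are
  handled one-vs-rest by the caller.
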