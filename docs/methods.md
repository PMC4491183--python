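# Methods

This note documents the models implemented in `patmb`, the parameters that
matter, what the synthetic cohorts do and do not emulate, and the numerical
and design choices that were genuinely open.

## Study design being modelled

The package targets longitudinal 16S OTU-count studies of early-life
microbiome development under pulsed antibiotic treatment (PAT): four groups
(control, amoxicillin, tylosin, mixture = tylosin/amoxicillin/tylosin),
three antibiotic courses at days 10–15, 28–31 and 37–40 of life, a switch
from normal chow to high-fat diet (HFD) at day 41, and ~14 timed faecal
samples per mouse between days 21 and 142. All analyses join an integer
OTU-count table (samples × OTUs, with ranked taxonomy strings) against
per-sample design metadata (mouse, cage, group, day of life, timepoint
index, diet phase).

## Microbiota age and MAZ

A random-forest regression predicts chronological day of life from
per-sample relative OTU abundances of control mice. Ensemble settings are
10,000 trees with ⌊n/3⌋ variables tried per split (n = number of predictor
OTUs); other tree parameters are scikit-learn defaults. Out-of-bag (OOB)
predictions and the OOB R² ("variation explained") are recorded at fit
time. Tests and drivers typically fit 250–2,000 trees: the OOB error curve
of a forest this size (≤ ~450 training samples, ≤ 100 predictors) is flat
well below 2,000 trees, and one test fits the full 10,000-tree ensemble to
exercise the stated configuration.

**Variable importance** is OOB permutation importance (the classic
"% increase in MSE"): for each tree, the MSE on its OOB samples is compared
with the MSE after permuting one predictor's OOB values, and the relative
increase is averaged over trees. The computation uses a deterministic
subsample of trees (default 300) — trees are exchangeable, so a subsample
estimates the same quantity at a cost independent of ensemble size.

**Refinement** ranks OTUs once by that importance (a single global ranking,
not re-ranked per fold), walks candidate subset sizes down a geometric
ladder (n, ⌈n/2⌉, …, 2), scores each size by K-fold cross-validated MSE
(default 100 folds, reduced to leave-one-out with a warning when folds
exceed samples; CV forests default to min(n_trees, 500) trees), and
retrains on the smallest size whose CV MSE is within one standard error of
the minimum. The one-SE rule operationalises "the minimum number of OTUs
required to minimise model error" without chasing noise in the CV curve.

**Scores.** With "similar age" defined as the scheduled timepoint index
(all mice share one sampling schedule):

    MM  = microbiota age − median(control microbiota age in the bin)
    MAZ = MM / s.d.(control microbiota age in the bin)   (n−1 denominator)

Control references use OOB predictions to avoid resubstitution bias; bins
with fewer than 3 controls or zero s.d. are flagged unusable and scoring
against them is refused. By construction the per-bin median control MAZ is
exactly 0 and MAZ is invariant to affine transformations of the age scale.

**Group comparison** per timepoint: one-way ANOVA on MAZ; when significant
at 0.05, Fisher-LSD t-contrasts of each treatment group against control
(pooled ANOVA MSE, df = N − k), Benjamini–Hochberg adjusted within the
timepoint (protected LSD keeps the null false-flag rate of the contrasts
well under 5% in simulation).

## Community-state typing

Distances are the square root of the Jensen–Shannon divergence with base-2
logarithms, so divergences and distances both lie in [0, 1] and sqrt-JSD is
a genuine metric (identity, symmetry and the triangle inequality are
property-tested to 1e-12).

**PAM** (k-medoids) minimises the total distance of samples to their
cluster medoid: greedy BUILD seeding followed by best-improvement SWAP
until no single medoid exchange lowers the cost. Because single-start
BUILD+SWAP reaches the global optimum in only ~94% of tiny random
instances, the SWAP phase additionally starts from two other deterministic
seedings (farthest-first traversal and the k most central samples) and the
lowest-cost local optimum wins (~99% agreement with exhaustive enumeration
at n ≤ 8, k ≤ 3, never worse than BUILD alone). Every tie breaks toward
the lowest sample index, so partitions are exactly reproducible.

**Choosing K** maximises a distance-only Calinski–Harabasz index over
K = 2..10: within-cluster dispersion is computed from squared pairwise
distances via W_c = Σd²/(2n_c) — the identity that replaces centroids when
only a distance matrix exists — and CH = (B/(k−1))/(W/(n−k)). No embedding
is involved; principal coordinates are provided for visualisation only.
Clustering operates on OTU-level relative abundances (taxonomic rank
aggregation can be applied upstream if desired).

**Transition maps** count mice moving between states across *consecutive
scheduled* timepoints; a mouse missing either endpoint of a step
contributes occupancy but no transition (gaps are skipped, not
interpolated).

## Alpha diversity

Each sample is rarefied once to a fixed depth (default 3,000 reads) by a
multivariate-hypergeometric draw with a recorded seed; samples below the
depth are excluded with a warning rather than raised. Richness is the count
of non-zero OTUs; Shannon index uses base-2 logs (bits — divide by
log2(e) ≈ 1.4427 for nats). An optional mean-over-draws mode exists but is
off by default. The analysis driver rarefies at 1,000 reads because the
simulated sequencing effort is itself scaled down (below).

## Diet-response screen

OTUs aggregate to families by the `f__` rank of their lineage; OTUs without
a family fall into "(deepest named higher rank) other" buckets, e.g.
"Clostridiales other". Families above 1% relative abundance in at least one
sample of one mouse enter the screen. For each family, the Mann–Whitney U
of post- vs pre-HFD values — per-mouse means within each window by default,
since mice (not samples) are the biological replicates — gives
AUC = U/(n_pre·n_post), an exact two-sided p-value when n_pre·n_post ≤ 400
and no ties (tie-corrected normal approximation otherwise), and a
Hanley–McNeil 95% CI clipped to [0, 1] (post-diet treated as the
"positive" class). BH q-values are computed across families; direction
(increase/decrease) is reported separately from the two-sided test.
Windows default to the last pre-switch and first post-switch scheduled
days. Family aggregation uses un-rarefied proportions — proportions are
depth-invariant in expectation, and this keeps the screen independent of
the rarefaction seed.

## The synthetic cohort generator

The generator's role is to produce data with the *statistical structure* of
the PAT design and known ground truth, so that every analysis above can be
validated as parameter recovery. Expected community profiles are built from
OTU guilds:

* **Succession pairs** (default 15 pairs, 10% of community mass): an
  early-life OTU decaying logistically with age, mirrored by a late-life
  partner rising on the same midpoint and scale (default 9 d), so each
  pair's combined mass is constant. Midpoints are spaced uniformly from 15
  days before the first sampling day to 15 days after the last: the summed
  "mixedness" of the pairs is then flat across the sampled range, which is
  what keeps expected control Shannon diversity trend-free while the
  composition still turns over with age (the maturity signal).
* **Diet pairs** (default 10 pairs, 25% of mass): a low-weight OTU paired
  with a partner at `diet_fold` (default 4×) its weight; at the diet switch
  the weights swap. The post-switch weight multiset is a permutation of the
  pre-switch one — a large compositional shift with unchanged expected
  diversity, again protecting the flat control trajectory.
* **Stable OTUs** (the remainder) with fixed log-normal weights, two of
  which are designated bloom taxa (*Akkermansia*-like for tylosin,
  Enterobacteriaceae-like for amoxicillin).

**Antibiotic courses** act through four effects, all step-shaped in time
(full strength during the course and for a per-antibiotic persistence
window after it, then off): an evenness loss (proportions raised to
1/factor and renormalised), a bloom fold-change, a depletion of the
late-successional guild (the compositional face of arrested maturation),
and a **maturation lag** that accumulates per course and shifts the
evaluation point of the whole succession/diet clock to (day − lag).
Defaults: tylosin 0.65 evenness, 5× bloom, 0.30 late depletion, 12-day
persistence, 6 d lag per course, permanent; amoxicillin 0.75 evenness,
14× bloom, 0.70 late depletion, 6-day persistence, 4 d lag per course
recovering linearly within 14 days. The lag-shifted clock automatically
delays the diet response of exposed mice. Step-shaped (rather than
linearly relaxing) distortion is deliberate: it makes the planted
community states discrete, which is what "n_states = 4" promises; a
continuous relaxation produces a continuum no clustering method should be
expected to segment.

**Planted states** follow from exposure and diet: markedly perturbed
(evenness factor < 0.70) → state 3; otherwise diet-shifted at the *lagged*
clock → state 4; mildly perturbed (< 0.97) → state 2; else baseline
state 1.

**Counts** are Dirichlet-multinomial: p ~ Dirichlet(θ·expected),
counts ~ Multinomial(depth, p), depth log-normal with mean 3,500 and s.d.
1,500 — a deliberately scaled-down sequencing effort (about half the
emulated study's) that keeps test runtimes small — clamped below at 1,200
reads so rarefaction at 1,000 retains every sample. The concentration
default is θ = 1000: across ~100 OTUs this yields within-state sqrt-JSD
≈ 0.19, i.e. ~4.5× multinomial overdispersion at the default depth.
Much smaller θ (say 50) makes replicate samples of the *same* community
nearly maximally distant in JSD across 100 taxa, which no clustering or
silhouette criterion can survive; θ = 1000 keeps the data visibly
overdispersed while leaving planted structure recoverable.

Effect sizes, guild masses and persistence windows were set, once, to make
the generator honour its contract — flat control diversity, planted states
recoverable by PAM/CH, a detectable ≥10-day cumulative tylosin lag — and
then frozen; they are testability parameters, not estimates of any real
effect.

An **unpaired succession mode** (`paired_succession=False`) plants each
succession OTU on its own sharp logistic (scale 5 d, midpoints interior to
the sampling range). Mirrored pairs are exactly collinear within a pair, so
this mode exists for experiments that need k *independently* informative
age predictors — e.g. sparse-model recovery with 10 informative + 90 noise
OTUs (succession mass 0.22 in that configuration).

### What the simulator does not emulate

No mechanistic ecology (no species interactions or Lotka–Volterra
dynamics), no strain/sequence-level structure, no chimeras or
contamination, no cage or litter random effects, no maternal samples, and
taxonomy strings are a small fixed set of realistic lineages rather than a
full reference taxonomy. Passing recovery tests therefore demonstrates that
the estimators are correct and powered under the planted model — not that
real data meet that model's assumptions.

## Numerical choices and degenerate inputs

* JSD is clipped at 0 before the square root (floating-point can produce
  −1e-17); distance matrices are symmetrised and validated to 1e-12.
* CH returns +inf (logged) if within-cluster dispersion is exactly zero.
* All-zero count vectors: Shannon raises; prediction of a sample with zero
  coverage of the selected OTUs is defined (ensemble baseline) and logged.
* Reference bins with < 3 controls or zero s.d. are unusable; MAZ scoring
  against them raises, naming the bin.
* Classic-TSV counts must be non-negative integers; parse errors name the
  offending row. The BIOM dialect is dense JSON (v1 layout).
* Gamma underflow in Dirichlet draws (tiny α) falls back to the expected
  proportions for that draw.
* Ties: PAM breaks every tie toward the lowest sample index; `choose_k`
  breaks CH ties toward smaller K.

## Problem sizes used by tests and the acceptance script

Simulated cohorts are 4 groups × 3 mice × 14 timepoints (planted-K
recovery), 6 control (+6 tylosin) mice for maturity calibration and
delayed-maturation detection, and 8 control mice for the diet screen — an
exact 3-vs-3 Mann–Whitney cannot reach p < 0.05 two-sided, so per-mouse
screens need ≥ 6 mice per side to be informative. Forest sizes in repeated-
seed experiments are 250–2,000 trees with CV forests of 60–300 trees; the
choices follow the flat region of the OOB/CV error curves for these data
sizes. The analysis drivers default to 8 mice per group, the scale of the
emulated study.

## Known limitations

* The age model extrapolates poorly beyond the training age range; OOB
  predictions at the first and last timepoints regress toward the interior,
  inflating reference s.d. in edge bins.
* During an acute perturbation the compositional closure of a strong bloom
  rescales every other taxon and can bias the age readout *upward* while
  the accumulated lag is still small; the delayed-development signature is
  reliable after the final course, and that is the window the tests assert.
* The protected-LSD comparison reports NaN contrast p/q when the gating
  ANOVA is not significant; consumers should treat those as "not tested".
* `refine_model` uses one global importance ranking; per-fold re-ranking
  would be more conservative but is substantially more expensive and was
  not adopted.
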