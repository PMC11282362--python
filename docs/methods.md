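# Methods

This note documents the models implemented in `sparsecomp`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
studies do and do not establish.

## The co-evolution simulator

The generative model is built for reductive genome evolution: a binary
ecological predictor X and a non-negative response Y (an organelle gene
count) evolve jointly down a rooted phylogeny. For a branch of length
t from ancestor a to descendant d:

- **Predictor.** Reversible mode: X_d = 1 − X_a with probability r,
  else X_a. Irreversible mode: X_d = 1 with probability r, else X_a —
  appropriate when acquiring a feature (say, parasitism) makes its
  subsequent loss unlikely.
- **Response.** Y_d = Y_a − dY with dY = t·u, where u ~ Uniform(0, m)
  if X_a = 0 and u ~ Uniform(c, m + c) if X_a = 1. Negative values are
  clipped to zero. The single draw of u per branch, multiplied by the
  branch length, is the natural reading of a loss rate "scaled by branch
  length"; per-unit-time compounding would be an alternative model but
  changes nothing qualitative at the branch lengths used here.

The predictor therefore influences the *rate* of loss, not a target
value the response adapts toward. An Ornstein–Uhlenbeck (stabilizing
selection) simulator is deliberately out of scope: gene loss is
monotone, often irreversible, and has no obvious optimum, so a
rate-modulation model is the appropriate control.

**Observation model.** True X = 1 tips are recorded as 0 with
probability p; true X = 0 tips are never misrecorded. This one-way
false-negative structure mimics trait databases where a positive record
is almost surely real but an absent record is uninformative. Occlusion
consumes an independent random substream, so the same evolutionary
history can be re-observed at different p.

**Defaults.** r is usually not set directly but calibrated by bisection
(common random numbers, 400 Monte-Carlo simulations per evaluation) so
that the mean number of innovations — branches where X switches 0 → 1 —
hits a target; the headline studies use 8 innovations on a 256-tip
balanced tree, giving r ≈ 0.018. The loss scale is m = 5 per unit
branch length with root response y0 = 100: y0 only matters through how
often the zero floor is hit, and these values keep the floor essentially
unreached on the depth-8 trees used (maximum possible loss 80 < 100),
which is the regime the statistical analyses assume. Effect sizes c are
benchmarked at {0, m/2, m}; the model is jointly scale-invariant in
(m, c, y0), so only the ratio c/m matters away from the floor.

Y is kept continuous in the simulator; it is rounded to the nearest
integer only where a method requires counts (the Poisson model), with a
log message when rounding actually changes values.

## Trees

- **Balanced trees**: full bifurcations with uniform branch lengths, the
  idealized control topology.
- **Birth–death trees**: forward simulation from two root lineages with
  exponential waiting times (birth rate b, death rate ν < b), stopped
  the moment the extant count reaches n, then run forward by one more
  exponential waiting time so the final split does not create
  zero-length sister tips; extinct lineages are pruned and unary nodes
  suppressed. Fully extinct runs are redrawn, up to 1000 times.
- **Missing branch lengths**: if any branch lacks a length (taxonomy
  trees), every branch is substituted with length 1 before any
  length-dependent computation, and the substitution is logged. Grafen's
  covariance needs no lengths by construction.
- Polytomies are handled natively throughout; nothing assumes
  bifurcation, and no random resolution is performed.

## Covariance structures

For tips i, j with Brownian matrix V (V_ij = shared root-to-MRCA path
length):

| model | form | parameter |
|---|---|---|
| identity | I | — |
| brownian | V | — |
| pagel_lambda | off-diagonals of V times λ | λ ∈ [0, 1] |
| martins_hansen | exp(−α·d_ij), patristic d | α > 0 |
| grafen | path sums of height^ρ differences | ρ > 0 |

Grafen heights are (number of descendant tips − 1)/(n − 1), root height
1, tips 0; the height is raised to ρ before the Brownian path-sum rule
is applied. All matrices are symmetric positive semi-definite by
construction; before factorization a diagonal jitter of
1e−10·tr(V)/n absorbs rounding-level indefiniteness.

## Regression methods and p-values

**GLS/PGLS.** β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y with design [1, x], σ² profiled by
maximum likelihood, everything solved through Cholesky factorization
(never an explicit inverse). The slope p-value is a likelihood-ratio
test against the intercept-only model with the same covariance family,
referred to χ²(1). When the covariance parameter is estimated
(`parameter="estimate"`), it is profiled by bounded scalar maximization
— λ on [0, 1], α on [1e−4/T, 50/T] with T the tree diameter, ρ on
[0.01, 10] — **separately under the null and alternative** models. The
honest profile LRT costs a second optimization but keeps the test
correctly sized; fixing the null's parameter at the alternative's
estimate inflates rejection. ML (not REML) likelihoods are used; the
choice is validated by the null-calibration study below. Because the
bounded search can miss a boundary optimum, both endpoints are always
evaluated explicitly.

**Poisson GEE.** Log-link Poisson with working correlation
R = D^(−1/2) V D^(−1/2) (V Brownian, D its diagonal), fitted by
Fisher-scoring-style GEE updates to relative tolerance 1e−8 (at most 100
iterations; divergence is reported via `converged=False`, never an
exception). Dispersion φ is the Pearson statistic over n − 2, and the
slope test is a Wald z with model-based variance scaled by φ, referred
to the normal — no phylogenetic degrees-of-freedom correction is
attempted; instead the test's actual size is measured by simulation.

**Naive OLS** (no phylogeny) uses the ordinary two-sided t-test and
exists as the baseline whose inflation the benchmark quantifies.

The predictor is coded 0/1 without standardization, so a slope reads
directly as "average change in gene count associated with the trait".

**Pagel's λ** for a single trait is the ML λ of the intercept-only GLS
model, the standard phylogenetic-signal summary (1 ≈ full Brownian
structure, 0 ≈ star phylogeny).

## Non-parametric pipeline

Internal nodes are labeled recursively from the tips: an ancestor is
predictor-positive only if *all* its immediate children are positive
(applied recursively), and its response is the mean of its children's
responses. "Children" rather than "all tip descendants" is the reading
adopted; the alternative would re-weight responses on unbalanced trees
and is not implemented. At every internal node whose children disagree
in the predictor, one contrast Y⁺ − Y⁻ is recorded (class means under
multifurcation). Contrasts come from disjoint child sets, hence are
phylogenetically separate. The observed (occluded) predictor is used,
matching how the methods are benchmarked.

The contrast list is tested by:

- **Wilcoxon signed-rank**: zeros dropped, average ranks for ties; exact
  null by convolution over all 2ⁿ sign assignments for n ≤ 25 (doubled
  ranks make tied average ranks integral), tie-corrected
  continuity-corrected normal approximation beyond. An all-zero list
  returns p = 1 with a flag rather than raising.
- **Bootstrap percentile**: B resamples of the differences, two-sided
  p = 2·min(tail fractions) around zero, floored at 2/B since an empty
  empirical tail only bounds p below the Monte-Carlo resolution.
  Two-sided doubling matches the Wilcoxon convention.

**Clade blocking.** The Scheirer–Ray–Hare test ranks all observations
jointly and partitions rank sums of squares by group, block (the clade,
taken as the root-child partition), and interaction; each H is
SS/(SS_total/(N−1)) against χ². Sums of squares use the
between-level-means form; with one block the group H reduces exactly to
tie-corrected Kruskal–Wallis, which is also exposed directly for
single-clade features. Clade-mean normalization (subtract each clade's
mean response) is provided for the normalize-then-PLM route.

## Benchmark harness

A grid over tree specs × reversibility × effect c × occlusion p runs
every requested method on fresh simulations and reports the rejection
rate at α per cell — a false-positive rate where c = 0, a true-positive
rate otherwise. Balanced-tree cells reuse one fixed tree across
replicates; birth–death cells draw a fresh tree per replicate. Cell
seeds are derived from the base seed by hashing the cell coordinates
(CRC-32 into a SeedSequence), so any cell reproduces in isolation.
Replicates where a method cannot run (e.g. the observed predictor is
constant after occlusion) are recorded as non-converged and excluded
from the rate denominator, with the exclusion count reported.

A dedicated single-innovation null plants one predictor origin on a
seeded random internal branch with no effect on the response; this is
the pseudoreplication worst case on which phylogeny-blind OLS shows its
false-positive inflation while PGLS stays calibrated.

## Screening pipeline

For each (feature, value) hypothesis: binarize (missing values are
*undefined* and excluded, never coded 0 — the guard against
clade-definition artifacts such as "palm" correlating with gene count
merely because the label exists only in plants); restrict to the subtree
rooted at the MRCA of the positive species; apply the influence filter;
fit Brownian-covariance PGLS and the Poisson GEE; and report a
significance profile `plm/pglm` with `**` = below α/n_tests, `*` =
below α, `-` = neither.

The influence filter rejects a hypothesis when either predictor class
has ≤ 2 distinct response values and any of those values has fewer than
6 observations *within that class* — a single-valued class is treated as
at least as degenerate as a two-valued one. A flag switches to the
stricter pooled-both-classes reading. The Bonferroni denominator
defaults to the number of hypotheses that actually reached fitting
(logged), overridable by the caller; which convention a given study used
is often ambiguous, so it is explicit here.

Species names are reconciled across tree, table, and response by exact
match after whitespace/case normalization; fuzzy matching is out of
scope.

**Synthetic fixture.** `make_planted_trait_table` builds the screening
control: one clade-specific feature — defined only within the largest
root-child clade, missing outside it, evolving irreversibly inside with
effect c = m on the loss rate — among independent coin-flip decoy
features defined everywhere (carrier prevalence 0.2). A label-shuffle
switch permutes the species names as a negative control.

## Curation tool

`scan_articles` streams a MediaWiki-export style XML dump, applies a
user regex to each page body, and records ±window-character snippets
(default 300) in document order, re-verifiable against the pattern.
Candidate terms are wiki-link targets (`[[...]]`), falling back to
capitalized multi-word spans when a snippet has no links. The emitted
HTML review page is fully self-contained (inline CSS/JS, no network):
checkboxes per candidate, a manual-entry box, and a compile button that
produces one comma-separated list, re-ingested by
`parse_selection_list` (trim, drop empties, de-duplicate preserving
order). The selection itself is manual by design — the tool exists to
make human curation fast, not to replace it.

## What the synthetic studies show — and what they don't

Problem sizes: null calibration uses 300 replicates on 128 tips; power
and inflation studies 100 replicates on 256 tips; contrast tests 200
replicates; λ recovery and screening 20 replicates each. These sizes
give binomial standard errors of roughly 0.01–0.05 on the reported
rates.

Measured behaviour (recomputed by `scripts/acceptance.py`): PGLS and the
Poisson GEE hold their nominal size under the null (rates near 0.05);
naive OLS rejects several times too often on the single-clade null while
PGLS stays calibrated; PGLS retains useful power when half the positive
observations are hidden (≈ 0.34–0.41 at c = m, p = 0.5, versus ≈ 0.84
without occlusion, and always well above the null rate); the
sibling-contrast Wilcoxon is conservative but substantially less
powerful than PGLS; λ estimation recovers ≈ 1 on Brownian traits and 0
on shuffled ones; the screen ranks the planted feature first in most
runs and the shuffled control essentially never survives Bonferroni.
Power at the Bonferroni level is the binding constraint for the
screening study: with effects no larger than c = m, a planted feature is
Bonferroni-robust in roughly three-quarters of runs, not all.

The generator emulates reductive, rate-modulated evolution with biased
observation on known trees. It does not emulate: errors in the tree
itself, non-random (systematically biased) sampling of species,
between-clade differences in baseline loss rate beyond what the shared
tree induces, measurement error in the response, or multi-predictor
confounding. Passing these controls therefore shows the methods are
sound under the stated violations, not that any particular real-data
correlation is causal.

## Known limitations

- The GEE Poisson variance is model-based (dispersion-scaled), not a
  sandwich estimator; its size is simulation-validated rather than
  theoretically exact.
- The exact Wilcoxon null is O(n·Σranks) by convolution — fine to
  n = 25, approximation beyond.
- SRH sums of squares use the between-means partition, which for badly
  unbalanced two-factor layouts differs from a regression-based (Type
  II/III) partition.
- `calibrate_r` assumes the innovation count is monotone in r over the
  searched interval, which holds in the small-r regime of interest.
- Tree containers are O(n²) in covariance construction; the methods are
  intended for the ~10²–10³-tip scale of the studies here.
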