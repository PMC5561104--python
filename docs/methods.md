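# Methods

## Coordinate model

All intervals are BED-style 0-based half-open; 1-based inclusive inputs are
converted at the reading boundary (`one_based=True`).  Strand is ignored
throughout: consensus voting, window counting and overlap annotation are
strand-symmetric operations.  A `GenomeLayout` (chrom.sizes) is the
coordinate authority; intervals overhanging a chromosome are an error by
default (`clip=True` truncates), and unwanted chromosomes (e.g. chrY, which
is routinely excluded from female-derived cell-line cistromes) are removed
with an explicit `drop_chroms` filter rather than hard-coded.

## Consensus voting

Each input peak set is collapsed (merging overlapping and book-ended
intervals) before voting, so one dataset contributes at most one vote per
position; without this, a set with internally overlapping records would
dominate the count.  The vote is a sweep over interval boundary events,
producing a step function of depth per chromosome; the consensus at
threshold τ is the set of maximal runs of depth ≥ τ, each scored with the
maximum depth inside the run (the natural per-interval reproducibility
summary; no minimum run length is imposed by default).  Fractional τ is
resolved as ceil(fraction × n): the conservative majority reading of
"75% of the inputs" (4 studies → 3, 6 → 5).  τ=1 reproduces the collapsed
union and τ=n the per-base intersection, which the tests verify against a
per-base bitmap oracle on toy chromosomes (≤ 100 kb) alongside τ-nesting
and permutation invariance.

The hierarchical build runs three chained votes: per study, all replicates
must agree (τ = n_replicates); per experimental context, a configurable
fraction of study cistromes must agree (default 0.75); the reference is the
τ=1 union of context cistromes.  Co-occurrence classes Ck then partition
the reference by the number of context cistromes overlapping each site
(≥ 1 bp by default; configurable).  Overlap annotation against independent
feature groups uses a per-group replicate-support rule: a site is a hit iff
it overlaps at least `min_support` of the group's replicate sets (e.g. two
of three chromatin-interaction-anchor replicates; all replicates for
copy-number calls).

## Background calibration

The empirical null re-places every interval uniformly at random on its own
chromosome with its length preserved (the behaviour of `bedtools shuffle
-chrom`); shuffled intervals may overlap within a set and are collapsed
before voting, like real inputs.  For each replicate the full consensus is
rebuilt at every τ and the interval and bp counts recorded; the output
table contrasts observed counts with the random mean, SD, and 5%/95%
quantiles per τ.  The choice of τ from this table is deliberately left to
the user: the table quantifies the false-positive side (random collisions)
while the false-negative side depends on how heterogeneous the real inputs
are.  Replicate seeds derive from the master seed by a counter scheme
(`default_rng([seed, replicate])`), so any replicate is independently
reproducible and prefixes agree across different `n_reps`.

## Signal extraction and normalization

Windows of ± `half_window` (default 5 000 bp) are anchored at the site
midpoint floor((start+end)/2) and fractioned into `bin_size` (default
50 bp) bins — 200 bins per site at defaults.  Reads are assigned by their
placement midpoint by default (`fiveprime` available); a read at position
p falls in bin (p − window_start) // bin_size, half-open on the right.
Sites whose window would cross a chromosome end are dropped (with a logged
count) rather than zero-padded, so the row universe stays identical across
experiments.  A single-window variant (± 200 bp) returns per-site counts
and their mean for intensity comparisons across conditions.

Size factors are the median of per-row count-to-geometric-mean ratios.
Rows containing any zero are excluded from both the geometric mean and the
median (the convention of the count-based differential methods this
estimator comes from); an optional pseudocount includes them instead.  The
geometric mean is computed in log space for overflow safety, equal to the
direct product form within 1e-12 on feasible inputs; the median over an
even number of rows is the mean of the two central order statistics (taken
in linear, not log, space).  Exact algebraic fixed point: the size factors
of a normalized matrix are all equal (each equals the geometric mean of the
original factors), asserted to 1e-10 in the tests.

The two-step strategy first normalizes each factor's datasets jointly
across contexts and averages the normalized profiles within each context
(making one factor comparable between contexts), then normalizes the
per-factor averages within each context (making factors comparable inside a
context).  A factor or context with a single column skips its scaling step
with a warning rather than failing.

## Co-occupancy correlation

Per site, Pearson r between the site's bin vector in the reference factor's
normalized profile and in each candidate cofactor's, computed on
context-matched profiles.  Sites where either vector is constant carry no
shape information; they are excluded from class means (not zero-imputed,
which would bias means toward 0 for empty windows) and counted.  Class
summaries are arithmetic means of defined r.  Site ranking averages r
across a chosen cofactor subset, sorts descending with stable ties (input
site order), and labels quartiles Q1 (top) … Q4.  A concatenated mode (one
r over all bins of all sites) exists for diagnostics; the per-site-then-
average form is the default because it weights every site equally
regardless of signal magnitude.

## Chromatin-state overlay

Segmentations are validated as non-overlapping labeled partitions.
Majority assignment labels a site with the state covering most of its bp,
ties broken to the lexicographically smallest label (deterministic, and
indifferent in practice since ties are measure-zero for real segmentations);
sites with no segmented bp get `unsegmented`.  Enrichment is bp-weighted
(observed fraction / state genome fraction); Z-scores standardize the
ratios across states within each feature row using the sample (n−1) SD, so
a row reads as "which states are enriched or depleted for this feature".
With fewer than two distinct ratios the Z row is undefined and flagged
(e.g. a feature drawn exactly proportionally to state sizes).  Per-site
counts (via majority assignment) are reported separately from bp-weighted
enrichment, since subset composition figures conventionally use site
fractions.

## Synthetic study conditions

The generator plants every kind of structure the toolkit is meant to
recover, with defaults chosen once as the package's benchmark conditions:

* genome: 3 chromosomes × 1 Mb — large enough that same-length shuffled
  intervals essentially never stack to full depth, small enough for
  per-base oracles;
* truth cistrome: 500 non-overlapping sites of 200–400 bp (typical
  point-source peak widths);
* studies: 8, each detecting a truth site independently with probability
  0.9, boundaries jittered by N(0, 20 bp), plus 100 uniform noise peaks —
  so recovery at τ=6 follows the Binomial(8, 0.9) tail P(X≥6) ≈ 0.962;
* signal: per-site Gaussian bump (σ = 8 bins, amplitude 20 ± 50% across
  sites) on a baseline Poisson mean of 15, scaled by planted size factors
  (1.0, 2.5, 0.4) — every scaled mean stays ≥ 5, keeping zero bins rare so
  the zero-exclusion rule removes almost nothing; cofactor-like experiments
  share the bump, null factors are flat;
* segmentation: 1 kb blocks cycling through 5 states; features drawn from
  the planted state with probability 0.8, uniformly otherwise.

What the generator does *not* emulate: GC and mappability bias, fragment-
length effects, duplicate reads, broad/multimodal signal domains, and
correlated noise between studies.  Passing tests therefore demonstrate the
estimators' correctness and statistical behaviour under their stated
assumptions (unimodal signal, independent studies), not robustness to every
artifact of real libraries — on real data the background calibration and
the replicate-support rules are the guards against such artifacts.

Problem sizes in the test-bench (200 random oracle instances, 50–500
planted sites, 100 shuffle replicates) were chosen as the smallest sizes at
which the statistical tolerances quoted above are meaningful.

## Numerical and degenerate-input choices

* Collapse before every vote; idempotent; book-ended intervals merge under
  the half-open convention.
* Inconsistent chromosome universes across input sets are an error unless a
  layout defines the universe or `permissive=True`.
* `normchip` with a single experiment or with no all-positive row raises
  with an actionable message (pseudocount suggestion).
* Shuffling with an exclusion mask uses rejection sampling capped at 1 000
  attempts per interval, then errors.
* All randomness flows through `numpy.random.Generator` seeded explicitly;
  every simulation output and every plan-runner output is byte-identical
  across reruns for a fixed seed (manifests carry no timestamps).

## Known limitations

* The consensus vote operates on positions, not peak identities: adjacent
  peaks from different inputs can chain into one consensus run if they
  overlap pairwise.
* Correlation is descriptive (no p-values, no multiple-testing layer), as
  appropriate for ranking candidate cofactors rather than testing them.
* Enrichment Z-scores standardize across states within a feature; the
  column-wise reading (across features within a state) is a different
  question and is available by transposing the feature/state roles.
* The signal model targets unimodal, point-source profiles; broad marks
  (e.g. large heterochromatin domains) violate the shared-bump assumption.
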