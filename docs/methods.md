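# Methods

`recombpast` asks whether the *history* of recombination at a locus — not
just its long-term average — can be recovered from a sample of present-day
DNA sequences. The answer is assembled from four parts: a coalescent
simulator in which the recombination rate changes through time, a suite of
recombination-sensitive summary statistics, an n-tuple subsampling
bootstrap that converts one dataset into a distribution of summaries at
different time depths, and discriminant-analysis classification of loci
into recombination-history models. Closed-form coalescent results bound
what any such method can achieve.

## Rate trajectories

A trajectory r(t) gives the locus-wide recombination rate
(events/bp/generation) at time t generations *before present*. Four shape
families are supported, each in increasing- and decreasing-toward-present
variants:

| shape       | unnormalized curve u(t)                              | curve parameter defaults |
|-------------|------------------------------------------------------|--------------------------|
| constant    | 1                                                    | —                        |
| linear      | t or (T − t), pinned to zero at one end of the window| —                        |
| exponential | exp(±λt)                                             | λ = 5×10⁻⁴ /gen          |
| logistic    | K·N₀·e^{±gt} / (K + N₀(e^{±gt} − 1))                 | K = 100, N₀ = 1, g = 9×10⁻⁴ /gen |

Each curve is multiplied by a constant so that its time-average over the
change window [0, T] (default T = 10⁴ generations) equals the mean rate
r̄ (default 3.75×10⁻⁸): the **equal-total-recombination constraint**. Only
the apportionment of recombination through time distinguishes the models.
Beyond the window the rate is held at its ancient-end value r(T); this
keeps the deep-past contrast between models (a linearly-increasing locus
had *no* recombination before the window) while keeping every rate
finite. The "constant low/high" models used in the four-model test are
constants at 15% and 85% of the linear model's maximum (2r̄), i.e.
0.3r̄ and 1.7r̄.

Two genuinely open choices, resolved as follows: the linear trajectory is
pinned at zero (a positive floor would change the low/high constants),
and N₀ = 1 is read as the logistic curve's initial size in the standard
notation.

## Coalescent simulation with time-varying recombination

The simulator runs Kingman's n-coalescent with recombination backward in
time over an ancestral recombination graph. The trajectory is discretized
into piecewise-constant epochs (default 20-generation step, matching the
time-series grid); within an epoch all rates are constant and the
competing exponential clocks are sampled exactly, with draws that
overshoot an epoch boundary discarded and redrawn from the boundary
(exact by memorylessness). In coalescent units of 2N generations:
coalescence at rate k(k−1)/2 among k lineages, recombination at rate
(ρ/2)·span per lineage — span being the breakable length between the
lineage's outermost ancestral material, trapped material included (ms
convention) — and infinite-sites mutation as a Poisson process at rate
θ/2 per unit time per unit length, with ρ = 4Ne·r·L and θ = 4Ne·μ·L.
Defaults (Ne = 10⁴ diploid, n = 100 haplotypes, L = 10 kb,
μ = r̄ = 3.75×10⁻⁸, hence θ = ρ = 15) emulate a generic human-like deme
at a strongly recombining locus.

Ancestral segments carry the set of sampled leaves below them as a
bitmask; a stretch whose carriers reach the full sample has found its
marginal MRCA and is dropped, so the simulation terminates when no
ancestral material remains. Mutations are laid down afterwards on
"branch pieces" (a lineage's constant-segment lifetime between two
events), each mutation flipping exactly the carriers recorded for the
segment it hits, which guarantees every emitted column segregates.
Sampling a locus at a past time point τ simply evaluates the trajectory
at τ + t.

Calibration is enforced by tests: mean S matches Watterson's θ·Σ1/i; the
S, π and Rmin distributions agree with msprime at ρ ∈ {0, 15}
(two-sample Kolmogorov–Smirnov, α = 0.001); mean S is invariant to the
trajectory's shape; and the number of recombination events in the graph
scales with the rate. Not modelled: gene conversion, selection and
transmission distortion, demographic change, migration, and fine-scale
spatial rate variation within the locus (the rate is uniform along the
10 kb at any instant).

A per-replicate event cap of 10⁷ guards against runaway
parameterizations; exceeding it raises rather than truncating. Random
streams derive from (seed, replicate index), so any replicate can be
regenerated alone.

## Summary statistics

Nine statistics per dataset: S (segregating sites — the negative
control, its mean independent of recombination), Rmin (Hudson–Kaplan
four-gamete bound: the maximum number of pairwise-disjoint open intervals
between incompatible site pairs, greedy scan by right endpoint), rmmg
(Myers–Griffiths haplotype bound max(0, H − S − 1), applied to the whole
locus rather than composited over subintervals), nHaps, HapDiv
(sample-corrected haplotype heterozygosity), Wall's B and Q (congruent
*adjacent* segregating-site pairs; Q's partition count A follows the
congruent-pairs-only reading of the original definition), Hudson's C,
and ZnS (mean pairwise r²).

Rmin and rmmg both bound the *true* number of recombination events from
below, and neither dominates the other in general: a matrix with many
distinct haplotypes over few sites can push the haplotype bound above the
four-gamete bound (six haplotypes over three sites force at least two
events the four-gamete test cannot see). On coalescent-generated data at
this study's diversity levels the haplotype bound is almost always the
smaller of the two — and provably cannot exceed the four-gamete bound
within a quartet.

**Hudson's C.** The estimator equates the observed variance S²_k of the
n(n−1)/2 pairwise difference counts (divisor = number of pairs) with its
expectation and solves for the locus-wide ρ. The expectation used is

    E[S²_k] = θ·2(n−2)/(3(n−1)) + θ²·F(C)·(n−2)(7n+3)/(9n(n−1)),

with θ̂ = mean pairwise difference and
F(C) = (2/C²)·∫₀^C (C−x)(x+18)/(x²+13x+18) dx, the average correlation of
pairwise coalescence times across the locus. The construction is exact at
C = 0 (it reduces to the classical moments of pairwise differences,
E[S²_k] = Var(K_pair) − Var(k̄)) and damps the θ² component by the
two-locus covariance for C > 0; F is evaluated in closed form (roots of
x²+13x+18, i.e. √97), with a series below C = 0.01 to avoid cancellation.
E[S²_k] is monotone decreasing in C, so the root is found by bisection
(tolerance 10⁻⁶), clamped to 0 when the observed variance exceeds the
C = 0 expectation and to C_max (default 150 = 10× the simulated ρ) when
it falls below the expectation there.

**Undefined values.** Statistics with vanishing denominators (Wall's B
and ZnS at S < 2, Wall's Q at S = 0, all S-scaled values at S = 0) are
NaN, and downstream aggregation skips them instead of zero-filling —
young quartets are frequently monomorphic, and substituting zeros would
bias their feature distributions. The *scaled* suite divides the eight
recombination summaries by S, a proxy for subsample age (older subsamples
carry more mutations *and* more detectable recombination); scaling is
division, with multiplication available as a configuration choice.

## n-tuple subsampling and features

From each dataset, `n_subsamples` subsets of `tuple_n` haplotypes are
drawn independently and uniformly without replacement within a draw
(duplicates across draws allowed; sites monomorphic within a subset are
dropped). The feature vector is the mean, unbiased variance and maximum
of each of the 9 unscaled and 8 scaled summaries over the draws — 51
features — plus per-statistic defined counts for diagnostics. A single
defined value yields variance 0; an empty set yields a missing feature,
imputed later with the training-fold feature mean.

## Classification

LDA (pooled covariance) and QDA (per-class), uniform priors (all designs
are balanced), implemented over scikit-learn with mean-imputation and
standardization fitted inside each training fold only. Accuracy is
jackknife (leave-one-out) cross-validation: each dataset is assigned by a
model trained on all others. Ties break to the earliest declared label.
LDA is the default; on this task it classifies at least as accurately as
QDA, consistent with its better behaviour when class covariances are
similar and training sets moderate.

## Theory

For m sampled lineages, E[T_i] = 2/(i(i−1)) and Var[T_i] = E[T_i]² in
units of N generations (haploid; 2N for autosomes) — the final two
lineages take on average half the tree height, so old recombination is
recorded by very few branches. The probability that a subsample of n
spans the basal split is (n−1)/(n+1) averaged over trees, and
1 − [C(a,n) + C(b,n)]/C(a+b,n) for a fixed split (a, b); all subsamples
spanning the root see the *same* two deep branches, which bounds the
information recoverable about the oldest events. (The printed source for
the variance formula is garbled; it is implemented as the exponential
mean-squared identity.)

## Experiment scales

The full design uses 10⁴ datasets per model with 10³ quartets each and a
time-series grid of 500 × 20-generation intervals at 10⁴ replicates. The
package's **desk scale** — 300 datasets per model, 200 subsamples, an
n-tuple sweep over {4, 20, 50, 77, 96}, and time-series grids of ~40
points at 250 replicates — keeps a complete run on one CPU within
minutes while preserving the qualitative structure (subset ordering,
lag behaviour); assignment accuracies at this scale carry roughly ±5
percentage points of combined Monte-Carlo and training-set-size
uncertainty, and the paper-scale design remains available through
`ExperimentConfig`. Leave-one-out refits are performed in full (no
downdating) at this scale.

The correlation study pools equal numbers of datasets per model and
correlates the *per-dataset full-sample* summaries; matrices with and
without S, and for the scaled suite, are all reported, with zero-variance
summaries (rmmg barely varies under these conditions) returned as
missing. The local-regression smoother used for presentation is a
degree-2 weighted polynomial fit under the cubic-spline (SPH) kernel with
a bandwidth equal to the 50%-nearest-neighbour distance plus 10% of the
data range; it is exact on quadratics and is never used for inference.

## Known limitations

* The simulator is a research implementation in Python: exact but not
  tuned for very large ρ or sample sizes (cost grows with the number of
  ARG events).
* Hudson's C follows the moment construction above; published
  implementations of the 1987 estimator differ in conventions (variance
  divisor, caps, numerical solution), and values on real data should be
  compared within one convention only.
* The synthetic data emulate a single panmictic constant-size deme with
  complete, phased, error-free haplotypes and infinite-sites mutation.
  Real data add demography, structure, phasing error and missingness,
  all of which can mimic or mask recombination-rate change, so passing
  tests here demonstrate feasibility under idealized conditions, not
  field-ready power.
* Classification accuracy depends on the subsample count and training-set
  size; desk-scale accuracies are reproducible but sit a few points from
  the full-scale design's values.
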