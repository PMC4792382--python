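# Methods

`sweepshape` classifies large genomic windows as centred on a hard selective
sweep, centred on a soft sweep (selection on a single standing variant),
linked to either kind of sweep, or neutrally evolving.  This note records the
model, the simulation machinery and its approximations, the numerical
choices, and what the package's tests do and do not establish.

## The classifier

A window is divided into 11 adjacent, equally sized subwindows.  In each
subwindow nine summary statistics are computed: π (mean pairwise diversity),
Watterson's θ̂_W, Fay & Wu's θ̂_H, the number of distinct haplotypes K,
haplotype homozygosity H1 = Σp_i², H12 = (p₁+p₂)² + Σ_{i>2}p_i², H2/H1 =
(H1 − p₁²)/H1, Kelly's Z_nS (mean pairwise r² over sites), and ω_max (the
maximised ratio of within-flank to cross-flank r² over all split points).
Each statistic's 11 values are divided by their sum,

  x_i ↦ x_i / Σ_j x_j ,

so the 99-element feature vector records only the *shape* of each
statistic's spatial curve, not its magnitude.  This is the property that
buys robustness to demography: population-size history shifts the levels of
diversity genome-wide but perturbs the spatial pattern around a sweep far
less.  Tajima's D is computed as a diagnostic but deliberately excluded
from the features (it is signed, and the normalization assumes nonnegative
values).

Classification uses an extremely-randomized-trees ensemble of 100 trees.
Hyperparameters (max_features ∈ {1, 3, √F, F}; max_depth ∈ {3, 10, ∞};
min_samples_split ∈ {2, 3, 10}; min_samples_leaf ∈ {1, 3, 10}; bootstrap
on/off; Gini vs entropy) are chosen by 10-fold cross-validated grid search
on mean accuracy; classes are balanced by construction so accuracy is
unambiguous.  Posterior class probabilities are the ensemble's soft-vote
fractions.  The five classes are assembled from simulations as: hard and
soft = sweeps centred in the middle subwindow; hard-linked and soft-linked
= sweeps centred in any of the ten other subwindows (a sweep even one
subwindow off-centre counts as linked); neutral = no sweep.

## Coalescent simulations

Training and test data are simulated with msprime over a unit-length locus
with locus-wide scaled rates θ = 4N·u·L and ρ = 4N·r·L.  Defaults follow the
study design: 100 sampled chromosomes; equilibrium per-subwindow θ = 50 and
ρ = 80 (locus 550 and 880) at N = 10,000; sweep strength α = 2Ns drawn
uniformly from a configured range (s here is the heterozygote advantage;
msprime's convention, with genotype fitnesses 1, 1+s/2, 1+s, makes
s_msprime = α/N); fixation time τ ~ U(0, 0.2N) generations at equilibrium;
soft-sweep onset frequency f ~ U(0.05, 0.2) at equilibrium and
U(2/(2N), 0.2) under the non-equilibrium models.

Five demographic histories are built in: equilibrium; an African human
model (exponential growth from 14,474 to 424,000 beginning ~5.1 kya, deep
history 7,310 until 148 kya); a European human model (out-of-Africa
contraction to 1,861 at 51 kya, second contraction to 1,032 at 23 kya, slow
growth to 9,300 by 5.1 kya, then fast growth to 512,000); and mild/severe
three-epoch bottlenecks (contraction to 29% or 2.9% of N at 0.044×2N
generations ago, recovery at 0.0084×2N).  Generation time for year
conversions is 25 years.  Human-model θ and ρ are drawn per replicate from
truncated normal priors (CV 0.2, truncated to [0.5×, 2×] the mean) whose
means correspond to μ = 1.2×10⁻⁸ and r = 1×10⁻⁸ per bp per generation over
11 × 200 kb; the prior shape and truncation bounds are this package's own
choice, made once. Sweep fixation times for the human models are uniform
over the growth phase (≤ ~5.1 kya African, ≤ 51 kya European); bottleneck
sweeps use one of the presets {0, 0.022×2N, 0.044×2N} generations.

### Sweep machinery and its approximations

A sweep simulation has up to four stages, all stitched through msprime tree
sequences:

1. τ generations of neutral history under the true demography.
2. The sweep phase proper: msprime's structured-coalescent sweep model,
   from frequency 1−1/(2N) back to the onset frequency (1/(2N) for hard
   sweeps, f for soft).  msprime cannot change population size during this
   model, so the size is held constant at the harmonic mean of N(t) over
   the expected (deterministic logistic) sweep duration, solved
   self-consistently; if the realized stochastic duration outruns the
   reserved window the simulation is retried with a doubled buffer.
3. Soft sweeps only — the standing-variation drift phase, which msprime
   cannot simulate at all: lineages still ancestral at the selected site
   (they necessarily carry the derived allele) are evolved under a
   structured coalescent restricted to the derived class.  The class-size
   path f(t) is a conditioned Wright–Fisher jump process from f down to the
   allele's origin (simulated at a rescaled size of ≤1000 and stretched
   back, exploiting the diffusion limit's scale invariance).  Pairs
   coalesce at rate k(k−1)/2 · 1/(2N f(t)) per generation; recombination at
   the per-generation map rate splits a lineage at a uniform breakpoint and
   the side not carrying the selected site escapes to the neutral
   background.  The race is simulated in virtual drift generations but
   recorded compressed into an infinitesimal interval above the sweep
   onset, so the neutral background resumes immediately — otherwise every
   other lineage would idle for the drift duration and accumulate spurious
   mutations.  The mutations the sweeping haplotypes themselves accumulate
   during those virtual generations are restored explicitly: each
   lineage's material-length × duration exposure feeds a Poisson draw of
   biallelic sites attached to that lineage.
4. The deep neutral history, resumed by msprime from the resulting tree
   sequence under the original (unflattened) demography.

Consequences worth knowing: (i) the compression shifts deep history
recentwards by the drift duration, slightly reducing total tree height —
largely cancelled by the shape-only normalization; (ii) escaped flank
material does not coalesce during the virtual drift window; (iii)
ancestral-background lineages cannot recombine *onto* the sweeping
background; (iv) the drift-phase class size uses a harmonic-mean population
size rather than the instantaneous N(t).  In the limit f → 1/(2N) stage 3
vanishes and soft sweeps reduce exactly to hard sweeps; the test suite
verifies this convergence, the neutral moment identities
E[π] = E[θ̂_W] = E[θ̂_H] = θ, diversity recovery with sweep age, and the
sweep-phase duration against a brute-force conditioned Wright–Fisher
forward simulation.

The standalone trajectory simulator (`simulate_trajectory`) uses
per-generation binomial updates under genic selection, rejection-conditioned
on fixation (and, for soft sweeps, a neutral drift segment conditioned on
reaching f), at the demography's reference size.

## What the simulations do and do not emulate

Simulated data are phased, perfectly polarized, error-free haplotypes with
every site accessible, under a single panmictic population and selection on
a single standing variant (no recurrent-mutation soft sweeps, no partial
sweeps, no background selection).  Passing benchmarks therefore demonstrate
that the method recovers sweeps *under its own generative assumptions* and
that the shape representation is robust to the demographic misspecification
scenarios tested — not that real data with phasing error, polarization
error, or uneven accessibility would classify equally well.  The genome-scan
module addresses the accessibility and polarization issues mechanically
(per-site normalization, outgroup agreement rules, >50%-masked frames
omitted) but inherits the other assumptions.

## Numerical and design choices

- Subwindow assignment is floor(position × 11), clamped to the last
  subwindow; a statistic whose 11 raw values sum to zero yields the uniform
  vector 1/11 (the shape is undefined; uniform is the least informative
  choice and keeps vectors finite).
- ω_max splits run over l ∈ {2, …, S−2} so both flanks always contain at
  least one within-flank pair; splits whose cross-flank r² sum is zero are
  skipped, and if all are skipped ω_max = 0.  Windows with S < 2 report
  Z_nS = 0; S < 4 report ω_max = 0.  Ties among equally frequent haplotypes
  leave H12 unchanged, so no tie-break rule is needed.
- LD statistics are O(S²); subwindows with more than 1000 segregating sites
  are thinned to 1000 (seeded, deterministic) for Z_nS and ω_max only.
- Feature order is frozen and versioned (`sweepshape-fv-1`); serialized
  models carry the tag and the scan refuses mismatched models.
- min_samples_split = 1 appears in older tree-library conventions but is
  not a legal split; the grid uses 2, which preserves the semantics.
- Real-data frames with any omitted subwindow are skipped entirely rather
  than renormalized over fewer subwindows, which would distort the shape.
- Sites whose ancestral state cannot be inferred (outgroups disagree, no
  outgroup aligned, or the inferred base matches neither human allele) are
  discarded from both the SNP set and the accessible-site denominator.
- The scan's subwindow grid is anchored at the start of the analyzed
  region; sample sizes differing from the training size trigger a warning
  but not an error (all statistics are frequency-based).

## Problem sizes for the benchmark reproduction

The acceptance pipeline (`scripts/acceptance.py`, shared with the test
suite) runs at desk scale, the package's own choice of problem size:
250 training simulations per class per selection range (weak α ~ U(25,250),
intermediate U(250,2500), strong U(2500,25000); soft f ~ U(0.05,0.2)),
200 independent test regions per condition, composite sweep-vs-unselected
test sets of 200 per side (proportioned 100/100 vs 67/67/66) whose
standing-variant sweeps draw f ~ U(2/(2N),0.2) — broader than the training
design, deliberately — and a 2-point "small" hyperparameter grid
(max_features ∈ {√F, F}, unlimited depth) with 10-fold CV; the full
432-point grid is available as `grid="full"`.  At these sizes
binomial noise on a call percentage is ±3 points and on an AUC around
±0.01–0.02, which is why the acceptance tests use ±5 points and ±0.03
respectively.

## Known limitations

- The drift-phase engine tracks only derived-class lineages; its
  approximations (listed above) have not been validated against discoal
  output within this package, only against internal limits and moments.
- Bottleneck-model benchmarks are implemented (models, presets) but are not
  part of the reproduced headline numbers.
- The ms-format reader assumes binary alleles and one mutation per site;
  multi-allelic records must be filtered upstream.
- Zygotic (unphased) LD, iHS/nS_L-type statistics and between-subwindow LD
  are not implemented.
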