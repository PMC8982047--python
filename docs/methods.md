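# Methods

This note documents the models implemented in `haplodfe`, the conventions
and numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the package's known limitations.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Model overview and assumptions

The method infers the strength of selection on a set of A unlinked loci
whose derived focal allele segregates at sample frequency f (all analyses
here use f = 1%), from the window-binned pairwise identity-by-state lengths
L among the n haplotypes carrying each focal allele.  Its assumptions:

- one panmictic population with piecewise-constant diploid size (epochs,
  most ancient first; the most ancient epoch is treated as open-ended);
- genic selection, genotype fitnesses 1, 1+2hs, 1+2s with dominance
  h = ½ by default, so the heterozygote effect is s and γ = 4Ns is the
  standard population-scaled coefficient (N is the most ancient epoch's
  diploid size; s is constant per generation, so the effective scaled
  coefficient changes across epochs with N);
- infinite sites within each locus; no gene conversion; all loci share the
  selection parameter (or draw it from a common DFE); haplotypes carrying
  the ancestral allele are ignored;
- IBS records are treated as independent in a composite likelihood;
  uncertainty therefore comes from a locus-level bootstrap, never from the
  curvature of the composite surface.

The dominance default is h = ½; recessive or dominant variants change the
conditional trajectory law and are exposed in `SelectionParams` but not
studied here.

A note on the fitness convention: with h = ½ the update
x′ = x(1 + s + 2s(1−h)x)/(w̄) equals the frequently used
(1, 1+sh′, 1+s′) parameterisation with s′ = 2s.  The (1, 1+2hs, 1+2s)
convention was chosen because it is what the standard forward
Poisson-Random-Field simulators use, making γ = 4Ns directly comparable
with the population-genetics literature.

## Allele-frequency trajectories

`simulate_prf` is a forward Wright-Fisher simulator under the Poisson
Random Field: Poisson(θ/2 · N(t)/N_ancient) new mutations per generation,
each starting at one copy, each evolving by binomial sampling around the
selection-adjusted expected frequency.  Burn-in defaults to 10·N_ancient
generations, enough for mutation-selection balance (verified in the tests
via the 1/i neutral frequency spectrum).

Conditioning on the present-day frequency draws a Binomial(S, x) sample
count per trajectory and retains those inside f ± tolerance.  Two additions
to that contract:

- a retained trajectory must hold at least n derived copies in the
  population (n carrier haplotypes are to be drawn from it).  With S ≪ 2N
  this clause almost never binds; at the desk scales used here S is
  comparable to 2N and the binomial count could otherwise exceed the
  population count.  The clause appears consistently in the conditioning,
  the importance-sampling proposal and the target density.
- the sign-symmetry of conditioned trajectories under constant N (equal
  age distributions for ±|γ| at the same frequency) is a *fixed-frequency*
  property: a loose binomial smear weights the deleterious and advantageous
  stationary frequency densities differently and visibly breaks the
  comparison.  The symmetry test therefore conditions through a large S
  with a tolerance band, which pins the population frequency tightly.

`sample_conditioned_trajectories` draws from the frequency-conditioned
stationary ensemble.  For constant N it exploits the PRF's site
independence: batches of single-mutation paths are simulated from one copy
and every (path, generation) visit is accepted with its binomial band
probability — the exact visit-weighted renewal ensemble, with no burn-in.
All visit probabilities are scaled down by a constant (`visit_thinning`,
default 0.2); the scale cancels from the ensemble but makes repeat
acceptances of one long-lived path rare, keeping draws nearly independent.
This sampler was validated against an exact computation (the age
distribution of an allele at count j is proportional to the j-step
transition mass from one copy, summed by transition-matrix iteration) and
against an independent visit-tally oracle.  For nonequilibrium models the
ancient epoch is burned in once and the short recent epochs are replayed
from advancing checkpoints of the ancient standing variation.

The analytic pairwise coalescent time uses the per-generation hazard 1/c_t
within the derived class (c_t = parental copy count going backward), with
certain coalescence at the origin; it is validated against a two-lineage
parent-choice simulation, and the conditional coalescent reproduces it
exactly at r = 0 (closed form P(L > d) = Σ_t P(T2 = t) e^(−2utd)).

Allele age is the trajectory length in generations; the neutral conditioned
mean matches the classical closed form −4N(x/(1−x))ln x.

## Importance sampling

Rejection sampling at the target frequency wastes almost all forward
simulation, so likelihood tables use backward proposals: the present-day
population count is proposed proportionally to Binom(S, x).pmf(k) over all
counts (covering the full support of the sample-count conditioning), and
the count walks backward under the time-reversed kernel of the stationary
neutral mutation-drift flux, q(y|x) ∝ (1/y)·Binom(2N_here, y/2N_back).pmf(x),
tabulated per population-size pair (a plain binomial backward kernel is
used above a size cap; the weights correct either kernel).  The reversed
kernel was chosen over the simpler binomial backward walk after the latter
produced heavy-tailed weights whose log accumulates a random walk in path
length; with the reversed-flux kernel neutral-target weights are nearly
flat and estimates match rejection sampling within Monte-Carlo error (a
dedicated test asserts this for a bounded trajectory functional and for
the window pmfs themselves).

The target density is the forward product: origination intensity ∝ N at
the origin generation, Wright-Fisher binomial transitions with selection,
and the binomial sampling mass of the recorded sample count; γ-independent
constants cancel in the self-normalised estimator.  One selection-free
proposal set serves a whole γ grid; each grid point gets its own weights
and effective sample size ESS = (Σw)²/Σw², and grid points with ESS below
a threshold (default 100) are masked, never silently reported.

## Conditional coalescent with recombination

Backward in time while the allele segregates, each lineage belongs to the
derived or the ancestral background (sizes: trajectory count and
2N(t) − count).  Lineages pick parents uniformly within their class, so
parent collisions give the exact discrete genealogy, including forced
multiple mergers as the count approaches one; at the origin the last
derived lineage's material transfers to the ancestral background and the
process continues as an unconditional coalescent, fast-forwarded with
geometric waiting times between events (clamped at epoch boundaries).

Recombination: per generation each lineage breaks with probability
r × (span), where the span runs from the focal position to the farthest
edge of its ancestral material; the piece on the focal side keeps the
lineage's background while the far piece rejoins the derived background
with probability x(t), else the ancestral one.  A breakpoint falling
between the material and the focal site switches the whole lineage's
background.  Events within a generation are thinned to at most one
coalescence per class and one break per lineage, resolved coalescence
first — per-generation probabilities are well below one in the regimes
simulated.  Only material inside [0, l] is tracked; segments whose carrier
set reaches the full sample have found their local common ancestor and are
dropped.

Mutations are laid down per branch segment with exposure batching: when a
lineage's material changes (or it terminates), Poisson(u × length ×
duration) mutations are placed uniformly on its segments, carried by that
segment's descendant set.  Positions are continuous (infinite sites);
export floors them to base pairs, keeping distinct float keys internally.

`window_probabilities` pools all C(n,2) pairwise lengths across `reps`
haplotype sets (default 100) in the direction(s) implied by the focal
position and returns the empirical window pmf.  The pooled pmf for a
left-end focal site and for a midpoint site are statistically
indistinguishable per direction; the desk-scale presets place the focal
site at the midpoint and use both directions.

## IBS statistics

Windows are half-open (prev, next] with an open-ended last window: a
length exactly on a boundary belongs to the lower window, and a pair with
no difference within the flank falls in window M via an infinity sentinel.
Distances are measured from the focal coordinate to the discordant site
(1-based inclusive when reading VCFs); at 50-kb-scale windows the ≤50 bp
ambiguity against the last-identical-site convention is immaterial.
Optional singleton masking removes, per locus, sites carried by exactly
one of the derived haplotypes before lengths are computed; it can only
push lengths outward (a tested invariant).  Sites with missing genotypes
in either haplotype of a pair are skipped as non-informative.  The record
count obeys ℓ = directions × Σ C(n_locus, 2) exactly.

## Selection likelihood

`build_table` evaluates the per-γ window pmfs with a
sampling-importance-resampling layer: one subset of trajectory slots is
resampled from the *mixture* of the per-grid-point resampling laws, its
window pmfs are simulated once, and every grid point reweights the same
subset.  This decouples the statistical trajectory count K from the
simulation budget and, more importantly, makes the Monte-Carlo noise
common across the grid so it largely cancels from likelihood differences —
the quantity the grid search consumes.  With flat weights and a budget of
K the construction reduces to the plain self-normalised average.

The composite surface sums record counts against log table pmfs; empty
estimated windows are floored at 1/(10·K·reps·C(n,2)) with a warning, and
flooring provably never changes the argmax when no observed window is
affected.  Ties break toward the smallest |γ|, then the negative sign
(conservative toward neutrality).  The default grid spans [−200, 200];
the DFE path uses unit spacing on the deleterious half-grid.  Loci with
heterogeneous recombination rates are assigned to the stratum table whose
r is nearest in log space, and stratum surfaces add; a grid point is
masked if any stratum's ESS fails the threshold.

## DFE of standing variants and of new mutations

The frequency-conditioned DFE is a gamma over deleterious |4Ns|,
discretized to unit bins centred on integers and tail-collapsed at τ
(default 200; the last bin absorbs the tail so normalisation is exact).
(α, β) are fitted by grid search; the default grids follow the published
convention that the shape is the small-valued parameter (≈0.2) and the
scale the large-valued one.  The fit identifies the distribution's mean
(α·β, after collapse) much better than α and β separately — they trade
off along a ridge.

The Bayes conversion to the new-mutation DFE uses three probabilities
estimated from forward PRF runs that share one accounting convention:
every mutation arising during the recorded horizon (8·N_ancient
generations by default, plus the recent epochs, from an empty population —
long enough to cover any 1%-variant age) counts in the denominator, and
"at f" means its present-day binomial sample draw lands in the band with
at least n population copies.  Because all three probabilities share the
convention, the horizon choice cancels in the conversion, and on shared
counts the conversion is an exact algebraic identity (tested).  Runs
extend adaptively until every probability rests on at least `min_hits`
at-frequency events; θ in these runs is a pure batching knob, since
per-site independence makes the probabilities θ-free.  The converted bins
are renormalised (Monte-Carlo noise breaks exact normalisation) and any
bin moved by more than 1% of total mass is flagged.  Only neutral or
deleterious effects are modelled; a signed DFE is out of scope.

Bootstrap intervals resample loci with replacement, keeping each locus's
full record block; replicates where the estimator fails are dropped and
more than 10% drops fail the run.  For the conversion experiment the band
additionally propagates the Poisson uncertainty of the simulation counts
behind the shared frequency probabilities
(`FrequencyConditionals.resampled`); without it, the band covers only data
resampling and systematically misses by the shared Monte-Carlo offset.

## ABC demography

Plain rejection: parameter draws from log-uniform priors on sizes and
uniform priors on times; the summary is the pooled window-proportion
vector of A neutral loci conditioned at f; Euclidean distance; the closest
quantile (default 5%) is accepted and posterior medians reported.  No
post-acceptance regression adjustment — the simplest defensible ABC, with
the summary, distance and quantile all configurable.

## Synthetic data and desk-scale study conditions

The generator *is* the study design.  Two preset scenarios mirror the
canonical 1%-variant studies at desk scale, rescaled so that the
population-scaled parameters are preserved (4Ns, θ and ρ are invariant
under N ↦ N/k, s,u,r ↦ k·s,u,r):

- constant size: N = 1,000 diploids; S = 2,000 chromosomes, f = 1%
  (20 carrier haplotypes); locus u = 4.4×10⁻⁷, r = 1×10⁻⁷ per bp,
  l = 125 kb, focal site at the midpoint; six windows of 10 kb per flank.
- expansion: 500 → 5,000 diploids ten generations ago (a ten-fold growth
  at 0.02·N_ancient generations, the canonical human-like scenario in
  scaled units), same sampling and locus parameters.

The window extent was chosen, as one would on real data, so each bounded
window captures an informative share of the pooled L distribution; the
per-bp rates give θ_locus ≈ 220, matching the canonical simulated-region
design.  The forward simulator's θ is 100.  Recovery experiments use
A = 100 loci per replicate and 20 replicates per condition; likelihood
tables use K = 4,000 proposals with ~700-slot resampled subsets and 3
haplotype sets per trajectory.  These sizes are the package's desk-scale
choices; they reproduce magnitude recovery for 4Ns ∈ {0, ±50, ±100} under
constant size (sign unidentifiable, estimates split across signs) and
signed recovery of ±50 after the expansion.

What the generator does not emulate: linked selection across loci,
variable mutation rate, phasing or calling error, ancestral-state
misidentification, gene conversion, population structure.  Passing tests
demonstrate internal consistency of the method under its own model at
desk scale, not robustness to those real-data complications (singleton
masking is implemented as the mitigation for calling error at rare sites).

## Known limitations and reproducible mismatches

- **Age-ratio magnitude.** The classical diffusion-theory contrast between
  neutral and strongly selected variants at 1% frequency is often quoted
  as an approximately 8-fold mean-age difference at 4Ns = 100.  An exact
  computation for the discrete Wright-Fisher model (transition-matrix
  iteration, no Monte Carlo) gives, under this package's sampling design
  (N = 1,000, binomial sample of 400 chromosomes) and its genic 4Ns
  convention, a ratio near 4.6 — and near 3.1 under the alternative
  homozygote-effect reading of s.  The simulators reproduce the exact
  values to Monte-Carlo precision, and the neutral mean age matches the
  Kimura-Ohta closed form, so the package reports the ~4.5-fold value it
  actually computes; reaching 8-fold would require an allelic effect twice
  the genic reading of 4Ns = 100, which no standard convention provides.
- **DFE<sub>f</sub> mean at desk scale.** The window-pmf gradient per unit
  of deleterious 4Ns is ~7×10⁻⁴ in the first window, and the 1%-frequency
  filter caps the conditional mean near 16 regardless of the generating
  DFE's scale, so the whole DFE<sub>f</sub>-mean signal (~0.01) is the
  size of a desk-budget likelihood table's Monte-Carlo error.  Replicate
  fits then collapse to grid corners systematically, and averaging cannot
  remove a shared table error.  The corresponding recovery test asserts
  the property honestly and fails at desk scale; making the table error
  negligible requires orders of magnitude more simulation (the full-scale
  analyses this design is based on budget ~10⁷ haplotype simulations per
  table).  The Bayes-conversion route, whose probabilities come from
  forward-simulation counts, recovers the new-mutation DFE bins well.
- Composite-likelihood surfaces are not confidence surfaces; only the
  locus bootstrap is offered.
- ESS is necessary, not sufficient: a gated grid point may still carry a
  poorly explored trajectory space, particularly for strong positive
  selection far from the neutral proposal.
- The coalescent simulator supports at most 62 carrier haplotypes per
  locus (bitmask carrier sets).
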