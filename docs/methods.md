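# Methods

## The estimation problem

`scrhybrid` estimates the population density of animals that cannot all be
individually recognized, from spatially referenced detection data.  The
common skeleton of every model in the package is spatial capture–recapture
(SCR): each animal *i* has a latent activity center *s_i*, and its
probability (or expected rate) of being recorded at detector *j* decays with
the Euclidean distance *d_ij* between the detector and the activity center
as a half-normal kernel,

    p_ij = p0 · exp(−d_ij² / (2σ²))        (probabilities)
    λ_ij = λ0 · exp(−d_ij² / (2σ²))        (rates),

where *p0* (or *λ0*) is the baseline at the activity center and σ is a
spatial scale parameter proportional to home-range size.  The unknown
population size is handled by parameter-expanded data augmentation: the
population is embedded in *M* pseudo-individuals with inclusion indicators
*z_i* ~ Bernoulli(ψ); activity centers are uniform over a rectangular state
space *S* of area *A*; abundance is N = Σ z_i and density D = N/A.

The variants differ only in their observation model:

| Variant | Data | Observation model |
|---|---|---|
| SC | counts of unidentified animals | n_jk ~ Poisson(op_jk · Σ_i z_i λ0 k_ij) |
| SPA | binary detections | y_jk ~ Bernoulli(1 − Π_i (1 − p_ij op_jk z_i)) |
| SMR | + identified resights of marked animals | marked: y_ijk ~ Poisson(λ0 k_ij op_jk a_ik); unmarked as SC with the marked set excluded |
| gSMR | + live-capture (marking) histories | marking: y_ij ~ Binomial(K, p0.marking k_ij z_i) |
| SCR | binary genetic detections in scat survey cells | y_ij ~ Bernoulli(p0_j k_ij z_i), one survey pass |
| hybrid | marking + camera resight/count + genetic | all of the above jointly, with shared z, s, σ |

Here k_ij is the half-normal kernel, op the trap-operation fraction and a
the availability indicator.  GPS telemetry enters any variant as
*fix_il* ~ Normal₂(s_i, σ²I) for collared animals, sharing σ with the
detection kernels.

Identity linkage in the joint model is by id equality across streams: a
captured animal must carry the same id in the marking, resight, genetic and
telemetry tables (physically captured animals are always genotyped, so the
genotype–collar correspondence is known).  Known individuals not encountered
by some method contribute explicit all-zero histories there, which is how
the joint model shares information on baseline detection parameters.  An
unmarked animal photographed and also genotyped cannot be deterministically
linked; camera counts of unmarked animals therefore always stay marginal
(summed over the non-marked included individuals), and no partial-identity
linkage is attempted.

## Priors

ψ ~ Beta(1,1); σ ~ Uniform(0, 20 000 m); p0 and p0.marking ~ Beta(1,1);
λ0.resight and λ0.marking ~ Uniform(0, 5) per occasion; s_i ~ Uniform(S).
With the survey-effort covariate on the genetic baseline,
p0_j = logit⁻¹(α0 + α1·effort_j); α0 has a standard-logistic prior (exactly
Beta(1,1) on logit⁻¹(α0), so the covariate-free model is nested with an
unchanged prior) and α1 ~ Normal(0, 2).  The effort covariate is entered in
raw kilometers; standardization made no structural difference at the effort
ranges simulated and is left to the caller.

The marking process is Binomial(K_marking, p0.marking·kernel) by default.  A
Poisson-rate form (λ0.marking·kernel·K) is selectable via
`ModelSpec(marking_poisson=True)`; the two appear interchangeably in the
literature on the marking submodel, and the binomial is the stricter choice
for capture histories that are 0/1 per occasion.

Group structure ("sex" or "status") gives every detection parameter and σ a
two-level index.  Labels are observed for handled (marked) animals and
optionally for genotyped ones; for the rest of the augmented population the
label is latent, g_i ~ Bernoulli(π) with π ~ Beta(1,1).  This sub-prior is a
design choice of the package: without it, group-specific parameters would be
undefined for the unobserved population segment.

## Sampler

The sampler is a bespoke Metropolis-within-Gibbs kernel (numba-compiled),
not a delegation to a general-purpose probabilistic-programming engine,
because the discrete inclusion indicators and the marginal unmarked-count
likelihood are the computational core of the method and need to be testable
against brute-force enumeration.

Per iteration: z_i is drawn from its full conditional for every augmented
individual (detected and collared individuals have z ≡ 1); ψ and π from
their conjugate Beta full conditionals; each activity center by a bivariate
Gaussian random walk whose per-individual scale adapts toward a 0.2–0.5
acceptance rate during burn-in only (frozen afterwards, preserving detailed
balance), with excluded individuals redrawn from the uniform prior (their
likelihood is flat in s); latent group labels from their two-point full
conditional; and each scalar detection parameter by a random walk on the
log (rates, σ) or logit (probabilities) scale with the appropriate Jacobian,
rejecting outside the prior bounds.

The marginal SC/SMR likelihood couples individuals through the detector
rate-sums T_j = Σ_i z_i λ0 k_ij.  These are updated incrementally inside the
z/s/g sweeps and rebuilt from scratch at the start of every scalar-parameter
block, so floating-point drift cannot survive one iteration.  Scalar
proposals recompute only the likelihood components the parameter enters.
The kernel's running log-likelihood is checked in the test suite against an
independent NumPy reference implementation of every component, at the exact
final chain state.

For validation the kernel also accepts finite grids for s, σ and p0
(independence proposals, uniform prior over the grid).  On a discretized
instance the model becomes exactly enumerable, and the sampled posterior
over N is required to match exhaustive enumeration to total-variation
distance < 0.02.

Initial values are dispersed across chains: σ near half the mean
nearest-neighbor detector spacing (jittered), activity centers at each
individual's detection centroid (telemetry mean when available), z = 1 for
all detected individuals and Bernoulli(½) otherwise.  An initial state with
non-finite joint density is redrawn (up to 100 times).  Defaults follow the
reference workflow: 3 chains × 50 000 iterations, 15 000 burn-in, no
thinning; convergence is gated on split-chain R-hat < 1.1 for every
monitored parameter, and `extend_until_converged` refits with doubled chain
length until the gate passes or the extension budget is exhausted (the
result then carries `converged=False`).

## Preprocessing rules

* Photo events within one station × species stream chain into an
  independent sequence when gaps are ≤ 30 minutes; sequences are timestamped
  at their first event.
* Camera occasions are half-open 14-day bins (default 10 occasions); an
  event on a bin boundary belongs to the later occasion.  Detections of a
  marked animal in occasions where it was unavailable (not yet collared, or
  dead) are discarded, not moved to the unmarked pool.
* Fractional trap operation multiplies the encounter rate (a camera
  functional m of 14 days scales the occasion's expected count by m/14);
  the binary case reduces to switching the occasion off.
* Scats aggregate to the centers of 1-km grid cells; repeated detections of
  one genotype in one cell collapse to a single binary detection; scats in
  unsurveyed cells are dropped with a log message.
* GPS tracks are subsampled uniformly without replacement to 100 fixes per
  individual to blunt temporal autocorrelation.
* Planar metric coordinates are required input; map projection is out of
  scope.

## Posterior summaries

For each parameter: mean, median, sd, equal-tailed 95% interval (BCI),
shortest 95% interval (HPDI, exactly ⌈0.95·n⌉ draws inside), CV = sd/mean,
and split-chain R-hat.  The posterior mode — the headline point estimate for
density — is computed by Gaussian KDE (Scott plug-in bandwidth) maximized on
a 512-point grid for continuous parameters, and as the modal integer (ties
toward the smaller value) for N; the mode estimator is a package choice, as
common reporting practice does not pin one down.  Density is reported per
100 km².  Adequacy checks warn when the 97.5th percentile of N exceeds
0.9 M, when the 97.5th percentile of ψ exceeds 0.9, and when the state-space
buffer is not larger than 2.5 × the posterior median σ.

Genotyping bookkeeping reports success percentages rounded half away from
zero, plus unique-individual and post-deduplication detection counts.

## Synthetic data

The generator draws from exactly the model above: uniform activity centers,
binomial live capture (animals with ≥ 1 capture form the marked set),
Poisson camera encounters split into identified resights (marked) and
summed unidentified counts (unmarked), Bernoulli genetic detection with the
logit-linear effort baseline thinned per scat by a genotyping success
probability *before* deduplication (mimicking laboratory failure order), and
bivariate-normal GPS fixes.  Event-level CSV streams (photo timestamps, scat
coordinates, capture and GPS tables) are emitted such that the
preprocessing pipeline reproduces the directly generated encounter
structures bit for bit; camera events within a station are spaced over an
hour apart so the 30-minute rule never merges them.

The reference scenario places N = 60 animals (15/100 km²) in a 20 × 20 km
state space with σ = 1500 m, λ0.resight = 0.3/occasion over 10 occasions on
a central 8 × 8 1-km camera grid, a 5 × 5 marking grid with K = 5 and
p0.marking = 0.2 (yielding roughly 6–12 collared animals), a 10 × 10 grid of
1-km scat cells with 1.5–2 km of search effort each (α0 = −2, α1 = 0.5,
genotyping success 0.9), and 100 fixes per collared animal.  A larger
`study_scenario()` mirrors the field design more closely (≈ 26 × 26 km,
90 cameras, 4-km² scat cells searched 6–8 km, and a 20% transient group
whose σ is 12× the resident value — transience is represented purely as a
larger home-range scale, not as drifting activity centers).

What the generator does *not* emulate: movement autocorrelation within GPS
tracks (fixes are iid), behavioral responses to traps, habitat-driven
density variation, open-population turnover, and misidentification.
Passing recovery tests therefore demonstrates correctness of the estimator
under its own assumptions, not robustness to their violation in field data.

## Validation scale and numerical choices

Validation runs use problem sizes chosen to make a 20-replicate study
practical on one core: augmentation M = 120 (twice the true N; the adequacy
checks stay silent), hybrid fits at 3 chains × 10 000 iterations with 3 000
burn-in, genetic-SCR fits at 3 × 4 000, and marked-model (gSMR) fits at
3 × 3 000.  At these sizes the 95% BCIs for density and σ cover the
generating values in ≥ 16/20 replicates, the hybrid density CV is below the
genetic-SCR CV in ≥ 15/20, and telemetry reduces the posterior sd of σ in
≥ 15/20 — the qualitative precision ordering expected when more data
streams share one latent structure.

Degenerate inputs: a positive count at a detector-occasion with zero
operation or availability is rejected at validation time (impossible under
the design); all-zero data are valid; constant chains report R-hat 1.0 with
a degenerate-variance warning; empty detector arrays contribute nothing to
the likelihood, which is what makes the cross-variant reduction identities
exact.

## Known limitations

* Group structure is limited to two levels (sex, or resident/transient).
* Density is homogeneous; no habitat covariates on the point process.
* Euclidean distance only; no ecological-distance kernels.
* The sampler is single-chain-serial; chains run sequentially on one core.
* σ is shared across detection methods within a group — a modeling
  assumption of the joint posterior, not a switch.
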