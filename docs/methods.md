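# Methods

## The task and its frequency structure

Each participant completes 8 blocks. In a block's test phase, previously
encoded objects (shown in the upper or lower screen half) and new distractors
receive an old/new judgment; an "old" answer triggers an up/down source
judgment. A test phase has 20 old and 10 new objects, so a full session
yields 80 trials per trial type (UP-old, DOWN-old, NEW). Answered trials
fall into a 3×3 frequency table — trial type (tree) × response category
(old&up, old&down, new). Missed trials (no response in time) are excluded
from the table and tallied per tree: the processing-tree model has no
no-response branch, and misses carry separate information (they are analysed
descriptively, not modelled). Rates computed from the table use *presented*
trials as the denominator, so a participant with misses can have
FA + CR < 100% on new items; this convention is what makes the published
style of accuracy table internally consistent.

## Discrimination indices

Item memory: `Pr = hit − FA` (Snodgrass & Corwin). Spatial memory:
`source Pr = (correct − incorrect) / 160`, with 160 = 8 × 20 the number of
source trials a perfect item-memory performer would face. The fixed
denominator removes the dependence of the source-trial count on item-memory
performance; it is exposed as a configurable design constant for other
designs. Source correct/incorrect counts include only true-old trials
answered "old" (the only trials on which a source prompt occurs).

The false-alarm asymmetry check reuses the perimetric VMA formula on counts
of "down" vs "up" source attributions for false alarms,
`(FA_down − FA_up)/mean × 100`. No closed form for this quantity is
standard; applying the same normalised-asymmetry index keeps it commensurate
with the perimetry VMA. It is undefined (None, never NaN) when a participant
has no false alarms.

## The dual-process source-item tree

Six probabilities: recollection `S_up`, `S_down` (object + position
retrieved jointly), familiarity `I_up`, `I_down` (item recognised without
its position), old-guessing `o`, and up-guessing `g`. A deliberate and
documented topology choice: **one shared `g` governs the source guess both
after successful familiarity and after an uninformed old-guess.** A source
answer is forced in both situations, and a design with 6 free category
probabilities cannot identify two separate guessing rates; the shared-`g`
source-item topology is the conventional, identifiable one and is consistent
with all parameter definitions used here.

The model is just-identified: the NEW tree gives `o` and `g` in closed form,
and each old tree then inverts to `(1−S)(1−I)` and `(1−S)I`. This moment
estimator is exact on noiseless proportions and serves as the independent
oracle for the numeric MLE, which maximises the multinomial log-likelihood
on the logit scale (L-BFGS-B, 10 seeded starts, moment estimate as the first
start, boundary clipping at 1e-9, ties broken by smaller parameter norm).
At an interior optimum the two coincide and G² at the MLE is ~0; raw moment
estimates outside [0, 1] are clipped and flagged.

## Latent-trait hierarchical model

Participant `i`'s parameter `p` on the probability scale is
`θ_ip = Φ(μ_p + β_p·x_i + δ_ip)` with `δ_i ~ N(0, Σ)` over the 6 parameters;
`x_i` is an optional binary covariate (e.g. sex), off by default in
synthetic runs. Priors: `μ_p, β_p ~ N(0, 1)` on the probit scale and a
scaled inverse-Wishart on `Σ = diag(λ) Q diag(λ)` with `Q ~ IW(I, df = 7)`
and `λ_p ~ U(0, 10)` — the common weakly-informative latent-trait defaults;
all hyperparameters are configurable.

The sampler is a bespoke Metropolis-within-Gibbs scheme that carries the
per-participant probit values `η_i = μ + β x_i + δ_i` as state:

1. `η_ip`: scalar random-walk Metropolis, vectorised across participants
   (full conditionals factorise over `i`);
2. a joint translation move per parameter shifting `μ_p` and all `η_ip`
   together — without it the group-mean direction only moves
   O(step/√n) per sweep and mixes an order of magnitude slower;
3. `μ` and `β`: exact conjugate multivariate-normal Gibbs updates;
4. `Q`: exact conjugate inverse-Wishart update on the scaled residuals;
5. `λ_p`: scalar Metropolis under the uniform prior.

Proposal step sizes adapt every 50 iterations toward ~44% acceptance during
burn-in and are frozen afterwards, so the post-burn-in chain is a valid
Markov chain. Default settings follow the study configuration (50,000
iterations, 10,000 burn-in, thinning 10); at least two chains are required
so that split-R̂ is meaningful, with R̂ < 1.05 the convergence rule. Chains
are seeded by spawning from a single seed; identical config + seed gives
bit-identical draws. Non-converged results are returned flagged, never
discarded silently. Reported group-level posteriors are the
inverse-probit-transformed group means `Φ(μ_p)`.

Posterior predictive checks: for each retained draw a replicate cohort is
simulated from the individual-level parameters (per-tree trial counts fixed
at the observed ones). T1 is the summed squared deviation between observed
and expected across-participant mean category frequencies; T2 the same for
the across-participant 9×9 covariance matrix, whose model expectation is the
between-participant covariance of expected frequencies plus the average
within-participant multinomial covariance. The exact distance (summed
squared deviation) is this package's documented choice; `p = P(T_rep ≥
T_obs)`, with values in (0.05, 0.95) indicating adequate fit.

Group differences subtract the older group's probability-scale group-mean
draws from the young group's, paired by index after a seeded shuffle (the
fits are independent, so any pairing is valid; shuffling removes accidental
alignment). Intervals are central (equal-tailed) 95% credible intervals —
the HPD/central distinction is unstated in the source convention, and
central intervals are reproducible without density estimation. Draw-count
mismatches are resolved by seeded subsampling of the longer set.

## Gaze quality control

Velocities come from symmetric differences (`numpy.gradient` over the
timestamp vector, one-sided at the ends). The per-axis dispersion estimate
is the median-based robust standard deviation `sqrt(median(v²) − median(v)²)`
familiar from microsaccade detection, and a sample is saccadic when
`(v_x/λσ_x)² + (v_y/λσ_y)² > 1` with `λ = 6` by default (configurable; the
classic velocity-threshold setting). Maximal runs of non-saccadic samples
become fixations with centroid coordinates; fixations under 100 ms are
removed. Fujii 2/4 grading uses fixation *centroids* (not raw samples):
stable if ≥75% fall within 2°, relatively unstable if not but ≥75% fall
within 4°, unstable — and excluded — below that. Boundary conventions:
distance exactly equal to the radius is inside; exactly 75% meets the
criterion (the rule excludes *strictly below* 75%). Multi-block recordings
are segmented per block and centroids pooled per participant before
classification.

## Perimetry geometry

Isopter points (meridian angle, eccentricity) are sorted by angle and joined
linearly into a polygon — by construction star-shaped about fixation, hence
simple; the validity check is defensive. The polygon is clipped against the
half-planes above/below the horizontal meridian (shapely; areas are shoelace
areas), giving upper/lower hemifield areas in deg², and
`VMA = (lower − upper)/mean × 100`. Linear interpolation between sampled
meridians means areas are inscribed-polygon approximations: a circle sampled
every 15° is ~1.1% small, every 5° ~0.13% — the error cancels in the VMA
ratio for similar hemifield sampling. Antisymmetry and scale invariance are
property-tested. The smallest stimulus isopter (I1e) is parsed but excluded
from VMA tables by default, matching the analysed isopter set (V1e, III1e,
II1e); per-eye values are reported separately with optional averaging.

## Synthetic data

`gen_cohort` draws each participant's probit-scale latent vector from the
group multivariate normal, transforms to MPT probabilities, draws per-trial
categorical outcomes per tree, applies an independent Bernoulli miss process
(default 2%), and spreads trials evenly over 8 blocks. Defaults are the
study conditions: 25 young / 20 older, 80 trials per tree. Default group
means echo the qualitative published pattern — a young−older `S_up` gap of
0.20, similar familiarity, slightly lower `o` in the older group — without
claiming to match unpublished posterior values; the default latent SD is 0.3
on the probit scale (≈0.12 on the probability scale near 0.5), a typical
interindividual spread for latent-trait MPT fits, with an identity latent
correlation. Realised per-participant multinomial counts are retained in the
ground truth, so tabulation can be checked for exact agreement.

What the generator does *not* emulate: item-level effects (no
pre-experimental source expectations, no counterbalancing structure),
serial-position or block-learning effects, realistic reaction times
(placeholder lognormal draws), and non-independent miss mechanisms. Passing
recovery tests therefore shows the estimation machinery is correct under the
model's own assumptions — not that real data satisfy those assumptions.

`gen_gaze` builds 1000-Hz streams as ~400-ms fixation epochs at
category-specific target offsets joined by 20-ms ramps; targets are chosen
so the classification is guaranteed even if adjacent epochs merge (averages
of neighbouring targets stay in the intended annulus). `gen_isopters`
scales lower vs upper radii to the target asymmetry
(`ρ = l²/u² = (2+v)/(2−v)`, `v = VMA/100`), adds small multiplicative radius
noise, and runs a short fixed-point calibration so the realised polygonal
VMA lands within 0.05 of target (feasible for |VMA| < 200).

## Problem sizes and numerical choices

Tests and the acceptance script run the hierarchical model with reduced
chains (5,000 iterations, 1,000 burn-in, thinning 5, two chains) on the
full 45-participant cohort — enough for R̂ ≤ ~1.01 and group-mean recovery
within 0.10 given the sampler's mixing moves; the package default remains
the full study configuration. Posterior predictive checks subsample at most
1,000 draws and require at least 100. Logit-scale optimisation clips
probabilities at 1e-9; likelihood terms use `0·log 0 = 0`. Probit
transforms use `scipy.special.ndtr`/`ndtri`, exact to machine precision on
the ranges used.

## Known limitations

- The hierarchical sampler is a general-purpose random-walk scheme; heavily
  boundary-concentrated data (near-zero category counts for most
  participants) mix more slowly and may need longer chains.
- With a single shared `g`, fits to designs where source guessing plausibly
  differs after familiarity vs uninformed guessing are not distinguishable;
  this is a property of the design, not the implementation.
- The moment estimator requires every NEW-tree category observed; aggregate
  tables from very small cohorts may need the MLE with random starts alone.
- Perimetry areas assume one radius per meridian (star-shaped fields);
  ring scotomas or split isopters are out of scope.
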