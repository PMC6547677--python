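# Methods

`dyadsync` implements a complete dyadic autonomic-synchrony analysis:
interbeat intervals (IBI) are cleaned and segmented, per-epoch sympathetic
(CSI) and parasympathetic (logRSA) indices are computed, converted to
residualized-change reactivity, and modelled with a lagged dyadic
multilevel model; per-dyad synchrony coefficients feed multivariate
affiliation models. A synthetic-dyad generator with known ground truth
exercises every stage. This note records the models, the defaults and why
they were chosen, and the limits of what the synthetic studies show.

## Signal processing

**QC rule.** Interval `k` is flagged iff `ibi[k] <= 0.6 * ibi[k+1]` — the
signature of a spuriously detected extra R wave, which turns one cycle
into two short ones. The rule is scale-invariant and never flags the last
interval. `merge_adjacent` correction sums a flagged interval with a
neighbour when the merged value lands within 20% of a local median taken
over intervals away from any flag; the successor is tried first, then the
predecessor. The predecessor fallback matters: a near-half split flags the
*second* fragment (the first fragment is not short relative to its twin),
so its true mate precedes it. Merging conserves cumulative duration
exactly.

**Segmentation.** Epoch `k` of an analysis window is the padded interval
`[30k - 12, 30(k+1) + 12)` seconds: 54-s inputs whose central 30 s tile
the window, matching index software that discards 12 s of filter
transient from each end. A beat belongs to a segment iff its terminating
time falls in the half-open window; margins come from the baseline and
recovery recordings, and a missing margin raises an error naming the
epoch.

**CSI.** The Poincaré plot of successive intervals `(IBI_n, IBI_{n+1})`
is rotated 45°; the longitudinal axis L is 4 SD along the identity, the
transverse axis T is 4 SD across it, and CSI = L/T. For a stationary
Gaussian series with lag-1 autocorrelation ρ, CSI = √((1+ρ)/(1−ρ)) — the
closed form the tests check (ρ = 0.6 → 2.0). Collinear point sets (T ≈ 0)
raise a degeneracy error rather than returning infinity.

**logRSA.** The IBI sequence is interpolated against beat end-times
(piecewise cubic by default; linear fallback), resampled at 10 Hz,
band-passed to 0.12–0.40 Hz, trimmed by 12 s per edge, and the natural
log of the remaining variance is returned. A pure sinusoidal modulation
of amplitude A gives logRSA ≈ log(A²/2). The band-pass is a zero-phase
4th-order Butterworth (`sosfiltfilt`): an FIR with a sharp 0.12 Hz edge
at 10 Hz would need more taps than the 540-sample segment provides, so
the IIR realization is used; its passband error and stop-band attenuation
are verified on analytic signals (in-band sinusoid recovered within 0.1
log-units; a 0.05 Hz tone suppressed by > 3 log-units). Values below −20
log-units are reported missing (numerically degenerate), as are segments
with fewer than 20 beats.

**Reactivity.** Residualized change: per branch, epoch indices are
regressed on the participant's baseline mean (same 54-s measurement
operator, computed over the 5-min baseline) pooled across the whole
sample; the residual is the reactivity score. Pooling across conditions
is deliberate — residualizing within condition would absorb the condition
effects the synchrony model is meant to estimate. Zero baseline variance
triggers a logged fallback to simple change scores.

## The synchrony model

Each dyad member serves in turn as the modelled outcome ("both directed
rows"). For target j with partner i:

    y_jt = b0 + ρ·y_j,t−1 + (β_sync + u_d)·y_it
           + β_T·Talk + β_C·Coop + interactions + ε_jt

with dyad-level random intercept and synchrony slope (unstructured
covariance; the parasympathetic specification adds a random lagged-own
slope), participant-level random intercepts, and AR(1) residual
correlation φ within each directed series. Conditions are coded +1/−1.
The lag is built at the 30-s epoch level within each series; the first
epoch is dropped.

Estimation is profiled maximum likelihood (so likelihood-ratio tests
across nested random structures are valid): fixed effects are solved by
GLS inside each covariance evaluation, covariance parameters live on
unconstrained scales (log SDs, atanh correlations and atanh φ) and are
optimised by L-BFGS-B with a Nelder–Mead polish; clusters sharing a
layout are processed as one batched linear-algebra call. Fits agree with
R `nlme::lme` (ML) to ~4 decimal places on shared fixtures; one test
keeps that cross-check alive.

**Inference conventions.** Denominator df follow the between-within
rule: a term gets the df of the innermost grouping level at which its
column varies (condition terms: 67 − 1 − 3 = 63 on the full design;
epoch-level terms: 1206 − 134 − 6 = 1066, with the intercept counted at
the innermost level). Partial effect sizes are r = t/√(t² + df), signed
like t. Wald CIs for fixed effects use t quantiles at those df.
Variance-component and φ intervals use profile likelihood for a single
headline fit; replication studies use Wald intervals on the transformed
scale from the observed information, which are far cheaper. Estimated
marginal reactivity means per condition cell are linear combinations of
the condition coefficients (at synchrony = lag = 0) with condition-level
df.

**Cluster-robust intervals.** Both directed series of a dyad are built
from the same two people, and symmetric coupling forces their residuals
to correlate (see below); the working model ignores this, so
information-based standard errors are optimistic (measured coverage
0.83–0.91 at nominal 95% in the replication study). The package
therefore also provides a clustered sandwich covariance over the joint
(fixed-effect, covariance-parameter) vector — CR1 meat with the
J/(J−1) correction and t(J−1) quantiles — and the replication studies
validate those intervals instead. Reported model tables keep the
conventional model-based SEs for comparability with standard mixed-model
output.

**Random-slope LRT.** Removing the dyad-level synchrony slope removes
its variance and its covariances with the remaining dyad-level effects:
2 parameters for the sympathetic specification, 3 for the
parasympathetic one. The χ² reference is used without a boundary
mixture correction (conventional in this literature); see the caveats
below for how far that reference can be trusted on dyadic panels.

**Pseudo-dyad surrogate.** Participants are re-paired uniformly at
random, never with their true partner, within sex × condition strata
(single-dyad strata are skipped with a warning); the model is refit and
the slope-variance LRT recorded per re-pairing, with the distribution
over many re-pairings reported rather than a single draw.

## The affiliation models

The three outcomes (perceived similarity 1–7, friendship interest 1–7,
negative affect 1–5) are stacked into one long response. Each outcome
gets a full fixed-effect set — conditions × reactivity × synchrony up to
the 4-way product, predictors on their natural scale — its own residual
variance, and a dyad-level random intercept; the three intercepts may
correlate (unstructured 3×3), which is what makes the model
multivariate. Non-convergence of the unstructured structure falls back
to diagonal with a flag. These models are estimated by REML: with 48
fixed effects in ~400 rows the ML variance bias (factor (n−p)/n ≈ 0.88)
makes every fixed-effect test anticonservative (measured null type-I
~0.09 under ML vs the nominal 0.05), and no variance-component LRT is
run on this model family, so REML costs nothing. The synchrony model
stays on ML because its random-structure LRTs require it. The dyad-level synchrony coefficient
(fixed slope + BLUP deviation) is attached to both members; reactivity
is each member's own mean. On the complete design the between-within
rule yields 402 − 67 − 48 = 287 df for every outcome-specific term.

Simple effects are probed at each requested condition (±1) crossed with
reactivity and synchrony at mean ± 1 sample SD; non-probed condition
factors are averaged (set to 0). Pairwise contrasts within the probed
family are Tukey-adjusted via the studentized range,
p = P(Q_{k,df} > √2·|t|), which reduces exactly to the two-sided t
probability at k = 2. Only adjusted p-values are reported.

## The synthetic-dyad generator

Defaults are the emulated study's conditions: 67 dyads in a 2×2
between-dyad design (cell counts 16/16/15/20, ~70% female pairs), ten
30-s task epochs after a 5-min baseline, β_sync = 0.30, σ_sync = 0.20,
ρ = −0.25, φ = 0.50, residual SD 0.805, condition shifts
(talk 0.20, coop 0.14, talk×coop 0.035). Coupling moderation by
condition defaults to zero (none was observed in the emulated design).

**Construction.** Requiring the directed equation to hold for *both*
orderings forces a unique Gaussian form: the two members' per-epoch
innovations are jointly normal with cross-correlation equal to the
dyad's slope s_d and evolve as a vector AR(1) in φ. Then each directed
conditional expectation is exactly `b0 + ρ·own lag + s_d·partner +
conditions` with AR(1) residuals, per-dyad OLS (direction-wise) is
unbiased for s_d, and the mixed model's estimands coincide with the
generator's parameters. Three consequences are unavoidable and worth
understanding:

1. *Stability clip.* The coupled mean recursion has spectral radius
   |ρ|/(1 − |s|); slopes are clipped to |s| ≤ 0.93·(1 − |ρ|)
   (~2% of draws at defaults), so the realized slope SD is ~0.188
   against the nominal 0.20.
2. *Signal–noise lock.* The directed residual variance equals
   (1 − s²) × the series variance; "noiseless" coupling in both
   directions collapses the series to a fixed point. Oracle checks
   therefore run at long series or many dyads rather than at zero
   noise.
3. *Cross-direction residual correlation −s.* Forced by the symmetric
   construction; the fitted model assumes the two directions
   independent. This is exactly the situation the published model faces
   on real dyads.

The innovation chain restarts (independently, from stationarity) at the
first modelled epoch so that the first lag value is exogenous, matching
how the likelihood conditions on it. Participants are exchangeable:
every series has the same innovation scale (anchored so the mean dyad's
residual SD equals `sigma_resid`). Dyad- and participant-level intercept
heterogeneity is available (`sd_dyad_intercept`,
`sd_participant_intercept`) but defaults to zero: shared level effects
make the partner regressor endogenous with respect to the outcome's
random effects and are not part of the emulated conditions.

**Raw IBI emulation.** Each participant's IBI series spans baseline +
task with margins: base heart period 800 ms, sinusoidal respiratory
modulation at 0.25 Hz whose per-epoch amplitude is √(2·exp(target
logRSA)) so the band-limited variance tracks the baseline level plus the
panel's parasympathetic reactivity trajectory, plus 2 ms white jitter.
Amplitudes are constant within an epoch; the 12-s edge truncation of the
54-s windows removes the boundaries, so recovered logRSA is clean.
Artifact injection splits a chosen fraction of beats at u ~ U(0.4, 0.6)
— both fragments then fall below 0.6 of the neighbouring beat, which is
what makes the planted splits detectable by the QC rule — and records
ground-truth positions; fragment pairs sum exactly to the original
interval.

**Affiliation outcomes.** Linear in the dyad's true slope, the
participant's mean reactivity, condition codes and the configured
interactions; dyad-level intercepts (shared by both members) and
participant-level residuals are correlated across outcomes through one
3×3 correlation matrix with outcome-specific scales (SDs ~0.9/1.0/0.45,
near the questionnaire scales' dispersions). Values are continuous;
no truncation to the 1–7 range (truncation would bias the recovery
studies the generator exists to support).

## What the replication studies show — and what they cannot

With 200 replicates at the study scale, the mixed model recovers
β_sync, ρ and φ with |bias| < 0.03, and the cluster-robust intervals
cover at roughly the nominal rate. Two findings are properties of the
*published model class* on symmetrically coupled dyads, not
implementation defects, and both were confirmed independently with
R nlme on shared datasets:

- **σ_sync inflates by ≈ +0.03–0.04.** The slope-variance term
  `v_s·x x'` is nearly collinear with the AR(1) residual covariance
  (the partner-series regressor has the same autocorrelation shape as
  the residuals), and the stacked two-direction quasi-likelihood is not
  a proper joint density away from the null, so realized regressor
  fluctuations are partly absorbed as slope variance.
- **The slope-variance LRT is strongly anticonservative on dyadic
  panels.** On fully null data (no coupling at all) the χ²(2) statistic
  is typically ~12 — nlme reproduces this to two decimals — so its
  nominal 5% size is unattainable, and re-paired pseudo-dyads inherit
  the same inflation. The surrogate diagnostic remains informative as a
  *contrast* (re-paired slope variance sits well below true-pair slope
  variance, and a planted shared-stimulus signal raises it), but its
  p-values should not be read at face value. Users analysing real data
  with this model should apply the same caution to published χ²
  slope-variance tests.

The BLUP-truth correlation for per-dyad slopes is bounded by
√reliability ≈ 0.52 at ten epochs with φ = 0.5 — a ceiling set by the
design, not the estimator.

The generator emulates the statistical structure of the study, not its
physiology: real CSI/logRSA series have skewed marginals, respiration is
not a fixed-frequency sinusoid, artifacts are not clean mid-cycle
splits, and real dyads may couple asymmetrically or nonlinearly. Passing
tests certify the pipeline's arithmetic and its statistical calibration
under the stated model — they do not certify the model's adequacy for
any particular physiological dataset.

## Numerical choices

- Deviance evaluations Cholesky-factor per-cluster covariances; clusters
  with identical layout are batched. Finite-difference steps (1e-5) are
  sized to dominate the factorization's noise floor.
- Correlation parameters use atanh with bounds ±6; log-SDs are bounded
  in [−8, 5]; a 3×3 correlation block that leaves the PD cone is
  smoothly projected back with a penalty so line searches keep gradient
  signal.
- The LRT clamps χ² at 0 (boundary); df equals the count of removed
  (co)variance parameters.
- Ties/degenerate inputs: empty series, zero baseline variance,
  collinear Poincaré clouds, single-dyad strata and sub-minimum beat
  counts all have explicit, tested behaviours (error, fallback, skip,
  or missing value) rather than silent propagation.
- All randomness flows from one top-level seed through named,
  hash-derived child streams; a config + seed pair reproduces every
  table byte-for-byte.
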