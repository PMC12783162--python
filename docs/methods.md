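# Methods

## Data model

A survey consists of sites visited on a small number of occasions within a
closed season. Detection histories are 0/1/NaN matrices (NaN = occasion not
surveyed; such occasions contribute nothing to the likelihood, the standard
missing-at-random treatment). Sites with an entirely missing history are
dropped from fits. The study-emulation design uses two occasions per site —
two consecutive 1-km halves of a 2-km trail segment — so closure holds by
construction, together with the assumptions that species are never falsely
identified and that heterogeneity is carried by covariates.

Covariate handling follows common occupancy-software practice:

- continuous site covariates are z-scaled (sample SD, n−1 denominator, the
  default of mainstream statistics software); the (mean, sd) pair is stored
  so prediction grids can be expressed on the raw scale;
- collinearity is screened with pairwise Pearson correlations; for each pair
  with |r| above the threshold (default 0.6) the covariate listed *later* in
  the caller's priority order is dropped. The absolute-value reading and the
  deterministic order rule are our choices where convention is silent;
- serial dependence between consecutive occasions is absorbed by a
  "recapture" detection covariate: 0 on occasion 1, the previous occasion's
  detection afterwards (a missing previous occasion counts as 0). For two
  occasions this is exactly the detected-on-occasion-1 indicator; for K > 2
  we generalise it as the lag-1 detection;
- the 3-level substrate quality score enters detection models as a numeric
  covariate centred at level 2 by the generators; callers can expand it to
  indicator terms themselves if they prefer a categorical treatment.

## Likelihoods and fitting

Both likelihoods are exact finite mixtures over latent occupancy states
(2 states for one species, 4 for two). The two-species model conditions B's
detection in the both-present state on A's *observed* same-occasion
detection (rBA vs rBa); since A's history is data, no summation over A's
latent detection is needed. When A's occasion is missing but B's is not, B's
detection uses rBa (no observed cue from A). The default detection
constraint ties pA = rA and pB = rBA = rBa ("no species effect on
detection"); the fully free five-block variant is available.

Parameters are logit-linear in covariates. Fitting is multi-start L-BFGS-B
(default 10 starts: the origin plus seeded N(0, 1.5) draws) with all
coefficients box-bounded at ±15 on the logit scale so that separation-prone
sparse data stay finite instead of diverging. Duplicate (design row,
history) patterns are collapsed to weighted unique rows before optimisation
— an exact transformation that makes intercept-only and
categorical-covariate fits cost O(#patterns) per likelihood evaluation.

Non-convergence is a *reported state*, never an exception, because sparse
spoor data genuinely produce it: a fit is flagged unconverged when the
optimiser fails, when any coefficient sits at the ±15 bound (boundary
estimate, e.g. an all-detections or zero-detection species), or when the
observed information is not invertible/positive definite. Variance matrices
are inverses of central-difference Hessians of the negative log-likelihood
at the optimum; derived quantities (per-site ψ̂, SIF, profile curves) get
delta-method SEs from numerical gradients through the coefficient
covariance.

Ties in multi-start optima are broken first-found; likelihood values are
floored at 1e−300 before logging to keep degenerate parameter proposals
finite during optimisation.

## Species interaction factor

φ is implemented as ψAB/(ψA·ψB) with ψAB = ψA·ψBA and
ψB = ψA·ψBA + (1−ψA)·ψBa — the ratio of joint occupancy to its
value under independence, the form used throughout the two-species
co-occurrence literature. An alternative denominator ψBA·ψBa is available
behind `printed_denominator=True` for comparison only; it does not equal 1
under independence and is not used by any threshold logic. Algebraically
φ = 1 exactly when ψBA = ψBa, and the implementation returns exactly 1.0 in
that case rather than leaving it to floating-point cancellation.

The pair-level summary reports the arithmetic mean of site-level φᵢ with a
delta-method SE of that mean (φ at mean covariates is available through the
profile operation evaluated at z = 0). Significance is "95% CI excludes 1".
For an SP fit the constraint forces φᵢ ≡ 1 and the SE of the interaction
contrast is exactly 0.

## Synthetic surveys

The generators are the likelihoods run forwards, so empirical history
frequencies converge to the model's history distribution (verified at
n = 100 000 in the tests); they add two realistic features the basic
likelihood does not contain — the lag-1 recapture effect on detection and
the substrate effect — which the fitting covariates then absorb.

The study emulation generates 269 + 499 = 768 two-occasion sites in two
areas. Landscape covariates are standard-normal draws; prey/threat layers
(buffalo, impala, kudu, cattle, poaching) have logit-linear occupancy in the
landscape and moderate detection; carnivore layers are coupled to the
dominant predator's latent state with area-specific contrasts: in the
well-protected area the dominant tracks water, one subordinate avoids it
(wild dog), one is independent of it (spotted hyena); in the heavily-used
area carnivores track prey surfaces and threats are widespread; the wild dog
is the rarest layer. Prey covariates for carnivores use the prey's true
occupancy-probability surface, mirroring the pipeline's use of estimated
ψ̂ as covariates. Substrate frequencies default to (0.4, 0.4, 0.2). All
generating values are the emulation's own defaults chosen once for
qualitative realism (detection layers sparse but estimable); they are not
estimates from any real survey, so passing tests demonstrate correctness of
the machinery and estimator behaviour under the assumed design, not
agreement with any particular field system. Features of real data the
emulation does not contain: spatial autocorrelation beyond the recapture
effect, observer heterogeneity, covariate measurement error, and
non-stationary occupancy within a season.

## Pipeline

Areas are analysed separately end to end. Prey/threat occupancy surfaces are
estimated first (univariate landscape models ranked by AIC; the per-site
*unconditional* ψ̂ of the top model becomes a carnivore covariate —
history-conditioned occupancy is available as an option). Carnivore
covariate selection is univariate (single covariates generalise better
inside two-species models), top covariate = lowest-AIC converged model, ties
broken by listed order, null model carried forward when nothing converges.
Pair models (SP and SP+INT, substrate on detection, shared detection
constraint) re-estimate all coefficients jointly inside the two-species
likelihood, carrying only the covariate *identities* from the single-species
stage. Ranking uses strict ΔAIC < 2 candidate sets; Akaike weights are
normalised over the supplied model set only. Every fit attempted appears in
the run log with its convergence flag; outputs are a pure function of
(config, seed, data), and written files contain no timestamps so reruns are
byte-identical.

Default problem sizes (768-site emulation, 5 optimiser starts in the
pipeline, 100 replicates of 2000 sites in the replicate studies) keep a full
run in the tens of seconds to a few minutes on one CPU while leaving
Monte-Carlo error well inside the tolerances the tests assert.

## Known limitations

- Single-season models only; no dynamic (multi-season) occupancy, no false
  positives, no Bayesian fitting, and at most two interacting species, with
  dominance declared by the caller rather than estimated.
- Numerical Hessians can mis-diagnose convergence within ~1e−2 of the logit
  bound; the boundary flag is deliberately conservative.
- The delta-method SE of the averaged SIF is a first-order approximation;
  for very sparse subordinates (few detections) profile-likelihood or
  bootstrap intervals would be more faithful.
- The collinearity screen is pairwise; a covariate collinear with a linear
  combination of others passes it.
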