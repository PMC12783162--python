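# cooccupancy

Occupancy models for detection/non-detection wildlife surveys with imperfect
detection: single-season single-species models, conditional two-species
(dominant/subordinate) co-occurrence models, species interaction factors
with delta-method uncertainty, AIC model selection, matched synthetic-survey
generators, and an end-to-end analysis pipeline.

The package is aimed at ecologists analysing repeat-visit presence/absence
data — e.g. spoor (track) transects walked as consecutive segments — who
want to ask not just *where does a species occur?* but *does one species'
occurrence change where a dominant competitor occurs?*

## The models

**Single species.** A site *i* is occupied with probability ψᵢ; an occupied
site yields independent detections with probability pᵢₖ per occasion *k*.
Both are logit-linear in covariates. The likelihood of history *hᵢ* is

```
L(ψ, p; hᵢ) = ψᵢ ∏ₖ pᵢₖ^hᵢₖ (1−pᵢₖ)^(1−hᵢₖ)  +  (1−ψᵢ) · I(no detections)
```

**Two species.** A dominant species A and a subordinate B are coupled through
ψA, ψBA = P(B | A present), ψBa = P(B | A absent), with detection parameters
pA, pB (species alone), rA (A when both present) and rBA/rBa (B when both
present, given A was/was not detected that occasion). The *SP* model
constrains ψBA = ψBa; *SP+INT* frees them.

**Species interaction factor.** φ = ψA·ψBA / (ψA·ψB), with
ψB = ψA·ψBA + (1−ψA)·ψBa. φ < 1 means avoidance, φ = 1 independence,
φ > 1 co-occurrence beyond independence; a 95% CI excluding 1 is flagged
significant. Standard errors propagate the coefficient covariance (inverse
observed information) through the φ map by the delta method.

All fits are multi-start quasi-Newton maximum likelihood; models are ranked
by AIC with ΔAIC, Akaike weights and model likelihoods, and candidate sets
use a strict ΔAIC < 2 rule.

## Worked example

```python
import cooccupancy as co

cfg = co.SimulationConfig(
    n_sites=2000, seed=11,
    psi_a=0.5, psi_ba=0.2, psi_ba0=0.6,   # B avoids A
    p_a=0.5, p_b=0.5,
)
dataset, _ = co.simulate_two_species(cfg)

sp   = co.fit_two_species(dataset, "A", "B", interaction=False, n_starts=5, seed=0)
intr = co.fit_two_species(dataset, "A", "B", interaction=True,  n_starts=5, seed=0)
print(co.rank_models([(f.name, f.neg2loglik, f.K) for f in (sp, intr)]))
est = co.sif_estimate(intr)
print(est.phi_mean, est.se, est.significant)
```

prints (from `python examples/two_species_sif.py`):

```
                        name  neg2loglik  K         aic  delta_aic       weight  model_likelihood
psi(None, None, SP+INT) p(.) 7805.700601  5 7815.700601   0.000000 1.000000e+00      1.000000e+00
    psi(None, None, SP) p(.) 7978.571868  4 7986.571868 170.871267 7.866398e-38      7.866398e-38

SIF = 0.432 +/- 0.037 (95% CI 0.358-0.505, significant=True)
```

The conditional model wins decisively (ΔAIC ≈ 171) and the fitted SIF sits
well below 1 with a CI excluding 1: B significantly avoids sites occupied by
A, as simulated (true φ = 0.5).

Other narrative scripts in `examples/` cover single-species fitting and
prediction (`single_species_occupancy.py`), SIF profiles along an
environmental gradient (`sif_covariate_profile.py`), and the full two-park
pipeline on the packaged 768-site study emulation (`study_pipeline.py`),
which ends with one SIF row per dominant–subordinate pair per park.

A thin CLI mirrors the library: `occu simulate`, `occu fit-single`,
`occu fit-two`, `occu rank`, `occu pipeline`.

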