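"""Single-season single-species occupancy models.

The zero-inflated detection model of MacKenzie et al.: a site is occupied
with probability psi, and an occupied site yields independent Bernoulli(p_k)
detections per occasion.  Both psi and p are logit-linear in covariates:

    logit(psi_i) = x_i' beta_psi,    logit(p_ik) = w_ik' beta_p

The site likelihood for history h_i (0/1, NaN = skipped occasion) is

    L_i = psi_i * prod_k p_ik^h_ik (1-p_ik)^(1-h_ik)
          + (1 - psi_i) * I(no detections at site i).

Fitting is by multi-start quasi-Newton maximum likelihood; standard errors
come from the inverse observed information, and derived quantities (per-site
psi-hat, detection-conditioned occupancy) use the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._optim import (
    LOGIT_BOUND,
    aggregate_patterns,
    fit_summary,
    multistart_minimize,
    safe_log,
)
from .data import CovariateSpec, DetectionDataset, ValidationError

__all__ = [
    "SingleSpeciesFit",
    "OccupancySummary",
    "site_likelihood_single",
    "negloglik_single",
    "fit_single_species",
    "predict_site_occupancy",
    "conditional_site_occupancy",
]


def site_likelihood_single(psi: float, p: np.ndarray, history: np.ndarray) -> float:
    """Likelihood of one site's detection history; missing occasions are skipped."""
    p = np.asarray(p, dtype=float)
    h = np.asarray(history, dtype=float)
    if not 0 <= psi <= 1 or np.any((p < 0) | (p > 1)):
        raise ValueError("psi and p must lie in [0, 1]")
    obs = ~np.isnan(h)
    if not obs.any():
        raise ValidationError("history is all-missing: site is uninformative, drop it")
    ph, hh = p[obs], h[obs]
    det = float(np.prod(np.where(hh == 1, ph, 1.0 - ph)))
    never = float(np.all(hh == 0))
    return psi * det + (1.0 - psi) * never


def _nll_arrays(beta: np.ndarray, X: np.ndarray, W: np.ndarray, h: np.ndarray,
                weights: np.ndarray | None = None) -> float:
    """Vectorised negative log-likelihood over (possibly weighted) sites."""
    npsi = X.shape[1]
    psi = expit(X @ beta[:npsi])
    p = expit(W @ beta[npsi:])
    obs = ~np.isnan(h)
    hh = np.nan_to_num(h)
    logdet = np.where(obs, hh * safe_log(p) + (1.0 - hh) * safe_log(1.0 - p), 0.0).sum(axis=1)
    never = np.where(obs, hh, 0.0).sum(axis=1) == 0
    lik = psi * np.exp(logdet) + (1.0 - psi) * never
    w = np.ones(len(lik)) if weights is None else weights
    return float(-(w * safe_log(lik)).sum())


def negloglik_single(
    beta: np.ndarray,
    dataset: DetectionDataset,
    spec: CovariateSpec,
    species: str | None = None,
) -> float:
    """-log likelihood of the dataset at coefficient vector ``beta``.

    ``beta`` stacks the occupancy block (intercept + psi_terms) then the
    detection block (intercept + p_terms).
    """
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta must be finite")
    spec.validate(dataset)
    sp = species or dataset.species[0]
    X = dataset.psi_design(spec.psi_terms)
    W = dataset.p_design(spec.p_terms)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(W)):
        raise ValidationError("non-finite covariate in design matrix")
    if beta.size != X.shape[1] + W.shape[2]:
        raise ValueError("beta length does not match design matrices")
    h = dataset.histories[sp]
    keep = ~np.isnan(h).all(axis=1)
    return _nll_arrays(beta, X[keep], W[keep], h[keep])


@dataclass
class SingleSpeciesFit:
    """MLE of a single-species occupancy model."""

    species: str
    spec: CovariateSpec
    beta_psi: np.ndarray
    beta_p: np.ndarray
    vcov: np.ndarray | None
    neg2loglik: float
    K: int
    converged: bool
    boundary: bool
    message: str
    per_site_psi: np.ndarray
    per_site_p: np.ndarray
    n_sites: int
    coef_names: list[str] = field(default_factory=list)

    @property
    def beta(self) -> np.ndarray:
        return np.concatenate([self.beta_psi, self.beta_p])

    @property
    def aic(self) -> float:
        return self.neg2loglik + 2.0 * self.K

    def coef_table(self):
        import pandas as pd

        se = (
            np.sqrt(np.diag(self.vcov))
            if self.vcov is not None
            else np.full(self.K, np.nan)
        )
        return pd.DataFrame({"term": self.coef_names, "estimate": self.beta, "se": se})


def fit_single_species(
    dataset: DetectionDataset,
    spec: CovariateSpec,
    species: str | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> SingleSpeciesFit:
    """Maximum-likelihood fit of the occupancy model; degrades gracefully.

    A dataset with zero detections (psi unidentifiable), an optimiser
    failure, a boundary estimate, or a singular information matrix all yield
    ``converged=False`` rather than an exception, mirroring how sparse spoor
    data behave in practice.
    """
    spec.validate(dataset)
    sp = species or dataset.species[0]
    X = dataset.psi_design(spec.psi_terms)
    W = dataset.p_design(spec.p_terms)
    h = dataset.histories[sp]
    keep = ~np.isnan(h).all(axis=1)
    Xk, Wk, hk = X[keep], W[keep], h[keep]
    names = ["psi_intercept"] + [f"psi_{t}" for t in spec.psi_terms]
    names += ["p_intercept"] + [f"p_{t}" for t in spec.p_terms]
    n_par = len(names)

    if np.nansum(hk) == 0:
        nan = np.full(n_par, np.nan)
        return SingleSpeciesFit(
            sp, spec, nan[: X.shape[1]], nan[X.shape[1]:], None, np.nan, n_par,
            converged=False, boundary=False,
            message="no detections: occupancy unidentifiable",
            per_site_psi=np.full(dataset.n_sites, np.nan),
            per_site_p=np.full((dataset.n_sites, dataset.n_occasions), np.nan),
            n_sites=int(keep.sum()), coef_names=names,
        )

    (Xa, Wa, ha), wts = aggregate_patterns(Xk, Wk, hk)
    Wa = Wa.reshape(len(wts), dataset.n_occasions, W.shape[2])
    ha = ha.reshape(len(wts), dataset.n_occasions)

    def nll(b):
        return _nll_arrays(b, Xa, Wa, ha, wts)

    res = multistart_minimize(nll, n_par, n_starts, seed)
    vcov, converged, boundary, message = fit_summary(nll, res)
    beta = res.x
    npsi = X.shape[1]
    return SingleSpeciesFit(
        sp, spec, beta[:npsi], beta[npsi:], vcov,
        neg2loglik=2.0 * res.fun, K=n_par, converged=converged, boundary=boundary,
        message=message,
        per_site_psi=expit(X @ beta[:npsi]),
        per_site_p=expit(W @ beta[npsi:]),
        n_sites=int(keep.sum()), coef_names=names,
    )


@dataclass
class OccupancySummary:
    """Per-site occupancy predictions with the mean and range across sites."""

    per_site: np.ndarray
    mean: float
    range: tuple[float, float]


def predict_site_occupancy(fit: SingleSpeciesFit, dataset: DetectionDataset) -> OccupancySummary:
    """Model-predicted (unconditional) psi-hat per site, its mean and range."""
    if not np.all(np.isfinite(fit.beta_psi)):
        raise ValidationError("cannot predict from an unfitted model")
    X = dataset.psi_design(fit.spec.psi_terms)
    psi = expit(X @ fit.beta_psi)
    return OccupancySummary(psi, float(psi.mean()), (float(psi.min()), float(psi.max())))


def conditional_site_occupancy(fit: SingleSpeciesFit, dataset: DetectionDataset) -> np.ndarray:
    """P(site occupied | its detection history), the empirical-Bayes update.

    Detection implies presence (no false positives), so any site with a
    detection gets 1; an all-zero site gets
    psi * prod(1-p_k) / (psi * prod(1-p_k) + 1 - psi) over observed occasions.
    """
    if not np.all(np.isfinite(fit.beta_psi)):
        raise ValidationError("cannot predict from an unfitted model")
    X = dataset.psi_design(fit.spec.psi_terms)
    W = dataset.p_design(fit.spec.p_terms)
    psi = expit(X @ fit.beta_psi)
    p = expit(W @ fit.beta_p)
    h = dataset.histories[fit.species]
    obs = ~np.isnan(h)
    detected = np.nansum(h, axis=1) > 0
    miss = np.where(obs, 1.0 - p, 1.0).prod(axis=1)
    cond = psi * miss / (psi * miss + 1.0 - psi)
    return np.where(detected, 1.0, cond)
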