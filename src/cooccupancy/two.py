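"""Conditional two-species occupancy models and the species interaction factor.

A dominant species A and a subordinate B are modelled jointly through the
conditional parameterization:

    psiA  = P(A occupies a site)
    psiBA = P(B occupies | A present)
    psiBa = P(B occupies | A absent)

with detection parameters pA, pB (a species alone), rA (A when both present)
and rBA / rBa (B when both present, given A was / was not detected on the
same occasion).  The *SP* variant constrains psiBA = psiBa (occupancy of B
independent of A); the *INT* variant frees them.

The species interaction factor phi is the ratio of joint occupancy to the
product expected under independence,

    phi = psiA * psiBA / (psiA * psiB),   psiB = psiA*psiBA + (1-psiA)*psiBa,

so phi < 1 signals avoidance, phi = 1 independence, and phi > 1 aggregation.
Standard errors of phi and of its site average are propagated from the
coefficient covariance by the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._optim import (
    aggregate_patterns,
    fit_summary,
    multistart_minimize,
    safe_log,
)
from .data import DetectionDataset, ValidationError

__all__ = [
    "TwoSpeciesParams",
    "TwoSpeciesFit",
    "SIFEstimate",
    "joint_state_probs",
    "site_likelihood_two",
    "fit_two_species",
    "compute_sif",
    "sif_estimate",
    "sif_profile",
    "two_model_name",
]


@dataclass
class TwoSpeciesParams:
    """Scalar parameter set for one site (probability scale)."""

    psiA: float
    psiBA: float
    psiBa: float
    pA: float
    pB: float
    rA: float
    rBA: float
    rBa: float

    def __post_init__(self) -> None:
        for nm in ("psiA", "psiBA", "psiBa", "pA", "pB", "rA", "rBA", "rBa"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm}={v} outside [0, 1]")

    @classmethod
    def constant(cls, value: float) -> "TwoSpeciesParams":
        return cls(*([value] * 8))


def joint_state_probs(psiA, psiBA, psiBa):
    """Latent-state distribution over {AB, Ab, aB, ab}; components sum to 1."""
    psiA, psiBA, psiBa = (np.asarray(v, dtype=float) for v in (psiA, psiBA, psiBa))
    return np.stack(
        [
            psiA * psiBA,
            psiA * (1.0 - psiBA),
            (1.0 - psiA) * psiBa,
            (1.0 - psiA) * (1.0 - psiBa),
        ],
        axis=-1,
    )


def _bern_prod(p, h, obs):
    """prod over observed occasions of p^h (1-p)^(1-h), scalar inputs as arrays."""
    return float(np.prod(np.where(obs, np.where(h == 1, p, 1.0 - p), 1.0)))


def site_likelihood_two(params: TwoSpeciesParams, historyA, historyB) -> float:
    """Likelihood of one site's joint (A, B) detection history.

    Mixture over the four latent occupancy states.  B's detection in the
    both-present state is conditioned on A's *observed* same-occasion
    detection (rBA if A was detected, rBa otherwise; a missing A occasion
    counts as not detected).  Missing occasions are skipped per species.
    """
    hA = np.asarray(historyA, dtype=float)
    hB = np.asarray(historyB, dtype=float)
    if hA.shape != hB.shape:
        raise ValidationError("historyA and historyB must have the same length")
    obsA, obsB = ~np.isnan(hA), ~np.isnan(hB)
    if not (obsA.any() or obsB.any()):
        raise ValidationError("both histories all-missing: site is uninformative")
    w = joint_state_probs(params.psiA, params.psiBA, params.psiBa)
    a_detected = np.nan_to_num(hA) == 1
    q = np.where(a_detected, params.rBA, params.rBa)
    state_AB = _bern_prod(params.rA, hA, obsA) * float(
        np.prod(np.where(obsB, np.where(hB == 1, q, 1.0 - q), 1.0))
    )
    no_det_A = not np.any(hA[obsA] == 1)
    no_det_B = not np.any(hB[obsB] == 1)
    state_Ab = _bern_prod(params.pA, hA, obsA) * float(no_det_B)
    state_aB = float(no_det_A) * _bern_prod(params.pB, hB, obsB)
    state_ab = float(no_det_A and no_det_B)
    return float(w @ np.array([state_AB, state_Ab, state_aB, state_ab]))


def compute_sif(psiA, psiBA, psiBa, printed_denominator: bool = False):
    """Species interaction factor phi for given conditional occupancies.

    The default denominator is the independence product psiA * psiB.  The
    alternative ``printed_denominator=True`` divides by psiBA * psiBa
    instead; it is provided for comparison only and is not the quantity the
    avoidance/independence/aggregation thresholds refer to.
    """
    psiA = np.asarray(psiA, dtype=float)
    psiBA = np.asarray(psiBA, dtype=float)
    psiBa = np.asarray(psiBa, dtype=float)
    if np.any((psiA <= 0) | (psiA >= 1)):
        raise ValueError("psiA must lie strictly inside (0, 1)")
    if np.any((psiBA == 0) & (psiBa == 0)):
        raise ValueError("psiBA and psiBa cannot both be 0 (B never occurs)")
    if printed_denominator:
        denom = psiBA * psiBa
        if np.any(denom == 0):
            raise ValueError("printed-denominator SIF undefined when psiBA*psiBa = 0")
        out = psiA * psiBA / denom
    else:
        psiB = psiA * psiBA + (1.0 - psiA) * psiBa
        # algebraically phi == 1 whenever psiBA == psiBa; return it exactly
        out = np.where(psiBA == psiBa, 1.0, psiA * psiBA / np.maximum(psiA * psiB, 1e-300))
    return float(out) if out.ndim == 0 else out


def two_model_name(covA: str | None, covB: str | None, interaction: bool,
                   p_cov: str = "Substrate") -> str:
    kind = "SP+INT" if interaction else "SP"
    return f"psi({covA or 'None'}, {covB or 'None'}, {kind}) p({p_cov})"


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_DET_BLOCKS = {"shared": ["pA", "pB"], "free": ["pA", "rA", "pB", "rBA", "rBa"]}


@dataclass
class TwoSpeciesFit:
    """MLE of the conditional two-species model."""

    species_a: str
    species_b: str
    interaction: bool
    detection_constraint: str
    psi_a_terms: list[str]
    psi_ba_terms: list[str]
    psi_ba0_terms: list[str]
    p_terms: list[str]
    beta: np.ndarray
    blocks: dict[str, slice]
    vcov: np.ndarray | None
    neg2loglik: float
    K: int
    converged: bool
    boundary: bool
    message: str
    coef_names: list[str]
    name: str = ""
    # design matrices retained for delta-method propagation of derived maps
    _XA: np.ndarray | None = field(default=None, repr=False)
    _XBA: np.ndarray | None = field(default=None, repr=False)
    _XBa: np.ndarray | None = field(default=None, repr=False)
    _W: np.ndarray | None = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return self.neg2loglik + 2.0 * self.K

    def _psi_arrays(self, beta=None):
        b = self.beta if beta is None else beta
        psiA = expit(self._XA @ b[self.blocks["psiA"]])
        psiBA = expit(self._XBA @ b[self.blocks["psiBA"]])
        if self.interaction:
            psiBa = expit(self._XBa @ b[self.blocks["psiBa"]])
        else:
            psiBa = expit(self._XBa @ b[self.blocks["psiBA"]])
        return psiA, psiBA, psiBa

    @property
    def per_site_psiA(self):
        return self._psi_arrays()[0]

    @property
    def per_site_psiBA(self):
        return self._psi_arrays()[1]

    @property
    def per_site_psiBa(self):
        return self._psi_arrays()[2]

    def detection_probs(self) -> dict[str, np.ndarray]:
        """Per site-occasion detection probabilities for all five parameters."""
        b, W = self.beta, self._W
        out = {}
        if self.detection_constraint == "shared":
            pA = expit(W @ b[self.blocks["pA"]])
            pB = expit(W @ b[self.blocks["pB"]])
            out = {"pA": pA, "rA": pA, "pB": pB, "rBA": pB, "rBa": pB}
        else:
            for nm in _DET_BLOCKS["free"]:
                out[nm] = expit(W @ b[self.blocks[nm]])
        return out

    def coef_table(self):
        se = (
            np.sqrt(np.diag(self.vcov))
            if self.vcov is not None
            else np.full(self.K, np.nan)
        )
        return pd.DataFrame({"term": self.coef_names, "estimate": self.beta, "se": se})


def _two_nll_arrays(beta, blocks, interaction, constraint, XA, XBA, XBa, W, hA, hB, wts):
    psiA = expit(XA @ beta[blocks["psiA"]])
    psiBA = expit(XBA @ beta[blocks["psiBA"]])
    psiBa = expit(XBa @ beta[blocks["psiBa" if interaction else "psiBA"]])
    if constraint == "shared":
        pA = rA = expit(W @ beta[blocks["pA"]])
        pB = rBA = rBa = expit(W @ beta[blocks["pB"]])
    else:
        pA = expit(W @ beta[blocks["pA"]])
        rA = expit(W @ beta[blocks["rA"]])
        pB = expit(W @ beta[blocks["pB"]])
        rBA = expit(W @ beta[blocks["rBA"]])
        rBa = expit(W @ beta[blocks["rBa"]])

    obsA, obsB = ~np.isnan(hA), ~np.isnan(hB)
    hA0, hB0 = np.nan_to_num(hA), np.nan_to_num(hB)
    q = np.where(hA0 == 1, rBA, rBa)

    def logprod(p, h, obs):
        return np.where(obs, h * safe_log(p) + (1.0 - h) * safe_log(1.0 - p), 0.0).sum(axis=1)

    no_det_A = np.where(obsA, hA0, 0.0).sum(axis=1) == 0
    no_det_B = np.where(obsB, hB0, 0.0).sum(axis=1) == 0
    state_AB = np.exp(logprod(rA, hA0, obsA) + logprod(q, hB0, obsB))
    state_Ab = np.exp(logprod(pA, hA0, obsA)) * no_det_B
    state_aB = no_det_A * np.exp(logprod(pB, hB0, obsB))
    state_ab = (no_det_A & no_det_B).astype(float)

    w = joint_state_probs(psiA, psiBA, psiBa)
    lik = (
        w[:, 0] * state_AB + w[:, 1] * state_Ab + w[:, 2] * state_aB + w[:, 3] * state_ab
    )
    return float(-(wts * safe_log(lik)).sum())


def fit_two_species(
    dataset: DetectionDataset,
    species_a: str,
    species_b: str,
    psi_a_terms: list[str] | None = None,
    psi_ba_terms: list[str] | None = None,
    psi_ba0_terms: list[str] | None = None,
    p_terms: list[str] | None = None,
    interaction: bool = True,
    detection_constraint: str = "shared",
    n_starts: int = 10,
    seed: int = 0,
) -> TwoSpeciesFit:
    """Fit the conditional two-species model by multi-start maximum likelihood.

    ``interaction=False`` fits the SP constraint (one shared linear predictor
    for psiBA = psiBa); ``interaction=True`` fits SP+INT with separate psiBA
    and psiBa predictors.  ``detection_constraint="shared"`` (default, the
    no-species-effect-on-detection constraint) ties pA = rA and
    pB = rBA = rBa; ``"free"`` estimates all five detection blocks.
    Non-convergence is reported on the returned fit, never raised.
    """
    if detection_constraint not in _DET_BLOCKS:
        raise ValueError("detection_constraint must be 'shared' or 'free'")
    psi_a_terms = list(psi_a_terms or [])
    psi_ba_terms = list(psi_ba_terms or [])
    psi_ba0_terms = list(psi_ba0_terms if psi_ba0_terms is not None else psi_ba_terms)
    p_terms = list(p_terms or [])

    XA = dataset.psi_design(psi_a_terms)
    XBA = dataset.psi_design(psi_ba_terms)
    XBa = dataset.psi_design(psi_ba0_terms)
    W = dataset.p_design(p_terms)
    hA = dataset.histories[species_a]
    hB = dataset.histories[species_b]
    keep = ~(np.isnan(hA).all(axis=1) & np.isnan(hB).all(axis=1))

    blocks: dict[str, slice] = {}
    names: list[str] = []
    pos = 0

    def add_block(nm, terms, width):
        nonlocal pos
        blocks[nm] = slice(pos, pos + width)
        names.append(f"{nm}_intercept")
        names.extend(f"{nm}_{t}" for t in terms)
        pos += width

    add_block("psiA", psi_a_terms, XA.shape[1])
    add_block("psiBA", psi_ba_terms, XBA.shape[1])
    if interaction:
        add_block("psiBa", psi_ba0_terms, XBa.shape[1])
    for nm in _DET_BLOCKS[detection_constraint]:
        add_block(nm, p_terms, W.shape[2])
    n_par = pos
    name = two_model_name(
        ", ".join(psi_a_terms) or None,
        ", ".join(psi_ba_terms) or None,
        interaction,
        ", ".join(p_terms).title() or ".",
    )

    def unconverged(msg):
        return TwoSpeciesFit(
            species_a, species_b, interaction, detection_constraint,
            psi_a_terms, psi_ba_terms, psi_ba0_terms, p_terms,
            beta=np.full(n_par, np.nan), blocks=blocks, vcov=None,
            neg2loglik=np.nan, K=n_par, converged=False, boundary=False,
            message=msg, coef_names=names, name=name,
            _XA=XA, _XBA=XBA, _XBa=XBa, _W=W,
        )

    if np.nansum(hA[keep]) == 0 or np.nansum(hB[keep]) == 0:
        return unconverged("a species has zero detections: model unidentifiable")

    K = dataset.n_occasions
    (XAa, XBAa, XBaa, Wa, hAa, hBa), wts = aggregate_patterns(
        XA[keep], XBA[keep], XBa[keep], W[keep], hA[keep], hB[keep]
    )
    Wa = Wa.reshape(len(wts), K, W.shape[2])
    hAa = hAa.reshape(len(wts), K)
    hBa = hBa.reshape(len(wts), K)

    def nll(b):
        return _two_nll_arrays(
            b, blocks, interaction, detection_constraint, XAa, XBAa, XBaa, Wa, hAa, hBa, wts
        )

    res = multistart_minimize(nll, n_par, n_starts, seed)
    vcov, converged, boundary, message = fit_summary(nll, res)
    return TwoSpeciesFit(
        species_a, species_b, interaction, detection_constraint,
        psi_a_terms, psi_ba_terms, psi_ba0_terms, p_terms,
        beta=res.x, blocks=blocks, vcov=vcov, neg2loglik=2.0 * res.fun, K=n_par,
        converged=converged, boundary=boundary, message=message, coef_names=names,
        name=name, _XA=XA, _XBA=XBA, _XBa=XBa, _W=W,
    )


# ---------------------------------------------------------------------------
# SIF estimation
# ---------------------------------------------------------------------------

@dataclass
class SIFEstimate:
    """Site-level and site-averaged species interaction factor."""

    phi_site: np.ndarray
    phi_mean: float
    se: float
    ci95: tuple[float, float]
    significant: bool


def _delta_se(fun, beta, vcov, step=1e-5):
    """Delta-method SE of scalar fun(beta) given coefficient covariance."""
    if vcov is None:
        return np.nan
    g = np.empty(beta.size)
    for i in range(beta.size):
        bp, bm = beta.copy(), beta.copy()
        h = step * (1.0 + abs(beta[i]))
        bp[i] += h
        bm[i] -= h
        g[i] = (fun(bp) - fun(bm)) / (2.0 * h)
    var = float(g @ vcov @ g)
    return float(np.sqrt(max(var, 0.0)))


def sif_estimate(fit: TwoSpeciesFit, printed_denominator: bool = False) -> SIFEstimate:
    """Average SIF across sites with a delta-method SE and 95% CI.

    The interval is phi_mean +/- 1.96 * SE; the association is flagged
    significant when the interval excludes 1.
    """
    if not fit.converged:
        raise ValidationError(f"fit did not converge: {fit.message}")

    def mean_phi(beta):
        psiA, psiBA, psiBa = fit._psi_arrays(beta)
        return float(np.mean(compute_sif(psiA, psiBA, psiBa, printed_denominator)))

    psiA, psiBA, psiBa = fit._psi_arrays()
    phi_site = np.atleast_1d(compute_sif(psiA, psiBA, psiBa, printed_denominator))
    phi_mean = float(phi_site.mean())
    if not fit.interaction and not printed_denominator:
        se = 0.0  # psiBA = psiBa by constraint: phi is identically 1
    else:
        se = _delta_se(mean_phi, fit.beta, fit.vcov)
    ci = (phi_mean - 1.96 * se, phi_mean + 1.96 * se)
    significant = bool(np.isfinite(se) and (ci[0] > 1.0 or ci[1] < 1.0))
    return SIFEstimate(phi_site, phi_mean, se, ci, significant)


def sif_profile(
    fit: TwoSpeciesFit,
    dataset: DetectionDataset,
    covariate_name: str,
    grid: np.ndarray | None = None,
    n_points: int = 20,
) -> pd.DataFrame:
    """SIF and conditional occupancies along a covariate gradient.

    The grid is on the raw covariate scale (back-transformed from the
    z-scale recorded at standardization time); all other covariates are held
    at their mean (z = 0).  Returns one row per grid value with phi, its
    delta-method SE, and psiA / psiBA / psiBa — the ingredients of
    profile-style co-occurrence curves.
    """
    all_terms = fit.psi_a_terms + fit.psi_ba_terms + fit.psi_ba0_terms
    if covariate_name not in all_terms:
        raise ValidationError(
            f"covariate {covariate_name!r} does not appear in any occupancy predictor"
        )
    mu, sd = dataset.standardization.get(covariate_name, (0.0, 1.0))
    if grid is None:
        z = dataset.site_covariates[covariate_name].to_numpy(dtype=float)
        grid = np.linspace(z.min(), z.max(), n_points) * sd + mu
    grid = np.asarray(grid, dtype=float)
    zgrid = (grid - mu) / sd

    def row_design(terms, zval):
        x = np.ones(1 + len(terms))
        for j, t in enumerate(terms):
            x[1 + j] = zval if t == covariate_name else 0.0
        return x

    rows = []
    for raw, zval in zip(grid, zgrid):
        xA = row_design(fit.psi_a_terms, zval)
        xBA = row_design(fit.psi_ba_terms, zval)
        xBa = row_design(fit.psi_ba0_terms, zval)

        def point(beta):
            psiA = expit(xA @ beta[fit.blocks["psiA"]])
            psiBA = expit(xBA @ beta[fit.blocks["psiBA"]])
            psiBa = expit(
                xBa @ beta[fit.blocks["psiBa" if fit.interaction else "psiBA"]]
            )
            return psiA, psiBA, psiBa

        psiA, psiBA, psiBa = point(fit.beta)
        phi = compute_sif(psiA, psiBA, psiBa)
        se = _delta_se(lambda b: float(compute_sif(*point(b))), fit.beta, fit.vcov)
        rows.append(
            {
                "covariate": covariate_name,
                "value": raw,
                "z": zval,
                "psiA": float(psiA),
                "psiBA": float(psiBA),
                "psiBa": float(psiBa),
                "phi": float(phi),
                "se_phi": se,
            }
        )
    return pd.DataFrame(rows)
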