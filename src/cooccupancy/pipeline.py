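"""End-to-end co-occurrence analysis pipeline.

Per survey area, the stages are:

1. z-standardize landscape covariates and screen collinearity (|r| > 0.6
   drops the later-listed covariate);
2. fit single-species occupancy models for prey/threat layers and attach
   each layer's per-site psi-hat as a site covariate for the carnivores;
3. fit univariate single-species carnivore models (detection: substrate +
   previous-detection), rank by AIC, and keep the top covariate per species,
   falling back to the null model when nothing converges;
4. fit conditional two-species models (SP and SP+INT) for every
   dominant-subordinate pair, carrying the top covariates;
5. rank the pair models, build the delta-AIC < 2 candidate set;
6. report the site-averaged species interaction factor with delta-method SE
   and a SIF profile along the dominant's top covariate.

Every fit attempted is logged with its convergence status; non-convergence
is propagated as a flagged result, never a silent drop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    CovariateSpec,
    DetectionDataset,
    add_recapture_covariates,
    collinearity_screen,
    standardize_covariates,
)
from .selection import candidate_set, rank_models
from .simulate import generate_study_emulation
from .single import conditional_site_occupancy, fit_single_species, predict_site_occupancy
from .two import TwoSpeciesFit, fit_two_species, sif_estimate, sif_profile, _delta_se

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "summarize_pair"]

_LANDSCAPE = ["water", "bushlands", "settlement_dist"]
_PREY = ["buffalo", "impala", "kudu", "cattle", "poaching"]

# Candidate occupancy covariates per carnivore: landscape features plus the
# estimated occupancy surfaces of that species' principal prey and threats.
_CANDIDATES = {
    "lion": _LANDSCAPE + ["buffalo_occ", "kudu_occ", "cattle_occ", "poaching_occ"],
    "cheetah": _LANDSCAPE + ["impala_occ", "kudu_occ", "cattle_occ", "poaching_occ"],
    "leopard": _LANDSCAPE + ["impala_occ", "cattle_occ", "poaching_occ"],
    "hyena": _LANDSCAPE + ["buffalo_occ", "kudu_occ", "cattle_occ", "poaching_occ"],
    "wild_dog": _LANDSCAPE + ["impala_occ", "kudu_occ", "cattle_occ", "poaching_occ"],
}


@dataclass
class PipelineConfig:
    """Configuration of the multi-stage co-occurrence analysis."""

    seed: int = 0
    n_starts: int = 5
    collinearity_threshold: float = 0.6
    delta_aic_cutoff: float = 2.0
    landscape_covariates: list[str] = field(default_factory=lambda: list(_LANDSCAPE))
    prey_species: list[str] = field(default_factory=lambda: list(_PREY))
    dominant: str = "lion"
    subordinates: list[str] = field(
        default_factory=lambda: ["cheetah", "leopard", "hyena", "wild_dog"]
    )
    carnivore_candidates: dict = field(default_factory=lambda: {k: list(v) for k, v in _CANDIDATES.items()})
    # "unconditional": model-predicted psi-hat; "conditional": history-informed
    prey_covariate_mode: str = "unconditional"
    data_path: str | None = None
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    """All pipeline outputs: pair summaries, model tables, profiles, log."""

    pair_summary: pd.DataFrame  # one SIF row per dominant-subordinate pair per area
    model_table: pd.DataFrame  # AIC bookkeeping for every two-species model
    candidate_sets: pd.DataFrame  # delta-AIC < cutoff subsets, pair-wise
    selection_table: pd.DataFrame  # univariate single-species rankings
    profiles: pd.DataFrame  # SIF-vs-covariate curves
    correlations: dict
    log: list[str]
    config: PipelineConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pair_summary.to_csv(out / "pair_summary.csv", index=False)
        self.model_table.to_csv(out / "model_table.csv", index=False)
        self.candidate_sets.to_csv(out / "candidate_sets.csv", index=False)
        self.selection_table.to_csv(out / "selection_table.csv", index=False)
        self.profiles.to_csv(out / "sif_profiles.csv", index=False)
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")
        summary = {
            "n_pairs": int(len(self.pair_summary)),
            "config": {k: v for k, v in asdict(self.config).items() if k != "carnivore_candidates"},
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")


def _univariate_selection(ds, species, candidates, p_terms, n_starts, seed, log):
    """Null + one-covariate psi models, ranked by AIC; returns (rows, fits)."""
    fits = {}
    records = []
    for terms in [[]] + [[c] for c in candidates]:
        spec = CovariateSpec(psi_terms=terms, p_terms=list(p_terms))
        fit = fit_single_species(ds, spec, species=species, n_starts=n_starts, seed=seed)
        nm = f"psi({', '.join(terms) or '.'}) p({', '.join(p_terms)})"
        log.append(f"fit single {species} {nm}: converged={fit.converged} ({fit.message})")
        fits[nm] = fit
        if fit.converged:
            records.append((nm, fit.neg2loglik, fit.K))
    if not records:
        return None, fits
    return rank_models(records), fits


def _attach_prey_covariates(ds, config, retained, area, log):
    """Stage 2: estimate prey/threat occupancy and attach psi-hat covariates."""
    out = ds
    for prey in config.prey_species:
        if prey not in ds.histories:
            log.append(f"[{area}] prey layer {prey!r} missing; skipped")
            continue
        ds_r = add_recapture_covariates(out, [prey])
        ranked, fits = _univariate_selection(
            ds_r, prey, retained, ["substrate", f"recap_{prey}"],
            config.n_starts, config.seed, log,
        )
        if ranked is None:
            log.append(f"[{area}] no converged occupancy model for {prey}; covariate omitted")
            continue
        top = fits[ranked["name"].iloc[0]]
        if config.prey_covariate_mode == "conditional":
            psi_hat = conditional_site_occupancy(top, ds_r)
        else:
            psi_hat = predict_site_occupancy(top, ds_r).per_site
        out = out.copy()
        out.site_covariates[f"{prey}_occ"] = psi_hat
        log.append(
            f"[{area}] {prey}: top model {ranked['name'].iloc[0]}, "
            f"mean psi-hat {float(np.mean(psi_hat)):.3f}"
        )
    return out


def summarize_pair(fit_sp: TwoSpeciesFit | None, fit_int: TwoSpeciesFit | None) -> dict:
    """Condense a pair's SP/SP+INT fits into one summary row.

    The row reports site-averaged psiA, psiBA, psiBa, the five detection
    probabilities, and the averaged SIF with delta-method SE and the
    CI-excludes-1 significance flag, all from the lower-AIC converged fit.
    If neither fit converged the row is flagged and left empty.
    """
    fits = [f for f in (fit_sp, fit_int) if f is not None and f.converged]
    base = {
        "model": "",
        "psiA": np.nan, "psiBA": np.nan, "psiBa": np.nan,
        "pA": np.nan, "pB": np.nan, "rA": np.nan, "rBA": np.nan, "rBa": np.nan,
        "phi": np.nan, "se_phi": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
        "significant": False, "converged": False,
    }
    if not fits:
        return base
    top = min(fits, key=lambda f: f.aic)
    psiA, psiBA, psiBa = top._psi_arrays()
    det = top.detection_probs()
    est = sif_estimate(top)

    def mean_of(which):
        def fn(beta):
            return float(np.mean(top._psi_arrays(beta)[which]))
        return _delta_se(fn, top.beta, top.vcov)

    base.update(
        model=top.name,
        psiA=float(psiA.mean()), se_psiA=mean_of(0),
        psiBA=float(psiBA.mean()), se_psiBA=mean_of(1),
        psiBa=float(psiBa.mean()), se_psiBa=mean_of(2),
        pA=float(det["pA"].mean()), pB=float(det["pB"].mean()),
        rA=float(det["rA"].mean()), rBA=float(det["rBA"].mean()), rBa=float(det["rBa"].mean()),
        phi=est.phi_mean, se_phi=est.se, ci_lo=est.ci95[0], ci_hi=est.ci95[1],
        significant=est.significant, converged=True,
    )
    return base


def run_pipeline(config: PipelineConfig | None = None, dataset: DetectionDataset | None = None) -> PipelineResult:
    """Run the full multi-stage analysis; see the module docstring for stages.

    With no ``dataset`` (and no ``config.data_path``), the packaged 768-site
    study emulation is generated from ``config.seed``.  The result is a pure
    function of (config, seed, input data).
    """
    config = config or PipelineConfig()
    log: list[str] = [f"pipeline start (seed={config.seed})"]
    if dataset is None:
        if config.data_path:
            from .data import load_detection_data

            species = [config.dominant] + config.subordinates + config.prey_species
            dataset = load_detection_data(config.data_path, species=species)
            log.append(f"loaded {dataset.n_sites} sites from {config.data_path}")
        else:
            dataset = generate_study_emulation(config.seed).dataset
            log.append(f"generated study emulation: {dataset.n_sites} sites")

    pair_rows, model_rows, cand_rows, sel_rows, profile_frames = [], [], [], [], []
    correlations = {}
    areas = list(dict.fromkeys(dataset.area))
    for area in areas:
        ds = dataset.subset(dataset.area == area)
        log.append(f"[{area}] {ds.n_sites} sites")
        # stage 1: standardize + collinearity screen
        ds = standardize_covariates(ds, config.landscape_covariates)
        retained, corr = collinearity_screen(
            ds, config.landscape_covariates, config.collinearity_threshold
        )
        correlations[area] = corr
        log.append(f"[{area}] retained landscape covariates: {retained}")
        # stage 2: prey/threat occupancy surfaces
        ds = _attach_prey_covariates(ds, config, retained, area, log)
        # stage 3: univariate carnivore model selection
        tops: dict[str, list[str]] = {}
        for sp in [config.dominant] + config.subordinates:
            cands = [
                c
                for c in config.carnivore_candidates.get(sp, retained)
                if c in ds.site_covariates.columns
            ]
            ds_r = add_recapture_covariates(ds, [sp])
            ranked, fits1 = _univariate_selection(
                ds_r, sp, cands, ["substrate", f"recap_{sp}"],
                config.n_starts, config.seed, log,
            )
            if ranked is None:
                tops[sp] = []
                log.append(f"[{area}] {sp}: no converged model; null carried forward")
            else:
                top_name = ranked["name"].iloc[0]
                tops[sp] = list(fits1[top_name].spec.psi_terms)
                for _, r in ranked.iterrows():
                    sel_rows.append({"area": area, "species": sp, **r.to_dict()})
                log.append(f"[{area}] {sp}: top covariate {tops[sp] or ['(null)']}")
        # stages 4-6: two-species models per pair
        for sub_sp in config.subordinates:
            pair = f"{config.dominant}-{sub_sp}"
            fits = {}
            for interaction in (False, True):
                fit = fit_two_species(
                    ds,
                    config.dominant,
                    sub_sp,
                    psi_a_terms=tops[config.dominant],
                    psi_ba_terms=tops[sub_sp],
                    p_terms=["substrate"],
                    interaction=interaction,
                    n_starts=config.n_starts,
                    seed=config.seed,
                )
                fits[interaction] = fit
                log.append(
                    f"[{area}] {pair} {fit.name}: converged={fit.converged} ({fit.message})"
                )
            converged = [f for f in fits.values() if f.converged]
            if converged:
                ranked = rank_models([(f.name, f.neg2loglik, f.K) for f in converged])
                for _, r in ranked.iterrows():
                    model_rows.append({"area": area, "pair": pair, **r.to_dict()})
                for _, r in candidate_set(ranked, config.delta_aic_cutoff).iterrows():
                    cand_rows.append({"area": area, "pair": pair, **r.to_dict()})
            row = summarize_pair(fits[False], fits[True])
            pair_rows.append({"area": area, "pair": pair, **row})
            top_fit = min(converged, key=lambda f: f.aic) if converged else None
            if top_fit is not None and tops[config.dominant]:
                prof = sif_profile(top_fit, ds, tops[config.dominant][0], n_points=10)
                prof.insert(0, "pair", pair)
                prof.insert(0, "area", area)
                profile_frames.append(prof)

    log.append("pipeline complete")
    result = PipelineResult(
        pair_summary=pd.DataFrame(pair_rows),
        model_table=pd.DataFrame(model_rows),
        candidate_sets=pd.DataFrame(cand_rows),
        selection_table=pd.DataFrame(sel_rows),
        profiles=pd.concat(profile_frames, ignore_index=True)
        if profile_frames
        else pd.DataFrame(),
        correlations=correlations,
        log=log,
        config=config,
    )
    if config.out_dir:
        result.write(config.out_dir)
    return result
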