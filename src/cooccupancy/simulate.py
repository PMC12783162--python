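"""Synthetic detection/non-detection surveys.

Generators mirror the likelihoods exactly: occupancy states are Bernoulli
draws from logit-linear (or constant) probabilities, detections are
occasion-level Bernoulli draws conditional on occupancy, and the two-species
generator couples the subordinate's occupancy and detection to the dominant
exactly as the conditional model assumes.  Every generator is a pure
function of its configuration and seed.

``generate_study_emulation`` produces a full spoor-survey emulation of a
two-park carnivore study design: 269 + 499 = 768 two-occasion sites, a
three-level substrate detection covariate, landscape covariates, five
prey/threat detection layers, and five carnivore layers whose occupancy is
coupled to the dominant predator (lion) with area-specific interaction
directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data import DetectionDataset
import pandas as pd

__all__ = [
    "SimulationConfig",
    "simulate_single",
    "simulate_two_species",
    "generate_study_emulation",
    "StudyEmulation",
    "EMULATION_CONFIG",
]

# Default substrate level frequencies for levels (1, 2, 3); the midpoint
# level 2 is the centring point of the substrate detection effect.
SUBSTRATE_FREQS = (0.4, 0.4, 0.2)


@dataclass
class SimulationConfig:
    """Generating values for one simulated survey.

    Probability blocks accept either a float (constant probability) or a
    logit-scale coefficient dict ``{"intercept": a, "<covariate>": b, ...}``
    with the special keys ``"substrate"`` (effect per level, centred at
    level 2) and ``"recap"`` (effect of the same species' previous-occasion
    detection).  Site covariates named in any dict are drawn N(0,1) unless
    given in ``covariates`` as ``("normal", mu, sd)`` or ``("beta", a, b)``.
    """

    n_sites: int
    n_occasions: int = 2
    seed: int = 0
    # single-species blocks
    psi: float | dict = 0.5
    p: float | dict = 0.5
    # two-species blocks (A dominant, B subordinate)
    psi_a: float | dict = 0.5
    psi_ba: float | dict = 0.5
    psi_ba0: float | dict = 0.5
    p_a: float | dict = 0.5
    r_a: float | dict | None = None  # defaults to p_a
    p_b: float | dict = 0.5
    r_ba: float | dict | None = None  # defaults to p_b
    r_ba0: float | dict | None = None  # defaults to p_b
    covariates: dict = field(default_factory=dict)
    substrate_freqs: tuple = SUBSTRATE_FREQS
    area: str = "all"


def _named_covariates(*blocks) -> list[str]:
    special = {"intercept", "substrate", "recap"}
    names: list[str] = []
    for b in blocks:
        if isinstance(b, dict):
            names.extend(k for k in b if k not in special and k not in names)
    return names


def _draw_covariates(rng, config: SimulationConfig, names: list[str]) -> pd.DataFrame:
    cols = {}
    for nm in names:
        spec = config.covariates.get(nm, ("normal", 0.0, 1.0))
        kind = spec[0]
        if kind == "normal":
            cols[nm] = rng.normal(spec[1], spec[2], size=config.n_sites)
        elif kind == "beta":
            cols[nm] = rng.beta(spec[1], spec[2], size=config.n_sites)
        else:
            raise ValueError(f"unknown covariate generator {kind!r}")
    return pd.DataFrame(cols, index=range(config.n_sites))


def _site_prob(block, covs: pd.DataFrame, n: int) -> np.ndarray:
    """Resolve a psi-type block to an (n,) probability vector."""
    if not isinstance(block, dict):
        return np.full(n, float(block))
    eta = np.full(n, float(block.get("intercept", 0.0)))
    for k, b in block.items():
        if k in ("intercept", "substrate", "recap"):
            continue
        eta += b * covs[k].to_numpy()
    return expit(eta)


def _occasion_prob(block, covs, substrate, prev, n, k_occ) -> np.ndarray:
    """Resolve a detection block to an (n, K) probability matrix."""
    if not isinstance(block, dict):
        return np.full((n, k_occ), float(block))
    eta = np.full((n, k_occ), float(block.get("intercept", 0.0)))
    for k, b in block.items():
        if k == "intercept":
            continue
        if k == "substrate":
            eta += b * (substrate - 2.0)
        elif k == "recap":
            eta += b * prev
        else:
            eta += b * covs[k].to_numpy()[:, None]
    return expit(eta)


def _draw_substrate(rng, n, k, freqs) -> np.ndarray:
    return rng.choice([1.0, 2.0, 3.0], size=(n, k), p=list(freqs))


def _draw_history(rng, z, block, covs, substrate, n, k_occ):
    """Detections for one species with lag-1 recapture feedback."""
    h = np.zeros((n, k_occ))
    prev = np.zeros((n, k_occ))
    for k in range(k_occ):
        if k > 0:
            prev[:, k] = h[:, k - 1]
        p = _occasion_prob(block, covs, substrate, prev, n, k_occ)[:, k]
        h[:, k] = rng.binomial(1, z * p)
    return h


def simulate_single(config: SimulationConfig):
    """Simulate one single-species survey; returns (dataset, truth).

    ``truth`` holds the latent occupancy states ``z``, the per-site psi and
    the realized detection probabilities, for parameter-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    covs = _draw_covariates(rng, config, _named_covariates(config.psi, config.p))
    n, k_occ = config.n_sites, config.n_occasions
    psi = _site_prob(config.psi, covs, n)
    z = rng.binomial(1, psi)
    substrate = _draw_substrate(rng, n, k_occ, config.substrate_freqs)
    h = _draw_history(rng, z, config.p, covs, substrate, n, k_occ)
    ds = DetectionDataset(
        site_id=np.array([f"s{i:05d}" for i in range(n)]),
        area=np.array([config.area] * n),
        histories={"species": h},
        site_covariates=covs.copy(),
        occasion_covariates={"substrate": substrate},
    )
    return ds, {"z": z, "psi": psi}


def simulate_two_species(config: SimulationConfig):
    """Simulate a coupled two-species survey; returns (dataset, truth).

    A's occupancy comes from psi_a; B's from psi_ba where A is present and
    psi_ba0 where absent.  On each occasion, A is detected with r_a (both
    present) or p_a (alone); B with r_ba / r_ba0 according to A's realized
    same-occasion detection (both present) or p_b (alone).
    """
    rng = np.random.default_rng(config.seed)
    r_a = config.r_a if config.r_a is not None else config.p_a
    r_ba = config.r_ba if config.r_ba is not None else config.p_b
    r_ba0 = config.r_ba0 if config.r_ba0 is not None else config.p_b
    covs = _draw_covariates(
        rng,
        config,
        _named_covariates(
            config.psi_a, config.psi_ba, config.psi_ba0,
            config.p_a, r_a, config.p_b, r_ba, r_ba0,
        ),
    )
    n, k_occ = config.n_sites, config.n_occasions
    psiA = _site_prob(config.psi_a, covs, n)
    psiBA = _site_prob(config.psi_ba, covs, n)
    psiBa = _site_prob(config.psi_ba0, covs, n)
    zA = rng.binomial(1, psiA)
    zB = rng.binomial(1, np.where(zA == 1, psiBA, psiBa))

    prevA = np.zeros((n, k_occ))
    prevB = np.zeros((n, k_occ))
    hA = np.zeros((n, k_occ))
    hB = np.zeros((n, k_occ))
    substrate = _draw_substrate(rng, n, k_occ, config.substrate_freqs)
    both = (zA == 1) & (zB == 1)
    for k in range(k_occ):
        if k > 0:
            prevA[:, k] = hA[:, k - 1]
            prevB[:, k] = hB[:, k - 1]
        pa = _occasion_prob(config.p_a, covs, substrate, prevA, n, k_occ)[:, k]
        ra = _occasion_prob(r_a, covs, substrate, prevA, n, k_occ)[:, k]
        probA = np.where(both, ra, pa)
        hA[:, k] = rng.binomial(1, zA * probA)
        pb = _occasion_prob(config.p_b, covs, substrate, prevB, n, k_occ)[:, k]
        rba = _occasion_prob(r_ba, covs, substrate, prevB, n, k_occ)[:, k]
        rba0 = _occasion_prob(r_ba0, covs, substrate, prevB, n, k_occ)[:, k]
        probB = np.where(both, np.where(hA[:, k] == 1, rba, rba0), pb)
        hB[:, k] = rng.binomial(1, zB * probB)

    ds = DetectionDataset(
        site_id=np.array([f"s{i:05d}" for i in range(n)]),
        area=np.array([config.area] * n),
        histories={"A": hA, "B": hB},
        site_covariates=covs.copy(),
        occasion_covariates={"substrate": substrate},
    )
    return ds, {"zA": zA, "zB": zB, "psiA": psiA, "psiBA": psiBA, "psiBa": psiBa}


# ---------------------------------------------------------------------------
# Study-design emulation
# ---------------------------------------------------------------------------

# Generating values for the two-park emulation.  Chosen to reproduce the
# qualitative structure of a spoor survey across a well-protected park
# ("Kruger": lion tracks water, wild dog avoids lion, hyena independent of
# lion) and a heavily-used park ("Limpopo": carnivores track prey, poaching
# and cattle widespread), with the wild dog the rarest carnivore.  These are
# the emulation's own defaults, not estimates from any real survey.
EMULATION_CONFIG: dict = {
    "areas": {"Kruger": 269, "Limpopo": 499},
    "landscape": ["water", "bushlands", "settlement_dist"],
    # prey/threat psi blocks per area (logit scale; landscape covariates are z-scaled draws)
    "prey": {
        "buffalo": {
            "Kruger": {"intercept": 0.6, "water": 1.2},
            "Limpopo": {"intercept": -0.5, "water": 1.2},
            "p": {"intercept": 0.5, "substrate": -0.5, "recap": 0.5},
        },
        "impala": {
            "Kruger": {"intercept": 0.3, "water": 0.9},
            "Limpopo": {"intercept": 0.0, "water": 0.9},
            "p": {"intercept": 0.7, "substrate": -0.5, "recap": 0.5},
        },
        "kudu": {
            "Kruger": {"intercept": 0.8, "bushlands": 0.8},
            "Limpopo": {"intercept": 0.4, "bushlands": 0.8},
            "p": {"intercept": 0.5, "substrate": -0.5, "recap": 0.5},
        },
        "cattle": {
            "Kruger": {"intercept": -3.5, "settlement_dist": -0.8},
            "Limpopo": {"intercept": -1.0, "settlement_dist": -1.0},
            "p": {"intercept": 0.8, "substrate": -0.4, "recap": 0.5},
        },
        "poaching": {
            "Kruger": {"intercept": -2.5, "settlement_dist": -0.6},
            "Limpopo": {"intercept": -1.2, "settlement_dist": -0.8},
            "p": {"intercept": 0.2, "substrate": -0.4, "recap": 0.5},
        },
    },
    # carnivore psi blocks; prey names refer to the prey's true occupancy
    # probability surface (centred at 0.5); "lion" in a subordinate block is
    # the conditional-occupancy contrast delta applied to lion's latent state
    "carnivores": {
        "lion": {
            "Kruger": {"intercept": -0.9, "water": 0.8},
            "Limpopo": {"intercept": -1.7, "buffalo": 2.4},
            "p": {"intercept": -0.4, "substrate": -0.5, "recap": 0.4},
        },
        "cheetah": {
            "Kruger": {"intercept": -2.1, "impala": 1.0, "lion": 1.3},
            "Limpopo": {"intercept": -2.3, "impala": 1.5, "lion": 1.1},
            "p": {"intercept": -0.5, "substrate": -0.4, "recap": 0.6},
        },
        "leopard": {
            "Kruger": {"intercept": -1.2, "water": 0.5, "lion": 0.8},
            "Limpopo": {"intercept": -1.1, "impala": 2.0, "lion": 0.9},
            "p": {"intercept": -0.2, "substrate": -0.4, "recap": 0.8},
        },
        "hyena": {
            "Kruger": {"intercept": -0.3, "bushlands": -0.7, "lion": 0.0},
            "Limpopo": {"intercept": -1.1, "kudu": 1.6, "lion": 0.8},
            "p": {"intercept": 0.6, "substrate": -0.4, "recap": 0.5},
        },
        "wild_dog": {
            "Kruger": {"intercept": -1.8, "bushlands": -0.6, "lion": -1.4},
            "Limpopo": {"intercept": -2.9, "lion": 0.8},
            "p": {"intercept": -0.9, "substrate": -0.4, "recap": 0.6},
        },
    },
}


@dataclass
class StudyEmulation:
    """A packaged study-design emulation: data plus generating truth."""

    dataset: DetectionDataset
    truth: dict
    config: dict

    def write_csv(self, path) -> None:
        from .data import write_detection_data

        write_detection_data(self.dataset, path)


def _emulate_area(rng, area: str, n: int, cfg: dict):
    k_occ = 2
    covs = pd.DataFrame({nm: rng.normal(0.0, 1.0, n) for nm in cfg["landscape"]})
    substrate = _draw_substrate(rng, n, k_occ, SUBSTRATE_FREQS)
    histories: dict[str, np.ndarray] = {}
    truth: dict = {"area": area}

    prey_prob: dict[str, np.ndarray] = {}
    for sp, spc in cfg["prey"].items():
        psi = _site_prob(spc[area], covs, n)
        z = rng.binomial(1, psi)
        histories[sp] = _draw_history(rng, z, spc["p"], covs, substrate, n, k_occ)
        prey_prob[sp] = psi
        truth[f"psi_{sp}"] = psi
        truth[f"z_{sp}"] = z

    def carnivore_psi(block, z_lion):
        eta = np.full(n, float(block.get("intercept", 0.0)))
        for k, b in block.items():
            if k in ("intercept", "lion"):
                continue
            if k in prey_prob:
                eta += b * (prey_prob[k] - 0.5)
            else:
                eta += b * covs[k].to_numpy()
        if z_lion is not None and "lion" in block:
            eta += block["lion"] * z_lion
        return expit(eta)

    lion_cfg = cfg["carnivores"]["lion"]
    psi_lion = carnivore_psi(lion_cfg[area], None)
    z_lion = rng.binomial(1, psi_lion)
    histories["lion"] = _draw_history(rng, z_lion, lion_cfg["p"], covs, substrate, n, k_occ)
    truth["psi_lion"], truth["z_lion"] = psi_lion, z_lion

    for sp, spc in cfg["carnivores"].items():
        if sp == "lion":
            continue
        psi = carnivore_psi(spc[area], z_lion)
        z = rng.binomial(1, psi)
        histories[sp] = _draw_history(rng, z, spc["p"], covs, substrate, n, k_occ)
        truth[f"psi_{sp}"] = psi
        truth[f"z_{sp}"] = z

    ds = DetectionDataset(
        site_id=np.array([f"{area[:3].lower()}_{i:04d}" for i in range(n)]),
        area=np.array([area] * n),
        histories=histories,
        site_covariates=covs,
        occasion_covariates={"substrate": substrate},
    )
    return ds, truth


def _concat_datasets(parts: list[DetectionDataset]) -> DetectionDataset:
    return DetectionDataset(
        site_id=np.concatenate([p.site_id for p in parts]),
        area=np.concatenate([p.area for p in parts]),
        histories={
            sp: np.concatenate([p.histories[sp] for p in parts]) for sp in parts[0].species
        },
        site_covariates=pd.concat(
            [p.site_covariates for p in parts], ignore_index=True
        ),
        occasion_covariates={
            nm: np.concatenate([p.occasion_covariates[nm] for p in parts])
            for nm in parts[0].occasion_covariates
        },
    )


def generate_study_emulation(seed: int = 0, config: dict | None = None) -> StudyEmulation:
    """Generate the full two-park, 768-site study emulation.

    Deterministic in ``seed``: the same seed yields a byte-identical CSV via
    :meth:`StudyEmulation.write_csv`.
    """
    cfg = config or EMULATION_CONFIG
    rng = np.random.default_rng(seed)
    parts, truths = [], {}
    for area, n in cfg["areas"].items():
        ds, truth = _emulate_area(rng, area, n, cfg)
        parts.append(ds)
        truths[area] = truth
    return StudyEmulation(_concat_datasets(parts), truths, cfg)
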