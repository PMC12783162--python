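import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import cooccupancy as co

from conftest import make_dataset

probs = st.floats(0.03, 0.97)


def two_species_enumeration(params, hA, hB):
    """Explicit 4-latent-state oracle for one site's joint likelihood."""
    hA, hB = np.asarray(hA, float), np.asarray(hB, float)
    obsA, obsB = ~np.isnan(hA), ~np.isnan(hB)
    w = [
        params.psiA * params.psiBA,
        params.psiA * (1 - params.psiBA),
        (1 - params.psiA) * params.psiBa,
        (1 - params.psiA) * (1 - params.psiBa),
    ]

    def bern(p, h, obs):
        return np.prod(np.where(obs, np.where(h == 1, p, 1 - p), 1.0))

    noA = not np.any(hA[obsA] == 1)
    noB = not np.any(hB[obsB] == 1)
    q = np.where(np.nan_to_num(hA) == 1, params.rBA, params.rBa)
    states = [
        bern(params.rA, hA, obsA) * bern(q, hB, obsB),
        bern(params.pA, hA, obsA) * noB,
        noA * bern(params.pB, hB, obsB),
        float(noA and noB),
    ]
    return float(np.dot(w, states))


class TestJointStateProbs:
    def test_hand_values(self):
        np.testing.assert_allclose(
            co.joint_state_probs(0.18, 0.08, 0.01),
            [0.0144, 0.1656, 0.0082, 0.8118],
            atol=1e-12,
        )

    def test_dominant_certain(self):
        w = co.joint_state_probs(1.0, 0.3, 0.9)
        assert w[2] == 0.0 and w[3] == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(a=probs, ba=probs, b0=probs)
    def test_sums_to_one(self, a, ba, b0):
        assert co.joint_state_probs(a, ba, b0).sum() == pytest.approx(1.0, abs=1e-12)


class TestSiteLikelihoodTwo:
    def test_all_half_no_detections(self):
        p = co.TwoSpeciesParams.constant(0.5)
        assert co.site_likelihood_two(p, [0, 0], [0, 0]) == pytest.approx(
            0.390625, abs=1e-12
        )

    def test_subordinate_never_present(self):
        p = co.TwoSpeciesParams(0.6, 0.0, 0.0, 0.4, 0.5, 0.4, 0.5, 0.5)
        # B impossible: likelihood reduces to A-only term psiA * pA(1-pA)
        assert co.site_likelihood_two(p, [1, 0], [0, 0]) == pytest.approx(
            0.6 * 0.4 * 0.6, abs=1e-12
        )

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(co.ValidationError):
            co.site_likelihood_two(co.TwoSpeciesParams.constant(0.5), [1, 0], [1, 0, 0])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        a=probs, ba=probs, b0=probs, pA=probs, pB=probs, rA=probs, rBA=probs, rBa=probs
    )
    def test_normalizes_over_joint_histories(self, a, ba, b0, pA, pB, rA, rBA, rBa):
        """Sum over all 16 (K=2) joint histories is exactly 1."""
        params = co.TwoSpeciesParams(a, ba, b0, pA, pB, rA, rBA, rBa)
        total = sum(
            co.site_likelihood_two(params, hA, hB)
            for hA in itertools.product([0, 1], repeat=2)
            for hB in itertools.product([0, 1], repeat=2)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_normalizes_k3(self):
        params = co.TwoSpeciesParams(0.45, 0.7, 0.25, 0.5, 0.35, 0.6, 0.55, 0.3)
        total = sum(
            co.site_likelihood_two(params, hA, hB)
            for hA in itertools.product([0, 1], repeat=3)
            for hB in itertools.product([0, 1], repeat=3)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        a=probs, ba=probs, b0=probs, pA=probs, pB=probs, rA=probs, rBA=probs, rBa=probs,
        hA1=st.integers(0, 1), hA2=st.integers(0, 1),
        hB1=st.integers(0, 1), hB2=st.integers(0, 1),
    )
    def test_matches_latent_state_enumeration(
        self, a, ba, b0, pA, pB, rA, rBA, rBa, hA1, hA2, hB1, hB2
    ):
        params = co.TwoSpeciesParams(a, ba, b0, pA, pB, rA, rBA, rBa)
        lhs = co.site_likelihood_two(params, [hA1, hA2], [hB1, hB2])
        rhs = two_species_enumeration(params, [hA1, hA2], [hB1, hB2])
        assert lhs == pytest.approx(rhs, abs=1e-14)

    def test_b_marginal_reduces_to_single_species(self):
        """With psiBA = psiBa and pB = rBA = rBa, summing the joint likelihood
        over A's histories recovers B's single-species likelihood."""
        params = co.TwoSpeciesParams(0.37, 0.44, 0.44, 0.52, 0.31, 0.66, 0.31, 0.31)
        for hB in itertools.product([0, 1], repeat=2):
            marginal = sum(
                co.site_likelihood_two(params, hA, hB)
                for hA in itertools.product([0, 1], repeat=2)
            )
            single = co.site_likelihood_single(0.44, [0.31, 0.31], hB)
            assert marginal == pytest.approx(single, abs=1e-10)


class TestComputeSIF:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(a=probs, x=probs)
    def test_independence_identity_exact(self, a, x):
        assert co.compute_sif(a, x, x) == 1.0

    def test_hand_value_near_table(self):
        # psiB = 0.19*0.37 + 0.81*0.36 = 0.3619; phi = 0.0703 / (0.19*0.3619)
        assert co.compute_sif(0.19, 0.37, 0.36) == pytest.approx(
            0.0703 / (0.19 * 0.3619), abs=1e-12
        )
        assert co.compute_sif(0.19, 0.37, 0.36) == pytest.approx(1.0224, abs=1e-3)

    def test_subordinate_only_with_dominant(self):
        # psiBa = 0 makes phi collapse to 1/psiA
        for a in (0.2, 0.5, 0.9):
            assert co.compute_sif(a, 0.3, 0.0) == pytest.approx(1 / a, abs=1e-12)

    def test_printed_denominator_variant(self):
        assert co.compute_sif(
            0.19, 0.37, 0.36, printed_denominator=True
        ) == pytest.approx(0.19 * 0.37 / (0.37 * 0.36), abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            co.compute_sif(1.0, 0.5, 0.5)
        with pytest.raises(ValueError):
            co.compute_sif(0.5, 0.0, 0.0)


class TestFitTwoSpecies:
    def test_recovers_generating_parameters(self):
        """psiA=0.5, psiBA=0.7, psiBa=0.3, p=0.6, n=3000: within 0.07 of truth."""
        cfg = co.SimulationConfig(
            n_sites=3000, seed=7, psi_a=0.5, psi_ba=0.7, psi_ba0=0.3, p_a=0.6, p_b=0.6
        )
        ds, _ = co.simulate_two_species(cfg)
        fit = co.fit_two_species(ds, "A", "B", n_starts=5, seed=0)
        assert fit.converged
        est = {k: float(expit(fit.beta[v])[0]) for k, v in fit.blocks.items()}
        assert est["psiBA"] > est["psiBa"]
        assert est["psiA"] == pytest.approx(0.5, abs=0.07)
        assert est["psiBA"] == pytest.approx(0.7, abs=0.07)
        assert est["psiBa"] == pytest.approx(0.3, abs=0.07)

    def test_sp_preferred_under_true_independence(self):
        """When psiBA = psiBa truly, the SP constraint wins AIC most of the time."""
        wins = 0
        n_rep = 60
        for rep in range(n_rep):
            cfg = co.SimulationConfig(
                n_sites=600, seed=40_000 + rep,
                psi_a=0.5, psi_ba=0.5, psi_ba0=0.5, p_a=0.55, p_b=0.55,
            )
            ds, _ = co.simulate_two_species(cfg)
            sp = co.fit_two_species(ds, "A", "B", interaction=False, n_starts=2, seed=0)
            intr = co.fit_two_species(ds, "A", "B", interaction=True, n_starts=2, seed=0)
            if sp.converged and intr.converged and sp.aic <= intr.aic:
                wins += 1
        assert wins > n_rep / 2

    def test_matches_grid_search_oracle(self):
        """Intercept-only SP+INT fit vs an iterative-zoom brute-force grid."""
        patterns_A = np.array([[1, 0], [0, 0], [0, 1], [1, 1], [0, 0]], float)
        patterns_B = np.array([[0, 1], [0, 0], [1, 0], [0, 0], [1, 1]], float)
        hA = np.repeat(patterns_A, 4, axis=0)
        hB = np.repeat(patterns_B, 4, axis=0)
        ds = make_dataset(hA, hB)
        fit = co.fit_two_species(ds, "A", "B", n_starts=8, seed=0)
        assert fit.converged

        def grid_nll(theta):
            psiA, psiBA, psiBa, pA, pB = (theta[..., i] for i in range(5))
            out = 0.0
            for a, b in zip(patterns_A, patterns_B):
                prA = np.prod(np.where(a == 1, pA[..., None], 1 - pA[..., None]), axis=-1)
                prB = np.prod(np.where(b == 1, pB[..., None], 1 - pB[..., None]), axis=-1)
                noA, noB = float((a == 0).all()), float((b == 0).all())
                lik = (
                    psiA * psiBA * prA * prB
                    + psiA * (1 - psiBA) * prA * noB
                    + (1 - psiA) * psiBa * noA * prB
                    + (1 - psiA) * (1 - psiBa) * noA * noB
                )
                out = out - 4.0 * np.log(np.maximum(lik, 1e-300))
            return out

        lo, hi = np.full(5, 0.01), np.full(5, 0.99)
        for _ in range(6):
            axes = [np.linspace(lo[i], hi[i], 13) for i in range(5)]
            grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 5)
            best = grid[np.argmin(grid_nll(grid))]
            span = (hi - lo) / 6
            lo = np.clip(best - span, 1e-4, 1 - 1e-4)
            hi = np.clip(best + span, 1e-4, 1 - 1e-4)

        fitted = np.array(
            [float(expit(fit.beta[fit.blocks[k]])[0]) for k in ("psiA", "psiBA", "psiBa", "pA", "pB")]
        )
        np.testing.assert_allclose(fitted, best, atol=1e-3)
        assert fit.neg2loglik / 2 == pytest.approx(grid_nll(best[None])[0], abs=1e-3)

    def test_zero_detection_species_graceful(self):
        ds = make_dataset(np.zeros((30, 2)), np.eye(30, 2))
        fit = co.fit_two_species(ds, "A", "B", n_starts=2, seed=0)
        assert not fit.converged
        assert "zero detections" in fit.message


class TestSIFEstimate:
    def test_sp_constraint_forces_independence(self):
        cfg = co.SimulationConfig(
            n_sites=800, seed=5, psi_a=0.5, psi_ba=0.5, psi_ba0=0.5, p_a=0.5, p_b=0.5
        )
        ds, _ = co.simulate_two_species(cfg)
        fit = co.fit_two_species(ds, "A", "B", interaction=False, n_starts=3, seed=0)
        est = co.sif_estimate(fit)
        assert np.all(est.phi_site == 1.0)
        assert est.se == 0.0 and not est.significant

    def test_intercept_only_matches_scalar_sif(self):
        cfg = co.SimulationConfig(
            n_sites=1500, seed=6, psi_a=0.5, psi_ba=0.7, psi_ba0=0.3, p_a=0.6, p_b=0.6
        )
        ds, _ = co.simulate_two_species(cfg)
        fit = co.fit_two_species(ds, "A", "B", n_starts=3, seed=0)
        est = co.sif_estimate(fit)
        scalars = [float(expit(fit.beta[fit.blocks[k]])[0]) for k in ("psiA", "psiBA", "psiBa")]
        assert est.phi_mean == pytest.approx(co.compute_sif(*scalars), abs=1e-12)
        assert est.se > 0

    def test_unconverged_fit_rejected(self):
        ds = make_dataset(np.zeros((20, 2)), np.zeros((20, 2)))
        fit = co.fit_two_species(ds, "A", "B", n_starts=2, seed=0)
        with pytest.raises(co.ValidationError):
            co.sif_estimate(fit)


@pytest.fixture(scope="module")
def cov_fit():
    # the covariate enters psiBa only, so d(phi)/dx < 0 along the grid
    cfg = co.SimulationConfig(
            n_sites=2500, seed=9,
        psi_a=0.5,
        psi_ba={"intercept": 0.6},
        psi_ba0={"intercept": -0.6, "x": 0.9},
        p_a=0.55, p_b=0.55,
    )
    ds, _ = co.simulate_two_species(cfg)
    ds = co.standardize_covariates(ds, ["x"])
    fit = co.fit_two_species(
        ds, "A", "B",
        psi_a_terms=[], psi_ba_terms=[], psi_ba0_terms=["x"],
        n_starts=5, seed=0,
    )
    return ds, fit


class TestSIFProfile:

    def test_positive_psiBa_slope_gives_decreasing_phi(self, cov_fit):
        ds, fit = cov_fit
        assert fit.converged
        prof = co.sif_profile(fit, ds, "x", n_points=12)
        assert fit.beta[fit.blocks["psiBa"]][1] > 0  # recovered positive slope
        assert np.all(np.diff(prof["phi"].to_numpy()) < 0)
        assert np.all(prof["se_phi"].to_numpy() >= 0)

    def test_profile_at_mean_matches_intercepts(self, cov_fit):
        ds, fit = cov_fit
        mu, _ = ds.standardization["x"]
        prof = co.sif_profile(fit, ds, "x", grid=np.array([mu]))
        psiA0 = float(expit(fit.beta[fit.blocks["psiA"]][0]))
        psiBA0 = float(expit(fit.beta[fit.blocks["psiBA"]][0]))
        psiBa0 = float(expit(fit.beta[fit.blocks["psiBa"]][0]))
        assert prof["phi"].iloc[0] == pytest.approx(
            co.compute_sif(psiA0, psiBA0, psiBa0), abs=1e-10
        )

    def test_flat_when_no_slopes(self):
        cfg = co.SimulationConfig(
            n_sites=1200, seed=13, psi_a=0.5, psi_ba=0.65, psi_ba0=0.35,
            p_a=0.55, p_b=0.55, covariates={"x": ("normal", 0.0, 1.0)},
        )
        ds, _ = co.simulate_two_species(cfg)
        ds.site_covariates["x"] = np.random.default_rng(0).normal(size=ds.n_sites)
        fit = co.fit_two_species(
            ds, "A", "B", psi_a_terms=["x"], n_starts=4, seed=0
        )
        # force the x slope to zero: profile must be flat
        fit.beta[fit.blocks["psiA"]][1] = 0.0
        prof = co.sif_profile(fit, ds, "x", n_points=8)
        assert prof["phi"].std() == pytest.approx(0.0, abs=1e-12)

    def test_absent_covariate_rejected(self, cov_fit):
        ds, fit = cov_fit
        with pytest.raises(co.ValidationError):
            co.sif_profile(fit, ds, "nope")
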