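import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, roots_hermitenorm

from genegroups import animal_model as am
from genegroups import pedigree as pdg
from genegroups.animal_model import ChainConfig, PriorSpec, _gibbs
from genegroups.drift import gene_drop
from genegroups.simulate import reduced_config, simulate_reliable
from conftest import toy_observations


def _quiet_fit(fitter, design, chain, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fitter(design, chain=chain, **kw)


class TestBuildDesign:
    def test_columns_and_centring(self):
        obs, ped = toy_observations(100, seed=1)
        d = am.build_design(obs, ped)
        assert d.columns == ["intercept", "q", "f", "year", "clutch_date", "sex"]
        year = d.X[:, d.columns.index("year")]
        clutch = d.X[:, d.columns.index("clutch_date")]
        assert abs(year.mean()) < 1e-12
        assert abs(clutch.mean()) < 1e-12

    def test_single_brood_single_level(self):
        obs, ped = toy_observations(8, seed=2)
        obs["brood_id"] = "only"
        obs["cohort"] = 2000
        d = am.build_design(obs, ped)
        assert len(d.brood_levels) == 1

    def test_all_female_sex_column_zero(self):
        obs, ped = toy_observations(10, seed=3)
        obs["sex"] = "F"
        d = am.build_design(obs, ped)
        assert not d.X[:, d.columns.index("sex")].any()

    def test_missing_covariate_lists_ids(self):
        obs, ped = toy_observations(10, seed=4)
        obs.loc[3, "clutch_date"] = np.nan
        with pytest.raises(am.ModelError, match="I3"):
            am.build_design(obs, ped)

    def test_brood_spanning_cohorts_rejected(self):
        obs, ped = toy_observations(10, seed=5)
        obs["brood_id"] = "shared"
        with pytest.raises(am.ModelError, match="cohort"):
            am.build_design(obs, ped)

    def test_unknown_id_rejected(self):
        obs, ped = toy_observations(10, seed=6)
        obs.loc[0, "id"] = "STRANGER"
        with pytest.raises(am.ModelError, match="STRANGER"):
            am.build_design(obs, ped)


class TestFitValidation:
    def test_non_binary_phenotype_rejected(self):
        obs, ped = toy_observations(20, seed=7)
        d = am.build_design(obs, ped)
        d.y = d.y + 0.5
        with pytest.raises(am.ModelError, match="binary"):
            am.fit(d)

    def test_constant_q_inestimable(self):
        obs, ped = toy_observations(20, seed=8)
        obs["q"] = 0.25
        d = am.build_design(obs, ped)
        with pytest.raises(am.ModelError, match="inestimable"):
            am.fit(d)


class TestDeterminism:
    def test_same_seed_identical_draws(self, reduced_dataset):
        res, ped = reduced_dataset
        d = am.build_design(res.observations, ped)
        chain = ChainConfig(iterations=60, burn_in=20, thin=1, seed=42)
        s1 = _quiet_fit(am.fit, d, chain)
        s2 = _quiet_fit(am.fit, d, chain)
        assert np.array_equal(s1.beta, s2.beta)
        assert np.array_equal(s1.v_a, s2.v_a)
        assert np.array_equal(s1.a, s2.a)

    def test_no_groups_variant_deterministic(self, reduced_dataset):
        res, ped = reduced_dataset
        d = am.build_design(res.observations, ped)
        chain = ChainConfig(iterations=40, burn_in=10, thin=1, seed=5)
        s1 = _quiet_fit(am.fit_no_groups_variant, d, chain)
        s2 = _quiet_fit(am.fit_no_groups_variant, d, chain)
        assert "q" not in s1.beta_columns
        assert np.array_equal(s1.beta, s2.beta)


class TestGaussianOracle:
    def test_posterior_means_match_mme_blup(self):
        """With variances fixed at truth, the Gaussian-response variant must
        reproduce BLUP/GLS from directly solved mixed-model equations."""
        res = simulate_reliable(
            reduced_config(seed=7, n_cohorts=3, n_founders=8,
                           adult_capacity=20), min_observations=30)
        obs = res.observations
        ped = pdg.prune_to_phenotyped(res.build_pedigree(), obs["id"])
        design = am.build_design(obs, ped)
        rng = np.random.default_rng(0)
        truth = {"V_A": 0.5, "V_brood": 0.3, "V_year": 0.4, "V_residual": 1.0}
        a_true = gene_drop(ped, truth["V_A"], seed=11)
        b_true = rng.normal(0, np.sqrt(truth["V_brood"]), len(design.brood_levels))
        c_true = rng.normal(0, np.sqrt(truth["V_year"]), len(design.year_levels))
        beta_true = np.array([0.5, -1.0, -2.0, 0.1, -0.01, 0.3])
        design.y = (design.X @ beta_true + a_true[design.animal_idx]
                    + b_true[design.brood_idx] + c_true[design.year_idx]
                    + rng.normal(0, 1, design.n_obs))

        s = am.fit_gaussian(design, chain=ChainConfig(
            iterations=4000, burn_in=500, thin=1, seed=2),
            fixed_variances=truth)

        # dense MME oracle
        n, p = design.X.shape
        n_ped = design.n_ped
        n_b, n_c = len(design.brood_levels), len(design.year_levels)
        Za = np.zeros((n, n_ped)); Za[np.arange(n), design.animal_idx] = 1
        Zb = np.zeros((n, n_b)); Zb[np.arange(n), design.brood_idx] = 1
        Zc = np.zeros((n, n_c)); Zc[np.arange(n), design.year_idx] = 1
        W = np.hstack([design.X, Za, Zb, Zc])
        Ginv = np.zeros((p + n_ped + n_b + n_c,) * 2)
        Ginv[:p, :p] = np.eye(p) / 1e10
        Ginv[p:p + n_ped, p:p + n_ped] = design.a_inv.toarray() / truth["V_A"]
        Ginv[p + n_ped:p + n_ped + n_b, p + n_ped:p + n_ped + n_b] = \
            np.eye(n_b) / truth["V_brood"]
        Ginv[p + n_ped + n_b:, p + n_ped + n_b:] = np.eye(n_c) / truth["V_year"]
        sol = np.linalg.solve(W.T @ W + Ginv, W.T @ design.y)
        assert np.abs(s.a.mean(axis=0) - sol[p:p + n_ped]).max() < 0.05
        assert np.abs(s.beta.mean(axis=0) - sol[:p]).max() < 0.05


class TestBinaryOracle:
    def test_posterior_matches_numerical_integration(self):
        """With variance components pinned near zero the model reduces to a
        logistic-normal regression whose posterior is computable by
        quadrature; the PG sampler must reproduce it."""
        rng = np.random.default_rng(5)
        n = 60
        x = rng.random(n)
        y = (rng.random(n) < expit(0.4 - 2.0 * x + rng.normal(0, 1, n))).astype(float)
        ped = pdg.Pedigree([pdg.Individual(id=f"I{i}", cohort=2000 + (i % 3))
                            for i in range(n)])
        obs = pd.DataFrame({
            "id": [f"I{i}" for i in range(n)], "survival": y, "sex": "F",
            "clutch_date": 0.0,
            "brood_id": [f"{2000 + (i % 3)}_b{i}" for i in range(n)],
            "cohort": [2000 + (i % 3) for i in range(n)], "q": x, "f": 0.0})
        design = am.build_design(obs, ped)
        keep = [design.columns.index("intercept"), design.columns.index("q")]
        design.X = design.X[:, keep]
        design.columns = ["intercept", "q"]

        s = _gibbs(design, PriorSpec(),
                   ChainConfig(iterations=12000, burn_in=1000, thin=2, seed=9),
                   binary=True,
                   fixed_variances={"V_A": 1e-10, "V_brood": 1e-10,
                                    "V_year": 1e-10},
                   autocorr_warn=np.inf)

        nodes, w0 = roots_hermitenorm(41)
        w0 = w0 / np.sqrt(2 * np.pi)

        def loglik(b0, b1):
            p = (expit((b0 + b1 * x)[:, None] + nodes[None, :]) * w0).sum(axis=1)
            return np.log(np.where(y == 1, p, 1 - p)).sum()

        b0g = np.linspace(-2.5, 3.5, 121)
        b1g = np.linspace(-7, 3, 121)
        L = np.array([[loglik(a_, b_) for b_ in b1g] for a_ in b0g])
        P = np.exp(L - L.max())
        P /= P.sum()
        m0 = (P.sum(axis=1) * b0g).sum()
        m1 = (P.sum(axis=0) * b1g).sum()
        s1 = np.sqrt((P.sum(axis=0) * (b1g - m1) ** 2).sum())
        assert s.beta[:, 0].mean() == pytest.approx(m0, abs=0.05)
        assert s.beta[:, 1].mean() == pytest.approx(m1, abs=0.08)
        assert s.beta[:, 1].std() == pytest.approx(s1, rel=0.1)


class TestHeritability:
    def test_ratio_arithmetic(self):
        s = am.PosteriorSamples(
            v_a=np.array([1.0, 0.36]), v_brood=np.array([0.0, 0.19]),
            v_year=np.array([0.0, 1.11]), beta=np.zeros((2, 1)),
            beta_columns=["intercept"], a=np.zeros((2, 1)), ped_ids=["x"],
            year_levels=[2000])
        h2 = am.heritability(s)
        assert h2[0] == pytest.approx(0.5)
        assert h2[1] == pytest.approx(0.36 / 2.66)  # ~0.135, near reported 0.13
        assert np.all((h2 > 0) & (h2 < 1))


class TestNullAndPermutation:
    def test_zero_genetic_variance_recovered(self):
        """Data simulated without additive variance: posterior V_A should
        concentrate below the simulated brood variance."""
        res = simulate_reliable(reduced_config(seed=21, v_a=0.0, v_brood=0.6),
                                min_observations=450)
        obs = res.observations
        ped = pdg.prune_to_phenotyped(res.build_pedigree(), obs["id"])
        d = am.build_design(obs, ped)
        s = _quiet_fit(am.fit, d, ChainConfig(iterations=500, burn_in=200,
                                              thin=1, seed=1))
        assert np.median(s.v_a) < 0.6

    def test_label_permutation_shrinks_group_effect(self):
        """Permuting phenotypes across individuals destroys the q-survival
        association, so |posterior mean g| must collapse."""
        res = simulate_reliable(reduced_config(seed=22, g=-4.0),
                                min_observations=450)
        obs = res.observations
        ped = pdg.prune_to_phenotyped(res.build_pedigree(), obs["id"])
        d = am.build_design(obs, ped)
        chain = ChainConfig(iterations=500, burn_in=200, thin=1, seed=2)
        s_real = _quiet_fit(am.fit, d, chain)
        rng = np.random.default_rng(0)
        obs_perm = obs.copy()
        obs_perm["survival"] = rng.permutation(obs["survival"].to_numpy())
        d_perm = am.build_design(obs_perm, ped)
        s_perm = _quiet_fit(am.fit, d_perm, chain)
        assert abs(s_perm.g.mean()) < 0.5 * abs(s_real.g.mean())

    def test_variants_agree_when_g_zero(self):
        res = simulate_reliable(reduced_config(seed=23, g=0.0),
                                min_observations=450)
        obs = res.observations
        ped = pdg.prune_to_phenotyped(res.build_pedigree(), obs["id"])
        d = am.build_design(obs, ped)
        chain = ChainConfig(iterations=600, burn_in=200, thin=1, seed=3)
        s_groups = _quiet_fit(am.fit, d, chain)
        s_plain = _quiet_fit(am.fit_no_groups_variant, d, chain)
        total1 = s_groups.v_a + s_groups.v_brood + s_groups.v_year
        total2 = s_plain.v_a + s_plain.v_brood + s_plain.v_year
        assert abs(total1.mean() - total2.mean()) / total1.mean() < 0.25


def test_target_autocorr_refit_doubles_thinning(reduced_dataset):
    res, ped = reduced_dataset
    d = am.build_design(res.observations, ped)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s = am.fit_with_target_autocorr(
            d, chain=ChainConfig(iterations=60, burn_in=10, thin=1, seed=0),
            target=1e-9, max_rounds=2)
    assert s.thin == 2  # one doubling after the unattainable-target first round


class TestSummaries:
    def test_hpd_contains_central_mass(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(20_000)
        lo, hi = am.hpd_interval(draws)
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)

    def test_summary_layout(self, reduced_dataset):
        res, ped = reduced_dataset
        d = am.build_design(res.observations, ped)
        s = _quiet_fit(am.fit, d, ChainConfig(iterations=50, burn_in=10,
                                              thin=1, seed=0))
        tab = s.summary()
        assert {"parameter", "posterior_mean", "posterior_mode", "hpd_lower",
                "hpd_upper", "prop_negative"} <= set(tab.columns)
        assert "V_A" in tab["parameter"].values
        assert "heritability" in tab["parameter"].values

    def test_save_load_roundtrip(self, tmp_path, reduced_dataset):
        res, ped = reduced_dataset
        d = am.build_design(res.observations, ped)
        s = _quiet_fit(am.fit, d, ChainConfig(iterations=30, burn_in=5,
                                              thin=1, seed=0))
        s.save(tmp_path / "s.npz")
        back = am.PosteriorSamples.load(tmp_path / "s.npz")
        assert np.array_equal(back.beta, s.beta)
        assert back.beta_columns == s.beta_columns
        assert np.array_equal(back.a, s.a)
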