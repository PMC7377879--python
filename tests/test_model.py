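import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from trajmix import (
    MixtureState,
    ModelData,
    ModelSpec,
    Priors,
    deviance,
    linear_predictor,
    log_component_marginal,
    log_mixture_likelihood,
)
from trajmix.data import with_observations
from trajmix.model import ModelError

from conftest import make_dataset


def toy_model(values, covariates=None, fixed=(), K=1):
    ds = make_dataset(values, covariates)
    spec = ModelSpec(K=K, panel=ds.panel, fixed_covariates=tuple(fixed),
                     center_covariates=False)
    return ds, ModelData(ds, spec), spec


def make_state(spec, N, *, w=None, mu=None, D=None, beta=None, phi=None, b=None, U=None):
    K, q, J, p = spec.K, spec.q, spec.J, spec.p
    return MixtureState(
        w=np.full(K, 1.0 / K) if w is None else np.asarray(w, float),
        mu=np.zeros((K, q)) if mu is None else np.asarray(mu, float),
        D=np.repeat(np.eye(q)[None], K, axis=0) if D is None else np.asarray(D, float),
        beta=np.zeros((J, p)) if beta is None else np.asarray(beta, float),
        phi=np.ones(J) if phi is None else np.asarray(phi, float),
        b=np.zeros((N, q)) if b is None else np.asarray(b, float),
        U=np.zeros(N, dtype=int) if U is None else np.asarray(U, int),
    )


def mc_log_marginal(data, sid, k, state, n_draws, rng):
    """Brute-force Monte-Carlo integration over the random effects.

    Independent oracle for the closed-form component marginal:
    log (1/M) sum_s p(y | b_s) with b_s ~ N(mu_k, D_k).
    """
    g, col = data.locate(sid)
    y = g.Y[:, col]
    fixed = g.fixed_contrib(state.beta)[:, col]
    phi_obs = state.phi[g.region_of_obs]
    L = np.linalg.cholesky(state.D[k])
    B = state.mu[k][None, :] + rng.standard_normal((n_draws, state.mu.shape[1])) @ L.T
    means = fixed[:, None] + g.Z @ B.T                     # (m, M)
    ll = -0.5 * (((y[:, None] - means) ** 2) / phi_obs[:, None]
                 + np.log(2 * np.pi * phi_obs)[:, None]).sum(axis=0)
    lmax = ll.max()
    wts = np.exp(ll - lmax)
    est = lmax + np.log(wts.mean())
    se = wts.std(ddof=1) / (wts.mean() * np.sqrt(n_draws))
    return est, se


class TestLinearPredictor:
    def test_intercept_only(self):
        ds, data, spec = toy_model({"p": ("patient", {("rA", 0): 1, ("rA", 12): 1, ("rA", 24): 1})})
        state = make_state(spec, 1, b=[[3.5, 0.0]])
        np.testing.assert_allclose(linear_predictor(data, "p", "rA", state), [3.5] * 3)

    def test_slope_only_time_in_years(self):
        ds, data, spec = toy_model({"p": ("patient", {("rA", 0): 0, ("rA", 12): 0, ("rA", 24): 0})})
        state = make_state(spec, 1, b=[[0.0, -0.5]])
        # slope is per year: visits at 0/12/24 months are 0/1/2 years
        np.testing.assert_allclose(linear_predictor(data, "p", "rA", state), [0.0, -0.5, -1.0])

    def test_fixed_effect_only(self):
        ds, data, spec = toy_model(
            {"p": ("patient", {("rA", 0): 0, ("rA", 12): 0})},
            covariates={"p": {"x": 3.0}}, fixed=("x",),
        )
        state = make_state(spec, 1, beta=[[2.0]])
        np.testing.assert_allclose(linear_predictor(data, "p", "rA", state), [6.0, 6.0])


class TestComponentMarginal:
    def _instance(self):
        ds, data, spec = toy_model(
            {"p": ("patient", {("rA", 0): -1.0, ("rA", 12): -2.0,
                               ("rB", 0): 0.5, ("rB", 12): -0.5})},
        )
        q = spec.q
        rng = np.random.default_rng(7)
        A = rng.standard_normal((q, q)) * 0.3
        D = A @ A.T + 0.5 * np.eye(q)
        mu = np.array([[-1.0, -0.5, 0.2, -0.3]])
        state = make_state(spec, 1, mu=mu, D=D[None], phi=[0.8, 1.3])
        return data, state

    def test_degenerate_random_effects_limit(self):
        data, state = self._instance()
        state.D = 1e-12 * np.eye(4)[None]
        got = log_component_marginal(data, "p", 0, state)
        g, col = data.locate("p")
        mean = g.Z @ state.mu[0]
        sd = np.sqrt(state.phi[g.region_of_obs])
        expected = norm.logpdf(g.Y[:, col], mean, sd).sum()
        assert got == pytest.approx(expected, abs=1e-6)

    def test_matches_monte_carlo(self):
        data, state = self._instance()
        closed = log_component_marginal(data, "p", 0, state)
        est, se = mc_log_marginal(data, "p", 0, state, 20_000, np.random.default_rng(11))
        assert abs(closed - est) < 4 * se

    def test_invariant_to_observation_row_order(self):
        ds, data, spec = toy_model(
            {"p": ("patient", {("rA", 0): -1.0, ("rA", 12): -2.0,
                               ("rB", 0): 0.5, ("rB", 12): -0.5})},
        )
        state = make_state(spec, 1)
        ref = log_component_marginal(data, "p", 0, state)
        shuffled = ds.observations.sample(frac=1.0, random_state=3)
        data2 = ModelData(with_observations(ds, shuffled), spec)
        assert log_component_marginal(data2, "p", 0, state) == pytest.approx(ref, rel=1e-12)


class TestMixtureLikelihoodAndDeviance:
    def _setup(self, K=2):
        ds, data, spec = toy_model(
            {"p1": ("patient", {("rA", 0): -1.0, ("rA", 12): -2.0}),
             "p2": ("patient", {("rA", 0): 0.3, ("rA", 12): 0.1})},
            K=K,
        )
        return ds, data, spec

    def test_single_component_identity(self):
        _, data, spec = self._setup(K=1)
        state = make_state(spec, 2)
        assert log_mixture_likelihood(data, "p1", state) == pytest.approx(
            log_component_marginal(data, "p1", 0, state)
        )

    def test_identical_components_collapse(self):
        _, data, spec = self._setup(K=2)
        state = make_state(spec, 2)
        assert log_mixture_likelihood(data, "p1", state) == pytest.approx(
            log_component_marginal(data, "p1", 0, state)
        )

    def test_symmetric_allocation_probability(self):
        # subject equidistant between two mirror components -> 0.5 / 0.5
        ds, data, spec = toy_model(
            {"p": ("patient", {("rA", 0): 0.0, ("rA", 12): 0.0})}, K=2,
        )
        state = make_state(spec, 1, mu=[[1.0, 0.0], [-1.0, 0.0]])
        from trajmix.model import component_loglik_matrix
        row = component_loglik_matrix(data, state)[0]
        post = np.exp(np.log(state.w) + row - logsumexp(np.log(state.w) + row))
        np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-12)

    def test_label_permutation_invariance(self):
        _, data, spec = self._setup(K=2)
        rng = np.random.default_rng(5)
        mu = rng.standard_normal((2, 2))
        state = make_state(spec, 2, w=[0.3, 0.7], mu=mu)
        ref = log_mixture_likelihood(data, "p1", state)
        perm = make_state(spec, 2, w=[0.7, 0.3], mu=mu[::-1])
        assert log_mixture_likelihood(data, "p1", perm) == pytest.approx(ref, rel=1e-12)

    def test_deviance_additive_over_subjects(self):
        ds, data, spec = self._setup(K=2)
        state = make_state(spec, 2, mu=[[0.0, 0.0], [-1.0, -0.5]])
        total = deviance(data, state)
        parts = sum(log_mixture_likelihood(data, sid, state) for sid in ("p1", "p2"))
        assert total == pytest.approx(-2.0 * parts)

    def test_duplicated_subject_doubles_contribution(self):
        values = {"p1": ("patient", {("rA", 0): -1.0, ("rA", 12): -2.0})}
        ds1, data1, spec = toy_model(values, K=1)
        values2 = dict(values)
        values2["p1copy"] = values["p1"]
        ds2, data2, _ = toy_model(values2, K=1)
        state1 = make_state(spec, 1)
        state2 = make_state(spec, 2)
        assert deviance(data2, state2) == pytest.approx(2.0 * deviance(data1, state1))


class TestSpecAndPriors:
    def test_spec_roundtrip(self):
        ds, _, spec = toy_model({"p": ("patient", {("rA", 0): 1.0})})
        assert ModelSpec.from_dict(spec.to_dict()) == spec

    def test_priors_roundtrip_and_validation(self):
        p = Priors(dirichlet_concentration=2.0, beta_var=100.0)
        assert Priors.from_dict(p.to_dict()) == p
        with pytest.raises(ModelError):
            Priors(dispersion_shape=-1.0)
        with pytest.raises(ModelError):
            Priors(dirichlet_concentration=0.0)

    def test_missing_covariate_is_an_error(self):
        with pytest.raises(ModelError, match="missing"):
            toy_model(
                {"p": ("patient", {("rA", 0): 1.0})},
                covariates={"p": {}}, fixed=("age",),
            )

    def test_state_snapshot_roundtrip(self, tmp_path):
        ds, data, spec = toy_model({"p": ("patient", {("rA", 0): 1.0, ("rA", 12): 2.0})})
        state = make_state(spec, 1, mu=[[-1.0, 0.5]])
        path = tmp_path / "state.npz"
        state.save(path)
        back = MixtureState.load(path)
        np.testing.assert_array_equal(back.mu, state.mu)
        np.testing.assert_array_equal(back.U, state.U)

    def test_covariance_blocks(self):
        ds, _, _ = toy_model({"p": ("patient", {("rA", 0): 1, ("rB", 0): 1})})
        spec = ModelSpec(K=1, panel=ds.panel, covariance_structure="block_by_region")
        assert [list(b) for b in spec.covariance_blocks()] == [[0, 1], [2, 3]]
        diag = ModelSpec(K=1, panel=ds.panel, covariance_structure="diagonal")
        assert len(diag.covariance_blocks()) == 4
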