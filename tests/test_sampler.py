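import numpy as np
import pytest

from trajmix import (
    ChainConfig,
    GibbsSampler,
    ModelData,
    ModelSpec,
    Priors,
    SimulationDesign,
    generate_cohort,
    initialize,
    relabel,
    retained_sample_count,
    run_chain,
)
from trajmix.standardize import fit_reference, to_zscores

from conftest import make_chain


@pytest.fixture(scope="module")
def small_z_cohort():
    """Well-separated 2-cluster cohort on the z-scale, standardized."""
    design = SimulationDesign(
        n_patients=30, n_controls=40, weights=(0.5, 0.5),
        cluster_intercepts=((-3.0, -3.0, -3.0, -3.0), (0.0, 0.0, 0.0, 0.0)),
        cluster_slopes=((-0.5, -0.5, -0.5, -0.5), (0.0, 0.0, 0.0, 0.0)),
    )
    ds, truth = generate_cohort(design, seed=21)
    z = to_zscores(ds, fit_reference(ds)).patients
    return design, z, truth


class TestBookkeeping:
    @pytest.mark.parametrize(
        "n_iter,burn_in,thin,expected",
        [(750_000, 250_000, 500, 1000), (10, 0, 1, 10), (11, 1, 3, 3)],
    )
    def test_retained_sample_count(self, n_iter, burn_in, thin, expected):
        cfg = ChainConfig(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=0)
        assert retained_sample_count(cfg) == expected

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iter=10, burn_in=10, thin=1)
        with pytest.raises(ValueError):
            ChainConfig(n_iter=10, burn_in=0, thin=11)  # retains nothing
        with pytest.raises(ValueError):
            ChainConfig(init_strategy="bogus")


class TestInitialize:
    def _data(self, small_z_cohort, K=2):
        design, z, _ = small_z_cohort
        spec = ModelSpec(K=K, panel=z.panel)
        return ModelData(z, spec)

    def test_given_means_zero_noise_identity(self, small_z_cohort, default_priors):
        data = self._data(small_z_cohort)
        means = np.zeros((2, data.q))
        means[0, 0::2] = -3.0
        cfg = ChainConfig(init_strategy="given_means_plus_noise", seed=4,
                          init_means=means, noise_half_width=0.0)
        state = initialize(data, default_priors, cfg)
        np.testing.assert_array_equal(state.mu, means)

    def test_kmeans_recovers_separated_clouds(self, small_z_cohort, default_priors):
        design, z, truth = small_z_cohort
        data = self._data(small_z_cohort)
        cfg = ChainConfig(init_strategy="kmeans_baseline", seed=4)
        state = initialize(data, default_priors, cfg)
        labels = state.U
        true = truth.labels.loc[data.subject_ids].to_numpy()
        agree = max((labels == true).mean(), (labels == 1 - true).mean())
        assert agree == 1.0

    def test_same_seed_same_state(self, small_z_cohort, default_priors):
        data = self._data(small_z_cohort)
        cfg = ChainConfig(init_strategy="default", seed=9)
        s1 = initialize(data, default_priors, cfg)
        s2 = initialize(data, default_priors, cfg)
        np.testing.assert_array_equal(s1.U, s2.U)
        np.testing.assert_array_equal(s1.mu, s2.mu)
        np.testing.assert_array_equal(s1.b, s2.b)


class TestSweepMechanics:
    def test_weight_update_posterior_mean(self, small_z_cohort, default_priors):
        """Dirichlet conditional with delta=1: allocations (3,1) over 4 subjects
        give E[w | U] = ((1+3)/(2+4), (1+1)/(2+4)) = (4/6, 2/6)."""
        design, z, _ = small_z_cohort
        four = z.subset("patient")
        four = type(four)(four.panel, four.subjects[:4],
                          four.observations[four.observations["subject_id"].isin(
                              [s.subject_id for s in four.subjects[:4]])].copy(),
                          four.value_units)
        spec = ModelSpec(K=2, panel=four.panel)
        data = ModelData(four, spec)
        rng = np.random.default_rng(0)
        sampler = GibbsSampler(data, default_priors, rng)
        state = initialize(data, default_priors, ChainConfig(seed=1), rng)
        state.U = np.array([0, 0, 0, 1])
        draws = []
        for _ in range(4000):
            sampler.update_weights(state)
            draws.append(state.w.copy())
        emp = np.mean(draws, axis=0)
        np.testing.assert_allclose(emp, [4.0 / 6.0, 2.0 / 6.0], atol=0.01)

    def test_b_conditional_degenerate_prior_limit(self, small_z_cohort, default_priors):
        """With D -> 0 the b_i full conditional collapses onto mu_k."""
        design, z, _ = small_z_cohort
        spec = ModelSpec(K=1, panel=z.panel)
        data = ModelData(z, spec)
        rng = np.random.default_rng(0)
        sampler = GibbsSampler(data, default_priors, rng)
        state = initialize(data, default_priors, ChainConfig(seed=1), rng)
        state.mu = np.full((1, data.q), -1.25)
        state.D = 1e-12 * np.eye(data.q)[None]
        sampler.update_random_effects(state)
        np.testing.assert_allclose(state.b, -1.25, atol=1e-4)


class TestRunChain:
    def _fit(self, small_z_cohort, seed=5, **kw):
        design, z, _ = small_z_cohort
        spec = ModelSpec(K=2, panel=z.panel)
        cfg = ChainConfig(n_iter=400, burn_in=100, thin=5, seed=seed,
                          init_strategy="kmeans_baseline", **kw)
        return run_chain(z, spec, Priors(), cfg), cfg

    def test_retained_count_and_prob_rows(self, small_z_cohort):
        chain, cfg = self._fit(small_z_cohort)
        assert chain.n_draws == retained_sample_count(cfg) == 60
        np.testing.assert_allclose(chain.probs.sum(axis=2), 1.0, atol=1e-9)

    def test_same_seed_bit_identical(self, small_z_cohort):
        c1, _ = self._fit(small_z_cohort)
        c2, _ = self._fit(small_z_cohort)
        np.testing.assert_array_equal(c1.deviance, c2.deviance)
        np.testing.assert_array_equal(c1.mu, c2.mu)

    def test_recovers_separated_clusters(self, small_z_cohort):
        from sklearn.metrics import adjusted_rand_score

        design, z, truth = small_z_cohort
        chain, _ = self._fit(small_z_cohort)
        chain = relabel(chain)
        labels = chain.probs.mean(axis=0).argmax(axis=1)
        true = truth.labels.loc[chain.subject_ids].to_numpy()
        assert adjusted_rand_score(true, labels) >= 0.9

    def test_save_load_roundtrip(self, small_z_cohort, tmp_path):
        chain, _ = self._fit(small_z_cohort)
        chain.save(tmp_path / "chain")
        from trajmix import ChainResult

        back = ChainResult.load(tmp_path / "chain")
        np.testing.assert_array_equal(back.mu, chain.mu)
        assert back.subject_ids == chain.subject_ids
        assert back.config == chain.config


class TestRelabel:
    def test_identity_when_no_switching(self):
        probs = np.tile(np.array([[0.9, 0.1], [0.2, 0.8]]), (30, 1, 1))
        chain = make_chain(probs, relabeled=False)
        out = relabel(chain)
        np.testing.assert_array_equal(out.probs, chain.probs)
        assert out.relabeled

    def test_manual_permutation_restored(self):
        rng = np.random.default_rng(3)
        base = rng.dirichlet([5, 1], size=(30, 4))  # (30 draws, 4 subjects, K=2)
        probs = base.copy()
        probs[7] = probs[7][:, ::-1]  # flip one draw's labels
        chain = make_chain(probs, relabeled=False,
                           deviance=np.linspace(10, 20, 30))
        out = relabel(chain)
        np.testing.assert_allclose(out.probs[7], base[7])

    def test_deviance_unchanged(self):
        rng = np.random.default_rng(8)
        probs = rng.dirichlet([2, 2, 2], size=(25, 6))
        dev = rng.normal(100, 5, size=25)
        chain = make_chain(probs, relabeled=False, deviance=dev)
        out = relabel(chain)
        np.testing.assert_array_equal(out.deviance, dev)
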