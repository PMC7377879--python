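"""Gibbs sampler for the trajectory mixture model.

All full conditionals are conjugate, so one sweep is a systematic scan of
direct draws:

    (a) U_i  ~ Categorical( w_k f_{i,k}(y_i) )     [b_i integrated out]
    (b) w    ~ Dirichlet( delta + n_1, ..., delta + n_K )
    (c) b_i  ~ Gaussian full conditional given U_i, mu, D, beta, phi
    (d) mu_k ~ Gaussian full conditional given {b_i : U_i = k}
    (e) D_k^{-1} ~ Wishart full conditional (per covariance block)
    (f) beta_j   ~ Gaussian full conditional
    (g) phi_j    ~ inverse-gamma full conditional

Sampling U_i from the random-effects-integrated likelihood and then b_i
given U_i is a valid blocked update and mixes far better than conditioning
the allocation on the current b_i.  Empty components are allowed during
sampling (the Dirichlet prior keeps their weights positive); components
empty in the final classification are reported, not an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from scipy.stats import wishart
from sklearn.cluster import AgglomerativeClustering, KMeans

from .data import LongitudinalDataset
from .model import (
    MixtureState,
    ModelData,
    ModelError,
    ModelSpec,
    NumericalError,
    Priors,
    component_loglik_matrix,
)

INIT_STRATEGIES = (
    "default",
    "kmeans_baseline",
    "hierarchical_baseline",
    "given_means_plus_noise",
)


class SamplerError(RuntimeError):
    pass


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings.  Retained draws = floor((n_iter - burn_in)/thin)."""

    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 15
    seed: int = 0
    init_strategy: str = "default"
    noise_half_width: float = 0.0
    init_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_iter < 1 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("need n_iter >= 1, burn_in >= 0, thin >= 1")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if retained_sample_count(self) < 1:
            raise ValueError("configuration retains no draws")
        if self.init_strategy not in INIT_STRATEGIES:
            raise ValueError(f"unknown init_strategy {self.init_strategy!r}")
        if self.noise_half_width < 0:
            raise ValueError("noise_half_width must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_iter": self.n_iter, "burn_in": self.burn_in, "thin": self.thin,
            "seed": self.seed, "init_strategy": self.init_strategy,
            "noise_half_width": self.noise_half_width,
            "init_means": None if self.init_means is None else np.asarray(self.init_means).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainConfig":
        d = dict(d)
        if d.get("init_means") is not None:
            d["init_means"] = np.asarray(d["init_means"], dtype=float)
        return cls(**d)


def retained_sample_count(config: ChainConfig) -> int:
    """Number of post-burn-in draws kept after thinning."""
    return (config.n_iter - config.burn_in) // config.thin


@dataclass
class ChainResult:
    """Retained posterior draws plus per-draw subject-component probabilities."""

    subject_ids: list[str]
    spec: ModelSpec
    config: ChainConfig
    covariate_names: list[str]
    covariate_center: np.ndarray
    w: np.ndarray          # (R, K)
    mu: np.ndarray         # (R, K, q)
    D: np.ndarray          # (R, K, q, q)
    beta: np.ndarray       # (R, J, p)
    phi: np.ndarray        # (R, J)
    probs: np.ndarray      # (R, N, K) P(U_i = k | y_i, state_r)
    alloc: np.ndarray      # (R, N)
    b: np.ndarray          # (R, N, q) subject random-effect draws
    deviance: np.ndarray   # (R,)
    relabeled: bool = False

    @property
    def n_draws(self) -> int:
        return self.w.shape[0]

    @property
    def K(self) -> int:
        return self.w.shape[1]

    def save(self, directory) -> None:
        """Persist as one array archive plus a JSON config echo."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "draws.npz",
            w=self.w, mu=self.mu, D=self.D, beta=self.beta, phi=self.phi,
            probs=self.probs, alloc=self.alloc, b=self.b, deviance=self.deviance,
            covariate_center=self.covariate_center,
        )
        meta = {
            "subject_ids": self.subject_ids,
            "spec": self.spec.to_dict(),
            "config": self.config.to_dict(),
            "covariate_names": self.covariate_names,
            "relabeled": self.relabeled,
        }
        (directory / "chain.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "ChainResult":
        directory = Path(directory)
        meta = json.loads((directory / "chain.json").read_text())
        arrs = np.load(directory / "draws.npz")
        return cls(
            subject_ids=meta["subject_ids"],
            spec=ModelSpec.from_dict(meta["spec"]),
            config=ChainConfig.from_dict(meta["config"]),
            covariate_names=meta["covariate_names"],
            covariate_center=arrs["covariate_center"],
            w=arrs["w"], mu=arrs["mu"], D=arrs["D"], beta=arrs["beta"],
            phi=arrs["phi"], probs=arrs["probs"], alloc=arrs["alloc"],
            b=arrs["b"], deviance=arrs["deviance"], relabeled=bool(meta["relabeled"]),
        )

    def export_traces(self, path) -> None:
        """Deviance and mixture-weight traces as CSV for external diagnostics."""
        cols = {"deviance": self.deviance}
        for k in range(self.K):
            cols[f"w_{k + 1}"] = self.w[:, k]
        pd.DataFrame(cols).to_csv(path, index=False)


# -- per-subject least-squares summaries (initialization only) ----------------


def _ols_summaries(data: ModelData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject OLS intercept/slope per region, baseline values, residual variances."""
    N, q, J = data.N, data.q, data.J
    bhat = np.zeros((N, q))
    baseline = np.zeros((N, J))
    ssr = np.zeros(J)
    nres = np.zeros(J)
    for g in data.groups:
        for j, sl in enumerate(g.region_slices):
            t = g.Z[sl, 2 * j + 1]
            Yj = g.Y[sl, :]
            baseline[g.idx, j] = Yj[np.argmin(t), :]
            if len(t) >= 2:
                A = np.column_stack([np.ones_like(t), t])
                coef, *_ = np.linalg.lstsq(A, Yj, rcond=None)
                resid = Yj - A @ coef
                ssr[j] += (resid ** 2).sum()
                nres[j] += max(len(t) - 2, 0) * g.n
            else:
                coef = np.vstack([Yj[0, :], np.zeros(g.n)])
            bhat[g.idx, 2 * j] = coef[0]
            bhat[g.idx, 2 * j + 1] = coef[1]
    phi0 = np.where(nres > 0, ssr / np.maximum(nres, 1), 1.0)
    phi0 = np.maximum(phi0, 1e-3)
    return bhat, baseline, phi0


def initialize(
    data: ModelData,
    priors: Priors,
    config: ChainConfig,
    rng: np.random.Generator | None = None,
) -> MixtureState:
    """Build a valid starting state under the configured strategy.

    ``kmeans_baseline`` / ``hierarchical_baseline`` cluster the baseline-visit
    values cross-sectionally and seed mu_k with empirical per-cluster means of
    quick per-subject least-squares trajectory estimates.
    ``given_means_plus_noise`` perturbs supplied cluster means by
    U(-h, +h) per coordinate (h = ``noise_half_width``), echoing restarts
    from a previous solution with added uniform noise.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    spec = data.spec
    K, q, J = spec.K, spec.q, spec.J
    bhat, baseline, phi0 = _ols_summaries(data)

    for attempt in range(20):
        mu_given = None
        if config.init_strategy == "default":
            U = rng.integers(0, K, size=data.N)
        elif config.init_strategy == "kmeans_baseline":
            km = KMeans(n_clusters=K, n_init=10, random_state=int(rng.integers(2 ** 31)))
            U = km.fit_predict(baseline)
        elif config.init_strategy == "hierarchical_baseline":
            if K == 1:
                U = np.zeros(data.N, dtype=int)
            else:
                U = AgglomerativeClustering(n_clusters=K).fit_predict(baseline)
        else:  # given_means_plus_noise
            if config.init_means is None:
                raise SamplerError("init_strategy given_means_plus_noise requires init_means")
            mu_given = np.asarray(config.init_means, dtype=float)
            if mu_given.shape != (K, q):
                raise SamplerError(f"init_means must have shape {(K, q)}, got {mu_given.shape}")
            h = config.noise_half_width
            mu_given = mu_given + rng.uniform(-h, h, size=mu_given.shape)
            d2 = ((bhat[:, None, :] - mu_given[None, :, :]) ** 2).sum(axis=2)
            U = d2.argmin(axis=1)
        counts = np.bincount(U, minlength=K)
        if (counts > 0).all() or config.init_strategy in ("kmeans_baseline", "hierarchical_baseline"):
            break
    else:
        raise SamplerError("could not initialize without an empty cluster after 20 attempts")

    if mu_given is not None:
        mu = mu_given
    else:
        mu = np.vstack([
            bhat[U == k].mean(axis=0) if (U == k).any() else bhat.mean(axis=0)
            for k in range(K)
        ])
    pooled = np.cov(bhat.T) if data.N > q else np.eye(q)
    pooled = np.atleast_2d(pooled) + 1e-2 * np.eye(q)
    mask = np.zeros((q, q))
    for blk in spec.covariance_blocks():
        mask[np.ix_(blk, blk)] = 1.0
    D = np.repeat((pooled * mask)[None, :, :], K, axis=0)
    state = MixtureState(
        w=np.full(K, 1.0 / K),
        mu=mu,
        D=D,
        beta=np.zeros((J, data.p)),
        phi=phi0.copy(),
        b=bhat.copy(),
        U=U.astype(int),
    )
    state.validate()
    return state


# -- the sampler --------------------------------------------------------------


def _chol(A: np.ndarray, what: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        try:
            return np.linalg.cholesky(A + 1e-8 * np.trace(A) / A.shape[0] * np.eye(A.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"{what}: matrix not PD after jitter") from exc


class GibbsSampler:
    """Systematic-scan Gibbs sampler bound to one cohort and prior."""

    def __init__(self, data: ModelData, priors: Priors, rng: np.random.Generator):
        self.data = data
        self.priors = priors
        self.rng = rng
        spec = data.spec
        self.K, self.q, self.J, self.p = spec.K, spec.q, spec.J, data.p
        self.blocks = spec.covariance_blocks()
        self.xi = np.full(self.q, float(priors.mean_prior_mean))
        self.Cinv = np.eye(self.q) / priors.mean_prior_var
        self.Sinv = {len(b): np.eye(len(b)) / priors.wishart_scale for b in self.blocks}
        # per-region Gram matrices of the fixed design (constant across sweeps)
        self.gram = np.zeros((self.J, self.p, self.p))
        for g in data.groups:
            counts = np.bincount(g.region_of_obs, minlength=self.J)
            if self.p:
                CtC = g.C.T @ g.C
                for j in range(self.J):
                    self.gram[j] += counts[j] * CtC

    # each update_* method draws one block's full conditional in place

    def update_allocations(self, state: MixtureState) -> np.ndarray:
        """Draw U_i from P(U_i=k) ∝ w_k f_{i,k}(y_i); returns the probabilities."""
        loglik = component_loglik_matrix(self.data, state)
        logp = np.log(state.w)[None, :] + loglik
        logp -= logp.max(axis=1, keepdims=True)
        probs = np.exp(logp)
        probs /= probs.sum(axis=1, keepdims=True)
        u = self.rng.random(self.data.N)
        state.U = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
        state.U = np.minimum(state.U, self.K - 1)
        return probs

    def update_weights(self, state: MixtureState) -> None:
        counts = np.bincount(state.U, minlength=self.K)
        state.w = self.rng.dirichlet(self.priors.dirichlet_concentration + counts)

    def _dinv(self, state: MixtureState) -> np.ndarray:
        Dinv = np.empty_like(state.D)
        for k in range(self.K):
            L = _chol(state.D[k], f"D[{k}]")
            Dinv[k] = cho_solve((L, True), np.eye(self.q))
        return Dinv

    def update_random_effects(self, state: MixtureState, Dinv: np.ndarray | None = None) -> None:
        Dinv = self._dinv(state) if Dinv is None else Dinv
        for g in self.data.groups:
            phi_obs = state.phi[g.region_of_obs]
            ZtP = (g.Z / phi_obs[:, None]).T            # (q, m)
            P0 = ZtP @ g.Z                               # (q, q)
            R0 = g.Y - g.fixed_contrib(state.beta)       # (m, n_g)
            Ug = state.U[g.idx]
            for k in np.unique(Ug):
                cols = np.where(Ug == k)[0]
                A = P0 + Dinv[k]
                L = _chol(A, "b full conditional precision")
                rhs = ZtP @ R0[:, cols] + (Dinv[k] @ state.mu[k])[:, None]
                mean = cho_solve((L, True), rhs)
                noise = solve_triangular(
                    L.T, self.rng.standard_normal((self.q, len(cols))), lower=False
                )
                state.b[g.idx[cols], :] = (mean + noise).T

    def update_cluster_means(self, state: MixtureState, Dinv: np.ndarray | None = None) -> None:
        Dinv = self._dinv(state) if Dinv is None else Dinv
        for k in range(self.K):
            members = state.U == k
            n_k = int(members.sum())
            prec = self.Cinv + n_k * Dinv[k]
            rhs = self.Cinv @ self.xi
            if n_k:
                rhs = rhs + Dinv[k] @ state.b[members].sum(axis=0)
            L = _chol(prec, "mu full conditional precision")
            mean = cho_solve((L, True), rhs)
            noise = solve_triangular(L.T, self.rng.standard_normal(self.q), lower=False)
            state.mu[k] = mean + noise

    def update_cluster_precisions(self, state: MixtureState) -> None:
        for k in range(self.K):
            members = state.U == k
            n_k = int(members.sum())
            E = state.b[members] - state.mu[k]
            Dk = np.zeros((self.q, self.q))
            for blk in self.blocks:
                d = len(blk)
                S_post_inv = self.Sinv[d] + E[:, blk].T @ E[:, blk]
                df = self.priors.wishart_df_for(d) + n_k
                scale = np.linalg.inv(S_post_inv)
                scale = (scale + scale.T) / 2.0
                prec_blk = wishart.rvs(df=df, scale=scale, random_state=self.rng)
                prec_blk = np.atleast_2d(prec_blk)
                Lp = _chol(prec_blk, f"D[{k}] precision block")
                Dk[np.ix_(blk, blk)] = cho_solve((Lp, True), np.eye(d))
            state.D[k] = (Dk + Dk.T) / 2.0

    def update_fixed_effects(self, state: MixtureState) -> None:
        if self.p == 0:
            return
        rhs = np.zeros((self.J, self.p))
        for g in self.data.groups:
            resid = g.Y - g.Z @ state.b[g.idx, :].T     # (m, n_g)
            for j, sl in enumerate(g.region_slices):
                s = resid[sl, :].sum(axis=0)            # (n_g,)
                rhs[j] += g.C.T @ s
        for j in range(self.J):
            prec = np.eye(self.p) / self.priors.beta_var + self.gram[j] / state.phi[j]
            L = _chol(prec, "beta full conditional precision")
            mean = cho_solve((L, True), rhs[j] / state.phi[j])
            noise = solve_triangular(L.T, self.rng.standard_normal(self.p), lower=False)
            state.beta[j] = mean + noise

    def update_dispersions(self, state: MixtureState) -> None:
        ssr = np.zeros(self.J)
        for g in self.data.groups:
            e = g.Y - g.Z @ state.b[g.idx, :].T - g.fixed_contrib(state.beta)
            for j, sl in enumerate(g.region_slices):
                ssr[j] += (e[sl, :] ** 2).sum()
        shape = self.priors.dispersion_shape + self.data.n_obs_per_region / 2.0
        rate = self.priors.dispersion_rate + ssr / 2.0
        state.phi = rate / self.rng.gamma(shape)

    def sweep(self, state: MixtureState) -> MixtureState:
        """One full systematic scan; mutates and returns ``state``."""
        self.update_allocations(state)
        self.update_weights(state)
        Dinv = self._dinv(state)
        self.update_random_effects(state, Dinv)
        self.update_cluster_means(state, Dinv)
        self.update_cluster_precisions(state)
        self.update_fixed_effects(state)
        self.update_dispersions(state)
        return state

    def evaluate(self, state: MixtureState) -> tuple[np.ndarray, float]:
        """Allocation probabilities P(U_i=k | y_i, state) and mixture deviance."""
        loglik = component_loglik_matrix(self.data, state)
        logp = np.log(state.w)[None, :] + loglik
        per_subject = logsumexp(logp, axis=1)
        probs = np.exp(logp - per_subject[:, None])
        return probs, float(-2.0 * per_subject.sum())


def gibbs_sweep(
    state: MixtureState,
    data: ModelData,
    priors: Priors,
    rng: np.random.Generator,
) -> MixtureState:
    """Functional wrapper around :meth:`GibbsSampler.sweep`."""
    return GibbsSampler(data, priors, rng).sweep(state)


def run_chain(
    dataset: LongitudinalDataset | ModelData,
    spec: ModelSpec | None,
    priors: Priors,
    config: ChainConfig,
) -> ChainResult:
    """Fit the mixture by MCMC and return the retained draws.

    Accepts either a standardized dataset plus a ``ModelSpec``, or a
    pre-assembled :class:`ModelData`.  Bit-reproducible given
    ``config.seed``; all randomness flows from one generator.
    """
    if isinstance(dataset, ModelData):
        data = dataset
    else:
        if spec is None:
            raise ModelError("spec is required when passing a dataset")
        data = ModelData(dataset, spec)
    rng = np.random.default_rng(config.seed)
    sampler = GibbsSampler(data, priors, rng)
    state = initialize(data, priors, config, rng)

    R = retained_sample_count(config)
    K, q, J, p, N = data.spec.K, data.q, data.J, data.p, data.N
    out = ChainResult(
        subject_ids=list(data.subject_ids),
        spec=data.spec,
        config=config,
        covariate_names=list(data.covariate_names),
        covariate_center=data.covariate_center.copy(),
        w=np.empty((R, K)), mu=np.empty((R, K, q)), D=np.empty((R, K, q, q)),
        beta=np.empty((R, J, p)), phi=np.empty((R, J)),
        probs=np.empty((R, N, K)), alloc=np.empty((R, N), dtype=int),
        b=np.empty((R, N, q)), deviance=np.empty(R),
    )
    r = 0
    for t in range(1, config.n_iter + 1):
        try:
            sampler.sweep(state)
        except NumericalError as exc:
            raise SamplerError(f"sweep failed at iteration {t}: {exc}") from exc
        if t > config.burn_in and (t - config.burn_in) % config.thin == 0 and r < R:
            probs, dev = sampler.evaluate(state)
            out.w[r] = state.w
            out.mu[r] = state.mu
            out.D[r] = state.D
            out.beta[r] = state.beta
            out.phi[r] = state.phi
            out.probs[r] = probs
            out.alloc[r] = state.U
            out.b[r] = state.b
            out.deviance[r] = dev
            r += 1
    assert r == R
    return out


def relabel(chain: ChainResult) -> ChainResult:
    """Undo label switching by pivot alignment.

    The pivot is the retained draw with the highest mixture likelihood
    (lowest deviance).  Every draw's component indices are permuted to
    maximize agreement between its allocation-probability matrix and the
    pivot's (optimal assignment on the K×K overlap matrix); the mixture
    likelihood of each draw is unchanged.
    """
    if chain.n_draws == 0:
        raise SamplerError("cannot relabel an empty chain")
    out = ChainResult(
        subject_ids=list(chain.subject_ids), spec=chain.spec, config=chain.config,
        covariate_names=list(chain.covariate_names),
        covariate_center=chain.covariate_center.copy(),
        w=chain.w.copy(), mu=chain.mu.copy(), D=chain.D.copy(),
        beta=chain.beta.copy(), phi=chain.phi.copy(), probs=chain.probs.copy(),
        alloc=chain.alloc.copy(), b=chain.b.copy(),
        deviance=chain.deviance.copy(), relabeled=True,
    )
    pivot = int(np.argmin(chain.deviance))
    P0 = chain.probs[pivot]
    K = chain.K
    for r in range(chain.n_draws):
        overlap = P0.T @ chain.probs[r]          # (K, K): pivot comp × draw comp
        rows, cols = linear_sum_assignment(-overlap)
        perm = cols[np.argsort(rows)]            # draw component matching pivot k
        if np.array_equal(perm, np.arange(K)):
            continue
        out.w[r] = chain.w[r, perm]
        out.mu[r] = chain.mu[r, perm]
        out.D[r] = chain.D[r, perm]
        out.probs[r] = chain.probs[r][:, perm]
        inv = np.empty(K, dtype=int)
        inv[perm] = np.arange(K)
        out.alloc[r] = inv[chain.alloc[r]]
    return out
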