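"""Mixture of multivariate linear mixed models: likelihood and priors.

For subject i, region j and visit l the conditional mean is

    E(Y_ijl | beta_j, b_ij) = x_i' beta_j + z_ijl' b_ij ,

with Gaussian residuals of region-specific variance phi_j.  The random
design z is (1, t) with t in years from baseline, so each subject carries a
per-region random intercept and slope, collected into one joint vector
b_i of length q = 2J.  The mixture acts on the random effects
(hierarchical centering):

    b_i | U_i = k  ~  N(mu_k, D_k) ,      P(U_i = k) = w_k .

Cross-region dependence lives in the off-diagonal blocks of D_k.  Fixed
effects beta_j and dispersions phi_j are population parameters shared by
all clusters.  Integrating b_i out gives the closed-form component
marginal used both for the deviance and for allocation sampling:

    y_i | U_i = k  ~  N(X_i beta + Z_i mu_k,  Z_i D_k Z_i' + Phi_i) .
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .data import LongitudinalDataset, RegionPanel

LOG_2PI = float(np.log(2.0 * np.pi))

MONTHS_PER_YEAR = 12.0


class ModelError(ValueError):
    pass


class NumericalError(RuntimeError):
    """Covariance assembly failed to be positive definite."""


@dataclass(frozen=True)
class ModelSpec:
    """Structural specification of the mixture model.

    Parameters
    ----------
    K : number of mixture components (>= 1).
    panel : region panel; defines J and the block order of b_i.
    fixed_covariates : names of per-subject covariates entering every
        region's fixed design (coefficients are region-specific).  Only
        time-constant covariates are supported.
    covariance_structure : ``full`` (one joint q×q D_k, the default),
        ``block_by_region`` (independent 2×2 intercept/slope blocks), or
        ``diagonal``.
    center_covariates : subtract the sample mean from each covariate column
        before fitting (recommended: the hierarchically centered intercepts
        absorb the covariate means otherwise, which slows mixing).
    """

    K: int
    panel: RegionPanel
    fixed_covariates: tuple[str, ...] = ()
    covariance_structure: str = "full"
    center_covariates: bool = True

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ModelError("K must be >= 1")
        if self.covariance_structure not in ("full", "block_by_region", "diagonal"):
            raise ModelError(f"unknown covariance_structure {self.covariance_structure!r}")

    @property
    def J(self) -> int:
        return len(self.panel)

    @property
    def q(self) -> int:
        return 2 * self.J

    @property
    def p(self) -> int:
        return len(self.fixed_covariates)

    def random_effect_names(self) -> list[str]:
        out = []
        for name in self.panel.names:
            out += [f"{name}:intercept", f"{name}:slope"]
        return out

    def covariance_blocks(self) -> list[np.ndarray]:
        q = self.q
        if self.covariance_structure == "full":
            return [np.arange(q)]
        if self.covariance_structure == "block_by_region":
            return [np.array([2 * j, 2 * j + 1]) for j in range(self.J)]
        return [np.array([r]) for r in range(q)]

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "regions": list(self.panel.names),
            "region_kinds": list(self.panel.kinds),
            "fixed_covariates": list(self.fixed_covariates),
            "covariance_structure": self.covariance_structure,
            "center_covariates": self.center_covariates,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        panel = RegionPanel(tuple(d["regions"]), tuple(d.get("region_kinds", ())))
        return cls(
            K=int(d["K"]),
            panel=panel,
            fixed_covariates=tuple(d.get("fixed_covariates", ())),
            covariance_structure=d.get("covariance_structure", "full"),
            center_covariates=bool(d.get("center_covariates", True)),
        )


@dataclass(frozen=True)
class Priors:
    """Weakly-informative conjugate priors.

    w ~ Dirichlet(delta, ..., delta); mu_k ~ N(xi, c_mu I); D_k^{-1} ~
    Wishart(nu, s_D I) per covariance block (nu defaults to block dim + 1);
    beta ~ N(0, v_beta I); phi_j ~ InvGamma(a, b).  All proper; all
    exposed in configuration.
    """

    dirichlet_concentration: float = 1.0
    mean_prior_mean: float = 0.0
    mean_prior_var: float = 100.0
    wishart_df: float | None = None
    wishart_scale: float = 1.0
    beta_var: float = 1.0e4
    dispersion_shape: float = 0.01
    dispersion_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.dirichlet_concentration <= 0:
            raise ModelError("dirichlet_concentration must be > 0")
        for name in ("mean_prior_var", "wishart_scale", "beta_var",
                     "dispersion_shape", "dispersion_rate"):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be > 0")

    def wishart_df_for(self, block_dim: int) -> float:
        df = self.wishart_df if self.wishart_df is not None else block_dim + 1
        if df <= block_dim - 1:
            raise ModelError(f"Wishart df {df} not > block dim - 1 = {block_dim - 1}")
        return float(df)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Priors":
        return cls(**d)


@dataclass
class MixtureState:
    """All model parameters at one MCMC iteration."""

    w: np.ndarray          # (K,) simplex weights
    mu: np.ndarray         # (K, q) cluster means of random effects
    D: np.ndarray          # (K, q, q) cluster covariances, PD
    beta: np.ndarray       # (J, p) fixed effects per region
    phi: np.ndarray        # (J,) residual variances, > 0
    b: np.ndarray          # (N, q) subject random effects
    U: np.ndarray          # (N,) allocations in 0..K-1

    def validate(self) -> None:
        K, q = self.mu.shape
        if not np.isclose(self.w.sum(), 1.0) or (self.w <= 0).any():
            raise ModelError("weights must be positive and sum to 1")
        if (self.phi <= 0).any():
            raise ModelError("residual variances must be positive")
        for k in range(K):
            if not np.allclose(self.D[k], self.D[k].T):
                raise ModelError(f"D[{k}] not symmetric")
            np.linalg.cholesky(self.D[k])
        if self.U.min() < 0 or self.U.max() >= K:
            raise ModelError("allocations out of range")

    def copy(self) -> "MixtureState":
        return MixtureState(
            self.w.copy(), self.mu.copy(), self.D.copy(),
            self.beta.copy(), self.phi.copy(), self.b.copy(), self.U.copy(),
        )

    def save(self, path) -> None:
        """Snapshot the full state to one archive (e.g. to resume a chain)."""
        np.savez(path, w=self.w, mu=self.mu, D=self.D, beta=self.beta,
                 phi=self.phi, b=self.b, U=self.U)

    @classmethod
    def load(cls, path) -> "MixtureState":
        a = np.load(path)
        state = cls(w=a["w"], mu=a["mu"], D=a["D"], beta=a["beta"],
                    phi=a["phi"], b=a["b"], U=a["U"].astype(int))
        state.validate()
        return state


# -- design assembly ----------------------------------------------------------


@dataclass
class PatternGroup:
    """Subjects sharing one visit pattern (identical Z_i and Phi_i layout)."""

    idx: np.ndarray            # subject positions in the dataset order
    Z: np.ndarray              # (m, q) random-effects design
    Y: np.ndarray              # (m, n_g) stacked observations, region-major
    C: np.ndarray              # (n_g, p) covariate rows
    region_of_obs: np.ndarray  # (m,) region index per observation row
    region_slices: list[slice]

    @property
    def m(self) -> int:
        return self.Z.shape[0]

    @property
    def n(self) -> int:
        return len(self.idx)

    def fixed_contrib(self, beta: np.ndarray) -> np.ndarray:
        """X_i beta for every subject in the group, as an (m, n_g) matrix."""
        if self.C.shape[1] == 0:
            return np.zeros((self.m, self.n))
        S = self.C @ beta.T               # (n_g, J)
        return S.T[self.region_of_obs, :]  # (m, n_g)


class ModelData:
    """Pre-assembled design matrices for one modeling cohort.

    Subjects are grouped by visit pattern so that every group shares a
    single Z matrix and marginal covariance per component; the sampler and
    the marginal likelihood are vectorized within groups.
    """

    def __init__(self, dataset: LongitudinalDataset, spec: ModelSpec):
        self.spec = spec
        self.panel = spec.panel
        if tuple(dataset.panel.names) != tuple(spec.panel.names):
            raise ModelError("dataset panel does not match model spec panel")
        self.subject_ids = list(dataset.subject_ids)
        self.N = len(self.subject_ids)
        if self.N == 0:
            raise ModelError("empty modeling cohort")

        # covariate matrix, complete-case enforced (no silent imputation)
        names = spec.fixed_covariates
        C = np.zeros((self.N, len(names)))
        incomplete = []
        for i, s in enumerate(dataset.subjects):
            for c, name in enumerate(names):
                v = s.covariates.get(name, np.nan)
                try:
                    v = float(v)
                except (TypeError, ValueError):
                    v = np.nan
                if np.isnan(v):
                    incomplete.append((s.subject_id, name))
                v = 0.0 if np.isnan(v) else v
                C[i, c] = v
        if incomplete:
            raise ModelError(
                "subjects with missing/non-numeric model covariates "
                f"(no silent imputation): {incomplete[:5]}"
            )
        self.covariate_center = C.mean(axis=0) if (spec.center_covariates and self.N > 0 and C.size) else np.zeros(len(names))
        self.C = C - self.covariate_center
        self.covariate_names = list(names)

        obs = dataset.observations
        by_subject = dict(tuple(obs.groupby("subject_id", sort=False)))
        J, q = spec.J, spec.q

        sigs: dict[tuple, list[int]] = {}
        times_of: list[list[np.ndarray]] = []
        values_of: list[list[np.ndarray]] = []
        for i, sid in enumerate(self.subject_ids):
            if sid not in by_subject:
                raise ModelError(f"subject {sid!r} has no observations")
            sub = by_subject[sid]
            per_region_t, per_region_v = [], []
            for name in self.panel.names:
                rows = sub[sub["region"] == name].sort_values("visit_months")
                if len(rows) == 0:
                    raise ModelError(f"subject {sid!r} has no observations for region {name!r}")
                per_region_t.append(rows["visit_months"].to_numpy() / MONTHS_PER_YEAR)
                per_region_v.append(rows["value"].to_numpy())
            times_of.append(per_region_t)
            values_of.append(per_region_v)
            sig = tuple(tuple(np.round(t, 9)) for t in per_region_t)
            sigs.setdefault(sig, []).append(i)

        self.groups: list[PatternGroup] = []
        self._locator: dict[int, tuple[int, int]] = {}
        for sig, members in sigs.items():
            t0 = times_of[members[0]]
            m = sum(len(t) for t in t0)
            Z = np.zeros((m, q))
            region_of_obs = np.zeros(m, dtype=int)
            region_slices = []
            row = 0
            for j, tj in enumerate(t0):
                sl = slice(row, row + len(tj))
                Z[sl, 2 * j] = 1.0
                Z[sl, 2 * j + 1] = tj
                region_of_obs[sl] = j
                region_slices.append(sl)
                row += len(tj)
            Y = np.column_stack(
                [np.concatenate(values_of[i]) for i in members]
            )
            g = PatternGroup(
                idx=np.asarray(members, dtype=int),
                Z=Z,
                Y=Y,
                C=self.C[np.asarray(members, dtype=int), :],
                region_of_obs=region_of_obs,
                region_slices=region_slices,
            )
            gi = len(self.groups)
            self.groups.append(g)
            for col, i in enumerate(members):
                self._locator[i] = (gi, col)

        self.n_obs_per_region = np.zeros(J)
        for g in self.groups:
            counts = np.bincount(g.region_of_obs, minlength=J)
            self.n_obs_per_region += counts * g.n

    @property
    def q(self) -> int:
        return self.spec.q

    @property
    def J(self) -> int:
        return self.spec.J

    @property
    def p(self) -> int:
        return self.spec.p

    def locate(self, subject_id: str) -> tuple[PatternGroup, int]:
        i = self.subject_ids.index(subject_id)
        gi, col = self._locator[i]
        return self.groups[gi], col

    def centered_profile(self, profile: dict) -> np.ndarray:
        """Encode a raw covariate profile on the model's (centered) scale."""
        vals = []
        for c, name in enumerate(self.covariate_names):
            if name not in profile:
                raise ModelError(f"covariate profile is missing {name!r}")
            vals.append(float(profile[name]) - self.covariate_center[c])
        return np.asarray(vals)


# -- likelihood ---------------------------------------------------------------


def _chol_with_jitter(V: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.mean(np.diag(V))
        try:
            return np.linalg.cholesky(V + jitter * np.eye(V.shape[0]))
        except np.linalg.LinAlgError as exc:
            cond = np.linalg.cond(V)
            raise NumericalError(
                f"marginal covariance not PD (condition number {cond:.3g})"
            ) from exc


def component_loglik_matrix(data: ModelData, state: MixtureState) -> np.ndarray:
    """log f_{i,k}(y_i) for every subject i and component k, shape (N, K).

    f_{i,k} is the random-effects-integrated Gaussian marginal
    N(X_i beta + Z_i mu_k, Z_i D_k Z_i' + Phi_i).
    """
    K = state.mu.shape[0]
    out = np.empty((data.N, K))
    for g in data.groups:
        phi_obs = state.phi[g.region_of_obs]
        R0 = g.Y - g.fixed_contrib(state.beta)
        for k in range(K):
            V = g.Z @ state.D[k] @ g.Z.T
            V[np.diag_indices_from(V)] += phi_obs
            L = _chol_with_jitter(V)
            res = R0 - (g.Z @ state.mu[k])[:, None]
            W = solve_triangular(L, res, lower=True, check_finite=False)
            quad = np.einsum("ij,ij->j", W, W)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            out[g.idx, k] = -0.5 * (g.m * LOG_2PI + logdet + quad)
    return out


def log_component_marginal(data: ModelData, subject_id: str, k: int, state: MixtureState) -> float:
    """Closed-form log marginal likelihood of one subject under component k."""
    i = data.subject_ids.index(subject_id)
    return float(component_loglik_matrix(data, state)[i, k])


def log_mixture_likelihood(data: ModelData, subject_id: str, state: MixtureState) -> float:
    """log sum_k w_k f_{i,k}(y_i) for one subject."""
    i = data.subject_ids.index(subject_id)
    row = component_loglik_matrix(data, state)[i]
    return float(logsumexp(np.log(state.w) + row))


def deviance(data: ModelData, state: MixtureState) -> float:
    """-2 * sum_i log f_i(y_i; theta): the mixture deviance."""
    ll = component_loglik_matrix(data, state)
    per_subject = logsumexp(np.log(state.w)[None, :] + ll, axis=1)
    return float(-2.0 * per_subject.sum())


def linear_predictor(data: ModelData, subject_id: str, region: str, state: MixtureState) -> np.ndarray:
    """Conditional mean x_i' beta_j + z' b_ij over one subject's visits for one region."""
    g, col = data.locate(subject_id)
    j = data.panel.index(region)
    sl = g.region_slices[j]
    i = data.subject_ids.index(subject_id)
    fixed = float(g.C[list(g.idx).index(i), :] @ state.beta[j]) if data.p else 0.0
    return g.Z[sl, 2 * j] * state.b[i, 2 * j] + g.Z[sl, 2 * j + 1] * state.b[i, 2 * j + 1] + fixed
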