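"""Interpretive outputs: MDS embedding, fitted-value maps, display masking.

Rendered brain surfaces are out of scope; everything here produces tables
(region × cluster × time values, embedding coordinates) that external
plotting tools can consume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelError
from .sampler import ChainResult

logger = logging.getLogger(__name__)

DEFAULT_TIMES_MONTHS = (0.0, 12.0, 24.0)


@dataclass
class EmbeddingResult:
    """Classical MDS embedding of the subject probability matrix."""

    subject_ids: list[str]
    coordinates: np.ndarray   # (N, d), columns ordered by descending eigenvalue
    eigenvalues: np.ndarray   # full spectrum of the double-centered matrix

    def to_frame(self, grouping: np.ndarray | None = None) -> pd.DataFrame:
        d = {"subject_id": self.subject_ids}
        for c in range(self.coordinates.shape[1]):
            d[f"dim{c + 1}"] = self.coordinates[:, c]
        if grouping is not None:
            d["group"] = grouping
        return pd.DataFrame(d)

    def to_csv(self, path, grouping: np.ndarray | None = None) -> None:
        self.to_frame(grouping).to_csv(path, index=False)


def mds_embed(prob_matrix: np.ndarray, d: int = 5, subject_ids: list[str] | None = None) -> EmbeddingResult:
    """Classical (Torgerson) MDS on Euclidean distances between probability rows.

    Double-centers the squared-distance matrix, eigendecomposes, and keeps
    the ``d`` leading non-negative directions.  Deterministic; coordinates
    are centered and exactly reproduce the input distances whenever ``d``
    reaches the configuration's intrinsic dimension.
    """
    X = np.asarray(prob_matrix, dtype=float)
    N = X.shape[0]
    if not 1 <= d <= max(N - 1, 1):
        raise ValueError(f"need 1 <= d <= N-1 = {N - 1}")
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    J = np.eye(N) - np.full((N, N), 1.0 / N)
    B = -0.5 * J @ sq @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(eigval.max(), 0.0) * 1e-12
    n_pos = int(pos.sum())
    if d > n_pos:
        warnings.warn(
            f"requested d={d} exceeds the {n_pos} positive eigenvalue(s); truncating",
            RuntimeWarning,
        )
        d = max(n_pos, 1)
    coords = eigvec[:, :d] * np.sqrt(np.maximum(eigval[:d], 0.0))
    coords = coords - coords.mean(axis=0)
    return EmbeddingResult(
        subject_ids=list(subject_ids) if subject_ids is not None else [str(i) for i in range(N)],
        coordinates=coords,
        eigenvalues=eigval,
    )


@dataclass
class ClusterMaps:
    """Per (cluster, time, region) fitted z-values with dispersion and masking.

    ``table`` columns: cluster (1-based), time_months, region, median, q1,
    q3, masked.  ``quartile_basis`` records whether q1/q3 are across
    posterior draws (default) or across within-cluster subjects.
    """

    table: pd.DataFrame
    covariate_profile: dict
    quartile_basis: str = "posterior_draws"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def fitted_maps(
    chain: ChainResult,
    covariate_profile: dict,
    times_months: tuple[float, ...] = DEFAULT_TIMES_MONTHS,
) -> ClusterMaps:
    """Cluster fitted values at a fixed covariate profile.

    For each retained draw, cluster k, region j, time t (months):

        fit = x' beta_j + mu_k[j, intercept] + mu_k[j, slope] * t/12

    where x is the profile encoded on the model's covariate scale.  The
    reported value per cell is the across-draw median; q1/q3 are the
    across-draw quartiles.  Values are in control-referenced SD units when
    the chain was fit on standardized data.
    """
    if not chain.relabeled:
        raise ModelError("fitted_maps needs a relabeled chain")
    x = np.array([
        float(covariate_profile[name]) - center
        if name in covariate_profile
        else _missing(name)
        for name, center in zip(chain.covariate_names, chain.covariate_center)
    ])
    J = chain.beta.shape[1]
    K = chain.K
    fixed = chain.beta @ x if len(x) else np.zeros((chain.n_draws, J))  # (R, J)
    rows = []
    for k in range(K):
        inter = chain.mu[:, k, 0::2]   # (R, J)
        slope = chain.mu[:, k, 1::2]
        for t in times_months:
            fit = fixed + inter + slope * (t / 12.0)   # (R, J)
            med = np.median(fit, axis=0)
            q1 = np.percentile(fit, 25, axis=0)
            q3 = np.percentile(fit, 75, axis=0)
            for j, region in enumerate(chain.spec.panel.names):
                rows.append({
                    "cluster": k + 1, "time_months": float(t), "region": region,
                    "median": float(med[j]), "q1": float(q1[j]), "q3": float(q3[j]),
                    "masked": False,
                })
    return ClusterMaps(pd.DataFrame(rows), dict(covariate_profile))


def _missing(name: str):
    raise ModelError(f"covariate profile is missing {name!r}")


def subject_quartile_maps(
    chain: ChainResult,
    labels: np.ndarray,
    times_months: tuple[float, ...] = DEFAULT_TIMES_MONTHS,
) -> ClusterMaps:
    """Alternative dispersion maps: quartiles across within-cluster subjects.

    Uses the posterior mean random effects per subject; q1/median/q3 are
    taken over the subjects assigned to each cluster.  Clusters with no
    assigned subjects are omitted.
    """
    if not chain.relabeled:
        raise ModelError("subject_quartile_maps needs a relabeled chain")
    bmean = chain.b.mean(axis=0)          # (N, q)
    labels = np.asarray(labels)
    rows = []
    for k in range(chain.K):
        members = np.where(labels == k)[0]
        if members.size == 0:
            continue
        inter = bmean[members, 0::2]      # (n_k, J)
        slope = bmean[members, 1::2]
        for t in times_months:
            fit = inter + slope * (t / 12.0)
            for j, region in enumerate(chain.spec.panel.names):
                rows.append({
                    "cluster": k + 1, "time_months": float(t), "region": region,
                    "median": float(np.median(fit[:, j])),
                    "q1": float(np.percentile(fit[:, j], 25)),
                    "q3": float(np.percentile(fit[:, j], 75)),
                    "masked": False,
                })
    return ClusterMaps(pd.DataFrame(rows), {}, quartile_basis="within_cluster_subjects")


def apply_display_mask(maps: ClusterMaps, threshold: float = -2.0) -> ClusterMaps:
    """Mask cells whose median fitted value is not strictly below ``threshold``.

    With the default threshold of −2 control SDs, only regions at least two
    standard deviations below the control mean are shown; a median exactly
    at the threshold is masked (strictly-below rule).  Underlying values
    are retained — masking is a lossless display layer.
    """
    table = maps.table.copy()
    table["masked"] = ~(table["median"] < threshold)
    return ClusterMaps(table, dict(maps.covariate_profile), maps.quartile_basis)
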