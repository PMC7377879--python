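"""Subject-level classification with explicit uncertainty.

Soft clustering: each subject gets a posterior probability of belonging to
each component, averaged over retained MCMC draws.  Hard labels use the
maximum-probability rule.  Two uncertainty mechanisms are layered on top,
in this order:

1. *Outlier clusters*: components whose max-probability membership is
   smaller than ``min_size`` are too thin to interpret; their members are
   flagged ``outlier_cluster_member``.
2. *HPD uncertainty*: a subject whose top component's highest-posterior-
   density interval (over the per-draw allocation probabilities) overlaps
   another component's interval cannot be classified with high certainty
   and is flagged ``hpd_uncertain``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .sampler import ChainResult

logger = logging.getLogger(__name__)

ASSIGNED = "assigned"
HPD_UNCERTAIN = "hpd_uncertain"
OUTLIER_MEMBER = "outlier_cluster_member"


class ClassificationError(ValueError):
    pass


@dataclass
class ClassificationResult:
    """Posterior mean probabilities, HPD intervals, labels, and flags.

    ``labels`` are 0-based component indices (max-probability rule); the
    flag of a subject is exactly one of ``assigned``, ``hpd_uncertain`` or
    ``outlier_cluster_member``.  ``retained_ids`` are the subjects that
    survive both exclusions and enter downstream interpretation.
    """

    subject_ids: list[str]
    prob_matrix: np.ndarray     # (N, K) posterior means, rows sum to 1
    hpd_lower: np.ndarray       # (N, K)
    hpd_upper: np.ndarray       # (N, K)
    coverage: float
    labels: np.ndarray          # (N,)
    flags: np.ndarray           # (N,) object array of flag strings

    @property
    def retained_ids(self) -> list[str]:
        return [sid for sid, f in zip(self.subject_ids, self.flags) if f == ASSIGNED]

    def cluster_sizes(self) -> np.ndarray:
        K = self.prob_matrix.shape[1]
        keep = self.flags == ASSIGNED
        return np.bincount(self.labels[keep], minlength=K)

    def to_frame(self) -> pd.DataFrame:
        K = self.prob_matrix.shape[1]
        d = {"subject_id": self.subject_ids,
             "label": self.labels + 1,
             "flag": self.flags}
        for k in range(K):
            d[f"p_{k + 1}"] = self.prob_matrix[:, k]
        for k in range(K):
            d[f"hpd_low_{k + 1}"] = self.hpd_lower[:, k]
            d[f"hpd_high_{k + 1}"] = self.hpd_upper[:, k]
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _require_relabeled(chain: ChainResult) -> None:
    if not chain.relabeled:
        raise ClassificationError(
            "chain has not been relabeled; run trajmix.relabel(chain) first "
            "(averaging probabilities across draws is meaningless under label switching)"
        )


def posterior_probabilities(chain: ChainResult) -> np.ndarray:
    """Posterior mean probability matrix p̂_{i,k}, shape (N, K).

    Means of the per-draw allocation probabilities (not frequencies of the
    sampled hard allocations — see :func:`allocation_frequencies` for that
    estimator).  Rows sum to 1.
    """
    _require_relabeled(chain)
    return chain.probs.mean(axis=0)


def allocation_frequencies(chain: ChainResult) -> np.ndarray:
    """Alternative p̂ estimator: relative frequencies of sampled allocations U_i."""
    _require_relabeled(chain)
    K = chain.K
    out = np.zeros((len(chain.subject_ids), K))
    for k in range(K):
        out[:, k] = (chain.alloc == k).mean(axis=0)
    return out


def assign_max_prob(prob_matrix: np.ndarray) -> np.ndarray:
    """Maximum-posterior-probability labels; ties break to the lowest index."""
    prob_matrix = np.asarray(prob_matrix)
    labels = prob_matrix.argmax(axis=1)
    top = prob_matrix.max(axis=1, keepdims=True)
    ties = (np.isclose(prob_matrix, top).sum(axis=1) > 1)
    if ties.any():
        logger.warning(
            "max-probability ties for %d subject(s); broken toward the lowest cluster index",
            int(ties.sum()),
        )
    return labels


def hpd_intervals(chain: ChainResult, coverage: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Shortest (HPD) interval of the per-draw allocation probabilities, per (i, k)."""
    _require_relabeled(chain)
    if not 0.0 < coverage < 1.0:
        raise ClassificationError("coverage must be in (0, 1)")
    if chain.n_draws < 10:
        raise ClassificationError(
            f"only {chain.n_draws} retained draws; HPD intervals are unstable below 10"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hdi = az.hdi(chain.probs[None, ...], hdi_prob=coverage)  # (N, K, 2)
    return hdi[..., 0], hdi[..., 1]


def hpd_uncertainty(
    chain: ChainResult,
    coverage: float = 0.95,
    rule: str = "overlap",
    lower_bound_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flag subjects whose component membership is uncertain.

    ``rule="overlap"`` (default): uncertain iff the HPD interval of the top
    component's probability overlaps any other component's interval for the
    same subject.  ``rule="lower_bound"``: uncertain iff the top
    component's HPD lower bound falls below ``lower_bound_threshold``.
    Returns (uncertain mask, hpd_lower, hpd_upper).
    """
    lo, hi = hpd_intervals(chain, coverage)
    pbar = posterior_probabilities(chain)
    top = pbar.argmax(axis=1)
    N, K = pbar.shape
    uncertain = np.zeros(N, dtype=bool)
    if rule == "overlap":
        for i in range(N):
            t = top[i]
            for k in range(K):
                if k == t:
                    continue
                if lo[i, t] <= hi[i, k] and lo[i, k] <= hi[i, t]:
                    uncertain[i] = True
                    break
    elif rule == "lower_bound":
        uncertain = lo[np.arange(N), top] < lower_bound_threshold
    else:
        raise ClassificationError(f"unknown HPD rule {rule!r}")
    return uncertain, lo, hi


def flag_outlier_clusters(labels: np.ndarray, min_size: int = 3) -> np.ndarray:
    """Mask of subjects assigned to clusters with fewer than ``min_size`` members."""
    if min_size < 1:
        raise ClassificationError("min_size must be >= 1")
    labels = np.asarray(labels)
    K = labels.max() + 1 if labels.size else 0
    sizes = np.bincount(labels, minlength=K)
    return sizes[labels] < min_size


def classify(
    chain: ChainResult,
    coverage: float = 0.95,
    min_cluster_size: int = 3,
    rule: str = "overlap",
    estimator: str = "mean_probability",
) -> ClassificationResult:
    """Full classification pipeline on a relabeled chain.

    Flag precedence is deterministic: outlier-cluster membership is
    evaluated first on the max-probability labels; HPD uncertainty is then
    evaluated on the remaining subjects only, so a subject in an excluded
    outlier cluster keeps the ``outlier_cluster_member`` flag even if its
    intervals also overlap.
    """
    if estimator == "mean_probability":
        pbar = posterior_probabilities(chain)
    elif estimator == "allocation_frequency":
        pbar = allocation_frequencies(chain)
    else:
        raise ClassificationError(f"unknown estimator {estimator!r}")
    labels = assign_max_prob(pbar)
    outlier = flag_outlier_clusters(labels, min_cluster_size)
    uncertain, lo, hi = hpd_uncertainty(chain, coverage, rule)
    flags = np.array([ASSIGNED] * len(labels), dtype=object)
    flags[uncertain] = HPD_UNCERTAIN
    flags[outlier] = OUTLIER_MEMBER  # outlier precedence over HPD
    return ClassificationResult(
        subject_ids=list(chain.subject_ids),
        prob_matrix=pbar,
        hpd_lower=lo,
        hpd_upper=hi,
        coverage=coverage,
        labels=labels,
        flags=flags,
    )
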