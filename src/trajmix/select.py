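"""Hybrid model selection across candidate chains.

Candidates (different K, different initializations) are scored on three
criteria — posterior mean deviance, worst lag-1 autocorrelation among
monitored scalar traces, and mean classification certainty — each min-max
scaled to [0, 1] across candidates with 1 = best, and combined by a
weighted (default equal-weight) mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import ClassificationResult
from .sampler import ChainResult

logger = logging.getLogger(__name__)


@dataclass
class ModelScorecard:
    K: int
    init_strategy: str
    seed: int
    deviance_raw: float
    autocorr_raw: float
    certainty_raw: float
    deviance_scaled: float = np.nan
    autocorr_scaled: float = np.nan
    certainty_scaled: float = np.nan
    combined: float = np.nan


def deviance_summary(chain: ChainResult) -> float:
    """Posterior mean of the retained deviance trace."""
    if chain.n_draws == 0:
        raise ValueError("empty deviance trace")
    return float(chain.deviance.mean())


def _lag1_autocorr(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0.0:
        logger.warning("constant monitored trace; lag-1 autocorrelation taken as 0")
        return 0.0
    x = x - x.mean()
    return float(np.dot(x[:-1], x[1:]) / np.dot(x, x))


def autocorrelation_score(chain: ChainResult, monitored: list[np.ndarray] | None = None) -> float:
    """Max |lag-1 autocorrelation| over monitored scalar traces (lower = better).

    Default monitors are the deviance trace and each mixture-weight trace:
    scalar, and label-robust once the chain is relabeled.
    """
    if chain.n_draws < 20:
        raise ValueError("need at least 20 retained draws for a stable autocorrelation")
    if monitored is None:
        monitored = [chain.deviance] + [chain.w[:, k] for k in range(chain.K)]
    return float(max(abs(_lag1_autocorr(t)) for t in monitored))


def certainty_score(classification: ClassificationResult) -> float:
    """Mean over subjects of max_k p̂_{i,k}; in [1/K, 1], higher = better."""
    return float(classification.prob_matrix.max(axis=1).mean())


def _minmax(values: np.ndarray, *, higher_is_better: bool) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        logger.warning("criterion identical across candidates; contributes 1 to all")
        return np.ones_like(values, dtype=float)
    scaled = (values - lo) / (hi - lo)
    return scaled if higher_is_better else 1.0 - scaled


def hybrid_rank(
    candidates: list[ModelScorecard],
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[ModelScorecard]:
    """Scale the three criteria to [0,1] across candidates and rank.

    Deviance and autocorrelation are inverted (smaller raw = scaled 1);
    certainty is direct.  Combined score is the weighted mean of the three
    scaled criteria; ties break toward smaller K.  Returns a new list in
    rank order (best first).
    """
    if len(candidates) < 2:
        raise ValueError("hybrid ranking needs at least 2 candidates")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    dev = _minmax(np.array([c.deviance_raw for c in candidates]), higher_is_better=False)
    ac = _minmax(np.array([c.autocorr_raw for c in candidates]), higher_is_better=False)
    cert = _minmax(np.array([c.certainty_raw for c in candidates]), higher_is_better=True)
    out = []
    for i, c in enumerate(candidates):
        out.append(ModelScorecard(
            K=c.K, init_strategy=c.init_strategy, seed=c.seed,
            deviance_raw=c.deviance_raw, autocorr_raw=c.autocorr_raw,
            certainty_raw=c.certainty_raw,
            deviance_scaled=float(dev[i]), autocorr_scaled=float(ac[i]),
            certainty_scaled=float(cert[i]),
            combined=float(w[0] * dev[i] + w[1] * ac[i] + w[2] * cert[i]),
        ))
    out.sort(key=lambda c: (-c.combined, c.K))
    return out


def score_chain(chain: ChainResult, classification: ClassificationResult) -> ModelScorecard:
    """Raw three-criterion scorecard for one candidate chain."""
    return ModelScorecard(
        K=chain.K,
        init_strategy=chain.config.init_strategy,
        seed=chain.config.seed,
        deviance_raw=deviance_summary(chain),
        autocorr_raw=autocorrelation_score(chain),
        certainty_raw=certainty_score(classification),
    )


def scorecard_frame(candidates: list[ModelScorecard]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in candidates])
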