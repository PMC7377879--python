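"""Shared fixtures: tiny hand-built cohorts and synthetic chain objects."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from trajmix import (
    ChainConfig,
    ChainResult,
    LongitudinalDataset,
    ModelSpec,
    Priors,
    RegionPanel,
    SubjectRecord,
)


def make_dataset(values: dict, covariates: dict | None = None, regions=None) -> LongitudinalDataset:
    """Build a dataset from {subject_id: {(region, months): value}} plus group tags.

    ``values`` maps subject_id -> ("control"|"patient", {(region, months): value}).
    """
    rows = []
    region_order = list(regions) if regions else []
    subjects = []
    for sid, (group, meas) in values.items():
        subjects.append(SubjectRecord(sid, group, (covariates or {}).get(sid, {})))
        for (region, months), v in meas.items():
            if region not in region_order:
                region_order.append(region)
            rows.append({"subject_id": sid, "visit_months": float(months),
                         "region": region, "value": float(v)})
    panel = RegionPanel(tuple(region_order))
    return LongitudinalDataset(panel, subjects, pd.DataFrame(rows))


def make_chain(
    probs: np.ndarray,
    subject_ids: list[str] | None = None,
    relabeled: bool = True,
    mu: np.ndarray | None = None,
    beta: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    deviance: np.ndarray | None = None,
    seed: int = 0,
) -> ChainResult:
    """Construct a ChainResult directly from per-draw probability matrices.

    Used to test classification/selection/visualization logic against
    hand-chosen posterior draws without running MCMC.
    """
    probs = np.asarray(probs, dtype=float)
    R, N, K = probs.shape
    panel = RegionPanel(("regA",))
    spec = ModelSpec(K=K, panel=panel,
                     fixed_covariates=tuple(covariate_names or ()))
    q, J, p = spec.q, spec.J, spec.p
    mu = np.zeros((R, K, q)) if mu is None else np.asarray(mu, dtype=float)
    beta = np.zeros((R, J, p)) if beta is None else np.asarray(beta, dtype=float)
    cfg = ChainConfig(n_iter=max(R, 2), burn_in=0, thin=1, seed=seed)
    return ChainResult(
        subject_ids=list(subject_ids or [f"s{i}" for i in range(N)]),
        spec=spec,
        config=cfg,
        covariate_names=list(covariate_names or []),
        covariate_center=np.zeros(p),
        w=np.full((R, K), 1.0 / K),
        mu=mu,
        D=np.repeat(np.eye(q)[None, None], R, axis=0).repeat(K, axis=1),
        beta=beta,
        phi=np.ones((R, J)),
        probs=probs,
        alloc=probs.argmax(axis=2),
        b=np.zeros((R, N, q)),
        deviance=np.zeros(R) if deviance is None else np.asarray(deviance, float),
        relabeled=relabeled,
    )


@pytest.fixture(scope="session")
def default_priors() -> Priors:
    return Priors()
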