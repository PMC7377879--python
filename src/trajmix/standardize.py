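"""Control-referenced z-standardization.

Patient measurements are converted to z-scores against the control
(cognitively unimpaired) group at the matching region and scheduled
visit:

    z_{j,t} = (x_{j,t} - mean_{j,t}^{ctrl}) / sd_{j,t}^{ctrl}

Standardizing per visit (not only at baseline) removes both the normal-
ageing *level* and the normal-ageing *change over time*, so a patient
z-trajectory expresses atrophy beyond what healthy ageing explains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LongitudinalDataset, with_observations


class StandardizationError(ValueError):
    pass


@dataclass(frozen=True)
class VisitMap:
    """Maps actual acquisition times (months) to scheduled nominal visits.

    Default schedule 0/12/24 months with a ±3-month tolerance window.
    """

    nominal: tuple[float, ...] = (0.0, 12.0, 24.0)
    tolerance_months: float = 3.0

    def assign(self, visit_months: float) -> float:
        for t in self.nominal:
            if abs(visit_months - t) <= self.tolerance_months:
                return t
        raise StandardizationError(
            f"visit time {visit_months} months maps to no nominal visit "
            f"{self.nominal} (tolerance ±{self.tolerance_months})"
        )

    def assign_series(self, visit_months: pd.Series) -> pd.Series:
        nominal = np.asarray(self.nominal, dtype=float)
        t = visit_months.to_numpy(dtype=float)
        dist = np.abs(t[:, None] - nominal[None, :])
        idx = dist.argmin(axis=1)
        bad = dist[np.arange(len(t)), idx] > self.tolerance_months
        if bad.any():
            raise StandardizationError(
                f"unmappable visit times (months): {sorted(set(t[bad]))[:5]}"
            )
        return pd.Series(nominal[idx], index=visit_months.index)


@dataclass
class ReferenceNorms:
    """Per (region, nominal visit) control mean/SD used for z-scoring.

    SDs use the sample (n−1) denominator; every entry requires at least two
    controls and strictly positive variance.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: region, visit_months, mean, sd, n

    def __post_init__(self) -> None:
        required = {"region", "visit_months", "mean", "sd", "n"}
        if not required.issubset(self.table.columns):
            raise StandardizationError(f"norms table needs columns {sorted(required)}")
        if (self.table["sd"] <= 0).any():
            bad = self.table[self.table["sd"] <= 0].iloc[0]
            raise StandardizationError(
                f"non-positive SD in norms at ({bad.region}, {bad.visit_months})"
            )
        if (self.table["n"] < 2).any():
            bad = self.table[self.table["n"] < 2].iloc[0]
            raise StandardizationError(
                f"fewer than 2 controls at ({bad.region}, {bad.visit_months})"
            )
        self._lookup = self.table.set_index(["region", "visit_months"])

    def entry(self, region: str, visit: float) -> tuple[float, float]:
        try:
            row = self._lookup.loc[(region, visit)]
        except KeyError:
            raise StandardizationError(f"no norm entry for ({region}, {visit})") from None
        return float(row["mean"]), float(row["sd"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceNorms":
        return cls(pd.read_csv(path))


def fit_reference(
    dataset: LongitudinalDataset,
    visit_map: VisitMap | None = None,
    sd_convention: str = "sample",
) -> ReferenceNorms:
    """Compute control means/SDs per (region, nominal visit).

    ``dataset`` may contain both groups; only controls contribute.  Norms are
    fitted before any patient filtering so the reference is stable.  A cell
    with fewer than two controls or zero variance is an error naming the cell.
    ``sd_convention`` selects the sample (n−1, default — control cells are
    small) or population (n) denominator.
    """
    if sd_convention not in ("sample", "population"):
        raise StandardizationError(f"unknown sd_convention {sd_convention!r}")
    ddof = 1 if sd_convention == "sample" else 0
    visit_map = visit_map or VisitMap()
    controls = dataset.controls
    obs = controls.observations.copy()
    obs["nominal_visit"] = visit_map.assign_series(obs["visit_months"])
    rows = []
    for (region, visit), grp in obs.groupby(["region", "nominal_visit"], sort=True):
        n = len(grp)
        if n < 2:
            raise StandardizationError(
                f"({region}, {visit} months): only {n} control observation(s); need ≥2"
            )
        sd = float(grp["value"].std(ddof=ddof))
        if sd <= 0:
            raise StandardizationError(
                f"({region}, {visit} months): zero variance among controls"
            )
        rows.append(
            {"region": region, "visit_months": float(visit),
             "mean": float(grp["value"].mean()), "sd": sd, "n": n}
        )
    return ReferenceNorms(pd.DataFrame(rows))


def to_zscores(
    dataset: LongitudinalDataset,
    norms: ReferenceNorms,
    visit_map: VisitMap | None = None,
) -> LongitudinalDataset:
    """Replace every measurement by its control-referenced z-score.

    The returned dataset has ``value_units == "cu_z"`` (control-referenced
    standard deviations).  An observation whose (region, nominal visit) has
    no norm entry raises an error naming the subject and time.
    """
    visit_map = visit_map or VisitMap()
    obs = dataset.observations.copy()
    nominal = visit_map.assign_series(obs["visit_months"])
    key = pd.MultiIndex.from_arrays([obs["region"], nominal])
    try:
        ref = norms.table.set_index(["region", "visit_months"]).loc[key]
    except KeyError:
        for i in range(len(obs)):
            r, v = obs["region"].iat[i], nominal.iat[i]
            if (r, v) not in norms.table.set_index(["region", "visit_months"]).index:
                raise StandardizationError(
                    f"no norm for subject {obs['subject_id'].iat[i]} at "
                    f"({r}, {v} months)"
                ) from None
        raise
    obs["value"] = (obs["value"].to_numpy() - ref["mean"].to_numpy()) / ref["sd"].to_numpy()
    return with_observations(dataset, obs, value_units="cu_z")
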