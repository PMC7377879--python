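"""Cohort data model: long-format subject × visit × region measurements.

The canonical on-disk representation is tidy/long: one row per
(subject, visit, region) measurement, with a separate per-subject
covariate table.  Visit times are real months from the first
acquisition, so 0 is the baseline visit by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
PATIENT = "patient"
GROUPS = (CONTROL, PATIENT)

MEASUREMENT_COLUMNS = ["subject_id", "group", "visit_months", "region", "value"]


class CohortValidationError(ValueError):
    """Raised when a cohort file or dataset violates a structural invariant."""


@dataclass(frozen=True)
class RegionPanel:
    """Ordered set of regions entering the model.

    The order is fixed for the lifetime of an analysis: region ``j`` of the
    model is ``names[j]``.  ``kinds`` distinguishes cortical-thickness from
    volumetric measures (relevant for choosing covariates such as
    intracranial volume, not for the likelihood itself).
    """

    names: tuple[str, ...]
    kinds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.names:
            raise CohortValidationError("region panel must be non-empty")
        if len(set(self.names)) != len(self.names):
            raise CohortValidationError("region names must be unique")
        kinds = self.kinds or tuple(_guess_kind(n) for n in self.names)
        object.__setattr__(self, "kinds", kinds)
        if len(self.kinds) != len(self.names):
            raise CohortValidationError("kinds must match names in length")
        bad = set(self.kinds) - {"thickness", "volume"}
        if bad:
            raise CohortValidationError(f"unknown region kinds: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, region: str) -> int:
        return self.names.index(region)


def _guess_kind(name: str) -> str:
    low = name.lower()
    if "vol" in low or low in {
        "hippocampus", "amygdala", "putamen", "caudate",
        "thalamus", "accumbens", "pallidum",
    }:
        return "volume"
    return "thickness"


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: identifier, group membership, and model covariates."""

    subject_id: str
    group: str
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortValidationError(
                f"subject {self.subject_id!r}: unknown group label {self.group!r}"
            )


@dataclass
class LongitudinalDataset:
    """Validated long-format cohort.

    ``observations`` has columns subject_id, visit_months, region, value with
    one row per measurement; (subject_id, visit_months, region) is unique.
    ``value_units`` records whether values are raw measurements or
    control-referenced z-scores (``"cu_z"``).
    """

    panel: RegionPanel
    subjects: list[SubjectRecord]
    observations: pd.DataFrame
    value_units: str = "raw"

    def __post_init__(self) -> None:
        self._subject_index = {s.subject_id: s for s in self.subjects}
        if len(self._subject_index) != len(self.subjects):
            raise CohortValidationError("subject_id must be unique within a dataset")
        obs = self.observations
        missing = [c for c in ("subject_id", "visit_months", "region", "value") if c not in obs.columns]
        if missing:
            raise CohortValidationError(f"observations missing columns: {missing}")
        obs = obs.reset_index(drop=True)
        obs["visit_months"] = obs["visit_months"].astype(float)
        obs["value"] = obs["value"].astype(float)
        if (obs["visit_months"] < 0).any():
            row = obs.index[obs["visit_months"] < 0][0]
            raise CohortValidationError(f"negative visit time at observation row {row}")
        dup = obs.duplicated(subset=["subject_id", "visit_months", "region"])
        if dup.any():
            row = obs[dup].iloc[0]
            raise CohortValidationError(
                "duplicate (subject, visit, region) row: "
                f"({row.subject_id}, {row.visit_months}, {row.region})"
            )
        unknown_subj = set(obs["subject_id"]) - set(self._subject_index)
        if unknown_subj:
            raise CohortValidationError(
                f"observations reference unknown subjects: {sorted(unknown_subj)[:5]}"
            )
        unknown_reg = set(obs["region"]) - set(self.panel.names)
        if unknown_reg:
            raise CohortValidationError(
                f"observations reference regions outside the panel: {sorted(unknown_reg)[:5]}"
            )
        self.observations = obs

    # -- convenience accessors -------------------------------------------------

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def subject(self, subject_id: str) -> SubjectRecord:
        return self._subject_index[subject_id]

    def subset(self, group: str) -> "LongitudinalDataset":
        """Restrict to one group (``"control"`` or ``"patient"``)."""
        keep = [s for s in self.subjects if s.group == group]
        ids = {s.subject_id for s in keep}
        obs = self.observations[self.observations["subject_id"].isin(ids)]
        return LongitudinalDataset(self.panel, keep, obs.copy(), self.value_units)

    @property
    def controls(self) -> "LongitudinalDataset":
        return self.subset(CONTROL)

    @property
    def patients(self) -> "LongitudinalDataset":
        return self.subset(PATIENT)

    def visit_counts(self) -> pd.Series:
        """Distinct visit times per subject."""
        return self.observations.groupby("subject_id")["visit_months"].nunique()

    def covariate_table(self) -> pd.DataFrame:
        rows = [{"subject_id": s.subject_id, "group": s.group, **s.covariates} for s in self.subjects]
        return pd.DataFrame(rows).set_index("subject_id")


# -- I/O ----------------------------------------------------------------------


def read_cohort(
    measurements_path,
    covariates_path=None,
    panel: RegionPanel | None = None,
) -> LongitudinalDataset:
    """Read a cohort from delimited text files.

    ``measurements_path`` must have columns subject_id, group, visit_months,
    region, value (UTF-8, comma-delimited, header mandatory, dot decimal
    separator).  ``covariates_path``, if given, has subject_id plus named
    covariate columns.  When ``panel`` is omitted it is inferred from the
    order of first appearance of regions in the file.
    """
    meas = pd.read_csv(measurements_path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in meas.columns]
    if missing:
        raise CohortValidationError(
            f"{measurements_path}: missing required columns {missing}"
        )
    bad_group = ~meas["group"].isin(GROUPS)
    if bad_group.any():
        row = meas.index[bad_group][0]
        raise CohortValidationError(
            f"{measurements_path}: unknown group label {meas.loc[row, 'group']!r} at row {row + 2}"
        )
    group_per_subject = meas.groupby("subject_id")["group"].nunique()
    if (group_per_subject > 1).any():
        sid = group_per_subject.index[group_per_subject > 1][0]
        raise CohortValidationError(f"subject {sid!r} appears with more than one group label")

    covs: dict[str, dict] = {}
    if covariates_path is not None:
        cov_df = pd.read_csv(covariates_path)
        if "subject_id" not in cov_df.columns:
            raise CohortValidationError(f"{covariates_path}: missing subject_id column")
        for _, row in cov_df.iterrows():
            covs[str(row["subject_id"])] = {
                k: row[k] for k in cov_df.columns if k != "subject_id"
            }

    if panel is None:
        seen = list(dict.fromkeys(meas["region"]))
        panel = RegionPanel(tuple(seen))

    meas["subject_id"] = meas["subject_id"].astype(str)
    subjects = [
        SubjectRecord(sid, grp, covs.get(sid, {}))
        for sid, grp in meas.drop_duplicates("subject_id")[["subject_id", "group"]].itertuples(index=False)
    ]
    obs = meas[["subject_id", "visit_months", "region", "value"]].copy()
    return LongitudinalDataset(panel, subjects, obs)


def write_cohort(dataset: LongitudinalDataset, measurements_path, covariates_path=None) -> None:
    """Write a dataset back to the CSV dialect accepted by :func:`read_cohort`."""
    group_of = {s.subject_id: s.group for s in dataset.subjects}
    out = dataset.observations.copy()
    out["group"] = out["subject_id"].map(group_of)
    out[MEASUREMENT_COLUMNS].to_csv(measurements_path, index=False)
    if covariates_path is not None:
        cov = dataset.covariate_table().drop(columns=["group"]).reset_index()
        cov.to_csv(covariates_path, index=False)


def wide_to_long(wide: pd.DataFrame, region_columns: list[str]) -> pd.DataFrame:
    """Convenience converter from a wide table (one column per region) to the
    canonical long format.  Expects subject_id, group, visit_months columns."""
    for c in ("subject_id", "group", "visit_months"):
        if c not in wide.columns:
            raise CohortValidationError(f"wide table missing column {c!r}")
    return wide.melt(
        id_vars=["subject_id", "group", "visit_months"],
        value_vars=region_columns,
        var_name="region",
        value_name="value",
    )


# -- filtering ----------------------------------------------------------------


def filter_min_visits(
    dataset: LongitudinalDataset,
    min_visits: int = 2,
    *,
    schedule: tuple[float, ...] | None = None,
    tolerance_months: float = 3.0,
) -> LongitudinalDataset:
    """Drop subjects with fewer than ``min_visits`` distinct visit times.

    Controls are subject to the same rule as patients.  By default a visit
    counts whenever a measurement exists at that time; passing ``schedule``
    switches to the strict-continuity variant, which requires the retained
    visits to be the *first* ``min_visits`` nominal waves with no gaps
    (e.g. a subject seen at 0 and 24 months but not 12 is dropped).
    Removals are logged with their subject ids.
    """
    if min_visits < 1:
        raise ValueError("min_visits must be >= 1")
    counts = dataset.visit_counts()
    removed: list[str] = []
    keep_ids: set[str] = set()
    for sid in dataset.subject_ids:
        times = sorted(
            dataset.observations.loc[
                dataset.observations["subject_id"] == sid, "visit_months"
            ].unique()
        )
        ok = len(times) >= min_visits
        if ok and schedule is not None:
            waves = sorted(schedule)
            hit = [any(abs(t - w) <= tolerance_months for t in times) for w in waves]
            # continuity: the attended waves must form a gap-free prefix run
            n_prefix = 0
            for h in hit:
                if h:
                    n_prefix += 1
                else:
                    break
            ok = n_prefix >= min_visits
        if ok:
            keep_ids.add(sid)
        else:
            removed.append(sid)
    if removed:
        logger.info(
            "filter_min_visits(min_visits=%d): removed %d subject(s): %s",
            min_visits, len(removed), ", ".join(removed),
        )
    if not keep_ids:
        raise CohortValidationError(
            "filter_min_visits removed every subject; inspect visit structure "
            f"(counts: {counts.to_dict()})"
        )
    keep_subjects = [s for s in dataset.subjects if s.subject_id in keep_ids]
    obs = dataset.observations[dataset.observations["subject_id"].isin(keep_ids)]
    return LongitudinalDataset(dataset.panel, keep_subjects, obs.copy(), dataset.value_units)


def with_observations(dataset: LongitudinalDataset, obs: pd.DataFrame, value_units: str | None = None) -> LongitudinalDataset:
    """Return a copy of ``dataset`` with a replaced observation table."""
    return LongitudinalDataset(
        dataset.panel,
        list(dataset.subjects),
        obs,
        value_units if value_units is not None else dataset.value_units,
    )
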