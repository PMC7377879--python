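"""Synthetic longitudinal cohorts with known ground truth.

The generator draws data from exactly the statistical structure the
mixture model assumes: a control group measured on a regular 0/12/24-month
schedule whose raw values follow a linear normal-ageing trajectory plus
Gaussian noise, and a patient group whose control-referenced z-trajectories
follow cluster-specific random intercepts and slopes with region-correlated
random effects, shared covariate effects, and Gaussian residuals.  The
24-month visit is attended with probability < 1 by patients, mirroring the
typical structure of a longitudinal imaging cohort in which every patient
has baseline and 12-month scans but some miss the 24-month wave.

Raw units are realistic (mm cortical thickness, mm³ subcortical volume) so
the standardization step is exercised for real; ground-truth cluster
parameters are stated in control-SD (z) units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from .classify import ASSIGNED, HPD_UNCERTAIN, OUTLIER_MEMBER, ClassificationResult
from .data import CONTROL, PATIENT, LongitudinalDataset, RegionPanel, SubjectRecord

logger = logging.getLogger(__name__)

DEFAULT_REGIONS = ("hippocampus", "entorhinal", "inferior_temporal", "precuneus")
DEFAULT_KINDS = ("volume", "thickness", "thickness", "thickness")

# Default cluster geometry (z units): a diffuse/typical pattern with marked
# atrophy everywhere and fast progression, a minimal-atrophy pattern, and a
# hippocampal-sparing pattern with cortical but little hippocampal loss.
DEFAULT_INTERCEPTS = (
    (-2.0, -2.0, -2.0, -2.0),   # diffuse
    (-0.4, -0.6, -0.4, -0.3),   # minimal atrophy
    (-0.4, -0.8, -2.0, -2.0),   # hippocampal sparing
)
DEFAULT_SLOPES = (
    (-0.60, -0.60, -0.55, -0.50),
    (-0.15, -0.20, -0.10, -0.10),
    (-0.10, -0.20, -0.50, -0.55),
)


class SimulationError(ValueError):
    pass


def _psd_factor(D: np.ndarray) -> np.ndarray:
    """Factor L with L L' = D for a positive *semi*-definite D.

    Degenerate designs (zero random-effect spread) are legitimate for
    testing, so plain Cholesky is not enough.
    """
    try:
        return np.linalg.cholesky(D)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh((D + D.T) / 2.0)
        if vals.min() < -1e-10 * max(vals.max(), 1.0):
            raise SimulationError("random-effect covariance is not positive semi-definite") from None
        return vecs * np.sqrt(np.maximum(vals, 0.0))


@dataclass
class SimulationDesign:
    """Parameters of one synthetic cohort.

    Sample sizes default to the archetypal longitudinal subtype cohort:
    72 patients (all with baseline and 12-month visits, 57/72 expected at
    24 months) and 31 controls with complete 0/12/24-month follow-up.
    Cluster intercepts/slopes are in control-SD units (per region, slope
    per year); the control trajectory is in raw measurement units.
    """

    n_controls: int = 31
    n_patients: int = 72
    weights: tuple[float, ...] = (0.50, 0.35, 0.15)
    regions: tuple[str, ...] = DEFAULT_REGIONS
    region_kinds: tuple[str, ...] = DEFAULT_KINDS
    cluster_intercepts: tuple = DEFAULT_INTERCEPTS
    cluster_slopes: tuple = DEFAULT_SLOPES
    re_sd_intercept: float = 0.30
    re_sd_slope: float = 0.10
    intercept_slope_corr: float = -0.20
    cross_region_corr: float = 0.30
    residual_sd: float = 0.50
    control_level: tuple[float, ...] = (3500.0, 3.40, 2.80, 2.30)
    control_change_per_year: tuple[float, ...] = (-35.0, -0.020, -0.015, -0.010)
    control_sd: tuple[float, ...] = (350.0, 0.30, 0.15, 0.12)
    visit_schedule_months: tuple[float, ...] = (0.0, 12.0, 24.0)
    patient_attendance: tuple[float, ...] = (1.0, 1.0, 57.0 / 72.0)
    age_mean: float = 75.0
    age_sd: float = 7.0
    sex_p_female: float = 0.47
    education_mean: float = 16.0
    education_sd: float = 3.0
    # covariate coefficients (z units per covariate unit), shared by clusters
    beta_age: float = -0.02
    beta_sex_female: float = 0.20
    beta_education: float = 0.01
    # model-violation mode for robustness testing only: per-cluster additive
    # shift applied to every covariate coefficient (breaks the shared-beta
    # assumption); None keeps effects identical across clusters.
    cluster_beta_shift: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.weights = tuple(float(w) for w in self.weights)
        if abs(sum(self.weights) - 1.0) > 1e-9 or any(w <= 0 for w in self.weights):
            raise SimulationError("weights must be positive and sum to 1")
        if len(self.cluster_intercepts) != self.K or len(self.cluster_slopes) != self.K:
            raise SimulationError("cluster means must have one row per cluster")
        if not all(0 < a <= 1 for a in self.patient_attendance):
            raise SimulationError("attendance probabilities must be in (0, 1]")
        for name in ("region_kinds", "control_level", "control_change_per_year", "control_sd"):
            if len(getattr(self, name)) != self.J:
                raise SimulationError(f"{name} must have one entry per region")
        _psd_factor(self.random_effect_cov())  # PSD check

    @property
    def K(self) -> int:
        return len(self.weights)

    @property
    def J(self) -> int:
        return len(self.regions)

    @property
    def q(self) -> int:
        return 2 * self.J

    @property
    def panel(self) -> RegionPanel:
        return RegionPanel(tuple(self.regions), tuple(self.region_kinds))

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return ("age", "sex_female", "education_years")

    def reference_profile(self) -> dict:
        """Covariate profile at which cluster effects are expressed."""
        return {
            "age": self.age_mean,
            "sex_female": self.sex_p_female,
            "education_years": self.education_mean,
        }

    def beta_matrix(self) -> np.ndarray:
        """(J, 3) covariate coefficients, identical across regions by default."""
        row = np.array([self.beta_age, self.beta_sex_female, self.beta_education])
        return np.tile(row, (self.J, 1))

    def cluster_means(self) -> np.ndarray:
        """(K, q) ground-truth random-effect means, interleaved (int, slope) per region."""
        mu = np.zeros((self.K, self.q))
        mu[:, 0::2] = np.asarray(self.cluster_intercepts, dtype=float)
        mu[:, 1::2] = np.asarray(self.cluster_slopes, dtype=float)
        return mu

    def random_effect_cov(self) -> np.ndarray:
        """Shared q×q random-effect covariance D.

        Within a region, intercept and slope are correlated
        (``intercept_slope_corr``); across regions, intercepts correlate
        with intercepts and slopes with slopes (``cross_region_corr``).
        """
        J, q = self.J, self.q
        vi, vs = self.re_sd_intercept ** 2, self.re_sd_slope ** 2
        cis = self.intercept_slope_corr * self.re_sd_intercept * self.re_sd_slope
        D = np.zeros((q, q))
        for j in range(J):
            D[2 * j, 2 * j] = vi
            D[2 * j + 1, 2 * j + 1] = vs
            D[2 * j, 2 * j + 1] = D[2 * j + 1, 2 * j] = cis
            for j2 in range(J):
                if j2 != j:
                    D[2 * j, 2 * j2] = self.cross_region_corr * vi
                    D[2 * j + 1, 2 * j2 + 1] = self.cross_region_corr * vs
        return D

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()}
        d["cluster_intercepts"] = [list(r) for r in self.cluster_intercepts]
        d["cluster_slopes"] = [list(r) for r in self.cluster_slopes]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimulationDesign":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        return cls(**d)


@dataclass
class SimulationTruth:
    """Ground truth accompanying a generated cohort."""

    labels: pd.Series              # patient subject_id -> 0-based true cluster
    random_effects: pd.DataFrame   # patients × q, true b_i in z units
    design: SimulationDesign

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "subject_id": self.labels.index,
            "true_cluster": self.labels.to_numpy() + 1,
        }).to_csv(path, index=False)


def generate_cohort(
    design: SimulationDesign, seed: int
) -> tuple[LongitudinalDataset, SimulationTruth]:
    """Draw one cohort from the design.  Deterministic given ``seed``.

    Patients left with fewer than two attended visits have their attendance
    redrawn (logged), which preserves the marginal attendance rates only
    approximately; with the default schedule (baseline and 12-month visits
    mandatory) redraws never trigger.
    """
    rng = np.random.default_rng(seed)
    sched = np.asarray(design.visit_schedule_months, dtype=float)
    t_years = sched / 12.0
    mu = design.cluster_means()
    D = design.random_effect_cov()
    Dchol = _psd_factor(D)
    beta = design.beta_matrix()
    ref = design.reference_profile()

    subjects: list[SubjectRecord] = []
    rows: list[dict] = []

    # controls: raw linear normal-ageing trajectory + measurement noise
    for c in range(design.n_controls):
        sid = f"CU{c + 1:04d}"
        subjects.append(SubjectRecord(sid, CONTROL, {
            "age": float(rng.normal(design.age_mean, design.age_sd)),
            "sex_female": float(rng.random() < design.sex_p_female),
            "education_years": float(rng.normal(design.education_mean, design.education_sd)),
        }))
        for j, region in enumerate(design.regions):
            vals = (design.control_level[j]
                    + design.control_change_per_year[j] * t_years
                    + design.control_sd[j] * rng.standard_normal(len(sched)))
            for t, v in zip(sched, vals):
                rows.append({"subject_id": sid, "visit_months": t, "region": region, "value": v})

    labels = np.zeros(design.n_patients, dtype=int)
    b_all = np.zeros((design.n_patients, design.q))
    pids = []
    for i in range(design.n_patients):
        sid = f"AD{i + 1:04d}"
        pids.append(sid)
        k = int(rng.choice(design.K, p=design.weights))
        labels[i] = k
        b = mu[k] + Dchol @ rng.standard_normal(design.q)
        b_all[i] = b
        cov = {
            "age": float(rng.normal(design.age_mean, design.age_sd)),
            "sex_female": float(rng.random() < design.sex_p_female),
            "education_years": float(rng.normal(design.education_mean, design.education_sd)),
        }
        subjects.append(SubjectRecord(sid, PATIENT, cov))
        # covariate effects relative to the design's reference profile,
        # so cluster means live on the profile's scale
        x = np.array([cov[n] - ref[n] for n in design.covariate_names])
        beta_i = beta
        if design.cluster_beta_shift is not None:
            beta_i = beta + design.cluster_beta_shift[k]
        for attempt in range(100):
            attend = rng.random(len(sched)) < np.asarray(design.patient_attendance)
            if attend.sum() >= 2:
                break
            logger.info("redrawing attendance for %s (fewer than 2 visits)", sid)
        else:
            raise SimulationError(f"could not draw >=2 visits for {sid}")
        for j, region in enumerate(design.regions):
            fixed = float(beta_i[j] @ x)
            for v_idx in np.where(attend)[0]:
                ty = t_years[v_idx]
                z = (fixed + b[2 * j] + b[2 * j + 1] * ty
                     + design.residual_sd * rng.standard_normal())
                raw = (design.control_level[j]
                       + design.control_change_per_year[j] * ty
                       + design.control_sd[j] * z)
                rows.append({
                    "subject_id": sid, "visit_months": sched[v_idx],
                    "region": region, "value": raw,
                })

    dataset = LongitudinalDataset(design.panel, subjects, pd.DataFrame(rows))
    truth = SimulationTruth(
        labels=pd.Series(labels, index=pd.Index(pids, name="subject_id")),
        random_effects=pd.DataFrame(b_all, index=pids),
        design=design,
    )
    return dataset, truth


@dataclass
class RecoveryReport:
    """Agreement between ground-truth and estimated clusterings."""

    ari: float
    n_assigned: int
    n_outlier: int
    n_uncertain: int
    confusion: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"ARI={self.ari:.3f} over {self.n_assigned} assigned subjects "
                f"({self.n_outlier} outlier-cluster, {self.n_uncertain} HPD-uncertain)\n"
                f"{self.confusion}")


def truth_recovery_report(truth: SimulationTruth, classification: ClassificationResult) -> RecoveryReport:
    """ARI between true and assigned labels, plus a correspondence table.

    The adjusted Rand index is computed over subjects with the ``assigned``
    flag; excluded subjects (outlier-cluster members, HPD-uncertain) are
    tallied in dedicated columns of the correspondence table, whose rows
    are the true clusters and whose row sums equal the true cluster sizes.
    """
    cls_ids = set(classification.subject_ids)
    if set(truth.labels.index) != cls_ids:
        raise SimulationError("truth and classification cover different subject sets")
    order = classification.subject_ids
    true = truth.labels.loc[order].to_numpy()
    est = classification.labels
    flags = classification.flags
    assigned = flags == ASSIGNED
    ari = float(adjusted_rand_score(true[assigned], est[assigned])) if assigned.sum() > 1 else float("nan")

    K_true = int(true.max()) + 1
    K_est = int(classification.prob_matrix.shape[1])
    cols = [f"cluster_{k + 1}" for k in range(K_est)] + [OUTLIER_MEMBER, HPD_UNCERTAIN, "Sum"]
    table = pd.DataFrame(0, index=[f"true_{k + 1}" for k in range(K_true)] + ["Sum"], columns=cols)
    for tk, ek, f in zip(true, est, flags):
        row = f"true_{tk + 1}"
        col = f"cluster_{ek + 1}" if f == ASSIGNED else f
        table.loc[row, col] += 1
        table.loc[row, "Sum"] += 1
        table.loc["Sum", col] += 1
        table.loc["Sum", "Sum"] += 1
    return RecoveryReport(
        ari=ari,
        n_assigned=int(assigned.sum()),
        n_outlier=int((flags == OUTLIER_MEMBER).sum()),
        n_uncertain=int((flags == HPD_UNCERTAIN).sum()),
        confusion=table,
    )
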