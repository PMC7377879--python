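import numpy as np
import pandas as pd
import pytest

from trajmix import SimulationDesign, generate_cohort, truth_recovery_report
from trajmix.classify import ASSIGNED, ClassificationResult
from trajmix.examples import cluster_proportions, correspondence_table
from trajmix.simulate import SimulationError


def classification_from_labels(subject_ids, labels, K, flags=None):
    """Build a hard ClassificationResult directly from labels (test helper)."""
    N = len(subject_ids)
    P = np.zeros((N, K))
    P[np.arange(N), labels] = 1.0
    return ClassificationResult(
        subject_ids=list(subject_ids), prob_matrix=P,
        hpd_lower=P.copy(), hpd_upper=P.copy(), coverage=0.95,
        labels=np.asarray(labels),
        flags=np.array(list(flags) if flags is not None else [ASSIGNED] * N, dtype=object),
    )


class TestGenerateCohort:
    def test_degenerate_generator_exactly_linear(self):
        design = SimulationDesign(
            n_patients=5, n_controls=4,
            re_sd_intercept=0.0, re_sd_slope=0.0,
            intercept_slope_corr=0.0, cross_region_corr=0.0,
            residual_sd=0.0,
            beta_age=0.0, beta_sex_female=0.0, beta_education=0.0,
            patient_attendance=(1.0, 1.0, 1.0),
        )
        ds, truth = generate_cohort(design, seed=3)
        mu = design.cluster_means()
        obs = ds.patients.observations
        for sid, k in truth.labels.items():
            for j, region in enumerate(design.regions):
                rows = obs[(obs.subject_id == sid) & (obs.region == region)].sort_values("visit_months")
                t = rows.visit_months.to_numpy() / 12.0
                z_true = mu[k, 2 * j] + mu[k, 2 * j + 1] * t
                raw = (design.control_level[j] + design.control_change_per_year[j] * t
                       + design.control_sd[j] * z_true)
                np.testing.assert_allclose(rows.value.to_numpy(), raw, rtol=1e-12)

    def test_control_cell_means_within_clt_bound(self):
        design = SimulationDesign(n_controls=500, n_patients=2)
        ds, _ = generate_cohort(design, seed=11)
        obs = ds.controls.observations
        for j, region in enumerate(design.regions):
            for t in design.visit_schedule_months:
                cell = obs[(obs.region == region) & (obs.visit_months == t)]["value"]
                want = design.control_level[j] + design.control_change_per_year[j] * t / 12.0
                se = design.control_sd[j] / np.sqrt(len(cell))
                assert abs(cell.mean() - want) < 3 * se

    def test_same_seed_identical_cohort(self):
        d = SimulationDesign(n_patients=10, n_controls=8)
        ds1, t1 = generate_cohort(d, seed=5)
        ds2, t2 = generate_cohort(d, seed=5)
        pd.testing.assert_frame_equal(ds1.observations, ds2.observations)
        pd.testing.assert_series_equal(t1.labels, t2.labels)

    def test_patients_always_have_baseline_and_12m(self):
        d = SimulationDesign(n_patients=40, n_controls=5)
        ds, _ = generate_cohort(d, seed=2)
        counts = ds.patients.visit_counts()
        assert counts.min() >= 2

    def test_invalid_weights_rejected(self):
        with pytest.raises(SimulationError):
            SimulationDesign(weights=(0.7, 0.7))

    def test_design_yaml_roundtrip(self, tmp_path):
        d = SimulationDesign(n_patients=12, weights=(0.6, 0.4),
                             cluster_intercepts=((-2.0,) * 4, (0.0,) * 4),
                             cluster_slopes=((-0.5,) * 4, (0.0,) * 4))
        path = tmp_path / "design.yaml"
        d.to_yaml(path)
        back = SimulationDesign.from_yaml(path)
        assert back.weights == d.weights
        np.testing.assert_allclose(back.cluster_means(), d.cluster_means())


class TestRecoveryReport:
    def _truth(self, labels):
        d = SimulationDesign(n_patients=len(labels))
        ids = [f"AD{i + 1:04d}" for i in range(len(labels))]
        from trajmix.simulate import SimulationTruth

        return SimulationTruth(
            labels=pd.Series(labels, index=pd.Index(ids, name="subject_id")),
            random_effects=pd.DataFrame(np.zeros((len(labels), d.q)), index=ids),
            design=d,
        )

    def test_perfect_agreement(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        truth = self._truth(labels)
        cls = classification_from_labels(truth.labels.index, labels, K=3)
        rep = truth_recovery_report(truth, cls)
        assert rep.ari == pytest.approx(1.0)

    def test_random_labels_near_zero_ari(self):
        rng = np.random.default_rng(0)
        true = rng.integers(0, 3, size=600)
        est = rng.integers(0, 3, size=600)
        truth = self._truth(true)
        cls = classification_from_labels(truth.labels.index, est, K=3)
        rep = truth_recovery_report(truth, cls)
        assert abs(rep.ari) < 0.05

    def test_confusion_row_sums_equal_true_sizes(self):
        true = np.array([0, 0, 0, 1, 1, 2])
        est = np.array([0, 1, 0, 1, 1, 0])
        flags = [ASSIGNED] * 5 + ["hpd_uncertain"]
        truth = self._truth(true)
        cls = classification_from_labels(truth.labels.index, est, K=2, flags=flags)
        rep = truth_recovery_report(truth, cls)
        sums = rep.confusion["Sum"]
        assert sums["true_1"] == 3 and sums["true_2"] == 2 and sums["true_3"] == 1
        assert rep.confusion.loc["Sum", "Sum"] == 6

    def test_disjoint_subjects_rejected(self):
        truth = self._truth(np.array([0, 1]))
        cls = classification_from_labels(["x", "y"], np.array([0, 1]), K=2)
        with pytest.raises(SimulationError):
            truth_recovery_report(truth, cls)


class TestExampleTables:
    def test_correspondence_margins(self):
        t = correspondence_table(with_margins=True)
        assert t.loc["Sum", "Sum"] == 72
        assert t.loc["Minimal atrophy", "Sum"] == 20
        assert t.loc["Minimal atrophy", "Minimal Atrophy"] == 17

    def test_cluster_proportions(self):
        got = cluster_proportions([34, 23, 9, 3], total=72)
        np.testing.assert_allclose(np.round(got, 1), [47.2, 31.9, 12.5, 4.2])
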