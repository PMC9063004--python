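import numpy as np
import pytest

from deltarad.delta import build_delta_table
from deltarad.pipeline import PipelineConfig, extract_cohort_features
from deltarad.schedule import TreatmentSchedule
from deltarad.selection import rank_by_gini, select_top_k
from deltarad.synthetic import CohortSpec, generate_cohort, generate_patient
from deltarad.validation import compute_auc


def small_spec(**kw):
    defaults = dict(n_patients=6, n_responders=3, grid_shape=(24, 24, 24), seed=1)
    defaults.update(kw)
    return CohortSpec(**defaults)


def cohort_features(cohort, config=None):
    patients = {
        p.patient_id: {
            "assignment": p.assignment,
            "images": {k + 1: (p.volumes[k], p.masks[k]) for k in range(p.n_fractions)},
        }
        for p in cohort.patients
    }
    return extract_cohort_features(patients, config or PipelineConfig())


class TestGeneratePatient:
    def _schedule(self):
        return TreatmentSchedule.from_bed("P01", 72.0, bed_per_fx=14.4)

    def test_fixed_seed_reproduces_volumes_exactly(self):
        spec = small_spec()
        a = generate_patient(spec, "P01", "RS", self._schedule(), seed=42)
        b = generate_patient(spec, "P01", "RS", self._schedule(), seed=42)
        for va, vb in zip(a.volumes, b.volumes):
            np.testing.assert_array_equal(va, vb)
        np.testing.assert_array_equal(a.masks[0], b.masks[0])

    def test_all_perturbations_off_means_identical_fractions(self):
        spec = small_spec(noise_sd=0.0, smoothness_jitter_sd=0.0, effect_size=0.0)
        p = generate_patient(spec, "P01", "RS", self._schedule(), seed=7)
        for v in p.volumes[1:]:
            np.testing.assert_array_equal(v, p.volumes[0])

    def test_effect_changes_only_the_assigned_image(self):
        kw = dict(noise_sd=0.0, smoothness_jitter_sd=0.0)
        quiet = generate_patient(
            small_spec(effect_size=0.0, **kw), "P01", "RS", self._schedule(), seed=7
        )
        loud = generate_patient(
            small_spec(effect_size=0.5, **kw), "P01", "RS", self._schedule(), seed=7
        )
        eff = loud.assignment.bed20_image_index - 1
        for k, (a, b) in enumerate(zip(quiet.volumes, loud.volumes)):
            if k == eff:
                assert not np.array_equal(a, b)
            else:
                np.testing.assert_array_equal(a, b)

    def test_roi_size_in_gtv_range(self):
        p = generate_patient(small_spec(grid_shape=(32, 32, 32)), "P01", "NR", self._schedule(), seed=3)
        assert 400 <= p.masks[0].sum() <= 3200

    def test_tiny_roi_rejected(self):
        spec = small_spec(roi_semiaxis_range=(0.3, 0.4))
        with pytest.raises(ValueError):
            generate_patient(spec, "P01", "NR", self._schedule(), seed=0)


class TestGenerateCohort:
    def test_default_composition_matches_study(self):
        cohort = generate_cohort(CohortSpec(seed=0))
        labels = list(cohort.labels.values())
        assert len(cohort.patients) == 30
        assert labels.count("RS") == 11
        assert labels.count("NR") == 19
        rates = {p.schedule.bed_per_fraction for p in cohort.patients}
        assert rates <= {11.0, 11.9, 12.3, 14.4, 20.0, 26.4}

    def test_every_schedule_reaches_both_bins(self):
        cohort = generate_cohort(CohortSpec(seed=0))
        for asg in cohort.assignments.values():
            assert asg.bed20_image_index is not None
            assert asg.bed40_image_index is not None
            assert asg.bed20_in_window

    def test_cohort_deterministic_in_seed(self):
        a = generate_cohort(small_spec(seed=5))
        b = generate_cohort(small_spec(seed=5))
        for pa, pb in zip(a.patients, b.patients):
            np.testing.assert_array_equal(pa.volumes[0], pb.volumes[0])

    def test_non_default_size_samples_reference_mix(self):
        cohort = generate_cohort(small_spec(n_patients=7, n_responders=2, seed=3))
        assert len(cohort.patients) == 7
        assert list(cohort.labels.values()).count("RS") == 2


class TestInjectedSignal:
    def test_responder_drift_inflates_bed20_deltas(self):
        """Group-mean |delta| at BED20 is larger for RS than NR when only RS
        drifts there (Monte-Carlo over 20 patients)."""
        spec = CohortSpec(
            n_patients=20, n_responders=10, grid_shape=(24, 24, 24),
            noise_sd=0.02, smoothness_jitter_sd=0.02, seed=11,
        )
        cohort = generate_cohort(spec)
        feats = cohort_features(cohort)
        table = build_delta_table(feats, cohort.assignments, cohort.labels, "BED20")
        mag = table.data.abs()
        rs = mag.loc[table.labels == "RS"].mean()
        nr = mag.loc[table.labels == "NR"].mean()
        # the drift dominates for the clear majority of the panel
        assert (rs > nr).mean() > 0.8

    def test_selected_features_recover_class_separation(self):
        """The RF top-2 at BED20 are genuinely class-separating: their
        univariate separation beats the panel median in >= 80% of cohorts."""
        hits = 0
        n_cohorts = 10
        for k in range(n_cohorts):
            cohort = generate_cohort(CohortSpec(seed=300 + k))
            feats = cohort_features(cohort)
            table = build_delta_table(feats, cohort.assignments, cohort.labels, "BED20")
            clean = table.dropna()
            y = (clean.labels == "RS").to_numpy().astype(int)
            sep = {
                c: abs(compute_auc(clean.data[c].to_numpy(), y) - 0.5)
                for c in clean.data.columns
            }
            top2 = select_top_k(rank_by_gini(table, n_trees=100, seed=k), 2)
            med = np.median(list(sep.values()))
            hits += all(sep[f] >= med and sep[f] >= 0.25 for f in top2)
        assert hits >= int(0.8 * n_cohorts)
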