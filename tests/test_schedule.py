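import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltarad.schedule import (
    TreatmentSchedule,
    assign_dose_bins,
    bed_per_fraction,
    compute_bed,
    reference_cohort,
)


class TestComputeBed:
    @pytest.mark.parametrize(
        "n,d,expected",
        [(5, 10, 100.0), (5, 12, 132.0), (1, 10, 20.0), (3, 10, 60.0)],
    )
    def test_linear_quadratic_formula(self, n, d, expected):
        assert compute_bed(n, d, alpha_beta=10) == pytest.approx(expected)

    def test_vanishes_with_dose(self):
        assert compute_bed(1, 1e-9) == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("n,d", [(0, 10), (5, 0), (5, -1)])
    def test_rejects_non_positive_inputs(self, n, d):
        with pytest.raises(ValueError):
            compute_bed(n, d)

    @given(
        n=st.integers(1, 10),
        d=st.floats(0.5, 30),
        eps=st.floats(0.1, 5),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_n_and_d(self, n, d, eps):
        base = compute_bed(n, d)
        assert compute_bed(n + 1, d) > base
        assert compute_bed(n, d + eps) > base


class TestBedPerFraction:
    @pytest.mark.parametrize(
        "total,n,expected", [(72, 5, 14.4), (100, 5, 20.0), (42.0, 1, 42.0)]
    )
    def test_examples(self, total, n, expected):
        assert bed_per_fraction(total, n) == pytest.approx(expected)

    def test_zero_fractions_rejected(self):
        with pytest.raises(ValueError):
            bed_per_fraction(100, 0)


class TestDoseBinAssignment:
    @pytest.mark.parametrize(
        "bed_fx,n,expected",
        [
            (14.4, 5, (3, 4)),
            (20.0, 5, (2, 3)),
            (11.9, 5, (3, 5)),
            (26.4, 5, (2, 3)),
            (11.0, 5, (3, 5)),
            (12.3, 5, (3, 5)),
            (20.0, 3, (2, 3)),
        ],
    )
    def test_first_crossing_indices(self, bed_fx, n, expected):
        s = TreatmentSchedule.from_bed("x", bed_fx * n, bed_per_fx=bed_fx, n_fractions=n)
        a = assign_dose_bins(s)
        assert (a.bed20_image_index, a.bed40_image_index) == expected
        assert a.bed20_in_window

    def test_unreachable_bin_is_none_not_error(self):
        # 3 fractions at 14.4 Gy BED: 40 Gy is crossed at fraction 3 but
        # image 4 does not exist
        s = TreatmentSchedule.from_bed("x", 43.2, bed_per_fx=14.4, n_fractions=3)
        a = assign_dose_bins(s)
        assert a.bed20_image_index == 3
        assert a.bed40_image_index is None

    def test_overshooting_the_20_to_30_window_is_flagged(self):
        # 16 Gy/fx: first crossing of 20 Gy lands at 32 Gy cumulative
        s = TreatmentSchedule.from_bed("x", 80.0, bed_per_fx=16.0, n_fractions=5)
        a = assign_dose_bins(s)
        assert not a.bed20_in_window

    def test_cumulative_bed_invariants(self):
        s = TreatmentSchedule.from_bed("x", 72.0, bed_per_fx=14.4)
        a = assign_dose_bins(s)
        assert 20 <= a.bed_before_bed20 <= 30
        assert a.bed_before_bed40 >= 40
        assert 2 <= a.bed20_image_index < a.bed40_image_index <= s.n_fractions


class TestScheduleConstruction:
    def test_n_recovered_from_bed_ratio(self):
        s = TreatmentSchedule.from_bed("x", 72.0, bed_per_fx=14.4)
        assert s.n_fractions == 5

    def test_rounded_published_rate_accepted(self):
        # printed per-fraction rate 11.0 for total 54.8 gives ratio 4.98
        s = TreatmentSchedule.from_bed("x", 54.8, bed_per_fx=11.0)
        assert s.n_fractions == 5
        assert s.bed_per_fraction == 11.0

    def test_far_from_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            TreatmentSchedule.from_bed("x", 70.0, bed_per_fx=16.0)

    def test_physical_prescription_roundtrip(self):
        s = TreatmentSchedule.from_physical("x", 5, 10.0)
        assert s.total_bed == pytest.approx(100.0)
        assert s.bed_per_fraction == pytest.approx(20.0)


class TestReferenceCohort:
    def test_cohort_composition(self):
        ref = reference_cohort()
        assert len(ref) == 30
        assert (ref["response"] == "RS").sum() == 11
        assert (ref["response"] == "NR").sum() == 19

    def test_total_bed_summary_statistics(self):
        total = reference_cohort()["total_bed_gy"].astype(float)
        assert float(total.median()) == pytest.approx(100.0)
        assert float(total.min()) == pytest.approx(54.8)
        assert float(total.max()) == pytest.approx(132.0)

    def test_all_printed_fraction_pairs_reproduced(self):
        ref = reference_cohort()
        for row in ref.itertuples():
            a = assign_dose_bins(row.schedule)
            assert a.bed20_pair == row.bed20_pair, row.patient_id
            assert a.bed40_pair == row.bed40_pair, row.patient_id

    def test_rate_times_fractions_consistent_with_total(self):
        # printed rates are rounded to 0.1 Gy, so allow that rounding
        for row in reference_cohort().itertuples():
            s = row.schedule
            assert s.bed_per_fraction * s.n_fractions == pytest.approx(
                s.total_bed, abs=0.1 * s.n_fractions
            )
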