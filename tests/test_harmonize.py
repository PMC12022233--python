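import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myodx.cohort import CohortTable, SampleRecord
from myodx.harmonize import (
    CohortHarmonizer,
    HarmonizedTable,
    harmonize_cohort,
    loo_rescale,
    reduce_sides,
    scale_age,
)


class TestReduceSides:
    def test_symmetric_muscle(self):
        rec = SampleRecord("s", "p", "src", "d", None, None, "bilateral",
                           "0-4", scores={"soleus": (2.0, 2.0),
                                          "fhl": (1.0, 1.0)})
        reduced, a_mean, a_sd = reduce_sides(rec)
        assert reduced.scores["soleus"] == 2.0
        assert a_mean == 0.0 and a_sd == 0.0

    def test_asymmetry_in_normalized_units(self):
        # L=1, R=3 on 0-4: mean rank 2, |25 - 75| = 50 normalized units
        rec = SampleRecord("s", "p", "src", "d", None, None, "bilateral",
                           "0-4", scores={"soleus": (1.0, 3.0),
                                          "fhl": (0.0, 0.0)})
        reduced, a_mean, _ = reduce_sides(rec)
        assert reduced.scores["soleus"] == 2.0
        assert a_mean == pytest.approx(25.0)  # mean of {50, 0}

    def test_population_sd_over_muscles(self):
        rec = SampleRecord("s", "p", "src", "d", None, None, "bilateral",
                           "FF", scores={"a_m": (10.0, 10.0),
                                         "b_m": (0.0, 50.0),
                                         "c_m": (0.0, 100.0)})
        _, a_mean, a_sd = reduce_sides(rec)
        asyms = np.array([0.0, 50.0, 100.0])
        assert a_mean == pytest.approx(asyms.mean())
        assert a_sd == pytest.approx(asyms.std())  # n denominator

    def test_non_bilateral_passthrough(self, ff_record):
        reduced, a_mean, a_sd = reduce_sides(ff_record)
        assert reduced is ff_record
        assert np.isnan(a_mean) and np.isnan(a_sd)


class TestLooRescale:
    @pytest.mark.parametrize("scores,rel,mi", [
        ((0.0, 50.0, 100.0), (-75.0, 0.0, 75.0), 50.0),
        ((100.0, 0.0, 0.0), (100.0, -50.0, -50.0), 100.0 / 3.0),
        ((30.0, 30.0, 30.0, 30.0), (0.0, 0.0, 0.0, 0.0), 30.0),
    ])
    def test_worked_examples(self, scores, rel, mi):
        relative, involvement = loo_rescale(np.array(scores))
        assert relative == pytest.approx(np.array(rel))
        assert involvement == pytest.approx(mi)

    def test_fewer_than_two_observed_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            loo_rescale(np.array([50.0, np.nan, np.nan]))

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=30),
           st.floats(-30, 30))
    @settings(max_examples=100, deadline=None)
    def test_shift_moves_only_mean_involvement(self, values, c):
        """Adding a constant to all of a patient's scores leaves relative
        scores unchanged and shifts mean involvement by exactly c."""
        x = np.array(values)
        rel0, mi0 = loo_rescale(x)
        rel1, mi1 = loo_rescale(x + c)
        assert np.allclose(rel0, rel1, atol=1e-9)
        assert mi1 - mi0 == pytest.approx(c, abs=1e-9)

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_bounds(self, values):
        rel, mi = loo_rescale(np.array(values))
        assert np.all(rel >= -100 - 1e-9) and np.all(rel <= 100 + 1e-9)
        assert 0 <= mi <= 100


class TestScaleAge:
    def test_endpoints_and_midpoint(self):
        assert scale_age(10, (10, 70)) == -100.0
        assert scale_age(70, (10, 70)) == 100.0
        assert scale_age(40, (10, 70)) == 0.0
        assert scale_age(55, (10, 70)) == 50.0

    def test_clipping_outside_training_range(self):
        assert scale_age(200, (10, 70)) == 100.0
        assert scale_age(-5, (10, 70)) == -100.0

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            scale_age(5, (30, 30))


class TestHarmonizeCohort:
    def test_single_bilateral_record_smoke(self):
        rec = SampleRecord("s", "p", "src", "d", 40.0, "M", "bilateral",
                           "0-4", scores={"soleus": (1.0, 3.0),
                                          "fhl": (0.0, 0.0),
                                          "tibialis_anterior": (4.0, 4.0)})
        # single-record cohort: the imputer and age range fit on it alone
        table = harmonize_cohort(
            CohortTable(records=[rec]),
            target_muscles=["soleus", "fhl", "tibialis_anterior"])
        row = table.frame.iloc[0]
        rel = row[table.muscles].astype(float)
        observed = rel.dropna()
        assert ((observed >= -100) & (observed <= 100)).all()
        assert 0 <= row["mean_involvement"] <= 100

    def test_scale_identity(self):
        """A discrete score and its exact FF equivalent give identical
        features: 0-4 level 2 == FF 50 after normalization."""
        shared = dict(age=40.0, sex="M", side_mode="average")
        rec_a = SampleRecord("a", "pa", "src", "d", scale="0-4",
                             scores={"soleus": 2.0, "fhl": 0.0,
                                     "tibialis_anterior": 4.0}, **shared)
        rec_b = SampleRecord("b", "pb", "src", "d", scale="FF",
                             scores={"soleus": 50.0, "fhl": 0.0,
                                     "tibialis_anterior": 100.0}, **shared)
        table = harmonize_cohort(
            CohortTable(records=[rec_a, rec_b]),
            target_muscles=["soleus", "fhl", "tibialis_anterior"])
        cols = ["soleus", "fhl", "tibialis_anterior", "mean_involvement"]
        a = table.frame.iloc[0][cols].astype(float)
        b = table.frame.iloc[1][cols].astype(float)
        assert np.allclose(a, b, atol=1e-9)

    def test_ranges_on_generated_cohort(self, harmonized_small):
        X = harmonized_small.frame[harmonized_small.muscles].to_numpy(float)
        assert np.nanmin(X) >= -100 and np.nanmax(X) <= 100
        mi = harmonized_small.frame["mean_involvement"].to_numpy(float)
        assert mi.min() >= 0 and mi.max() <= 100
        assert not np.isnan(harmonized_small.X).any()

    def test_age_range_learned_from_fit_data_only(self, small_cohort):
        cohort, _ = small_cohort
        h = CohortHarmonizer().fit(cohort)
        lo, hi = h.age_range_
        ages = [r.age for r in cohort.records if r.age is not None]
        assert lo == pytest.approx(min(ages))
        assert hi == pytest.approx(max(ages))

    def test_deterministic(self, small_cohort):
        cohort, _ = small_cohort
        t1 = harmonize_cohort(cohort)
        t2 = harmonize_cohort(cohort)
        assert np.array_equal(t1.X, t2.X)

    def test_csv_round_trip(self, tmp_path, harmonized_small):
        path = tmp_path / "h.csv"
        harmonized_small.to_csv(path)
        back = HarmonizedTable.read_csv(path)
        assert back.muscles == harmonized_small.muscles
        assert np.allclose(back.X, harmonized_small.X, atol=1e-6)
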