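import math

import numpy as np
import pytest

from myodx.cohort import (
    CohortTable,
    SampleRecord,
    align_feature_space,
    expand_group,
    merge_muscles,
    read_cohort_csv,
    write_cohort_csv,
)
from myodx.taxonomy import MuscleTaxonomy, default_taxonomy


class TestMerge:
    def test_mean_of_members(self, ff_record, taxonomy):
        merged = merge_muscles(ff_record, "peronei", taxonomy)
        assert merged.scores["peronei"] == pytest.approx(30.0)
        assert "peroneus_brevis" not in merged.scores
        assert merged.scores["soleus"] == 70.0  # untouched

    def test_constant_group_unchanged(self, taxonomy):
        rec = SampleRecord("s", "p", "src", "d", None, None, "average", "0-4",
                           scores={"peroneus_brevis": 3.0,
                                   "peroneus_longus": 3.0})
        assert merge_muscles(rec, "peronei", taxonomy).scores["peronei"] == 3.0

    def test_bilateral_per_side_means(self, taxonomy):
        rec = SampleRecord("s", "p", "src", "d", None, None, "bilateral", "0-4",
                           scores={"peroneus_brevis": (0.0, 4.0),
                                   "peroneus_longus": (2.0, 2.0)})
        merged = merge_muscles(rec, "peronei", taxonomy)
        assert merged.scores["peronei"] == (1.0, 3.0)

    def test_missing_member_error_names_it(self, taxonomy):
        rec = SampleRecord("s", "p", "src", "d", None, None, "average", "FF",
                           scores={"peroneus_brevis": 10.0})
        with pytest.raises(KeyError, match="peroneus_longus"):
            merge_muscles(rec, "peronei", taxonomy)

    def test_unknown_group_error(self, ff_record, taxonomy):
        with pytest.raises(KeyError, match="nonsense"):
            merge_muscles(ff_record, "nonsense", taxonomy)

    def test_member_order_irrelevant(self, taxonomy):
        a = SampleRecord("s", "p", "src", "d", None, None, "average", "FF",
                         scores={"peroneus_brevis": 20.0,
                                 "peroneus_longus": 40.0})
        b = SampleRecord("s", "p", "src", "d", None, None, "average", "FF",
                         scores={"peroneus_longus": 40.0,
                                 "peroneus_brevis": 20.0})
        assert (merge_muscles(a, "peronei", taxonomy).scores
                == merge_muscles(b, "peronei", taxonomy).scores)


class TestExpand:
    def test_copies_group_score_to_members(self, taxonomy):
        rec = SampleRecord("s", "p", "src", "d", None, None, "average", "0-4",
                           scores={"biceps_femoris": 2.0})
        out = expand_group(rec, "biceps_femoris", taxonomy)
        assert out.scores["bflh"] == 2.0 and out.scores["bfsh"] == 2.0
        assert "biceps_femoris" not in out.scores

    def test_zero_propagates(self, taxonomy):
        rec = SampleRecord("s", "p", "src", "d", None, None, "average", "0-4",
                           scores={"glutei": 0.0})
        out = expand_group(rec, "glutei", taxonomy)
        assert all(out.scores[m] == 0.0
                   for m in taxonomy.members("glutei"))

    def test_merge_then_expand_constant_is_identity(self, taxonomy):
        scores = {"peroneus_brevis": 2.0, "peroneus_longus": 2.0}
        rec = SampleRecord("s", "p", "src", "d", None, None, "average", "0-4",
                           scores=dict(scores))
        round_trip = expand_group(merge_muscles(rec, "peronei", taxonomy),
                                  "peronei", taxonomy)
        assert round_trip.scores == scores

    def test_unknown_group_error(self, ff_record, taxonomy):
        with pytest.raises(KeyError):
            expand_group(ff_record, "soleus", taxonomy)


class TestAlign:
    def _cohort(self, scores, side_mode="average", scale="FF"):
        rec = SampleRecord("s", "p", "src", "d", None, None, side_mode, scale,
                           scores=scores)
        return CohortTable(records=[rec])

    def test_merges_toward_group_target(self):
        cohort = self._cohort({"psoas": 10.0, "iliacus": 30.0})
        out = align_feature_space(cohort, ["iliopsoas"])
        assert out.records[0].scores == {"iliopsoas": 20.0}

    def test_identity_when_already_aligned(self):
        cohort = self._cohort({"soleus": 55.0, "fhl": 5.0})
        out = align_feature_space(cohort, ["soleus", "fhl"])
        assert out.records[0].scores == {"soleus": 55.0, "fhl": 5.0}

    def test_expands_enclosing_group_toward_member_target(self):
        cohort = self._cohort({"biceps_femoris": 42.0})
        out = align_feature_space(cohort, ["bflh", "bfsh"])
        assert out.records[0].scores == {"bflh": 42.0, "bfsh": 42.0}

    def test_absent_muscles_stay_missing(self):
        cohort = self._cohort({"soleus": 55.0})
        out = align_feature_space(cohort, ["soleus", "tibialis_anterior",
                                           "peronei"])
        assert out.records[0].scores == {"soleus": 55.0}

    def test_partial_group_not_invented(self):
        # one peroneus observed: the peronei target must stay missing
        cohort = self._cohort({"peroneus_brevis": 10.0})
        out = align_feature_space(cohort, ["peronei"])
        assert "peronei" not in out.records[0].scores


class TestValidation:
    def test_out_of_range_reported_per_record(self):
        rec = SampleRecord("bad1", "p", "src", "d", None, None, "average",
                           "0-4", scores={"soleus": 9.0})
        report = CohortTable(records=[rec]).validate()
        assert "bad1" in report and "soleus" in report["bad1"][0]

    def test_bilateral_needs_pairs(self):
        rec = SampleRecord("s", "p", "src", "d", None, None, "bilateral",
                           "0-4", scores={"soleus": 2.0})
        assert any("pair" in p for p in rec.validate())

    def test_clean_cohort_passes(self, small_cohort):
        cohort, _ = small_cohort
        assert cohort.validate() == {}


class TestCsvRoundTrip:
    def test_records_survive(self, tmp_path, small_cohort):
        cohort, _ = small_cohort
        path = tmp_path / "cohort.csv"
        write_cohort_csv(cohort, path)
        back = read_cohort_csv(path)
        assert len(back) == len(cohort)
        for a, b in zip(cohort.records, back.records):
            assert a.sample_id == b.sample_id
            assert a.disease == b.disease
            assert a.side_mode == b.side_mode
            assert a.scale == b.scale
            assert set(a.scores) == set(b.scores)
            for m in a.scores:
                assert np.allclose(np.atleast_1d(a.scores[m]),
                                   np.atleast_1d(b.scores[m]), atol=1e-9)

    def test_level_labels_accepted(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "sample_id,patient_id,source_id,disease,age,sex,side_mode,scale,"
            "soleus,fhl\n"
            "s1,p1,src,d,40,M,average,2a2b,2a,3\n"
            "s2,p2,src,d,,F,average,0-4,1.5,\n")
        cohort = read_cohort_csv(path)
        assert cohort.records[0].scores == {"soleus": 2.0, "fhl": 4.0}
        assert cohort.records[1].scores == {"soleus": 1.5}
        assert cohort.records[1].age is None


class TestTaxonomy:
    def test_group_members_must_be_canonical(self):
        with pytest.raises(ValueError, match="non-canonical"):
            MuscleTaxonomy(muscles=frozenset({"a"}),
                           groups={"g": frozenset({"a", "b"})})

    def test_group_cannot_contain_itself(self):
        with pytest.raises(ValueError):
            MuscleTaxonomy(muscles=frozenset({"g", "a"}),
                           groups={"g": frozenset({"g", "a"})})

    def test_save_load_round_trip(self, tmp_path, taxonomy):
        for name in ("tax.json", "tax.yaml"):
            path = tmp_path / name
            taxonomy.save(path)
            assert MuscleTaxonomy.load(path) == taxonomy
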