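"""Recurrence, maternal-origin classification, paired deltas, summaries."""

import pandas as pd
import pytest

from mtrnahet import (
    FilterConfig,
    VariantCall,
    bin_by_level,
    classify_origin,
    classify_origins,
    paired_deltas,
    recurrent_variants,
    synonymy_summary,
    top_variants,
    variant_delta_averages,
)
from mtrnahet.cohort import CohortError, validate_metadata


def meta_two_mice():
    rows = []
    for mouse in ("mA", "mB"):
        for j in (1, 2):
            cx = f"{mouse}_occ{j}"
            rows.append([f"{cx}_ooc", mouse, "9wk", "oocyte", cx])
            rows.append([f"{cx}_cum", mouse, "9wk", "cumulus", cx])
    return pd.DataFrame(
        rows, columns=["sample_id", "mouse_id", "age_group", "cell_type", "complex_id"]
    )


def call(sample, pos, h, ref="A", alt="G", depth=10000):
    return VariantCall(sample, pos, ref, alt, max(1, round(h * depth)), depth)


class TestMetadata:
    def test_valid(self):
        validate_metadata(meta_two_mice())

    def test_duplicate_cell_type_in_complex_rejected(self):
        meta = meta_two_mice()
        meta.loc[0, "complex_id"] = "mA_occ2"
        with pytest.raises(CohortError):
            validate_metadata(meta)

    def test_mouse_in_two_age_groups_rejected(self):
        meta = meta_two_mice()
        meta.loc[0, "age_group"] = "3wk"
        with pytest.raises(CohortError):
            validate_metadata(meta)


class TestRecurrence:
    def test_oocyte_plus_cumulus_is_recurrent(self):
        calls = [call("mA_occ1_ooc", 100, 0.05), call("mA_occ1_cum", 100, 0.20)]
        rvs = recurrent_variants(calls, meta_two_mice())
        assert len(rvs) == 1
        rv = rvs[0]
        assert rv.mouse_id == "mA" and rv.n_samples_detected == 2
        assert rv.per_sample_h["mA_occ2_ooc"] == 0.0  # zero-filled non-detections
        assert len(rv.per_sample_h) == 4

    def test_single_sample_variant_dropped(self):
        rvs = recurrent_variants([call("mA_occ1_ooc", 100, 0.05)], meta_two_mice())
        assert rvs == []

    def test_sharing_across_mice_does_not_count(self):
        calls = [call("mA_occ1_ooc", 100, 0.05), call("mB_occ1_ooc", 100, 0.05)]
        assert recurrent_variants(calls, meta_two_mice()) == []

    def test_same_position_different_alts_are_distinct(self):
        calls = [call("mA_occ1_ooc", 100, 0.05, alt="G"),
                 call("mA_occ1_cum", 100, 0.05, alt="T")]
        assert recurrent_variants(calls, meta_two_mice()) == []

    def test_below_detection_threshold_not_counted(self):
        calls = [call("mA_occ1_ooc", 100, 0.05), call("mA_occ1_cum", 100, 0.02)]
        filters = FilterConfig(detection_threshold=0.03)
        rvs = recurrent_variants(calls, meta_two_mice(), filters)
        assert rvs == []

    def test_unknown_sample_rejected(self):
        with pytest.raises(CohortError, match="unknown"):
            recurrent_variants([call("ghost", 100, 0.05)], meta_two_mice())

    def test_duplicate_record_rejected(self):
        calls = [call("mA_occ1_ooc", 100, 0.05), call("mA_occ1_ooc", 100, 0.06)]
        with pytest.raises(CohortError, match="duplicate"):
            recurrent_variants(calls, meta_two_mice())

    def test_output_subset_of_input_with_two_supports(self):
        calls = [call("mA_occ1_ooc", 100, 0.05), call("mA_occ1_cum", 100, 0.2),
                 call("mA_occ2_cum", 250, 0.4), call("mB_occ1_ooc", 250, 0.4)]
        rvs = recurrent_variants(calls, meta_two_mice())
        in_keys = {(c.sample_id, c.position, c.alt) for c in calls}
        for rv in rvs:
            assert rv.n_samples_detected >= 2
            supporting = {(s, rv.position, rv.alt)
                          for s, h in rv.per_sample_h.items() if h > 0}
            assert supporting <= in_keys


class TestOriginClassification:
    def _rv(self, calls, meta, **kw):
        rvs = recurrent_variants(calls, meta)
        assert len(rvs) == 1
        return classify_origin(rvs[0], meta, **kw)

    def test_two_cumulus_no_oocyte_is_maternal_cumulus_only(self):
        calls = [call("mA_occ1_cum", 100, 0.1), call("mA_occ2_cum", 100, 0.15)]
        rv = self._rv(calls, meta_two_mice())
        assert rv.origin == "maternal" and rv.oocyte_detection == "cumulus_only"

    def test_oocyte_below_one_percent_still_cumulus_only(self):
        # oocyte h = 0.9% is below the 1% detection threshold, so never enters
        # the call set at default filters; classification sees cumulus only
        calls = [call("mA_occ1_cum", 100, 0.1), call("mA_occ2_cum", 100, 0.15)]
        rv = self._rv(calls, meta_two_mice())
        assert rv.oocyte_detection == "cumulus_only"

    def test_two_oocytes_only_is_unclassified_oocyte_detected(self):
        calls = [call("mA_occ1_ooc", 100, 0.1), call("mA_occ2_ooc", 100, 0.15)]
        rv = self._rv(calls, meta_two_mice())
        assert rv.origin == "unclassified" and rv.oocyte_detection == "oocyte_detected"

    def test_single_cumulus_maternal_under_relaxed_criterion(self):
        calls = [call("mA_occ1_ooc", 100, 0.1), call("mA_occ1_cum", 100, 0.15)]
        strict = self._rv(calls, meta_two_mice())
        relaxed = self._rv(calls, meta_two_mice(), maternal_min_cumulus=1)
        assert strict.origin == "unclassified" and relaxed.origin == "maternal"

    def test_no_cumulus_samples_warns_unclassified(self, caplog):
        meta = meta_two_mice()
        meta = meta[meta["cell_type"] == "oocyte"].reset_index(drop=True)
        calls = [call("mA_occ1_ooc", 100, 0.1), call("mA_occ2_ooc", 100, 0.15)]
        rvs = recurrent_variants(calls, meta)
        rv = classify_origin(rvs[0], meta)
        assert rv.origin == "unclassified"

    def test_classes_partition(self):
        calls = [call("mA_occ1_cum", 100, 0.1), call("mA_occ2_cum", 100, 0.15),
                 call("mA_occ1_ooc", 100, 0.05)]
        rvs = classify_origins(recurrent_variants(calls, meta_two_mice()),
                               meta_two_mice())
        for rv in rvs:
            assert rv.origin in ("maternal", "unclassified")
            detected_oocyte = any(
                h > 0 for s, h in rv.per_sample_h.items() if s.endswith("ooc"))
            assert (rv.oocyte_detection == "oocyte_detected") == detected_oocyte


class TestPairedDeltas:
    def test_sign_convention(self):
        calls = [call("mA_occ1_ooc", 100, 0.05), call("mA_occ1_cum", 100, 0.25)]
        d = paired_deltas(calls, meta_two_mice())
        d = [x for x in d if x.complex_id == "mA_occ1"]
        assert len(d) == 1
        assert d[0].delta == pytest.approx(-0.20)

    def test_cumulus_only_variant_records_zero_oocyte(self):
        calls = [call("mA_occ1_cum", 100, 0.10)]
        d = paired_deltas(calls, meta_two_mice())[0]
        assert d.h_oocyte == 0.0 and d.delta == pytest.approx(-0.10)

    def test_equal_levels_zero_delta(self):
        calls = [call("mA_occ1_ooc", 100, 0.1), call("mA_occ1_cum", 100, 0.1)]
        assert paired_deltas(calls, meta_two_mice())[0].delta == pytest.approx(0.0)

    def test_incomplete_complex_skipped(self, caplog):
        meta = meta_two_mice().drop(index=1).reset_index(drop=True)  # drop mA_occ1_cum
        calls = [call("mA_occ1_ooc", 100, 0.05)]
        assert paired_deltas(calls, meta) == []

    def test_average_a_and_b(self):
        # variant present in 1 of 4 complexes, delta -0.1
        calls = [call("mA_occ1_cum", 100, 0.10)]
        deltas = paired_deltas(calls, meta_two_mice())
        avg = variant_delta_averages(deltas, n_complexes=4)
        row = avg.iloc[0]
        assert row["avg_A"] == pytest.approx(-0.025)  # zeros included
        assert row["avg_B"] == pytest.approx(-0.10)  # zeros excluded


class TestBins:
    @pytest.mark.parametrize("values,expected", [
        ([0.02, 0.12, 0.60], (1, 1, 1)),
        ([0.05, 0.07], (2, 0, 0)),
        ([], (0, 0, 0)),
        ([0.10, 0.50], (0, 2, 0)),  # both boundaries belong to the middle bin
        ([0.01], (1, 0, 0)),
    ])
    def test_partition(self, values, expected):
        assert bin_by_level(values) == expected

    def test_below_min_af_rejected(self):
        with pytest.raises(CohortError):
            bin_by_level([0.005])

    def test_counts_sum_to_input_size(self):
        import numpy as np
        h = np.random.default_rng(2).uniform(0.01, 1.0, 200)
        assert sum(bin_by_level(h)) == 200


class TestSummaries:
    def test_single_nonsynonymous_variant_tabulated(self, ann):
        meta = meta_two_mice()
        pos = 12216  # inside mt-Nd5
        ref = ann.base(pos)
        alt = next(b for b in "ACGT"
                   if b != ref and ann.classify_substitution(pos, b) == "non_synonymous")
        calls = [call("mA_occ1_ooc", pos, 0.04, ref=ref, alt=alt),
                 call("mA_occ2_ooc", pos, 0.05, ref=ref, alt=alt)]
        rvs = recurrent_variants(calls, meta)
        syn, region = synonymy_summary(rvs, ann, meta)
        row = syn[(syn.cell_type == "oocyte") & (syn.bin == "(1%,10%)")
                  & (syn.synonymy == "non_synonymous")]
        assert row["count"].iloc[0] == 1
        assert syn[syn.cell_type == "cumulus"]["count"].sum() == 0
        assert region.set_index("region_class")["count"]["protein_coding"] == 1

    def test_noncoding_variant_in_region_summary_only(self, ann):
        meta = meta_two_mice()
        ref = ann.base(233)
        alt = next(b for b in "ACGT" if b != ref)
        calls = [call("mA_occ1_ooc", 233, 0.04, ref=ref, alt=alt),
                 call("mA_occ1_cum", 233, 0.05, ref=ref, alt=alt)]
        rvs = recurrent_variants(calls, meta)
        syn, region = synonymy_summary(rvs, ann, meta)
        assert syn["count"].sum() == 0
        assert region.set_index("region_class")["count"]["rRNA"] == 1

    def test_empty_input_all_zero(self, ann):
        syn, region = synonymy_summary([], ann, meta_two_mice())
        assert syn["count"].sum() == 0 and region.empty


class TestTopVariants:
    def _rvs(self):
        meta = meta_two_mice()
        calls = [
            call("mA_occ1_ooc", 100, 0.30), call("mA_occ1_cum", 100, 0.30),
            call("mA_occ1_ooc", 200, 0.20), call("mA_occ1_cum", 200, 0.20),
            call("mA_occ1_ooc", 300, 0.10), call("mA_occ1_cum", 300, 0.10),
        ]
        return recurrent_variants(calls, meta), meta

    def test_rank_by_mean_h(self):
        rvs, _ = self._rvs()
        top = top_variants(rvs, 2, "mean_h")
        assert list(top["pos"]) == [100, 200]

    def test_tie_breaks_by_position(self):
        rvs, _ = self._rvs()
        top = top_variants(rvs, 3, "mean_h")
        assert list(top["pos"]) == [100, 200, 300]

    def test_k_larger_than_available_returns_all(self):
        rvs, _ = self._rvs()
        assert len(top_variants(rvs, 50, "mean_h")) == 3

    def test_mean_abs_delta_requires_meta(self):
        rvs, meta = self._rvs()
        with pytest.raises(CohortError):
            top_variants(rvs, 2, "mean_abs_delta")
        top = top_variants(rvs, 3, "mean_abs_delta", meta)
        assert set(top["pos"]) == {100, 200, 300}
        assert (top["score"] == 0).all()  # oocyte and cumulus levels equal
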