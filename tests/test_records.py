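"""Record parsing, derivation, merging, filtering and transforms."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from eggshape import (
    DerivedMeasurement,
    FinalEggRecord,
    IncompleteRecordError,
    MeasurementParseError,
    TextEggRecord,
    derive_text,
    exclusion_filters,
    exclusion_thresholds,
    merge,
    parse_measurement,
    process_raw,
    representative_value,
    synthetic_raw_records,
    transform,
    write_final_tsv,
)


class TestParseMeasurement:
    @pytest.mark.parametrize(
        "raw, kind, primary, secondary, decimals",
        [
            ("0.6 ± 0.05", "avg_dev", 0.6, 0.05, 1),
            ("0.6 +/- 0.05 mm", "avg_dev", 0.6, 0.05, 1),
            ("0.5–0.7 mm", "range", 0.5, 0.7, 1),
            ("0.5-0.7", "range", 0.5, 0.7, 1),
            ("0.7 to 0.95 mm", "range", 0.7, 0.95, 1),
            ("1 mm", "single", 1.0, None, 0),
            ("1.00 mm", "single", 1.0, None, 2),
            ("0.125", "single", 0.125, None, 3),
        ],
    )
    def test_grammar(self, raw, kind, primary, secondary, decimals):
        d = parse_measurement(raw)
        assert d.kind == kind
        assert d.primary_value == pytest.approx(primary)
        if secondary is None:
            assert d.secondary_value is None
        else:
            assert d.secondary_value == pytest.approx(secondary)
        assert d.decimal_places == decimals

    def test_avg_dev_takes_precedence_over_range(self):
        d = parse_measurement("0.5-0.7, mean 0.6 ± 0.05")
        assert d.kind == "avg_dev"

    def test_reversed_range_normalised(self):
        d = parse_measurement("0.7–0.5")
        assert (d.primary_value, d.secondary_value) == (0.5, 0.7)

    @pytest.mark.parametrize("raw", ["", "egg large", "0.6 cm", "600 µm"])
    def test_rejects_unparseable_or_foreign_units(self, raw):
        with pytest.raises(MeasurementParseError):
            parse_measurement(raw)

    @given(st.floats(0.01, 99.0), st.integers(0, 4))
    def test_roundtrip_formatted_single_values(self, value, decimals):
        text = f"{value:.{decimals}f} mm"
        if float(text.split()[0]) <= 0:
            return
        d = parse_measurement(text)
        assert d.kind == "single"
        assert d.primary_value == float(text.split()[0])
        assert d.decimal_places == decimals


class TestRepresentativeValue:
    def test_all_kinds(self):
        assert representative_value(parse_measurement("0.6 ± 0.05")) == 0.6
        assert representative_value(parse_measurement("0.5–0.7")) == pytest.approx(0.6)
        assert representative_value(parse_measurement("1 mm")) == 1.0


class TestDeriveText:
    def test_width_breadth_ordering(self):
        rec = TextEggRecord(genus="Gryllus", width=parse_measurement("0.3"),
                            breadth=parse_measurement("0.5"))
        d = derive_text(rec)
        assert d.width_mm == 0.5 and d.breadth_mm == 0.3

    def test_volume_and_aspect_from_length_width(self):
        rec = TextEggRecord(genus="Gryllus", length=parse_measurement("1"),
                            width=parse_measurement("0.5"))
        d = derive_text(rec)
        assert d.volume_mm3 == pytest.approx(math.pi / 6 * 1 * 0.25, rel=1e-9)
        assert d.aspect_ratio == pytest.approx(2.0)
        assert d.volume_provenance == "text"

    def test_reported_volume_used_only_without_dimensions(self):
        rec = TextEggRecord(genus="Gryllus", volume_reported=0.2)
        d = derive_text(rec)
        assert d.volume_mm3 == 0.2
        assert d.volume_provenance == "reported"
        assert d.aspect_ratio is None

    def test_record_without_any_measurement_rejected(self):
        with pytest.raises(IncompleteRecordError):
            TextEggRecord(genus="Gryllus")

    def test_genus_required(self):
        with pytest.raises(IncompleteRecordError):
            TextEggRecord(genus="", length=parse_measurement("1"))


class TestMerge:
    def test_text_precedence(self):
        text = derive_text(TextEggRecord(genus="G", length=parse_measurement("1.0"),
                                         width=parse_measurement("0.5")))
        image = DerivedMeasurement(aspect_ratio=2.2, asymmetry=0.1,
                                   length_mm=1.1, width_mm=0.5, volume_mm3=0.17)
        rec = merge(text, image)
        assert rec.length_mm == 1.0
        assert rec.provenance["length"] == "text"
        assert rec.aspect_ratio == pytest.approx(2.0)

    def test_image_only_record(self):
        image = DerivedMeasurement(aspect_ratio=2.2, asymmetry=0.1, length_mm=1.1,
                                   width_mm=0.5, volume_mm3=0.17)
        rec = merge(None, image)
        assert rec.length_mm == 1.1 and rec.provenance["length"] == "image"

    def test_asymmetry_and_curvature_only_from_images(self):
        text = derive_text(TextEggRecord(genus="G", length=parse_measurement("1.0"),
                                         width=parse_measurement("0.5")))
        rec = merge(text, None)
        assert rec.asymmetry is None and rec.curvature_rad is None

    def test_both_missing_rejected(self):
        with pytest.raises(IncompleteRecordError):
            merge(None, None)


def _records_with_ars(values):
    return [FinalEggRecord(aspect_ratio=v, image_aspect_ratio=v) for v in values]


class TestExclusionFilters:
    def test_removes_top_tenth_of_a_percent(self):
        ars = 1.0 + np.arange(1, 10001) / 10000.0
        kept = exclusion_filters(_records_with_ars(ars))
        assert len(kept) == 9990

    def test_identical_values_all_kept(self):
        kept = exclusion_filters(_records_with_ars([2.0] * 100))
        assert len(kept) == 100

    def test_curvature_nulled_for_oblate(self):
        rec = FinalEggRecord(aspect_ratio=0.8, image_aspect_ratio=0.8,
                             curvature_rad=0.3)
        (out,) = exclusion_filters([rec])
        assert out.curvature_rad is None

    def test_idempotent_with_frozen_thresholds(self):
        ars = 1.0 + np.arange(1, 10001) / 10000.0
        records = _records_with_ars(ars)
        thr = exclusion_thresholds(records)
        once = exclusion_filters(records, thresholds=thr)
        twice = exclusion_filters(once, thresholds=thr)
        assert once == twice

    def test_empty_input(self):
        assert exclusion_filters([]) == []


class TestTransform:
    def test_values(self):
        rec = FinalEggRecord(length_mm=10.0, volume_mm3=1.0, aspect_ratio=10.0,
                             asymmetry=0.0, curvature_rad=0.25)
        out = transform(rec)
        assert out.log10_volume == 0.0
        assert out.log10_aspect_ratio == pytest.approx(1.0)
        assert out.log10_length == pytest.approx(1.0)
        assert out.sqrt_asymmetry == 0.0
        assert out.sqrt_curvature == 0.5

    def test_nonpositive_log_domain_rejected(self):
        with pytest.raises(ValueError):
            transform(FinalEggRecord(length_mm=0.0, aspect_ratio=1.0))

    @given(st.floats(1e-6, 1e6))
    def test_log_roundtrip(self, v):
        out = transform(FinalEggRecord(volume_mm3=v))
        assert 10 ** out.log10_volume == pytest.approx(v, rel=1e-12)


class TestPipeline:
    def test_synthetic_pipeline_runs_and_is_byte_stable(self):
        df = synthetic_raw_records(n=500, seed=3)
        out1, out2 = io.StringIO(), io.StringIO()
        write_final_tsv(process_raw(df, apply_filters=True), out1)
        write_final_tsv(process_raw(df.copy(), apply_filters=True), out2)
        assert out1.getvalue() == out2.getvalue()
        assert len(out1.getvalue().splitlines()) > 400

    def test_text_precedence_in_pipeline(self):
        df = synthetic_raw_records(n=300, seed=1)
        final = process_raw(df, apply_filters=False)
        both = final["text_length"].notna() & final["image_length"].notna()
        assert both.any()
        sub = final[both]
        assert (sub["length"] == sub["text_length"]).all()
        assert (sub["provenance_length"] == "text").all()

    def test_transform_columns_consistent(self):
        final = process_raw(synthetic_raw_records(n=200, seed=2), apply_filters=False)
        has_vol = final["volume"].notna()
        assert np.allclose(10 ** final.loc[has_vol, "log10_volume"],
                           final.loc[has_vol, "volume"], rtol=1e-9)
        has_asym = final["asymmetry"].notna()
        assert np.allclose(final.loc[has_asym, "sqrt_asymmetry"] ** 2,
                           final.loc[has_asym, "asymmetry"], rtol=1e-9)
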