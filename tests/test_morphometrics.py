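import pytest
from hypothesis import given
from hypothesis import strategies as st

from paleosnake.errors import ValidationError
from paleosnake.morphometrics import (
    RATIO_DEFS,
    PositionClass,
    VertebraSpecimen,
    classify_trunk_position,
    compute_ratio_suite,
    read_measurements_csv,
    select_size_estimation_specimens,
    write_measurements_csv,
)


class TestRatioSuite:
    def test_exact_division(self):
        s = VertebraSpecimen("s1", lengths_mm={"coW": 12.0, "coH": 10.0})
        report = compute_ratio_suite(s, decimals=1)
        assert report.ratios["coW/coH"] == 1.2

    def test_cotyle_wider_than_high_at_observed_extreme(self, vasuki_like_specimen):
        # the large mid-trunk morphotype has coW/coH = 1.2 and prW/cL well above 1
        report = compute_ratio_suite(vasuki_like_specimen, decimals=1)
        assert report.ratios["coW/coH"] == 1.2
        assert report.ratios["prW/cL"] == 1.8

    def test_single_length_all_missing(self):
        s = VertebraSpecimen("s2", lengths_mm={"cL": 40.0})
        report = compute_ratio_suite(s)
        assert report.ratios == {}
        assert sorted(report.missing) == sorted(RATIO_DEFS)

    def test_ratio_and_missing_names_partition_vocabulary(self, vasuki_like_specimen):
        report = compute_ratio_suite(vasuki_like_specimen)
        names = set(report.ratios) | set(report.missing)
        assert names == set(RATIO_DEFS)
        assert not set(report.ratios) & set(report.missing)

    def test_half_up_rounding(self):
        s = VertebraSpecimen("s3", lengths_mm={"coW": 12.5, "coH": 10.0})
        assert compute_ratio_suite(s, decimals=1).ratios["coW/coH"] == 1.3
        # 1.25 rounds up, not to even
        s2 = VertebraSpecimen("s4", lengths_mm={"coW": 1.25, "coH": 1.0})
        assert compute_ratio_suite(s2, decimals=1).ratios["coW/coH"] == 1.3

    def test_nonpositive_length_rejected_naming_field(self):
        with pytest.raises(ValidationError, match="coH"):
            VertebraSpecimen("bad", lengths_mm={"coW": 12.0, "coH": -1.0})

    def test_no_lengths_rejected(self):
        with pytest.raises(ValidationError):
            compute_ratio_suite(VertebraSpecimen("empty"))

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, scale):
        base = {"coW": 12.0, "coH": 10.0, "prW": 90.0, "cL": 50.0, "nsH": 15.0,
                "tvH": 70.0}
        s1 = VertebraSpecimen("a", lengths_mm=base)
        s2 = VertebraSpecimen(
            "b", lengths_mm={k: v * scale for k, v in base.items()}
        )
        r1 = compute_ratio_suite(s1, decimals=3)
        r2 = compute_ratio_suite(s2, decimals=3)
        for name in r1.ratios:
            assert r1.ratios[name] == pytest.approx(r2.ratios[name], abs=2e-3)


class TestTrunkClassification:
    def test_wide_vertebra_is_mid_trunk(self):
        s = VertebraSpecimen("w", lengths_mm={"prW": 111.4, "cL": 62.7})
        assert classify_trunk_position(s) is PositionClass.MTV

    def test_hypapophysis_wins_over_ratio(self):
        s = VertebraSpecimen(
            "a",
            lengths_mm={"prW": 111.4, "cL": 62.7},
            flags={"hypapophysis_present": True},
        )
        assert classify_trunk_position(s) is PositionClass.ATV

    def test_ratio_exactly_one_is_posterior_trunk(self):
        s = VertebraSpecimen("b", lengths_mm={"prW": 50.0, "cL": 50.0})
        assert classify_trunk_position(s) is PositionClass.POSTERIOR_TRUNK

    def test_no_information_is_unknown(self):
        assert (
            classify_trunk_position(VertebraSpecimen("c", lengths_mm={"coW": 5.0}))
            is PositionClass.UNKNOWN
        )

    def test_idempotent_and_specimen_local(self, vasuki_like_specimen):
        first = classify_trunk_position(vasuki_like_specimen)
        second = classify_trunk_position(vasuki_like_specimen)
        assert first is second is PositionClass.MTV

    def test_width_field_switchable(self):
        s = VertebraSpecimen("d", lengths_mm={"poW": 80.0, "cL": 50.0})
        assert classify_trunk_position(s, "poW") is PositionClass.MTV
        assert classify_trunk_position(s, "prW") is PositionClass.UNKNOWN


class TestSelection:
    def _mtv(self, sid, prw):
        return VertebraSpecimen(
            sid, lengths_mm={"prW": prw, "cL": 50.0},
            flags={"chisel_process_present": True},
        )

    def _atv(self, sid, prw):
        return VertebraSpecimen(
            sid, lengths_mm={"prW": prw, "cL": 50.0},
            flags={"hypapophysis_present": True},
        )

    def test_filters_and_sorts_descending(self):
        col = [self._mtv("m1", 90.0), self._atv("a1", 70.0), self._mtv("m2", 111.4)]
        sel = select_size_estimation_specimens(col)
        assert [s.specimen_id for s in sel] == ["m2", "m1"]

    def test_all_atv_yields_empty(self):
        assert select_size_estimation_specimens([self._atv("a1", 70.0)]) == []

    def test_tie_break_lexicographic(self):
        col = [self._mtv("zz", 90.0), self._mtv("aa", 90.0)]
        assert [s.specimen_id for s in select_size_estimation_specimens(col)] == [
            "aa", "zz",
        ]

    def test_idempotent_sublist(self):
        col = [self._mtv("m1", 90.0), self._mtv("m2", 100.0), self._atv("a", 60.0)]
        sel = select_size_estimation_specimens(col)
        assert all(s in col for s in sel)
        assert select_size_estimation_specimens(sel) == sel

    def test_empty_collection_rejected(self):
        with pytest.raises(ValidationError):
            select_size_estimation_specimens([])


class TestCsvRoundTrip:
    def test_round_trip_preserves_missingness(self, tmp_path):
        specimens = [
            VertebraSpecimen(
                "v1", series_index=1,
                lengths_mm={"cL": 40.0, "prW": 70.0},
                angles_deg={"alpha_syn": 56.6},
                flags={"hypapophysis_present": True},
            ),
            VertebraSpecimen("v2", lengths_mm={"coW": 12.0}),
        ]
        path = tmp_path / "meas.csv"
        write_measurements_csv(specimens, path, header_comment="fixture")
        back = read_measurements_csv(path)
        assert [s.specimen_id for s in back] == ["v1", "v2"]
        assert back[0].lengths_mm == specimens[0].lengths_mm
        assert back[0].angles_deg == specimens[0].angles_deg
        assert back[0].flags.get("hypapophysis_present") is True
        assert "cL" not in back[1].lengths_mm  # missing stays missing, never zero
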