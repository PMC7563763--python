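"""Reserve table loading, missingness semantics and transformations."""

import io

import numpy as np
import pytest

from reservesar import (
    GROUPS,
    PREDICTORS,
    TransformRules,
    load_italian_reserves,
    load_richness_table,
    subset_group,
    write_table,
)

HEADER = (
    "id,name,latitude,longitude,area_km2,elev_min_m,elev_max_m,"
    "elev_range_m,elev_mean_m,richness.g1"
)


def _csv(*rows):
    return io.StringIO("\n".join([HEADER, *rows]))


class TestLoading:
    def test_fixture_shape_and_group_counts(self, reserves):
        assert len(reserves) == 23
        assert reserves.groups == GROUPS
        expected = {
            "Carabidae": 18,
            "Hydradephaga": 15,
            "coprophagous_Scarabaeoidea": 18,
            "phytophagous_Scarabaeoidea": 18,
            "total_Scarabaeoidea": 18,
            "Tenebrionidae": 18,
        }
        assert {g: reserves.group_count(g) for g in GROUPS} == expected

    def test_missing_is_distinct_from_zero(self, reserves):
        by_id = {r.reserve_id: r for r in reserves.records}
        assert by_id[5].richness["coprophagous_Scarabaeoidea"] == 0
        assert by_id[1].richness["Hydradephaga"] is None

    def test_elev_range_mismatch_warns_not_fails(self):
        # stated range 150 vs max - min = 100
        with pytest.warns(UserWarning, match="elev_range"):
            table = load_richness_table(
                _csv("1,a,42.0,12.0,10,100,200,150,150,5")
            )
        assert len(table) == 1

    def test_fixture_itself_carries_a_range_inconsistency(self):
        # one montane reserve reports sampling-point range 1820 over a
        # 400-2200 m span; kept as printed, surfaced as a warning
        with pytest.warns(UserWarning, match="reserve 1"):
            load_italian_reserves()

    @pytest.mark.parametrize(
        "rows, message",
        [
            ((), "no records"),
            (("1,a,42,12,10,0,5,5,2,3", "1,b,41,12,9,0,5,5,2,4"), "duplicate"),
            (("1,a,42,12,-3,0,5,5,2,3",), "area"),
            (("1,a,42,12,10,0,5,5,2,-4",), "negative richness"),
            (("1,a,42,12,10,0,5,5,2,2.5",), "integer"),
        ],
    )
    def test_invalid_inputs_are_hard_errors(self, rows, message):
        with pytest.raises(ValueError, match=message):
            load_richness_table(_csv(*rows))

    def test_roundtrip_through_csv_is_lossless(self, reserves):
        buf = io.StringIO()
        write_table(reserves, buf)
        buf.seek(0)
        again = load_richness_table(buf)
        assert again == reserves

    def test_write_rejects_empty(self):
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            write_table(pd.DataFrame(), io.StringIO())

    def test_alternate_elevations_touch_only_reserve_8(
        self, reserves, reserves_hydradephaga_elev
    ):
        for a, b in zip(reserves.records, reserves_hydradephaga_elev.records):
            if a.reserve_id == 8:
                assert (b.elev_min_m, b.elev_max_m) == (350, 1450)
                assert b.elev_range_m == 1106
            else:
                assert a == b


class TestSubsetGroup:
    def test_plus_one_group_keeps_zero_count_reserves(self, reserves):
        ds = subset_group(reserves, "coprophagous_Scarabaeoidea")
        assert ds.n == 18
        assert ds.plus_one_response
        idx = ds.reserve_ids.index(5)
        assert ds.response[idx] == 0.0  # log10(0 + 1)

    def test_tenebrionidae_complete_cases(self, reserves):
        ds = subset_group(reserves, "Tenebrionidae")
        assert ds.n == 18
        assert not ds.plus_one_response

    def test_coastal_zero_min_elevation_transforms_to_zero(self, reserves):
        ds = subset_group(reserves, "Carabidae")
        idx = ds.reserve_ids.index(9)
        assert ds.predictors["log_elev_min"][idx] == 0.0  # log10(0 + 1)

    def test_exclusions_shrink_the_dataset(self, reserves):
        assert subset_group(reserves, "Hydradephaga").n == 15
        assert subset_group(reserves, "Hydradephaga", exclude_ids=(9,)).n == 14

    def test_all_predictors_present_and_aligned(self, reserves):
        ds = subset_group(reserves, "Carabidae")
        assert set(ds.predictors) == set(PREDICTORS)
        for col in ds.predictors.values():
            assert len(col) == ds.n
        np.testing.assert_allclose(
            ds.predictors["log_area"], np.log10(ds.raw["area_km2"])
        )

    def test_zero_counts_without_plus_one_rule_refused(self, reserves):
        bare = TransformRules(
            plus_one_responses=frozenset(),
            plus_one_predictors=frozenset({"log_elev_min"}),
        )
        with pytest.raises(ValueError, match="plus-one"):
            subset_group(reserves, "coprophagous_Scarabaeoidea", bare)

    def test_too_few_complete_cases(self):
        table = load_richness_table(
            _csv(
                "1,a,42,12,10,0,5,5,2,3",
                "2,b,41,12,9,0,5,5,2,4",
            )
        )
        with pytest.raises(ValueError, match="complete cases"):
            subset_group(table, "g1")

    def test_unknown_group_is_an_error(self, reserves):
        with pytest.raises(KeyError):
            subset_group(reserves, "Curculionidae")
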