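"""Schema validation, CSV round-trips, composites, and design assembly."""

import numpy as np
import pandas as pd
import pytest

from latentconn import data_model as dm
from latentconn.data_model import (ModelSpec, ResponseTable, SchemaError,
                                   ValidationError, build_design, covid_impact,
                                   cronbach_alpha, preset_names, preset_spec,
                                   read_responses, subscale_scores,
                                   write_responses)


class TestReadWrite:
    def test_round_trip_preserves_values_and_missingness(self, tiny_df, tmp_path):
        table = ResponseTable(tiny_df)
        path = tmp_path / "resp.csv"
        write_responses(table, path)
        back = read_responses(path)
        assert len(back) == 3
        assert back.df["conn_artist"].tolist() == [3, 3, 3]
        assert back.df["ios_audience"].isna().all()
        pd.testing.assert_frame_equal(
            back.df.astype(object), table.df.astype(object), check_dtype=False)

    def test_out_of_range_ordinal_rejected_naming_row_and_column(self, tiny_df, tmp_path):
        tiny_df.loc[1, "conn_artist"] = 9
        tiny_df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValidationError, match="conn_artist.*row 1"):
            read_responses(tmp_path / "bad.csv")

    def test_missing_required_header_is_schema_error(self, tiny_df, tmp_path):
        tiny_df.drop(columns="age_years").to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(SchemaError, match="age_years"):
            read_responses(tmp_path / "bad.csv")

    def test_duplicate_participant_concert_pair_rejected(self, tiny_df):
        tiny_df.loc[1, "participant_id"] = "P0"
        with pytest.raises(ValidationError, match="duplicate"):
            ResponseTable(tiny_df)

    def test_illegal_condition_label_rejected(self, tiny_df):
        tiny_df.loc[0, "condition"] = "vr"  # legal only in concert 2
        with pytest.raises(ValidationError, match="concert 1"):
            ResponseTable(tiny_df)


class TestCovidImpact:
    @pytest.mark.parametrize("items,expected", [
        ((1, 1, 1, 1, 1, 1), 1.0),
        ((1, 2, 3, 4, 5, 3), 3.0),
        ((2, 4, 4, 2, 3, 5), 10 / 3),
    ])
    def test_mean_of_six_items(self, items, expected):
        assert covid_impact(items) == pytest.approx(expected)

    def test_item_order_invariant_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            items = rng.integers(1, 6, size=6)
            assert covid_impact(items) == covid_impact(items[::-1])
            assert 1.0 <= covid_impact(items) <= 5.0

    def test_missing_item_policies(self):
        items = (1, 2, np.nan, 4, 5, 3)
        assert np.isnan(covid_impact(items))
        assert covid_impact(items, policy="available") == pytest.approx(3.0)


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        x = np.tile(np.array([[1.0], [2], [3], [4]]), (1, 4))
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_shift_invariance(self):
        assert cronbach_alpha([[1, 2], [2, 3], [3, 4], [4, 5]]) == pytest.approx(1.0)
        rng = np.random.default_rng(1)
        x = rng.integers(1, 6, size=(20, 6)).astype(float)
        shifted = x.copy()
        shifted[:, 2] += 7
        assert cronbach_alpha(shifted) == pytest.approx(cronbach_alpha(x))

    def test_zero_total_variance_signalled(self):
        with pytest.raises(ZeroDivisionError):
            cronbach_alpha([[1, 2], [2, 1], [1, 2], [2, 1]])

    def test_matches_definition_on_random_matrix(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(30, 5))
        k = 5
        want = k / (k - 1) * (1 - np.var(x, axis=0, ddof=1).sum()
                              / np.var(x.sum(axis=1), ddof=1))
        assert cronbach_alpha(x) == pytest.approx(want)


class TestSubscales:
    MAP = {"a": "social", "b": "social", "c": "physical", "d": "physical"}

    def test_constant_items_give_constant_subscales(self):
        scores = subscale_scores({k: 3 for k in "abcd"}, self.MAP)
        assert scores == {"physical": 3.0, "social": 3.0, "overall": 3.0}

    def test_two_item_subscale_mean(self):
        scores = subscale_scores({"a": 2, "b": 4, "c": 1, "d": 1}, self.MAP)
        assert scores["social"] == pytest.approx(3.0)

    def test_mapping_swap_only_changes_affected_subscales(self):
        items = {"a": 1, "b": 2, "c": 4, "d": 5}
        base = subscale_scores(items, self.MAP)
        swapped = subscale_scores(items, {**self.MAP, "b": "physical"})
        assert swapped["overall"] == base["overall"]
        assert swapped["social"] != base["social"]
        assert swapped["physical"] != base["physical"]

    def test_unmapped_item_is_config_error(self):
        with pytest.raises(KeyError, match="unmapped"):
            subscale_scores({"a": 1, "zz": 2}, self.MAP)


class TestModelSpec:
    def test_complex_predictors_superset_of_simple(self):
        for scope, model in [(1, "model2"), (2, "model1"), (3, "model1"),
                             ("overall", "model5")]:
            scope_s = "overall" if scope == "overall" else f"concert{scope}"
            simple = preset_spec(f"{scope_s}-simple-{model}")
            cmplx = preset_spec(f"{scope_s}-complex-{model}")
            for o in ("artist", "audience"):
                assert set(simple.predictors(o)) <= set(cmplx.predictors(o))

    def test_construct_specific_predictors_stay_on_their_construct(self):
        spec = preset_spec("concert1-complex-model5")
        assert "fan_status" in spec.predictors("artist")
        assert "fan_status" not in spec.predictors("audience")
        assert "with_others" in spec.predictors("audience")
        assert "with_others" not in spec.predictors("artist")
        assert "know_audience" not in spec.predictors("artist")

    def test_unknown_preset_names_valid_ones(self):
        with pytest.raises(KeyError, match="concert1-simple-model1"):
            preset_spec("concert9-simple-model1")

    def test_all_presets_resolve(self):
        for name in preset_names():
            spec = preset_spec(name)
            assert spec.name == name

    def test_concert3_drops_connectivity_and_fan_status(self):
        spec = preset_spec("concert3-complex-model2")
        assert "connectivity_problem" not in spec.predictors("artist")
        assert "fan_status" not in spec.predictors("artist")


class TestBuildDesign:
    def test_scaling_and_gender_coding(self, study_table):
        spec = preset_spec("concert1-simple-model1")
        design = build_design(study_table, spec)
        X = design.frames["artist"]
        df = study_table.subset(1).df
        complete = df.loc[~X.index.isin([])].reset_index(drop=True)
        row0_age = complete.loc[0, "age_years"]
        assert X.loc[0, "age_10"] == pytest.approx(row0_age / 10.0)
        not_woman = complete["gender"] != "woman"
        assert (X.loc[not_woman[:len(X)].values, "woman"] == 0).all()

    def test_deterministic_and_column_order_stable(self, study_table):
        spec = preset_spec("concert2-complex-model3")
        d1 = build_design(study_table, spec)
        d2 = build_design(study_table, spec)
        for o in ("artist", "audience"):
            pd.testing.assert_frame_equal(d1.frames[o], d2.frames[o])
            assert list(d1.frames[o].columns) == spec.predictors(o) \
                or set(d1.frames[o].columns) < set(spec.predictors(o))

    def test_constant_predictor_dropped_with_warning(self, study_table):
        df = study_table.subset(3).df.copy()
        df["fan_status"] = 1
        df.loc[df.index[0], "fan_status"] = 2  # exactly one fan
        df.loc[df.index[0], "fan_status"] = 1  # now constant
        spec = ModelSpec(concert_scope=3, predictor_set="complex",
                         main_predictors=["zoom"])
        with pytest.warns(UserWarning, match="fan_status"):
            design = build_design(ResponseTable(df), spec)
        assert "fan_status" not in design.frames["artist"].columns
        assert ("fan_status", "artist", "constant") in design.dropped_columns

    def test_missing_covariate_rows_dropped_and_counted(self, study_table):
        df = study_table.subset(1).df.copy()
        df.loc[df.index[2], "empathic_concern"] = np.nan
        design = build_design(ResponseTable(df),
                              preset_spec("concert1-simple-model1"))
        assert design.n_dropped_rows == 1
        assert len(design.frames["artist"]) == len(df) - 1

    def test_outcomes_keep_missing_as_na(self, study_table):
        design = build_design(study_table, preset_spec("concert1-simple-model1"))
        ios = pd.concat([design.outcomes[("artist", "ios7")],
                         design.outcomes[("audience", "ios7")]])
        assert ios.isna().sum() == 2
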