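import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from ftirbone import features as ft


def make_pixel_table(values: dict[str, list[float]]) -> pd.DataFrame:
    n = len(next(iter(values.values())))
    df = pd.DataFrame(values)
    df["line_index"] = 0
    df["point_index"] = range(n)
    df["x_um"] = 0.0
    df["y_um"] = 0.0
    df["valid"] = True
    return df


class TestComputeCategoryThresholds:
    def test_four_value_fixture_matches_hand_computation(self):
        # lower half {1,2}: mean 1.5, sd 0.7071; upper half {3,4}: mean 3.5
        low, high = ft.compute_category_thresholds([1, 2, 3, 4])
        assert low == pytest.approx(1.5 - np.sqrt(0.5), abs=1e-6)
        assert high == pytest.approx(3.5 + np.sqrt(0.5), abs=1e-6)

    def test_oracle_on_enumerated_fixtures(self):
        def oracle(v):
            v = np.sort(np.asarray(v, float))
            med = np.median(v)
            lower, upper = v[v <= med], v[v > med]
            if upper.size == 0:
                upper = lower
            sd = lambda x: np.std(x, ddof=1) if x.size > 1 else 0.0
            return lower.mean() - sd(lower), upper.mean() + sd(upper)

        fixtures = [
            [1, 2, 3, 4, 5],           # odd length, median in lower half
            [2, 2, 2, 9],              # median ties go to the lower half
            [0.5, 1.5, 1.5, 8, 9, 10],
            list(range(20)),
        ]
        for v in fixtures:
            assert ft.compute_category_thresholds(v) == pytest.approx(oracle(v), abs=1e-9)

    def test_constant_vector_collapses_to_the_constant(self):
        low, high = ft.compute_category_thresholds([3.3] * 8)
        assert low == high == pytest.approx(3.3)

    def test_fewer_than_four_values_raises(self):
        with pytest.raises(ValueError, match="4"):
            ft.compute_category_thresholds([1.0, 2.0, 3.0])

    @given(
        st.lists(st.floats(0.1, 100.0), min_size=4, max_size=40),
        st.floats(0.001, 0.9),
    )
    @settings(max_examples=60, deadline=None)
    def test_adding_values_below_low_never_raises_it(self, values, frac):
        # Holds whenever the new extreme value does not eject members from
        # the lower half; an ejected high member can shrink the lower-half SD
        # enough to raise the threshold, so the median split must be stable.
        low, _ = ft.compute_category_thresholds(values)
        extra = low - abs(low) * frac - 1.0
        v = np.asarray(values, float)
        old_lower = set(np.flatnonzero(v <= np.median(v)))
        new_lower = set(np.flatnonzero(v <= np.median(np.append(v, extra))))
        assume(old_lower == new_lower)
        new_low, _ = ft.compute_category_thresholds(values + [extra])
        assert new_low <= low + 1e-9


class TestCategorize:
    published = ft.CategoryThresholds.published_defaults()

    def test_published_defaults_load(self):
        assert self.published.mmr == (3.580, 5.230)
        assert self.published.cpr == (0.008, 0.010)
        assert self.published.crystallinity == (1.072, 1.164)
        assert self.published.xlr == (3.065, 3.769)

    @pytest.mark.parametrize(
        "value,expected",
        [(3.580, "medium"), (3.579, "low"), (5.230, "medium"), (5.231, "high")],
    )
    def test_boundaries_are_medium(self, value, expected):
        assert ft.categorize(value, self.published.mmr) == expected

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            ft.categorize(np.nan, self.published.mmr)


class TestCategoryAreaStats:
    def test_matches_brute_force_on_ten_pixel_fixture(self):
        # mmr values: 3 low / 5 medium / 2 high under the published thresholds
        mmr = [3.0, 3.1, 3.5, 4.0, 4.2, 4.5, 4.8, 5.0, 5.5, 6.0]
        tbl = make_pixel_table(
            {"mmr": mmr, "cpr": [0.009] * 10, "crystallinity": [1.1] * 10, "xlr": [3.4] * 10}
        )
        thr = ft.CategoryThresholds.published_defaults()
        stats = ft.category_area_stats(tbl, thr)
        groups = {"low": [v for v in mmr if v < 3.580],
                  "medium": [v for v in mmr if 3.580 <= v <= 5.230],
                  "high": [v for v in mmr if v > 5.230]}
        assert [len(groups[c]) for c in ("low", "medium", "high")] == [3, 5, 2]
        for cat, vals in groups.items():
            row = stats.loc[("mmr", cat)]
            frac = len(vals) / 10
            assert row["area_um2"] == pytest.approx(len(vals) * 36.0)
            assert row["area_fraction"] == pytest.approx(frac, abs=1e-9)
            assert row["norm_mean"] == pytest.approx(np.mean(vals) * frac, abs=1e-9)
            assert row["norm_sd"] == pytest.approx(np.std(vals, ddof=1) * frac, abs=1e-9)

    def test_fractions_sum_to_one_and_areas_conserve(self):
        rng = np.random.default_rng(0)
        tbl = make_pixel_table(
            {
                "mmr": rng.normal(4.4, 1.0, 50),
                "cpr": rng.normal(0.009, 0.002, 50),
                "crystallinity": rng.normal(1.12, 0.05, 50),
                "xlr": rng.normal(3.4, 0.4, 50),
            }
        )
        stats = ft.category_area_stats(tbl, ft.CategoryThresholds.published_defaults())
        for p in ft.FTIR_PARAMS:
            sub = stats.loc[p]
            assert sub["area_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
            assert sub["area_um2"].sum() == pytest.approx(50 * 36.0)

    def test_all_medium_gives_plain_mean(self):
        tbl = make_pixel_table(
            {"mmr": [4.0, 4.5, 5.0], "cpr": [0.009] * 3,
             "crystallinity": [1.1] * 3, "xlr": [3.4] * 3}
        )
        stats = ft.category_area_stats(tbl, ft.CategoryThresholds.published_defaults())
        assert stats.loc[("mmr", "medium"), "area_fraction"] == 1.0
        assert stats.loc[("mmr", "low"), "area_fraction"] == 0.0
        assert stats.loc[("mmr", "medium"), "norm_mean"] == pytest.approx(4.5)

    def test_empty_table_raises(self):
        tbl = make_pixel_table({"mmr": [], "cpr": [], "crystallinity": [], "xlr": []})
        with pytest.raises(ValueError):
            ft.category_area_stats(tbl, ft.CategoryThresholds.published_defaults())


class TestAssembleIrFeatures:
    def make_random_table(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        return make_pixel_table(
            {
                "mmr": rng.normal(4.4, 0.8, n),
                "cpr": rng.normal(0.009, 0.0015, n),
                "crystallinity": rng.normal(1.12, 0.05, n),
                "xlr": rng.normal(3.4, 0.35, n),
            }
        )

    def test_exactly_44_named_features(self):
        feats = ft.assemble_ir_features(
            self.make_random_table(), ft.CategoryThresholds.published_defaults()
        )
        assert len(feats) == 44
        assert list(feats) == list(ft.IR_FEATURES)

    def test_uniform_table_gives_zero_sd_features(self):
        tbl = make_pixel_table(
            {"mmr": [4.4] * 10, "cpr": [0.009] * 10,
             "crystallinity": [1.12] * 10, "xlr": [3.4] * 10}
        )
        feats = ft.assemble_ir_features(tbl, ft.CategoryThresholds.published_defaults())
        for p in ft.FTIR_PARAMS:
            assert feats[f"{p}_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_overall_means_equal_brute_force(self):
        tbl = self.make_random_table(seed=3)
        feats = ft.assemble_ir_features(tbl, ft.CategoryThresholds.published_defaults())
        for p in ft.FTIR_PARAMS:
            assert feats[f"{p}_mean"] == pytest.approx(tbl[p].mean(), abs=1e-9)
            assert feats[f"{p}_sd"] == pytest.approx(tbl[p].std(ddof=1), abs=1e-9)

    def test_row_permutation_invariance(self):
        tbl = self.make_random_table(seed=7)
        thr = ft.CategoryThresholds.published_defaults()
        shuffled = tbl.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = ft.assemble_ir_features(tbl, thr)
        b = ft.assemble_ir_features(shuffled, thr)
        assert a == pytest.approx(b)


class TestBuildCohortTable:
    def make_inputs(self, n=5):
        patients = pd.DataFrame(
            {"patient_id": [f"P{i:03d}" for i in range(n)], "age": 60.0}
        )
        feats = {
            pid: {name: float(i) for i, name in enumerate(ft.IR_FEATURES)}
            for pid in patients["patient_id"]
        }
        return patients, feats

    def test_one_row_per_patient(self):
        patients, feats = self.make_inputs(67)
        out = ft.build_cohort_table(feats, patients)
        assert len(out) == 67
        assert set(ft.IR_FEATURES) <= set(out.columns)

    def test_csv_round_trip_is_byte_stable(self, tmp_path):
        patients, feats = self.make_inputs()
        out = ft.build_cohort_table(feats, patients)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        out.to_csv(p1, index=False, float_format="%.12g")
        pd.read_csv(p1).to_csv(p2, index=False, float_format="%.12g")
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_patient_named_in_error(self):
        patients, feats = self.make_inputs()
        del feats["P003"]
        with pytest.raises(ValueError, match="P003"):
            ft.build_cohort_table(feats, patients)

    def test_duplicate_patient_raises(self):
        patients, feats = self.make_inputs()
        patients = pd.concat([patients, patients.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            ft.build_cohort_table(feats, patients)
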