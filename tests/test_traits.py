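"""FFQ trait preprocessing: filter, averaging, scaling, age adjustment, INT."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from famres.simulate import SimConfig, simulate_dataset
from famres.traits import (
    PreprocessConfig,
    SurveyTable,
    TraitError,
    adjust_age,
    average_surveys,
    filter_energy,
    inverse_normal_transform,
    nutrient_density,
    percent_energy,
    preprocess,
)


def make_table(energies, iids=None, **nutrients):
    n = len(energies)
    df = pd.DataFrame({
        "fid": ["F1"] * n,
        "iid": iids if iids is not None else [str(i) for i in range(n)],
        "survey": list(range(n)) if iids is None else _survey_index(iids),
        "age": np.linspace(30, 60, n),
        "sex": ["male", "female"] * (n // 2) + ["male"] * (n % 2),
        "energy_kcal": energies,
        **nutrients,
    })
    units = {k: "g/d" for k in nutrients}
    return SurveyTable(records=df, units=units)


def _survey_index(iids):
    seen = {}
    out = []
    for i in iids:
        seen[i] = seen.get(i, 0) + 1
        out.append(seen[i])
    return out


class TestFilterEnergy:
    @pytest.mark.parametrize(
        "energy,kept",
        [(750, False), (799.9, False), (800, True), (2000, True),
         (4200, True), (4200.1, False), (5000, False)],
    )
    def test_inclusive_bounds(self, energy, kept):
        table = make_table([energy, 2000, 2100])
        out, excluded = filter_energy(table)
        assert (energy in out.records["energy_kcal"].values) is kept

    def test_planted_outliers_bookkeeping(self):
        table = make_table([500, 5000] + [2000] * 8)
        kept, excluded = filter_energy(table)
        assert len(kept.records) == 8
        assert sorted(excluded["excluded_reason"]) == [
            "energy above bound", "energy below bound",
        ]

    def test_per_person_mode_drops_whole_person(self):
        table = make_table([500, 2000, 2100], iids=["a", "a", "b"])
        kept, excluded = filter_energy(table, mode="per-person")
        assert set(kept.records["iid"]) == {"b"}
        assert len(excluded) == 2

    def test_nonpositive_energy_rejected_at_construction(self):
        with pytest.raises(TraitError, match="non-positive energy"):
            make_table([0.0, 2000])


class TestAverageSurveys:
    def test_single_survey_identity(self):
        table = make_table([2000], carb=[300.0])
        person = average_surveys(table)
        assert person.loc[0, "energy_kcal"] == 2000
        assert person.loc[0, "n_surveys"] == 1

    def test_arithmetic_mean(self):
        table = make_table([2000, 2400], iids=["a", "a"], carb=[300.0, 340.0])
        person = average_surveys(table)
        assert person.loc[0, "energy_kcal"] == pytest.approx(2200)
        assert person.loc[0, "carb"] == pytest.approx(320)

    def test_matches_brute_force_on_generator_fixture(self):
        cfg = SimConfig(n_families=30, seed=3)
        _, data = simulate_dataset(cfg)
        table = SurveyTable(data.records, data.units)
        person = average_surveys(table).set_index(["fid", "iid"])
        for key, sub in data.records.groupby(["fid", "iid"]):
            assert person.loc[key, "energy_kcal"] == pytest.approx(
                sub["energy_kcal"].sum() / len(sub)
            )
            assert person.loc[key, "n_surveys"] == len(sub)


class TestScaling:
    def test_density(self):
        assert nutrient_density(60.0, 2000.0) == pytest.approx(30.0)
        assert nutrient_density(0.0, 2000.0) == 0.0
        with pytest.raises(TraitError):
            nutrient_density(10.0, 0.0)

    def test_percent_energy_reference_values(self):
        # printed cohort means: 341 g carb, 78.7 g fat, 84.6 g protein at 2411 kcal
        assert percent_energy(341, "carbohydrate", 2411) == pytest.approx(56.6, abs=0.1)
        assert percent_energy(78.7, "fat", 2411) == pytest.approx(29.4, abs=0.1)
        assert percent_energy(84.6, "protein", 2411) == pytest.approx(14.0, abs=0.1)
        assert percent_energy(0.0, "protein", 2411) == 0.0

    def test_unknown_macro_rejected(self):
        with pytest.raises(TraitError, match="unknown macronutrient"):
            percent_energy(10.0, "fiber", 2000.0)

    def test_macros_sum_to_100_when_they_supply_all_energy(self):
        carb, protein, fat = 250.0, 75.0, 60.0
        energy = 4 * carb + 4 * protein + 9 * fat
        total = (
            percent_energy(carb, "carbohydrate", energy)
            + percent_energy(protein, "protein", energy)
            + percent_energy(fat, "fat", energy)
        )
        assert total == pytest.approx(100.0)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_homogeneous_of_degree_zero(self, scale):
        base = percent_energy(80.0, "fat", 2400.0)
        assert percent_energy(80.0 * scale, "fat", 2400.0 * scale) == pytest.approx(base)
        assert nutrient_density(50.0 * scale, 2400.0 * scale) == pytest.approx(
            nutrient_density(50.0, 2400.0)
        )


class TestAdjustAge:
    def test_exact_linear_trait_residuals_vanish(self):
        age = np.array([30.0, 40, 50, 60])
        resid = adjust_age(2.0 * age, age)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_residuals_sum_to_zero_and_recover_slope(self, rng):
        age = rng.uniform(20, 70, 500)
        noise = rng.standard_normal(500)
        y = 0.5 * age + noise
        resid = adjust_age(y, age)
        assert resid.sum() == pytest.approx(0.0, abs=1e-8)
        # the fitted slope is what was removed: regress removed part on age
        removed = y - y.mean() - resid
        slope = np.polyfit(age, removed, 1)[0]
        se = np.sqrt(1.0 / ((age - age.mean()) ** 2).sum())
        assert abs(slope - 0.5) < 2 * se

    def test_constant_age_centres_with_warning(self):
        with pytest.warns(UserWarning, match="constant age"):
            resid = adjust_age([1.0, 2.0, 3.0], [40.0, 40.0, 40.0])
        assert np.allclose(resid, [-1, 0, 1])


class TestInverseNormalTransform:
    def test_middle_of_three_is_zero(self):
        out = inverse_normal_transform([10.0, 20.0, 30.0])
        assert out[1] == pytest.approx(0.0, abs=1e-12)

    def test_smallest_of_three_blom(self):
        # Probit((1 - 3/8) / (3 + 1 - 3/4)) = Probit(0.625/3.25) = -0.86942
        out = inverse_normal_transform([5.0, 6.0, 7.0])
        assert out[0] == pytest.approx(-0.86942, abs=1e-4)
        assert out[0] == pytest.approx(stats.norm.ppf(0.625 / 3.25))

    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=5, max_size=60,
            unique=True,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_input(self, values):
        vals = np.asarray(values)
        out = inverse_normal_transform(vals)
        order = np.argsort(vals)
        assert np.all(np.diff(out[order]) > 0)

    def test_near_standard_moments_and_symmetric(self, rng):
        y = rng.gamma(2.0, 2.0, 400)  # strongly skewed input
        out = inverse_normal_transform(y)
        assert out.mean() == pytest.approx(0.0, abs=1e-8)
        assert out.std(ddof=0) == pytest.approx(1.0, abs=0.01)
        assert abs(stats.skew(out)) < 0.1

    def test_ties_get_average_rank(self):
        out = inverse_normal_transform([1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        assert out[1] == out[2] == out[3]

    def test_degenerate_inputs(self):
        with pytest.raises(TraitError, match="all values tied"):
            inverse_normal_transform([3.0, 3.0, 3.0])
        with pytest.warns(UserWarning, match="distinct"):
            inverse_normal_transform([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])


class TestPipeline:
    def _run(self, seed=17):
        cfg = SimConfig(n_families=60, seed=seed)
        _, data = simulate_dataset(cfg)
        pcfg = PreprocessConfig(
            gram=["carbohydrate", "protein", "fat"],
            density=["protein"],
            percent=["carbohydrate", "fat"],
        )
        return preprocess(SurveyTable(data.records, data.units), pcfg)

    def test_provenance_records_fixed_order(self):
        tt = self._run()
        steps = [p["step"] for p in tt.provenance]
        assert steps == [
            "filter_energy", "average_surveys", "scale", "adjust_age",
            "inverse_normal_transform",
        ]

    def test_expected_trait_columns_and_units(self):
        tt = self._run()
        assert "carbohydrate_pct_kcal" in tt.trait_names
        assert tt.units["protein_per1000kcal"] == "g/d per 1000 kcal"
        assert tt.units["energy_kcal"] == "kcal/d"

    def test_traits_standardised_after_int(self):
        tt = self._run()
        for name in tt.trait_names:
            col = tt.values[name]
            assert col.mean() == pytest.approx(0.0, abs=1e-8)
            assert abs(stats.skew(col)) < 0.1

    def test_bit_reproducible(self, tmp_path):
        a, b = self._run(), self._run()
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.write(pa)
        b.write(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_roundtrip_read(self, tmp_path):
        tt = self._run()
        path = tmp_path / "traits.tsv"
        tt.write(path)
        from famres.traits import read_trait_table

        again = read_trait_table(path)
        assert again.trait_names == tt.trait_names
        assert again.provenance == tt.provenance
        pd.testing.assert_frame_equal(
            again.values, tt.values, check_exact=False, atol=1e-9
        )
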