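"""Life-table construction: growth fits, mortality relations, Weibull
survivorship, age-fecundity models and the component-toggle variants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agestruct.life_tables import (
    AgeFecundityModel,
    FecundityLengthModel,
    GrowthModel,
    WeibullSurvivorship,
    age_fecundity,
    annual_survival,
    build_empirical_life_table,
    build_theoretical_life_table,
    enumerate_toggle_models,
    fecundity_from_length,
    fit_von_bertalanffy,
    natural_mortality_at_age,
    null_constant_survival,
    read_life_table_tsv,
    toggle_life_table_components,
    weibull_annual_mortality,
    weibull_scale,
    write_life_table_tsv,
)


class TestVonBertalanffy:
    def test_exact_data_identity(self):
        g = GrowthModel(100.0, 0.3, -0.5)
        ages = np.arange(1, 11, dtype=float)
        fit, summary = fit_von_bertalanffy(ages, g.length_at_age(ages))
        assert fit.L_inf == pytest.approx(100.0, abs=1e-6)
        assert fit.K == pytest.approx(0.3, abs=1e-6)
        assert fit.t0 == pytest.approx(-0.5, abs=1e-6)
        assert summary["rss"] < 1e-12

    def test_length_zero_at_t0(self):
        g = GrowthModel(100.0, 0.3, -0.5)
        ages = np.arange(1, 11, dtype=float)
        fit, _ = fit_von_bertalanffy(ages, g.length_at_age(ages))
        assert fit.length_at_age(fit.t0) == pytest.approx(0.0, abs=1e-6)

    def test_too_few_distinct_ages_rejected(self):
        with pytest.raises(ValueError, match="distinct ages"):
            fit_von_bertalanffy([1, 1, 2], [10, 11, 20])

    def test_beats_grid_search_oracle_on_noisy_data(self):
        """Median |K error| of the least-squares fit should not exceed a
        brute-force grid search oracle's on the same noisy data."""
        true = GrowthModel(100.0, 0.3, -0.5)
        ages = np.repeat(np.arange(1.0, 11.0), 5)
        Ls = np.linspace(62, 141, 16)
        Ks = np.arange(0.06, 0.92, 0.045)  # coarse; does not contain true K
        t0s = np.linspace(-1.9, 1.1, 7)
        grid = np.stack(np.meshgrid(Ls, Ks, t0s, indexing="ij"), axis=-1).reshape(-1, 3)
        # oracle prediction matrix: one row per grid point
        pred = grid[:, 0:1] * (1.0 - np.exp(-grid[:, 1:2] * (ages[None, :] - grid[:, 2:3])))
        rng = np.random.default_rng(123)
        err_fit, err_grid = [], []
        for _ in range(120):
            y = true.length_at_age(ages) + rng.normal(0, 2.0, ages.size)
            fit, _ = fit_von_bertalanffy(ages, y)
            err_fit.append(abs(fit.K - true.K))
            best = np.argmin(((pred - y[None, :]) ** 2).sum(axis=1))
            err_grid.append(abs(grid[best, 1] - true.K))
        assert np.median(err_fit) <= np.median(err_grid) + 1e-12


class TestMortalityAndSurvival:
    g = GrowthModel(100.0, 0.2, 0.0)

    def test_mortality_equals_K_at_asymptote(self):
        assert natural_mortality_at_age(100.0, self.g) == pytest.approx(0.2)

    def test_quarter_length_gives_eightfold_K(self):
        assert natural_mortality_at_age(25.0, self.g) == pytest.approx(8 * 0.2)

    @given(st.floats(min_value=1.0, max_value=99.0), st.floats(min_value=0.1, max_value=0.9))
    @settings(max_examples=50, deadline=None)
    def test_mortality_decreasing_in_length(self, L1, frac):
        L2 = L1 + frac * (100.0 - L1)
        assert natural_mortality_at_age(L1, self.g) > natural_mortality_at_age(L2, self.g)

    def test_length_above_Linf_rejected_or_clamped(self):
        with pytest.raises(ValueError):
            natural_mortality_at_age(101.0, self.g)
        assert natural_mortality_at_age(101.0, self.g, clamp=True) == pytest.approx(0.2)

    @pytest.mark.parametrize("m, s", [(0.0, 1.0), (np.log(2), 0.5)])
    def test_annual_survival_values(self, m, s):
        assert annual_survival(m) == pytest.approx(s)

    def test_negative_mortality_rejected(self):
        with pytest.raises(ValueError):
            annual_survival(-0.1)

    def test_cumulative_survivorship_is_product(self):
        ms = [0.1, 0.5, 0.3]
        total = np.prod([annual_survival(m) for m in ms])
        assert total == pytest.approx(annual_survival(sum(ms)))


class TestFecundityLength:
    @pytest.mark.parametrize(
        "model, length, expected",
        [
            (FecundityLengthModel("power", 1.0, 0.0), 37.0, 1.0),
            (FecundityLengthModel("exponential", 2.0, 0.0), 12.0, 2.0),
            (FecundityLengthModel("power", 2.0, 3.0), 10.0, 2000.0),
        ],
    )
    def test_forms(self, model, length, expected):
        assert fecundity_from_length(model, length) == pytest.approx(expected)

    def test_negative_linear_clamped_with_warning(self):
        model = FecundityLengthModel("linear", -100.0, 1.0)
        with pytest.warns(RuntimeWarning, match="clamped"):
            assert fecundity_from_length(model, 10.0) == 0.0

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            FecundityLengthModel("quadratic", 1.0, 1.0)


class TestEmpiricalTable:
    g = GrowthModel(80.0, 0.3, -0.2)
    fl = FecundityLengthModel("power", 0.5, 2.0)

    def test_maturity_masking(self):
        tab = build_empirical_life_table(self.g, self.fl, maturity=3, lifespan=8)
        assert tab.rel_fecundity[0] == 0.0 and tab.rel_fecundity[1] == 0.0
        assert np.all(tab.rel_fecundity[2:] > 0)

    def test_terminal_survival_zero(self):
        tab = build_empirical_life_table(self.g, self.fl, maturity=1, lifespan=6)
        assert tab.survival[-1] == 0.0
        assert np.all(tab.survival[:-1] > 0)

    def test_identical_inputs_identical_tables(self):
        a = build_empirical_life_table(self.g, self.fl, 2, 7, sex="female")
        b = build_empirical_life_table(self.g, self.fl, 2, 7, sex="male")
        np.testing.assert_array_equal(a.survival, b.survival)
        np.testing.assert_array_equal(a.rel_fecundity, b.rel_fecundity)

    def test_tsv_round_trip(self, tmp_path):
        tab = build_empirical_life_table(self.g, self.fl, 2, 7, sex="female")
        path = tmp_path / "sp.tsv"
        write_life_table_tsv(path, {"female": tab}, "sp")
        back = read_life_table_tsv(path)["female"]
        np.testing.assert_allclose(back.survival, tab.survival)
        np.testing.assert_allclose(back.rel_fecundity, tab.rel_fecundity)


class TestWeibull:
    def test_scale_c1_lifespan10(self):
        assert weibull_scale(10.0, 1.0) == pytest.approx(10.0 / 4.605170, rel=1e-6)

    @pytest.mark.parametrize("c", [0.01, 0.1, 1.0, 3.0, 30.0])
    @pytest.mark.parametrize("lifespan", [3, 10, 21])
    def test_one_percent_at_lifespan(self, c, lifespan):
        surv = WeibullSurvivorship(c=c, lifespan=float(lifespan))
        assert surv.survivorship(lifespan) == pytest.approx(0.01, abs=1e-12)

    @pytest.mark.parametrize("c", [0.01, 0.05, 0.3, 1.0, 2.0, 10.0, 30.0])
    def test_cumulative_annual_product_is_one_percent(self, c):
        lifespan = 12
        surv = WeibullSurvivorship(c=c, lifespan=float(lifespan))
        M = [weibull_annual_mortality(a, surv) for a in range(lifespan)]
        assert np.prod([1 - m for m in M]) == pytest.approx(0.01, abs=1e-9)

    def test_c1_constant_mortality(self):
        lifespan = 10
        surv = WeibullSurvivorship(c=1.0, lifespan=float(lifespan))
        M = np.array([weibull_annual_mortality(a, surv) for a in range(lifespan)])
        np.testing.assert_allclose(M, 1 - 0.01 ** (1 / lifespan), rtol=1e-9)

    def test_type_iii_front_loaded(self):
        surv = WeibullSurvivorship(c=0.1, lifespan=10.0)
        assert weibull_annual_mortality(0, surv) > 10 * weibull_annual_mortality(8, surv)

    def test_type_i_back_loaded(self):
        surv = WeibullSurvivorship(c=30.0, lifespan=10.0)
        assert weibull_annual_mortality(0, surv) < 1e-6
        assert weibull_annual_mortality(9, surv) > 0.9

    def test_age_outside_span_rejected(self):
        surv = WeibullSurvivorship(c=1.0, lifespan=10.0)
        with pytest.raises(ValueError):
            weibull_annual_mortality(10, surv)


class TestAgeFecundity:
    def test_constant_equal_after_maturity(self):
        f = age_fecundity(AgeFecundityModel("constant"), range(1, 8), maturity=2)
        assert np.all(f[1:] == 1.0) and f[0] == 0.0

    def test_exponential_consecutive_ratio(self):
        f = age_fecundity(AgeFecundityModel("exponential", f=0.142), range(1, 8), maturity=1)
        np.testing.assert_allclose(f[1:] / f[:-1], np.exp(0.142), rtol=1e-12)

    def test_negative_rate_peaks_at_maturity(self):
        f = age_fecundity(AgeFecundityModel("exponential", f=-0.3), range(1, 10), maturity=3)
        assert f[2] == 1.0 and np.all(np.diff(f[2:]) < 0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            AgeFecundityModel("logistic")


class TestTheoreticalTable:
    def test_c1_maturity1_is_geometric(self):
        tab = build_theoretical_life_table(1, 8, 1.0, AgeFecundityModel("constant"))
        assert np.allclose(tab.survival[:-1], tab.survival[0])
        assert tab.survival[-1] == 0.0

    def test_b_depends_on_lifespan(self):
        a = build_theoretical_life_table(1, 6, 0.5, AgeFecundityModel("constant"))
        b = build_theoretical_life_table(1, 12, 0.5, AgeFecundityModel("constant"))
        assert not np.isclose(a.meta["b"], b.meta["b"])
        assert not np.isclose(a.survival[0], b.survival[0])

    @pytest.mark.parametrize("c", [0.01, 0.1, 1.0, 5.0, 30.0])
    @pytest.mark.parametrize("f", [-1.0, 0.0, 0.5, 1.0])
    def test_invariants_across_grid(self, c, f):
        tab = build_theoretical_life_table(2, 9, c, AgeFecundityModel("exponential", f=f))
        tab.validate()
        assert tab.rel_fecundity.max() == pytest.approx(1.0)
        assert np.all(np.diff(tab.survivorship()) <= 1e-15)


class TestToggles:
    @staticmethod
    def _bio_pair():
        g = GrowthModel(60.0, 0.35, 0.0)
        fl = FecundityLengthModel("power", 1.0, 3.0)
        return {
            "maturity": 3,
            "lifespan": 8,
            "table_f": build_empirical_life_table(g, fl, 3, 8, sex="female"),
            "table_m": build_empirical_life_table(g, fl, 3, 8, sex="male"),
        }

    def test_sixteen_variants(self):
        models = enumerate_toggle_models()
        assert len(models) == 16
        assert models[0]["toggles"] == dict.fromkeys(
            ("maturity", "age_survival", "age_fecundity", "sex_specific"), False
        )
        assert all(models[-1]["toggles"].values())

    def test_null_model_constant_rates(self):
        pair = toggle_life_table_components(self._bio_pair(), {})
        tab = pair["female"]
        expected_s = null_constant_survival(8)
        assert expected_s == pytest.approx(1e-4 ** (1 / 7))
        np.testing.assert_allclose(tab.survival[:-1], expected_s)
        assert np.all(tab.rel_fecundity == tab.rel_fecundity[0])
        assert tab.maturity == 1.0
        np.testing.assert_array_equal(tab.survival, pair["male"].survival)

    def test_all_on_recovers_biological_tables(self):
        species = self._bio_pair()
        pair = toggle_life_table_components(
            species, dict.fromkeys(("maturity", "age_survival", "age_fecundity", "sex_specific"), True)
        )
        np.testing.assert_allclose(pair["female"].survival, species["table_f"].survival)
        np.testing.assert_allclose(pair["female"].rel_fecundity, species["table_f"].rel_fecundity)
        assert pair["female"].maturity == species["maturity"]

    def test_unknown_toggle_rejected(self):
        with pytest.raises(ValueError, match="unknown toggles"):
            toggle_life_table_components(self._bio_pair(), {"senescence": True})

    def test_shared_null_survival_rule(self):
        assert null_constant_survival(5, shared_max_lifespan=21) == pytest.approx(
            1e-4 ** (1 / 20)
        )
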