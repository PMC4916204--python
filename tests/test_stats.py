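import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spatbeat import (
    CohortConfig,
    ParameterError,
    fisher_exact,
    fit_hr_model,
    make_cohort,
    mcnemar_exact,
    rank_anova_q10,
)
from oracles import fisher_two_sided_enumeration, hypergeometric_table_probabilities


class TestMcNemarExact:
    @pytest.mark.parametrize(
        "b,c,expected",
        [
            (8, 0, 0.0078125),  # 8 discordant pairs, all one-way: 2/2^8
            (3, 0, 0.25),       # 3 discordant pairs: 2/2^3
            (0, 0, 1.0),        # no information
            (5, 5, 1.0),        # perfectly balanced discordance
        ],
    )
    def test_closed_form_values(self, b, c, expected):
        assert mcnemar_exact(b, c) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(b=st.integers(0, 25), c=st.integers(0, 25))
    def test_symmetry_and_range(self, b, c):
        p = mcnemar_exact(b, c)
        assert p == mcnemar_exact(c, b)
        assert 0.0 < p <= 1.0

    @settings(max_examples=25, derandomize=True)
    @given(b=st.integers(0, 20), c=st.integers(0, 20))
    def test_agrees_with_statsmodels_exact(self, b, c):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        res = sm_mcnemar([[5, b], [c, 5]], exact=True)
        assert mcnemar_exact(b, c) == pytest.approx(res.pvalue, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            mcnemar_exact(-1, 2)


class TestFisherExact:
    def test_reported_asystole_table(self):
        # 8/8 vs 3/8 asystolic: prints as P = 0.026
        assert fisher_exact([[8, 0], [3, 5]]) == pytest.approx(0.02564, abs=5e-5)

    def test_identical_rows_give_unity(self):
        assert fisher_exact([[4, 4], [4, 4]]) == 1.0

    def test_degenerate_margin_gives_unity(self):
        assert fisher_exact([[0, 0], [3, 5]]) == 1.0
        assert fisher_exact([[0, 3], [0, 5]]) == 1.0

    def test_probabilities_sum_to_one_for_study_margins(self):
        probs = hypergeometric_table_probabilities(11, 5, 8)
        assert sum(probs) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("r1,r2,c1", [(8, 8, 11), (10, 6, 7), (20, 20, 13),
                                          (5, 35, 12), (16, 16, 16)])
    def test_agrees_with_full_enumeration_oracle(self, r1, r2, c1):
        for a in range(max(0, c1 - r2), min(r1, c1) + 1):
            table = [[a, r1 - a], [c1 - a, r2 - (c1 - a)]]
            assert fisher_exact(table) == pytest.approx(
                fisher_two_sided_enumeration(table), abs=1e-12
            )

    def test_type_one_error_at_most_nominal_under_null(self, rng):
        # exact-test conservatism: rejection rate <= 0.05 at alpha = 0.05
        n_reps, alpha, n = 2000, 0.05, 8
        x = rng.binomial(n, 0.5, size=n_reps)
        y = rng.binomial(n, 0.5, size=n_reps)
        cache: dict[tuple[int, int], float] = {}
        rejections = 0
        for a, b in zip(x, y):
            p = cache.setdefault(
                (a, b), fisher_exact([[a, n - a], [b, n - b]])
            )
            rejections += p < alpha
        assert rejections / n_reps <= alpha

    def test_non_integer_entries_rejected(self):
        with pytest.raises(ParameterError):
            fisher_exact([[1.5, 2], [3, 4]])


def _simulated_frame(rng, rho=0.0, sigma_u=5.0, sigma_e=3.0, slope=6.0,
                     group_effect=3.0, interaction=-1.5, phase_effect=2.0,
                     n_per_group=6):
    temps = [22, 20, 18, 16, 14, 12, 10, 12, 14, 16, 18, 20, 22]
    phases = ["cooling"] * 7 + ["warming"] * 6
    rows = []
    for g in ("Ta10", "Ta22"):
        for i in range(n_per_group):
            u = rng.normal(0.0, sigma_u)
            eps = rng.normal(0.0, sigma_e, size=len(temps))
            for k in range(1, len(temps)):
                eps[k] = rho * eps[k - 1] + np.sqrt(1 - rho**2) * eps[k]
            for k, (t, ph) in enumerate(zip(temps, phases)):
                is10 = g == "Ta10"
                y = (
                    80.0
                    + group_effect * is10
                    + (slope + interaction * is10) * (t - 22)
                    + phase_effect * (ph == "warming")
                    + u
                    + eps[k]
                )
                rows.append(
                    dict(spat_id=f"{g}_{i}", group=g, step_index=k, set_point=t,
                         phase=ph, hr_active=y, hr_zeroed=y)
                )
    return pd.DataFrame(rows)


class TestFitHRModel:
    def test_noise_free_cohort_recovers_slopes_exactly(
        self, noise_free_config, default_protocol
    ):
        ds = make_cohort(noise_free_config, default_protocol, seed=0)
        fit = fit_hr_model(ds, convention="zeroed")
        assert fit.slope("Ta22") == pytest.approx(5.0, abs=1e-6)
        assert fit.slope("Ta10") == pytest.approx(5.0, abs=1e-6)
        assert fit.params["group_Ta10:temp_c"] == pytest.approx(0.0, abs=1e-6)
        assert fit.intercept_22c("Ta22") == pytest.approx(80.0, abs=1e-5)

    def test_matches_statsmodels_mixedlm_when_rho_is_zero(self, rng):
        import statsmodels.api as sm

        df = _simulated_frame(rng)
        fit = fit_hr_model(df, ar1=False)
        g = (df["group"] == "Ta10").to_numpy(float)
        tc = df["set_point"].to_numpy(float) - 22.0
        ph = (df["phase"] == "warming").to_numpy(float)
        X = np.column_stack([np.ones(len(df)), g, tc, g * tc, ph])
        ref = sm.MixedLM(df["hr_zeroed"].to_numpy(), X, groups=df["spat_id"]).fit(
            reml=True
        )
        assert np.allclose(fit.params.to_numpy(), ref.fe_params, atol=1e-4)
        assert np.allclose(fit.bse.to_numpy(), np.asarray(ref.bse_fe), atol=1e-3)
        assert fit.sigma_u2 == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), rel=0.01
        )
        assert fit.sigma_e2 == pytest.approx(float(ref.scale), rel=0.01)

    def test_recovers_ar1_coefficient(self, rng):
        df = _simulated_frame(rng, rho=0.6, n_per_group=10)
        fit = fit_hr_model(df)
        assert fit.method == "reml_ar1"
        assert fit.rho == pytest.approx(0.6, abs=0.2)

    def test_parameter_recovery_from_generated_cohorts(self):
        fits = [fit_hr_model(make_cohort(seed=s), convention="zeroed")
                for s in range(5)]
        s22 = np.mean([f.slope("Ta22") for f in fits])
        s10 = np.mean([f.slope("Ta10") for f in fits])
        assert s22 == pytest.approx(7.3, rel=0.10)
        assert s10 == pytest.approx(5.1, rel=0.10)

    def test_spat_relabelling_within_group_leaves_estimates_unchanged(self, rng):
        df = _simulated_frame(rng)
        fit_a = fit_hr_model(df, ar1=False)
        swapped = df.copy()
        swapped["spat_id"] = swapped["spat_id"].replace(
            {"Ta10_0": "Ta10_1", "Ta10_1": "Ta10_0"}
        )
        fit_b = fit_hr_model(swapped, ar1=False)
        assert np.allclose(fit_a.params.to_numpy(), fit_b.params.to_numpy(), atol=1e-6)

    def test_active_only_convention_drops_asystolic_rows(self):
        ds = make_cohort(seed=9)
        fit = fit_hr_model(ds, convention="active_only")
        n_active = int(ds.segments["hr_active"].notna().sum())
        assert fit.n_obs == n_active

    def test_too_few_spat_rejected(self, rng):
        df = _simulated_frame(rng, n_per_group=1)
        with pytest.raises(ParameterError):
            fit_hr_model(df)


class TestRankAnovaQ10:
    @staticmethod
    def frame(rng, group_shift=0.0, n=8, base=2.5, sd=0.4):
        rows = []
        for g in ("Ta10", "Ta22"):
            for ph in ("cooling", "warming"):
                vals = rng.normal(base + group_shift * (g == "Ta10"), sd, size=n)
                rows += [dict(q10=v, group=g, phase=ph) for v in vals]
        return pd.DataFrame(rows)

    def test_all_equal_values_give_zero_f_unit_p(self):
        df = pd.DataFrame(
            dict(q10=[2.0] * 16,
                 group=["Ta10"] * 8 + ["Ta22"] * 8,
                 phase=(["cooling"] * 4 + ["warming"] * 4) * 2)
        )
        out = rank_anova_q10(df)
        for term in ("group", "phase", "interaction"):
            assert out[term]["F"] == 0.0
            assert out[term]["p"] == 1.0

    def test_power_against_shifted_group(self, rng):
        # per-cell spread 0.8: the scale of between-animal Q10 variation
        # implied by SEMs of 0.2-0.3 at n = 8
        hits = 0
        for _ in range(50):
            out = rank_anova_q10(self.frame(rng, group_shift=1.0, sd=0.8))
            hits += out["group"]["p"] < 0.05
        assert hits >= 40  # >= 80% of replicates detect a 1.0 group shift

    def test_invariant_under_monotone_transform(self, rng):
        df = self.frame(rng, group_shift=0.5)
        out_raw = rank_anova_q10(df)
        df2 = df.assign(q10=np.exp(df["q10"]))
        out_exp = rank_anova_q10(df2)
        for term in ("group", "phase", "interaction"):
            assert out_raw[term]["F"] == pytest.approx(out_exp[term]["F"], rel=1e-9)

    def test_single_level_factor_dropped_with_warning(self, rng):
        df = self.frame(rng, group_shift=1.0)
        df = df[df["phase"] == "cooling"]
        with pytest.warns(UserWarning, match="phase"):
            out = rank_anova_q10(df)
        assert np.isnan(out["phase"]["F"])
        assert np.isfinite(out["group"]["F"])
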