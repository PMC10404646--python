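"""Group-level statistics: learning tests, mixed models, correlations."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tripletsl.behavior_sim import CohortSpec, simulate_cohort
from tripletsl.errors import FitError
from tripletsl.inference import (
    compare_correlations,
    correlation_suite,
    development_analysis,
    effect_size_g,
    fit_accuracy_mixed_logistic,
    fit_composite_model,
    fit_rt_mixed_model,
    median_split_ages,
    morey_within_se,
    one_sample_learning_tests,
    partial_correlation,
    welch_test,
)
from tripletsl.response_scoring import score_bundle
from tripletsl.sl_metrics import (
    build_afc_table,
    build_composite_table,
    build_rt_table,
    compute_measures,
    composite_scores,
)


def measures_frame(slopes, accs, task="syllable"):
    n = len(slopes)
    return pd.DataFrame(
        {
            "participant_id": [f"p{i}" for i in range(n)],
            "task": task,
            "rt_slope": slopes,
            "afc_accuracy": accs,
        }
    )


def participants_frame(n, group="TD"):
    return pd.DataFrame({"participant_id": [f"p{i}" for i in range(n)], "group": group})


class TestOneSampleLearning:
    def test_accuracy_test_matches_closed_form(self):
        acc = [0.75, 0.8125, 0.875, 0.75]
        m = measures_frame([np.nan] * 4, acc)
        (res,) = one_sample_learning_tests(m, participants_frame(4))
        x = np.array(acc)
        t_hand = (x.mean() - 0.5) / (x.std(ddof=1) / 2)
        assert res.statistic == pytest.approx(t_hand, abs=1e-12)
        assert res.p == pytest.approx(stats.t.sf(t_hand, 3), abs=1e-12)
        assert res.sidedness == "greater"

    def test_slope_test_is_one_tailed_negative(self):
        rng = np.random.default_rng(0)
        m = measures_frame(rng.normal(-0.03, 0.01, 20), [np.nan] * 20)
        (res,) = one_sample_learning_tests(m, participants_frame(20))
        assert res.sidedness == "less"
        assert res.statistic < 0 and res.p < 0.001

    def test_all_zero_slopes_are_exact_chance(self):
        m = measures_frame([0.0] * 6, [np.nan] * 6)
        (res,) = one_sample_learning_tests(m, participants_frame(6))
        assert res.statistic == 0.0 and res.p == 0.5

    def test_zero_variance_off_null_is_degenerate(self):
        m = measures_frame([-0.02] * 6, [np.nan] * 6)
        with pytest.raises(FitError):
            one_sample_learning_tests(m, participants_frame(6))


class TestEffectSizeAndWelch:
    def test_identical_groups_have_zero_effect(self, rng):
        a = rng.normal(0, 1, 20)
        assert effect_size_g(a, a.copy()) == 0.0

    def test_matches_hand_computed_hedges_correction(self):
        a = np.array([3.1, 2.4, 4.0, 3.3, 2.8, 3.9, 3.0, 2.2, 3.6, 3.5])
        b = np.array([2.0, 2.6, 1.8, 2.9, 2.3, 1.9, 2.7, 2.1, 2.5, 2.4])
        df = 18
        pooled = np.sqrt(((9 * a.var(ddof=1)) + (9 * b.var(ddof=1))) / df)
        d = (a.mean() - b.mean()) / pooled
        expected = d * (1 - 3 / (4 * df - 1))
        assert effect_size_g(a, b) == pytest.approx(expected, abs=1e-12)

    def test_unit_shift_approaches_one_at_large_n(self, rng):
        a = rng.normal(1, 1, 4000)
        b = rng.normal(0, 1, 4000)
        assert effect_size_g(a, b) == pytest.approx(1.0, abs=0.08)

    def test_welch_df_fractional_and_g_attached(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 3, 20)
        res = welch_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.df == pytest.approx(ref.df)
        assert res.df != int(res.df)  # Welch df is fractional here
        assert res.effect_size_g is not None


class TestFisherComparison:
    def test_equal_correlations_give_zero(self):
        res = compare_correlations(0.4, 30, 0.4, 50)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_closed_form_value(self):
        # (atanh(.5) - 0) / sqrt(1/27 + 1/27) = 2.018
        res = compare_correlations(0.5, 30, 0.0, 30)
        assert res.statistic == pytest.approx(2.018, abs=5e-4)

    def test_antisymmetric_in_sample_order(self):
        a = compare_correlations(0.6, 40, 0.2, 35)
        b = compare_correlations(0.2, 35, 0.6, 40)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            compare_correlations(1.0, 30, 0.2, 30)
        with pytest.raises(FitError):
            compare_correlations(0.5, 3, 0.2, 30)

    def test_agrees_with_permutation_reference(self):
        """Fisher-z p agrees with a label-permutation reference on a small
        two-sample fixture (within Monte-Carlo error)."""
        rng = np.random.default_rng(4)
        n = 45
        # group A: correlated pairs; group B: independent
        xa = rng.normal(size=n)
        ya = 0.6 * xa + 0.8 * rng.normal(size=n)
        xb = rng.normal(size=n)
        yb = rng.normal(size=n)
        ra = np.corrcoef(xa, ya)[0, 1]
        rb = np.corrcoef(xb, yb)[0, 1]
        res = compare_correlations(ra, n, rb, n)

        x = np.concatenate([xa, xb])
        y = np.concatenate([ya, yb])
        obs = abs(np.arctanh(ra) - np.arctanh(rb))
        count = 0
        nperm = 3000
        for _ in range(nperm):
            perm = rng.permutation(2 * n)
            ia, ib = perm[:n], perm[n:]
            r1 = np.corrcoef(x[ia], y[ia])[0, 1]
            r2 = np.corrcoef(x[ib], y[ib])[0, 1]
            count += abs(np.arctanh(r1) - np.arctanh(r2)) >= obs
        p_perm = (count + 1) / (nperm + 1)
        assert res.p == pytest.approx(p_perm, abs=0.05)


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_controls(self, rng):
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        r, n, p = partial_correlation(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_irrelevant_control_changes_little(self, rng):
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        z = rng.normal(size=200)  # unrelated control
        r_plain, *_ = partial_correlation(x, y)
        r_part, *_ = partial_correlation(x, y, z)
        assert r_part == pytest.approx(r_plain, abs=0.02)

    def test_collinear_pair_is_perfect(self, rng):
        x = rng.normal(size=10)
        r, _, _ = partial_correlation(x, 2 * x + 3)
        assert r == pytest.approx(1.0)

    def test_matches_residual_oracle_on_hand_table(self):
        x = np.array([3.0, 5.0, 2.0, 7.0, 6.0, 4.0])
        y = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 3.0])
        z = np.array([2.0, 3.0, 1.0, 5.0, 4.0, 2.5])
        r, n, p = partial_correlation(x, y, z)
        # independent OLS-residual computation
        X = np.column_stack([np.ones(6), z])
        rx = x - X @ np.linalg.solve(X.T @ X, X.T @ x)
        ry = y - X @ np.linalg.solve(X.T @ X, X.T @ y)
        assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(size=40)
        z = rng.normal(size=40)
        y = 0.4 * x + 0.5 * z + rng.normal(size=40)
        r, n, p = partial_correlation(x, y, z)
        ref = pingouin.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        p_col = next(c for c in ("p_val", "p-val", "p-unc") if c in ref.columns)
        assert p == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-9)

    def test_handles_missing_values_pairwise(self, rng):
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30)
        x[3] = np.nan
        r, n, p = partial_correlation(x, y)
        assert n == 29


class TestCorrelationSuite:
    def test_pairwise_partial_correlations_per_group(self, small_cohort, small_measures):
        m, _ = small_measures
        wide = m.pivot_table(index="participant_id", columns="task", values="composite")
        res = correlation_suite(wide, small_cohort.participants, controls=("age_years",))
        assert {c.group for c in res} <= {"TD", "ASD"}
        for c in res:
            assert -1 <= c.r <= 1 and c.p_adjusted >= c.p - 1e-12
            assert c.controls == ("age_years",)

    def test_holm_adjustment_is_monotone(self, small_cohort, small_measures):
        m, _ = small_measures
        wide = m.pivot_table(index="participant_id", columns="task", values="composite")
        res = [c for c in correlation_suite(wide, small_cohort.participants) if c.group == "TD"]
        ps = [c.p for c in res]
        padj = [c.p_adjusted for c in res]
        order = np.argsort(ps)
        assert np.all(np.diff(np.array(padj)[order]) >= -1e-12)


class TestMoreyWithinSE:
    def toy(self):
        # 3 participants x 2 conditions, participant offsets removable
        return pd.DataFrame(
            {
                "participant_id": ["a", "a", "b", "b", "c", "c"],
                "task": ["t1", "t2"] * 3,
                "value": [1.0, 2.0, 3.0, 4.5, 5.0, 6.2],
            }
        )

    def test_matches_hand_computation_for_two_conditions(self):
        df = self.toy()
        se = morey_within_se(df, value_col="value")
        pivot = df.pivot(index="participant_id", columns="task", values="value")
        norm = pivot.sub(pivot.mean(axis=1), axis=0) + pivot.to_numpy().mean()
        hand = norm.std(ddof=1) / np.sqrt(3) * np.sqrt(2 / 1)
        np.testing.assert_allclose(se, hand, atol=1e-12)

    def test_pure_participant_offsets_give_zero(self):
        df = self.toy()
        df["value"] = [1.0, 2.0, 11.0, 12.0, 21.0, 22.0]  # same profile, shifted
        se = morey_within_se(df, value_col="value")
        np.testing.assert_allclose(se, 0.0, atol=1e-12)

    def test_invariant_to_between_participant_shifts(self):
        df = self.toy()
        se0 = morey_within_se(df, value_col="value")
        df2 = df.copy()
        df2.loc[df2.participant_id == "b", "value"] += 100.0
        np.testing.assert_allclose(morey_within_se(df2, value_col="value"), se0, atol=1e-12)

    def test_single_condition_warns_and_returns_plain_se(self):
        df = self.toy()[self.toy().task == "t1"]
        with pytest.warns(UserWarning, match="one condition"):
            se = morey_within_se(df, value_col="value")
        assert se["t1"] == pytest.approx(np.std([1, 3, 5], ddof=1) / np.sqrt(3))


class TestMedianSplit:
    def test_even_symmetric_ages_split_in_half(self):
        ages = pd.Series([6.0, 7.0, 9.0, 10.0])
        half = median_split_ages(ages)
        assert list(half) == ["younger", "younger", "older", "older"]

    def test_duplicated_median_goes_younger_deterministically(self):
        ages = pd.Series([6.0, 8.0, 8.0, 8.0, 11.0])
        half = median_split_ages(ages)
        assert list(half) == ["younger", "younger", "younger", "younger", "older"]

    def test_identical_ages_rejected(self):
        with pytest.raises(FitError):
            median_split_ages(pd.Series([8.0] * 5))


@pytest.fixture(scope="module")
def planted_cohort():
    """Moderate cohort with a strong TD-only linguistic slope advantage."""
    effects = {
        ("TD", "linguistic"): (-0.04, 0.75),
        ("TD", "nonlinguistic"): (0.0, 0.60),
        ("ASD", "linguistic"): (0.0, 0.55),
        ("ASD", "nonlinguistic"): (0.0, 0.60),
    }
    spec = CohortSpec(
        n_per_group={"TD": 30, "ASD": 30}, effects=effects, missing_task_prob=0.0, seed=21
    )
    bundle = simulate_cohort(spec)
    scored = score_bundle(bundle)
    m = compute_measures(scored, bundle)
    m, dom = composite_scores(m, bundle.configs)
    return bundle, scored, m, dom


class TestMixedModels:
    def test_rt_model_recovers_planted_interaction_sign(self, planted_cohort):
        bundle, scored, m, dom = planted_cohort
        fit = fit_rt_mixed_model(build_rt_table(scored, bundle))
        row = fit.coef.loc["group_c:domain_c:order_c"]
        assert row["estimate"] < 0 and row["p"] < 0.05
        assert fit.n_groups == 60

    def test_rt_model_needs_multiple_participants(self, planted_cohort):
        bundle, scored, *_ = planted_cohort
        rt = build_rt_table(scored, bundle)
        solo = rt[rt.participant_id == rt.participant_id.iloc[0]]
        with pytest.raises(FitError):
            fit_rt_mixed_model(solo)

    def test_composite_model_sees_group_and_interaction(self, planted_cohort):
        bundle, scored, m, dom = planted_cohort
        fit = fit_composite_model(build_composite_table(m, bundle))
        assert fit.coef.loc["group_c", "estimate"] > 0  # TD coded +0.5
        assert fit.coef.loc["group_c:domain_c", "estimate"] > 0

    def test_logistic_model_recovers_group_log_odds(self):
        """Constructed binomial data with a known group logit gap."""
        rng = np.random.default_rng(8)
        rows = []
        for g, base in (("TD", 0.65), ("ASD", 0.15)):  # gap = 0.5 log-odds
            for i in range(40):
                pid = f"{g}{i}"
                intercept = base + rng.normal(0, 0.3)
                for task, cfg in (("letter", ("linguistic", "visual")),
                                  ("syllable", ("linguistic", "auditory")),
                                  ("image", ("nonlinguistic", "visual")),
                                  ("tone", ("nonlinguistic", "auditory"))):
                    p = 1 / (1 + np.exp(-intercept))
                    for t in range(16):
                        rows.append(
                            {
                                "participant_id": pid,
                                "group": g,
                                "sex": "F" if rng.random() < 0.5 else "M",
                                "task": task,
                                "domain": cfg[0],
                                "modality": cfg[1],
                                "item_id": f"{task}:{t}",
                                "correct": int(rng.random() < p),
                            }
                        )
        fit = fit_accuracy_mixed_logistic(pd.DataFrame(rows))
        est = fit.coef.loc["group_c", "estimate"]
        assert 0.2 < est < 0.8  # true 0.5 on the log-odds scale
        assert fit.converged

    def test_all_correct_flags_separation(self, planted_cohort):
        bundle, *_ = planted_cohort
        afc = build_afc_table(bundle).copy()
        afc["correct"] = 1
        fit = fit_accuracy_mixed_logistic(afc)
        assert not fit.converged and fit.singular
        assert "separation" in fit.notes


class TestDevelopment:
    def test_age_widening_gap_recovered(self):
        """A group x domain gap that grows with age yields the planted
        interaction sign in the continuous-age model."""
        rng = np.random.default_rng(15)
        rows, meta = [], []
        for g in ("TD", "ASD"):
            for i in range(40):
                pid = f"{g}{i}"
                age = rng.uniform(6, 12.5)
                meta.append({"participant_id": pid, "group": g,
                             "sex": "F" if rng.random() < 0.5 else "M",
                             "age_years": age})
                for dom in ("linguistic", "nonlinguistic"):
                    gap = 0.25 * (age - 9.0) if (g == "TD" and dom == "linguistic") else 0.0
                    rows.append({"participant_id": pid, "domain": dom,
                                 "score": gap + rng.normal(0, 0.4)})
        res = development_analysis(pd.DataFrame(rows), pd.DataFrame(meta))
        assert res.continuous.coef.loc["group_c:domain_c:age_z", "estimate"] > 0
        assert res.continuous.coef.loc["group_c:domain_c:age_z", "p"] < 0.05
        assert set(res.subgroup_fits) == {"younger", "older"}
        assert sum(s["TD"] + s["ASD"] for s in res.subgroup_sizes.values()) == 80

    def test_identical_ages_fail_split(self):
        rows = pd.DataFrame(
            {"participant_id": ["a", "a", "b", "b"], "domain": ["linguistic", "nonlinguistic"] * 2,
             "score": [0.1, 0.2, 0.3, 0.4]}
        )
        meta = pd.DataFrame(
            {"participant_id": ["a", "b"], "group": ["TD", "ASD"], "sex": ["F", "M"],
             "age_years": [8.0, 8.0]}
        )
        with pytest.raises(FitError):
            development_analysis(rows, meta)
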