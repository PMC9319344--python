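"""Cox fits vs oracles, LASSO selection, risk indices, KM/log-rank, ROC, C."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index

from bcmeta import synthetic as syn
from bcmeta import survival as sv


def _cohort(time, event, **genes):
    idx = [f"p{i}" for i in range(len(time))]
    return sv.SurvivalCohort(
        pd.Series(time, index=idx, dtype=float),
        pd.Series(event, index=idx, dtype=int),
        pd.DataFrame(genes, index=idx, dtype=float),
    )


def random_cohort(seed, n=120, beta=(0.7,), censor=0.25, p=None):
    rng = np.random.default_rng(seed)
    p = p or len(beta)
    x = rng.normal(size=(n, p))
    lp = x[:, : len(beta)] @ np.asarray(beta)
    t = rng.exponential(np.exp(-lp))
    c = (rng.exponential(t.mean() / max(censor, 1e-9), size=n)
         if censor else np.full(n, np.inf))
    event = (t <= c).astype(int)
    obs = np.minimum(t, c) + 1e-9
    return _cohort(obs, event, **{f"g{j}": x[:, j] for j in range(p)})


class TestCoxUnivariate:
    def test_constant_covariate_raises(self):
        cohort = _cohort([1, 2, 3, 4], [1, 1, 1, 0], g=[2.0, 2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="constant"):
            sv.cox_univariate(cohort, "g")

    def test_matches_grid_search_partial_likelihood_maximizer(self):
        cohort = random_cohort(0, n=150, beta=(0.7,))
        est = sv.cox_univariate(cohort, "g0").table["coef"].iloc[0]
        x = cohort.expression["g0"].to_numpy()
        t = cohort.time.to_numpy()
        e = cohort.event.to_numpy()
        grid = np.arange(est - 0.05, est + 0.05, 1e-4)
        lls = [sv.breslow_loglik(b * x, t, e) for b in grid]
        assert abs(grid[int(np.argmax(lls))] - est) < 1e-3

    def test_matches_lifelines_on_tie_free_data(self):
        cohort = random_cohort(1, n=200, beta=(0.5,))
        fit = sv.cox_univariate(cohort, "g0")
        df = pd.DataFrame(
            {"t": cohort.time, "e": cohort.event, "x": cohort.expression["g0"]}
        )
        ll = CoxPHFitter().fit(df, "t", "e")
        assert fit.table["coef"].iloc[0] == pytest.approx(
            ll.params_["x"], abs=1e-5
        )
        assert fit.table["se"].iloc[0] == pytest.approx(
            ll.standard_errors_["x"], abs=1e-5
        )

    def test_null_type_one_error_calibrated(self):
        rej = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cohort = random_cohort(seed, n=150, beta=(0.0,))
            rej += sv.cox_univariate(cohort, "g0").table["p"].iloc[0] < 0.05
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(rej / n_seeds - 0.05) <= 3 * se

    def test_monotone_likelihood_raises(self):
        # perfectly separating covariate -> diverging coefficient
        cohort = _cohort(
            [1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1],
            g=[5.0, 4.0, 3.0, 2.0, 1.0, 0.0],
        )
        with pytest.raises(ValueError, match="monotone|converge"):
            sv.cox_univariate(cohort, "g")


class TestCoxMultivariate:
    def test_independent_covariates_match_univariate_within_2se(self):
        cohort = random_cohort(2, n=300, beta=(0.6, -0.4, 0.0))
        fit, _ = sv.cox_multivariate(cohort, ["g0", "g1", "g2"])
        for g in ["g0", "g1", "g2"]:
            uni = sv.cox_univariate(cohort, g).table
            diff = abs(fit.table.loc[g, "coef"] - uni.loc[g, "coef"])
            assert diff <= 2 * (fit.table.loc[g, "se"] + uni.loc[g, "se"])

    def test_matches_lifelines_joint_fit(self):
        cohort = random_cohort(3, n=250, beta=(0.5, -0.5))
        fit, _ = sv.cox_multivariate(cohort, ["g0", "g1"])
        df = pd.DataFrame(
            {
                "t": cohort.time,
                "e": cohort.event,
                "g0": cohort.expression["g0"],
                "g1": cohort.expression["g1"],
            }
        )
        ll = CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(
            fit.table["coef"], ll.params_[["g0", "g1"]], atol=1e-5
        )

    def test_training_cindex_at_least_half(self):
        cohort = random_cohort(4, n=200, beta=(0.8,))
        fit, _ = sv.cox_multivariate(cohort, ["g0"])
        assert fit.cindex >= 0.5

    def test_duplicated_covariate_raises(self):
        cohort = random_cohort(5, n=100, beta=(0.5,), p=2)
        cohort.expression["g1"] = cohort.expression["g0"]
        with pytest.raises(ValueError, match="collinear"):
            sv.cox_multivariate(cohort, ["g0", "g1"])

    def test_covariate_budget_guard(self):
        cohort = random_cohort(6, n=30, beta=(0.5,), p=20)
        with pytest.raises(ValueError, match="events"):
            sv.cox_multivariate(cohort, [f"g{j}" for j in range(20)])


class TestLassoSelect:
    def test_rerun_with_same_seed_is_identical(self):
        cohort, _ = syn.simulate_survival_cohort(
            syn.SimConfig(seed=5, survival=syn.SurvivalSimConfig(
                n_patients=200, n_genes=30,
                log_hr={"G0001": 0.8, "G0002": -0.8}))
        )
        genes = list(cohort.expression.columns)
        a = sv.lasso_cox_select(cohort, genes, iters=5, seed=7)
        b = sv.lasso_cox_select(cohort, genes, iters=5, seed=7)
        assert a[0] == b[0]
        pd.testing.assert_series_equal(a[1], b[1])

    def test_planted_genes_selected(self):
        cohort, _ = syn.simulate_survival_cohort(
            syn.SimConfig(seed=8, survival=syn.SurvivalSimConfig(
                n_patients=300, n_genes=40,
                log_hr={"G0001": 0.9, "G0002": -0.9}))
        )
        sel, freq = sv.lasso_cox_select(
            cohort, list(cohort.expression.columns), iters=10, seed=0
        )
        assert {"G0001", "G0002"} <= set(sel)

    def test_pure_noise_selects_nothing(self):
        cohort = random_cohort(9, n=150, beta=(0.0,), p=20, censor=0.2)
        with pytest.warns(UserWarning, match="no gene"):
            sel, _ = sv.lasso_cox_select(
                cohort, list(cohort.expression.columns), iters=5, seed=1
            )
        assert sel == []


class TestRiskIndex:
    def test_prognostic_signature_unit_expression(self):
        model = sv.RiskModel(
            ["COL3A1", "FOXM1", "PLK4"], [0.5405, 1.6748, -0.9583]
        )
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0]], columns=["COL3A1", "FOXM1", "PLK4"]
        )
        assert sv.risk_index(model, expr).iloc[0] == pytest.approx(1.2570)

    def test_predictive_signature_unit_expression_absolute(self):
        genes = ["ANXA5", "CD44", "NCAM1", "SPP1", "CDCA8", "KIF14"]
        coefs = [-0.87492, 0.50317, 0.46781, 0.54406, -1.70391, 1.54315]
        model = sv.RiskModel(genes, coefs, absolute_value=True)
        expr = pd.DataFrame([[1.0] * 6], columns=genes)
        assert sv.risk_index(model, expr).iloc[0] == pytest.approx(0.47936)
        # the absolute value wraps the signed sum
        expr2 = pd.DataFrame([[0, 0, 0, 0, 1.0, 0]], columns=genes)
        assert sv.risk_index(model, expr2).iloc[0] == pytest.approx(1.70391)

    def test_zero_expression_and_missing_gene(self):
        model = sv.RiskModel(["a", "b"], [1.0, -2.0])
        expr = pd.DataFrame([[0.0, 0.0]], columns=["a", "b"])
        assert sv.risk_index(model, expr).iloc[0] == 0.0
        with pytest.raises(ValueError, match="b"):
            sv.risk_index(model, expr[["a"]])

    def test_coefficient_scaling_equivariance(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        m1 = sv.RiskModel(["a", "b"], [0.5, -1.0])
        m2 = sv.RiskModel(["a", "b"], [1.5, -3.0])
        s1, s2 = sv.risk_index(m1, expr), sv.risk_index(m2, expr)
        np.testing.assert_allclose(3 * s1, s2, atol=1e-12)
        assert ((s1 > s1.median()) == (s2 > s2.median())).all()

    def test_json_round_trip(self):
        model = sv.RiskModel(["a"], [0.25], absolute_value=True, endpoint="RFS")
        assert sv.RiskModel.from_json(model.to_json()) == model


class TestMedianSplit:
    def test_hand_computed_logrank_on_six_patients(self):
        # risk table enumeration for groups A=(2+,4,6), B=(1,3,5+):
        # events at t=1,3,4,6 -> O_A - E_A = 2 - 17/6; V = 221/180
        cohort = _cohort([2, 4, 6, 1, 3, 5], [0, 1, 1, 1, 1, 0],
                         g=[0, 0, 0, 1, 1, 1])
        split = sv.median_split_km_logrank(
            pd.Series([0, 0, 0, 1, 1, 1.0], index=cohort.time.index), cohort
        )
        # by-hand risk table at the event times t = 1, 3, 4, 6 (one event
        # each): group-B at-risk counts, group-A at-risk counts, B's events
        n1 = [3, 2, 1, 0]
        n2 = [3, 2, 2, 1]
        o1 = [1, 1, 0, 0]
        e1 = [a / (a + b) for a, b in zip(n1, n2)]
        var = sum(a * b / (a + b) ** 2 for a, b in zip(n1, n2))
        chi2 = (sum(o1) - sum(e1)) ** 2 / var
        assert split.chi2 == pytest.approx(chi2, rel=1e-6)

    def test_null_rejection_rate(self):
        rej = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cohort = random_cohort(seed + 500, n=80, beta=(0.0,), censor=0.0)
            scores = pd.Series(
                np.random.default_rng(seed).normal(size=80),
                index=cohort.time.index,
            )
            rej += sv.median_split_km_logrank(scores, cohort).p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert abs(rej / n_seeds - 0.05) <= 3 * se

    def test_balanced_groups_and_tie_to_low(self):
        cohort = random_cohort(10, n=101, beta=(0.5,))
        scores = pd.Series(np.arange(101, dtype=float),
                           index=cohort.time.index)
        split = sv.median_split_km_logrank(scores, cohort)
        sizes = split.groups.value_counts()
        assert abs(sizes["high"] - sizes["low"]) <= 1
        assert split.groups.loc[scores.index[50]] == "low"  # median itself

    def test_equal_scores_raise(self):
        cohort = random_cohort(11, n=20, beta=(0.5,))
        with pytest.raises(ValueError, match="equal"):
            sv.median_split_km_logrank(
                pd.Series(1.0, index=cohort.time.index), cohort
            )


class TestTimeDependentROC:
    def test_perfect_ranking_gives_unit_auc(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2, size=100) + 0.01
        cohort = _cohort(t, np.ones(100), g=np.zeros(100))
        scores = pd.Series(-t, index=cohort.time.index)
        roc = sv.time_dependent_roc(scores, cohort, horizons=(1.0, 2.0))
        for h, auc in roc.auc.items():
            assert auc == pytest.approx(1.0)

    def test_random_scores_near_half(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = rng.exponential(3, size=300) + 0.01
            cohort = _cohort(t, (rng.random(300) < 0.8).astype(int),
                             g=np.zeros(300))
            scores = pd.Series(rng.normal(size=300), index=cohort.time.index)
            aucs.append(sv.time_dependent_roc(scores, cohort,
                                              horizons=(3.0,)).auc[3.0])
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_uncensored_reduces_to_empirical_cumulative_dynamic_auc(self):
        rng = np.random.default_rng(1)
        n = 150
        t = rng.exponential(2, size=n) + 0.01
        scores = 0.5 * t + rng.normal(size=n)  # imperfect ranking
        cohort = _cohort(t, np.ones(n), g=np.zeros(n))
        s = pd.Series(-scores, index=cohort.time.index)
        for h in (1.0, 2.0):
            auc = sv.time_dependent_roc(s, cohort, horizons=(h,)).auc[h]
            cases = t <= h
            # plain Mann-Whitney of scores: cases should score higher
            sc, sn = -scores[cases], -scores[~cases]
            grid = sc[:, None] > sn[None, :]
            ties = sc[:, None] == sn[None, :]
            expected = (grid + 0.5 * ties).mean()
            assert auc == pytest.approx(expected, abs=1e-10)

    def test_horizon_beyond_followup_raises(self):
        cohort = _cohort([1, 2, 3, 4], [1, 1, 1, 1], g=[0, 0, 0, 0.0])
        with pytest.raises(ValueError, match="follow-up"):
            sv.time_dependent_roc(
                pd.Series([1, 2, 3, 4.0], index=cohort.time.index),
                cohort, horizons=(10.0,),
            )


class TestCindex:
    def test_perfect_and_tied_scores(self):
        t = np.array([5, 4, 3, 2, 1.0])
        cohort = _cohort(t, np.ones(5), g=np.zeros(5))
        scores = pd.Series(np.arange(5, dtype=float), index=cohort.time.index)
        assert sv.harrell_cindex(scores, cohort) == 1.0
        tied = pd.Series(1.0, index=cohort.time.index)
        assert sv.harrell_cindex(tied, cohort) == 0.5

    def test_censored_example_matches_pair_enumeration(self):
        time = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 0, 1, 1, 0])
        scores = np.array([3.0, 1.0, 2.0, 2.5, 0.5])
        cohort = _cohort(time, event, g=np.zeros(5))
        s = pd.Series(scores, index=cohort.time.index)
        conc = usable = 0
        for i in range(5):
            for j in range(5):
                if time[i] < time[j] and event[i] == 1:
                    usable += 1
                    conc += (scores[i] > scores[j]) + 0.5 * (
                        scores[i] == scores[j]
                    )
        assert sv.harrell_cindex(s, cohort) == pytest.approx(conc / usable)

    def test_matches_lifelines_concordance(self):
        cohort = random_cohort(12, n=200, beta=(0.7,))
        scores = cohort.expression["g0"] * 0.7
        ours = sv.harrell_cindex(scores, cohort)
        theirs = concordance_index(
            cohort.time, -scores, cohort.event
        )
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_usable_pairs_raises(self):
        cohort = _cohort([1, 2, 3.0], [0, 0, 0], g=[1, 2, 3.0])
        with pytest.raises(ValueError, match="usable"):
            sv.harrell_cindex(
                pd.Series([1, 2, 3.0], index=cohort.time.index), cohort
            )


def test_end_to_end_prognostic_pipeline_separates_risk_groups():
    hits = 0
    for seed in range(10):
        cfg = syn.SimConfig(
            seed=seed,
            survival=syn.SurvivalSimConfig(
                n_patients=300, n_genes=61,
                log_hr={"G0001": 0.8, "G0002": -0.9, "G0003": 0.8},
                censoring_rate=0.3,
            ),
        )
        cohort, _ = syn.simulate_survival_cohort(cfg)
        genes = list(cohort.expression.columns)
        sig = [
            g for g in genes
            if sv.cox_univariate(cohort, g).table["p"].iloc[0] < 0.05
        ]
        selected, _ = sv.lasso_cox_select(cohort, sig, iters=10, seed=seed)
        if not selected:
            continue
        _, model = sv.cox_multivariate(cohort, selected)
        scores = sv.risk_index(model, cohort.expression)
        split = sv.median_split_km_logrank(scores, cohort)
        hits += split.p < 0.01
    assert hits >= 9
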