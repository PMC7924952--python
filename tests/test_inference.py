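"""Likelihoods, maximum-likelihood fitting, hazard-ratio tables."""

import math

import numpy as np
import pandas as pd
import pytest

from fractrans import (
    ALLOWED_TRANSITIONS,
    CovariateProfile,
    EventHistoryDataset,
    ModelParameters,
    PanelDataset,
    TransitionRecord,
    TYPICAL_WOMAN_RATES,
    closed_form_mle,
    exact_time_loglik,
    fit_mle,
    hazard_ratio_table,
    panel_loglik,
    records_from_events,
)
from fractrans import simulate as sim
from fractrans.inference import DataValidationError, FittedModel


def _rec(sid, state, entry, exit_, dest, **prof):
    return TransitionRecord(sid, state, entry, exit_, dest,
                            CovariateProfile(**prof))


class TestRecordsFromEvents:
    @staticmethod
    def _frame(rows):
        cols = ["subject_id", "time_years", "state", "age", "sex", "tscore",
                "bmi", "falls", "prior_fx", "cvd", "cancer", "neuro", "ra",
                "copd", "t2d"]
        base = {c: 0 for c in cols[5:]}
        return pd.DataFrame([{**base, "subject_id": sid, "time_years": t,
                              "state": s, "age": 70 + t, "sex": "F",
                              "tscore": -1.5, "bmi": 26.6}
                             for sid, t, s in rows])

    def test_censored_fracture_free(self):
        data = records_from_events(self._frame([("a", 0, 1), ("a", 10, 1)]))
        assert len(data) == 1
        rec = data.records[0]
        assert (rec.state, rec.destination, rec.duration) == (1, None, 10)

    def test_fracture_then_death(self):
        data = records_from_events(
            self._frame([("a", 0, 1), ("a", 4, 2), ("a", 7, 5)]))
        assert len(data) == 2
        first, second = data.records
        assert (first.state, first.entry, first.exit, first.destination) == (1, 0, 4, 2)
        assert (second.state, second.entry, second.exit, second.destination) == (2, 4, 7, 5)
        # age covariate refreshed at state entry
        assert second.profile.age_at_event == pytest.approx(74.0)

    def test_disallowed_jump_names_subject(self):
        with pytest.raises(DataValidationError, match="bad_subj"):
            records_from_events(
                self._frame([("bad_subj", 0, 1), ("bad_subj", 2, 4)]))

    def test_simulated_roundtrip_preserves_sufficient_stats(self, small_cohort):
        _, cohort, data = small_cohort
        frame = sim.cohort_to_long_frame(cohort)
        reparsed = records_from_events(frame)
        assert reparsed.transition_counts() == data.transition_counts()
        for state, t in data.time_at_risk().items():
            assert reparsed.time_at_risk()[state] == pytest.approx(t)


class TestExactTimeLoglik:
    def test_censored_record_is_minus_lambda_t(self, woman_params):
        lam = TYPICAL_WOMAN_RATES[(1, 2)] + TYPICAL_WOMAN_RATES[(1, 5)]
        data = EventHistoryDataset([_rec("a", 1, 0.0, 8.0, None)])
        assert exact_time_loglik(woman_params, data) == pytest.approx(-lam * 8)

    def test_event_record_adds_log_intensity(self, woman_params):
        lam = TYPICAL_WOMAN_RATES[(1, 2)] + TYPICAL_WOMAN_RATES[(1, 5)]
        data = EventHistoryDataset([_rec("a", 1, 0.0, 8.0, 2)])
        expected = -lam * 8 + math.log(TYPICAL_WOMAN_RATES[(1, 2)])
        assert exact_time_loglik(woman_params, data) == pytest.approx(expected)

    def test_zero_intensity_event_is_minus_inf(self):
        rates = dict(TYPICAL_WOMAN_RATES)
        rates[(1, 2)] = 0.0
        params = ModelParameters.from_rates(rates)
        data = EventHistoryDataset([_rec("a", 1, 0.0, 2.0, 2)])
        assert exact_time_loglik(params, data) == -np.inf

    def test_matches_per_record_summation_oracle(self, small_cohort):
        cfg, _, data = small_cohort
        records = data.records[:100]
        subset = EventHistoryDataset(records)
        params = sim.true_parameters(cfg, "F")
        # brute force: loop records, sum hazards one by one
        expected = 0.0
        for rec in records:
            total = 0.0
            for s in subset.state_space.exits(rec.state):
                total += params.intensity(rec.state, s, rec.profile)
            expected -= total * rec.duration
            if rec.destination is not None:
                expected += math.log(
                    params.intensity(rec.state, rec.destination, rec.profile))
        assert exact_time_loglik(params, subset) == pytest.approx(expected, abs=1e-10)

    def test_additive_over_disjoint_subjects(self, small_cohort):
        cfg, _, data = small_cohort
        params = sim.true_parameters(cfg, "F")
        ids = data.subjects()
        a, b = data.subset(ids[:100]), data.subset(ids[100:])
        assert exact_time_loglik(params, a) + exact_time_loglik(params, b) == \
            pytest.approx(exact_time_loglik(params, data))


class TestPanelLoglik:
    def test_same_state_snapshots_closed_form(self, woman_params):
        # from state 4 the only exit is death: P_44(dt) = exp(-q45 dt)
        panel = PanelDataset(snapshots={"a": [(0.0, 4), (3.0, 4)]},
                             profiles={"a": CovariateProfile()})
        assert panel_loglik(woman_params, panel) == pytest.approx(
            -TYPICAL_WOMAN_RATES[(4, 5)] * 3)

    def test_two_step_jump_uses_path_through_middle_state(self, woman_params):
        panel = PanelDataset(snapshots={"a": [(0.0, 1), (2.0, 3)]},
                             profiles={"a": CovariateProfile()})
        ll = panel_loglik(woman_params, panel)
        assert np.isfinite(ll) and ll < 0
        from fractrans import build_generator, transition_probability
        Q = build_generator(woman_params, CovariateProfile())
        assert ll == pytest.approx(math.log(transition_probability(Q, 2.0)[0, 2]))

    def test_fine_grid_panel_approaches_exact_loglik(self):
        """With exactly dated deaths, the panel likelihood on an ever finer
        visit grid converges to the exact-time likelihood.  (Interval-
        censored fractures contribute probabilities rather than densities,
        so the two likelihoods are only commensurable on death events.)"""
        rng = np.random.default_rng(3)
        q15, censor, delta = 0.08, 15.0, 0.05
        rates = dict.fromkeys(ALLOWED_TRANSITIONS, 0.0)
        rates[(1, 5)] = q15
        params = ModelParameters.from_rates(rates)
        records, snapshots, profiles = [], {}, {}
        for i in range(100):
            sid = f"s{i}"
            t_death = rng.exponential(1 / q15)
            died = t_death < censor
            end = t_death if died else censor
            records.append(_rec(sid, 1, 0.0, end, 5 if died else None))
            grid = [(float(v), 1) for v in np.arange(0.0, end, delta)]
            if died:
                grid.append((end, 5))
            else:
                grid.append((end, 1))
            snapshots[sid] = grid
            profiles[sid] = CovariateProfile()
        ll_exact = exact_time_loglik(params, EventHistoryDataset(records))
        ll_panel = panel_loglik(params, PanelDataset(snapshots, profiles))
        assert ll_panel == pytest.approx(ll_exact, rel=0.005)


class TestClosedFormMle:
    def test_rate_is_events_over_time(self):
        data = EventHistoryDataset([
            _rec("a", 4, 0.0, 4.0, 5), _rec("b", 4, 0.0, 5.0, 5),
            _rec("c", 4, 0.0, 1.0, None)])
        params = closed_form_mle(data)
        assert math.exp(params.transitions[(4, 5)].alpha) == pytest.approx(0.2)

    def test_first_fracture_rate_per_1000_py(self):
        # 184 first fractures over 11,968 person-years in state 1
        n, py = 184, 11_968.0
        recs = [_rec(f"s{i}", 1, 0.0, py / n, 2) for i in range(n)]
        params = closed_form_mle(EventHistoryDataset(recs))
        q12 = math.exp(params.transitions[(1, 2)].alpha)
        assert q12 == pytest.approx(0.0154, abs=5e-5)
        assert round(1000 * q12) == 15

    def test_zero_events_hits_boundary(self):
        data = EventHistoryDataset([_rec("a", 1, 0.0, 10.0, None)])
        params = closed_form_mle(data)
        assert params.transitions[(1, 2)].boundary
        assert params.transitions[(1, 2)].rate(CovariateProfile()) == 0.0


class TestFitMle:
    def test_no_covariate_fit_equals_closed_form(self, small_cohort):
        _, _, data = small_cohort
        fit = fit_mle(data)
        closed = closed_form_mle(data)
        for key, tp in fit.params.transitions.items():
            if tp.boundary:
                assert closed.transitions[key].boundary
                continue
            a, b = math.exp(tp.alpha), math.exp(closed.transitions[key].alpha)
            assert a == pytest.approx(b, rel=1e-4)  # 4 significant figures

    def test_loglik_field_matches_likelihood_at_estimate(self, small_cohort):
        _, _, data = small_cohort
        fit = fit_mle(data, covariates=("age",))
        assert fit.loglik == pytest.approx(exact_time_loglik(fit.params, data))

    def test_score_vanishes_at_optimum(self, small_cohort):
        _, _, data = small_cohort
        fit = fit_mle(data, covariates=("age", "tscore"))
        eps = 1e-5
        for key, tp in fit.params.transitions.items():
            if tp.boundary:
                continue
            base = tp.alpha
            tp.alpha = base + eps
            up = exact_time_loglik(fit.params, data)
            tp.alpha = base - eps
            down = exact_time_loglik(fit.params, data)
            tp.alpha = base
            n_ev = max(fit.n_events[key], 1)
            assert abs(up - down) / (2 * eps) / n_ev < 1e-4

    def test_large_sample_recovery_within_3_se(self):
        cfg = sim.default_config(n_women=25_000, n_men=0)
        baseline = sim.sample_baseline(cfg, 7)
        cohort = sim.simulate_paths(cfg, baseline, 8)
        data = sim.apply_observation(cohort, "exact")
        fit = fit_mle(data, covariates=("age", "tscore"))
        truth = sim.true_parameters(cfg, "F")
        for key, tp in fit.params.transitions.items():
            assert abs(tp.alpha - truth.transitions[key].alpha) < \
                3 * fit.se_alpha(*key)
            for c in ("age", "tscore"):
                assert abs(tp.beta[c] - truth.transitions[key].beta[c]) < \
                    3 * fit.se_beta(*key, c)

    def test_no_deaths_flags_boundaries(self):
        recs = [_rec(f"s{i}", 1, 0.0, 5.0, 2 if i < 3 else None)
                for i in range(10)]
        fit = fit_mle(EventHistoryDataset(recs))
        for key in ((1, 5), (2, 5), (3, 5), (4, 5)):
            assert fit.params.transitions[key].boundary

    def test_matches_statsmodels_poisson_glm(self, small_cohort):
        """Independent oracle: the exact-time likelihood of one transition
        is a Poisson GLM with log person-time offset."""
        import statsmodels.api as sm

        _, _, data = small_cohort
        covs = ("age", "tscore")
        fit = fit_mle(data, covariates=covs)
        coding = fit.params.coding
        recs = [r for r in data.records if r.state == 1]
        X = np.column_stack([np.ones(len(recs))] +
                            [[coding.encode(r.profile)[c] for r in recs]
                             for c in covs])
        y = np.array([1.0 if r.destination == 2 else 0.0 for r in recs])
        off = np.log([r.duration for r in recs])
        glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
        tp = fit.params.transitions[(1, 2)]
        assert tp.alpha == pytest.approx(glm.params[0], abs=1e-6)
        assert tp.beta["age"] == pytest.approx(glm.params[1], abs=1e-6)
        assert tp.beta["tscore"] == pytest.approx(glm.params[2], abs=1e-6)
        assert fit.se_alpha(1, 2) == pytest.approx(glm.bse[0], rel=1e-4)


class TestHazardRatioTable:
    @staticmethod
    def _fit_with(beta, var):
        params = ModelParameters.from_rates(
            TYPICAL_WOMAN_RATES, beta={key: {"male": beta}
                                       for key in ALLOWED_TRANSITIONS})
        cov = {key: np.diag([0.01, var]) for key in ALLOWED_TRANSITIONS}
        return FittedModel(params=params, covariance=cov, loglik=0.0,
                           converged=True, covariates=("male",),
                           n_events=dict.fromkeys(ALLOWED_TRANSITIONS, 10))

    def test_null_coefficient(self):
        table = hazard_ratio_table(self._fit_with(0.0, 0.04))
        row = table[(table.from_state == 1) & (table.to_state == 2)].iloc[0]
        assert row.hr == pytest.approx(1.0)
        assert row.ci_low < 1 < row.ci_high
        assert not row.significant

    def test_post_fracture_mortality_hr(self):
        # HR 2.40 with SE 0.1487 on the log scale -> 95% CI 1.79-3.21
        table = hazard_ratio_table(self._fit_with(math.log(2.40), 0.1487**2))
        row = table[(table.from_state == 2) & (table.to_state == 5)].iloc[0]
        assert row.hr == pytest.approx(2.40)
        assert row.ci_low == pytest.approx(1.79, abs=0.005)
        assert row.ci_high == pytest.approx(3.21, abs=0.005)
        assert row.significant

    def test_ci_matches_direct_normal_quantiles(self):
        b, se = 0.31, 0.12
        table = hazard_ratio_table(self._fit_with(b, se**2))
        row = table.iloc[0]
        assert row.ci_low == pytest.approx(math.exp(b - 1.96 * se))
        assert row.ci_high == pytest.approx(math.exp(b + 1.96 * se))
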