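import dataclasses

import numpy as np
import pytest

import oligocea as oc
from oligocea.params import ValidationError

from conftest import constant_lifetable, with_settings, with_strategy


class TestShortRun:
    def test_surgery_expected_acute_cost(self, base_config):
        cost, util = oc.short_run(base_config.strategy("surgery"),
                                  base_config.settings)
        # 19,389 * (1 + 0.01) — a failed first session repeats the full cost
        assert cost == pytest.approx(19_582.89)
        assert util == 0.70

    def test_rfa_expected_acute_cost(self, base_config):
        cost, _ = oc.short_run(base_config.strategy("RFA"),
                               base_config.settings)
        assert cost == pytest.approx(11_972.23)  # 11,189 * 1.07

    def test_certain_first_session_has_no_second_cost(self, base_config):
        strat = with_strategy(base_config.strategy("MWA"), p_success_first=1.0)
        cost, _ = oc.short_run(strat, base_config.settings)
        assert cost == oc.total_treatment_cost(strat, base_config.settings)


class TestTransitionMatrix:
    def test_surgery_cycle1_no_recurrence_row(self, base_config, lifetable):
        p = oc.build_transition_matrix(base_config.strategy("surgery"),
                                       base_config.settings, lifetable,
                                       cycle=1, age=73)
        np.testing.assert_allclose(p[0], [0.8425, 0.025, 0.05, 0.0825])

    def test_rows_sum_to_one(self, base_config, lifetable):
        for strat in base_config:
            for cycle, age in [(1, 73), (2, 74), (15, 87), (27, 99)]:
                p = oc.build_transition_matrix(strat, base_config.settings,
                                               lifetable, cycle, age)
                np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
                assert np.all((p >= 0) & (p <= 1))

    def test_death_row_absorbing(self, base_config, lifetable):
        p = oc.build_transition_matrix(base_config.strategy("RFA"),
                                       base_config.settings, lifetable, 5, 77)
        np.testing.assert_array_equal(p[3], [0, 0, 0, 1])

    def test_hepatic_death_is_flat_state_probability(self, base_config,
                                                     zero_lifetable):
        p = oc.build_transition_matrix(base_config.strategy("MWA"),
                                       base_config.settings, zero_lifetable,
                                       cycle=3, age=75)
        assert p[1, 3] == pytest.approx(0.12)
        assert p[2, 3] == pytest.approx(0.05)

    def test_compounding_variant_combines_with_background(self, base_config):
        settings = dataclasses.replace(
            base_config.settings,
            recurrence_mortality_compounds_background=True)
        table = constant_lifetable(0.1)
        p = oc.build_transition_matrix(base_config.strategy("MWA"), settings,
                                       table, cycle=3, age=75)
        assert p[1, 3] == pytest.approx(1 - 0.9 * 0.88)
        assert p[2, 3] == pytest.approx(1 - 0.9 * 0.95)

    def test_cycle2_uses_background_mortality(self, base_config, lifetable):
        strat = base_config.strategy("surgery")
        p = oc.build_transition_matrix(strat, base_config.settings, lifetable,
                                       cycle=2, age=80)
        assert p[0, 3] == pytest.approx(lifetable.qx_at(80))

    def test_outgoing_sum_above_one_raises(self, base_config):
        strat = with_strategy(base_config.strategy("RFA"),
                              p_hepatic_recurrence=0.05)
        table = constant_lifetable(0.95)
        with pytest.raises(ValidationError, match="> 1"):
            oc.build_transition_matrix(strat, base_config.settings, table,
                                       cycle=2, age=80)


class TestRunCohortClosedForms:
    def test_immortal_perfect_health_accrues_full_horizon(self, base_config,
                                                          zero_lifetable):
        strat = with_strategy(base_config.strategy("MWA"), p_success_first=1.0,
                              qol_first_month=1.0, mortality_year1=0.0,
                              p_hepatic_recurrence=0.0, p_other_recurrence=0.0)
        settings = dataclasses.replace(base_config.settings, discount_rate=0.0)
        out = oc.run_cohort(strat, settings, zero_lifetable)
        assert out.expected_qaly == pytest.approx(27.0, abs=1e-12)

    @pytest.mark.parametrize("q,r", [(0.05, 0.03), (0.2, 0.0), (0.0, 0.1)])
    def test_geometric_annuity_closed_form(self, base_config, q, r):
        # constant hazard, no recurrence, utility 1: the discounted QALY sum
        # is a geometric series plus the first-cycle one-month adjustment
        qol1 = 0.7
        strat = with_strategy(base_config.strategy("surgery"),
                              mortality_year1=q, p_hepatic_recurrence=0.0,
                              p_other_recurrence=0.0, qol_first_month=qol1)
        settings = dataclasses.replace(
            base_config.settings, discount_rate=r,
            first_cycle_utility="one_month_blend",
            half_cycle_correction=False)
        n = settings.n_cycles
        out = oc.run_cohort(strat, settings, constant_lifetable(q))
        ratio = (1 - q) / (1 + r)
        series = sum(ratio ** (t - 1) for t in range(1, n + 1))
        expected = series + (qol1 / 12 + 11 / 12 - 1.0)
        assert out.expected_qaly == pytest.approx(expected, abs=1e-9)

    def test_half_cycle_annuity_closed_form(self, base_config):
        q, r, qol1 = 0.08, 0.03, 0.9
        strat = with_strategy(base_config.strategy("surgery"),
                              mortality_year1=q, p_hepatic_recurrence=0.0,
                              p_other_recurrence=0.0, qol_first_month=qol1)
        settings = dataclasses.replace(base_config.settings, discount_rate=r,
                                       first_cycle_utility="full_year",
                                       half_cycle_correction=True)
        n = settings.n_cycles
        surv = (1 - q) ** np.arange(n + 1)
        disc = (1 + r) ** -np.arange(n)
        u = np.ones(n)
        u[0] = qol1
        expected = float(np.sum(disc * u * 0.5 * (surv[:-1] + surv[1:])))
        out = oc.run_cohort(strat, settings, constant_lifetable(q))
        assert out.expected_qaly == pytest.approx(expected, abs=1e-9)


class TestCohortInvariants:
    def test_occupancy_conservation_and_monotone_death(self, base_outcomes):
        for out in base_outcomes:
            occ = out.trace.occupancy
            np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(np.diff(occ[:, oc.HealthState.DEATH]) >= -1e-15)
            assert np.all(occ >= -1e-15)

    def test_conservation_holds_on_random_configs(self, lifetable):
        for seed in range(20):
            cfg = oc.random_config(seed)
            for out in oc.run_all(cfg, lifetable):
                occ = out.trace.occupancy
                np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-9)
                assert np.all(np.diff(occ[:, oc.HealthState.DEATH]) >= -1e-12)

    def test_qaly_monotone_in_discount_rate(self, base_config, lifetable):
        strat = base_config.strategy("MWA")
        qalys = [oc.run_cohort(strat,
                               dataclasses.replace(base_config.settings,
                                                   discount_rate=r),
                               lifetable).expected_qaly
                 for r in (0.0, 0.01, 0.03, 0.05, 0.1)]
        assert all(a >= b for a, b in zip(qalys, qalys[1:]))

    def test_raising_hepatic_recurrence_never_helps(self, base_config,
                                                    lifetable):
        settings = base_config.settings
        base = base_config.strategy("MWA")
        prev_qaly, prev_rec_years = np.inf, -np.inf
        for p_hep in (0.0, 0.02, 0.05, 0.1, 0.2):
            out = oc.run_cohort(with_strategy(base, p_hepatic_recurrence=p_hep),
                                settings, lifetable)
            rec_years = out.trace.occupancy[:, 1:3].sum()
            assert out.expected_qaly <= prev_qaly + 1e-12
            assert rec_years >= prev_rec_years - 1e-12
            prev_qaly, prev_rec_years = out.expected_qaly, rec_years

    def test_cost_at_least_short_run_and_qaly_bounded(self, base_config,
                                                      base_outcomes):
        for out, strat in zip(base_outcomes, base_config):
            acute, _ = oc.short_run(strat, base_config.settings)
            assert out.expected_cost >= acute
            assert 0 <= out.expected_qaly <= base_config.settings.n_cycles


class TestRunAll:
    def test_one_outcome_per_strategy_in_order(self, base_config,
                                               base_outcomes):
        assert [o.strategy for o in base_outcomes] == ["surgery", "RFA", "MWA"]

    def test_identical_strategies_identical_outcomes(self, base_config,
                                                     lifetable):
        twin = with_strategy(base_config.strategy("MWA"), name="MWA2")
        cfg = oc.ModelConfig(settings=base_config.settings,
                             strategies=(base_config.strategy("MWA"), twin))
        a, b = oc.run_all(cfg, lifetable)
        assert a.expected_cost == b.expected_cost
        assert a.expected_qaly == b.expected_qaly

    def test_base_case_cost_ordering(self, base_outcomes):
        costs = {o.strategy: o.expected_cost for o in base_outcomes}
        assert costs["MWA"] < costs["RFA"] < costs["surgery"]

    def test_trace_export_schema(self, base_outcomes, tmp_path):
        path = tmp_path / "trace.csv"
        base_outcomes[0].trace.write_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df.columns) == ["cycle", "age", "occ_no_recurrence",
                                    "occ_hepatic", "occ_other", "occ_death",
                                    "cost_increment", "qaly_increment"]
        assert len(df) == 27
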