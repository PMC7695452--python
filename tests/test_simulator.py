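"""Stochastic germarium model: determinism, conservation laws, and
agreement with the estimator's forward model."""

import dataclasses
import io

import numpy as np
import pytest
from scipy import stats as sps

from fsclineage.estimators import estimate_pfc, forward_conversion_probability
from fsclineage.io import write_scoring_table
from fsclineage.model import EmptyTableError, LabelingConfig, ScoringTable
from fsclineage.simulator import (
    SimConfig,
    control_params,
    init_germarium,
    simulate_cohort,
    snapshot,
    step_cycle,
    summarize_cohort,
)
from fsclineage.stats import binomial_labeling_pmf

from conftest import make_obs


def table_bytes(table: ScoringTable) -> str:
    buf = io.StringIO()
    write_scoring_table(table, buf)
    return buf.getvalue()


class TestControlParams:
    def test_expected_divisions_near_seven(self):
        p = control_params()
        divisions = sum(c * q for c, q in zip(p.census, p.q_div))
        assert divisions == pytest.approx(6.83, abs=0.05)

    def test_census_and_probabilities(self):
        p = control_params()
        assert p.census == (8, 5, 3)
        assert all(0 <= q <= 1 for q in p.q_div)
        assert p.q_div[0] > p.q_div[1] > p.q_div[2]  # posterior-to-anterior gradient
        assert p.p_fc == 0.616

    def test_expected_ec_output(self):
        p = control_params()
        anterior = p.census[1] + p.census[2]
        assert anterior * p.p_ec == pytest.approx(1.4, abs=0.01)


class TestInit:
    def test_zero_mean_labels_nothing(self):
        state = init_germarium(control_params(), LabelingConfig(mean_labeled=0.0),
                               np.random.default_rng(0))
        assert state.n_marked_fsc == 0

    def test_full_mean_labels_everything(self):
        state = init_germarium(control_params(), LabelingConfig(mean_labeled=16.0),
                               np.random.default_rng(0))
        assert state.n_marked_fsc == 16

    def test_marked_count_distribution_is_binomial(self):
        """Goodness of fit of initial marked counts against the binomial
        labeling pmf (chi-squared at alpha = 0.01)."""
        params, labeling = control_params(), LabelingConfig()
        rng = np.random.default_rng(7)
        n_init = 40_000
        counts = np.bincount(
            [init_germarium(params, labeling, rng).n_marked_fsc for _ in range(n_init)],
            minlength=17,
        )
        expected = binomial_labeling_pmf(16, 3.2) * n_init
        # pool the sparse upper tail so every expected cell is >= 5
        keep = 10
        obs = np.append(counts[:keep], counts[keep:].sum())
        exp = np.append(expected[:keep], expected[keep:].sum())
        stat = ((obs - exp) ** 2 / exp).sum()
        assert sps.chi2.sf(stat, len(obs) - 1) > 0.01


class TestStepCycle:
    def test_census_restored_every_cycle(self):
        params = control_params()
        rng = np.random.default_rng(1)
        state = init_germarium(params, LabelingConfig(), rng)
        for _ in range(30):
            step_cycle(state, params, rng)
            counts = [0, 0, 0]
            for f in state.fscs:
                counts[f.layer - 1] += 1
            assert tuple(counts) == params.census

    def test_no_sinks_conserves_marked_count_exactly(self):
        """With all conversion and turnover switched off, marked and total
        counts are invariant over any number of cycles."""
        params = dataclasses.replace(
            control_params(), p_fc=0.0, p_ec=0.0, ec_return=0.0, ec_death=0.0
        )
        rng = np.random.default_rng(2)
        state = init_germarium(params, LabelingConfig(), rng)
        marked0 = state.n_marked_fsc
        for _ in range(20):
            step_cycle(state, params, rng)
            assert state.n_marked_fsc == marked0
            assert len(state.fscs) == 16

    def test_certain_conversion_without_division_empties_layer1(self):
        """q = 0 and p_fc = 1: every layer-1 resident converts in one cycle
        and layer 1 is refilled entirely from layer 2."""
        params = dataclasses.replace(
            control_params(), q_div=(0.0, 0.0, 0.0), p_fc=1.0, p_ec=0.0,
            ec_return=0.0, ec_death=0.0,
        )
        rng = np.random.default_rng(3)
        state = init_germarium(params, LabelingConfig(mean_labeled=16.0), rng)
        step_cycle(state, params, rng)
        assert state.marked_fc_last_cycle == 8  # the whole starting layer 1
        # census restored by promotion and compensatory division
        counts = [0, 0, 0]
        for f in state.fscs:
            counts[f.layer - 1] += 1
        assert tuple(counts) == params.census

    def test_single_marked_fsc_matches_forward_probability(self):
        """Monte-Carlo per-cycle marked-FC probability for one marked
        cycle-start layer-1 FSC equals the analytic forward formula."""
        params = control_params()
        rng = np.random.default_rng(4)
        trials = 60_000
        hits = 0
        for _ in range(trials):
            state = init_germarium(params, LabelingConfig(mean_labeled=0.0), rng)
            state.fscs[0].marked = True
            assert state.fscs[0].layer == 1
            step_cycle(state, params, rng)
            hits += state.marked_fc_last_cycle >= 1
        expected = forward_conversion_probability(params.p_fc, params.q_div[0])
        se = np.sqrt(expected * (1 - expected) / trials)
        assert abs(hits / trials - expected) < 3.5 * se


class TestSnapshot:
    def test_unmarked_state_gives_all_zero_observation(self):
        params = control_params()
        rng = np.random.default_rng(5)
        state = init_germarium(params, LabelingConfig(mean_labeled=0.0), rng)
        step_cycle(state, params, rng)
        obs = snapshot(state, params, rng)
        assert obs.n_marked_fsc == 0 and obs.n_marked_ec == 0
        assert not obs.immediate_fc_present and not obs.any_fc_present

    def test_full_edu_index_labels_every_marked_fsc(self):
        params = dataclasses.replace(control_params(), edu_index=(1.0, 1.0, 1.0))
        rng = np.random.default_rng(6)
        state = init_germarium(params, LabelingConfig(mean_labeled=16.0), rng)
        obs = snapshot(state, params, rng)
        assert (obs.edu_l1, obs.edu_l2, obs.edu_l3) == (
            obs.n_marked_l1, obs.n_marked_l2, obs.n_marked_l3,
        )

    def test_edu_fractions_match_layer_indices(self):
        """Aggregate EdU fractions of marked FSCs across many snapshots
        match the per-layer indices within sampling error."""
        params = control_params()
        cfg = SimConfig(params=params, labeling=LabelingConfig(),
                        n_germaria=3000, snapshot_days=(6.0,), seed=11)
        table = simulate_cohort(cfg)
        summary = summarize_cohort(table)[0]
        for observed, expected in zip(summary["edu_index_by_layer"], params.edu_index):
            assert observed == pytest.approx(expected, abs=0.025)


class TestCohort:
    def test_same_seed_reproduces_byte_identical_tables(self):
        cfg = SimConfig(params=control_params(), labeling=LabelingConfig(),
                        n_germaria=40, snapshot_days=(6.0, 12.0), seed=99)
        assert table_bytes(simulate_cohort(cfg)) == table_bytes(simulate_cohort(cfg))

    def test_different_seeds_differ(self):
        base = dict(params=control_params(), labeling=LabelingConfig(),
                    n_germaria=40, snapshot_days=(6.0,))
        t1 = simulate_cohort(SimConfig(seed=1, **base))
        t2 = simulate_cohort(SimConfig(seed=2, **base))
        assert table_bytes(t1) != table_bytes(t2)

    def test_row_count_and_day_blocks(self):
        cfg = SimConfig(params=control_params(), labeling=LabelingConfig(),
                        n_germaria=25, snapshot_days=(6.0, 12.0), seed=1)
        table = simulate_cohort(cfg)
        assert len(table) == 50
        days = [o.day for o in table]
        assert days == [6.0] * 25 + [12.0] * 25

    def test_edu_absent_outside_edu_days(self):
        cfg = SimConfig(params=control_params(), labeling=LabelingConfig(),
                        n_germaria=10, snapshot_days=(6.0, 12.0), seed=1)
        table = simulate_cohort(cfg)
        for o in table:
            if o.day == 12.0:
                assert o.edu_l1 is None and o.edu_ec is None
            else:
                assert o.edu_l1 is not None

    def test_fractional_day_rejected(self):
        with pytest.raises(ValueError, match="whole number"):
            SimConfig(params=control_params(), labeling=LabelingConfig(),
                      n_germaria=5, snapshot_days=(6.2,), seed=1)

    def test_parameter_recovery_single_cohort(self):
        """The immediate-FC estimator recovers the generating conversion
        probability from one simulated cohort at control parameters."""
        params = control_params()
        cfg = SimConfig(params=params, labeling=LabelingConfig(),
                        n_germaria=1750, snapshot_days=(6.0,), seed=0)
        table = simulate_cohort(cfg)
        est = estimate_pfc(table, 25.1, 33.4, day=6.0)
        assert abs(est.p_hat - params.p_fc) < 0.05
        assert est.n_informative > 400

    def test_variance_grows_while_mean_is_conserved(self):
        """Neutral drift: the marked-FSC mean stays flat from 6 d to 12 d
        while the across-germaria variance keeps growing."""
        cfg = SimConfig(params=control_params(), labeling=LabelingConfig(),
                        n_germaria=700, snapshot_days=(6.0, 12.0), seed=21)
        summary = summarize_cohort(simulate_cohort(cfg))
        s6 = next(s for s in summary if s["day"] == 6.0)
        s12 = next(s for s in summary if s["day"] == 12.0)
        binom_var = 16 * 0.2 * 0.8
        assert s6["var_marked_fsc"] > 2 * binom_var
        assert s12["var_marked_fsc"] > s6["var_marked_fsc"]
        sem = np.sqrt(s12["var_marked_fsc"] / 700)
        assert abs(s12["mean_marked_fsc"] - s6["mean_marked_fsc"]) < 2.5 * sem


class TestSummaries:
    def test_empty_table_rejected(self):
        with pytest.raises(EmptyTableError):
            summarize_cohort(ScoringTable())

    def test_all_zero_observations(self):
        table = ScoringTable(observations=[
            make_obs(gid=f"g{i}", l1=0, l2=0, l3=0) for i in range(4)
        ])
        summary = summarize_cohort(table)[0]
        assert summary["mean_marked_fsc"] == 0.0
        assert summary["frac_with_marked_fsc"] == 0.0
        assert summary["layer_occupancy"] == [0.0, 0.0, 0.0]

    def test_layer_proportions(self):
        table = ScoringTable(observations=[make_obs("g1", l1=2, l2=1, l3=1)])
        summary = summarize_cohort(table)[0]
        assert summary["layer_occupancy"] == [0.5, 0.25, 0.25]
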