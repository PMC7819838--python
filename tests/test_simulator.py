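"""Semi-Markov generator: determinism, degenerate configs, occupancy, realism."""

import numpy as np
import pytest

from neosleep import (
    DurationLaw,
    SimConfig,
    SubjectCovariates,
    expected_occupancy,
    extract_bouts,
    sample_bout_frame,
    simulate_cohort,
    simulate_subject,
    state_percentages,
    transition_table,
)
from neosleep.hypnogram import _runs, enforce_min_state_rule


class TestConfigValidation:
    def test_transition_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(transition_probs={"W": {"AS": 0.9}})

    def test_self_transition_rejected(self):
        with pytest.raises(ValueError, match="self-transition"):
            SimConfig(transition_probs={"W": {"W": 1.0}})

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SimConfig(nextstate_factor_as=-1.0)

    def test_round_trips_through_dict(self):
        cfg = SimConfig()
        assert SimConfig.from_dict(cfg.to_dict()).to_dict() == cfg.to_dict()


class TestDeterminism:
    def test_same_seed_same_hypnogram(self, default_config):
        cov = SubjectCovariates(pma_weeks=33.0, cortisol_ug_dl=0.3)
        a = simulate_subject(default_config, cov, 42)
        b = simulate_subject(default_config, cov, 42)
        assert a.states == b.states
        assert [(e.kind, e.time_min) for e in a.events] == [
            (e.kind, e.time_min) for e in b.events
        ]

    def test_cohort_bit_identical(self, default_config):
        a = simulate_cohort(default_config, 12, seed=9)
        b = simulate_cohort(default_config, 12, seed=9)
        for ha, hb in zip(a.hypnograms, b.hypnograms):
            assert ha.states == hb.states
            assert ha.covariates == hb.covariates

    def test_single_subject_cohort_reduces_to_simulate_subject(self, default_config):
        cohort = simulate_cohort(default_config, 1, seed=5)
        rng = np.random.default_rng(np.random.SeedSequence(5).spawn(1)[0])
        from neosleep.simulate import default_covariate_sampler

        covs = default_covariate_sampler(rng)
        h = simulate_subject(default_config, covs, rng, subject_id="S0001")
        assert cohort.hypnograms[0].states == h.states

    def test_seed_changes_data(self, default_config):
        a = simulate_cohort(default_config, 5, seed=1)
        b = simulate_cohort(default_config, 5, seed=2)
        assert any(
            ha.states != hb.states for ha, hb in zip(a.hypnograms, b.hypnograms)
        )


class TestDegenerateConfig:
    def test_point_mass_cycle_alternates_exactly(self):
        cfg = SimConfig(
            duration_laws={
                "AS": DurationLaw("fixed", {"value": 10.0}),
                "QS": DurationLaw("fixed", {"value": 10.0}),
            },
            transition_probs={"AS": {"QS": 1.0}, "QS": {"AS": 1.0}},
            pma_factors={},
            nextstate_factor_as=1.0,
            ts_insertion_prob=0.0,
            lance_prob=0.0,
            non_noxious_prob=0.0,
            recording_min_range=(60.0, 60.0),
        )
        h = simulate_subject(cfg, SubjectCovariates(), 7)
        runs = _runs(h.states)
        # 10-minute point-mass bouts are 20 epochs; the first run is the
        # residual of the equilibrium in-progress bout, the last is truncated
        for state, _, length in runs[1:-1]:
            assert length == 20
        assert all(a != b for (a, _, _), (b, _, _) in zip(runs, runs[1:]))
        assert set(s for s, _, _ in runs) <= {"AS", "QS"}

    def test_no_lances_means_no_lance_events(self, quiet_config):
        h = simulate_subject(quiet_config, SubjectCovariates(pma_weeks=30.0), 3)
        assert h.events == []


class TestOccupancy:
    def test_symmetric_two_state_cycle(self):
        cfg = SimConfig(
            duration_laws={
                "AS": DurationLaw("fixed", {"value": 5.0}),
                "QS": DurationLaw("fixed", {"value": 5.0}),
            },
            transition_probs={"AS": {"QS": 1.0}, "QS": {"AS": 1.0}},
            pma_factors={},
            nextstate_factor_as=1.0,
            ts_insertion_prob=0.0,
        )
        occ = expected_occupancy(cfg, include_ts=False)
        assert occ["AS"] == pytest.approx(0.5)
        assert occ["QS"] == pytest.approx(0.5)

    def test_default_ordering_in_very_preterm(self, default_config):
        occ = expected_occupancy(default_config, SubjectCovariates(pma_weeks=30.0))
        assert occ["AS"] > occ["QS"] > occ["W"]

    def test_reducible_chain_rejected(self):
        cfg = SimConfig(
            transition_probs={"W": {"AS": 1.0}, "AS": {"W": 1.0}, "QS": {"AS": 1.0}}
        )
        with pytest.raises(ValueError, match="reducible"):
            expected_occupancy(cfg)

    def test_monte_carlo_matches_analytic(self, quiet_config):
        cov = SubjectCovariates(pma_weeks=30.0)
        cohort = simulate_cohort(
            quiet_config, 200, covariate_sampler=lambda r: cov, seed=0
        )
        expected = expected_occupancy(quiet_config, cov)
        for state in ("W", "AS", "TS", "QS"):
            empirical = float(
                np.mean([state_percentages(h)[state] for h in cohort.hypnograms])
            )
            assert empirical == pytest.approx(expected[state], abs=0.02)


@pytest.fixture(scope="module")
def big_table(quiet_config):
    cohort = simulate_cohort(quiet_config, 400, seed=17)
    bouts = []
    for h in cohort.hypnograms:
        h.states = enforce_min_state_rule(h.states)
        bouts.extend(extract_bouts(h))
    return transition_table(bouts)


class TestCohortRealism:
    def test_active_sleep_censoring_exceeds_quiet_sleep(self, big_table):
        # short recordings rarely outlast an active-sleep bout
        as_frac = big_table.loc["AS", "censored"] / big_table.loc["AS"].sum()
        qs_frac = big_table.loc["QS", "censored"] / big_table.loc["QS"].sum()
        assert as_frac > qs_frac + 0.2

    def test_quiet_sleep_returns_to_active_sleep(self, big_table):
        observed = big_table.loc["QS", ["W", "AS", "QS"]].sum()
        assert observed >= 20
        assert big_table.loc["QS", "AS"] / observed > 0.9  # truth is 117/118

    def test_wake_always_offsets_into_active_sleep(self, big_table):
        assert big_table.loc["W", "QS"] == 0


class TestBoutSampler:
    def test_destination_effect_applied(self, default_config, rng):
        frame = sample_bout_frame(
            default_config, "AS", 4000, rng, draw_destination=True
        )
        logs = np.log(frame["duration_min"])
        diff = logs[frame["dest_qs"] > 0].mean() - logs[frame["dest_qs"] == 0].mean()
        assert diff == pytest.approx(np.log(1.602), abs=0.06)

    def test_censor_range_produces_censoring(self, default_config, rng):
        frame = sample_bout_frame(
            default_config, "AS", 2000, rng, censor_range=(30, 70)
        )
        frac = 1.0 - frame["event_observed"].mean()
        assert 0.45 < frac < 0.7  # heavy censoring, as for active sleep

    def test_pma_factor_shifts_durations(self, default_config, rng):
        lo = sample_bout_frame(default_config, "W", 3000, rng, pma=30.0)
        hi = sample_bout_frame(default_config, "W", 3000, rng, pma=40.0)
        ratio = np.log(hi["duration_min"]).mean() - np.log(lo["duration_min"]).mean()
        assert ratio == pytest.approx(10 * np.log(1.146), abs=0.1)

    def test_destination_draw_only_for_active_sleep(self, default_config, rng):
        with pytest.raises(ValueError):
            sample_bout_frame(default_config, "W", 10, rng, draw_destination=True)
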