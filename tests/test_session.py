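"""Closed-loop sessions, experiments and the event-log round trip."""

import dataclasses

import numpy as np
import pytest

from runsync import (
    ConfigurationError,
    EventLogParseError,
    ExperimentDesign,
    Protocol,
    StrategyConfig,
    default_conditions,
    default_runner_params,
    estimate_cadence,
    read_event_log,
    run_experiment,
    run_session,
    write_event_log,
)
from runsync.session import _per_song_cadence_change

SHORT = Protocol(silence_duration=15.0, n_songs=2, song_duration=25.0)


class TestProtocol:
    def test_total_and_song_starts(self):
        p = Protocol()
        assert p.total == 300.0
        assert list(p.song_starts()) == [25.0, 80.0, 135.0, 190.0, 245.0]

    def test_segment_lookup(self):
        p = Protocol()
        assert p.segment_of(10.0) == 0
        assert p.segment_of(25.0) == 1
        assert p.segment_of(299.9) == 5


class TestRunSession:
    def test_decoupled_runner_step_count_independent_of_strategy(self):
        # drift disabled: strategy-specific rng streams would otherwise give
        # each condition a different comfort-tempo random walk
        params = default_runner_params(k_slow=0.0, k_fast=0.0, sigma_drift=0.0)
        counts = []
        for cond in default_conditions():
            log = run_session(params, cond, seed=5)
            counts.append(len(log.steps))
        expected = 300.0 / params.preferred_period
        assert all(abs(c - expected) < 0.01 * expected for c in counts)

    def test_determinism(self):
        params = default_runner_params()
        cond = StrategyConfig("S4", target_phase_deg=-70.0)
        a = run_session(params, cond, seed=123)
        b = run_session(params, cond, seed=123)
        assert np.array_equal(a.steps.times, b.steps.times)
        assert np.array_equal(a.beats.times, b.beats.times)

    def test_no_beats_during_silence_and_segment_bookkeeping(self):
        log = run_session(default_runner_params(), StrategyConfig("S2"), seed=3)
        assert np.all(log.beats.times >= log.protocol.silence_duration)
        assert np.all(log.beats.segments >= 1)
        # per-segment step counts cover the whole session
        total = sum(
            len(log.steps.for_segment(s)) for s in range(log.protocol.n_songs + 1)
        )
        assert total == len(log.steps)

    def test_silence_cadence_matches_preferred(self):
        params = default_runner_params()
        changes = []
        for seed in range(10):
            log = run_session(params, StrategyConfig("S1"), seed=seed)
            silence = log.steps.for_segment(0)
            changes.append(
                estimate_cadence(silence.times) - 60.0 / params.preferred_period
            )
        assert abs(np.mean(changes)) < 1.0  # SPM

    def test_forced_negative_phase_builds_negative_cadence_change(self):
        # deterministic runner: the slow-down grows over songs and saturates
        params = default_runner_params(sigma_motor=0.0, sigma_drift=0.0)
        log = run_session(params, StrategyConfig("S4", target_phase_deg=-70.0), seed=0)
        by_song = _per_song_cadence_change(log)
        values = [by_song[s] for s in sorted(by_song)]
        assert all(v < 0 for v in values)
        assert values[0] > values[-1]  # influence builds over time
        # saturation: late-song increments are tiny vs the first one
        assert abs(values[-1] - values[-2]) < 0.1 * abs(values[1] - values[0] - 1e-12) + 0.05

    def test_cadence_leaving_band_aborts(self):
        # absurd coupling gain: the S0 phase sweep drags the underlying rate
        # below 100 SPM as soon as it passes the steep side of the basin
        params = default_runner_params(
            k_slow=0.9, gamma=1.0, basin_halfwidth=180.0,
            sigma_motor=0.0, sigma_drift=0.0,
        )
        with pytest.raises(Exception) as exc_info:
            run_session(params, StrategyConfig("S0"), seed=0)
        assert "SPM" in str(exc_info.value)


class TestRunExperiment:
    def test_session_counts(self):
        res = run_experiment(
            ExperimentDesign(
                n_participants=3,
                conditions=[StrategyConfig("S0"), StrategyConfig("S1")],
                master_seed=1,
                protocol=SHORT,
            )
        )
        assert len(res.logs) == 6
        assert len(res.summary) == 6
        assert set(res.summary["condition"]) == {"S0", "S1"}

    def test_single_participant_single_condition(self):
        res = run_experiment(
            ExperimentDesign(
                n_participants=1, conditions=[StrategyConfig("S2")], master_seed=0
            )
        )
        assert len(res.summary) == 1
        assert len(res.per_song) == 5

    def test_follow_up_design_yields_77_sessions(self):
        # 11 participants x 7 conditions (S3-S5 at 0 deg plus S5[+30])
        conditions = [
            StrategyConfig("S0"),
            StrategyConfig("S1"),
            StrategyConfig("S2"),
            StrategyConfig("S3", target_phase_deg=0.0),
            StrategyConfig("S4", target_phase_deg=0.0),
            StrategyConfig("S5", target_phase_deg=0.0),
            StrategyConfig("S5", target_phase_deg=30.0),
        ]
        res = run_experiment(
            ExperimentDesign(
                n_participants=11, conditions=conditions, master_seed=2,
                protocol=SHORT,
            )
        )
        assert len(res.logs) == 77

    def test_reproducible_from_master_seed(self):
        design = ExperimentDesign(
            n_participants=2,
            conditions=[StrategyConfig("S1"), StrategyConfig("S2")],
            master_seed=77,
            protocol=SHORT,
        )
        a = run_experiment(design)
        b = run_experiment(design)
        assert a.summary.equals(b.summary)

    def test_condition_orders_unique_across_participants(self):
        design = ExperimentDesign(
            n_participants=6,
            conditions=[StrategyConfig("S0"), StrategyConfig("S1"), StrategyConfig("S2")],
            master_seed=5,
            protocol=SHORT,
        )
        res = run_experiment(design)
        orders = (
            res.summary.sort_values("order_slot")
            .groupby("participant_id")["condition"]
            .apply(tuple)
        )
        assert len(set(orders)) == 6  # 3! = 6 distinct orders, all used

    def test_duplicate_conditions_rejected(self):
        with pytest.raises(ConfigurationError):
            ExperimentDesign(
                n_participants=2,
                conditions=[StrategyConfig("S1"), StrategyConfig("S1")],
            )


class TestEventLogRoundTrip:
    def test_write_read_write_byte_identical(self, tmp_path):
        log = run_session(
            default_runner_params(), StrategyConfig("S3", target_phase_deg=-70.0),
            protocol=SHORT, seed=9,
        )
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_event_log(log, p1)
        write_event_log(read_event_log(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_round_trip_preserves_configs_and_times(self, tmp_path):
        log = run_session(
            default_runner_params(), StrategyConfig("S0"), protocol=SHORT, seed=4
        )
        path = tmp_path / "log.csv"
        write_event_log(log, path)
        back = read_event_log(path)
        assert back.seed == log.seed
        assert back.params == log.params
        assert back.strategy == log.strategy
        assert np.allclose(back.steps.times, log.steps.times, atol=1e-6)
        assert len(back.beats) == len(log.beats)

    def test_time_going_backwards_raises_with_line_number(self, tmp_path):
        log = run_session(
            default_runner_params(), StrategyConfig("S1"), protocol=SHORT, seed=2
        )
        path = tmp_path / "log.csv"
        write_event_log(log, path)
        lines = path.read_text().splitlines()
        lines[12], lines[13] = lines[13], lines[12]  # swap two event rows
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(EventLogParseError) as exc_info:
            read_event_log(path)
        assert "backwards" in str(exc_info.value)
        assert exc_info.value.line_number is not None

    def test_unknown_event_type_rejected(self, tmp_path):
        log = run_session(
            default_runner_params(), StrategyConfig("S1"), protocol=SHORT, seed=2
        )
        path = tmp_path / "log.csv"
        write_event_log(log, path)
        text = path.read_text().replace(",step,", ",hop,", 1)
        path.write_text(text)
        with pytest.raises(EventLogParseError, match="hop"):
            read_event_log(path)

    def test_silence_only_log_with_no_beats_is_valid(self, tmp_path):
        log = run_session(
            default_runner_params(), StrategyConfig("S1"), protocol=SHORT, seed=2
        )
        empty_beats = dataclasses.replace(
            log, beats=type(log.beats).empty()
        )
        path = tmp_path / "log.csv"
        write_event_log(empty_beats, path)
        back = read_event_log(path)
        assert len(back.beats) == 0
        assert len(back.steps) == len(log.steps)


class TestPhaseAttractorDynamics:
    def _phase_trajectory(self, start_phase_deg, n_steps=400):
        """Zero-noise runner against a fixed beat grid at its own tempo."""
        from runsync import RunnerState, default_runner_params, next_step_period
        from runsync.circstats import wrap_degrees

        params = default_runner_params(sigma_motor=0.0, sigma_drift=0.0)
        period = params.preferred_period
        state = RunnerState(0.0, period, 0.0)
        t = 0.0
        phase = start_phase_deg
        phases = []
        for _ in range(n_steps):
            p, state = next_step_period(state, params, phase)
            t += p
            # fixed grid, so phase advances by the period mismatch
            phase = wrap_degrees(phase + 360.0 * (p - period) / period)
            phases.append(phase)
        return phases

    def test_start_inside_basin_converges_to_preferred_phase(self):
        phases = self._phase_trajectory(-50.0)
        assert abs(phases[-1] - (-20.0)) < 1.0

    def test_start_outside_basin_persists(self):
        phases = self._phase_trajectory(120.0)
        assert abs(phases[-1] - 120.0) < 1.0

    def test_preferred_phase_recoverable_from_s1_resultants(self):
        # low-noise regime: the S1 per-song resultant angles cluster at the
        # runner's NMA attractor once songs lock (R above 0.6)
        from runsync import default_runner_params, per_song_resultants

        params = default_runner_params(
            sigma_motor=0.004, sigma_drift=0.0002, preferred_phase=-20.0
        )
        protocol = Protocol(silence_duration=25.0, n_songs=8, song_duration=55.0)
        angles, lengths = [], []
        for seed in range(6):
            log = run_session(params, StrategyConfig("S1"), protocol=protocol, seed=seed)
            frame = per_song_resultants(log)
            angles += frame["mean_angle_deg"].tolist()
            lengths += frame["resultant_length"].tolist()
        angles = np.asarray(angles)
        lengths = np.asarray(lengths)
        locked = lengths > 0.6
        assert locked.sum() >= 10
        rad = np.radians(angles[locked])
        w = lengths[locked]
        recovered = np.degrees(
            np.arctan2((w * np.sin(rad)).sum(), (w * np.cos(rad)).sum())
        )
        assert abs(recovered - params.preferred_phase) < 5.0
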