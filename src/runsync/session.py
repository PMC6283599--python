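"""Closed-loop runner-scheduler sessions and multi-participant experiments.

A session follows the study protocol (25 s of silence, then five 55 s
musical excerpts) with the footfall as the clock tick: at each step the
scheduler is notified, beats up to the next step are emitted from the
current grid, and the runner perceives its relative phase against the
already-emitted beats (no coupling before a song's first beat, none during
silence). An experiment runs each participant through each condition once,
with per-participant randomized condition orders (unique across participants
where the count permits) and deterministic per-session seed streams derived
from one master seed.
"""

from __future__ import annotations

import dataclasses
import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circstats import assign_phases, circular_descriptives, per_song_resultants
from .events import EventTrain
from .exceptions import ConfigurationError, EventLogParseError, SimulationError
from .runner import RunnerParams, RunnerState, next_step_period, sample_runner_params
from .strategies import BeatScheduler, StrategyConfig, estimate_cadence

__all__ = [
    "Protocol",
    "SessionLog",
    "ExperimentDesign",
    "ExperimentResult",
    "run_session",
    "run_experiment",
    "write_event_log",
    "read_event_log",
    "default_conditions",
]

# Simulation aborts if the instantaneous cadence leaves this plausibility band.
_ABORT_SPM_LO = 100.0
_ABORT_SPM_HI = 220.0


@dataclass(frozen=True)
class Protocol:
    """Session timing protocol: silence followed by equal-length songs."""

    silence_duration: float = 25.0
    n_songs: int = 5
    song_duration: float = 55.0

    def __post_init__(self):
        if self.silence_duration <= 0 or self.song_duration <= 0 or self.n_songs < 1:
            raise ConfigurationError("protocol durations must be positive")

    @property
    def total(self) -> float:
        return self.silence_duration + self.n_songs * self.song_duration

    def song_starts(self) -> np.ndarray:
        return self.silence_duration + self.song_duration * np.arange(self.n_songs)

    def segment_of(self, t: float) -> int:
        """0 for silence, 1..n_songs for songs (half-open [start, end))."""
        if t < self.silence_duration:
            return 0
        song = 1 + int((t - self.silence_duration) // self.song_duration)
        return min(song, self.n_songs)


@dataclass(frozen=True)
class SessionLog:
    """Complete record of one runner x strategy session."""

    participant_id: str
    condition: str
    steps: EventTrain
    beats: EventTrain
    params: RunnerParams
    strategy: StrategyConfig
    protocol: Protocol
    seed: int

    @property
    def gender(self) -> str:
        return self.params.gender_label

    def step_periods(self) -> np.ndarray:
        return np.diff(self.steps.times)

    def speed_series(self) -> np.ndarray:
        """Per-interval speed (m/s): stride length over step period.

        Stride length follows l = l0 * (T / T0)^a with a the stride
        compensation exponent, so near a = 1 speed barely responds to
        cadence change (slower steps are longer).
        """
        periods = self.step_periods()
        t0 = self.params.preferred_period
        stride = self.params.step_length * (periods / t0) ** self.params.stride_compensation
        return stride / periods

    def phase_series(self):
        return assign_phases(self.steps, self.beats)


def run_session(
    params: RunnerParams,
    strategy: StrategyConfig,
    protocol: Protocol | None = None,
    seed: int = 0,
    participant_id: str = "P000",
) -> SessionLog:
    """Simulate one closed-loop session; reproducible from (configs, seed)."""
    protocol = protocol or Protocol()
    rng = np.random.default_rng(seed)
    sched = BeatScheduler(strategy, rng)
    state = RunnerState(
        last_step_time=0.0,
        current_base_period=params.preferred_period,
        coupling_level=0.0,
    )
    song_starts = list(protocol.song_starts())
    total = protocol.total
    steps: list[float] = [0.0]
    t = 0.0
    next_song = 0  # index into song_starts

    while True:
        # perceived phase of the current step against the emitted grid
        phi = sched.measure_phase(t) if sched.song_index >= 1 else None
        sched.on_step(t, steps, measured_phase=phi)
        base_before = state.current_base_period
        period, state = next_step_period(state, params, phi, rng)
        # abort on the underlying step rate (base tempo x coupling), not on
        # single motor-noise-jittered intervals
        spm = 60.0 / (base_before * (1.0 + state.coupling_level))
        if not (_ABORT_SPM_LO < spm < _ABORT_SPM_HI):
            raise SimulationError(
                f"{participant_id}/{strategy.label}: cadence {spm:.1f} SPM at "
                f"t={t:.2f}s left the plausible ({_ABORT_SPM_LO:g}, "
                f"{_ABORT_SPM_HI:g}) SPM band"
            )
        t_next = t + period
        # song boundaries crossed before the next step
        while next_song < len(song_starts) and song_starts[next_song] <= t_next:
            s = song_starts[next_song]
            sched.emit_until(s)  # flush the previous song's remaining beats
            predicted = t + 60.0 / estimate_cadence(steps[-strategy.cadence_window :])
            song_end = s + protocol.song_duration
            sched.on_song_start(next_song + 1, s, song_end, steps, predicted)
            next_song += 1
        if t_next > total:
            sched.emit_until(total)
            break
        sched.emit_until(t_next)
        steps.append(t_next)
        t = t_next

    step_arr = np.asarray(steps)
    step_segments = np.fromiter(
        (protocol.segment_of(x) for x in step_arr), dtype=int, count=step_arr.size
    )
    return SessionLog(
        participant_id=participant_id,
        condition=strategy.label,
        steps=EventTrain(times=step_arr, segments=step_segments),
        beats=sched.emitted,
        params=params,
        strategy=strategy,
        protocol=protocol,
        seed=int(seed),
    )


def default_conditions() -> list[StrategyConfig]:
    """The six conditions of the initial experiment (S3-S5 at -70 deg)."""
    return [
        StrategyConfig("S0"),
        StrategyConfig("S1"),
        StrategyConfig("S2"),
        StrategyConfig("S3", target_phase_deg=-70.0),
        StrategyConfig("S4", target_phase_deg=-70.0),
        StrategyConfig("S5", target_phase_deg=-70.0),
    ]


@dataclass(frozen=True)
class ExperimentDesign:
    """A balanced within-participant experiment specification."""

    n_participants: int = 36
    conditions: Sequence[StrategyConfig] = field(default_factory=default_conditions)
    master_seed: int = 0
    population: Mapping | None = None
    protocol: Protocol = field(default_factory=Protocol)
    randomize_order: bool = True

    def __post_init__(self):
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate condition labels: {labels}")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be at least 1")


@dataclass(frozen=True)
class ExperimentResult:
    """Session logs plus tidy per-session and per-song summary tables."""

    logs: list[SessionLog]
    summary: pd.DataFrame
    per_song: pd.DataFrame
    design: ExperimentDesign


def _unique_order(
    rng: np.random.Generator, n_conditions: int, seen: set[tuple[int, ...]]
) -> tuple[int, ...]:
    # unique orders across participants where the permutation count permits
    can_be_unique = len(seen) < math.factorial(n_conditions)
    for _ in range(1000):
        order = tuple(int(i) for i in rng.permutation(n_conditions))
        if not can_be_unique or order not in seen:
            seen.add(order)
            return order
    raise ConfigurationError("failed to draw a unique condition order")


def run_experiment(design: ExperimentDesign) -> ExperimentResult:
    """Run every participant through every condition exactly once."""
    from .analysis import cadence_change, speed_change  # circular-import guard

    conditions = list(design.conditions)
    root = np.random.SeedSequence(design.master_seed)
    children = root.spawn(design.n_participants)
    logs: list[SessionLog] = []
    summary_rows = []
    song_rows = []
    seen_orders: set[tuple[int, ...]] = set()

    for i in range(design.n_participants):
        pid = f"P{i + 1:03d}"
        streams = children[i].spawn(2 + len(conditions))
        params = sample_runner_params(
            design.population, np.random.default_rng(streams[0])
        )
        if design.randomize_order:
            order = _unique_order(
                np.random.default_rng(streams[1]), len(conditions), seen_orders
            )
        else:
            order = tuple(range(len(conditions)))
        for slot, cond_idx in enumerate(order):
            strategy = conditions[cond_idx]
            seed = int(streams[2 + cond_idx].generate_state(1)[0] % (2**31))
            log = run_session(
                params, strategy, design.protocol, seed=seed, participant_id=pid
            )
            logs.append(log)
            series = log.phase_series()
            mean_phase = np.nan
            mean_r = np.nan
            if len(series):
                d = circular_descriptives(series)
                mean_phase, mean_r = d.mean_angle_deg, d.resultant_length
            summary_rows.append(
                {
                    "participant_id": pid,
                    "gender": params.gender_label,
                    "condition": strategy.label,
                    "order_slot": slot,
                    "cadence_change_pct": cadence_change(log),
                    "speed_change_pct": speed_change(log),
                    "mean_phase_deg": mean_phase,
                    "resultant_length": mean_r,
                    "seed": seed,
                }
            )
            resultants = per_song_resultants(log)
            by_song = _per_song_cadence_change(log)
            for _, row in resultants.iterrows():
                song_rows.append(
                    {
                        "participant_id": pid,
                        "gender": params.gender_label,
                        "condition": strategy.label,
                        "song": int(row["song"]),
                        "mean_phase_deg": row["mean_angle_deg"],
                        "resultant_length": row["resultant_length"],
                        "n_steps": int(row["n_steps"]),
                        "cadence_change_pct": by_song.get(int(row["song"]), np.nan),
                    }
                )
    return ExperimentResult(
        logs=logs,
        summary=pd.DataFrame(summary_rows),
        per_song=pd.DataFrame(song_rows),
        design=design,
    )


def _per_song_cadence_change(log: SessionLog) -> dict[int, float]:
    silence = log.steps.for_segment(0)
    if len(silence) < 2:
        return {}
    cad0 = estimate_cadence(silence.times)
    out = {}
    for song in range(1, log.protocol.n_songs + 1):
        seg = log.steps.for_segment(song)
        if len(seg) >= 2:
            out[song] = 100.0 * (estimate_cadence(seg.times) - cad0) / cad0
    return out


# ---------------------------------------------------------------------------
# Event-log CSV round trip
# ---------------------------------------------------------------------------

_LOG_MAGIC = "# runsync event log v1"
_COLUMNS = "participant_id,condition,segment,event_type,time_s,foot"


def _config_json(obj) -> str:
    return json.dumps(dataclasses.asdict(obj), sort_keys=True)


def write_event_log(log: SessionLog, path: str | Path) -> None:
    """Write a session to the shared event-log CSV (one row per event).

    The header comment block records the seed and the full configuration, so
    the file round-trips losslessly (write -> read -> write is byte
    identical; times carry 6 decimals, i.e. microsecond precision).
    """
    buf = io.StringIO()
    buf.write(_LOG_MAGIC + "\n")
    buf.write(f"# seed={log.seed}\n")
    buf.write(f"# participant_id={log.participant_id}\n")
    buf.write(f"# condition={log.condition}\n")
    buf.write(f"# runner={_config_json(log.params)}\n")
    buf.write(f"# strategy={_config_json(log.strategy)}\n")
    buf.write(f"# protocol={_config_json(log.protocol)}\n")
    buf.write(_COLUMNS + "\n")
    rows = []
    for i, t in enumerate(log.steps.times):
        foot = "NA" if log.steps.foot is None else str(log.steps.foot[i])
        rows.append((t, "step", int(log.steps.segments[i]), foot))
    for i, t in enumerate(log.beats.times):
        rows.append((t, "beat", int(log.beats.segments[i]), "NA"))
    rows.sort(key=lambda r: (r[0], r[1]))
    for t, etype, segment, foot in rows:
        buf.write(
            f"{log.participant_id},{log.condition},{segment},{etype},{t:.6f},{foot}\n"
        )
    Path(path).write_text(buf.getvalue())


def read_event_log(path: str | Path) -> SessionLog:
    """Read an event-log CSV back into a :class:`SessionLog`.

    Raises :class:`EventLogParseError` (naming the line) on malformed rows,
    unknown event types or times going backwards. An empty beat section is
    valid (an S0 silence-only log, for instance).
    """
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _LOG_MAGIC:
        raise EventLogParseError("missing event-log magic header", 1)
    header: dict[str, str] = {}
    body_start = None
    for i, line in enumerate(lines[1:], start=2):
        if line.startswith("# "):
            key, _, value = line[2:].partition("=")
            header[key] = value
        elif line == _COLUMNS:
            body_start = i + 1
            break
        else:
            raise EventLogParseError(f"unexpected header line: {line!r}", i)
    if body_start is None:
        raise EventLogParseError("missing column header row", len(lines))
    try:
        params = RunnerParams(**json.loads(header["runner"]))
        strategy = StrategyConfig(**json.loads(header["strategy"]))
        protocol = Protocol(**json.loads(header["protocol"]))
        seed = int(header["seed"])
    except (KeyError, json.JSONDecodeError, TypeError) as exc:
        raise EventLogParseError(f"bad configuration header: {exc}", body_start - 1)

    step_rows: list[tuple[float, int, str]] = []
    beat_rows: list[tuple[float, int]] = []
    last_time = -math.inf
    for lineno, line in enumerate(lines[body_start - 1 :], start=body_start):
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != 6:
            raise EventLogParseError(f"expected 6 fields, got {len(parts)}", lineno)
        _, _, seg_s, etype, time_s, foot = parts
        try:
            segment = int(seg_s)
            t = float(time_s)
        except ValueError as exc:
            raise EventLogParseError(str(exc), lineno)
        if etype not in ("step", "beat"):
            raise EventLogParseError(f"unknown event_type {etype!r}", lineno)
        if t < last_time:
            raise EventLogParseError(f"time going backwards ({t} < {last_time})", lineno)
        last_time = t
        if etype == "step":
            step_rows.append((t, segment, foot))
        else:
            beat_rows.append((t, segment))

    steps = EventTrain(
        times=np.array([r[0] for r in step_rows]),
        segments=np.array([r[1] for r in step_rows], dtype=int),
        foot=np.array([r[2] for r in step_rows]) if step_rows else None,
    )
    beats = EventTrain(
        times=np.array([r[0] for r in beat_rows]),
        segments=np.array([r[1] for r in beat_rows], dtype=int),
    )
    return SessionLog(
        participant_id=header.get("participant_id", "P000"),
        condition=header.get("condition", strategy.label),
        steps=steps,
        beats=beats,
        params=params,
        strategy=strategy,
        protocol=protocol,
        seed=seed,
    )
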