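"""Event-driven beat schedulers implementing alignment strategies S0-S5.

A scheduler observes footfalls and emits musical beat times on a piecewise-
uniform grid; beats already emitted are never retracted. The strategies:

S0  allochronic control: tempo offset by at least 20 BPM from the cadence
    assessed at song start, making synchronization impossible.
S1  one-time tempo matching at song start, random initial beat phase.
S2  continuous tempo adaptation (BPM follows SPM each step), phase free.
S3  continuous tempo adaptation plus a forced relative-phase start
    (configurable, 0 or -70 deg) at each song beginning.
S4  forced relative phase: tempo matched and the grid re-anchored on every
    step so the predicted next step lands at the target phase (full
    correction by default; sudden tempo changes).
S5  forced relative phase through a discrete adaptive-frequency oscillator:
    two-gain phase/frequency updates bounded to a 5% per-beat period change
    (smooth tempo adaptation).

No audio is modelled: a "song" is a beat grid with a tempo, and track
selection is idealized to exact tempo match, since every measured quantity
depends only on event times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .circstats import wrap_degrees
from .events import EventTrain
from .exceptions import ConfigurationError, InsufficientHistoryError

__all__ = [
    "STRATEGY_IDS",
    "StrategyConfig",
    "BeatScheduler",
    "estimate_cadence",
    "s0_offset_tempo",
]

STRATEGY_IDS = ("S0", "S1", "S2", "S3", "S4", "S5")

# Playable tempo band of the idealized music system (open interval, BPM).
_PLAYABLE_LO = 100.0
_PLAYABLE_HI = 220.0


def estimate_cadence(step_times: Sequence[float]) -> float:
    """Cadence (SPM) from the last w footfalls: 60 (w-1) / (t_w - t_1)."""
    t = np.asarray(step_times, dtype=float)
    if t.size < 2:
        raise InsufficientHistoryError("cadence estimation needs at least 2 steps")
    if not np.all(np.diff(t) > 0):
        raise ConfigurationError("step times must be strictly increasing")
    return 60.0 * (t.size - 1) / float(t[-1] - t[0])


def s0_offset_tempo(cadence_spm: float, rng: np.random.Generator) -> float:
    """Allochronic tempo: cadence +/- 20 BPM, sign random unless infeasible.

    A sign that would leave the playable (100, 220) BPM band is replaced by
    the feasible one, so |tempo - cadence| = 20 always.
    """
    up, down = cadence_spm + 20.0, cadence_spm - 20.0
    feasible = [t for t in (up, down) if _PLAYABLE_LO < t < _PLAYABLE_HI]
    if not feasible:
        raise ConfigurationError(f"no feasible 20 BPM offset for {cadence_spm} SPM")
    if len(feasible) == 1:
        return feasible[0]
    return feasible[int(rng.integers(2))]


@dataclass(frozen=True)
class StrategyConfig:
    """Configuration of one alignment strategy.

    target_phase_deg is the forced/start relative phase for S3 (start value)
    and S4/S5 (continuous goal); the studied values are -70, 0 and +30 deg.
    cadence_window is the number of footfalls used for tempo estimation.
    osc_gain_phase / osc_gain_freq are the S5 adaptive-oscillator gains
    (stable for phase gain < 1). max_step_shift caps the per-step S4 grid
    re-anchoring, as a fraction of the beat period (1 = full correction).
    """

    strategy_id: str
    target_phase_deg: float | None = None
    tempo_offset_bpm: float = 20.0
    cadence_window: int = 7
    osc_gain_phase: float = 0.5
    osc_gain_freq: float = 0.2
    max_step_shift: float = 1.0

    def __post_init__(self):
        if self.strategy_id not in STRATEGY_IDS:
            raise ConfigurationError(f"unknown strategy: {self.strategy_id!r}")
        if self.strategy_id == "S0" and abs(self.tempo_offset_bpm) < 20.0:
            raise ConfigurationError("S0 requires a tempo offset of at least 20 BPM")
        if self.cadence_window < 2:
            raise ConfigurationError("cadence_window must be at least 2")
        if self.osc_gain_phase <= 0 or self.osc_gain_freq <= 0:
            raise ConfigurationError("oscillator gains must be positive")
        if self.strategy_id in ("S3", "S4", "S5"):
            if self.target_phase_deg is None:
                raise ConfigurationError(f"{self.strategy_id} requires target_phase_deg")
            if not (-180.0 < self.target_phase_deg <= 180.0):
                raise ConfigurationError("target phase must lie in (-180, 180]")

    @property
    def label(self) -> str:
        """Human-readable condition label, e.g. 'S4[-70]'."""
        if self.strategy_id in ("S3", "S4", "S5") and self.target_phase_deg is not None:
            tp = self.target_phase_deg
            tp_str = f"{tp:+g}" if tp != 0 else "0"
            return f"{self.strategy_id}[{tp_str}]"
        return self.strategy_id

    @property
    def uses_forced_phase(self) -> bool:
        return self.strategy_id in ("S4", "S5")


@dataclass
class BeatScheduler:
    """Live beat grid of one strategy during one session.

    Holds the scheduler state (current beat period, next beat time, emitted
    beats, and the S5 oscillator frequency) and mutates it on song starts
    and footfalls. Deterministic given (config, rng seed, step stream).
    """

    config: StrategyConfig
    rng: np.random.Generator
    beat_period: float = field(default=0.375, init=False)
    next_beat_time: float = field(default=math.inf, init=False)
    omega: float = field(default=0.0, init=False)  # S5 oscillator, rad/s
    song_index: int = field(default=0, init=False)
    song_start: float = field(default=math.inf, init=False)
    song_end: float = field(default=math.inf, init=False)
    _times: list = field(default_factory=list, init=False)
    _songs: list = field(default_factory=list, init=False)

    # -- beat emission -----------------------------------------------------

    def emit_until(self, t: float) -> None:
        """Emit all grid beats with time <= t (clamped to the song window)."""
        limit = min(t, self.song_end)
        while self.next_beat_time <= limit:
            self._times.append(self.next_beat_time)
            self._songs.append(self.song_index)
            self.next_beat_time += self.beat_period

    @property
    def emitted(self) -> EventTrain:
        return EventTrain(
            times=np.asarray(self._times, dtype=float),
            segments=np.asarray(self._songs, dtype=int),
        )

    def beats_in_window(self, t0: float, t1: float) -> EventTrain:
        """Emitted beats with t0 <= t < t1."""
        return self.emitted.in_window(t0, t1)

    # -- phase measurement -------------------------------------------------

    def measure_phase(self, step_time: float) -> float | None:
        """Relative phase of a step against the already-emitted grid.

        Uses the last emitted beat of the current song as B1 and the next
        scheduled grid point as B2; returns None when the step precedes the
        song's first beat (no coupling that step).
        """
        if not self._times:
            return None
        b1 = self._times[-1]
        if b1 > step_time or b1 < self.song_start or self._songs[-1] != self.song_index:
            return None
        b2 = self.next_beat_time
        if not b2 > b1:
            return None
        return wrap_degrees(360.0 * (step_time - b1) / (b2 - b1))

    # -- song-start alignment ----------------------------------------------

    def on_song_start(
        self,
        song_index: int,
        song_start: float,
        song_end: float,
        recent_steps: Sequence[float],
        predicted_next_step: float,
    ) -> None:
        """Initialise the beat grid of a new song.

        S0: offset tempo, random initial phase. S1/S2: matched tempo, random
        initial phase. S3/S4/S5: matched tempo and the first beat placed so
        the predicted next step has the target relative phase (beat at
        predicted - (psi/360) * period, advanced by whole periods until it
        lies inside the song).
        """
        window = recent_steps[-self.config.cadence_window :]
        if len(window) < self.config.cadence_window:
            raise InsufficientHistoryError(
                f"{self.config.cadence_window} steps of history required at song start"
            )
        cadence = estimate_cadence(window)
        self.song_index = song_index
        self.song_start = song_start
        self.song_end = song_end

        sid = self.config.strategy_id
        if sid == "S0":
            tempo = s0_offset_tempo(cadence, self.rng)
            self.beat_period = 60.0 / tempo
            first = song_start + self.rng.uniform(0.0, self.beat_period)
        elif sid in ("S1", "S2"):
            self.beat_period = self._clamped_period(cadence)
            first = song_start + self.rng.uniform(0.0, self.beat_period)
        else:  # S3 / S4 / S5: forced-phase start
            self.beat_period = self._clamped_period(cadence)
            psi = float(self.config.target_phase_deg)
            first = predicted_next_step - (psi / 360.0) * self.beat_period
            while first < song_start:
                first += self.beat_period
            while first - self.beat_period >= song_start:
                first -= self.beat_period
        self.next_beat_time = first
        if sid == "S5":
            self.omega = 2.0 * math.pi / self.beat_period

    @staticmethod
    def _clamped_period(cadence_spm: float) -> float:
        tempo = min(max(cadence_spm, 120.0), 200.0)
        return 60.0 / tempo

    # -- per-step updates --------------------------------------------------

    def on_step(
        self,
        step_time: float,
        step_history: Sequence[float],
        measured_phase: float | None = None,
    ) -> None:
        """Notify the scheduler of a footfall at ``step_time``.

        S0/S1 leave the grid untouched. S2/S3 re-estimate the tempo with the
        grid phase preserved (next beat time unchanged). S4 additionally
        re-anchors the grid so the predicted next step lands at the target
        phase. S5 delegates to the adaptive oscillator.
        """
        if self.song_index == 0:
            return
        sid = self.config.strategy_id
        if sid in ("S0", "S1"):
            return
        window = step_history[-self.config.cadence_window :]
        if len(window) < 2:
            return
        cadence = estimate_cadence(window)
        if sid in ("S2", "S3"):
            self.beat_period = self._clamped_period(cadence)
            return
        if sid == "S4":
            self._forced_phase_update(step_time, cadence)
            return
        if sid == "S5":
            self.adaptive_oscillator_update(step_time, measured_phase)

    def _forced_phase_update(self, step_time: float, cadence_spm: float) -> None:
        """S4: match tempo and re-anchor the grid at the target phase."""
        self.beat_period = self._clamped_period(cadence_spm)
        period = self.beat_period
        psi = float(self.config.target_phase_deg)
        predicted = step_time + 60.0 / cadence_spm
        anchor = predicted - (psi / 360.0) * period
        # smallest anchor-grid point strictly after the current step
        n = math.floor((step_time - anchor) / period) + 1
        candidate = anchor + n * period
        cap = self.config.max_step_shift
        if cap < 1.0 and math.isfinite(self.next_beat_time):
            shift = candidate - self.next_beat_time
            shift = (shift + period / 2.0) % period - period / 2.0
            shift = float(np.clip(shift, -cap * period, cap * period))
            candidate = self.next_beat_time + shift
            while candidate <= step_time:
                candidate += period
        self._set_next_beat(candidate)

    def adaptive_oscillator_update(
        self, step_time: float, measured_phase: float | None
    ) -> None:
        """S5: two-gain adaptive-frequency oscillator update.

        With phase error e = wrap(psi - phi) in radians, the oscillator
        frequency moves by nu_omega * e / T and the grid shifts by
        nu_phi * e * T / (2 pi); both are bounded so the per-beat period
        change stays within 5%. e = 0 is a fixed point.
        """
        if self.config.strategy_id != "S5":
            raise ConfigurationError("adaptive oscillator update is S5-specific")
        if measured_phase is None:
            return
        psi = float(self.config.target_phase_deg)
        e = math.radians(wrap_degrees(psi - measured_phase))
        if e == 0.0:
            return
        period = self.beat_period
        # frequency adaptation, bounded to a 5% per-beat period change
        new_omega = self.omega + self.config.osc_gain_freq * e / period
        new_period = 2.0 * math.pi / new_omega
        new_period = float(np.clip(new_period, 0.95 * period, 1.05 * period))
        self.omega = 2.0 * math.pi / new_period
        self.beat_period = new_period
        # phase adaptation: shift the grid toward the target, same 5% bound
        delta = self.config.osc_gain_phase * e * period / (2.0 * math.pi)
        delta = float(np.clip(delta, -0.05 * period, 0.05 * period))
        self._set_next_beat(self.next_beat_time - delta)

    def _set_next_beat(self, t: float) -> None:
        # emitted beats are never retracted: keep the grid strictly ahead
        if self._times and t <= self._times[-1]:
            t = self._times[-1] + self.beat_period
        self.next_beat_time = t
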