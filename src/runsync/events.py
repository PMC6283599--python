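"""Ordered trains of recurring events (footfalls or musical beats).

An :class:`EventTrain` is the common currency between the simulation and the
analysis side of the package: a strictly increasing array of event times in
seconds, each tagged with a protocol segment (0 = silence, 1..n = song index)
and, for steps, optionally a foot label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["EventTrain"]


@dataclass(frozen=True)
class EventTrain:
    """Strictly increasing event times (s) with per-event segment labels.

    Parameters
    ----------
    times
        Event times in seconds, strictly increasing.
    segments
        Integer segment label per event; 0 denotes the silence segment,
        1..n_songs the song index. Defaults to all zeros.
    foot
        Optional foot labels ('L', 'R' or 'NA'), one per event.
    """

    times: np.ndarray
    segments: np.ndarray = None  # type: ignore[assignment]
    foot: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1:
            raise ConfigurationError("event times must be one-dimensional")
        if times.size and not np.all(np.isfinite(times)):
            raise ConfigurationError("event times must be finite")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ConfigurationError("event times must be strictly increasing")
        segments = self.segments
        if segments is None:
            segments = np.zeros(times.size, dtype=int)
        else:
            segments = np.asarray(segments, dtype=int)
            if segments.shape != times.shape:
                raise ConfigurationError("segments must match times in length")
        foot = self.foot
        if foot is not None:
            foot = np.asarray(foot)
            if foot.shape != times.shape:
                raise ConfigurationError("foot labels must match times in length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "segments", segments)
        object.__setattr__(self, "foot", foot)

    def __len__(self) -> int:
        return int(self.times.size)

    @classmethod
    def empty(cls) -> "EventTrain":
        return cls(times=np.empty(0), segments=np.empty(0, dtype=int))

    def in_window(self, t0: float, t1: float) -> "EventTrain":
        """Events with t0 <= t < t1 (half-open window)."""
        if not t0 < t1:
            raise ConfigurationError("window requires t0 < t1")
        mask = (self.times >= t0) & (self.times < t1)
        return self._masked(mask)

    def for_segment(self, segment: int) -> "EventTrain":
        """Events belonging to one protocol segment."""
        return self._masked(self.segments == segment)

    def _masked(self, mask: np.ndarray) -> "EventTrain":
        return EventTrain(
            times=self.times[mask],
            segments=self.segments[mask],
            foot=None if self.foot is None else self.foot[mask],
        )

    @staticmethod
    def concatenate(trains: list["EventTrain"]) -> "EventTrain":
        """Concatenate adjacent trains; the result must still be sorted."""
        if not trains:
            return EventTrain.empty()
        times = np.concatenate([t.times for t in trains])
        segments = np.concatenate([t.segments for t in trains])
        feet = [t.foot for t in trains]
        foot = None if any(f is None for f in feet) else np.concatenate(feet)
        return EventTrain(times=times, segments=segments, foot=foot)
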