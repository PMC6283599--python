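"""Relative phase angles and circular statistics for step/beat event trains.

The step-to-beat timing relation is expressed as a relative phase angle

    phi = 360 * (S_t - B1) / (B2 - B1)

where ``S_t`` is a footfall instant and ``B1 <= S_t < B2`` the bracketing
beats, wrapped to the signed half-open range (-180, +180] so that a negative
angle means the step preceded the closest beat (negative mean asynchrony).

Circular samples are summarised by the resultant vector (mean direction
``mean_angle`` and length ``R``), circular variance ``CV = 1 - R``, angular
deviation ``s = sqrt(2 (1 - R))`` (radians), and the non-standardized
trigonometric moments about the mean direction: circular skewness
``b = mean(sin 2(a - mean))`` and circular kurtosis
``k = mean(cos 2(a - mean))``. Under a uniform sample ``s -> sqrt(2) ~ 1.41``
and ``b, k -> 0``; a point mass gives ``s = 0``, ``k = 1``. Standardized
variants (Pewsey/Fisher) are available under distinct names.

The multi-sample homogeneity question ("did the alignment strategies produce
different phase-angle distributions?") is answered by the Wheeler-Watson-
Mardia uniform-scores test, asymptotically chi-square with 2(k-1) degrees of
freedom, with an optional permutation p-value for small groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventTrain
from .exceptions import ConfigurationError

if TYPE_CHECKING:  # pragma: no cover
    from .session import SessionLog

__all__ = [
    "wrap_degrees",
    "relative_phase_angle",
    "assign_phases",
    "PhaseSeries",
    "CircularDescriptives",
    "circular_descriptives",
    "standardized_skewness",
    "standardized_kurtosis",
    "per_song_resultants",
    "descriptives_frame",
    "WheelerWatsonMardiaResult",
    "wheeler_watson_mardia",
]


def wrap_degrees(angle):
    """Wrap angle(s) in degrees to the signed half-open range (-180, +180].

    +180 is kept positive (the wrap rule subtracts 360 only when the raw
    angle is strictly larger than 180), so the mapping is idempotent.
    """
    a = np.remainder(angle, 360.0)
    a = np.where(a > 180.0, a - 360.0, a)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(a)
    return a


def relative_phase_angle(step_time: float, prev_beat: float, next_beat: float) -> float:
    """Relative phase (degrees) of one step between its bracketing beats.

    Requires ``prev_beat <= step_time < next_beat``. Returns 0 deg iff the
    step coincides with the previous beat; the interval midpoint maps to
    +180 deg (kept positive at the wrap boundary).
    """
    if not next_beat > prev_beat:
        raise ConfigurationError("degenerate beat interval: B2 must exceed B1")
    if not (prev_beat <= step_time < next_beat):
        raise ConfigurationError(
            f"step at {step_time} outside bracketing interval [{prev_beat}, {next_beat})"
        )
    phi = 360.0 * (step_time - prev_beat) / (next_beat - prev_beat)
    return wrap_degrees(phi)


@dataclass(frozen=True)
class PhaseSeries:
    """Per-step relative phase angles with song bookkeeping.

    ``angles_deg`` lie in (-180, +180]; ``song_index`` gives the song each
    angle came from; ``excluded_count`` counts steps that had no bracketing
    beat pair (silence steps, steps before a song's first or after its last
    beat) and therefore never enter any statistic.
    """

    angles_deg: np.ndarray
    song_index: np.ndarray
    excluded_count: int

    def __post_init__(self):
        angles = np.asarray(self.angles_deg, dtype=float)
        songs = np.asarray(self.song_index, dtype=int)
        if angles.shape != songs.shape:
            raise ConfigurationError("angles and song indices must align")
        if angles.size and (angles.min() <= -180.0 or angles.max() > 180.0):
            raise ConfigurationError("phase angles must lie in (-180, 180]")
        object.__setattr__(self, "angles_deg", angles)
        object.__setattr__(self, "song_index", songs)

    def __len__(self) -> int:
        return int(self.angles_deg.size)

    def for_song(self, song: int) -> np.ndarray:
        return self.angles_deg[self.song_index == song]


def assign_phases(steps: EventTrain, beats: EventTrain) -> PhaseSeries:
    """Assign a relative phase angle to every step with a bracketing beat pair.

    Matching is done within song segments: a step in song ``i`` is only
    bracketed by beats of song ``i`` (beat grids are discontinuous across
    song boundaries). Steps without a pair are counted as excluded; an empty
    beat train yields an all-excluded, valid series.
    """
    angles: list[np.ndarray] = []
    songs: list[np.ndarray] = []
    assigned = 0
    for song in np.unique(beats.segments) if len(beats) else []:
        if song == 0:
            continue
        beat_t = beats.times[beats.segments == song]
        step_t = steps.times[steps.segments == song]
        if beat_t.size < 2 or step_t.size == 0:
            continue
        idx = np.searchsorted(beat_t, step_t, side="right")
        ok = (idx > 0) & (idx < beat_t.size)
        b1 = beat_t[idx[ok] - 1]
        b2 = beat_t[idx[ok]]
        phi = wrap_degrees(360.0 * (step_t[ok] - b1) / (b2 - b1))
        angles.append(np.atleast_1d(phi))
        songs.append(np.full(int(ok.sum()), song, dtype=int))
        assigned += int(ok.sum())
    if angles:
        return PhaseSeries(
            angles_deg=np.concatenate(angles),
            song_index=np.concatenate(songs),
            excluded_count=len(steps) - assigned,
        )
    return PhaseSeries(
        angles_deg=np.empty(0),
        song_index=np.empty(0, dtype=int),
        excluded_count=len(steps),
    )


@dataclass(frozen=True)
class CircularDescriptives:
    """One column of the circular summary table for a single angle sample."""

    mean_angle_deg: float
    resultant_length: float
    circular_variance: float
    angular_deviation_rad: float
    circular_skewness: float
    circular_kurtosis: float
    n: int


def _mean_direction(rad: np.ndarray) -> tuple[float, float]:
    c = float(np.mean(np.cos(rad)))
    s = float(np.mean(np.sin(rad)))
    return np.arctan2(s, c), float(np.hypot(c, s))


def circular_descriptives(angles_deg: Sequence[float] | PhaseSeries) -> CircularDescriptives:
    """Resultant vector and trigonometric-moment descriptives of one sample.

    ``circular_skewness``/``circular_kurtosis`` are the non-standardized
    second central trigonometric moments ``mean(sin 2(a - mean))`` and
    ``mean(cos 2(a - mean))``.
    """
    if isinstance(angles_deg, PhaseSeries):
        angles_deg = angles_deg.angles_deg
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ConfigurationError("circular descriptives require at least one angle")
    rad = np.radians(a)
    mean_rad, r = _mean_direction(rad)
    centered = rad - mean_rad
    b = float(np.mean(np.sin(2.0 * centered)))
    k = float(np.mean(np.cos(2.0 * centered)))
    return CircularDescriptives(
        mean_angle_deg=wrap_degrees(np.degrees(mean_rad)),
        resultant_length=r,
        circular_variance=1.0 - r,
        angular_deviation_rad=float(np.sqrt(2.0 * (1.0 - r))),
        circular_skewness=b,
        circular_kurtosis=k,
        n=int(a.size),
    )


def _second_moment(rad: np.ndarray) -> tuple[float, float]:
    c2 = float(np.mean(np.cos(2.0 * rad)))
    s2 = float(np.mean(np.sin(2.0 * rad)))
    return np.arctan2(s2, c2), float(np.hypot(c2, s2))


def standardized_skewness(angles_deg: Sequence[float]) -> float:
    """Fisher's standardized circular skewness R2 sin(m2 - 2m) / (1-R)^1.5."""
    rad = np.radians(np.asarray(angles_deg, dtype=float))
    mean_rad, r = _mean_direction(rad)
    mu2, r2 = _second_moment(rad)
    return float(r2 * np.sin(mu2 - 2.0 * mean_rad) / (1.0 - r) ** 1.5)


def standardized_kurtosis(angles_deg: Sequence[float]) -> float:
    """Fisher's standardized circular kurtosis (R2 cos(m2-2m) - R^4) / (1-R)^2."""
    rad = np.radians(np.asarray(angles_deg, dtype=float))
    mean_rad, r = _mean_direction(rad)
    mu2, r2 = _second_moment(rad)
    return float((r2 * np.cos(mu2 - 2.0 * mean_rad) - r**4) / (1.0 - r) ** 2)


def per_song_resultants(log: "SessionLog") -> pd.DataFrame:
    """One resultant vector per song of a session.

    Returns a frame with columns song, mean_angle_deg, resultant_length and
    n_steps; songs without any phased step appear with n_steps = 0 and NaN
    vector entries (absent, not zero).
    """
    series = assign_phases(log.steps, log.beats)
    rows = []
    for song in range(1, log.protocol.n_songs + 1):
        angles = series.for_song(song)
        if angles.size == 0:
            rows.append((song, np.nan, np.nan, 0))
        else:
            d = circular_descriptives(angles)
            rows.append((song, d.mean_angle_deg, d.resultant_length, d.n))
    return pd.DataFrame(
        rows, columns=["song", "mean_angle_deg", "resultant_length", "n_steps"]
    )


def descriptives_frame(logs: Iterable["SessionLog"]) -> pd.DataFrame:
    """Circular descriptives per participant x condition x song.

    Mirrors the layout of a circular summary table: one row per song with
    mean angle, R, CV, angular deviation, skewness, kurtosis and step count.
    """
    rows = []
    for log in logs:
        series = assign_phases(log.steps, log.beats)
        for song in sorted(np.unique(series.song_index)):
            d = circular_descriptives(series.for_song(int(song)))
            rows.append(
                {
                    "participant_id": log.participant_id,
                    "condition": log.condition,
                    "song": int(song),
                    "mean_angle_deg": d.mean_angle_deg,
                    "resultant_length": d.resultant_length,
                    "circular_variance": d.circular_variance,
                    "angular_deviation_rad": d.angular_deviation_rad,
                    "circular_skewness": d.circular_skewness,
                    "circular_kurtosis": d.circular_kurtosis,
                    "n_steps": d.n,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WheelerWatsonMardiaResult:
    statistic: float
    df: int
    pvalue: float
    pvalue_permutation: float | None = None


def wheeler_watson_mardia(
    groups: Sequence[Sequence[float]],
    permutations: int | None = None,
    rng: np.random.Generator | None = None,
) -> WheelerWatsonMardiaResult:
    """Wheeler-Watson-Mardia k-sample test of circular homogeneity.

    The pooled sample is replaced by uniform scores ``beta_i = 2 pi r_i / N``
    (circular ranks, ties broken by average rank) and

        W = 2 * sum_j (C_j^2 + S_j^2) / n_j

    with ``C_j``/``S_j`` the within-group sums of cos/sin of the scores.
    Under homogeneity W is asymptotically chi-square with 2(k-1) df. When any
    group has fewer than 10 observations the asymptotic p is unreliable; a
    permutation p-value is then computed automatically (999 resamples unless
    ``permutations`` says otherwise).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2:
        raise ConfigurationError("at least two groups are required")
    if any(a.size == 0 for a in arrays):
        raise ConfigurationError("all groups must be non-empty")
    sizes = np.array([a.size for a in arrays])
    pooled = wrap_degrees(np.concatenate(arrays))
    n_total = pooled.size
    ranks = stats.rankdata(pooled)  # average ranks on the cut circle
    beta = 2.0 * np.pi * ranks / n_total
    labels = np.repeat(np.arange(k), sizes)

    def _statistic(scores: np.ndarray) -> float:
        w = 0.0
        for j in range(k):
            sj = scores[labels == j]
            w += (np.cos(sj).sum() ** 2 + np.sin(sj).sum() ** 2) / sizes[j]
        return 2.0 * w

    w_obs = _statistic(beta)
    df = 2 * (k - 1)
    p_asym = float(stats.chi2.sf(w_obs, df))

    p_perm = None
    if permutations is None and sizes.min() < 10:
        permutations = 999
    if permutations:
        rng = np.random.default_rng() if rng is None else rng
        exceed = 0
        for _ in range(permutations):
            if _statistic(rng.permutation(beta)) >= w_obs:
                exceed += 1
        p_perm = (1 + exceed) / (permutations + 1)
    return WheelerWatsonMardiaResult(
        statistic=float(w_obs), df=df, pvalue=p_asym, pvalue_permutation=p_perm
    )
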