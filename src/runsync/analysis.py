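"""Statistical endpoints: kinematic changes, strategy comparisons, power.

Endpoints per session are the percent change of cadence (and speed) during
music relative to the preceding silence, the session mean relative phase and
resultant length, and per-song resultant vectors. Strategy comparisons use a
Friedman omnibus across conditions with Wilcoxon signed-rank follow-ups at a
Bonferroni-corrected alpha (0.05/15 ~ .003 for all 15 pairs of 6
conditions), effect size r = z / sqrt(n); parametric endpoints additionally
get a mixed-design condition x gender ANOVA. The phase-cadence relation is a
one-tailed Spearman rank correlation (directional hypothesis: more negative
forced phase, lower cadence). The design-stage sample-size computation
inverts the power of the within-factors repeated-measures F test via the
noncentral F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError
from .session import SessionLog
from .strategies import estimate_cadence

__all__ = [
    "cadence_change",
    "speed_change",
    "ComparisonResult",
    "StrategyComparison",
    "strategy_comparison",
    "mixed_anova_gender",
    "phase_cadence_correlation",
    "coherence_fraction",
    "rm_anova_power",
    "required_sample_size_rm_anova",
]


def _segment_mean_cadence(log: SessionLog, music: bool) -> float:
    if music:
        t0 = log.protocol.silence_duration
        steps = log.steps.times[log.steps.times >= t0]
    else:
        steps = log.steps.for_segment(0).times
    if steps.size < 2:
        raise ConfigurationError("segment has fewer than 2 steps")
    return estimate_cadence(steps)


def cadence_change(log: SessionLog) -> float:
    """Percent cadence change, music vs the preceding silence (negative =
    slow-down; zero indicates no difference)."""
    silence = _segment_mean_cadence(log, music=False)
    music = _segment_mean_cadence(log, music=True)
    return 100.0 * (music - silence) / silence


def speed_change(log: SessionLog) -> float:
    """Percent speed change, music vs silence, from the per-interval speed
    series (stride length x cadence)."""
    speeds = log.speed_series()
    mids = 0.5 * (log.steps.times[1:] + log.steps.times[:-1])
    in_silence = mids < log.protocol.silence_duration
    if in_silence.sum() < 1 or (~in_silence).sum() < 1:
        raise ConfigurationError("need speed samples in both silence and music")
    v0 = float(np.mean(speeds[in_silence]))
    v1 = float(np.mean(speeds[~in_silence]))
    return 100.0 * (v1 - v0) / v0


@dataclass(frozen=True)
class ComparisonResult:
    """One row of a comparison table (omnibus or pairwise)."""

    test: str
    comparison: str
    statistic: float
    df: float | None
    pvalue: float
    effect_size_r: float | None
    alpha_corrected: float
    significant: bool


@dataclass(frozen=True)
class StrategyComparison:
    omnibus: ComparisonResult
    pairwise: list[ComparisonResult]
    alpha_corrected: float

    def frame(self) -> pd.DataFrame:
        rows = [self.omnibus] + self.pairwise
        return pd.DataFrame([r.__dict__ for r in rows])


def _wilcoxon_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Signed-rank z statistic and two-sided p (normal approximation)."""
    d = x - y
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    res = stats.wilcoxon(x, y, method="approx", correction=False)
    return float(res.zstatistic), float(res.pvalue)


def strategy_comparison(
    summary: pd.DataFrame,
    endpoint: str = "resultant_length",
    nominal_alpha: float = 0.05,
) -> StrategyComparison:
    """Friedman omnibus plus all pairwise Wilcoxon follow-ups.

    ``summary`` must contain one row per participant x condition with the
    endpoint column; the design must be balanced (an error lists missing
    cells otherwise). The corrected alpha is nominal / number of pairwise
    comparisons; effect size r = z / sqrt(number of observations), counting
    both members of each pair (the convention that reproduces the reported
    magnitudes, e.g. z = -5.232 with 36 pairs -> r = -.62).
    """
    wide = summary.pivot(index="participant_id", columns="condition", values=endpoint)
    if wide.isna().any().any():
        missing = [
            f"{pid}:{cond}"
            for pid, row in wide.iterrows()
            for cond in wide.columns[row.isna()]
        ]
        raise ConfigurationError(f"unbalanced design, missing cells: {missing}")
    conditions = list(wide.columns)
    if len(conditions) < 2:
        raise ConfigurationError("need at least two conditions to compare")
    pairs = list(combinations(conditions, 2))
    alpha_corr = nominal_alpha / len(pairs)

    cols = [wide[c].to_numpy() for c in conditions]
    if all(np.allclose(c, cols[0]) for c in cols[1:]):
        chi2, p_omni = 0.0, 1.0
    elif len(cols) == 2:
        # scipy requires k >= 3; the k = 2 Friedman statistic from within-row
        # ranks: chi2 = (12 / (n k (k+1))) sum R_j^2 - 3 n (k+1), df = 1
        ranks = stats.rankdata(np.column_stack(cols), axis=1)
        n_rows, k = ranks.shape
        rank_sums = ranks.sum(axis=0)
        chi2 = 12.0 / (n_rows * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n_rows * (
            k + 1
        )
        p_omni = stats.chi2.sf(chi2, k - 1)
    else:
        chi2, p_omni = stats.friedmanchisquare(*cols)
    omnibus = ComparisonResult(
        test="friedman",
        comparison=" vs ".join(conditions),
        statistic=float(chi2),
        df=float(len(conditions) - 1),
        pvalue=float(p_omni),
        effect_size_r=None,
        alpha_corrected=alpha_corr,
        significant=bool(p_omni < nominal_alpha),
    )
    pairwise = []
    n = wide.shape[0]
    for a, b in pairs:
        z, p = _wilcoxon_z(wide[a].to_numpy(), wide[b].to_numpy())
        pairwise.append(
            ComparisonResult(
                test="wilcoxon",
                comparison=f"{a} vs {b}",
                statistic=z,
                df=None,
                pvalue=p,
                effect_size_r=z / np.sqrt(2 * n),
                alpha_corrected=alpha_corr,
                significant=bool(p < alpha_corr),
            )
        )
    return StrategyComparison(omnibus=omnibus, pairwise=pairwise, alpha_corrected=alpha_corr)


def mixed_anova_gender(
    summary: pd.DataFrame, endpoint: str = "cadence_change_pct"
) -> pd.DataFrame:
    """Mixed-design ANOVA: condition (within) x gender (between).

    Returns the effect table (Source, F, df, p-unc, ...) for the chosen
    parametric endpoint. Requires both genders present.
    """
    import pingouin as pg  # deferred: pingouin is slow to import

    if summary["gender"].nunique() < 2:
        raise ConfigurationError("mixed ANOVA requires both gender groups")
    return pg.mixed_anova(
        data=summary,
        dv=endpoint,
        within="condition",
        subject="participant_id",
        between="gender",
    )


def phase_cadence_correlation(
    mean_phase_deg: Sequence[float],
    cadence_change_pct: Sequence[float],
    alternative: str = "greater",
) -> tuple[float, float, int]:
    """Spearman rank correlation between achieved phase and cadence change.

    One-tailed ('greater') by default, per the directional hypothesis that
    a more positive relative phase raises cadence. Returns (rho, p, n).
    """
    phases = np.asarray(mean_phase_deg, dtype=float)
    changes = np.asarray(cadence_change_pct, dtype=float)
    ok = np.isfinite(phases) & np.isfinite(changes)
    phases, changes = phases[ok], changes[ok]
    if phases.size < 3:
        raise ConfigurationError("correlation requires at least 3 observations")
    if np.all(phases == phases[0]) or np.all(changes == changes[0]):
        raise ConfigurationError("correlation undefined for constant input")
    res = stats.spearmanr(phases, changes, alternative=alternative)
    return float(res.statistic), float(res.pvalue), int(phases.size)


def coherence_fraction(
    resultant_lengths: Iterable[float], threshold: float = 0.75
) -> float:
    """Share of songs run in phase coherence (per-song R >= threshold)."""
    r = np.asarray(list(resultant_lengths), dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ConfigurationError("no resultant lengths supplied")
    if r.min() < 0 or r.max() > 1:
        raise ConfigurationError("resultant lengths must lie in [0, 1]")
    return float(np.mean(r >= threshold))


def rm_anova_power(
    n: int,
    effect_size_f: float,
    alpha: float = 0.05,
    n_measurements: int = 6,
    corr: float = 0.5,
    nonsphericity_eps: float = 1.0,
) -> float:
    """Power of the within-factors repeated-measures F test for N subjects.

    Noncentral-F tail beyond the central critical value, with
    df1 = (m-1) eps, df2 = (N-1)(m-1) eps and noncentrality
    lambda = f^2 N m eps / (1 - rho).
    """
    if n < 2:
        return 0.0
    m, eps = n_measurements, nonsphericity_eps
    lam = effect_size_f**2 * n * m * eps / (1.0 - corr)
    df1 = (m - 1) * eps
    df2 = (n - 1) * (m - 1) * eps
    crit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def required_sample_size_rm_anova(
    effect_size_f: float,
    alpha: float = 0.05,
    power: float = 0.95,
    n_measurements: int = 6,
    corr: float = 0.5,
    nonsphericity_eps: float = 1.0,
    n_max: int = 100000,
) -> int:
    """Smallest N whose repeated-measures design reaches the target power.

    Bisection over the integer sample size with a linear confirmation that
    N-1 falls short, guaranteeing minimality.
    """
    if effect_size_f <= 0:
        raise ConfigurationError("power unreachable for a zero effect size")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ConfigurationError("alpha and power must lie in (0, 1)")
    if n_measurements < 2 or not (0 <= corr < 1) or not (0 < nonsphericity_eps <= 1):
        raise ConfigurationError("invalid design parameters")

    def achieved(n: int) -> float:
        return rm_anova_power(
            n, effect_size_f, alpha, n_measurements, corr, nonsphericity_eps
        )

    lo, hi = 2, 2
    while achieved(hi) < power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ConfigurationError(f"power {power} unreachable below N={n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if achieved(mid) >= power:
            hi = mid
        else:
            lo = mid + 1
    n = hi
    assert achieved(n) >= power and (n == 2 or achieved(n - 1) < power)
    return n
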