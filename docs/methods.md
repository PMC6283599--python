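# Methods

## Scope

`runsync` models a run-to-the-beat experiment at desk scale: synthetic
recreational runners are coupled in closed loop to six beat-alignment
strategies over a 300 s protocol (25 s of silence followed by five 55 s
musical excerpts), and the resulting step/beat event trains feed the
standard measurement and statistics pipeline of the field. No audio is
rendered anywhere: a "song" is a beat grid with a tempo, and every measured
quantity depends only on event times.

## Runner model

Footfall timing is a discrete phase-correcting map. With base (comfort)
period `T_base`, coupling level `c` and motor noise `eps ~ N(0,
sigma_motor)`:

    t[k+1]   = t[k] + T_base[k] * (1 + c[k]) + eps[k]
    c[k]     = c[k-1] + gamma * (c_target - c[k-1])
    c_target = -K(Delta) * sin(Delta)  if |Delta| <= basin halfwidth, else 0

`Delta` is the perceived relative phase minus the runner's preferred phase.
The preferred phase is the negative-mean-asynchrony (NMA) attractor:
runners prefer footfalls slightly before the beat, because the tactile
consequence of a footfall takes longer to reach the brain than the sound of
the beat. The bounded attraction basin gives HKB-style bistability: phases
started far from the attractor persist instead of converging.

Key properties engineered into this map:

- **Fixed point at the preferred phase.** `Delta = 0` gives `c_target = 0`;
  with zero noise the runner steps at its comfort period.
- **Saturation.** A phase held at constant `Delta` drives `c` to
  `-K sin(Delta)` with time constant `1/gamma` steps; at the defaults a
  forced -70 deg phase saturates near a 2.3% slow-down, building up over
  roughly the first song.
- **Asymmetry.** `K = k_slow` when the correction lengthens the period,
  `k_fast` when it shortens it (`k_slow > k_fast`), so slow-down under a
  -70 deg forcing is larger than the speed-up under +30 deg.
- **Bounded coupling.** `|c| <= max(k_slow, k_fast)` by construction.

The perceived phase at a step is computed against the beats the runner has
actually heard: the last emitted beat as `B1` and the next scheduled grid
point as `B2`. During silence, and before a song's first beat, there is no
coupling and `c` leaks back toward zero.

Timing noise is Gaussian on the step time; the comfort period performs a
reflected Gaussian random walk inside the natural cadence band (120-200
steps per minute). Per-step von Mises phase noise was considered and
rejected to keep the time domain primary.

### Parameters and defaults

| parameter | default | units | meaning |
|---|---|---|---|
| preferred_period | 0.375 | s | comfort period (160 SPM) |
| preferred_phase | -20 | deg | NMA attractor |
| basin_halfwidth | 60 | deg | attraction basin half-width |
| k_slow / k_fast | 0.030 / 0.010 | – | coupling gains (lengthen / shorten) |
| gamma | 0.05 | /step | coupling integrator leak |
| sigma_motor | 0.010 | s | per-step timing noise |
| sigma_drift | 0.0005 | s | comfort-period random walk |
| step_length | 1.05 | m | stride at the comfort period |
| stride_compensation | 0.9 | – | stride-length exponent (below) |

The preferred phase sits at the centre of the reported -20..-40 deg
attractor region; `gamma` makes the forced-phase effect build over the
first song rather than instantly; the gain asymmetry reproduces the ~-2.2%
versus ~+0.7% cadence asymmetry; `sigma_drift` yields a per-session
cadence-change noise floor of about 2% s.d., the same order as the
between-subject spread implied by published standard errors.

**Speed.** Speed is stride length over step period, with stride length
`l = l0 * (T/T0)^a` and `a = 0.9`: when cadence drops, the stride lengthens
almost proportionally, so speed barely moves (`v ~ (T/T0)^(a-1)`). This
encodes the robust empirical finding that forced-phase manipulations move
cadence but not speed; `a = 1` would make speed exactly invariant, `a = 0`
would make speed track cadence one-for-one.

### Population

Cohorts are drawn per participant: gender (female fraction 17/36), cadence
~ N(160, 10) SPM truncated to [130, 190], preferred phase ~ N(-20, 8) deg
truncated to [-45, 5], step length ~ N(1.05, 0.10) m, and per-gender
coupling gains k_slow ~ N(0.024, 0.005) for men and N(0.036, 0.005) for
women (mixture mean 0.030), with `k_fast = k_slow / 3`. The gender gap in
gain expresses the reported higher female entrainment capacity; it
propagates to a larger forced-phase cadence effect and a higher share of
phase-coherent songs for women. The magnitudes of inter-individual spreads
are design choices, not fits — nothing in the package estimates them from
data.

## Strategies

All schedulers are event-driven with the footfall as the clock tick, emit
beats from a piecewise-uniform grid, and never retract an emitted beat.
Cadence is estimated as `60 (w-1) / (t_w - t_1)` over the last `w = 7`
footfalls.

- **S0 (allochronic control):** tempo = cadence ± 20 BPM at each song
  start (sign random unless it would leave the open (100, 220) BPM playable
  band), random initial phase. The 12.5% tempo mismatch sweeps the relative
  phase through the full circle every ~3 s, so pooled phases are uniform.
- **S1 (fixed tempo):** tempo matched once per song, random initial phase.
- **S2 (continuous tempo):** beat period re-estimated every step; the grid
  anchor (next beat time) is preserved, so the phase is free.
- **S3:** S2 plus a forced-phase start: the first beat of each song is
  placed at `predicted_next_step - (psi/360) * period` (advanced by whole
  periods into the song), so the predicted next step lands at the target
  phase psi (0 or -70 deg).
- **S4 (forced phase, algorithmic):** tempo matched and the grid
  re-anchored on *every* step so the predicted next step lands at psi.
  Full correction per step by default (`max_step_shift = 1`), embodying
  the "sudden tempo changes" contrast with S5.
- **S5 (forced phase, adaptive oscillator):** a discrete adaptive-frequency
  oscillator. With phase error `e = wrap(psi - phi)` in radians, the
  frequency moves by `nu_omega * e / T` and the grid shifts by
  `nu_phi * e * T / (2 pi)`, both clamped so the per-beat period change
  stays within 5%. Defaults `nu_phi = 0.5`, `nu_omega = 0.2` give a stable
  spiral (discrete-time eigenvalues of magnitude ~0.84) converging in about
  ten steps; the phase gain must stay below 1 for stability.

Track selection is idealized to exact tempo match at song start. Whether
continuous tempo adaptation preserves grid phase exactly on a period change
is not observable in the original protocol; the phase-preserving update was
chosen for S2/S3.

## Session and experiment orchestration

At each step the scheduler is notified, beats up to the next step are
emitted, and song boundaries crossed before the next step trigger
`on_song_start` with the step history and a cadence-extrapolated predicted
next step. Songs abut seamlessly; no beats exist during silence. A session
aborts with a diagnostic if the *underlying* step rate (base period times
coupling, not a single noise-jittered interval) leaves (100, 220) SPM.

Experiments run every participant through every condition exactly once
with per-participant randomized condition orders, kept unique across
participants while the permutation count permits. All randomness derives
from one master seed through `numpy.random.SeedSequence` spawning, so
trajectories are byte-reproducible from (config, seed). Sessions round-trip
losslessly through a plain-CSV event log (6-decimal times, configuration
in comment headers).

## Measurement layer

Relative phase uses the bracketing-beat formula with the wrap rule
"subtract 360 when phi > 180", keeping +180 positive; steps in song `i` are
only bracketed by beats of song `i`, and steps without a bracketing pair
(silence, before a song's first beat, after its last) are excluded from all
statistics rather than wrapped to a single nearest beat. Circular skewness
and kurtosis are reported as the *non-standardized* trigonometric moments
about the mean direction (`mean sin 2(a - ø)`, `mean cos 2(a - ø)`), the
convention under which a uniform sample gives `s -> sqrt(2) ~ 1.41` rad and
`k -> 0` while a tight forced-phase sample gives `k ~ 0.75`; Fisher's
standardized variants are exposed under distinct names.

The Wheeler-Watson-Mardia k-sample homogeneity test replaces the pooled
sample with uniform scores `beta_i = 2 pi r_i / N` (average ranks on ties)
and refers `W = 2 sum_j (C_j^2 + S_j^2) / n_j` to chi-square with 2(k-1)
df; when any group has fewer than 10 observations a permutation p-value is
computed automatically.

## Statistics

- Strategy comparisons: Friedman omnibus (a hand-computed rank statistic
  for the k = 2 case scipy does not cover), all pairwise Wilcoxon
  signed-rank follow-ups at Bonferroni-corrected alpha (0.05/15 for six
  conditions), effect size `r = z / sqrt(2 n_pairs)` — the observation-count
  convention, which reproduces published magnitudes.
- Mixed-design condition x gender ANOVA via `pingouin.mixed_anova`.
- Phase-cadence relation: one-tailed Spearman rank correlation (directional
  hypothesis; two-tailed by flag).
- Phase coherence: share of songs with per-song R >= 0.75.
- Sample size: smallest integer N whose within-factors repeated-measures F
  test reaches target power, with `df1 = (m-1) eps`,
  `df2 = (N-1)(m-1) eps`, noncentrality `lambda = f^2 N m eps / (1-rho)`;
  found by bisection with a minimality confirmation. The conventional
  defaults m = 6, rho = 0.5, eps = 1 reproduce the published N = 28 for
  f = 0.25, alpha = .05, power = .95.

## Step detection

The synthetic accelerometer writes one Gaussian-windowed cosine burst per
footfall (centred on the step instant, so the rectified envelope peaks at
the true time — a deliberate idealization of a causal impact transient)
plus white noise at 100 Hz. Detection is envelope (rectify + 50 ms moving
average), adaptive threshold at median + 6 robust standard deviations
(MAD x 1.4826), peak picking with a 0.25 s refractory period (capping
detected cadence at 240 SPM, above the running band), and parabolic
sub-sample refinement so 10 ms quantization does not dominate phase
precision (10 ms ~ 10 deg at 170 SPM). Gyroscope fusion of the referenced
apparatus is omitted: only footfall instants feed the analysis.

## Numerical choices and degenerate inputs

- Angles cross module boundaries in degrees; radians are used internally
  and for the angular deviation, matching the conventional magnitudes.
- The wrap to (-180, 180] keeps the +180 boundary positive and is
  idempotent.
- Zero-variance population entries are honoured exactly (degenerate
  truncated normals return the mean).
- An all-identical endpoint yields a Friedman statistic of 0 and p = 1
  instead of a ties error; an all-zero Wilcoxon difference yields z = 0.
- Event-log parsing reports the offending line number; empty beat sections
  are valid.
- The sample-size search brackets exponentially, bisects, and asserts that
  N - 1 falls short.

## What the simulations do and do not show

The generator reproduces the *mechanisms* reported for this paradigm — the
NMA attractor with a bounded basin, forced-phase controllability, the
saturating and asymmetric cadence response, uniform phases under
allochronic music, gender-differentiated coupling, and null speed effects —
under Gaussian noise and a drifting comfort tempo. Passing tests therefore
demonstrate that the pipeline measures these mechanisms correctly, not that
the human population behaves like the generator: real runners show
fatigue, terrain and motivation effects, non-Gaussian and autocorrelated
timing noise, occasional sensor dropout (not modelled; the follow-up
study's two invalid trials are bookkeeping only), and individual attractor
strengths that no published table constrains. Consequently the package
treats published human-subject statistics (specific Friedman/Wilcoxon
values, mean cadence changes, correlation coefficients, coherence
percentages) as qualitative anchors only; its tests assert orderings,
signs, bands and internal identities that the mechanisms imply. Simulated
per-song coherence under the forced-phase strategies is tighter than real
data (R ~ 0.99 versus ~0.94) because the bracketing-beat measurement
partially cancels motor noise that real sensor chains would add back.

Problem sizes used by the test suite and the acceptance script — 36-runner
cohorts for the study-sized checks, 96 runners for the forced-phase
direction cohort, 400 for the gender-coherence ordering (sized from the
pilot effect size), 1000 null replicates for the type-I-error check — were
chosen so that each property is resolved with a comfortable margin at a
fixed seed while a full run stays in the order of a minute.
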