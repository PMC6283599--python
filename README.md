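# runsync

Simulation and analysis of **beat-synchronized running**: how do different
music-to-movement alignment strategies shape the phase relation between a
runner's footfalls and the musical beat — and through it, the runner's
cadence?

The package is aimed at researchers in sensorimotor synchronization and
auditory-motor coupling who want a tested, reproducible desk-scale model of
run-to-the-beat experiments: a generative runner with a negative-mean-
asynchrony (NMA) phase attractor is coupled, in closed loop, to six
event-driven beat schedulers, and the resulting step/beat event trains are
analysed with the field's standard circular-statistics and strategy-
comparison battery.

## The model in brief

**Relative phase.** A step at time `S_t` bracketed by beats `B1 <= S_t < B2`
has relative phase

```
phi = 360 * (S_t - B1) / (B2 - B1),   wrapped to (-180, +180]
```

so `phi < 0` means the footfall anticipated the closest beat (NMA). A
circular sample is summarised by the resultant vector (mean direction ø,
length R), circular variance `CV = 1 - R`, angular deviation
`s = sqrt(2(1-R))` (radians), circular skewness `b` and kurtosis `k`.

**Runner.** Step times follow a discrete phase-correcting map

```
t[k+1] = t[k] + T_base[k] * (1 + c[k]) + eps[k]
c[k]   = c[k-1] + gamma * (c_target - c[k-1])
c_target = -K(Delta) * sin(Delta) * 1[|Delta| <= basin]
```

with `Delta` the perceived phase minus the preferred phase (default -20
deg), asymmetric gains `K` (`k_slow > k_fast`), Gaussian motor noise `eps`
and a reflected random walk on the comfort period `T_base`. Holding the
phase at a constant offset saturates the coupling at `c* = -K sin(Delta)`
— about a 2.3% slow-down for a forced -70 deg phase.

**Strategies.** S0 plays music offset by 20 BPM (allochronic control); S1
matches tempo once per song; S2/S3 adapt tempo continuously (S3 with a
forced-phase start); S4 re-anchors the beat grid every step to force a
target phase; S5 does the same through an adaptive-frequency oscillator
with per-beat tempo changes bounded to 5% (smooth adaptation).

**Analysis.** Cadence/speed change of music vs the preceding silence,
Friedman + Wilcoxon (Bonferroni-corrected) strategy comparisons, a mixed
condition x gender ANOVA, the Wheeler-Watson-Mardia k-sample test of
circular homogeneity, Spearman phase-cadence correlation, phase-coherence
classification (R >= .75), and the noncentral-F sample-size computation for
repeated-measures designs.

## Worked example

```python
import runsync as rs

params = rs.default_runner_params()            # 160 SPM, NMA at -20 deg
cond = rs.StrategyConfig("S5", target_phase_deg=-70.0)
log = rs.run_session(params, cond, seed=1)     # 25 s silence + 5 x 55 s songs

print(rs.per_song_resultants(log).round(3))
print("cadence change: %.2f%%" % rs.cadence_change(log))
```

prints

```
   song  mean_angle_deg  resultant_length  n_steps
0     1         -69.868             0.993      146
1     2         -70.319             0.992      143
2     3         -70.125             0.994      144
3     4         -69.988             0.992      146
4     5         -70.408             0.991      148
cadence change: -0.58%
```

The adaptive oscillator holds every song within half a degree of the -70
deg target at near-perfect phase coherence (R ≈ 0.99): the runner is forced
to keep stepping well before the beat, which pulls cadence down (here
-0.58% for a single session; the cohort-average slow-down saturates around
-2%, while a +30 deg target produces a smaller speed-up and a target at the
runner's own preferred phase leaves cadence unchanged).

Full experiments (every participant runs every condition once, randomized
orders, seeded):

```python
design = rs.ExperimentDesign(n_participants=36, master_seed=7)
result = rs.run_experiment(design)             # 216 sessions, ~5 s
result.summary                                  # tidy per-session endpoints
```

A thin CLI wraps the same pipeline: `runsync simulate --config cfg.yaml
--out dir`, `runsync analyze --in dir --out dir [--plots]`, `runsync power`,
`runsync detect-steps --signal trace.csv --fs 100` (footfall extraction
from a 100 Hz accelerometer trace), `runsync example-config`.

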