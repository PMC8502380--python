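# urchinwalk

Analysis of regularly sampled 2-D escape trajectories from two-treatment
behavioural experiments — built around the study design in which slow
benthic invertebrates (sea urchins) are filmed by time-lapse in a circular
arena, with and without predator chemical cues, and each animal's full
escape path is characterised rather than just its first reaction.

The package is aimed at movement ecologists who have digitized time-lapse
coordinates (one position per fixed frame interval) and want, per
individual, the standard escape-kinematics summaries plus an
anomalous-diffusion characterisation, and, per study, the group-comparison
statistics.

## What it computes

**Kinematics.** Mean speed (average step length over the frame interval),
initial and final heading angles (four-quadrant arctangent of the
start-to-fifth-position and start-to-end vectors), signed turning angles,
and the straightness index

&nbsp;&nbsp;&nbsp;&nbsp;*I*<sub>s</sub> = ‖**x**<sub>N</sub> − **x**<sub>0</sub>‖ / Σ<sub>k</sub> ‖**x**<sub>(k+1)w</sub> − **x**<sub>kw</sub>‖

over non-overlapping windows of *w* steps, ranging from 1 (straight) to 0
(closed loop).

**Anomalous diffusion.** The q-th order structure functions of the
displacement modulus,

&nbsp;&nbsp;&nbsp;&nbsp;⟨‖ΔX<sub>τ</sub>‖<sup>q</sup>⟩ ∼ τ<sup>ζ(q)</sup>,

estimated over all ordered position pairs at log-spaced lags τ.  The
exponents ζ(q) are per-q slopes of log-moment versus log-lag regressions;
their through-origin slope against q is the single coefficient that places
a path on the continuum from Brownian motion (slope 0.5) through
superdiffusion to ballistic, straight-line motion (slope 1).

**Unpredictability and orientation.** Directional entropy — the Shannon H
(nats) of turning angles binned at 0.05 rad over (−π, π] — and the Rayleigh
test of heading-angle uniformity (z = n·R̄², two-term series p-value).

**Inference.** One-way linear models for speed and straightness; a
heteroscedastic generalized least squares fit (per-group residual variance,
ML, likelihood-ratio χ² on 1 df) for the ζ(q) slope, with Levene's test as
the variance diagnostic; and an ANCOVA of entropy on treatment, ζ-slope and
their interaction with sequential F tests.

**Synthetic studies.** A generator of Brownian, correlated-random-walk,
ballistic and Lévy trajectories with known diffusive properties, and a
whole-study simulator (29 + 21 animals, 3 m arena, 30 s frames, trials
truncated 10 cm from the wall) for validating every stage without
laboratory data.

## Worked example

```python
from urchinwalk import StudyConfig, analyze_study, simulate_study

dataset = simulate_study(StudyConfig(seed=1))
report = analyze_study(dataset)
```

Running `python examples/full_study_pipeline.py` (exactly the code above
plus printing) gives:

```
group sizes: {'control': 29, 'predator': 21}

per-group means (control vs predator):
  mean_speed       1.212 ->    1.601   (+32.1%)
  straightness     0.418 ->    0.955   (+128.8%)
  zeta_slope       0.733 ->    0.934   (+27.5%)
  entropy          3.405 ->    2.133   (-37.3%)

treatment-comparison models:
  straightness index   F =   52.79, p = 0.0000
  mean speed           F =  135.46, p = 0.0000
  slope of zeta(q)     chi2 =   24.85, p = 0.0000
  directional entropy  F =  233.57, p = 0.0000
  Levene (zeta slope)  W =   77.32, p = 0.0000
```

Predator-cue animals move ~32% faster, far straighter, their ζ(q) slopes
cluster tightly near the ballistic line (hence the significant Levene
test), and their turning-angle entropy is ~37% lower: under this
generator's settings the simulated escape response is faster, straighter
and *more* predictable, the qualitative pattern the pipeline is designed
to detect.  Other capabilities are demonstrated one per script in
`examples/`.

A command-line interface mirrors the library:

```sh
urchinwalk simulate study.csv --seed 4        # synthetic study -> long CSV
urchinwalk metrics study.csv metrics.csv      # per-individual metrics
urchinwalk analyze study.csv out/             # JSON report + model tables
urchinwalk report study.csv figs/             # violins, zeta fans, entropy plots
```

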