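# freekick

Does the defensive wall hurt the goalkeeper it is meant to protect?  A
wall blocks shots, but it also occludes the first 150–250 ms of a free
kick's flight from the goalkeeper's viewpoint, so the keeper starts
moving later, on less information.  `freekick` is a Python package for
studying exactly this trade-off: it simulates spin-influenced free-kick
trajectories under exact arrival constraints, computes when the ball
visually clears the wall, generates synthetic goalkeeper motion-capture
sessions with the behavioural structure such experiments assume, and runs
the full trial-exclusion → kinematics → statistics analysis pipeline.

It is written for movement scientists and sports-science researchers who
want a tested, reproducible implementation of this analysis — either to
run on synthetic sessions (no data required) or to ingest their own 90 Hz
motion-tracked goalkeeping logs.

## The model

**Ball flight.**  The ball is a point mass under gravity, quadratic drag
and a Magnus force:

    a = g − (ρ C_d A / 2m) |v| v + (ρ C_l A / 2m) |v| (ω̂ × v),

with the lift coefficient proportional to the spin ratio,
C_l = min(s·ωr/|v|, C_l^max).  A free kick is specified by its *arrival
constraints* — lateral position x_f and height y_f of the ball centre at
the goal-line crossing, and the flight time T — and the launch velocity
is found by a shooting method (fixed-step RK4, 1 ms step, damped Newton
on the terminal residual).  The standard design is 18 experimental kicks
from 23 m (3 lateral arrivals × 3 curve directions × 2 flight times,
1800 °/s spin when curved) plus 45 unanalysed dummy kicks.

**Occlusion.**  The wall is an opaque screen at the regulation 9.15 m;
the ball becomes visible at the first instant its whole disc clears the
defenders' shoulder line along the goalkeeper's line of sight.

**Outcomes.**  Per trial, the pipeline computes movement initiation (the
first ≥ 200 ms epoch in which a hand's absolute lateral velocity exceeds
5 % of its within-window maximum), the absolute interception error AE
(minimal xy distance between the ball and the closest of left hand,
right hand, or hand midpoint when the ball front passes that effector's
depth plane, solved on a 10⁻⁵ s grid), touch success against the palm
colliders, and the early movement bias X_early (lateral head displacement
500 ms before the ball reaches the goal, signed by curve or by required
movement direction).  Per-participant wall/no-wall differences feed a
Shapiro–Wilk-gated inference layer (paired t or signed-rank W = T⁺ − T⁻,
Mann–Whitney U between groups) with step-down Holm–Šídák control across
families of 7 confirmatory and 16 exploratory comparisons.

## Worked example

```python
import numpy as np
from freekick import (
    experiment_design, solve_kick, WallSpec, Viewpoint, visibility_onset,
    BehaviorParams, CorruptionParams, generate_session, run_qc,
    metrics_table, aggregate,
)

kicks = [k for k in experiment_design() if k.kind == "experimental"]
trajectories = {k.label: solve_kick(k) for k in kicks}
wall, view = WallSpec(), Viewpoint()
occlusion = {lab: visibility_onset(tr, wall, view)
             for lab, tr in trajectories.items()}
print(f"occlusion: {min(occlusion.values()):.3f}-{max(occlusion.values()):.3f} s "
      f"(mean {np.mean(list(occlusion.values())):.3f} s)")

logs = generate_session(trajectories, occlusion, BehaviorParams(),
                        CorruptionParams(), 5, seed=7, dummy_reps=0)
report, included = run_qc(logs)
print(f"excluded {report.excluded.sum()} of {len(report)} trials")

summary = aggregate(metrics_table(included))
delay = summary["initiation"]["effect"].mean() * 1000
ae = summary["ae"]["effect"].median() * 100
sr = summary["success"][["nowall", "wall"]].mean()
print(f"wall delays initiation by {delay:.0f} ms on average")
print(f"median interception-error increase with wall: {ae:.1f} cm")
print(f"success rate: {sr.nowall:.1f}% without wall, {sr.wall:.1f}% with wall")
```

Output:

```
occlusion: 0.191-0.237 s (mean 0.213 s)
excluded 48 of 900 trials
wall delays initiation by 86 ms on average
median interception-error increase with wall: 4.1 cm
success rate: 95.3% without wall, 69.8% with wall
```

Reading this: with the default geometry the wall hides the first ~0.2 s
of flight.  The synthetic keepers re-initiate a configurable fraction
(default 0.4) of that occlusion later, which the pipeline recovers as an
~86 ms initiation delay; starting later with the same capped hand speed
turns into a few centimetres more interception error and a lower touch
rate.  (Synthetic error magnitudes are larger than human data; see
`docs/methods.md`.)

The same analysis is available as a shell pipeline:

```sh
freekick --outdir runs/demo simulate   # solve the 63 kicks
freekick --outdir runs/demo generate   # synthetic sessions for both groups
freekick --outdir runs/demo qc         # exclusion rules -> qc_report.csv
freekick --outdir runs/demo analyze    # per-trial metrics -> metrics.csv
freekick --outdir runs/demo stats      # families + Holm–Šídák -> stats.csv
freekick --outdir runs/demo report     # wall-effect and success-rate tables
```

All stages are driven by one YAML config (`freekick init-config run.yaml`)
and a single master seed; every artifact embeds the config hash and seed.

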