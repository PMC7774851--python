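# Methods

This note documents the models, parameter choices and numerical decisions
behind `freekick`, and what the synthetic-data tests do and do not show
about real goalkeeping data.

## Coordinate frame and scenario

All computation uses one right-handed analysis frame: origin at the
goal-line midpoint on the ground, +x rightward from the goalkeeper, +y
up, +z from the goal toward the pitch.  Engine-frame files (+x leftward,
+z into the goal) are flipped at the I/O boundary only.  The kick
originates on the centreline 23 m from the goal with the ball resting on
the ground (release height = contact radius).  Times are seconds,
lengths metres; samples are 0-based on a 90 Hz grid.

## Ball flight

The ball is integrated as a point mass with acceleration

    a = g − k C_d |v| v + k C_l |v| (ω̂ × v),      k = ρA/2m,

under a fixed spin ω.  Parameters (all overridable in `AeroParams` /
the run config):

| parameter | default | note |
|---|---|---|
| ball mass | 0.430 kg | standard match ball |
| aero diameter | 0.22 m | simulation ball; the rendered/contact ball is 0.2447 m |
| air density | 1.225 kg/m³ | sea-level standard |
| C_d | 0.25 | typical post-critical football drag |
| C_l | min(1.0·S, 0.35) | S = ωr/\|v\| spin ratio; zero without spin |
| g | 9.81 m/s² | downward |

The two ball diameters reflect the scenario modelled: aerodynamics use a
regulation 0.22 m ball while collision/visibility use the slightly larger
rendered ball (circumference 0.769 m ⇒ diameter 0.2447 m).  The cited
aerodynamics literature does not pin down one drag/lift parameterisation;
the defaults above are standard football values, declared rather than
fitted, and every derived quantity (occlusion durations, deviations) is
reported from the simulated paths, not assumed.

The spin axis of a curved kick is built by tilting the vertical axis 15°
away from the goal about x, then yawing it about y toward the lateral
arrival point by arctan(x_f / 23 m) = ±3.73° for the ±1.5 m arrivals;
leftward curve (counter-clockwise spin seen from above) keeps the upward
axis, rightward curve negates it.  Because the spin *rate* (1800 °/s
experimental, 900 °/s dummy) rather than the curve magnitude is fixed,
the sideward deviation grows with flight time, and because the arrival
height is fixed, longer flights are higher and clear the wall earlier.

**Integration.**  Classical fixed-step RK4 with a 1 ms internal step
(adjusted to divide the flight time exactly), resampled onto the 90 Hz
frame grid by cubic spline; trajectories end at least 2 m past the goal
line.  Halving the step moves the goal-line crossing by < 0.1 mm.  The
inverse problem (3 launch-velocity unknowns vs. 3 terminal constraints)
is solved with scipy's damped hybrid Newton on the shooting residual,
started from the vacuum solution with a 12 % drag allowance; solutions
are accepted only below a 0.1 mm residual, and all 18 experimental kicks
solve in well under a second each.  With drag and spin disabled the
integrator agrees with the closed-form parabola to < 1e−6 m, which the
test suite uses as its independent oracle.

## Wall occlusion

The wall is an opaque rectangle from the ground to the defenders'
shoulder line, centred on the ball–goal line.  The ball counts as
visible when the lowest point of its projected disc clears the shoulders
along the line of sight from a single eye point; the onset is refined by
bisection below frame resolution.  A ball that never clears the
shoulders while behind the wall plane returns a flagged never-visible
result (it is the shoulder-clearing event that is being measured, not
mere unobstructedness).

The VR scene's true wall distance and defender height are unreported, so
these are free geometry parameters: distance 9.15 m (the ten-yard rule),
five defenders of 0.50 m width, eye height 1.70 m, and an effective
shoulder height of 1.40 m (defenders in a wall duck slightly; a 1.50 m
shoulder line of upright 1.8 m players gives occlusions up to ~0.27 s).
With these defaults the 18 experimental kicks are occluded for
0.191–0.237 s (mean 0.213 s), inside the 150–250 ms window such scenes
produce, and longer flights clear no later than shorter ones at equal
geometry.

## Synthetic goalkeeper sessions

The generator is a stand-in for human participants — an explicit
generative model with the statistical structure the analysis assumes,
not an estimate of human parameters.  Per trial:

* **Initiation.**  Lateral movement starts at `latency +
  partial_delay_fraction × occlusion`.  Latency is Gaussian per trial
  (mean 0.25 s, SD 0.03 s) around a Gaussian per-participant base
  (SD 0.02 s).  `partial_delay_fraction` = 0.4 of a ~0.21 s occlusion
  injects a wall-induced delay of ~85 ms — the keeper starts later with
  the wall, but earlier *relative to when the ball appears*.
* **Aiming.**  The hands (and, at half gain, the head) pursue the
  predicted goal-line crossing, re-planned every 0.1 s.  The prediction
  over-extrapolates the visible curvature: aim(t) = x_f + gain · a_lat ·
  (T−t)²/2 with gain 0.3, which biases the early movement in the curve
  direction, decaying to zero at arrival.  (A *veridical* linear
  extrapolation of a curving flight is biased opposite the bend —
  x(t) + ẋ(T−t) = x_f − a_lat(T−t)²/2 — and could not reproduce the
  curve-direction biases seen empirically; over-weighting the observed
  curvature does.)  A per-trial Gaussian aim error (SD 3 cm) is added.
* **Reaching.**  Hand speed ramps up smoothly over 60 ms (half-cosine)
  to a 2.0 m/s cap and homes onto the target with a 0.2 s terminal time
  constant.  Two deliberate consequences: (i) the quick velocity rise
  makes the 5 %-threshold onset detector agree with the programmed onset
  to within one frame on noise-free trials (a minimum-jerk profile,
  whose velocity rises ∝ t², would lag it by ~7 frames); (ii) the speed
  cap keeps clean trials under the 25 mm/frame hand-jump exclusion rule.
  The 0.2 s homing constant matters for inference: faster homing makes
  the re-planned pursuit of curved central targets multiphasic, which
  biases detected onsets differently with and without the wall (+3–4 ms
  on the recovered delay); at 0.2 s the pipeline recovers the injected
  delay without systematic error.
* **Artefacts.**  With known per-trial labels, frames are dropped
  (p = 0.025), single-frame 50 mm hand glitches injected (p = 0.02) and
  recordings truncated before the ball is 2 m past the goal (p = 0.015)
  — rates chosen to emulate the ~6 % exclusion rates of motion-tracked
  VR sessions.  Timestamps carry 0.3 ms jitter, within the frame-interval
  tolerance.

Randomness is split from one master seed into per-participant and
per-trial substreams (`numpy` SeedSequence), so single trials are
reproducible in isolation and sessions are byte-identical across runs.

**What passing tests show — and don't.**  The synthetic data exercise
every pipeline rule and reproduce the *structure* of the phenomenon
(later initiation with a wall by less than the occlusion; larger error
increase for shorter flights and for required sideward movement;
curve-direction early biases reduced by the wall; congruence asymmetry).
They do not emulate biomechanics (no dives, joint limits or hand
rotations), expertise beyond parameter values, or realistic error
magnitudes: because the hand-jump rule caps credible hand speeds at
2.25 m/s, far-ball reaches undershoot and synthetic absolute errors are
decimetres where human keepers score centimetres.  Wall-effect
*differences*, on which all tests operate, are unaffected by this scale
inflation.  Benchmark agreement with human data additionally requires
ingesting real session logs (the `unity` dialect reader exists for
that).

## Preprocessing

Exclusion rules, each independent, any of which excludes (never repairs)
a trial: inter-frame interval outside [0.5, 1.5] × (1/90 s); hand
displacement > 25 mm between frames; displacement ≥ 5 × the mean of its
two neighbours (with a 1 µm floor so exact rest does not self-trigger);
ball record stopping more than 0.25 m short of the simulated end 2 m
past the goal line.  "Record reaches ~2 m past the goal" is the
completeness reading adopted because the simulations end there; the
0.25 m tolerance forgives a final dropped frame.  Dummy trials are
removed before any rule is evaluated.

Included trials are resampled by natural cubic spline (no extrapolation)
onto an exact 90 Hz grid starting at the ball-motion-onset sample, then
head and hand channels pass a 4th-order 10 Hz low-pass Butterworth.  The
filter is zero-phase by default — forward–backward with the order halved
per pass, the movement-science norm, avoiding the ~30 ms onset lag a
causal pass introduces — with a causal single-pass mode behind a config
switch.  The ball channel is never filtered (it is the noise-free
simulated path).

## Outcome measures

* **Lateral velocity** uses gradient semantics (central differences,
  one-sided edges), exact for quadratics on the interior.
* **Initiation**: per hand, the start of the first ≥ 200 ms run with
  |v| above 5 % of that hand's maximum between ball onset and the first
  sample after the AE moment; the trial value is the earlier hand; a
  trial with no qualifying epoch is flagged, not defaulted.
* **AE**: for each effector (left, right, midpoint) the crossing of the
  ball *front* (centre minus contact radius along −z) through the
  effector's depth plane is located on a 1e−5 s interpolated grid; AE is
  the minimal xy distance at those crossings.  Ties are broken
  deterministically — single hand before midpoint, left before right.
  Against a 1e−6 s brute-force scan the analytic path agrees to < 1e−4 m.
* **Touch success**: sphere–box intersection between the contact-radius
  ball and the oriented 0.12 × 0.10 × 0.035 m palm colliders; for
  ingested logs a recorded collision flag takes precedence over the
  geometric recomputation (the recorded flag is what drove the scene).
* **X_early**: head x at (goal crossing − 0.5 s) minus head x at onset,
  sign-flipped to be positive in the curve direction (curved trials) or
  the required-movement direction (outer arrivals); 0.4/0.6 s probes are
  available for the robustness check and give the same sign pattern.

Aggregation is per-participant means over repetitions and averaged-out
factors, wall minus no-wall; empty cells propagate NaN rather than
raising, so missing cells surface in the statistics layer as flagged
untestable slots.

## Statistics

Shapiro–Wilk gates each comparison at p > 0.05 into a paired t (mean
reported) or an exact signed-rank test (median reported; W = T⁺ − T⁻ so
detrimental effects carry sign; zeros dropped; exact p for n ≤ 25).  AE
comparisons are non-parametric a priori — a positive-definite quantity
with optimal central tendency at zero.  The Mann–Whitney U for the one
between-group comparison uses the first-sample convention, recorded in
the result metadata.  Holm–Šídák adjusts each family step-down with
running-maximum monotonicity (and a guard so adjusted p never falls
below raw p by rounding); family sizes are fixed at 7 (confirmatory) and
16 (exploratory, eight per group) and shipped in the config so the
counts are auditable.  Untested slots keep their place in m.  A
summary-level null simulation (identical generative parameters for both
conditions, 1000 seeded repetitions) keeps the empirical family-wise
error of the 7-test chain within two Monte-Carlo standard errors of
0.05.

## Problem sizes

The shipped tests and acceptance checks use: all 18 experimental kicks
(plus all 63 where dummies matter), two-participant sessions for QC
label agreement, 15 synthetic participants × 180 experimental trials for
delay recovery, 100 random interception geometries for the AE oracle,
and 1000 repetitions for the null family-wise-error simulation — sizes
at which every Monte-Carlo criterion is stable under reseeding while the
whole suite runs in about a minute.

## Known limitations

* No post-bounce physics, wind, turbulence or spin decay; contact is
  detected but rebounds are not simulated.
* The wall is a screen: no per-player body shapes, gaps, or jumping.
* Occlusion durations depend on unreported scene geometry and are
  therefore calibrated to the documented 150–250 ms window, not known.
* The generator's behavioural parameters are plausible, not fitted;
  absolute outcome magnitudes are not comparable to human data (see
  above).
* Exact U and W conventions of other software vary; this package's
  conventions are declared in the output metadata.
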