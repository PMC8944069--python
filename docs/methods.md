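# Methods

## Model and procedure

`myosampler` treats the muscle redundancy problem probabilistically. The
observable is an elbow flexion–extension motion (angle and angular
velocity over 0.5 s); the latent quantities are the six muscle excitation
signals that produced it. Excitations are parameterized by 60 compact
radial-basis-function (CRBF) amplitudes (10 nodes per muscle, centers
every 0.0667 s from −0.05 to 0.55 s, width = two node spacings) squashed
through a numerically stable inverse logit. Compact support is the central
design property: each amplitude only reshapes the excitation inside its
node's 0.267 s window, so parameters stay locally decoupled — unlike
polynomial or Fourier bases, where every coefficient is global.

The forward model is a single-DOF elbow driven by six Hill-type
muscle–tendon units with rigid tendons and constant moment arms. Muscle
force combines a Gaussian active force–length curve (width 0.45 in
normalized length), a hyperbolic force–velocity curve (zero at the maximal
shortening velocity of 10 optimal lengths/s, eccentric plateau 1.4), an
exponential passive element (zero below optimal length, unit force at 60%
strain) and first-order activation dynamics (τ_act = 10 ms,
τ_deact = 40 ms). The 8-state ODE (angle, velocity, six activations) is
integrated with fixed-step classical RK4 at 2 ms for bit-reproducibility;
the integration loop and the full posterior evaluation are numba-compiled.

The posterior over amplitudes combines a tracking likelihood (positional
and velocity residuals scaled by 0.4 rad and 1.6 rad/s, summed over every
integrator reporting sample of the 0.5 s motion) with an effort prior: a
half-normal penalty with scale 0.08 on the summed integrated cubed
excitations, times a hard uniform box U(A) on [−30, 30] per amplitude
(outside the box the logistic is saturated to within 1e-13, so wider
search is redundant). Posterior = likelihood + prior holds exactly for
every evaluation; out-of-box proposals short-circuit to −∞ before any
simulation runs, and a diverged simulation maps to −∞ with a counter
rather than aborting the chain.

Sampling is delayed-rejection adaptive Metropolis (DRAM). Proposals are
multivariate normal; the covariance is s_d·(cov + 1e-6·I) with
s_d = 2.4²/d, recomputed every 100 iterations once 1,000 iterations (or 1%
of the chain, if larger) have accrued. The covariance estimate uses
exponentially weighted running moments with a 10,000-draw memory (exact
running moments until the window fills; `adapt_window=None` restores the
classic full-history recursion). The forgetting matters on this problem:
chains descend several hundred log-posterior units during burn-in, and a
full-history covariance stays inflated by that transit long after the
chain has localized, which was observed to trap occasional chains in
low-probability modes at a few percent acceptance. A windowed estimate
keeps the proposal matched to the chain's current neighbourhood. After a first-stage rejection, a second proposal is
drawn from the same covariance shrunk by 1/5 and accepted with the
standard two-stage probability that preserves detailed balance; if both
stages reject, the previous state is copied forward. A proposal with zero
posterior density is always rejected, including from a zero-density state,
so chains cannot drift while invalid. Chains are reproducible from
(master seed, chain id) via independent `SeedSequence` streams, and a
serial run equals any concurrent schedule.

## Synthetic reference data

The generator emulates a measured reference motion end to end:

1. **Target motion**: raised cosine, 0 → 90° → 0 over 0.5 s. The shape is
   a design choice (any smooth curve with zero endpoint velocities would
   do); the raised cosine has an analytic derivative and a peak angular
   velocity of π²/2 ≈ 9.87 rad/s.
2. **Ground-truth solve**: L-BFGS-B (finite-difference gradients, two
   fixed starts, deterministic) minimizes scaled tracking SSE + λ·effort
   over the 60 amplitudes, with λ = 1 so the optimum is tracking-dominated
   (achieved RMSE ≈ 0.13°, well under the 1° gate; maximum excitation
   ≈ 0.75, comfortably feasible). Using the same CRBF parameterization as
   the sampler makes the truth directly comparable to posterior draws.
3. **Measurement chain**: the truth kinematics are sampled at 100 Hz,
   given iid N(0, 0.01 rad²) noise, low-passed with a zero-phase
   (dual-pass) 2nd-order Butterworth at 15 Hz, and differentiated by
   central differences. The likelihood interpolates these observations
   onto its own grid, as one would with motion capture sampled below the
   model rate.

The generator reproduces bit-identically from (config, seed); no stored
data files are needed anywhere in the test suite.

What the synthetic data do *not* emulate: soft-tissue artifact and
marker-placement error (noise is iid Gaussian on the joint angle), model
mismatch (the same muscle model generates and fits the data), and
multi-DOF kinematic coupling. Passing tests therefore demonstrate the
correctness and calibration of the inference machinery, not robustness to
the structured errors of real motion-capture pipelines.

A mass-spring-damper fixture (closed-form underdamped solution, known
stiffness/damping, Gaussian observation noise) provides an independently
solvable system on which the same sampler demonstrably recovers parameters
inside its credible intervals.

## Default study geometry

The full-scale geometry (7 chains × 500,000 iterations) is supported but
the default `RunConfig` runs a scaled-down study: **6 chains × 200,000
iterations, 50% burn-in, 25 evenly spaced post-burn-in subsamples per
chain** (150 proposals). The length was chosen because cold-started chains
(uniform[−15,−5] amplitudes, i.e. silent muscles) need roughly 100–150k
iterations to reach the equilibrium log-posterior band; shorter chains
measure the burn-in transient rather than the posterior. Six chains rather
than four dilute the occasional straggler chain that equilibrates late.
With the compiled forward model the default study runs in ~10 minutes on
one CPU core.

Typical results at this geometry: average posterior-sample tracking RMSE
≈ 1.4–1.5° (angle) and ≈ 23°/s (velocity) — the velocity figure sits close
to the measurement-noise floor of the differentiated reference (~20°/s) —
posterior effort ≈ 0.10–0.17, flexor force concentrated in the first third
of the motion and extensor force in the middle third, and the ground-truth
force trajectories inside the sampled mean ± 2 SD envelopes at ≳ 90% of
time points. Split-R̂ stays well above 1.1 with ESS of order 10: the
chains characterize the posterior's tracking behaviour long before they
mix in the 60-dimensional amplitude space, and the diagnostics are
reported precisely to make that visible.

## Numerical choices and edge cases

- CRBF value at the support boundary |t−c| = w is defined as the
  continuous limit 0, avoiding the 1/(1−s²) singularity; the bump
  underflows to exactly 0 slightly inside the boundary in float64.
- The inverse logit applies `exp` only to negative arguments (two-branch
  form); no overflow for |F| up to at least 1e4. For F ≳ 14 the result is
  within machine epsilon of 1, which bounds any logit round-trip at
  ~e^F·eps.
- Amplitude bounds are enforced in the prior (−∞ outside), never by
  clipping, so the sampler sees the box as a hard rejection.
- Effort integrals use the trapezoidal rule on the likelihood grid.
- The fiber length is floored at 1% of the optimal length (slack
  muscle–tendon unit); hitting the floor logs a warning.
- Rank histograms use average ranks for ties and 20 bins; R̂ rank-
  normalizes via the Blom-type transform (r − 3/8)/(S + 1/4); both match
  the reference ArviZ implementations to 1e-6 (cross-checked in tests
  only).
- Degenerate (constant) chains report R̂ = NaN and ESS = 0 with a warning
  instead of raising.
- Parameter correlations in the diagnostics report are computed within
  each chain's post-burn-in draws and averaged across chains: with unmixed
  chains, pooling draws first would let between-chain displacement
  masquerade as correlation and mask the adjacent-node trade-offs the
  compact basis induces. The pooled-draw estimator remains available as
  `parameter_correlations`.

## Known limitations

- Constant moment arms and generic muscle parameters stand in for
  subject-specific geometry; the tracking-based results are robust to
  these choices but the absolute force magnitudes are illustrative.
- One delayed-rejection stage only; no gradient-based samplers (the
  posterior is treated as a black box by design).
- The scaled-down study does not mix in the full amplitude space (nor did
  the full-scale geometry in the motivating setting); inferences about
  individual amplitude marginals should lean on the reported R̂/ESS, while
  trajectory-level summaries (kinematics, forces, effort) stabilize much
  earlier.
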