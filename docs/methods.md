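# Methods

This note records the models behind `thermopid`, the defaults and why
they were chosen, the numerical choices that matter, and what the
package's synthetic benchmarks do and do not demonstrate about a
physical device.

## Closed-loop design model

The controller is designed against a canonical second-order closed
loop Q(s) = ωn²/(s² + 2ζωn s + ωn²). Transient requirements map to
pole constraints with the standard rules: ωn > 1.8/tr (the 1.8/ωn
rise-time rule is the 10–90% approximation for moderately damped
systems; for a critically damped loop the true 10–90% rise is
3.36/ωn, so a ζ = 1 design is conservative against the rise-time
requirement), σ > 4.6/tss (1% settling), and ζ above the root of
exp(−πζ/√(1−ζ²)) = Mp_max, solved by bisection on [0, 1−1e−9] to
|Mp(ζ) − Mp| < 1e−10 (deterministic, no seed).

The plant is the overdamped two-time-constant transfer function
P(s) = g/((τ1 s+1)(τ2 s+1)) with g in K per unit control input.
Internally all temperatures are °C; gains are per kelvin of error
(identical increments). Inverting C = Q/((1−Q)P) gives the PID with a
first-order derivative filter; this is the only reading of the design
equation that lands exactly on the PID structure, and continuous-time
algebra makes the closed loop equal Q(s) identically. Consequences
used as test oracles:

- the discrete loop (10 Hz, backward-Euler PID) reproduces the
  analytic Q(s) step response to <1% of the step amplitude whenever
  the derivative gain is not floored (see below);
- the derivative-filter constant follows τd = 1/(2ζωn), which for the
  benchmark phantom (ζ = 1, ωn = 0.2 rad/s) gives τd = 2.5 s and
  reproduces the benchmark Kp = 0.26 1/K; the companion value
  τd = 2.17 s sometimes quoted for the same design is inconsistent
  with that closure and is not used;
- Kd = κ(τ1−τd)(τ2−τd) evaluates to 0.118 s/K for the benchmark
  plant. Published roundings near 0.11 are treated as arithmetic
  artifacts, not targets.

When τ1 < τd the algebra calls for a negative derivative gain; the
implementation floors Kd at zero with a warning, because a negative
derivative gain amplifies noise and destabilizes the discrete loop.
The loop-equals-Q(s) equivalence deliberately does not hold in that
regime.

## Plant identification

Three readings are taken from a heating step response:

- static gain g = ΔT_saturation/u_step;
- graphical estimates: the time of maximum heating rate ("inflection
  delay") and the 63%-of-gain crossing τ63. For an overdamped
  second-order response the inflection time is
  τ1τ2·ln(τ2/τ1)/(τ2−τ1), which only approaches τ1 in the
  τ1 → 0 limit — for the benchmark phantom it is 13.3 s against
  τ1 = 2.96 s. The graphical readings are therefore reported for
  interpretability and used to initialize the fit, not as the final
  estimate;
- a two-exponential least-squares fit of the full step shape
  (`scipy.optimize.curve_fit`), which is the authoritative estimator.
  Noiseless synthetic steps recover (g, τ1, τ2) to well under 5%; at
  40 dB SNR the median over 100 seeded trials stays under 15% for all
  three parameters. Per-trial τ1 error can be much larger — the fast
  constant carries only a few seconds of signal under a 250 s
  envelope, an information limit no estimator escapes — so recovery
  claims are about the central estimate.

Short pulses that never reach 63% of the asymptote are identified by
supplying the saturation level from a model run; τ63 is then read off
the fitted curve. Non-monotone heating segments are rejected when a
widely smoothed trace dips more than 3× the robust (MAD-based)
standard deviation of the detrended signal below its running maximum.

The undamped natural frequency comes from the peak spacing of a
proportional-only closed-loop oscillation (5-sample pre-smoothing,
peaks must clear 3× the noise floor, first sample of a plateau on
ties). The characteristic equation 1 + kp·P(s) = 0 provides the
independent oracle: kp = 0.53 on the benchmark plant rings with a
31.0 s period, i.e. ωn ≈ 0.2 rad/s.

## Thermal phantom model

The phantom is a 1 ml agarose cylinder (radius 4.5 mm, height 15.7 mm
— derived from the stated volume, since only the tube volume is
given) with a copper wire (radius 1 mm, length 4.52 mm) at its center
and the probe 1.3 mm from the wire surface at mid-height. Gel
properties: ρ = 960 kg/m³, Cp = 3900 J/(kg·K), k = 0.566 W/(m·K),
h_conv = 21 W/(m²·K), T∞ = 21.1 °C. Wire properties are standard
copper (ρ = 8960, Cp = 385, k = 400 SI units). Convective loss is
applied on all outer surfaces (the physical sample hangs in air);
conduction to the holder is neglected.

The electromagnetic problem is not solved. The wire carries a uniform
volumetric source Q = c·H², calibrated so the steady probe rise at
the 9.78 kA/m reference field equals the measured 23 K; because the
conduction problem is linear, one trial steady solve plus scaling
fixes c. Quadratic field scaling (ΔT ∝ H²) is then exact by
construction and matches the physics of induced eddy-current power.

Discretization is cell-centered finite volumes on an axisymmetric
(r, z) grid, default 24 × 48. Face conductances put the two half-cells
in series (harmonic), keeping the scheme conservative across the
wire/gel interface; boundary faces add the convective film in series.
The wire is represented by exact cell-overlap fractions, which makes
the total deposited power independent of the grid — refinement then
probes only conduction error. Time stepping is implicit backward
Euler (unconditionally stable; factorization cached per Δt), default
Δt = 0.1 s in the loop and 0.5–1 s for open-loop studies; an explicit
scheme with an automatic Gershgorin stability check is available for
cross-validation. Verified discrete properties: energy balance to
round-off with insulated boundaries, steady wire power equal to
surface loss, maximum principle under cooling, <5% probe change
between the two finest grid levels and <1% under Δt halving. A grid
with less than one cell across the wire radius errs by >15% and is
flagged. The simulated step response has τ63 ≈ 270 s, the same order
as the physical phantom's 252 s; exact agreement is not expected
because the real tube geometry and 3D boundary details differ.

## Closed-loop runtime

Each 100 ms interval runs: sense → safety gate → PID → RC limit →
actuate → plant advance → dose update. Choices the hardware leaves
open, fixed here and exposed as config:

- backward-Euler integral with clamping anti-windup (integration
  frozen while the output saturates in the error's direction);
- derivative on the error through a first-order filter with constant
  τd (the design algebra differentiates the error, so the loop does
  too);
- bumpless start: the integral is preloaded to u_min/Ki so the
  controller wakes at the actuator floor; no preload when the floor
  is at or below zero;
- the RC smoother (τ = 0.2 s) is discretized exactly per step; the
  worst-case 0.25→1.25 V step slews at 4.99 V/s sampled at 1 ms,
  meeting the 5 V/s supply fault bound with equality only in the
  continuous limit;
- the safety gate strictly overrides the PID *and* the smoother: a
  tripped threshold forces zero output within one control step
  (modeling the supply's ≤0.2 s power-down as at most one step), and
  a missing or non-finite probe reading fails safe. Gate hysteresis
  is zero — the relay chatter this produces against an adversarial
  threshold is the expected behavior and is bounded by the plant lag;
- the volts→field map is linear through the supply anchors
  (0.25 V → 4.2 kA/m, 1.25 V → 9.8 kA/m) over the working range and
  falls to zero field at 0 V; a normalized mode (H = u·H_max,
  u ∈ [0, 1]) serves pure simulation studies;
- CEM43 uses R = 0.5 above / 0.25 below the 43 °C breakpoint
  (Sapareto–Dewey); the constants are config.

The tuned benchmark run (37 → 45 °C, 15 min) delivers CEM43 ≈ 56 min
against the 60 ± 5 min requirement; the gap below the 60 min plateau
is the rise phase, during which the actuator ceiling (not the linear
design) limits the heating rate.

With a noise model attached, the loop synthesizes one raw 10 kHz
block per interval, runs it through the persistent-state Butterworth
filter and takes the block mean — the same processing as the real
signal path; a seed is then mandatory and runs are bit-reproducible.

## Sensor signal chain

The raw path is 10 kHz sampling, a causal four-pole 100 Hz low-pass
Butterworth, then 1000-sample block averaging to the 10 Hz control
rate. The filter is discretized by impulse invariance rather than the
bilinear transform so its magnitude stays on the analog curve
1/√(1+(f/fc)⁸) — 3.01 dB at the cutoff and 80.0 dB one decade above —
instead of picking up warping (the bilinear design reads 81.2 dB at
1 kHz); the aliasing cost is negligible with the cutoff two decades
under the sample rate, and the DC gain is renormalized to exactly 1.
Averaging 1000 white-noise samples removes 30 dB of noise power;
chain group delay (≈4 ms filter + 50 ms half-block) stays under one
control interval. SNR is measured as trend power over residual power
after a 1 s moving-mean detrend with half a window trimmed at each
edge; a numerically zero residual reports +inf. Bench-specific SNR
figures (57.6 dB shielded, 69 dB reference reader) depend on the
physical EMI environment and are not reproduced; the chain is
validated by its analytic gains instead.

The synthetic sensor fixture adds seeded Gaussian noise, narrowband
interference tones and a DC offset to an upsampled clean trace. It
emulates wideband EMI statistics but not ground loops, shield
effectiveness or reader nonlinearity, so a passing chain test says
the *processing* meets its analytic gains, not that a particular
bench will reach a particular SNR.

## Sensitivity analysis

Inputs and uncertainties mirror the phantom's measured tolerances:
H_gel 9.78 kA/m ±5%, probe distance 1.3 mm ±5%, k_gel ±1%,
σ_gel ±5%, Cp ±1%, ρ ±1%, h_conv ±5% (a ±10% preset exists for the
field/placement pair). The "±X%" figures are read as the half-width
of a symmetric 95% interval: family 'normal' (default) uses
SD = X%/1.96 truncated at ±3 SD; 'uniform' spans baseline·(1±X%).
The family is a config switch because the choice materially changes
the output spread, which is why published output-PDF numbers
(mean 22.87 °C, SD 2.32 °C from a 3D finite-element surrogate) are
treated as qualitative, not targets.

The model function is a steady-state conduction solve on a coarse
12 × 24 grid, self-calibrated so the baseline vector returns the
measured 23 K rise, with ΔT ∝ H² exploited to avoid re-solving for
field variation. The 30 min evaluation time is ~6 thermal time
constants (>99.7% of steady), so the steady read is used directly;
heat capacity, density and gel electrical conductivity — transient-
or electromagnetic-only parameters — consequently have exactly zero
effect in the surrogate, consistent with their reported minor roles.
One desk-scale departure: h_conv ranks second after H_gel here,
ahead of probe distance and conductivity, because in a small phantom
losing heat only by surface convection the film coefficient sets the
steady temperature scale directly. The headline conclusions — field
amplitude dominates, interactions are negligible, the output PDF is
near-normal — hold across methods and seeds.

Morris screening uses radial one-at-a-time steps (4 levels, 20
trajectories, Δ = p/(2(p−1))) with effects in kelvin per unit range;
a failed model evaluation discards its whole trajectory with a
warning. Sobol indices use Saltelli pairing with Jansen-style
estimators on centered outputs (centering is essential: the
first-order estimator's Monte-Carlo error otherwise scales with the
output mean) at (d+2)·n evaluations, default n = 1024, with a
bootstrap Monte-Carlo error. Kernel density estimation uses Gaussian
kernels with Silverman bandwidth by default. All stochastic routines
require a seed and are reproducible; doubling n shrinks the
bootstrap error.

## File formats

Config files are INI-style key-value text with sections; every
physical key carries a unit suffix (`tau1_s`, `g_k_per_v`) to keep
oersted/kA·m and volt/field conversions explicit (1 Oe = 79.5775 A/m;
run headers log the conversion and the actuator anchors). Traces are
plain CSV (`time_s, T_probe_C[, T_safety_C, u_V, H_kA_per_m, gated,
cem43_min]`) with strict uniform-time validation and exact
round-trips. The verification report scores a run against the
treatment requirements (hold duration, dose, rise, overshoot,
settling, safety dominance, gate-event alternation) and renders as a
markdown table or JSON lines; requirements a trace is too short to
decide report "indeterminate".

## Known limitations

- No electromagnetic field solve: the calibrated Q ∝ H² source is
  exact for steady scaling but cannot capture spatial eddy-current
  structure in the wire.
- Material properties are temperature-independent and there is no
  perfusion term — appropriate for a gel phantom, not for tissue.
- The LTI plant mode is the identified small-signal model; large
  set-point excursions in a real system would show gain curvature.
- No adaptive retuning, MIMO, or model-predictive control; no
  hardware I/O, vendor data formats or real-time guarantees.
- The desk-scale problem sizes (24 × 48 grid, 10 Hz loops of up to
  15 simulated minutes, n = 256–1024 sensitivity samples) were chosen
  so the full verification suite runs in about a minute on one core
  while keeping every convergence margin comfortably inside its
  acceptance band.
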