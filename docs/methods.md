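# Methods

## Model

The superior colliculus (SC) is modelled as a one-dimensional field of
N = 100 rate-coded nodes; nodes 1–50 form the left SC map and 51–100 the
right.  Each node's internal state obeys a leaky integrator driven by
lateral input, external input and background noise,

    dx_i/dt = tau_i ( -x_i + sum_j w_ij A_j + I_ext,i(t) + I_n,i ),

with activity `A_i = 1/(1 + exp(-beta x_i)) - theta`, bounded in
(−θ, 1−θ).  `tau_i` is a per-node *rate constant* in ms⁻¹: larger tau means
faster accumulation (implied membrane time constants 1/tau ≈ 60–250 ms,
consistent with 200–400 ms saccade latencies).  The alternative
time-constant reading (`tau_semantics="time_constant"`) is available but
makes faster groups slower, contradicting the group-difference direction the
parameters are meant to express.

The reactive (stimulus-driven) input drives nodes 18–22 of the left SC with
strength `I_r = 1` from t = 50 ms; the planned (volitional) input drives the
mirror pool 78–82 of the right SC with `I_p = 1.5`.  Both stay on for
600 ms; the trial lasts 650 ms.  The decision readout is the activity of the
central node of each pool (node 20 = error prosaccade, node 80 =
antisaccade) against a shared threshold `T_h = 0.1791` (which corresponds to
an internal state of x ≈ 1.50); a crossing triggers a saccade command after
a 30 ms efferent (conduction) delay.

Trial-to-trial variability follows the LATER tradition: each trial draws one
rate per hemisphere, left from N(0.01685, 0.003) ms⁻¹ and right from
N(0.0065, 0.0016) ms⁻¹ in the control condition, left N(0.0135, 0.005) and
right N(0.004, 0.002) in the schizophrenia condition (draws rejected until
positive).  All other parameters are identical between conditions: the
patient deficit is *only* slower, noisier evidence accumulation.

## Interpretation choices the equations do not fix

Four conventions are underdetermined by the model equations; each is a
config switch, with defaults chosen as follows.

1. **Rectified lateral transmission** (`lateral_rectify=True`).  The shifted
   sigmoid gives suppressed nodes negative activity.  If signed activities
   are transmitted through the lateral weights, the constant inhibitory
   surround times a negative activity *excites* the rival map, and the two
   hemifields' activity sums cancel almost exactly — measured hemifield sums
   stay near zero and the inhibitory offset C loses all dynamical effect, so
   no winner-take-all competition can arise.  Activities entering the
   lateral sum are therefore clipped at zero (firing rates are
   non-negative); the state equation, readout and the x = 0 resting fixed
   point are untouched.

2. **Noise held per trial** (`noise_mode="per_trial"`).  The background
   current I_n,i ~ N(0, 0.05) is drawn once per node per trial.  Drawn fresh
   every Euler step (the `"per_step"` option) the noise averages down to
   state fluctuations of order 10⁻⁴ and plays no dynamical role; held per
   trial it shifts each pool's effective drive by a few hundredths — exactly
   the asymptote variability that lets a minority of trials cross the error
   threshold while most do not.

3. **Planned-input onset** (`planned_onset_mode="absolute"` in the
   calibrated conditions).  The task description admits two readings of the
   onset parameter T: planned input at t = T (both decision signals arrive
   together at T = 50 ms, their *afferent-delay difference* being the
   50 ms), or planned input T ms after the reactive input.  The relative
   reading leaves antisaccade latencies ~50 ms too slow at any kernel that
   fits the remaining statistics; the absolute reading is the default for
   the calibrated conditions, the relative one remains available (and is the
   raw `NetworkParams` default).

4. **Rate-draw granularity** (`tau_granularity="per_hemisphere"`).  One draw
   per hemisphere per trial preserves the LATER picture of a unitary
   decision signal with trial-varying rate.  Per-node draws
   (`"per_node"`) average within the 5-node pools, compress RT variability
   and fit the control statistics more tightly, but break the patient-side
   predictions badly (error rate ≈ 56 % vs 40 %, corrected errors ≈ 29 % vs
   58 %); the per-hemisphere default keeps the patient side an honest
   out-of-sample success.

## Kernel calibration

The lateral kernel is a shifted Gaussian of inter-node distance,
`w_ij = B (g(|i-j| dx) - C)`, symmetric and translation-invariant, with
linear (non-wrapped) distances.  The published constants are mutually
inconsistent with the published behaviour in three ways, found by direct
simulation: (i) with the `1/(4 pi sigma)` normalization every weight is
negative, so no node can ever reach threshold; (ii) dropping the
normalization, a width of sigma = 10 node spacings leaves the kernel
net-excitatory out to ±20 nodes, so any gain high enough to permit threshold
crossing ignites a hemifield-wide bump whose inhibition permanently clamps
the other map — the first pool to ignite always wins and corrected
antisaccades never occur; (iii) the printed offset C = 0.35 yields either
those pathologies or no crossings at all.  The kernel shape is therefore
treated as what the model text calls it — free parameters — and fitted
*once*, on the control condition only, by deterministic grid search
(`experiment.calibrate_kernel`; the gain-only search of
`experiment.calibrate_amplitude` is a special case).  The objective is the
summed squared relative error of the six control-side headline statistics
(three category medians, error rate, percentage of errors corrected,
antisaccade CV) at a fixed master seed.  The shipped result is

    kernel_norm   = "unnormalized"     (no 1/(4 pi sigma) factor)
    B (gain)      = 1.285
    C (offset)    = 0.272
    sigma         = 2.4 node spacings  (0.1508 rad)

giving near-neighbour excitation confined to ±3–4 nodes and constant
long-range inhibition of −B·C per unit activity.  The patient condition
reuses this kernel verbatim, so every patient statistic is an out-of-sample
prediction of the rate-distribution hypothesis.

## Numerics

Fixed-step explicit Euler, dt = 0.5 ms (1300 steps per trial), with the
noise current held constant over each step and no √dt rescaling; halving dt
moves noise-free threshold-crossing times by well under 1 ms.  Threshold
crossings are linearly interpolated between the bracketing samples (≥
comparison, first crossing only).  Ensembles are integrated in vectorized
chunks; every trial owns a counter-based child seed
(`SeedSequence((master_seed, index))`), so results are bit-reproducible,
independent of chunking, and extending an ensemble never reshuffles earlier
trials.  Rate draws use per-draw rejection of non-positive values.

All quantiles (medians, quartiles, the 5 %-percentile grid) use linear
interpolation between order statistics (numpy's default, "type 7").  The
Wilcoxon signed-rank test discards zero differences, midranks ties, and uses
exact enumeration of all 2ⁿ sign assignments for n ≤ 12 (valid under
midranks) with a tie- and continuity-corrected normal approximation above;
the z statistic is always reported from the approximation.  Reciprobit
regression excludes the 100 % grid point (infinite probit) and fits probit
on −1/RT by ordinary least squares; the homogeneity-of-slopes test is the
pooled regression with a group-by-predictor interaction (slope t on n−4
degrees of freedom; intercept t from the equal-slopes model on n−3), with
the convention t = 0 for a 0/0 ratio and ±∞ for a nonzero coefficient with
zero residual variance, so exactly-degenerate inputs remain well-defined.

## What the simulations do and do not show

The synthetic ensembles emulate the *statistical structure* of antisaccade
behaviour under the two parameter sets: latency distributions per category,
error rates and correction rates, and their group contrasts.  They do not
emulate saccade kinematics, spatial accuracy, express saccades, sequential
trial-to-trial effects, or any within-subject heterogeneity beyond the two
rate distributions — passing tests say nothing about real eye-movement
recordings beyond the model's own claims.

Problem sizes: reproduction runs use the study's 5000 trials per condition;
unit tests use 10–60-trial ensembles and shortened (300 ms) trials where
only mechanics are at stake.

## Known limitations

At the frozen control-side calibration, measured residuals against the
published simulated values remain, and the test suite reports them as
failures rather than hiding them:

* the control antisaccade CV is ≈ 0.30 against a published 0.17 — with the
  published right-SC rate spread (sigma2/mu2 ≈ 0.25) a LATER-style race
  cannot produce an interquartile CV of 0.17 under any variant examined;
* the percentage of errors corrected is ≈ 87 % (control) and ≈ 34 %
  (patient) against 98.09 % and 58.13 % — prompt correction wants weak
  winner-on-loser suppression while the published corrected-antisaccade
  interval medians (181/250 ms) want strong suppression, and a symmetric
  kernel cannot do both;
* a correct crossing is followed by a late error crossing in roughly 1–4
  trials per 10,000 rather than strictly never: with Gaussian per-trial
  noise there is always a tail in which a lucky reactive pool clears
  threshold after a slow antisaccade, and suppression strengths that
  eliminate it entirely push the RT statistics far from their targets.  All
  *ordering* properties (antisaccade slower than error within condition;
  patients slower, more error-prone and worse at correcting than controls)
  hold robustly.
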