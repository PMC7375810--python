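# Methods

## The canonical model

The fast subsystem is the planar unfolding of the degenerate
Takens–Bogdanov singularity,

    dx/dt = -y
    dy/dt = x^3 - mu2*x - mu1 - y*(nu + x + x^2),

with `x` the observable (a proxy for the field potential) and `y` an
auxiliary recovery variable. Fixed points sit at `y = 0` on the roots of
the cubic `x^3 - mu2*x - mu1`; their linear stability is governed by
`det = 3x^2 - mu2` (a saddle when negative) and `trace = -(nu + x + x^2)`.
The unfolding is valid in a neighbourhood of the singularity, so the three
parameters are constrained to a sphere of radius **R = 0.4** (configurable)
in `(mu2, -mu1, nu)` space; all parameter points produced from spherical
coordinates satisfy the constraint to machine precision.

Model time is dimensionless. For recordings, one time unit maps to
**0.0135 s** (configurable), chosen so the limit-cycle period (~9 time
units) lands near 8 Hz spiking while ictal lengths land in the tens of
seconds. Only relative timescales matter to the science.

### Slow drive

The slow variable `z` in [0, 1] parameterises a great-circle path on the
sphere. Two drives are implemented behind one contract (while the fast
subsystem rests, `z` heads toward the onset crossing; once it oscillates,
the drift reverses):

* **smooth** (default): `dz/dt = eps * dir * (1 - d/d*)`, where `d` is the
  distance of `(x, y)` from the nearest *stable* fixed point at the current
  `z`. Where no stable point exists the reference continues the nearest
  rest branch (its "ghost"), so a state that has just crossed a fold is not
  mistaken for a developed seizure. `d* = 0.15`: it must stay below the
  saddle-to-node separation, or the slow crawl near a homoclinic is read
  as rest; `|dz/dt|` is capped at `drive_cap * eps` (default 3).
* **hysteretic**: `dz/dt = ±eps`, switched by a windowed regime detector.
  Simple, but it stalls when the oscillation period outgrows the window
  near SN/SNIC/SH crossings; it is retained because the slow-wave types
  (SNIC/SNIC, SupH/SupH) burst by amplitude crossing the detection floor,
  which the distance rule cannot reproduce (it settles at constant
  amplitude instead).

`eps` defaults to 0.005 1/tu; experiments that need visible scaling laws
use 1e-4–1e-3 (see below). An ultraslow drift rotates a path endpoint
toward a target along a great circle at constant angular velocity (so it
stays on the sphere); the integrator refuses drifts faster than one ictal
length per 0.1 rad.

### Integration and regime detection

Euler–Maruyama in time with a Heun (predictor–corrector) deterministic
step for the fast variables: plain Euler destabilises the slow crawl near
saddles and ends seizures far from the true homoclinic. Noise is additive
on `x`, `y` and `z`, scaled by `sqrt(dt)`; fixed step (default dt = 0.01,
ensembles 0.02, guarded by `dt <= 1e-3/eps`); identical seed and settings
give bit-identical output. A blow-up guard (|x|, |y| < 1e3) aborts with the
failure time.

The regime detector calls a window oscillating when its peak-to-peak range
exceeds both five times the resting noise floor and an absolute amplitude
floor, with at least two zero crossings of the detrended signal. Two
calibrations matter: the noise floor is *measured* from the first completed
window (the weakly damped rest states amplify injected noise five- to
seven-fold), and the amplitude floor defaults to 0.4 because genuine limit
cycles of this unfolding have peak-to-peak above ~0.5 while
critical-slowing fluctuations near a fold reach ~0.3. The window default is
25 time units (at least two oscillation periods).

## The seizure map

Saddle-node curves are closed-form (double root at `x = s`:
`mu2 = 3s^2`, `mu1 = -2s^3`, sphere constraint fixing `nu`); the two
branches meet at cusps at the poles. Hopf points solve the fixed-point and
zero-trace conditions with `det > 0`; each is labelled super/subcritical by
the first Lyapunov coefficient, which for this vector field reduces to
`16 l1 = -2 + 6x(1+2x)/(3x^2 - mu2)` (negative = supercritical; verified
against simulation in the tests).

Regions are classified by a brute-force oracle: vectorised RK4 integration
(dt 0.05, 400 tu transient, 200 tu detection) from three initial
conditions per point (near the most unstable focus and two outer points),
plus the analytic fixed-point count. A trajectory counts as a cycle when
x keeps a range above **0.05** — below that threshold the slowly decaying
spirals near the Hopf curve leave ring-down residuals that masquerade as
cycles — with at least three upward zero crossings of `y`. The default
grid is 181x361 in (theta, phi), an equirectangular chart with the polar
angle measured from the +nu axis.

Cycle-death boundaries that have no closed form are traced from the grid
and sub-labelled: SNIC requires the fold to lie on the cycle's closure
*and* a divergent period (> 18 tu adjacent to the boundary); SH requires a
saddle on the cycle's closure (trajectory within 35% of the amplitude);
FLC requires the amplitude to stay finite (>= 0.1); fold-adjacent points
with neither signature are emitted unlabelled. Boundaries within 2.5 grid
steps of the Hopf curve belong to the analytic curve and are skipped.

Path crossings of analytic curves are found by bisection on the cubic
discriminant (SN) and on the tracked fixed-point trace (Hopf) to
|dz| <= 1e-6; numeric curves are intersected as polylines with the path's
plane. A fold crossing lying on a traced SNIC chain is relabelled SNIC;
numeric crossings that coincide in `z` with an analytic one defer to it;
tangential near-crossings are flagged, not dropped.

### Planar dynamotype enumeration

A hysteresis-loop type (onset O, offset F) is accepted when some
great-circle path has crossings `z_F < z_O` such that the interval between
them is bistable rest/seizure with exactly one occupied rest branch
(checked analytically at the exact path points — grid lookup misreports on
paths running parallel to a curve), only the cycle survives just beyond
`z_O`, the cycle is gone just below `z_F`, and no other crossing interrupts
the interval. The slow-wave types (one curve that both starts and stops
the seizure) are accepted where the curve directly separates oscillating
from resting territory. Every accepted pair is finally confirmed by
running the slow-driven model on (a trimmed neighbourhood of) its exemplar
path and requiring at least three complete rest/seizure alternations,
under either slow-drive mode; candidates that cannot sustain bursting
(e.g. a supercritical Hopf under the distance rule, which produces tonic
constant-amplitude spiking) are rejected.

On the R = 0.4 sphere at 181x361 this enumeration finds **eight** planar
dynamotypes: SN/SH, SN/SNIC, SN/SupH, SNIC/SNIC, SubH/FLC, SubH/SH,
SubH/SNIC and SupH/SupH. The count is sensitive to which SNIC-offset
corridors one admits: the two SNIC-offset hysteresis types are sustained
bursters here (their terminal ISIs diverge into the located fold-on-circle
crossing), but sit close to the fold curve where sub-labelling is
resolution-limited.

## Surrogate seizures

The generator writes down spike trains whose first and last `n_law = 10`
spikes follow the taxonomy's laws exactly (so they serve as analytic
ground truth): square-root amplitude growth/decay sampled half an interval
from the boundary; square-root frequency via per-gap evaluation of the
instantaneous period over a law span of three window lengths (a long
opening/closing interval, then gradual change); logarithmic ISI divergence
`ISI = isi*(1 + 0.8 ln(T/(t_off - t)))` ending 2% of the span before the
homoclinic time (steep enough that the terminal slowing survives 10%
jitter); constant laws for SN/SubH/FLC. Defaults: 8 Hz nominal rate,
amplitude 10 background SDs (SNR 10), 60 s duration, multiplicative
seeded jitter. Spikes are rendered as derivative-of-Gaussian biphasic
transients (50 ms width) on white Gaussian background; DC shifts are
sigmoid steps (6 SD, 0.3 s rise, 2 s persistence) on a DC-coupled channel,
and the AC channel is the zero-phase high-passed twin (0.3 Hz default —
high enough to remove a baseline step within the detector's persistence
horizon on a minute-long record).

What the surrogates do *not* emulate: 1/f background, artifacts, spatial
structure, or multi-bifurcation transitions. Passing the surrogate
validation therefore shows the decision rules and measurements are
internally consistent at realistic SNR, not that clinical recordings would
classify at the same rate.

## Measurements

Spike detection works on a Gaussian-smoothed (4 ms) trace minus a 0.45 s
running-median baseline (which removes in-seizure baseline shifts and the
filtered residue of DC steps while passing < 200 ms transients). Peaks
must rise above `c x SD` (c = 3, background SD re-measured on the
detrended trace) by their own prominence; a peak is rejected when its
half-prominence width exceeds 200 ms, or when it is the only prominent
peak in a supra-threshold run of the *background* deviation wider than
200 ms (a broad pedestal is not a spike; several prominent peaks bridged
at threshold are). The two lobes of a biphasic transient merge within a
60 ms refractory span, timed at their midpoint. Peak-to-peak amplitude is
measured in a ±30 ms window, bias-corrected by half the background's own
peak-to-peak floor; detections whose floor-corrected amplitude falls below
`c x SD`, or below 10% of the series' 90th percentile, are discarded.

Background statistics are median and scaled MAD over a >= 5 s pre-ictal
window ending 1 s before the marked onset. The DC-shift test runs on the
DC-coupled channel only (explicitly "not assessable" otherwise): a
median-filtered (0.25 s) deflection from the pre-boundary baseline that
exceeds five background SDs in the median over a full second (spike
residue may wiggle through the threshold), persists at least 1 s, and rose
from 10% of its plateau in under 0.5 s. "Five times the background
variance" is implemented as five standard deviations — a variance
threshold against a deflection in signal units is dimensionally
inconsistent.

## Classification

For each boundary window (first/last 10 spikes by default; 30 for
model-generated seizures, which run to hundreds of spikes) the candidate
laws are fitted with the bifurcation time free within ±5 s of the mark:
constant; `A = c*sqrt|t - t_bif|`; `ISI = 1/(c*sqrt|t - t_bif|)` (the
frequency law, fitted in ISI units so all rate laws share a target
variable and their AICc values are commensurable); and, at offset,
`ISI = a + b*(-ln(t_bif - t))` with `b > 0`. Selection is by small-sample
AICc (parameter counts 1/2/3), ties toward fewer parameters.

Onset order: amplitude-sqrt winning with the first amplitude "near zero"
(below 45% of the window maximum after floor subtraction — the operating
point must sit above the smallest detectable amplitude, ~3 SD out of SNR
10 — or below 65% with the sqrt law beating constant by > 6 AICc);
frequency-sqrt winning with a dominant first interval (> 3x the window
median, with the second interval still long — a single fold-ghost latency
followed by abrupt full-rate spiking is not a SNIC) or sustained
acceleration (first-three over last-three interval medians > 1.6; a pure
sqrt passage sampled at consecutive spikes bounds the single-interval
ratio near 2.1, so the ratio-3 test alone would be blind to genuine
passages); then DC shift present -> SN(+DC); otherwise SN(-DC)/SubH.
Offset mirrors it: ISI slowing (divergence law winning, with a long last
interval, sustained deceleration, or — because the homoclinic's divergence
is only logarithmic — a mild monotone growth of 10% with the law beating
constant by > 2 AICc) makes the SH family, split by the offset DC shift;
square-root amplitude decay to near zero with non-slowing ISI is SupH;
anything else is FLC. The slowing flag is reported independently for
cohort tabulation, where seizures shorter than 25 s are excluded from
offset tabulation. Confidence is a logistic map of the AICc margin, halved
under a low-spike-count flag. Fewer than four spikes, or spikes whose
floor-corrected median amplitude is within twice the background floor,
yield 'unclassified'.

## Experiments

**Gold-standard validation.** 60 seizures per grouped class (onsets SupH,
SNIC, SN(+DC), SN(-DC)/SubH; offsets SupH, FLC, SH(+DC), SH(-DC)/SNIC),
classified blind. Surrogate source: five onset/offset source combinations
cycle so each grouped class receives exactly 60. Simulator source: SN/SH
batches (eps 1e-4, sigma 0.001) cover SN(+DC) and SH(+DC); SubH/FLC
batches (eps 1e-4, sigma 0.01 — the subcritical escape needs noise) cover
SN(-DC)/SubH and FLC; SNIC/SNIC seizures are generated by a prescribed
quadratic slow ramp across the fold-on-circle crossing (the self-organised
slow-wave chatter does not yield isolated seizures of analysable length);
the SupH class is surrogate-provided, because the active-rest focus pocket
below the junction Hopf is only ~0.09 wide against noise-amplified
fluctuations and the model cannot isolate SupH-onset seizures robustly.
Simulator-sourced recalls are structurally limited: noise near the
homoclinic or cycle fold ejects the orbit to rest before the terminal
intervals stretch past the thresholds, and the model's SN onsets near the
fold-on-circle junction genuinely carry a SNIC-flavoured opening gap.

**Offset switching.** The SN/SupH exemplar path with its offset endpoint
drifting (2e-5 rad/tu) toward the SN/SH configuration, noise on all
variables (sigma_fast 0.005, sigma_slow 3e-4), eps 3e-4, 100 simulations.
Each complete seizure is classified; a within-seizure SupH->SH switch is a
spike-amplitude envelope that decays below half its peak, recovers by 50%,
and still terminates with ISI slowing.

**Status epilepticus.** The SN/SH path extended 1.5x its angle beyond the
SN curve into seizure-only territory; eps 1e-3 with the drive capped at
1x eps; noise levels 0–0.1 on the fast variables with sigma_slow half of
sigma_fast (the permittivity variable is buffeted by the same
fluctuations). Because the peak-to-peak detector saturates at high noise,
the ictal state is read from the model's own signature — the window-mean
of x dropping below the midline between the rest baseline (+0.5) and the
cycle mean (-0.5) — and runs tolerate interruptions up to 75 tu, matching
the waxing-and-waning character of clinical status epilepticus. SE is a
run exceeding ten times the zero-noise ictal length; occupancy of the
'seizure only' region is accumulated from the analytic fixed-point count
along the path over strictly seizing blocks.

## Problem sizes and runtime

The full map (181x361, oracle at three initial conditions) takes ~3
minutes on one core; enumeration with dynamic confirmation ~1 minute;
scaling-law ladders seconds; each validation arm 1–3 minutes; the switch
experiment and noise sweep a few minutes each at the sizes used by the
test suite and the acceptance script (50 switch simulations, 60–100 per
noise level).

## Known limitations

* Numeric offset curves are grid-resolution objects; sub-labels near
  curve junctions (saddle-node loop, Bautin neighbourhoods) are
  resolution-limited, and the planar enumeration count (8 here) depends on
  them.
* Near-homoclinic and near-fold terminations under noise end seizures
  before their asymptotic scaling laws are measurable; simulator-sourced
  validation recall is correspondingly below the surrogate-based figure.
* The smooth slow drive cannot produce slow-wave (single-curve) bursting,
  and the hysteretic drive chatters when periods outgrow its window; each
  experiment uses the drive suited to its dynamotype.
* The classifier's thresholds (near-zero fraction, slowing ratios,
  acceleration ratios) are operating points declared in the report of
  every run, not estimates of any clinical algorithm's internals.
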