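# Methods

`apdbench` benchmarks human ventricular action-potential (AP) models
against ex vivo trabecula measurements of drug-induced APD90 change under
IKr and/or ICaL inhibition. This note documents the models, the
protocol, the numerics, the synthetic-data generators, and the design
choices made where the design was genuinely open.

## The benchmark

Drug effects are modelled as simple pore block. For a drug at bath
concentration `D` with channel-specific half-inhibitory concentration
IC50 and Hill coefficient `h`, the current carried in the presence of
drug is

    I(D) = I0 / (1 + (D / IC50)^h)

so the fractional block is `1 − 1/(1 + (D/IC50)^h)`. Two independent
patch-clamp datasets ("Pharm" and "CiPA" protocol families) provide
IC50/h per drug and channel; both are packaged. IC50 values reported
only as a bound ("> X", no measurable block up to the highest tested
concentration) are treated as censored: the drug is modelled as fully
selective, with exactly zero block on that channel (this affects
Dofetilide's ICaL and Nifedipine's IKr).

Block enters a model purely as conductance scaling: `g_Kr ← g_Kr (1−b_Kr)`
and `g_CaL ← g_CaL (1−b_CaL)` (for ORd/GPB the whole L-type permeability
family scales jointly, since the Na+/K+ permeabilities of the channel
are defined relative to the Ca2+ permeability).

The protocol mirrors the experiments: 1 Hz pacing for 1500 cycles from
each model's reference initial state, then one AP recorded at 0.05 ms
resolution. ΔAPD90 is APD90(blocked) − APD90(drug-free) in the same
configuration. Models are scored against the study's 29 drug-
concentration conditions with

    E = Σ_k | ΔAPD90,sim,k − mean ΔAPD90,exp,k | / SEM_k ,

the per-condition error in multiples of the experimental standard error
of the mean. If a model predicts repolarisation failure at a study
condition (the AP no longer ends within the pacing cycle; see the
numerics section), its APD90 is at least the cycle length, so the
condition is scored at the cycle-length ceiling
`ΔAPD90 = 1000 ms − baseline APD90` — a conservative lower bound on the
model's error at that condition. A cubic response surface (full 10-term bivariate basis in
the two block fractions, unweighted ordinary least squares; optional
1/SEM² weighting) summarises the experimental points for visual
comparison, one surface per IC50 dataset.

## Trace metrics

Landmarks follow the sharp-electrode conventions: the peak is the upper
95th percentile of the beat's voltage samples (robust to impalement
spikes), the resting potential is the mean over the last 150 ms of the
beat, and APD90 runs from the upstroke to the first downward crossing of
`V90 = peak − 0.9 (peak − RMP)`.

Two details the convention leaves open are fixed as follows:

- **APD start.** Taken as the time of maximum dV/dt, the standard
  convention, estimated from forward differences with parabolic
  refinement (removes the half-sample grid bias on smooth upstrokes;
  ties on ideal square edges resolve to the first maximal interval).
- **Crossing interpolation.** The V90 crossing is located by linear
  interpolation refined with two Newton steps on the parabola through
  the three surrounding samples; plain linear interpolation leaves
  ~1e-5 ms errors at 0.05 ms sampling on curved repolarisation, which
  would dominate the generator-truth checks.

Quality-control flags make the experimental screening rules explicit
(they were applied by eye in the source data; thresholds here are
declared, configurable, not inferred): a beat-to-beat jump in RMP or
peak above 5 mV flags a discontinuity (electrode movement); a
discontinuity coinciding with an APD90 jump above 20 ms flags the
condition under which data were discarded; a positive dV/dt above
0.05 mV/ms sustained for 5 ms inside the 10–90 % repolarisation window
flags an early after-depolarisation (EAD); no depolarisation
(peak − RMP ≤ 20 mV), no repolarisation, or RMP outside (−105, −50) mV
flags a non-physiological beat.

## The model library

Three models are shipped as native transcriptions of their publications
(required tier), all endocardial:

- **TP** — ten Tusscher & Panfilov (2006), 19 states
  (g_to = 0.073, g_Ks = 0.392 mS/µF);
- **ORd** — O'Hara–Rudy (2011), 41 states (g_Kr = 0.046,
  g_Ks = 0.0034, g_K1 = 0.1908 mS/µF);
- **GPB** — Grandi–Pasqualini–Bers (2010), 39 states, with the
  endocardial Ito split (total 0.3× epicardial, 96.4 % slow) and
  intracellular K+ clamped as published.

The remaining roster entries (TP-M, GPB-M, ORd-M, ORd-KM, BPS, ToR-ORd,
ORd-CiPA, TNNP) are registered as *extended tier*: their published
parameterisations are not bundled, and requesting them raises an
explicit not-implemented error — never a silent fallback. The packaged
roster table carries their printed reference constants (e.g. IKs maximal
conductances 0.0011 mS/µF for ToR-ORd and 0.0196 mS/µF for ORd-M) so
transcription checks against the printed values remain possible.
Conductance scaling (`apply_conductance_scaling`) supports arbitrary
multiplicative variant definitions over the native bases and is
compositional; structural additions (borrowing another model's current
formulation) are rejected explicitly.

Parameter provenance: each registered model's parameter table is
digested (SHA-256) into the registry manifest, and a test compares the
manifest against the live registry, so accidental parameter drift fails
loudly.

A CellML 1.0/1.1 importer is provided as an optional capability for
users with model files: components, connections and content-MathML
equations (algebraic + first-order time derivatives, piecewise) are
compiled to an ODE right-hand side via sympy. No unit conversion is
attempted; models are taken in their declared unit system.

## Numerics

The pacing engine integrates each model with a hybrid
Rush–Larsen / forward-Euler scheme compiled with numba, the standard
approach for these stiff Hodgkin–Huxley-type systems: gating variables
(and other states linear in themselves, e.g. the TP06 RyR recovery
gate) advance by the exact exponential update toward their
voltage-dependent targets; concentrations and the membrane potential
advance explicitly. Each cycle uses a three-phase step schedule —
fine over the stimulus/upstroke, intermediate over the plateau
(subspace Ca2+ is the stiffest non-gate state), coarse in diastole:

| model | upstroke | plateau | diastole | cost per 1500-pace run |
|-------|----------|---------|----------|------------------------|
| TP    | 0.01 ms (0–2 ms)  | 0.05 ms (–450 ms) | 0.2 ms  | ≈ 10 s |
| ORd   | 0.005 ms (0–2 ms) | 0.025 ms (–500 ms)| 0.1 ms  | ≈ 40 s |
| GPB   | 0.01 ms (0–7 ms)  | 0.02 ms (–450 ms) | 0.05 ms | ≈ 50 s |

GPB needs special treatment: its explicit buffer states (calsequestrin,
sarcolemmal sites) have binding-equilibrium slopes ≫ 1 with relaxation
times down to 0.008 ms, which makes any explicit pool↔buffer coupling
unstable above ~0.015 ms. The GPB stepper therefore (i) advances all
buffer states by Rush–Larsen and debits the *realised* uptake from the
ion pools (mass-exact under splitting), (ii) sub-cycles that exchange at
≤ 0.0125 ms inside a Strang-style symmetric split, and (iii) updates
the tiny junctional/subsarcolemmal compartments semi-implicitly in
their dominant linear relaxation rates (up to 46 ms⁻¹).

Accuracy guards (all asserted in the test suite):

- halving every step size changes steady-state APD90 by < 0.1 ms for
  TP and ORd; GPB's stiff buffer splitting leaves a ~1 ms absolute
  APD90 bias that largely cancels in ΔAPD90 (< 2 ms asserted on the
  absolute value);
- one recorded beat agrees with SciPy's adaptive LSODA (rtol 1e-8) on
  the *same* right-hand side to 0.06 ms (TP), 0.04 ms (ORd), ~1 ms
  (GPB) — an independent-integrator cross-check of the stepper;
- fixed inputs give bit-identical trajectories.

Steady state is the fixed 1500-pace protocol, not a convergence test; a
convergence metric (|APD90 difference| of the last two paces, typically
< 0.01 ms) is reported but not acted on. The stimulus is applied at the
start of each cycle with each model's published amplitude, duration and
carried ion (K+ for TP/ORd; GPB clamps intracellular K+).

**Repolarisation failure.** Near-complete IKr block can push a model
into 2:1 repolarisation failure, where "the APD90 of the next AP" is
ill-defined. The engine records *two* consecutive APs after pre-pacing;
if either fails to produce a measurable repolarised AP, if the two
APD90s differ by more than 30 ms (2:1 alternation; stable
micro-alternans of a few ms, e.g. TP under 91 % IKr block, is a valid
steady response and is not flagged), or if the diastolic potential
leaves the physiological QC bounds (ORd at 100 % IKr block settles into
a permanently depolarised oscillation around −20 mV), the outcome is a
flagged NaN, which map plots render as flagged cells and contour/slope
fits exclude.

## Synthetic data

`synth_trace` builds multi-beat voltage traces from analytic pieces —
rest, half-cosine upstroke, flat plateau, smoothstep (cubic)
repolarisation — timed so that the V90 crossing falls exactly
`apd90_true` after the maximum-slope instant. Because every landmark is
analytic, metric implementations can be checked to 1e-6 ms. Gaussian
sample noise, per-beat APD jitter, persistent baseline steps (electrode
movement) and Gaussian EAD bumps are applied on top with the ground
truth recorded. What it does *not* emulate: 60 Hz interference,
electrode drift kinetics, rate adaptation, or beat-shape physiology
beyond the landmarks — so passing metric tests demonstrates correctness
of the measurement conventions, not robustness to every recording
artefact.

`synth_study` samples trabecula studies around a known ground-truth
response surface: per condition, true ΔAPD90 is the surface at the
condition's (IKr, ICaL) block; per-trabecula responses are Normal with
a stated SD (the study tables report mean ± SEM only; normality is the
generator's assumption, not a claim about trabeculae); records carry
the *sampled* mean and SEM, mirroring how the experimental summaries
were formed. With the simulated model as the data-generating truth, the
per-condition error |z| is then `|t_{n−1}|`-distributed; its mean
approaches `sqrt(2/π) ≈ 0.798` only in the large-n limit, so the
calibration check uses 30 trabeculae per condition (E|t₂₉| ≈ 0.805; at
the study's realistic n of 4–15 the expectation is 0.85–1.0).

## Problem sizes used in the checks

Printed-value checks (map values at printed coordinates, the Dofetilide
prediction) run the full published protocol: 1500 pre-paces per
condition (the test suite samples the selective-IKr sweeps at 3 block
fractions, sufficient for their maxima since the response is monotone;
the acceptance script runs the full 10 %-step sweeps). Qualitative and ordering checks run reduced pre-pacing
chosen so the outcome is insensitive to the residual slow drift:
model ranking by E uses 200 pre-paces per condition (the TP/ORd
separation is a factor ~5), the TP 0-ms-line slope uses a 5×5 map at
300 pre-paces with interpolated zero crossings, and ORd monotonicity
uses 200 pre-paces. The SEM-calibration check uses 290 synthetic
conditions.

## Known limitations

- Only nominal drug concentrations are modelled (`concentration_kind`
  is carried for future measured values).
- The Hill pore-block model ignores state-dependent binding kinetics
  and effects on channels other than IKr/ICaL.
- Extended-tier roster models are not runnable (no published
  parameterisations bundled).
- The E measure favours models predicting small ΔAPD90 under balanced
  block; the all-zero predictor's E over the packaged table is ≈ 89.7
  and is always reported alongside model scores as a reference.
- GPB's absolute APD90 carries the ~1 ms splitting bias discussed
  above.
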