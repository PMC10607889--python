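# Methods

This note documents the models the package implements, the parameters
that matter, the design choices made where the design was genuinely open,
and what the synthetic test bed does and does not show.

## Pharmacokinetic engine

Each drug follows a linear three-compartment mammillary model with an
effect-site compartment, written in V1-normalised concentrations
x = (c1, c2, c3, ce):

    dc1/dt = −(k10+k12+k13)·c1 + k21·c2 + k31·c3 + r(t)/V1
    dc2/dt =  k12·c1 − k21·c2
    dc3/dt =  k13·c1 − k31·c3
    dce/dt =  ke0·(c1 − ce)

Integration is exact per constant-rate segment (matrix exponential plus
the closed-form particular solution), cached per (parameter set, step), on
a 1-s simulation grid with control decisions every 10 s. This makes runs
bit-reproducible and removes integration error from every downstream
comparison; the test suite checks the stepper against an independent
fine-step Euler integration to < 1e-4 relative error.

Parameter sets (see `src/autotiva/pk/pk_parameters.yaml` for provenance):

| drug | model | covariates | ke0 default (1/min) |
|---|---|---|---|
| propofol | Marsh | total body weight | 1.21 ("modified Marsh") |
| remifentanil | Minto | age, weight, height, sex (James LBM) | 0.595 − 0.007·(age−40) |
| rocuronium | Wierda | total body weight | 0.168 |

ke0 values are a genuine open choice: several pairings coexist in TCI
practice and the clinical sources do not pin one down. We default to the
modified-Marsh 1.21 min⁻¹ because effect-site targeting with the classic
Diprifusor value (0.26 min⁻¹, also available by config) produces large,
slow plasma overshoots that are poorly suited to closed-loop titration.
All ke0 values are config overrides.

**TCI.** Plasma targeting solves the one-interval linear equation for the
rate landing c1 on the target (zero when above — pumps cannot remove
drug). Effect-site targeting bisects on a transient plasma target whose
predicted peak ce equals the requested target (prediction grid 10 s,
horizon 20 min), and degenerates to plasma maintenance at the effect
target once ce is within 1 % — the shortcut that keeps a 2-h closed-loop
run to a couple of seconds. A non-convergent bisection falls back to
plasma targeting and flags the result. Pump rates saturate at a
configurable maximum and targets at configurable safety caps (propofol
8 µg·mL⁻¹, remifentanil 12 ng·mL⁻¹) standing in for package-insert limits.

Units: propofol and rocuronium µg·mL⁻¹ (mass in mg), remifentanil
ng·mL⁻¹ (mass in µg); time in seconds internally, rates in mass/min.

## Online estimators

**Sigmoid BIS regression.** BIS(c) = E0 − Emax·cᵞ/(cᵞ+EC50ᵞ), fitted by
bounded nonlinear least squares (analytic Jacobian; bounds E0 ∈ [60,100],
Emax ∈ [1,100] with Emax ≤ E0 enforced, EC50 ∈ [10⁻³,30], γ ∈ [0.3,10]).
Initialisation: E0 = max observed BIS, Emax = E0 − min observed BIS,
EC50 = median concentration, γ = 2; during a run the previous solution
warm-starts the refit. Pairs are collected at 1 Hz from the start of the
propofol infusion, pairs with SQI < 80 are excluded, and the fit refreshes
every 30 s over the full history (no windowing — matching how the data
stream is described clinically, and giving the regression an
integral-action flavour: persistent BIS error accumulates evidence that
moves the fitted curve). The estimator refuses to fit (`NotReadyError`)
below 8 usable pairs or a concentration span under 0.5 µg·mL⁻¹;
controllers then hold the last valid target. BIS is paired with the
model-predicted *effect-site* concentration at the same timestamp — the
effect compartment already encodes the hysteresis, so no extra lag
correction is applied.

**Isobole hyperbola.** y = c/(x−a) + b fitted to (remifentanil Ce,
concurrent esTEC-P45) pairs appended at every 30-s refit, with c > 0 and
a below every observed x; degenerate (flat) data, with c → 0, is refused.
esMIC_δ = a + (100/δ)·√c. The δ → x mapping is the unique reading of
"δ % of the vertex-to-asymptote residual" consistent with the hyperbola's
geometry: at x = a + (100/δ)√c the residual above the asymptote is
(δ/100)·√c, and δ = 100 degenerates to the vertex abscissa, where the
slope is exactly −1. δ defaults to 20.

## Controllers

The printed clinical constants are defaults in `ControllerConfig`:
BIS target 45 and band 35–55; propofol floors 1.4 / 1.0 µg·mL⁻¹ with the
age cutoff at 80; remifentanil rescue target 4.0 ng·mL⁻¹ at BIS ≥ 70;
incision rate 0.5 µg·kg⁻¹·min⁻¹ of ideal body weight (BMI 22); bolus
range 50–100 µg. The unprinted magnitudes are explicit config fields,
chosen once:

- low-signal ramp +0.2 µg·mL⁻¹ per 5 min of continuous unreliability,
  capped +1.0 above the last reliable target (controller-side
  unreliability is SQI < 50 or EMG > 55 — deliberately looser than the
  SQI ≥ 80 scoring threshold, so the controller does not thrash on
  borderline signal);
- BIS-rise boost +0.5 µg·mL⁻¹ after 30 s above the band, decaying
  linearly over 5 min; a BIS ≥ 70 rescue triggers the same boost
  immediately (the clinical description gives no magnitude);
- "sudden" esMIC increase = Δ > 0.5 ng·mL⁻¹ between consecutive refits;
  bolus 50 + 50·min(1, (Δ−0.5)/1.5) µg, refractory 3 min;
- gradual decrease ≤ 0.1 ng·mL⁻¹·min⁻¹; increases jump in one tick
  (asymmetric tracking);
- incision hold 2 min, implemented as a rate override (not a floor or
  ceiling) of the TCI-derived rate; rescue hold 3 min. The rescue sets
  the target to max(current, 4.0) so it can never lower an
  already-higher target.

Propofol rule precedence: low-signal ramp → BIS-rise boost → floor clamp,
floor applied last and owning the rationale code when it binds.

The rocuronium loop waits for the TOF count to *recover* to 1 — a count
of 0 must have been observed first, so the transit through 1 during onset
of the induction bolus is not mistaken for recovery — then captures the
concurrent modelled concentration as the reference. Whether the loop
regulates plasma or effect-site concentration is ambiguous in the
clinical description; both modes are implemented and the default
regulates the effect site (`roc_mode`).

Induction (automatic): remifentanil 0.5 µg·kg⁻¹·min⁻¹ (IBW) from t = 0;
propofol 0.5 mg·kg⁻¹ over 10 s at t = 300 s; on loss of consciousness
(first BIS < 70 sustained 10 s) propofol 10 mg·kg⁻¹·h⁻¹ and, 60 s later,
rocuronium 0.6 mg·kg⁻¹; the closed loop engages once both estimators have
produced valid fits (or 5 min after the rocuronium bolus, whichever comes
first). If consciousness is not lost within 2 min of the bolus the
maintenance-rate infusion starts anyway — the escalation any clinician
would apply.

The manual comparator is a deliberately simplified rule-based clinician:
propofol plasma target stepped ±0.3 µg·mL⁻¹ on BIS excursions sustained
past a 30-s latency (60-s cooldown), remifentanil rate stepped on
sustained dual hemodynamic excursions with the 2 µg·kg⁻¹·min⁻¹ cap,
rocuronium from 7 µg·kg⁻¹·min⁻¹ stepped to hold TOF 1. It is a scripted
policy for in-silico contrast, not a model of clinician behavior.

## Virtual patients

The clinical studies used humans; every ground-truth mechanism here is
therefore the package's own construction, explicit and config-driven.

- **BIS truth**: Hill curve in propofol Ce whose EC50 shrinks with
  remifentanil via the saturating interaction
  EC50_eff = EC50·(1 − s_max·ce_r/(ce_r + C50_r)), defaults s_max = 0.66,
  C50_r = 1.0 ng·mL⁻¹. This form is chosen because it makes the true
  fixed-BIS isobole *exactly* a rectangular hyperbola
  (b = K·EC50·(1−s_max), c = K·EC50·s_max·C50_r, a = −C50_r, with K the
  fixed-effect Hill factor), i.e. the estimator's model class contains
  the truth — estimation error then comes from noise and pairing, not
  structural mismatch. Gaussian BIS noise, σ = 3 by default.
- **TOF truth**: first-twitch amplitude T1 = 1 − ceᵞ/(ceᵞ+EC50ᵞ)
  thresholded at T1 = 0.3/0.7/0.8/0.9 into counts 0–4, so ce = tof_ec50
  (T1 = 0.5) reads count 1 and, with tof_ec50 = 1.2 µg·mL⁻¹ and γ = 4.5,
  a 0.6 mg·kg⁻¹ bolus recovers to count 1 roughly 25–35 min later —
  the clinically reported window. TOF is sampled every 15 s; misreads
  occur only inside scheduled artifact windows.
- **Hemodynamics**: SBP = SBP0·(1 + g·stimulus/(1 + ce_r/IC50_r)) + noise
  (HR analogous; g = 0.5/0.45, IC50_r = 2 ng·mL⁻¹, noise 4 mmHg / 3 bpm);
  vasoactive administration adds a transient offset with a 2-min decay.
- **Population**: demographics from truncated normals matched to a
  surgical adult cohort (age 54.5 ± 14.9 y, height 160.5 ± 8.3 cm,
  BMI 23.3 ± 3.8, 70 % female); PD parameters log-normal around the
  typical values above; PK mismatch via per-drug central-volume
  multipliers, log-normal (σ_log = 0.12) truncated to [0.5, 2]. With
  multipliers of 1 and zero noise the controller's nominal
  concentrations equal the truth exactly (the mismatch knob).
- **Scenario**: loss-of-consciousness criterion, incision at LOC + 10 min
  (surgery start), sustained unit surgical stimulus from incision,
  optional extra stimuli, vasoactive events and low-SQI/high-EMG artifact
  windows, default 2-h maintenance.

What passing tests show — and do not. The test bed demonstrates that the
control laws, estimators and safety rules interact correctly and keep a
*model* patient in band under noise, artifacts and moderate PK mismatch.
It does not demonstrate clinical performance: real BIS dynamics are not a
static Hill surface, real TOF noise is not confined to scheduled windows,
and no respiratory/hemodynamic physiology is modelled beyond the
stimulus-response sketch above.

## Evaluation and statistics

Scoring follows the trial's definitions on the surgery window: sedation
deviation = reliable BIS (SQI ≥ 80) outside 35–55; insufficient analgesia
= episodes where SBP *and* HR both exceed 1.2× a rolling baseline (mean
over 1–5 min before onset), the crossing completing within 120 s from
below 1.1× ("rapid"), excluding 5 min after vasoactive administration
(the AND conjunction and the 120-s rise-time quantification are the
package's reading of the verbal/graphical definition; both are
configurable); relaxation deviation = valid TOF ≠ 1. Deviations separated
by < 10 s merge (1-Hz sampling jitter). Adequate time = operation time −
|union of the three deviation sets and the qualifying missing time|,
missing time qualifying only where at least one component is missing and
no present component deviates. The clinician-judgment clause of the
sedation definition is not computable in silico; optional manual
annotation intervals can be unioned in. The BIS-in-band ratio is reported
over reliable samples.

Statistics: pooled-variance one-sided non-inferiority t-test (margin 5
percentage points, one-sided 2.5 %) with its one-tailed 97.5 % lower
confidence bound, accepting raw samples or summary statistics (the two
routes agree to machine precision); normal-approximation power
power = Φ((Δ+margin)/(σ_pooled·√(2/n)) − z_{0.975}); and two-sided
Fisher's exact test (scipy) verified against a hypergeometric enumeration
oracle in the tests.

## Problem sizes and numerical choices

The in-silico cohort analyses use 20 virtual patients and 2-h
maintenance windows — enough for stable cohort means at desk scale; the
`trial` subcommand accepts any n. Seeds: one root seed drives everything,
with per-patient seeds derived via `numpy` SeedSequence spawning.
Nonlinear fits use `scipy.optimize.least_squares` with analytic Jacobians
and tight tolerances (1e-12/1e-13); fit degeneracy (flat hyperbola,
single-concentration sigmoid data, unreachable inversion targets) is
signalled as `NotReadyError` and handled by target-holding, never by
extrapolation.

## Known limitations

- The manual comparator is a caricature; its adequacy ratios should not
  be read as a model of clinician performance.
- The convention-dependent constants (ke0 pairings, ramp/hold
  magnitudes) are flagged above and overridable in config.
- Awakening/extubation endpoints are out of scope (recovery
  pharmacology is not modelled).
- The analgesia episode-end rule (both signals below 1.2× baseline, no
  hysteresis band) is one of two defensible readings; it is configurable.
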