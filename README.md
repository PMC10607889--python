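# autotiva

Closed-loop control of three-drug total intravenous anesthesia — propofol,
remifentanil and rocuronium — with a virtual-patient test bed and
trial-style evaluation.

## What problem this addresses

During general anesthesia an anesthesiologist continuously balances three
effects: **sedation** (monitored by the bispectral index, BIS, with a
target band of 35–55), **analgesia** (judged from blood-pressure and
heart-rate responses to surgical stimulus) and **muscle relaxation**
(monitored by the train-of-four count, TOF, with a target of 1). This
package implements, in simulation, an automated controller that closes all
three loops, together with the safety mechanisms needed to make such a
controller clinically plausible, and the statistical machinery to compare
it against a (scripted) manual comparator. It is aimed at researchers in
physiological closed-loop control and PK/PD modelling who want a fully
reproducible, parameterized implementation to experiment with.

## The algorithms at the core

**Propofol (sedation).** From the start of the infusion, paired
observations (Ce_propofol, BIS) are collected and a sigmoid Emax curve

    BIS(c) = E0 − Emax · cᵞ / (cᵞ + EC50ᵞ)

is refit online. Inverting it at the target BIS = 45 yields the patient's
estimated target effect-site concentration, **esTEC-P45**, which an
effect-site TCI tracks. Three safety rules modify the target: an upward
ramp while the BIS signal is unreliable (low SQI / high EMG / invalid), a
temporary additive boost when BIS rises above the band, and an
age-dependent floor (1.4 µg·mL⁻¹ under 80 years, 1.0 µg·mL⁻¹ at 80+).

**Remifentanil (analgesia).** Pairs of (Ce_remifentanil, concurrent
esTEC-P45) trace the individual analgesia–sedation isobole, modelled as a
rectangular hyperbola *y = c/(x − a) + b*. Its vertex (a + √c, b + √c) is
the point of slope −1: beyond it extra opioid spares almost no hypnotic.
The controller targets **esMIC₂₀** — the abscissa where the residual above
the asymptote falls to δ = 20 % of the vertex-to-asymptote gap:

    esMIC_δ = a + (100/δ)·√c

Safety rules: a fixed 0.5 µg·kg⁻¹·min⁻¹ (ideal body weight) rate at
surgical incision, a single 50–100 µg bolus on a sudden esMIC increase, a
forced 4.0 ng·mL⁻¹ target whenever BIS ≥ 70, and rate-limited gradual
descent when esMIC falls.

**Rocuronium (relaxation).** After the 0.6 mg·kg⁻¹ induction bolus the
loop waits for the TOF count to recover to 1, captures the concurrent
model-estimated effect-site concentration as the individual reference, and
regulates the modelled concentration there by TCI.

All drugs run on an exact (matrix-exponential) three-compartment +
effect-site PK engine with published parameter sets (Marsh, Minto, Wierda)
and plasma/effect-site TCI targeting.

## Worked example

Simulate one automatic-control case and score it:

```bash
autotiva run --out case.csv --seed 3
autotiva evaluate case.csv
```

which prints (seed 3, default scenario):

```
adequate_time_ratio: 85.36
sedation_ratio: 99.90
analgesia_ratio: 100.00
relaxation_ratio: 85.44
sedation_analgesia_ratio: 99.90
sedation_relaxation_ratio: 85.36
bis_in_range_ratio: 99.90
missing_time_s: 0.00
operation_time_s: 7200.00
analgesia_episodes: 0
movement_events: 0
```

Reading: over the 2-h surgery the three components were simultaneously
adequate 85.4 % of the time; the only deviations were the relaxation
(TOF ≠ 1) minutes early in surgery while the block from the induction
bolus was still wearing off toward the TOF-1 reference; reliable BIS
stayed inside 35–55 for 99.9 % of surgery and no insufficient-analgesia
episode occurred. The same Python API is
available as `autotiva.patient.simulate_run` /
`autotiva.evaluation.adequate_time_ratio`, and
`autotiva trial --n-per-group 10 --seed 1` runs a two-arm in-silico
comparison with the non-inferiority analysis (margin 5 percentage points,
one-sided 2.5 %).

The estimators follow the scikit-learn idiom:

```python
>>> from autotiva import BisSigmoidRegressor
>>> import numpy as np
>>> ce = np.linspace(0.2, 5, 12)
>>> est = BisSigmoidRegressor().fit(ce, 93 - 60*ce**2/(ce**2 + 2.5**2))
>>> round(est.invert(45.0), 4)   # esTEC-P45
5.0
```

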