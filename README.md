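# kinrace

Kinetic-race analysis of kinesin chemomechanical cycles, with a seeded
Monte-Carlo simulator of single-molecule motility data.

## The problem

Processive kinesin motors (kinesin-1, and the superprocessive kinesin-3
KIF1A) walk along microtubules in 8-nm steps. During every cycle the motor
passes through a vulnerable one-head-bound (1HB) state that resolves in one
of two ways: the tethered head attaches to the next tubulin site (rate
k<sub>on</sub><sup>TH</sup>), completing the step, or the bound head detaches
(rate k<sub>detach</sub>), terminating the run. Run length is therefore set
by a kinetic race:

```
p_detach = k_detach / (k_onTH + k_detach)  ≈  k_detach / k_onTH
steps per run = 1 / p_detach
k_onTH = k_detach × (run length / 8 nm)
```

Together with the affinity decomposition K<sub>D</sub> = k<sub>detach</sub> /
k<sub>on</sub><sup>Mt</sup>, these identities convert the observables of a
standard single-molecule/stopped-flow campaign — TIRF run lengths and dwell
times, pelleting isotherms, k<sub>obs</sub>-vs-[Mt] slopes, ATP-triggered
half-site-release saturation — into the underlying cycle rate constants.
`kinrace` implements this conversion with explicit units and 95% CI
propagation, the estimators the raw data require (left-truncated exponential
MLE, EM biexponential mixtures, Michaelis–Menten, Langmuir, weighted linear
fits, pause-aware segmented velocity), peptide net-charge and Debye-length
electrostatics for K-loop charge series, and a simulator of the stepping
cycle so every stage can be exercised and validated without instrument data.

It is written for single-molecule biophysicists who have event tables
(CSV), stopped-flow curves (CSV), and peptide sequences (FASTA), and want
cycle rate constants with honest error bars.

## Worked example

The package ships the published per-construct measurements for the KIF1A
loop-12 series. Running the race model on them:

```sh
$ kinrace race
construct  dwell_s  dwell_ci  off_rate_s  off_rate_ci  steps  steps_ci  kon_th_s  kon_th_ci error
   1A_393      1.8      0.08        0.56         0.02  375.0       3.0     208.0        9.0  None
 1A-K1L12      0.3      0.03        3.30         0.30   63.0       1.0     208.0       21.0  None
     Kin1      1.5      0.10        0.67         0.04  100.0       3.0      67.0        5.0  None
 K1-1AL12      1.4      0.10        0.71         0.05  113.0       3.0      80.0        6.0  None
```

Reading the first row: a 1.8 s dwell time in ADP corresponds to an off-rate
of 0.56 s⁻¹ from the weak-binding state; a 3.0 μm run length is 375 steps of
8 nm; their product estimates the tethered-head attachment rate at 208 s⁻¹.
The key biological result is visible in rows 1–2: swapping the K-loop out of
KIF1A leaves k<sub>on</sub><sup>TH</sup> unchanged (208 s⁻¹) while the
off-rate rises 6-fold — the K-loop's positive charge acts by stabilizing the
vulnerable 1HB state, not by speeding the step.

Buffer electrostatics and the charge–run-length scan:

```sh
$ kinrace buffers
BRB80   I=184 mM        Debye=0.71 nm
BRB12   I=36 mM         Debye=1.60 nm
$ kinrace regress
buffer  skipped  slope_um_per_charge  slope_ci95  intercept_um  intercept_ci95  n_points excluded
 BRB12    False             2.707143    0.897863      3.492857        1.904655         4
 BRB80    False             0.850000    0.122266     -0.366667        0.573476         3    4Q;5Q
```

Run length gains 2.7 ± 0.9 μm per unit of loop-12 charge at 36 mM ionic
strength, and only ~0.85 μm per charge at 184 mM where screening
(Debye length 0.7 nm) weakens the electrostatic contribution. Constructs
with no detectable processivity (4Q, 5Q in BRB80) are excluded and listed.

A full simulate → censor → fit round trip from Python:

```python
from kinrace import (CycleRates, DetectionSettings, apply_detection_censoring,
                     fit_exponential_truncated, simulate_processive_runs)

rates = CycleRates(k_on_TH=208, k_detach=0.56, k_step=212)
events = simulate_processive_runs(rates, 10_000, seed=1)
kept, removed = apply_detection_censoring(events, DetectionSettings(), "distance")
fit = fit_exponential_truncated([e.run_length_um for e in kept], cutoff=0.17)
print(f"run length {fit.tau:.2f} ± {fit.tau_ci95[0]:.2f} um "
      f"({removed} sub-resolution events censored)")
# run length 2.99 ± 0.06 um (589 sub-resolution events censored)
```

The fitted 2.99 μm matches the analytic mean (208/0.56) × 8 nm = 2.97 μm of
the generating race.

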