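# Methods

## The kinetic-race model

A processive kinesin dimer completes one 8-nm step per ATP hydrolyzed. After
hydrolysis the motor is one-head-bound (1HB) and weakly attached; the cycle
resolves either by tethered-head attachment at rate k_onTH (the run
continues) or by detachment of the bound head at rate k_detach (the run
ends). Treating cycles as independent Bernoulli trials gives

    p_detach = k_detach / (k_onTH + k_detach),

so the number of completed steps per run is geometric with mean
k_onTH / k_detach (support includes zero: a motor may detach before its
first step). The package exposes both the exact form of p_detach and the
first-order approximation k_detach / k_onTH commonly quoted when detachment
is rare; they differ by a relative factor of exactly p_detach.

Two independent routes to k_detach are supported:

* **dwell route** — the off-rate in saturating ADP is the reciprocal of the
  single-molecule dwell time (ADP populates the same weak-binding 1HB state
  the race passes through);
* **affinity route** — from the definition K_D = k_detach / k_onMt, the
  pelleting K_D times the stopped-flow bimolecular on-rate gives k_detach.

The two routes need not agree exactly (they weight fast sub-resolution
events differently), which is itself informative. For the affinity route the
packaged constants include K_D measured in both ADP and ATP; the
ADP-state and ATP-state K_D values differ by ~30% for the wild type, and the
published 18 s⁻¹ / 66 s⁻¹ detachment rates correspond numerically to the
ATP-column values (1.7 × 10.6 = 18.0; 7.2 × 9.1 = 65.5), not to the ADP
values named in the accompanying text (1.3 × 10.6 = 13.8). The package
computes from whichever K_D the caller supplies and takes no position on
which was intended; the bundled worked example uses the values that
reproduce the published numbers.

## Uncertainty propagation

Published fit uncertainties are symmetric 95% CIs without a stated
propagation rule. This package uses first-order relative-error quadrature
for all products, quotients and reciprocals:

    rel_ci(x*y) = rel_ci(x/y) = sqrt(rel_ci(x)^2 + rel_ci(y)^2),
    rel_ci(1/x) = rel_ci(x).

This reproduces the published per-construct CIs at displayed precision in
all but one cell: the loop-swap construct's k_onTH CI prints as ±19, which
is what quadrature gives when applied to the *rounded* off-rate and step
CIs, while full-precision propagation gives ±21. Full precision is retained
internally; rounding is strictly a render-time concern (off-rates to 2
significant figures with half-up ties, their CIs to 1 significant figure,
steps and k_onTH to the nearest integer, ties away from zero).

## The simulator

`simulate_processive_runs` draws the stepping cycle directly: a geometric
step count at the race odds, run length = steps × 8 nm, and a run duration
summing (steps + 1) exponential cycle times at the overall stepping rate
k_step. The stepping rate is velocity-calibrated (k_step = v / step size;
212 s⁻¹ at 1.7 μm/s) rather than built from sub-state kinetics, because
only the mean velocity of events is ever compared — no claim is made about
intra-cycle dwell partitioning. Dwell times are drawn from explicit
exponential mixtures; stopped-flow, half-site-release, and pelleting curves
are exact closed-form evaluations plus optional additive Gaussian noise
(noise SD 0 returns the curve to machine precision, which the tests rely
on). One root seed is taken per pipeline run and split into independent
child streams per stage, so a fixed (config, seed) pair reproduces every
artifact byte-for-byte.

Detection censoring mirrors kymograph practice: traces shorter than
3 pixels (distance axis, ATP motility assays) or 3 frames (time axis, ADP
dwell assays) are invisible and removed. Defaults are a 0.0567 μm pixel
(3 px = 0.17 μm) and a 0.1 s frame interval (10 fps; 3 frames = 0.3 s);
0.02 s and 0.2 s intervals correspond to the 50 fps and 5 fps acquisition
modes used for fast dwells and low-ionic-strength assays.

What the simulator deliberately does *not* emulate: localization error and
pixelation noise, photobleaching, pause states within runs, load dependence
of the rates, and motor-motor interactions. Passing round-trip tests
therefore demonstrates that the estimators are unbiased for the idealized
race process at realistic parameter scales and censoring — not that real
kymograph data are free of these additional effects.

## Estimators

**Left-truncated exponential (run lengths, single-exponential dwells).**
Censoring at cutoff c makes the observed distribution a left-truncated
exponential; by memorylessness the MLE is closed-form, tau = mean(x − c)
over x ≥ c, with CI 1.96·tau/√n. This is the primary method (efficient,
deterministic); a least-squares fit to the empirical survival (1-CDF) curve
is available for parity with graphical practice and agrees within CI on
exponential data. The MLE is exactly shift-equivariant, which the property
tests assert to machine precision.

**Two-component truncated mixture (fast/slow dwell populations).** Shifting
the post-cutoff samples by the cutoff leaves a plain two-exponential mixture
with the *same* taus (only the weights reweight toward the slow component),
so EM runs on the shifted data. Starts are deterministic quantile pairs; the
best log-likelihood wins; components are ordered tau1 < tau2 and a
degeneracy flag is raised at tau1/tau2 > 0.9, where the components are not
separately identifiable and the fit collapses to the single-exponential
answer. Reported weights describe the observed (post-cutoff) population,
the quantity a dwell-time histogram shows; per-component CIs use the
effective sample size n·w_k. Whether published biexponential fits
constrained the weights is not stated (the same fit is described both as
"equal weights" and as ~40%/60%); the generator accepts either and the
tests use the 40/60 split.

**Saturation and linear fits.** Michaelis–Menten (half-site release) and
Langmuir (pelleting) curves are nonlinear least squares
(scipy `curve_fit`, amplitude and half-saturation bounded positive, p0 from
the data's plateau and half-max); linear stopped-flow and charge-run-length
fits are statsmodels OLS, or inverse-variance WLS when per-point errors are
given. All CIs are 95%, from the t distribution with n − 2 df. Zero-signal
saturation data return amplitude 0 with a `no_signal` flag instead of a
spurious K.

**Charge–run-length regression.** Unweighted OLS of run length on loop-12
net charge per buffer is the primary mode; it yields 2.71 ± 0.90 μm/charge
for the low-ionic-strength series. For the three-point high-ionic-strength
series it yields 0.85, whereas the published figure quotes 0.9 ± 0.6; no
weighting of the three printed points reproduces 0.9 at two digits, so the
package reports its computed value (which is well inside the published CI)
rather than forcing agreement.

**Segmented velocity.** Kymograph segmentation is manual in the original
workflow. The automatic stand-in is a two-pass procedure: instantaneous
speeds over a 3-frame sliding window; frames slower than 25% of the trace
median speed classified as paused (a mostly-stationary trace falls back to
"any movement is motile"); contiguous motile stretches merged into
segments; segments displacing less than 3 pixels dropped. This reproduces
the one property the measurement is used for — segmented velocity exceeds
end-to-end velocity for pausing traces — and is not claimed to match manual
tracing segment-for-segment.

## Electrostatics

Net charge is the integer sum of K/R (+1) and D/E (−1) at pH ~6.9;
histidine is neutral (pKa ≈ 6 leaves it mostly deprotonated), matching the
integer charges used in the construct ledger; a custom `ChargeModel` can
override any residue. No Henderson–Hasselbalch titration is attempted.
Termini are ignored because the segments of interest are internal loops and
coiled-coils. The loop-12 ledger (WT +4/6K, SuperK +7/9K, K1L12 +1/1K,
4Q 0/2K, 5Q −1/1K) ships as packaged data because the underlying sequences
were published only graphically; ledger validation checks that every
point-substitution mutant's charge delta equals its lysine-count delta, and
recomputes charges when the user supplies sequences.

Ionic strength is the generic I = ½Σc_i z_i²; the BRB80 (184 mM) and BRB12
(36 mM) presets store their published ionic strengths as constants rather
than recomputing PIPES/EGTA/ATP speciation, which is buffer chemistry
outside this package's scope. The Debye length uses CODATA constants with
water εr = 78.5 at 298.15 K, λ_D ≈ 0.304 nm/√I(M), giving 0.71 and 1.60 nm
for the two presets.

## Problem sizes and numerical choices

The validation suite simulates 10,000 runs for race round trips (Monte-Carlo
SE ≈ 0.03 μm on a 3 μm run length, comfortably inside the 2% comparison
band), 5,000 dwells for biexponential recovery, and 200 replicates of 1,000
events for the tau-recovery coverage check; the acceptance script uses
100,000 runs (SE ≈ 0.01 μm) so its stochastic output is stable across seeds.
EM converges on a relative log-likelihood change of 1e-12 with a 5,000
iteration cap; curve fits bound parameters positive; degenerate designs
(all-equal x, empty samples, zero dwell) raise typed errors rather than
returning garbage. The truncated-geometric run-length distribution is
slightly coarser than its exponential limit: the analytic post-censoring
mean at the wild-type parameters is 2.978 μm rather than 3.0, a −0.7% grid
effect the stochastic tolerances absorb.

## Known limitations

* The race model assumes a single detachment-vulnerable state per cycle and
  unloaded motors; load-dependent detachment is out of scope.
* The affinity route to k_detach inherits any normalization bias of the
  pelleting assay (the loop-swap construct saturates at ~25% of the AMPPNP
  control, which may reflect either a much larger true K_D or partial
  activity).
* Biexponential fits near weight 0 or tau ratio 1 are intrinsically
  ill-conditioned; the degeneracy flag marks, but cannot rescue, such fits.
* The simulator's clean exponentials cannot detect analysis biases that
  arise from tracking noise or non-exponential pausing in real data.
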