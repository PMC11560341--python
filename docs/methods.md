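# Methods

## Problem and model

An excised nerve held at successively larger axial stretch ratios
λ = L/L0 loses compound action potential (CAP) amplitude; the package
quantifies that dose–response together with the tissue's passive
mechanics, and transfers both onto arbitrary axisymmetric geometries with
a reduced finite-element model.

**Mechanics.** The nerve is treated as an incompressible, isotropic,
hyperelastic cylinder in homogeneous uniaxial tension. With reference
cross-section A0 = π(d0/2)² (diameter averaged over repeated measurements,
section assumed circular), the axial Cauchy stress at peak force f is
T11 = f·λ/A0 — the factor λ is the incompressible area change A = A0/λ.
The strain energy is the two-parameter polynomial of Raghavan & Vorp,
W = α(I1−3) + β(I1−3)², giving the uniaxial Cauchy stress

    T11(λ) = [2α + 4β(λ² + 2λ⁻¹ − 3)] (λ² − λ⁻¹),   α, β ≥ 0 (MPa).

T11(1) = 0 and T11 is strictly increasing on λ ≥ 1 for α > 0, β ≥ 0. The
response is linear in (α, β), so the fit is a nonnegatively-constrained
*linear* least-squares problem with a unique global optimum; it is solved
with a bounded linear solver (`scipy.optimize.lsq_linear`) and validated
in the tests against an independent normal-equations/KKT oracle to
1e-8 MPa. The objective is unweighted least squares on Cauchy stress
(λ-weighting is available as an option). The nonnegativity bounds encode
convexity of the strain energy; all published estimates for this tissue
are positive.

**Signal chain.** Raw multi-sweep voltage traces are processed as:
stimulus-artifact blanking (linear interpolation across a configurable
window after each onset, default 0.5 ms, applied *before* filtering — a
large sharp artifact otherwise rings through the 100 Hz band edge for
several milliseconds and contaminates the CAP peak), then a 4th-order
Butterworth 100–5000 Hz band-pass applied forward–backward (zero phase, so
latencies are preserved), per-sweep baseline subtraction (mean of the 5 ms
preceding each onset; a truncated window is used with a warning when a
stimulus sits at the trace start), and a running median over 100 µs
(rounded up to an odd sample count — 11 samples at 100 kHz). Epochs are
aligned on the stimulus onsets, truncated to a common length and averaged.
The peak is the largest signed deflection after the blanking window
(polarity is a flag), replacing the manual point-picking of typical lab
workflows with a reproducible rule; latency is onset-to-peak. Reduction at
stretch n is R_n = (C_1.00 − C_n)/C_1.00 × 100, unclamped (amplitude
increases pass through as negative reductions).

Percent reduction is invariant to any linear, stretch-independent stage of
the chain (the filters scale all sweeps equally), which is why the
noiseless end-to-end tests can demand reduction errors at machine
precision while absolute amplitudes through the band-pass are attenuated
by a few percent.

**Dose–response mapping.** Per specimen, a cubic smoothing spline maps λ
to R. The smoothing parameter p ∈ [0, 1] follows the csaps convention
(p = 1 interpolates; internally p maps to the roughness weight
(1−p)/p of a penalised regression spline). The default p is 1
(interpolating): the experimental protocol yields few, low-noise points
per specimen after epoch averaging, and interpolation removes an
unreportable degree of freedom; p is overridable where measurement noise
warrants smoothing. Inversion returns the *first* (lowest-λ) crossing of
the target reduction, found from the exact piecewise-polynomial roots, and
never extrapolates outside the fitted λ range. Cohort confidence intervals
at reduction levels 0, 2.5, …, 50% pool the per-specimen inversions:
mean ± t_{0.975, n−1}·sd/√n, Student t because n ≈ 7. Grid points where
fewer than two specimens' curves reach the target are reported missing,
never fabricated.

**Fiber angles.** Angles (already extracted from second-harmonic
images upstream; this package consumes angle lists) are normalised to zero
mean per section — the mean direction along the nerve axis is the
reference — and pooled per nerve (a per-section option exists). Histograms
use exact 1° half-open bins [a, a+1) with the final upper edge closed; an
angle on an interior edge counts toward the upper bin. FWHM is measured on
the binned distribution: half of the peak bin percentage, crossings
located by linear interpolation between bin centers, peak ties broken
toward the distribution centroid; no kernel smoothing. Outliers are
removed by Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR) with quartiles by
linear interpolation of order statistics (numpy's default). Group
comparison: two-sided F-test on variances, then a pooled-variance t-test
when the F-test does not reject at 0.05, otherwise Welch.

**Finite-element rod.** Uniaxial tension of an incompressible isotropic
rod is statically determinate: the axial force F is constant along the
rod, so each element's stretch solves the scalar equation
T11(λe)·A0e/λe = F independently. This 1-D reduction reproduces the
3-D solution exactly for this load case while remaining verifiable against
closed forms, which is why it is used instead of a general-purpose FE
package. Element equations are solved by safeguarded Newton (bracketed on
[1, λcap], bisection fallback, |g| ≤ 1e-10 N, ≤ 100 iterations; λcap
defaults to 1.5). Stretch control wraps a Brent root find on F so the
length-weighted mean element stretch matches the target to 1e-8. CAP
reduction is mapped onto elements by *linear interpolation* of the
calibrated curve sampled at λ-step 0.001 (not spline evaluation); below
the calibrated range the reduction is 0, above it the boundary value is
used by default (policies: clamp / error / extend). Export is legacy-ASCII
VTK: nodes advanced by cumulative element elongations, local radius scaled
by λ^(−1/2) (isochoric kinematics), cell data stretch / axial stress / CAP
reduction. Volume is conserved identically: (A0e/λe)(λe·ΔLe) = A0e·ΔLe.

**Cohort statistics.** Two-way ANOVA (sex × side, with interaction) uses
Type II sums of squares via statsmodels, well-defined for the unbalanced
designs that arise when specimens are excluded; Type I and II coincide on
balanced designs, where the implementation is checked against a
closed-form sums-of-squares oracle. A constant response returns F = 0,
p = 1; an empty design cell drops the interaction with a warning. Latency
(unstretched vs terminal trials) uses a pooled-variance two-sample t-test,
with (t, p) = (0, 1) when both groups are constant and equal. The
significance threshold (0.05) lives in configuration, not logic.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis assumes,
with defaults matching the measured cohort: diameters uniform on
1.30–1.53 mm (mean 1.42), lengths 24.7–35.2 mm (mean 28.8), α on
0.037–0.31 MPa, β on 0.78–3.40 MPa, stimulation 0.33 Hz for 20 s at
100 kHz (7 sweeps: stimulus at t = 0 included, floor(duration·rate) + 1),
stimulus 2.0–2.2 V / 40–100 µs, stretch protocol 1.000–1.200 in steps of
0.025 with the experimental stopping rule (stop at the first trial
reaching 50% reduction or at λ = 1.20).

Choices where the experiment is silent:

* **CAP waveform**: biphasic difference of two Gaussians (rise σ 0.4 ms,
  fall σ 0.8 ms, undershoot 0.5, lobe delay 1.2 ms), normalised so its
  sampled peak equals the prescribed amplitude exactly. The lobes are
  charge-balanced, so the waveform passes the 100 Hz edge essentially
  unattenuated.
* **Reduction truth**: a logistic in λ centred at λ50 with width w,
  shifted/rescaled so R(1) = 0 and R(λ50) = 50 exactly, clipped just below
  100 (inactive for λ ≤ 1.2 at the default widths, w ∈ 0.015–0.025). Any
  smooth monotone family would do; the logistic has two interpretable
  parameters.
* **λ50 dispersion**: mean 1.108 with between-specimen sd 0.028, the value
  implied by the published cohort's 95% CI half-width of 0.026 at n = 7
  (0.026·√7 / t_{0.975,6}) and consistent with the observed 1.075–1.15
  range.
* **Stimulus artifact**: charge-balanced biphasic square of duration equal
  to the stimulus pulse (capacitive pickup carries no net charge).
* **Latency**: electrode distance defaults to L0/2 and conduction velocity
  to 4.8 m/s — neither is experimentally constrained; the defaults place
  the CAP peak near 3 ms, clear of the artifact window, mirroring the
  experimental practice of tuning stimulus duration to avoid overlap.
* **Noise**: additive white Gaussian on traces (default sd 0.02 mV);
  multiplicative lognormal on forces (keeps forces positive, default off).
* **Fiber angles**: wrapped normal on (−90°, 90°], sd = FWHM/(2√(2 ln 2)),
  control FWHM 14°, stretched 8°.

Not emulated: the analog electronics chain (electrode impedance, solution
conduction, amplifier characteristics), stimulus-intensity-dependent fiber
recruitment, conduction-velocity changes with stretch (latency is held
fixed across stretch levels), viscoelastic force relaxation, and any image
formation upstream of the angle lists. Passing tests therefore demonstrate
correctness of the *analysis* under the stated statistical assumptions,
not robustness to every physiological artifact of real recordings.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations to the
statistics they check: 50–200 replicates for oracle-equivalence, recovery
and calibration checks; 1e5 samples for Monte-Carlo FWHM convergence;
reduced recordings (20 kHz, 10 s) for pipeline integration tests where the
property under test does not depend on the sampling density, full-protocol
recordings (100 kHz, 20 s, 9 stretch levels) for the noiseless end-to-end
signal-chain check. Key tolerances: constitutive fit vs oracle 1e-8 MPa;
FE force balance 1e-10 N (element solves), λ agreement with closed form
1e-8; spline inversion 1e-9 via exact polynomial roots; CI calibration
asserts ≥ 90% empirical coverage of a nominal 95% interval over 200
replicates (binomial tolerance).

## Known limitations

* The rod model has no bending, shear, transverse grip effects, or 3-D
  stress concentrations; it is exact only for homogeneous uniaxial tension
  of each cross-section.
* No viscoelasticity or rate dependence: forces are peak values per
  stretch increment, as in the protocol.
* The dose–response curve is calibrated per specimen over its observed λ
  range only; predictions beyond it are clamped by default.
* Per-specimen published stress tables are unavailable, so individual
  parameter estimates can only be validated in round-trip form; the
  cohort-average fit (0.183, 1.88 MPa) is reproduced from the published
  per-nerve pairs.
* ANOVA p-values for sex/side effects depend on raw per-animal data that
  are not public; the implementation is instead validated against
  closed-form oracles and null-calibration simulations.
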