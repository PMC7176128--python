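# Methods

## Scope and data model

All computation happens at the level of volume-of-interest time-activity
curves (TACs); there is no image-domain handling. Three containers carry
the data: `FrameSchedule` (ordered contiguous frames, seconds),
`ContinuousCurve` (uniform fine grid, default 1 s, kBq/mL) and
`SampledTAC` (frame-averaged values tied to a schedule). Time is stored in
seconds everywhere; rate constants are user-facing per-minute (K1 in
mL/ccm/min, k2–k4 in min⁻¹, the units they are reported in clinically) and
converted to per-second at the model boundary.

## Frame binning

A reconstructed frame reports the average activity concentration over its
duration, so `bin_curve` defines the frame value as the time-average of
the piecewise-linear interpolant of the fine-grid curve over
[start, start+duration). Duration-weighted frame values therefore sum
exactly to the curve's trapezoid integral (mass conservation, tested to
1e−9 relative). One consequence: re-binning a step curve whose jumps sit
on grid points is exact only up to a single boundary grid cell per frame,
because the linear interpolant smears the jump over one cell; the
idempotence test asserts at that tolerance.

Bolus arrival on the short (e.g. 3-s) early frames is declared at the
first frame exceeding the mean of the first `baseline_frames` (default 3)
frames by `k_sigma` (default 5) baseline standard deviations. The rule is
this package's own convention — any operational definition on 3-s frames
is equivalent up to one frame width for a real bolus — and both knobs are
exposed.

## Input function

The synthetic whole-blood curve is a gamma-variate first pass,
g(t′) = (t′/t_p)^α · e^(α(1−t′/t_p)) with onset 15 s, peak 35 s and shape
α = 3 by default, plus a bi-exponential recirculation tail
(amplitudes 12% and 8% of peak; decay constants 0.5 and 0.02 min⁻¹ with a
fast rise), rescaled so the maximum equals the requested amplitude
(default 30 kBq/mL, a typical arterial peak for a ~150 MBq injection).
Both components integrate in closed form (incomplete gamma / exponentials),
which the tests use as an analytic oracle.

Plasma correction follows C_p(t) = C_wb(t)/(1−Hct) · f(t) with default
hematocrit 0.42 and parent fraction
f(t) = f_∞ + (1−f_∞)·e^(−λt), defaults f_∞ = 0.5, λ = 0.03 min⁻¹ —
plausible for an amino-acid tracer undergoing peripheral O-methylation,
explicitly placeholders rather than measured metabolite fractions. The
single corrected curve C_p feeds both the blood-volume term and the
convolution, exactly as the tissue model below is written; an option to
pass distinct whole-blood and plasma curves exists via the
`InputFunction` fields.

## Kinetic models

The reversible single-tissue model with blood volume (1T2k+VB) is

    C(t) = V_B · C_p(t) + (1 − V_B) · K1 · e^(−k2 t) ⊗ C_p(t),

and the two-tissue models add a second pool (k3 inward, k4 outward; k4 = 0
gives the irreversible 2T3k+VB). Both are solved through trapezoid-weighted
discrete convolution with exponential kernels on the 1-s grid — for the
two-tissue models via the analytic bi-exponential impulse response with a
guarded branch for the repeated-eigenvalue degeneracy. The convolution is
evaluated by an exact O(n) linear recursion (equivalent to the quadratic
sum to machine precision, tested), so a full 20-min simulation costs
microseconds and Monte Carlo experiments stay cheap. Against an adaptive
ODE integrator at rtol 1e−10 the curves agree to ~1e−5 sup-norm; the 1-s
step is negligible relative to the slowest time constant (1/k2 ≈ 11.5 min).

## Fitting and the two frame-evaluation conventions

`fit_model` minimises Σ wᵢ (TACᵢ − modelᵢ(θ))² with a bounded trust-region
least-squares solver (scipy `least_squares(method="trf")`, the bounded
analogue of Levenberg–Marquardt; accepted steps monotonically decrease the
objective). Defaults: uniform weights (frame-duration weighting available),
initialisation K1 = 0.1, k2 = 0.1, k3 = 0.05, k4 = 0.01, V_B = 0.05,
bounds K1, k2, k3, k4 ∈ [0, 2], V_B ∈ [0, 0.5], and a three-point
log-normal multi-start jitter fallback on non-convergence (reported as
`converged=False`, never raised).

How the continuous model curve is reduced to frame values before
residuals is a genuine design choice with scientific content, so both
conventions are implemented:

* `model_eval="bin"` (default) — the model is frame-averaged with the
  TAC's own schedule, the same reduction that produced the data.
  Statistically consistent: noiseless data refit to machine precision on
  every schedule, which is what the parameter-recovery tests and the
  acceptance script exercise.
* `model_eval="midpoint"` — the model is sampled at frame mid-times, the
  convention of conventional kinetic-analysis software. For slowly varying
  curves the two are indistinguishable, but a midpoint sample
  mis-represents the frame average across the bolus peak when early frames
  are coarse — a 45-s first frame mixes pre-bolus zeros with the peak while
  its midpoint sample sees something else entirely.

The Monte Carlo schedule comparison fits in midpoint mode by design:
the experiment asks how binning interacts with standard fitting practice,
and under the self-consistent `"bin"` convention every schedule is
(verifiably) unbiased and the comparison degenerates. Noiseless midpoint
fits alone already separate the schedules — K1 error +0.18% for
8x15/2x30/2x60/3x300 versus −1.16% for 4x45/3x90/5x150 — and with noise
the ranking below follows.

Model comparison uses the small-sample Akaike criterion for Gaussian
residuals, AICc = n·ln(SS/n) + 2k + 2k(k+1)/(n−k−1) with k = 3/4/5 free
parameters for the three models; ties within 1e−9 resolve to the more
parsimonious model.

Logan graphical analysis regresses ∫₀ᵗC dτ / C(t) on ∫₀ᵗC_p dτ / C(t)
over frame midpoints with t ≥ t* (default 600 s; an automatic mode takes
the largest tail window whose points stay within 10% of their own linear
fit). For reversible single-tissue kinetics the plot is exactly linear
with slope K1/k2 and intercept −1/k2, which the tests verify to 5%. Note
that t* = 600 s needs a schedule with at least three frame midpoints past
10 min — the study schedules ending in 3×300-s frames have only two, so
Logan analysis is run on finer late binnings (e.g. 20×60 s).

## Noise model and Monte Carlo

Per frame of value C and duration Δt, one realisation adds
c·(X − C)/√Δt with X ~ Poisson(C): zero-mean by construction (never
clipped), variance c²·C/Δt, independent across frames. Frame values in
kBq/mL are used directly as Poisson means, so c absorbs all count-rate
calibration and is meaningless in isolation; `calibrate_c` bisects c until
a pilot run's sd(K1) matches a target (default 0.013 mL/ccm/min, the scale
of recovered-K1 SDs in this kind of experiment). On the default synthetic
input this gives c ≈ 2.1.

`run_mc` simulates the noiseless TAC, bins it, and refits
`n_realizations` (default 1024) noisy copies; non-converged fits are
excluded and counted. Each realisation index owns a dedicated RNG
substream derived from (seed, index), shared across schedules, so
`compare_schedules` yields K1 draws paired by realisation and the
schedule-vs-best comparisons use paired Wilcoxon signed-rank tests.
Summaries report mean, SD and the normal-approximation 95% CI
(mean ± 1.96·SD/√n). With c calibrated as above, the fine-early schedules
recover the target K1 = 0.161 most closely and are mutually
indistinguishable, while coarse-early schedules differ significantly
(p < 0.001 paired); the worst |bias| observed is a few times the CI
half-width, i.e. small in absolute terms but systematic.

## Synthetic cohort

The generator emulates a ~14-patient, ~33-lesion study. Lesion kinetics:
log-normal K1 (median 0.161 mL/ccm/min, σ_log = 0.5) and k2 (median 0.087
min⁻¹, σ_log = 0.4), logit-normal V_B (median 0.084, σ = 0.4), each with a
shared per-patient random effect (ICC 0.3 — patients contribute up to
three lesions clinically, and some within-patient similarity is
physiologic). TACs come from the 1T2k+VB model and the patient's own
synthetic input (amplitude and peak-time scatter across patients).

Paired static uptake: TBRmax at 20 and 35 min are log-normal with
marginal means 1.4 and 1.2 and a common log-scale SD of 0.53 (reproducing
a coefficient of variation ≈ 0.57, hence SDs ≈ 0.8 and 0.67). The SD
splits into a shared lesion effect (σ = 0.51) and a small
reading-specific residual (σ = 0.15), i.e. within-lesion correlation
≈ 0.92 — static uptake of the same lesion 15 min apart is nearly
deterministic. The shared effect loads 0.8 on the lesion's log-K1 z-score,
making SUVmax genuinely downstream of K1 (so the K1–SUVmax Spearman
correlation is strongly positive by construction, as it is in real
cohorts). Reference-cortex SUVmax scatters around 1; SUV plumbing uses
2 MBq/kg dosing and N(75, 12²) kg body weight.

What the generator does **not** emulate: reconstruction noise correlation
between frames, delay/dispersion between artery and tissue, tissue
metabolite compartments, partial-volume effects, or any joint
(K1, k2, V_B) dependence beyond the patient random effect. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not clinical performance.

## Statistics

Paired Wilcoxon signed-rank tests drop zero differences (Wilcoxon's
original convention), use the exact permutation null for ≤ 25 retained
pairs — computed by a subset-sum count recursion on doubled average ranks,
so ties are handled exactly — and scipy's normal approximation with tie
and continuity corrections beyond. Benjamini–Hochberg adjustment
(statsmodels) is applied across exactly the family of tests passed in one
call; the family is never implicit. Spearman matrices use average-rank
ties with t-approximation p-values; constant columns yield NaN flags
rather than errors.

## Problem sizes and determinism

Default experiments run in seconds on one core: 1024 realisations × 5
schedules ≈ 20 s, a 33-lesion cohort < 1 s. The test suite uses 256
realisations for the schedule-comparison check and 200 TACs for the
model-selection majority, sizes at which the tested effects are already
stable across seeds. Every stochastic path takes an explicit seed or
`numpy.random.Generator`; identical seeds reproduce results bit-for-bit,
including written CSVs.

## Known limitations

* The parent-fraction defaults are placeholders, not measured metabolite
  data; absolute plasma scaling (and hence anything amplitude-dependent,
  like the calibrated c) should not be compared across different
  parameterisations.
* The Monte Carlo bias magnitudes depend on the synthetic input's peak
  shape; only the qualitative ordering (fine-early beats coarse-early) is
  a robust output.
* Logan Vt underestimates K1/k2 for slow lesions (small k2) within a
  20-min acquisition — an inherent property of the method at this
  duration, visible in the cohort's vt column.
* AICc assumes i.i.d. Gaussian residuals; with duration weighting or
  strongly heteroscedastic noise it is a heuristic ranking, not a
  calibrated probability statement.
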