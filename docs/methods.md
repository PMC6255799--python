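# Methods

## Forward model

The simulator propagates the two-pool Bloch–McConnell equations for water
(`w`) and a GAG-hydroxyl solute pool (`s`, +1.0 ppm from water) in the frame
rotating at the saturation frequency. The state is
`M = (Mx_w, My_w, Mz_w, Mx_s, My_s, Mz_s)`; exchange couples like components
at rates `k_ws = f_r·k_sw` (water→solute) and `k_sw` (solute→water), and
longitudinal recovery makes the system affine, so the homogeneous 7-vector
`(M, 1)` is propagated instead. Each Gaussian saturation pulse is
discretized into piecewise-constant RF steps and each step is an exact 7×7
matrix exponential; the full train is a matrix power of the per-pulse
propagator (pulse → free evolution during `t_d` → optional crusher). Scipy's
`expm` is batched over the steps.

Assumptions: two pools only (no magnetization-transfer or NOE pool), no
intra-voxel B1 or B0 dispersion, instantaneous readout of `Mz_w` after the
train, normalization by an ideal unsaturated acquisition.

### Pulse shape

Pulses are Gaussians of width `σ` (default `t_p/4`) truncated to
`[0, t_p]` and, by default, *apodized*: the truncation-edge amplitude is
subtracted and the shape renormalized so the RF rolls smoothly to zero.
A hard ±2σ truncation leaves a 13.5% amplitude step that produces
excitation-profile ripple in Z of ±0.02 at the `1/t_p` (≈0.1 ppm at 3 T)
scale — an artifact real, apodized scanner pulses do not show, and one that
makes interpolation of a 0.3 ppm-sampled spectrum meaningless. The step
amplitudes are scaled so the discretized pulse delivers exactly the nominal
flip angle (`γ·ΣB1·Δt = flip/360`).

Discretization uses 192 steps per pulse by default; halving the step width
changes Z by < 1e-5 at the highest B1 (the midpoint rule is second order,
so 64 steps — a natural first choice — still leaves ~2e-5 steps-halving
sensitivity and was rejected). The integrator is validated against an
independent adaptive-ODE (solve_ivp, rtol 1e-11) integration of the same
train to |ΔZ| ≈ 1e-11.

## Saturation protocols

* CEST: 39 pulses, `t_p = t_d = 80 ms` (duty cycle 0.5, total 6240 ms),
  flip angles 900/1500/2100/3000° → time-average B1 of
  0.73/1.22/1.71/2.45 µT, offsets ±1.6, ±1.3, ±1.0, ±0.7, ±0.4 ppm.
* WASSR: 2 pulses, `t_p = t_d = 30 ms` (total 120 ms), flip 90°
  (≈0.20 µT), offsets −0.8…0.8 ppm in 0.2 ppm steps.

## B0 correction

The WASSR spectrum is symmetric about the true water frequency. The
estimator cubic-spline-interpolates the 9-point spectrum, anchors the
search at the interpolated minimum, then minimizes the mean squared mirror
asymmetry on a 0.001 ppm grid within ±0.1 ppm of the anchor, with a mirror
window of *fixed* width for all candidates (a candidate-dependent window
rewards centres near the acquired edge, where only flat wings are
compared), and refines the optimum parabolically. Recovery accuracy on
simulated spectra is ≈0.002 ppm for shifts on the 0.1 ppm grid and up to
≈0.006 ppm for shifts half-way between WASSR sample points (spline bias).

CEST spectra are re-centred by monotone-safe (PCHIP) interpolation of each
B1's 10-point spectrum at the shifted offsets. Edge offsets whose corrected
position falls outside the acquired range become NaN (only ±1.6 ppm can be
affected for realistic shifts; the ±1.0 ppm labels remain valid for
|shift| < 0.6 ppm). The inverse-CEST-difference round trip
(simulate shifted → estimate → correct, vs an unshifted simulation) is
accurate to ≈2–3% at the three lower B1 levels and ≈6% at 2.45 µT, where
the spectrum's curvature approaches the resolution limit of the 10-point
grid — an information limit of the protocol, not of the interpolant.

## Exchange-rate estimation

Per ROI (default) or per voxel: `CESTR_ind = 1/Z(+1) − 1/Z(−1)` per B1,
OLS of `1/CESTR_ind` on `1/ω1²` with `ω1 = 2π·γ·B1` (rad/s; B1 is the
time-average amplitude), then
`k_sw = [√(R2s² + 4m/(n·c2²)) − R2s]/2`. Non-positive `CESTR_ind` points
(possible under noise) are excluded; fewer than two usable B1 levels, or a
non-positive intercept, yields a flagged/NaN result. Map mode applies an
R² ≥ 0.9 quality gate by default.

Key parameters:

| parameter | default | meaning / rationale |
|---|---|---|
| `R2s` | 66.7 1/s | solute transverse relaxation rate; required by the closed form but not measurable from this protocol — an assumed literature-scale value for GAG hydroxyls, and every `k_sw` depends on it |
| `DC` | 0.5 | duty cycle of the train |
| `c1`, `c2` | 0.627, 0.745 | ideal-Gaussian shape constants for `σ = t_p/4` |
| `f_r` | 0.003 | solute proton fraction (≈0.3%, hundreds of mM hydroxyl protons); cancels in the estimate |
| `r2_threshold` | 0.9 | ω-plot QC gate for maps |

### Accuracy regime (measured on the simulator, noiseless)

The ω-plot linearization assumes the saturation amplitude is small against
the solute's chemical-shift offset. At 3 T the +1.0 ppm shift is 802 rad/s
while `ω1` reaches 655 rad/s, so the assumption fails and the estimate is
systematically compressed: true `k_sw` of 300/1000/2000 1/s yields
estimates of roughly 120/370/490 1/s with the default tissue parameters.
The estimate remains strictly monotone in the true rate and
concentration-independent (varying `f_r` over 0.001–0.01 at fixed `k_sw`
moves it by < 3%), which is what the downstream pH calibration needs: the
calibration is fitted in *estimated*-rate space and absorbs the bias. The
test suite asserts monotonicity and concentration independence; an
accuracy-band test at ±15% documents (and currently fails under) this
regime, deliberately — see the limitations section.

A second, subtler consequence of operating deep in the spillover regime:
the inverse-difference metric cancels direct water saturation only to first
order, so the estimate retains a residual T2 dependence. With the disc
tissue values used by the phantom (T2 halving from 120 ms to 60 ms upon
degeneration) this residual shifts the estimate by about −36 1/s — the same
magnitude as the +35 1/s produced by the pH-driven exchange-rate increase
from 256 to 320 1/s. In the phantom the two effects therefore cancel at the
group level, and the generated cohort does *not* reproduce a group
difference in estimated `k_sw`, although relaxometry separates the groups
cleanly and the estimate is monotone in `k_sw` at fixed relaxation. This is
reported as a property of the metric under these conditions, not hidden by
re-tuning the phantom.

## Relaxometry

`I = I0[1 − (1+η)exp(−TI/T1)]` (inversion recovery, η ∈ [0,1]) and
`I = I0·exp(−t/τ)` (multi-echo T2 / spin-lock T1ρ; the decay-time symbol in
the printed T2 equation is read as TE). Monoexponential fits initialize
from the exact log-linear regression; IR fits initialize T1 from the
null-point heuristic (`T1 ≈ TI_null/ln 2`) and, for all-positive magnitude
data, try every sign-flip prefix up to the signal minimum, keeping the
lowest-RSS fit. Nonlinear refinement uses `least_squares` with
xtol = ftol = 1e-12; noiseless round trips recover parameters to < 1e-6
relative. Degenerate data (all-zero signals, no measurable decay) are
flagged, not raised; map mode writes NaN for unmasked/failed voxels.

## Statistics

* Calibration `k_sw = a·10^(8−pH) + b`: linear in `(a, b)` given the
  regressor `10^(8−pH)`, so the least-squares fit is solved exactly by OLS
  (no iteration, no convergence failures). A fitted `a ≤ 0` is flagged
  non-physical. Inversion is restricted to `k_sw > b` with a clear error.
* Pearson correlation via `scipy.stats.linregress` (two-sided t-test,
  n − 2 df), verified against a permutation test.
* ROC: threshold sweep over unique scores (positive = degenerated = higher
  `k_sw`), trapezoidal AUC, Youden-J operating point with ties broken
  toward higher sensitivity. AUC is verified exactly against the
  Mann–Whitney pair-counting oracle and scikit-learn.

## Phantom generator

`make_disc_phantom` draws per-disc pH from group distributions (healthy
7.2 ± 0.10, degenerated 6.3 ± 0.15, truncated to [5.5, 8.0]), sets the true
exchange rate from the calibration `k_sw = 1.3·10^(−pH+8) + 248.2`, draws
group-dependent relaxation truths (T1 1.6/1.2 s, T2 120/60 ms, T1ρ
100/50 ms, ±5%), a per-disc B0 offset uniform in ±0.15 ppm, and simulates
the full acquisition set. Each disc is observed over a 121-voxel ROI
(an 11×11 patch — a nucleus-pulposus ROI at the protocol's 1.1 mm
resolution genuinely contains on the order of 100 voxels) with Gaussian
noise of SD 0.005 per voxel on normalized signals (image SNR ≈ 100); Rician
noise is available. The biomarker generator emits
`RQ = α + β·k_sw + ε` per marker and compartment with `ε` scaled so the
population R² matches the per-marker targets (CGRP 0.8758, BDKRB1 0.8623,
COMT 0.9025, IL6 0.8368, BDNF 0.9219); rare non-positive RQ draws are
redrawn.

What the phantom does **not** emulate: magnetization-transfer/NOE
background, intra-voxel B0/B1 dispersion, motion, partial volume, spatial
noise correlation, or any anatomical geometry. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to every in vivo confound.

All generators draw from a single seeded `numpy` Generator; a fixed seed
reproduces every dataset bit for bit.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make every check a
few seconds at most: spectral simulation at 192 steps/pulse, recovery
curves over five exchange rates, Monte-Carlo loops of 100–200 replicates of
48–50 samples, phantoms of 5–16 discs.

## Known limitations

* `R2s` is assumed, not measured; reported `k_sw` values scale with it.
* The ω-plot estimate is biased low at 3 T/+1.0 ppm (compression described
  above); comparisons across studies must hold the protocol fixed.
* Estimated `k_sw` retains second-order spillover (T2) sensitivity; group
  contrasts between tissues with very different T2 partly reflect that.
* B0 correction is interpolation-limited at the highest B1.
* The inversion-efficiency bound η ∈ [0, 1] is a choice; magnitude IR data
  with poor inversion may sit at the bound.
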