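# Methods

## Signal model and processing conventions

All processing rests on one forward model: a free induction decay (FID) is
a sum of exponentially decaying complex sinusoids,
`s(t) = Σⱼ Aⱼ exp(iφⱼ) exp(i2πfⱼt − πΔνⱼt)`, sampled at the dwell time
`1/bandwidth`. The decay constant `πΔν` makes `Δνⱼ` the full width at half
maximum (Hz) of the absorption-mode Lorentzian. The discrete Fourier
transform is scaled by the dwell time (sum × dwell), approximating the
continuous transform, so an absorption line of amplitude `A` has peak
height `A/(πΔν)`; Parseval then holds exactly in the form
`Σ|s|²·dwell = Σ|S|²·Δf`. This scaling is what makes the MRSI quality gate
(below) unambiguous. Two consequences of discreteness matter and are
handled rather than ignored:

* the rectangle-rule transform carries a flat complex pedestal of height
  `dwell·s(0)/2` across the band; it is removed by the quadratic baseline
  correction, never by ad hoc subtraction;
* a line that has not fully decayed by the end of acquisition loses a
  fraction `exp(−πΔν·T)` of its integral to truncation ringing.

The ppm axis ascends with frequency (`ppm = carrier + f/f₀`, `f₀` = 75.4
MHz, the ¹³C Larmor frequency at 7 T). Carriers default to 179 ppm for
pyruvate experiments and 145 ppm for bicarbonate experiments — midway
between the lines each experiment quantifies, keeping every analysis
window far from the band edges.

Zero-order phasing maximises the real integral over the declared signal
windows. The optimum has the closed form `φ̂ = arg ΣC_w` (with `C_w` the
complex window integrals); the implementation uses a 360-point grid with
bounded 1-D refinement, which converges to the same value and is
deterministic. No first-order phase term is fitted: summed single-voxel
spectra with two resonances do not need one, and adding it would trade
robustness for an unidentifiable parameter at these linewidths.

Window integrals are trapezoidal on the real part, with partial bins
included by linear interpolation at the window bounds, so the integral is
continuous in the bounds, additive over adjacent windows, and linear in
the spectrum. Noise is the RMS of the mean-subtracted real part over a
declared signal-free window.

## Voxel fitting (MRSI)

Each voxel FID is fitted with four resonances — pyruvate (173 ppm),
lactate (185 ppm) and two small auxiliary lines (defaults 181 and 178 ppm,
pyruvate-hydrate- and alanine-like; configuration, not constants) — by
least squares in the time domain. The problem is solved by variable
projection: for fixed shifts, linewidths and common phase the non-negative
amplitudes are the exact solution of a linear NNLS subproblem, and only
the nine nonlinear parameters are iterated (trust-region reflective, with
bounds: shifts ±1.5 ppm of nominal, linewidths 5–200 Hz). Initialisation
is deterministic — nominal shifts, 30 Hz linewidths, amplitudes from
magnitude-spectrum peak heights, phase from the largest peak — so fits are
reproducible without random restarts. Non-convergence returns the best
parameters found with a flag, never an exception. On noiseless synthetic
voxels the fit recovers all parameters to better than one part in 10⁶,
and the fitted amplitude ratio agrees with a frequency-domain
window-integral quantification to <1% on isolated peaks.

The quality gate converts the fitted pyruvate amplitude to the peak height
of a 50 Hz-linewidth line (`A/(π·50)`) and requires it to exceed 11× the
RMS noise, strictly — a voxel at exactly 11× is excluded. The gate is a
display/QC convention; group comparisons between paws use all ROI voxels,
and both masks are kept separate so either convention is reproducible.
ROI selection includes a voxel iff its centre lies inside the polygon
(boundary counts as inside); voxel (r, c) has its centre at
`((c+0.5)·fov/n, (r+0.5)·fov/n)` mm, matching the proton-image pixel
convention. The grid noise level is the median of per-voxel tail-window
noise estimates. Voxel groups are compared with a Welch (unequal-variance)
t-test, two-sided p reported alongside a one-sided one, with no
multiplicity correction — the voxel-ratio variances of inflamed and
non-inflamed paws clearly differ, which is what motivates Welch over the
pooled test.

## pH estimation (dynamic bicarbonate)

The pipeline is: sum the FIDs with timestamps in [12 s, 39 s] (28 spectra
at 1 s spacing), transform, phase, quadratic baseline correction anchored
on all points outside the two analysis windows dilated by three expected
linewidths, integrate 123–127 ppm (CO₂) and 156–163 ppm (HCO₃⁻), and
convert with pH = pKa − log₁₀(ratio). pKa defaults to 6.17 but is a
parameter — literature values vary with temperature and ionic strength.

Two guards wrap the estimate. (1) An equilibration check computes
per-spectrum ratios, regresses them on time weighted by CO₂ SNR²
(spectra with CO₂ SNR ≤ 3 are unusable; at least 5 usable spectra are
required), and accepts when the slope's 95% interval contains zero or the
fitted relative drift is below 10% per 10 s. A failed check downgrades to
a warning on the result — the estimate is still returned, flagged.
(2) When the CO₂ window integral is at or below 3× its propagated noise
(`noise_rms · Δppm · √N_bins`), the estimate is censored and reported as a
lower bound computed from the 3σ detection limit: late in an acquisition
the hyperpolarized CO₂ signal decays below detectability, and an
uncensored ratio would then be pure noise.

Because the two windows have different widths (4 vs 7 ppm), the captured
tail fractions of the two Lorentzians differ slightly, biasing the pH by
about +0.003 at the default 8 Hz linewidth. The noiseless pipeline
recovers a known pH to <0.005 units; linewidths much above ~12 Hz would
push this structural bias past that figure, while much narrower lines
lose >1% of their integral to truncation ringing within the 171 ms
acquisition. The 8 Hz default balances the two.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of their configuration, seed included.

**MRSI phantom.** 32×32 voxels over a 40×40 mm² field of view, 128×128
proton reference, 256 complex points at 6000 Hz per voxel FID (42.7 ms
readout, consistent with the short-TR acquisition emulated; the protocol
source does not state a readout length, so this is the package's choice).
Paw regions are polygons; in-region voxels carry four Lorentzians with the
region's pyruvate amplitude and lactate = ratio × pyruvate, out-of-region
voxels are noise only. Per-voxel true ratios are jittered around the
regional mean (default SD 0.1) with the draws re-centred so the regional
ground-truth mean equals the configured value exactly — the jitter models
intra-paw heterogeneity, not uncertainty in the regional mean. Noise is
complex white Gaussian in the time domain (the standard MR noise model),
with the default level set so a unit pyruvate amplitude has peak SNR 20
under the 50 Hz-linewidth convention of the quality gate — comfortably
above the 11× threshold, as in displayed in vivo maps.

**Bicarbonate series.** Spectra every second from 12 s (1024 points,
6000 Hz, 10° flip), HCO₃⁻ and CO₂ lines at their window centres with a
fixed amplitude ratio `10^(pKa − pH)` and a common decay
`exp(−t/τ)·cos(flip)ⁿ` with a 10 s polarization half-life; differential
relaxation of the two species is deliberately out of scope. Equilibration
is instantaneous by default; an optional pre-equilibrium mode approaches
the equilibrium ratio as `1 − exp(−t/τ_eq)` to exercise the equilibration
check's rejection branch (τ_eq ≈ 16 s is comfortably rejected; much
faster approaches are indistinguishable from equilibrium within the
12–43 s observation window, which is the correct behaviour, not a test
artifact). The default noise level puts the CO₂ window integral of the
28-spectrum sum at SNR ≈ 100 (bicarbonate peak SNR ≈ 2–3·10³ — routine
for hyperpolarized spectra): the regime in which the minor resonance of a
~0.07–0.09 ratio is cleanly quantifiable, as it must have been for
per-paw pH values with group SDs of 0.06–0.09 to be measurable at n = 4.

**Paw study.** Long-format (mouse, day, side) table with CFA-side ankle
and footpad diameters shifted by per-day effect profiles over a PBS
baseline, Gaussian calliper noise (0.1 mm), and an ordinal 0–3 clinical
score from a rounded, clipped latent variable. Defaults (ankle +0.8 →
+1.2 mm over days 1–5, n = 5) reproduce robust per-day rejections at
p < 10⁻⁴, matching the swelling time courses the model emulates.

What passing tests on these generators shows is that the *pipeline*
recovers known ground truth under the stated noise model; they do not
model B₀ inhomogeneity, baseline roll from rapid digitisation, partial
volume, perfusion heterogeneity, or physiological ratio gradients, so
in vivo accuracy claims remain outside what the suite can establish.

## Statistics

Foot volume is `Σ areas × thickness` over outlined 2 mm slices, with no
end-slice correction (the segmentation protocol defines the extent). The
one-sided two-sample test is Welch by default (pooled optional) and
accepts (mean, SD, n) summaries so printed group statistics can be tested
exactly. The swelling/score analysis is an ordinary two-way fixed-effects
ANOVA on treatment × day (type-II sums of squares, mouse identity
ignored; the repeated-measures structure is acknowledged but not modelled
— per-day comparisons are available in a Welch variant for users who
distrust the pooled residual), with per-day comparisons Sidak-adjusted as
`p_adj = 1 − (1 − p)^m`. Under a null simulation the treatment F-test
rejects at the nominal 5% rate.

## Numerical choices and degenerate inputs

* Optimiser tolerances: `xtol=ftol=gtol=1e-12`, max 400 function
  evaluations per voxel; NNLS is exact per iteration.
* A zero fitted pyruvate amplitude leaves the voxel ratio undefined (NaN),
  which downstream means excluded, never zero.
* A non-positive bicarbonate integral raises — there is no pH to report.
* Empty resonance lists are valid (zero FID); empty time-window selections
  and sub-minimum baseline/noise windows raise with messages naming the
  offending window.
* Problem sizes in the test suite are chosen to exercise each Monte-Carlo
  claim at useful power on a laptop-scale budget (e.g. 100–500 seeds for
  calibration rates, 100 voxel fits for ratio recovery); the acceptance
  script uses 4 series per pH group and ~112-voxel phantom regions.

## Known limitations

* No kinetic modelling: ratios are amplitude ratios at a fixed time, not
  exchange rate constants; no pyruvate→lactate kPL fitting.
* No first-order phasing, apodization options, B₀/B₁ correction, spatial
  smoothing or partial-volume handling.
* No pH imaging: bicarbonate data are treated as coil-localised single
  spectra; intracellular/extracellular compartments are not modelled.
* The container format is deliberately minimal (JSON + raw float64);
  vendor raw formats and DICOM MRS are out of scope.
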