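# Methods

`ramangrad` models, analyzes, and maps label-free Raman monitoring of
extracellular metabolism in a diffusion-fed microreactor: a 15 mm culture
chamber supplied by a lateral nutrient reservoir, with spectra acquired
through glass windows at positions along the chamber (zones z1/z2/z3 at
increasing distance from the reservoir) over a four-day culture. Because no
public dataset exists for this acquisition design, the package carries a
full synthetic forward model; every analysis stage is exercised against
data whose ground truth is known.

## Reaction–diffusion forward model

Transport is one-dimensional diffusion along the chamber axis,

    ∂C/∂t = D ∂²C/∂x²  + reaction terms,     x ∈ [0, 15] mm,

solved with an explicit cell-centered finite-volume scheme (flux form, so a
closed domain conserves mass to machine precision). The reservoir acts on
the left face; the distal wall is zero-flux. Two reservoir idealizations are
available:

* an **infinite well** (Dirichlet: face concentrations held fixed), used for
  the adenine transport validation, where the reservoir is a large stock and
  the early-time profile is the semi-infinite closed form
  `C(x,t) = C0 · erfc(x / (2√(Dt)))`;
* a **finite well-mixed reservoir** (default, volume ratio 2× the chamber),
  whose concentrations evolve by mass balance with the chamber. This is the
  study condition: over four days the whole system depletes glucose and
  accumulates lactate, so temporal variation dominates spatial variation —
  the regime the monitoring method is designed to resolve — while
  diffusion-limited supply still grades the chamber from a well-perfused z1
  to a stressed distal z3.

Stability of the explicit scheme is enforced, not silently repaired: a user
time step violating `D·Δt/Δx² ≤ 1/2` for any analyte is refused with the
computed ratio; the auto-chosen step uses 0.45.

Reactions, applied where cells are present (areal density ρ, default 1):

* glucose uptake: Michaelis–Menten, `Vmax = 0.45 mM/h` at unit density,
  `Km = 1 mM`;
* lactate production: 2 lactate per glucose (glycolytic stoichiometry);
* pH: each lactate carries one proton; local pH = 7.4 − [lactate]/β with a
  HEPES-dominated buffer capacity β = 30 mM per pH unit, clipped to [0, 14].
  Tying acidity to the (diffusing) lactate field keeps acid transport
  consistent without a separate proton PDE;
* stress-marker release (the purine-like 680 cm⁻¹ species): constant rate
  0.05 mM/h wherever glucose < 5 mM or pH < 6.8. This rule is an explicit
  stand-in for biology that is not mechanistically settled (lysis vs
  secretion); both thresholds are configurable.

Diffusion coefficients default to the small-molecule aqueous decade
(10⁻¹⁰–10⁻⁹ m²/s): glucose 2.4, lactate 2.0, adenine 2.3, stress marker
2.5 mm²/h.

## Spectral rendering

A spectrum on the 600–1200 cm⁻¹ axis (1 cm⁻¹ spacing) is the sum of analyte
band responses, a medium signature, a slowly varying fluorescence baseline,
focal-height-dependent glass window bands, additive Gaussian detector noise
(default sd 1 count), and occasional cosmic-ray spikes (1–3 channels,
500–2000 counts, per-spectrum probability 0.1).

Metabolite bands are Lorentzians at their field-standard positions —
glucose 1125, lactate 853, adenine 725, stress marker 680 cm⁻¹ — with FWHM
8–12 cm⁻¹; the glass signatures are broad Gaussians with *different* band
sets for the top and bottom windows (different manufacturers), mixed in by
exponential proximity of the focal plane to each window (decay 0.15 mm).
Amplitudes place physiological concentrations at signal-to-noise of order
20–50.

pH sensing rests on two ingredients:

* **HEPES** (25 mM in the medium) is a two-state Henderson–Hasselbalch pair,
  pKa 7.5 (37 °C), with the protonated band at 1040 cm⁻¹ and the
  deprotonated band at 1048 cm⁻¹ at higher amplitude, so deprotonation
  shifts the apparent band up in wavenumber and intensity.
* a **medium titratable pool**: complex media contain many weak acids/bases
  whose overlapping pKa values make the aggregate protonation state
  quasi-linear in pH over a wide range. This is modeled as one band
  (895 cm⁻¹) scaled by the mean deprotonated fraction over a pKa grid
  3.5–10.5. Without it, a single pKa-7.5 transition carries essentially no
  pH information below ~6 or above ~9 and no linear model could cover the
  pH 4–10 calibration span; the published experiments give only the
  qualitative band behaviour, so the exact mapping is a model choice of this
  package.

What the generator does **not** emulate: photobleaching and drift between
days, wavenumber miscalibration between sessions, Poisson (shot-noise)
statistics, cell-density heterogeneity, 2-D/3-D transport, oxygen as an
explicit species (its effects are folded into the stress rule), and real
biological matrix variability. Tests passing on this generator therefore
demonstrate correctness of the *analysis chain* under the stated physics,
not performance on any particular instrument's data.

## Preprocessing chain

Five steps per spectrum, in order:

1. **Cosmic-ray removal** — residual against a 7-channel median filter,
   scored by a robust (MAD) z-score, threshold 8; only runs ≤ 3 channels
   wide are repaired (linear interpolation), so genuine bands — wider by
   construction — are never touched at realistic noise levels. Limitation:
   at very high SNR the 3-channel top of the sharpest (FWHM ≈ 8 cm⁻¹) band
   approaches the detector's width limit and may be interpolated across; the
   repair is symmetric, so band positions are preserved.
2. **Savitzky–Golay smoothing** — window 35, order 2; boundary windows are
   fit on the available samples (`mode="interp"`), avoiding fake edge peaks
   near 600 cm⁻¹.
3. **ALS baseline** — 10 iterations of `(W + λ DᵀD) z = W y` with the
   second-difference operator `D`, asymmetry `p = 0.01`, solved as a
   pentadiagonal banded system (cost linear in channels). The default
   smoothness is **λ = 10⁶**, the magnitude standard in baseline-correction
   practice for ~600-channel spectra. Values many decades smaller make the
   penalty negligible against the weights, the "baseline" then reproduces
   the signal and subtraction annihilates the spectrum; one such published
   value (10⁻⁶) is kept as `PRINTED_ALS_LAMBDA` for comparison but is not a
   usable default.
4. **Centering** — subtract the baseline, then the spectrum's own mean;
   every processed spectrum has exactly zero mean. No variance scaling is
   applied.
5. **Replicate averaging** — optional grouping by metadata keys, group sizes
   recorded.

The pipeline returns a log echoing every parameter used.

## Chemometrics

* **PCA**: truncated SVD of the column-centered matrix; the
  largest-magnitude element of each loading is made positive so score
  trajectories are reproducible. Degenerate (zero-variance) input is
  rejected rather than returning empty components.
* **ASCA**: grand mean; per factor (day, zone) the level-mean deviation
  broadcast to sample rows; residual completes the exact additive identity.
  Factor PCA runs on the effect matrices uncentered (they are centered by
  construction for balanced designs; for unbalanced designs level means are
  computed the same way and the zero-column-mean property is simply not
  asserted). Interaction terms are off by default and available by flag; no
  permutation testing is included.
* **PLS**: single-response NIPALS with the textbook deflation;
  coefficients `W(PᵀW)⁻¹q`. Zone projections use ±1-coded responses and
  report score projections only (two latent variables); the pH model picks
  its latent-variable count by leave-one-out RMSE, capped at 5.
* **Calibration**: ordinary least squares with `R² = 1 − SS_res/SS_tot`.

## Spatial analyses

* Band values are windowed means (center ± 5 cm⁻¹), robust to ≤ 1-channel
  drift and linear in the spectrum; the registry stores one canonical center
  per band (680, 1040) with the nearby literature variants (685, 1041) as
  aliases.
* Peak detection is a parabolic-interpolated argmax on the wavenumber
  scale (shift-equivariant); boundary/flat maxima return with a warning.
* Focal-plane selection runs PCA on the z-scan and accepts spectra whose
  score distance to the centroid of the scan's middle third stays within
  median + 3·1.4826·MAD of the middle-third distances (a robust ≈3σ rule —
  a 1-MAD cut would reject roughly half of a genuinely homogeneous
  cluster). The recommended height is the lowest accepted z at or above a
  0.3 mm clearance over the bottom window, i.e. as close to the cell layer
  as glass interference allows. Absence of a contiguous central cluster is
  an error, never a silent default.
* Diffusion-profile fitting is bounded nonlinear least squares of
  `C0·erfc(x/(2√(Dt)))` with multi-start over log-spaced D in
  [10⁻³, 10] mm²/h. Note that fitting *preprocessed* band intensities can
  carry a small additive offset from residual baseline + centering; the
  fit contract deliberately stays the two-parameter closed form.

## Problem sizes and determinism

Every generator consumes one integer seed, expanded into per-stage
substreams (seed ⊕ CRC32 of the stage name), so identical configurations
reproduce byte-identical outputs. Default analysis problem sizes — the
3 × 4 × 15 replicate design (plus matched no-cell control), 16-point
z-scan, 30 + 10 pH series, 6-level × 3-replicate dilution series, and a
~1 mm-step chamber map — run end to end in seconds on one CPU; test
simulations use coarser replicate counts (5) where only directional
conclusions are asserted.

## Known limitations

* The stress-release rule and the pH→band mapping are modeling choices, not
  published mechanisms; conclusions about the 680 cm⁻¹ band and absolute pH
  accuracy transfer to real data only qualitatively.
* The solver is first-order in time and the reservoir is well-mixed; neither
  matters at the accuracy the analyses need (the 2 % agreement with the
  closed form is verified in the tests).
* Despiking is reference-free and single-spectrum; spike-on-peak events in
  very low-noise spectra are its worst case.
* No wavenumber calibration/alignment, multiplicative scatter correction, or
  derivative spectroscopy; spectra are assumed on one shared axis.
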