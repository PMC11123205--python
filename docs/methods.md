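# Methods

`sfsmac` models and corrects motion artifacts in single-fiber spectroscopy
(SFS) recordings of brain hemodynamics.  A single multimode fiber (400 μm
core, NA 0.53, 16°-polished tip) delivers broadband light into tissue and
collects the backscatter, which a spectrometer resolves in time (~10 Hz)
and wavelength.  Motion of the animal perturbs the optical coupling along
the light path and produces broadband, step-like intensity shifts that
contaminate perfusion estimates.  This note documents the models, the
numerical choices, and what the synthetic experiments do and do not show.

## Reflectance and the measurement model

Backscatter frames `Ib(t, λ)` are normalized between two reference
spectra recorded with the fiber tip in glycerine (`Ig`, index-matched to
silica, near-zero specular return) and in air (`Ia`, strong index
mismatch):

    R(t, λ) = (Ib − Ig) / (Ia − Ig).

`R` is intentionally not clamped to [0, 1]; artifact excursions outside
that range are the phenomenon of interest.  References are linearly
interpolated onto the frame grid, never the reverse, and a vanishing
denominator is a hard error.  No dark-spectrum subtraction or exposure
normalization is applied: the normalization operates on raw counts, and
the dissimilarity metric below is exactly scale invariant, so detector
gain cancels.

The measured intensity decomposes into Fresnel terms at the fiber ends
plus the tissue return (`forward_intensity`):

    Ib = I·RaNf + I·TaNf·T·RfFb·T·TfNa + RSF·Iin·TbFf·T·TfNa,
    Iin = I·TaNf·T·TfFb.

In the 670–680 nm band the tissue term is comparatively small and
blood-insensitive, so intensity there tracks the interface terms — the
terms motion perturbs.  This underpins both the artifact metric and the
correction.

## Dissimilarity metric (DM)

    DM(i) = (S(i) − M(i)) / M(i),

with `S` the 670–680 nm band-summed intensity and `M` its mean over a
centered window of `N` samples (default: 1 s at the frame rate).  The
printed window definition `j = i−N/2 … i+N/2` contains N+1 samples while
normalizing by 1/N; we use a centered window of exactly `N` samples
normalized by the actual in-window count, truncated (not padded) at the
record edges, with even windows biased one sample to the past.  σ_DM, the
sample standard deviation of DM over non-overlapping chunks (1 s or 60 s
depending on the analysis), summarizes artifact magnitude; an overlapping
stride is available but chunk counts only reconcile with a partition.

RMSD between spectra is the standard `sqrt(mean((a−b)²))`.  A literal
rendering of the printed formula (squaring the summed deviations) is
available behind a flag for comparison only; the name of the quantity and
the magnitudes it must reproduce identify the standard form as the
intended one.

## Motion-artifact correction (MAC)

The zero-mean 670–680 nm band series `n̂(t) = S(t) − ⟨S⟩` proxies all
transmission-based changes.  Every wavelength channel is corrected by
subtracting its ordinary-least-squares projection on the proxy:

    Ic(λ, t) = I(λ, t) − m(λ)·n̂(t),

with `m(λ)` the OLS slope (intercept included) of `I(λ, ·)` on `n̂`.
Because `n̂` is zero-mean on the input record, correction preserves every
channel's temporal mean exactly.  Implemented as a scikit-learn
transformer (`MotionArtifactCorrector`) so it composes with pipelines;
`fit_mac`/`apply_mac` wrap it for `SpectralFrame` objects.

Choices that were genuinely open:

- **Regressor**: the band sum over 670–680 nm by default (averages noise);
  a `single_wavelength` option uses only the 680 nm column, the
  convention of "680 nm represents the range".
- **Fit span**: the full record by default.  An optional sample mask
  restricts the fit (e.g. to high-σ_DM segments); masking guards against
  hemodynamic leakage into `m` but is off by default.
- **Robustness**: a Huber-regression option exists because isolated spike
  artifacts defeat plain OLS; it is off by default to keep the canonical
  estimator.
- `m` is fit per recording; per-trial fitting is available by applying
  the estimator to trial sub-frames.

Known limitation, quantified by the dynamic experiment below: when the
record contains a hemodynamic trend that covaries with the proxy over the
fit span, plain full-record OLS absorbs part of it into `m`.  In the 7 s
dynamic validation this biases `m` low by ~19%, which caps the
during-artifact MSE reduction near 10^1.4 instead of the ~10^2 an
unbiased slope would give (the log-reduction is −2·log10 of the relative
slope error).  The sample-mask and robust options are the provided
mitigations; both are deliberately opt-in.

## Photon transport

A weighted Monte Carlo model of the probe in a homogeneous tissue block
(default 10×10×10 mm, absorbing boundaries, tip embedded 1 mm below the
top face — the block is large relative to the ~0.3 mm transport length;
a warning fires if any side is under 20 mean free paths).

- **Absorption** `μa = BV·(sO2·μHbO + (1−sO2)·μHb)` from whole-blood
  coefficients at 150 g/L hemoglobin; the bundled extinction table is a
  compact synthetic compilation of published landmark values (isosbestic
  points at ~500/545/570/584/797 nm, the HbO₂ 542/577 doublet, the Hb 555
  peak and 758 shoulder), PCHIP-interpolated.  545 nm is an exact
  isosbestic point of the table.  Defaults: BV = 1%, sO2 = 35%.
- **Scattering**: intralipid power law `μs = f·16·(λ/1 μm)^−2.4 mm⁻¹`
  with dilution f = 0.2 (the standard 2%-lipid brain phantom), giving
  μs ≈ 8–14 mm⁻¹ over 545–680 nm; Henyey–Greenstein phase function with
  `g(λ) = 1.1 − 0.58e−3·λ` (≈0.87 at 400 nm to ≈0.7 at 700 nm).
- **Indices**: Cauchy `n = A + B/λ² + C/λ⁴` for brain tissue (~1.36),
  fused silica (~1.46) and glycerine (~1.47); coefficients are recorded
  in `data/optical_constants.json` and flagged there as chosen published
  values where the instrument literature cites but does not print them.
- **Launch**: positions uniform over the core disc; directions uniform in
  solid angle within the internal acceptance cone `sinθ ≤ NA/n_f`,
  refracted through the 16° face by Snell's law with unpolarized Fresnel
  weight splitting.  A flat-tip configuration (`tip_angle_deg=0`) exists
  for debugging.  Lenses, beamsplitter, aperture and the 2 m patch cord
  are static and omitted; the fiber transmission T is treated as 1.
- **Transport**: exponential steps at 1/(μa+μs), per-collision weight
  attenuation by the albedo, Russian roulette below weight 1e−4 with
  survival 0.1.  The weight ledger (detected + absorbed + escaped =
  launched) balances within 1e−3 on every run; a fixed seed is
  bit-reproducible.  Per-run seeds derive from one master seed via
  `SeedSequence`, so scans parallelize reproducibly.
- **Detection**: weight crossing the tip-face disc from the tissue side is
  Fresnel-split; the transmitted part within the acceptance cone is
  detected, the rest is lost to the cladding.  The fiber body above the
  tip plane is *not* modelled — photons crossing the plane outside the
  core disc continue in tissue.  This is the main geometric
  approximation.
- **Artifact model**: a transmission coating at the fiber/brain interface
  multiplies every crossing weight by τ.  Detected tissue return
  therefore scales exactly τ² (launch + detection crossings) while the
  specular face reflection is untouched.
- **References**: with the tip in air or glycerine the return is the
  specular lobe of the angled face; the default evaluates it by
  deterministic quadrature over the launch cone, and an MC mode agrees
  within sampling error.  The 16° polish displaces the specular lobe by
  32°, so only the edge of the NA cone returns — the angled tip's
  purpose.

### Paired (continuous-absorption) estimator

Comparisons between absorbing and non-absorbing conditions at matched
geometry use an analog-scattering kernel that records each detected
packet's geometric weight and tissue pathlength `L`; the detected weight
at any `μa` is then `Σ w·exp(−μa·L)`.  Both conditions share identical
photon paths, so the shared-path variance cancels — the red-band
sensitivity (~1%) is resolvable at desk-scale photon counts where
independent runs would need ~10⁸ histories.  The independent two-run
scheme remains available (`method='independent'`) and the two estimators
agree within their combined standard errors (tested).

## Synthetic dynamic experiment

Hemodynamics follow the canonical double-gamma impulse response (shape
parameters 6/16/1/1 — the conventional canonical values, here unvalued in
the source formulation) convolved with a boxcar stimulus (2–4 s),
superposed with cardiac/respiratory/Mayer sinusoids at 1/0.2/0.07 Hz and
a DC bias.  Oscillation weights (0.015/0.010/0.008 with unit HRF weight)
are set so the pulsatile terms are ~10% of the HRF excursion — visible
but non-dominant physiological structure.  The min–max normalized
response y(t) ∈ [0, 1] drives concentrations

    μa(t) = μHb·(ΔC_HbR·y + C_HbT/2) + (ΔC_HbO·y + C_HbT/2)·μHbO,

with C_HbT = 50 μM, ΔC_HbO = 10 μM, ΔC_HbR = 2.5 μM.  Both excursions are
added with the same sign as formulated; a `deoxy_sign` flag flips the
deoxy excursion for the conventional activation polarity.  Records are
7 s at 10 Hz with the artifact as a 96% coating on 2–3.5 s.

Two engines produce the 545/680 nm backscatter time series:

- **lookup** (default): one pathlength run per wavelength, evaluated at
  ≥ 8 absorption knots spanning the μa(t) range and PCHIP-interpolated;
  queries outside the hull trigger logged knot extension, never silent
  extrapolation.  Artifact events scale the tissue return by τ(t)²
  analytically.  This quasi-deterministic engine is the closer analogue
  of deterministic ray-splitting simulators, whose per-sample noise floor
  is far below a stochastic photon count at the same nominal size.
- **full-mc**: a fresh transport run per time sample — the literal
  procedure, used where per-sample noise matters (e.g. the artifact-free
  control, where a noise-dominated 680 nm channel is what keeps the
  fitted correction near zero).

By default the ideal and corrupted frames share every random stream
except the coating, so an empty schedule reproduces the ideal frame
bit-exactly.  `independent_reference=True` rebuilds the artifact-free
series from independently seeded simulations — the two-series design of
the validation experiment, whose artifact-free regions then differ by the
simulation noise floor instead of being identically equal.  The
region-MSE analysis (regions 0–1.8 / 1.8–3.6 / 3.6–7 s; percent change
vs the 2 s pre-stimulus baseline) uses this mode, since ratios against an
identically-zero floor are degenerate.

What the generator does *not* emulate: pressure-induced local blood-flow
changes, flow/speckle dynamics, heart-rate variability, detector dark
current and wavelength-calibration drift.  Passing tests therefore show
correctness of the metric/correction pipeline under transmission-change
artifacts with HRF-shaped absorption, not robustness to every in-vivo
artifact mechanism.

## Problem sizes and tolerances

Desk-scale defaults (single CPU): the sensitivity scan uses 2.5×10⁵
photons × 4 repeats per wavelength with the paired estimator; the
coating experiment 1.5×10⁵ photons per condition on a 455–705 nm grid in
25 nm steps (the RMSD reporting band of the instrument analysis); the
dynamic experiment 5×10⁵ photons per lookup.  Tests use smaller sizes
with tolerances set from binomial/packet standard errors (3 SE unless
stated).  Stochastic MC assertions are seeded and deterministic.
Reference quadrature uses a 512×512 midpoint grid (converged to ≪1%).

## Command-line interface

`sfsmac` exposes `reflectance`, `dm`, `mac fit|apply`, `mc-sensitivity`,
`mc-shift`, `simulate-dynamic`, `figure4` and `run-paper-sims`, each
reproducible from `--seed` plus the echoed, hashed configuration;
`--fidelity {paper,ci}` switches between full and reduced problem sizes.
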