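# Methods

This note documents the models behind each module, the parameters that
matter, the synthetic data used to exercise them, and the numerical choices
made where the design was open.

## Buffer chemistry (`buffers`)

Tris buffers titrated with HCl contain TrisH⁺ and an equal amount of Cl⁻.
The acid/base split at a given pH follows the Henderson–Hasselbalch relation
with an activity correction for the cation,

    [Tris]/[TrisH⁺] = 10^(pH − pK) · γ₊,

with pK = 8.08 for Tris and γ₊ from the Davies equation
(log₁₀ γ = −A z² (√I/(1+√I) − 0.3 I), A = 0.509 at 25 °C, I in mol/l).
Since I depends on the split, the split is solved by damped fixed-point
iteration (damping 0.5, tolerance 10⁻⁶ mM, divergence signalled with the
last iterate).  For 10 mM Tris at pH 7.5 this yields 8.07 mM TrisH⁺/Cl⁻ and
1.93 mM free base, i.e. an ionic strength of ≈ 8 mM; adding 3 mM NaCl gives
≈ 11 mM.  Fully dissociated salts contribute ½ c z(z+1) assuming monovalent
counterions.  The Davies correction is applied to all charged species; note
that the Davies expression turns upward near I ≈ 0.4 M, far above any buffer
in scope (≤ 100 mM).

Unit conversions use a base-pair molar mass of 650 g/mol (sodium salt) and
the B-form rise of 0.34 nm/bp, both exposed as parameters.  The base-pair
count per protein spacing supports an explicit rounding convention
(`none`, `nearest`, `nearest-10`); at the default `nearest-10` a 10 nm
spacing reads as 30 bp.

## Persistence length from traced contours (`wlc`)

Molecules equilibrated in two dimensions on a surface obey

    ⟨cos θ(L)⟩ = exp(−L / 2P),

where θ(L) is the angle between unit tangents separated by arc length L.
The pipeline: resample each trace to a uniform arc-length step (default
5 nm, the tip-resolution scale); take tangents as **segment directions at
half-integer arc positions**; pool cos θ over all in-molecule pairs of all
molecules; bin by separation (bin width 5 nm); and fit exp(−L/2P) by
weighted least squares in linear space with weights 1/Var(bin mean),
default fit window L ∈ [5, 150] nm (beyond ~150 nm on 340 nm contours the
pair counts collapse).  A 3D convention exp(−L/P) is available via
`dims=3`.

Segment tangents rather than central differences: central differences
average adjacent segments, which multiplies the discrete correlation by
exp(step/4P) (a half-step offset) and biases a one-parameter exponential
fit upward by several percent.  With segment tangents the generated 2D WLC
ensemble satisfies the decay law exactly at multiples of the step.

Resampling places points at arc lengths 0, h, 2h, … S with
h = S/round(S/step): spacing is exactly uniform along the original
polyline, both endpoints are preserved, and h deviates from the request by
at most half a step.  On curved paths the chords between resampled points
differ from h at curvature order; the uniform-step check in
`tangent_correlation` therefore uses a 10⁻³ relative tolerance.

Estimator performance under study conditions (35 chains × 350 nm, 5 nm
step): single-ensemble scatter ≈ 6% SD; bias < 1% for P ∈ [30, 80] nm
(measured over seeded repeats in the test suite).

## Gyration-tensor imaging (`gyration`)

Per frame, the intensity-weighted center of mass and 2×2 second-moment
tensor are computed over background-subtracted pixels (pixel centers at
half-integer coordinates).  The long-axis length uses the uniform-rod
identity

    L∥ = sqrt(12 ⟨S∥⟩),

with S∥ the largest eigenvalue (by SVD of the symmetric tensor) averaged
over frames.  A literal linear reading "L∥ = 12⟨S∥⟩" is dimensionally
inconsistent (S carries length²); the square-root form is the only reading
that returns micrometer-scale long axes from μm² moments and is exact for a
homogeneous rod.

Background is the image median; the noise SD is 1.4826×MAD.  Pixels enter
the moments only if they exceed background + 2×noise SD **and** belong to
the largest connected component — without the connectivity restriction,
scattered Poisson-tail pixels at large distances dominate the second
moments.  Consequences of the 2σ support mask: objects with sharp edges
(rods, thresholded channel molecules) are unbiased, while Gaussian blobs
are truncated at the threshold radius, an ≈ 10–15% multiplicative
underestimate of L∥ at the synthetic SNRs used here.  It cancels in ratios
and leaves monotonicity intact; calibrated absolute blob sizes would need a
threshold-dependent correction, which is out of scope.

## Nanochannel extension analysis (`channels`)

The extension of a confined molecule is the span, projected on the channel
axis, of the above-threshold fluorescence; the threshold is background +
2×noise SD (background = image median, SD = 1.4826×MAD; "2× the
signal-to-background-noise" is read as 2 noise SDs).  Before thresholding
the image passes a 3-pixel median filter **along the channel axis only**:
this removes isolated shot-noise pixels exactly and is the identity on
monotone signal edges, so a blurred molecule boundary is untouched.
Above-threshold pixels are grouped (8-connectivity) and the brightest
component is taken as the molecule; the extension is the distance between
its outermost pixel centers along the axis.  Noise-free synthetic molecules
are recovered to the pixel; at SNR 10 with a 0.12 μm PSF the edge spread
costs ≲ 2 pixels.

Population statistics: a Gaussian is fitted to the extension histogram
(~√n bins); the fit is flagged poor below R² = 0.8 (bimodal populations
fail this).  Fragment rejection uses the cutoff mean − 2 SD **of the intact
population**, estimated robustly (median, 1.4826×MAD) in one pass — moment
estimates would be inflated by the fragments themselves.  For a pure
Gaussian population of ~30 the expected minimum sits at μ − 2.04σ, so a
2σ cutoff occasionally clips the extreme tail; this is inherent to the
rule, not to the estimator.

Condensed/coil classification: condensed iff the extension is at most
`compactness_factor` × PSF FWHM (boundary included) **and** the
peak-to-background ratio is at least `brightness_factor` × the median of a
coil reference population (without a reference the brightness test is
skipped with a warning).  Both factors default to 2.  The compactness
factor is an operational convention: the above-threshold span of a
diffraction-limited spot whose peak stands a factor ≳ 10 above the
threshold is itself ≈ 2.2–2.5 PSF FWHM, so 2.5 is the appropriate setting
for bright spots and is what the synthetic round-trips use.

The condensation threshold of a concentration series is the lowest tested
concentration with condensed fraction > ½, reported with the bracketing
interval (highest sub-threshold concentration, threshold); series that
never reach a majority return an open interval with a notice.  Relative
extensions divide by the contour length (57 μm for YOYO-stained T4 DNA by
default).

## SANS cylinder model and contrast variation (`sans`)

A protein coat bound along a stiff DNA fragment is modeled as a cylinder of
length L with N_p bound proteins and a normalized radial density ρ(r).  The
cross-section enters through the zeroth-order Hankel transform
a(q) = ∫ 2πr J₀(qr) ρ(r) dr, and the orientation-averaged structure factor
is

    S(q) = π N_p/(qL) · a²(q)          (asymptotic, qL ≫ 1)
    S(q) = N_p · a²(q) · Λ(qL)         (finite length),

with Λ(x) = 2 Si(x)/x − sinc²(x/2) the rod factor (Λ→1 as x→0, → π/x as
x→∞), reconciling the asymptotic form with the q→0 normalization to N_p.
Closed-form amplitudes: Gaussian ρ ⇒ a = exp(−q²r_p²/4); shell between r₁
and r₂ ⇒ a = 2[r₂J₁(qr₂) − r₁J₁(qr₁)]/(q(r₂²−r₁²)).  Both match an
adaptive-quadrature Hankel oracle to ≤ 10⁻⁸ relative (with a 10⁻¹² floor
near the amplitude zeros, where relative precision is ill-posed in double
precision).  Cross-sectional radii of gyration: r_p (Gaussian),
√((r₁²+r₂²)/2) (shell).

Contrast variation: the scattering-length-density difference of each
component varies linearly with the solvent D₂O fraction and vanishes at its
match point (40% for the protein, 64% for DNA; both configurable).  Curves
at ≥ 3 compositions determine the protein and DNA partial structure factors
by per-q weighted linear least squares; a cross term can be included behind
a flag but is neglected by default.  On noise-free synthetic mixtures the
decomposition is exact to machine precision, and the propagated per-q
standard errors are the appropriate weights for the subsequent profile fit.

Profile fitting minimizes weighted residuals of the asymptotic model over
(profile parameters, interspersion length L/N_p), excluding q < 3/L_rod
(default rod length 51 nm for 150 bp); r₁ is typically fixed at the DNA
radius of 1 nm.  Because a²(q) oscillates, χ² is multi-modal in the outer
radius, so the optimizer restarts from a small grid of radii and keeps the
best solution; parameter errors come from the fit covariance.  Under the
study conditions (shell r₁ = 1, r₂ = 6 nm, L/N_p = 10 nm, 5% multiplicative
noise, 4 contrasts) the fit recovers r₂ within ±0.5 nm and L/N_p within
±1 nm in ≥ 90% of repeats.

## Confined worm-like-chain Monte Carlo (`mc`)

Discrete WLC: beads connected by rigid bonds of length b (default 5 nm)
with bending energy E/kT = (P/2b) Σ θᵢ²; hard channel walls act on bead
centers in x and y (cross-section centered on the origin, axis along z);
optional excluded volume is a hard-core diameter between beads ≥ 2 bonds
apart, enforced by a spatial hash grid updated incrementally.

Moves: crankshaft (rotate a short interior run about the chord through its
ends; only the two joint angles change), pivot (rotate the shorter chain
side about a random axis through a bead), and reptation — delete a bead at
one end, append at the other with the new joint angle drawn from its
Boltzmann density sin θ·exp(−κθ²) via inverse CDF and uniform azimuth.  The
reptation proposal density cancels the bending weight exactly, so the move
is accepted whenever the new bead clears the wall and hard-core
constraints; detailed balance holds for all three moves.  Reptation is
essential: without it the global extension of a 2000-bead confined chain
decorrelates over ≫ 10³ sweeps.  Crankshaft/pivot amplitudes auto-tune
toward ~40% acceptance during the burn-in window only (first quarter by
default).  High crankshaft acceptance with the amplitude pinned at π is
normal at this discretization and not flagged.

Initialization grows the chain bead by bead from the Boltzmann angle
density with retries on wall/core violations ("grow"), starting the Markov
chain near a typical confined conformation; a straight-line seed is
available.  Estimates use the second half … first quarter discarded as
burn-in; errors come from a blocking analysis (2ᵏ block sizes, plateau
value); a stationarity flag compares the two production halves at 3
combined SE.

Extension observables: the z-span of the beads (default, matching the
thresholded-fluorescence span measured in experiments) and
sqrt(12 Var(z)), the homogeneous-rod equivalent length.

The headline experiment pairs a bare chain (P = 49.1 nm, full contour)
with a protein-coated chain (P = 60.4 nm, contour −20%) in a 200 × 300 nm
channel and reports 100·(1 − ⟨R_bound⟩/⟨R_bare⟩).  Two modeling points:

* **Self-avoidance is required.**  For an ideal chain the axial statistics
  are nearly independent of transverse confinement when the channel is
  wider than P, and the measured stretch change is ≈ 0.  With a hard-core
  diameter equal to the bond length (5 nm) the chain is in a de
  Gennes-like regime where R∥ ∝ L (w_eff P)^{1/3} D^{−2/3}, predicting a
  decrease of 1 − 0.8·(60.4/49.1)^{1/3} ≈ 14%; the simulations give
  14–15 ± 3%.  The experiment therefore defaults to excluded volume on.
* **Problem size.**  The chain is scaled to a 10 μm contour (2001 beads);
  the relative stretch change, not the absolute extension, is the
  compared quantity.  The extension autocorrelation time is ≈ 2×10³
  sweeps, so the default configuration (6 seeds × 5000 sweeps per arm)
  yields a standard error of ≈ 3 percentage points; per-seed values
  legitimately scatter by ±8 points.

Reference statistics for validation: the discrete chain with i.i.d. joint
angles has exactly ⟨R²ₑₑ⟩ = b²[n(1+c)/(1−c) − 2c(1−cⁿ)/(1−c)²] with
c = ⟨cos θ⟩ computed by quadrature; the continuous WLC form
2PL − 2P²(1−e^{−L/P}) agrees once evaluated at the chain's effective
persistence length −b/ln c (discretization shifts P by ~b/2P relative).  A
free rigid rod tumbles, so the rod limit (extension → contour within 2%)
is checked in a narrow channel that keeps the rod aligned.

## Synthetic data (`synth`)

All generators are deterministic given their seed and return the ground
truth they encoded.

* **2D WLC traces** — turning angles i.i.d. N(0, step/P), so the ensemble
  satisfies the 2D decay law exactly at multiples of the step; the polyline
  length equals the requested contour exactly.  Defaults mirror the study
  conditions: 35 chains, 350 nm contour (1000 bp), P = 49.1 or 60.4 nm,
  5 nm step.  Not modeled: tip-sample broadening, tracing errors, molecule
  overlap.
* **Channel images** — a coil is a one-row axial top-hat (extension 3–17 μm
  scale) blurred by a Gaussian PSF (σ = 0.12 μm, a diffraction-limited
  100× objective scale); a condensed molecule is a sub-resolution globule
  imaged as a Gaussian spot of width sqrt(spot² + psf²) whose peak is 3×
  the coil amplitude; Poisson noise at amplitude = SNR × background shot
  SD (background 20 counts).  Real coils have soft ends and intensity
  fluctuations along the molecule; the threshold rule is what is under
  test, so a top-hat suffices.
* **Bulk frames** — anisotropic Gaussian blob with axial second moment
  long_axis²/12 (or a uniform rod), random in-plane orientation per frame,
  Poisson noise.  No photobleaching, blinking, or tracking.
* **SANS datasets** — forward model c_p²(f)·S_protein + c_d²(f)·S_DNA
  (+ flat background) at compositions (0, 40, 64, 100)% D₂O with
  multiplicative Gaussian noise (σ = noise_pct × I); the DNA partial is a
  uniform rod of radius 1 nm.  Instrument resolution smearing (10%
  wavelength spread) is not modeled.

Passing round-trips on these generators demonstrates estimator
correctness under the stated noise models — not robustness to the
instrument effects listed as unmodeled.

## Known limitations

* The gyration long axis of smooth (Gaussian) objects is underestimated by
  the threshold mask truncation (see above); thresholded or sharp-edged
  objects are unaffected.
* The asymptotic SANS mode diverges at q→0 by construction; quantitative
  work below qL ≈ 3 must use the finite-length mode.
* The MC stretch experiment reports a ratio with SE ≈ 3 percentage points
  at its default budget; tightening it scales as 1/√(compute).
* Multi-acid speciation, temperature-dependent pK, and Pitzer-level
  activity models are out of scope for the buffer module.
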