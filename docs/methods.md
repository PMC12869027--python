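# Methods

This note records the models, parameter choices and numerical conventions
behind `patquant`, and what the synthetic studies do and do not demonstrate.

## Forward model and estimators

The per-voxel photoacoustic amplitude is p0 = Γ·ϕ·μa. Γ and the delivered
pulse energy are unknown positive per-location scales, so all concentrations
and THb/TSf outputs are *relative*; saturation percentages are
scale-invariant for every estimator (the scale cancels in the concentration
ratio).

- **LU** solves min ‖p0 − c_ox·ε_ox − c_de·ε_de‖² subject to c ≥ 0 by exact
  active-set non-negative least squares (`scipy.optimize.nnls`), not by
  clipping an unconstrained fit. An all-zero spectrum yields a flagged
  undefined saturation (NaN), never an exception, so whole-image maps stay
  computable.
- **CLU** is LU on p0/ϕ_ave. ϕ_ave may be tabulated on a denser grid than
  the measurement (e.g. simulated at 11 wavelengths, applied at a
  4-wavelength clinical set); it is linearly interpolated, never
  extrapolated, and must be strictly positive.
- **CC** scans candidate saturations (default 0–100% in 0.5% steps; ties go
  to the smallest candidate). For each candidate s the generators are
  ϕ_i(λ)·μa(λ; s); the spectrum's angle to the cone is the angle to its
  non-negative least-squares projection onto the generators. The angle is
  computed in chord form, 2·arcsin(‖p̂/|p̂| − p/|p|‖/2), which is exact near
  zero where arccos of a dot product loses all precision; exact cone members
  therefore report a residual at the rounding floor. Reported CC "THb" is
  the L2 norm of the projection (relative units) split according to the
  winning saturation.
- **Depth compensation** multiplies every pixel at depth z (cm, measured
  from the transducer face to the pixel center, row 0 shallowest) by
  exp[(μf+μb)·z], identically at all wavelengths; μb's wavelength dependence
  is ignored. Because the factor is wavelength-flat, ISDC %sO2 equals CLU
  %sO2 pixelwise, and only THb changes — this identity is asserted in tests.
  μb must come from the user (co-registered ultrasound in a clinical
  workflow, which this package does not model); the bundled default of
  0.5 cm⁻¹ is a synthetic-study setting.
- Map pixels whose cross-wavelength maximum amplitude falls below 5% of the
  image's 99th-percentile amplitude are flagged undefined (NaN %sO2, zero
  THb): unmixing noise-floor pixels is meaningless.

## Monte-Carlo transport

The voxel grid is 2-D (x, z) but photon directions are sampled in full 3-D
with the medium invariant along y. This matters: for the planar sources used
here a strictly planar random walk decays with the 2-D diffusion constant
√(2μa(μa+μs′)), about 18% below the 3-D value, whereas the y-invariant
3-D walk reproduces 3-D diffusion μ_eff = √(3μa(μa+μs′)) — the oracle the
tests check against (observed agreement ~7% at μa = 0.1, μs′ = 10 cm⁻¹).

Variance reduction: implicit capture (weight loses μa/μt per interaction)
with Russian roulette below weight 1e−4 (survival 0.1, survivors boosted
10×). Fluence is tallied by track length, which stays unbiased in
non-absorbing voxels. Roulette is a martingale, not per-history conserving,
so the simulator returns an exact weight ledger:
launched + roulette-gain − roulette-loss = absorbed + escaped to float
roundoff; without the roulette terms the balance holds statistically
(observed |imbalance| < 1e−4 relative at 2×10⁴ photons).

Each wavelength runs on a seed derived from the user seed (kept below 2³¹);
identical (seed, n_photons) reruns are bitwise identical. The source model
is two surface line segments flanking a central detector gap (defaults:
12 mm segments, 8 mm gap, 20° half-angle), an idealization of a fiber-
flanked endocavity probe with a diffusing sheath; pencil and full-width
sources are available for analytic limits.

## Eigenspectra and ϕ_ave

Sampled fluence spectra are normalized to 1 at the reference wavelength
(800 nm, near the hemoglobin isosbestic point; if absent, the nearest grid
wavelength is used and recorded) and reduced by a deterministic k-medoids
under cosine distance (central-point + farthest-point initialization, PAM
refinement). Medoids — not abstract components — guarantee every member is
a realizable fluence spectrum, which the cone's non-negativity semantics
require. The number kept defaults to the number of wavelengths (11 for the
phantom band). ϕ_ave is the ensemble mean of the member eigenspectra,
renormalized at the reference wavelength.

Two sampling routes exist. `extract_eigenspectra` takes an explicit voxel
mask (the generic contract). The calibration workflow uses
`eigenspectra_from_structures`, which averages the fluence over sub-regions
(quadrants) of each absorber structure before normalization. The averaging
matters because at desk-scale photon counts (10⁵/wavelength) per-voxel shot
noise would otherwise dominate the sampled spectral variation; the quadrant
split matters because whole-structure means collapse the sample family to a
one-dimensional depth sequence, discarding the lateral and intra-structure
(self-shading) components of the variation that the cone representation is
meant to cover.

μf is the negative slope of a least-squares line through ln(laterally
averaged fluence) versus depth (default fit band 0.6–3.0 cm, at 800 nm),
clamped at zero for non-decaying profiles; the fit R² is recorded. The
fitted μf includes geometric beam spreading near the source, not only
asymptotic attenuation — which is what the compensation should undo, since
the measured maps decay the same way.

## Synthetic world (what the generator emulates)

The digital phantoms define a *self-consistent* synthetic ground truth; all
optical constants are package defaults, not measurements:

- **Extinction tables** (CSV, 650–950 nm at 2 nm): literature-style smooth
  curves. The HbO2/Hb pair crosses at ~804 nm and is near-isosbestic
  (within 5%) at both 800 and 808 nm. The sulfate unit spectra satisfy
  ε_Cu(800) = 14.28·ε_Ni(800) exactly, with NiSO4 rising steeply over
  730–830 nm (oxy-analog role) and CuSO4 rising gently and monotonically
  toward a broad ~880 nm band. The *relative* slopes are what make a
  red-shifted fluence deficit read as under-saturation, reproducing the
  bias direction the compensators exist to fix.
- **Background bath**: Intralipid-like scattering, μs′(λ) = 1 cm⁻¹·(λ/800)^−2.4
  with g = 0.9, over a smooth water-dominated absorption rising from
  0.014 cm⁻¹ (730 nm) to 0.036 cm⁻¹ (830 nm). The monotone rise makes the
  deep fluence decrease with wavelength — the spectral-coloring direction
  the estimators assume. With a literal water curve the 740–760 nm band and
  800 nm dip give the deep fluence a W shape whose net bias, under this
  package's sulfate spectra, flips with depth; the smooth ramp is the
  deliberate modeling choice that keeps coloring common-mode.
- **Tube phantom** (default): 15 cross-sections of one continuous tube
  (diameter 1.5 mm, uniform TSf = 0.1 giving μa(800) ≈ 0.5 cm⁻¹), zig-
  zagging within a 14 mm lateral band at depths 6–30 mm in a 35×35 mm grid
  (0.25 mm voxels) — the compact band makes deep sections partially shadowed
  by shallow ones, as in a threaded-panel phantom. Keeping the sulfate load
  modest keeps the coloring background-dominated and hence nearly
  truth-independent ("relatively constant" LU bias); at several-fold higher
  loads tube self-filtering makes the bias truth-dependent and a single
  ϕ_ave over- or under-corrects by truth.
- **Forward model**: p = Γ·ϕ·μa (Γ ≡ 1 by default), acoustic damping
  exp(−μb z) with μb = 0.5 cm⁻¹, and additive white Gaussian noise at 30 dB
  SNR relative to the RMS absorber-voxel signal — noise on the beamformed
  map, not on RF channels, because beamformed maps are this package's
  input contract.
- **Sphere and clinical phantoms**: an agar sphere (2 cm, μs′ 2.5 cm⁻¹ at
  800 nm) threaded by 4 inner (2×40%, 2×75% %sNi) and 2 outer tubes; a
  layered medium (muscle 5 mm, peritoneal fluid 10 mm, ovary disk 20 mm,
  1–3 mm hemoglobin vessels at 2.3 mM total). Layer optical constants are
  plausible NIR soft-tissue values and fully configurable.
- **Lesion cohorts**: paired views of the same 15 malignant / 67 benign
  lesions. The compensated view plants benign/malignant means of
  (%sO2 73/63 ± 8, THb 1.0±0.25 / 1.9±0.35 → group ratio 1.9); the
  uncompensated view is derived from it (saturation shifted −5 points with
  extra spread; THb contrast compressed to a group ratio 1.4 with extra
  multiplicative depth variability). All effect sizes are synthetic design
  parameters.

What passing the synthetic studies shows: the estimators, compensation and
evaluation chain behave correctly and in the documented directions in a
world whose ground truth is known exactly. What it does not show: accuracy
on real tissue, where Grüneisen and optical-property heterogeneity, acoustic
bandwidth and speckle, patient-specific anatomy and beamforming artifacts —
all outside this package's scope — enter.

## Study workflows and problem sizes

The calibration run simulates a mixed-saturation tube phantom (tubes cycling
through 20/60/80/100%) at 10⁵ photons per wavelength over the 11-wavelength
band, and derives the eigenspectra, ϕ_ave and μf used for all truths — the
compensation is deliberately *not* tailored per phantom. The tube study
clusters the depth-compensated amplitude image (supra-97th-quantile
connected components, 8-connectivity, ≥8 pixels) inside a 4–31.5 mm analysis
band: compensation equalizes tube amplitudes across depth, and the deepest
rows of a compensated map contain exponentially amplified noise only. LU and
CLU read the raw cluster spectra; ISDC reads the compensated ones (so the
order is compensate, then cluster-average). Because TSf is relative, the
cross-depth spread of each method is compared on mean-normalized values;
comparing raw spreads would reward LU for being uniformly small at depth.

The compensator ranking draws trial fluences as symmetric-Dirichlet convex
combinations of the eigenspectra (in-cone by construction) over truths
10–100% in 10-point steps, 100 fluences per truth. Because the experiment is
stochastic end to end (Monte-Carlo fluence, random trial mixtures), a single
realization can end in a statistical dead heat when one eigenspectrum
happens to fall near the center of that realization's trial family; the
reproduction script therefore replicates the whole experiment five times on
derived seeds and pools the per-candidate trial errors before ranking
(`pooled_compensator_ranking`) — the claim under test is that the ensemble
mean is the *consistently* best single compensator, and pooling is what
measures consistency. The classification study
fits unregularized logistic regressions on standardized features and scores
them in-sample (a stratified 5-fold variant exists behind a flag).

These sizes (10⁵ photons/wavelength, 140×140 grid, 15 clusters × 4 truths,
1000 ranking trials per replicate, 50 cohorts) were chosen so Monte-Carlo
noise sits well
below the effects under study while a full run stays in the minutes range
on one core.

## Numerical conventions and edge cases

- No extrapolation anywhere: wavelength requests outside a table raise.
- Saturation is computed ratio-first and clamped to [0, 100] at the ulp
  level; zero total concentration → NaN with a `so2_defined` flag.
- Ranks are always a permutation of 1..n: ties break by MAE, then candidate
  index. The composite score is the mean of the four per-metric ranks
  (the least parametric combiner; a package choice).
- Robustness tolerance is 5 absolute percentage points of saturation error.
- Uniformity STD uses divisor n (population form).
- `fit_depth_attenuation` requires ≥5 depth samples and positive fluence in
  the band; μf is floored at 0.

## Known limitations

- 2-D (y-invariant) transport: correct depth statistics for planar sources,
  but no out-of-plane source/target geometry.
- Single global (μf, μb): residual depth bias remains wherever the true
  decay is not a single exponential (e.g. strong lateral heterogeneity).
- One ϕ_ave per acquisition: truth- and depth-dependent coloring beyond the
  common mode is not corrected by CLU (visible as the residual CLU spread in
  the tube study).
- No acoustic wave propagation, transducer PSF, speckle, or refractive-index
  mismatch; no absolute calibration of THb (Γ unknown).
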