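# patquant

Quantitative photoacoustic tomography (PAT): oxygen-saturation (%sO2) and
total-hemoglobin (THb) estimation from multispectral beamformed pressure
maps, with correction for the two fluence artifacts that corrupt naive
spectral unmixing — wavelength-dependent *spectral coloring* and
depth-dependent attenuation — plus a fully seedable digital-phantom
simulator so every stage can be validated without measurement data.

## Who this is for

Researchers working on functional PAT (e.g. transvaginal ultrasound-guided
PAT of ovarian lesions) who need per-pixel or per-region %sO2 and relative
THb estimates that remain quantitative at depth, and a synthetic test bench
for fluence-compensation strategies.

## The model

The beamformed pressure at location R and wavelength λ follows

    p0(R,λ) = Γ(R) · ϕ(R,λ) · μa(R,λ),      μa = c_ox·ε_ox(λ) + c_de·ε_de(λ)

with Γ the (wavelength-independent) Grüneisen coefficient, ϕ the local
fluence, and ε_ox/ε_de the molar extinction spectra of oxy-/deoxy-
hemoglobin. Four estimators are provided:

- **LU** (linear unmixing): non-negative least squares of p0 against
  (ε_ox, ε_de), assuming flat fluence. Systematically biased by spectral
  coloring.
- **CC** (convex cone): the fluence is modeled as a non-negative combination
  of Monte-Carlo-derived eigenspectra {ϕ_i}; %sO2 is the candidate s
  minimizing the angle between p0 and the cone spanned by
  {ϕ_i(λ)·μa(λ; s)}.
- **CLU** (compensated LU): LU applied to p0(λ)/ϕ_ave(λ), where ϕ_ave is the
  ensemble mean of the normalized eigenspectra (ϕ_ave(800 nm) = 1). A
  numerical study (`rank_compensators`) shows ϕ_ave is the best
  single-spectrum compensator among all individual eigenspectra by MAE and
  by a composite score.
- **ISDC** (integrated spectral and depth compensation): CLU plus the
  depth correction p0,c(z,λ) = p0(z,λ)·exp[(μf+μb)·z], with μf fitted from
  simulated fluence decay and μb the acoustic attenuation. The depth factor
  cancels in %sO2 and restores THb at depth.

The phantom analogs use NiSO4/CuSO4 (blood surrogates) with
%sNi = (C_Ni/14.28) / (C_Ni/14.28 + C_Cu) × 100 and
TSf = C_Ni/14.28 + C_Cu; the factor 14.28 accounts for the stronger specific
absorption of CuSO4.

Transport is a seedable voxel Monte Carlo on a 2-D (x, z) grid with full 3-D
Henyey–Greenstein scattering (the medium is invariant along y), implicit
capture and Russian roulette; fluence is tallied by track length.

## Worked example

The `demo` subcommand runs the synthetic end-to-end study: simulate a
calibration tube phantom over 730–830 nm (11 wavelengths), derive the 11
fluence eigenspectra, ϕ_ave and μf, then build depth-varying tube phantoms at
true %sNi of 20/60/80/100% (15 tube cross-sections each, 30 dB SNR), cluster
the cross-sections, and compare estimators:

```
$ patquant demo --seed 1 --out-dir demo_out
 truth  n_clusters    lu_bias    lu_mae  clu_bias  clu_mae  tsf_std_lu  tsf_std_isdc
  20.0          14 -10.279401 12.494475 -1.286102 8.891617    0.876127      0.067570
  60.0          15 -18.479911 18.479911 -9.114249 9.114249    0.829217      0.081804
  80.0          15 -14.781019 15.853396 -6.012156 9.851237    0.832379      0.082991
 100.0          15 -15.377748 15.377748 -7.848270 7.848270    0.825244      0.088837
phi_ave MAE rank: 1  composite rank: 1
```

Reading the table: flat-fluence LU underestimates %sNi by a roughly constant
15–18 points at truths ≥ 60% (`lu_bias`, in percentage points) — the
spectral-coloring signature — while CLU cuts the mean absolute error at every
truth (`clu_mae` vs `lu_mae`). The last two columns give the population
standard deviation of mean-normalized per-cluster TSf across depth: depth
compensation (ISDC) shrinks the spread by roughly 10× relative to LU,
i.e. the recovered total-sulfate values become uniform across 0.6–3 cm depth
as they physically are. The final line reports that the ensemble-mean
compensating spectrum ranks first among the 12 candidate compensators both
by MAE and by the composite score.

Library use mirrors the CLI:

```python
import patquant as pq

cal = pq.calibration_run(seed=1, n_photons=100_000)   # eigenspectra, mu_f
res = pq.tube_phantom_study(seed=1, calibration=cal)  # the table above
report, _ = pq.compensator_ranking_study(seed=1, calibration=cal)
```

## Layout

- `src/patquant/spectra.py` — wavelength grids, bundled extinction tables
- `src/patquant/photon_sim.py`, `_mc.py` — Monte-Carlo transport,
  eigenspectra, depth-decay fits
- `src/patquant/unmix.py` — LU / CLU / CC estimators
- `src/patquant/depthcomp.py` — depth compensation, whole-image maps
- `src/patquant/phantom_synth.py` — digital phantoms and the forward model
- `src/patquant/metrics_eval.py` — clustering, uniformity STD, THb ratio,
  compensator ranking, lesion classification
- `src/patquant/pipeline.py` — end-to-end studies; `cli.py` — the `patquant`
  command

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
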