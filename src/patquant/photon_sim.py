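"""Wavelength-resolved Monte-Carlo photon transport on digital phantoms.

Produces per-wavelength fluence volumes, log-linear depth-attenuation fits
(the mu_f used by depth compensation), and normalized fluence eigenspectra
with their ensemble mean phi_ave (the single-spectrum compensator used by
compensated linear unmixing).

Coordinate convention: z is depth from the transducer face in cm, positive
downward, row 0 shallowest; voxel centers sit at (i + 1/2) * voxel_size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._mc import run_mc
from .errors import (ConfigurationError, DegenerateMediumError,
                     DegenerateSampleError, LogDomainError)
from .spectra import REFERENCE_NM, Spectrum, WavelengthGrid

__all__ = [
    "DigitalPhantom", "FluenceVolume", "EigenspectraSet", "DepthModel",
    "SourceGeometry", "simulate_fluence", "extract_eigenspectra",
    "eigenspectra_from_structures", "fit_depth_attenuation",
    "absorber_sample_mask",
]


@dataclass
class DigitalPhantom:
    """Voxelized optical properties on a (z, x) grid.

    mu_a and mu_s are (n_wavelengths, nz, nx) in cm^-1; g (anisotropy) and the
    integer structure labels are (nz, nx).  Label 0 is background.
    """

    grid: WavelengthGrid
    voxel_size_mm: float
    mu_a: np.ndarray
    mu_s: np.ndarray
    g: np.ndarray
    labels: np.ndarray
    label_names: dict

    def __post_init__(self) -> None:
        nl = len(self.grid)
        if self.mu_a.shape[0] != nl or self.mu_s.shape != self.mu_a.shape:
            raise ValueError("mu_a/mu_s must be (n_wavelengths, nz, nx)")
        if np.any(self.mu_a < 0) or np.any(self.mu_s < 0):
            raise ValueError("mu_a and mu_s must be non-negative")
        if np.any(np.abs(self.g) > 1):
            raise ValueError("anisotropy g must lie in [-1, 1]")
        for lab in np.unique(self.labels):
            if int(lab) not in self.label_names:
                raise ValueError(f"label {lab} missing from label_names")

    @property
    def nz(self) -> int:
        return self.mu_a.shape[1]

    @property
    def nx(self) -> int:
        return self.mu_a.shape[2]

    def depths_cm(self) -> np.ndarray:
        """Depth of voxel centers, cm."""
        return (np.arange(self.nz) + 0.5) * self.voxel_size_mm / 10.0


@dataclass(frozen=True)
class SourceGeometry:
    """Surface illumination: x-extents (mm) of emitting segments at z = 0,
    emitting into a cone of the given half-angle around +z."""

    segments_mm: tuple
    half_angle_deg: float = 15.0

    @classmethod
    def pencil(cls, x_mm: float) -> "SourceGeometry":
        return cls(((x_mm, x_mm),), half_angle_deg=0.0)

    @classmethod
    def full_width(cls, width_mm: float, half_angle_deg: float = 0.0) -> "SourceGeometry":
        return cls(((0.0, width_mm),), half_angle_deg=half_angle_deg)

    @classmethod
    def probe(cls, center_mm: float, gap_mm: float = 8.0, width_mm: float = 12.0,
              half_angle_deg: float = 20.0) -> "SourceGeometry":
        """Two emitting segments flanking a central detector gap — an
        idealization of a fiber-flanked ultrasound probe."""
        left = (center_mm - gap_mm / 2 - width_mm, center_mm - gap_mm / 2)
        right = (center_mm + gap_mm / 2, center_mm + gap_mm / 2 + width_mm)
        return cls((left, right), half_angle_deg=half_angle_deg)


@dataclass
class FluenceVolume:
    """Per-wavelength fluence maps (n_wavelengths, nz, nx), normalized per
    launched photon; ``conservation`` holds the per-wavelength weight ledger."""

    grid: WavelengthGrid
    values: np.ndarray
    voxel_size_mm: float
    n_photons: int
    seed: int
    conservation: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("fluence must be finite and non-negative")
        if self.values.shape[0] != len(self.grid):
            raise ValueError("fluence wavelength axis must match the grid")

    @property
    def nz(self) -> int:
        return self.values.shape[1]

    def depths_cm(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.voxel_size_mm / 10.0


@dataclass
class EigenspectraSet:
    """Normalized fluence spectra {phi_i} plus their ensemble mean phi_ave.

    Every member and phi_ave equal 1 at the reference wavelength (800 nm by
    default, near the hemoglobin isosbestic point).
    """

    spectra: list
    phi_ave: Spectrum
    reference_wavelength: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.spectra) < 2:
            raise ValueError("an eigenspectra set needs at least 2 members")
        for s in list(self.spectra) + [self.phi_ave]:
            if np.any(s.amplitudes <= 0):
                raise ValueError("eigenspectra must be strictly positive")
            if abs(s.at(self.reference_wavelength) - 1.0) > 1e-9:
                raise ValueError("eigenspectra must equal 1 at the reference wavelength")

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass
class DepthModel:
    """Exponential depth-decay coefficients: optical (mu_f) and acoustic
    (mu_b), both cm^-1, summed in the compensation exponent."""

    mu_f: float
    mu_b: float = 0.0
    fit_range: tuple = (0.0, 0.0)
    fit_r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.mu_f < 0 or self.mu_b < 0:
            raise ValueError("attenuation coefficients must be non-negative")


def _child_seed(seed: int, i: int) -> int:
    return int((seed * 1000003 + 7919 * i + 1) % (2**31 - 1))


def simulate_fluence(phantom: DigitalPhantom, source: SourceGeometry,
                     n_photons: int, seed: int,
                     grid: WavelengthGrid | None = None) -> FluenceVolume:
    """Monte-Carlo fluence of ``phantom`` at every grid wavelength.

    Deterministic given (seed, n_photons): each wavelength runs on its own
    derived substream.  Fluence is the track-length estimate per launched
    photon; the returned ledger satisfies
    launched + gained - lost == absorbed + escaped to float roundoff.
    """
    grid = grid if grid is not None else phantom.grid
    if grid != phantom.grid:
        raise ConfigurationError("grid must match the phantom's wavelength grid")
    if n_photons < 1000:
        raise ConfigurationError("n_photons must be at least 1e3")
    if np.all(phantom.mu_a + phantom.mu_s == 0):
        raise DegenerateMediumError("medium has no absorption and no scattering")

    dv_cm = phantom.voxel_size_mm / 10.0
    xmax_mm = phantom.nx * phantom.voxel_size_mm
    seg = np.asarray(source.segments_mm, float)
    if np.any(seg < -1e-9) or np.any(seg > xmax_mm + 1e-9):
        raise ConfigurationError("source segments must lie on the phantom surface")
    seg_lo = np.ascontiguousarray(seg[:, 0] / 10.0)
    seg_hi = np.ascontiguousarray(seg[:, 1] / 10.0)
    cos_half = float(np.cos(np.deg2rad(source.half_angle_deg)))
    if source.half_angle_deg <= 0:
        cos_half = 1.0

    values = np.empty_like(phantom.mu_a)
    ledger = []
    g2d = np.ascontiguousarray(phantom.g, dtype=float)
    for i in range(len(grid)):
        tally, absorbed, escaped, lost, gained = run_mc(
            np.ascontiguousarray(phantom.mu_a[i], dtype=float),
            np.ascontiguousarray(phantom.mu_s[i], dtype=float),
            g2d, dv_cm, seg_lo, seg_hi, cos_half, int(n_photons),
            _child_seed(seed, i))
        values[i] = tally / (n_photons * dv_cm * dv_cm)
        ledger.append({"launched": float(n_photons), "absorbed": absorbed,
                       "escaped": escaped, "lost": lost, "gained": gained})
    return FluenceVolume(grid, values, phantom.voxel_size_mm, int(n_photons),
                         int(seed), ledger)


def absorber_sample_mask(phantom: DigitalPhantom, fluence: FluenceVolume,
                         max_per_decile: int = 20) -> np.ndarray:
    """Default eigenspectra sampling mask: absorber-labeled voxels with
    strictly positive fluence, thinned to at most ``max_per_decile`` voxels per
    depth decile (deterministic even thinning, no randomness)."""
    pos = np.all(fluence.values > 0, axis=0)
    cand = (phantom.labels > 0) & pos
    rows, cols = np.nonzero(cand)
    if rows.size == 0:
        raise DegenerateSampleError("no absorber voxels with positive fluence")
    edges = np.quantile(rows, np.linspace(0, 1, 11))
    keep = np.zeros_like(cand)
    for d in range(10):
        lo, hi = edges[d], edges[d + 1]
        sel = (rows >= lo) & (rows <= hi) if d == 9 else (rows >= lo) & (rows < hi)
        idx = np.nonzero(sel)[0]
        if idx.size > max_per_decile:
            idx = idx[np.linspace(0, idx.size - 1, max_per_decile).astype(int)]
        keep[rows[idx], cols[idx]] = True
    return keep


def _cosine_dist(a: np.ndarray) -> np.ndarray:
    n = a / np.linalg.norm(a, axis=1, keepdims=True)
    d = 1.0 - n @ n.T
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _k_medoids(d: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic k-medoids: central-point + farthest-point init, then
    alternating assignment / medoid update until stable."""
    m = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        mind = d[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(mind)))
    medoids = np.array(sorted(medoids))
    for _ in range(max_iter):
        assign = np.argmin(d[:, medoids], axis=1)
        new = medoids.copy()
        for j in range(k):
            members = np.nonzero(assign == j)[0]
            if members.size:
                new[j] = members[np.argmin(d[np.ix_(members, members)].sum(axis=1))]
        new = np.array(sorted(new))
        if np.array_equal(new, medoids):
            break
        medoids = new
    return medoids


def _reduce_spectra(samples: np.ndarray, grid: WavelengthGrid, iref: int,
                    n_keep: int, provenance: str) -> EigenspectraSet:
    if np.any(samples <= 0):
        raise DegenerateSampleError("sampled spectra must be strictly positive "
                                    "at every wavelength")
    normed = samples / samples[:, iref:iref + 1]
    if n_keep >= normed.shape[0]:
        members = normed
    else:
        idx = _k_medoids(_cosine_dist(normed), n_keep)
        members = normed[idx]
    phi_ave = members.mean(axis=0)
    phi_ave = phi_ave / phi_ave[iref]
    return EigenspectraSet(
        spectra=[Spectrum(grid, m) for m in members],
        phi_ave=Spectrum(grid, phi_ave),
        reference_wavelength=float(grid.values[iref]),
        provenance=provenance,
    )


def extract_eigenspectra(fluence: FluenceVolume, sample_mask: np.ndarray,
                         reference_wavelength: float = REFERENCE_NM,
                         n_keep: int | None = None) -> EigenspectraSet:
    """Reduce the sampled fluence spectra to ``n_keep`` representative
    normalized eigenspectra (k-medoids under cosine distance) plus phi_ave.

    Medoids guarantee every returned spectrum is a realizable fluence spectrum,
    which the convex-cone estimator's non-negativity semantics require.
    phi_ave is the ensemble mean of the member eigenspectra, renormalized to 1
    at the reference wavelength (nearest grid wavelength if 800 nm is absent).
    """
    grid = fluence.grid
    n_keep = n_keep if n_keep is not None else len(grid)
    ref = grid.nearest(reference_wavelength)
    iref = grid.index_of(ref)

    samples = fluence.values[:, sample_mask].T  # (m, n_wavelengths)
    if samples.shape[0] < n_keep:
        raise DegenerateSampleError(
            f"mask selects {samples.shape[0]} voxels, fewer than n_keep={n_keep}")
    return _reduce_spectra(
        samples, grid, iref, n_keep,
        provenance=f"k-medoids(n_keep={n_keep}) of {samples.shape[0]} sampled "
                   f"voxel spectra, normalized at {ref:g} nm")


def eigenspectra_from_structures(phantom: DigitalPhantom, fluence: FluenceVolume,
                                 reference_wavelength: float = REFERENCE_NM,
                                 n_keep: int | None = None,
                                 min_subregion_voxels: int = 6) -> EigenspectraSet:
    """Eigenspectra from sub-structure mean fluence spectra.

    Each absorber structure (tube cross-section, vessel) is split into up to
    four quadrants (by its median row, then median column) and the fluence
    spectrum is averaged over each quadrant before normalization and
    reduction.  Region averaging suppresses the per-voxel Monte-Carlo shot
    noise that would otherwise dominate the sampled spectral variation at
    desk-scale photon counts, while the quadrant split keeps the lateral and
    intra-structure (self-shading) components of the spectral variation that
    a single per-structure mean would average away — without them the sample
    family collapses to a one-dimensional depth sequence.
    """
    grid = fluence.grid
    n_keep = n_keep if n_keep is not None else len(grid)
    ref = grid.nearest(reference_wavelength)
    iref = grid.index_of(ref)
    labels = [lab for lab in np.unique(phantom.labels) if 0 < lab < 100]
    samples = []
    for lab in labels:
        rows, cols = np.nonzero(phantom.labels == lab)
        parts = [(rows, cols)]
        if rows.size >= 2 * min_subregion_voxels:
            zmed = np.median(rows)
            parts = [(rows[rows <= zmed], cols[rows <= zmed]),
                     (rows[rows > zmed], cols[rows > zmed])]
            split = []
            for r, c in parts:
                if r.size >= 2 * min_subregion_voxels:
                    xmed = np.median(c)
                    split += [(r[c <= xmed], c[c <= xmed]),
                              (r[c > xmed], c[c > xmed])]
                else:
                    split.append((r, c))
            parts = split
        for r, c in parts:
            if r.size:
                samples.append(fluence.values[:, r, c].mean(axis=1))
    samples = np.asarray(samples)
    if samples.shape[0] < 2:
        raise DegenerateSampleError("need at least 2 absorber structures")
    return _reduce_spectra(
        samples, grid, iref, min(n_keep, samples.shape[0]),
        provenance=f"k-medoids(n_keep={n_keep}) of {samples.shape[0]} "
                   f"sub-structure mean spectra, normalized at {ref:g} nm")


def fit_depth_attenuation(fluence: FluenceVolume, wavelength: float,
                          fit_range_cm: tuple) -> DepthModel:
    """Least-squares line through ln(laterally averaged fluence) vs depth.

    mu_f is the negative slope (clamped at zero for non-decaying profiles);
    fit_r2 records the goodness of the log-linear fit.
    """
    i = fluence.grid.index_of(fluence.grid.nearest(wavelength))
    depths = fluence.depths_cm()
    lo, hi = fit_range_cm
    sel = (depths >= lo) & (depths <= hi)
    if sel.sum() < 5:
        raise ConfigurationError("fit range must span at least 5 depth samples")
    prof = fluence.values[i].mean(axis=1)[sel]
    if np.any(prof <= 0):
        raise LogDomainError("laterally averaged fluence must be positive "
                             "over the fit range")
    y = np.log(prof)
    z = depths[sel]
    slope, intercept = np.polyfit(z, y, 1)
    yhat = slope * z + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DepthModel(mu_f=max(0.0, -float(slope)), mu_b=0.0,
                      fit_range=(float(lo), float(hi)), fit_r2=r2)
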