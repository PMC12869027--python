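"""Synthetic digital phantoms and the photoacoustic forward model.

Builders for the three phantom families used throughout:

* ``tube`` — a depth-varying tube phantom: ~15 sulfate-filled tube
  cross-sections (NiSO4/CuSO4, the oxy/deoxy surrogates) rendered as disks at
  staggered depths in an Intralipid-like scattering bath (mu_s' ~ 1 cm^-1).
  The nickel saturation %sNi and total sulfate TSf are the phantom analogs of
  %sO2 and THb:

      %sNi = (C_Ni/14.28) / (C_Ni/14.28 + C_Cu) * 100
      TSf  =  C_Ni/14.28 + C_Cu

  where 14.28 accounts for the stronger specific absorption of CuSO4.

* ``sphere`` — an ovary-mimicking agar sphere (~2 cm diameter) threaded by
  four tubes (two at %sNi = 40%, two at 75%) with two more tubes outside.

* ``clinical`` — a layered medium (muscle, peritoneal fluid, ovary) with
  embedded hemoglobin-filled vessels, used to generate compensating spectra
  for clinical-like wavelength sets.

The forward model is p0 = Gamma * phi * mu_a per voxel, optionally damped by
an acoustic depth factor exp(-mu_b z) (so depth compensation has a measurement
effect to undo) plus seeded additive white Gaussian noise at a target SNR
relative to the RMS absorber-voxel signal.

Layer/tissue optical constants are package defaults chosen to be plausible for
NIR soft tissue; they are configuration, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .depthcomp import PressureMap
from .errors import ConfigurationError
from .photon_sim import DigitalPhantom, FluenceVolume
from .spectra import ExtinctionTable, WavelengthGrid, build_absorption

__all__ = ["PhantomSpec", "GroundTruth", "sni_from_concentrations",
           "tsf_from_concentrations", "concentrations_for_sni",
           "build_phantom", "forward_pressure", "SNI_SCALE"]

#: CuSO4/NiSO4 specific-absorption ratio at 800 nm used in the %sNi definition
SNI_SCALE = 14.28

# bath / tissue-fluid background absorption (cm^-1), linear interpolation
# between knots: a smooth water-dominated trend rising with wavelength over
# the NIR imaging band, which makes the fluence at depth decrease with
# wavelength (the spectral-coloring direction the compensators assume)
_WATER_NM = np.array([650, 700, 730, 750, 780, 800, 830, 850, 900, 950], float)
_WATER_MUA = np.array([0.004, 0.007, 0.014, 0.017, 0.022, 0.028, 0.036,
                       0.042, 0.06, 0.17])

# per-tissue NIR absorption knots (cm^-1) and reduced scattering at 800 nm
# with a scattering power-law exponent: mus'(lambda) = musp800 * (lambda/800)^-b
_TISSUE_MUA = {
    "muscle": (np.array([650, 700, 750, 800, 850, 900, 950], float),
               np.array([0.35, 0.22, 0.16, 0.14, 0.15, 0.17, 0.30])),
    "peritoneal_fluid": (_WATER_NM, _WATER_MUA),
    "ovary": (np.array([650, 700, 750, 800, 850, 900, 950], float),
              np.array([0.20, 0.12, 0.085, 0.07, 0.075, 0.09, 0.15])),
}
_TISSUE_MUSP = {"muscle": (8.0, 0.6), "peritoneal_fluid": (0.1, 0.0),
                "ovary": (9.0, 0.7), "agar_sphere": (2.5, 0.5)}

#: Intralipid-like reduced scattering power-law exponent
_INTRALIPID_B = 2.4
_DEFAULT_G = 0.9


def sni_from_concentrations(c_ni: float, c_cu: float) -> float:
    """%sNi; NaN when both concentrations are zero."""
    if c_ni < 0 or c_cu < 0:
        raise ValueError("concentrations must be non-negative")
    num = c_ni / SNI_SCALE
    tot = num + c_cu
    if tot <= 0:
        return float("nan")
    return min(100.0, max(0.0, 100.0 * (num / tot)))


def tsf_from_concentrations(c_ni: float, c_cu: float) -> float:
    if c_ni < 0 or c_cu < 0:
        raise ValueError("concentrations must be non-negative")
    return c_ni / SNI_SCALE + c_cu


def concentrations_for_sni(target_sni_pct: float, tsf: float) -> tuple:
    """Algebraic inverse of the %sNi/TSf definitions: the (C_Ni, C_Cu) pair
    realizing a target saturation at a given total sulfate."""
    if not 0 <= target_sni_pct <= 100:
        raise ValueError("target %sNi must lie in [0, 100]")
    if tsf <= 0:
        raise ValueError("tsf must be positive")
    f = target_sni_pct / 100.0
    return SNI_SCALE * tsf * f, tsf * (1.0 - f)


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic phantom.

    Geometry in mm; concentrations per the extinction-table units (g/L for
    sulfates, molar for hemoglobin).  ``structures`` is a list of dicts, one
    per absorbing structure, produced by the kind-specific constructors.
    """

    kind: str
    nx: int = 140
    nz: int = 140
    voxel_size_mm: float = 0.25
    structures: list = field(default_factory=list)
    layers: list = field(default_factory=list)
    background_musp_800: float = 1.0
    background_g: float = _DEFAULT_G
    noise_snr_db: float | None = 30.0
    seed: int = 0

    @property
    def width_mm(self) -> float:
        return self.nx * self.voxel_size_mm

    @property
    def depth_mm(self) -> float:
        return self.nz * self.voxel_size_mm

    @classmethod
    def tube(cls, sni_pct=60.0, tsf: float = 0.1, n_tubes: int = 15,
             tube_diameter_mm: float = 1.5, depth_range_mm=(6.0, 30.0),
             lateral_span_mm: float = 14.0,
             nx: int = 140, nz: int = 140, voxel_size_mm: float = 0.25,
             noise_snr_db: float | None = 30.0, seed: int = 0) -> "PhantomSpec":
        """Depth-varying tube phantom: ~15 cross-sections of one continuous
        tube (uniform TSf) threaded through a point grid, staggered in depth
        and zig-zagging within a ``lateral_span_mm``-wide central band (so
        deeper cross-sections are partially shadowed by shallower ones, as in
        a physical threaded-panel phantom).  ``sni_pct`` may be a scalar (all
        tubes) or a per-tube sequence."""
        sni = np.broadcast_to(np.asarray(sni_pct, float), (n_tubes,))
        depths = np.linspace(depth_range_mm[0], depth_range_mm[1], n_tubes)
        width = nx * voxel_size_mm
        lateral = (width - lateral_span_mm) / 2.0 + \
            lateral_span_mm * ((np.arange(n_tubes) * 7) % 11) / 10.0
        structures = []
        for i in range(n_tubes):
            c_ni, c_cu = concentrations_for_sni(float(sni[i]), tsf)
            structures.append({
                "name": f"tube_{i + 1}", "x_mm": float(lateral[i]),
                "z_mm": float(depths[i]), "diameter_mm": tube_diameter_mm,
                "composition": {"NiSO4": c_ni, "CuSO4": c_cu},
                "true_pct": float(sni[i]), "true_total": tsf,
            })
        return cls(kind="tube", nx=nx, nz=nz, voxel_size_mm=voxel_size_mm,
                   structures=structures, noise_snr_db=noise_snr_db, seed=seed)

    @classmethod
    def sphere(cls, sphere_diameter_mm: float = 20.0, tsf: float = 0.4,
               tube_diameter_mm: float = 1.5, nx: int = 160, nz: int = 160,
               voxel_size_mm: float = 0.25, noise_snr_db: float | None = 30.0,
               seed: int = 0) -> "PhantomSpec":
        """Ovary-mimicking agar sphere with four inner tubes (2 x 40%,
        2 x 75% %sNi) and two outer tubes (40% and 75%)."""
        cx = nx * voxel_size_mm / 2.0
        cz = 18.0
        r = sphere_diameter_mm / 2.0
        inner = [(cx - 5, cz - 4, 40.0), (cx + 5, cz - 4, 75.0),
                 (cx - 5, cz + 4, 40.0), (cx + 5, cz + 4, 75.0)]
        outer = [(cx - r - 6, cz - 6, 40.0), (cx + r + 6, cz + 6, 75.0)]
        structures = []
        for i, (x, z, s) in enumerate(inner + outer):
            c_ni, c_cu = concentrations_for_sni(s, tsf)
            structures.append({
                "name": f"tube_{i + 1}", "x_mm": x, "z_mm": z,
                "diameter_mm": tube_diameter_mm,
                "composition": {"NiSO4": c_ni, "CuSO4": c_cu},
                "true_pct": s, "true_total": tsf,
            })
        layers = [{"name": "agar_sphere", "shape": "disk", "x_mm": cx,
                   "z_mm": cz, "diameter_mm": sphere_diameter_mm}]
        return cls(kind="sphere", nx=nx, nz=nz, voxel_size_mm=voxel_size_mm,
                   structures=structures, layers=layers,
                   noise_snr_db=noise_snr_db, seed=seed)

    @classmethod
    def clinical(cls, muscle_mm: float = 5.0, fluid_mm: float = 10.0,
                 ovary_diameter_mm: float = 20.0, vessels=None,
                 thb_molar: float = 2.3e-3, nx: int = 160, nz: int = 160,
                 voxel_size_mm: float = 0.25, noise_snr_db: float | None = 30.0,
                 seed: int = 0) -> "PhantomSpec":
        """Layered transvaginal-imaging-like medium: muscle, peritoneal fluid,
        and an ovary disk with embedded blood vessels.

        ``vessels``: list of (x_mm, z_mm, diameter_mm, so2_pct); default two
        vessels inside the ovary at 75% and 60% saturation.
        """
        width = nx * voxel_size_mm
        cx = width / 2.0
        ovary_z = muscle_mm + fluid_mm + ovary_diameter_mm / 2.0
        if vessels is None:
            vessels = [(cx - 4.0, ovary_z - 3.0, 2.0, 75.0),
                       (cx + 4.0, ovary_z + 3.0, 1.5, 60.0)]
        structures = []
        for i, (x, z, d, s) in enumerate(vessels):
            structures.append({
                "name": f"vessel_{i + 1}", "x_mm": x, "z_mm": z,
                "diameter_mm": d,
                "composition": {"HbO2": thb_molar * s / 100.0,
                                "Hb": thb_molar * (1.0 - s / 100.0)},
                "true_pct": s, "true_total": thb_molar,
            })
        layers = [
            {"name": "muscle", "shape": "slab", "z_from_mm": 0.0, "z_to_mm": muscle_mm},
            {"name": "peritoneal_fluid", "shape": "slab", "z_from_mm": muscle_mm,
             "z_to_mm": muscle_mm + fluid_mm},
            {"name": "ovary", "shape": "disk", "x_mm": cx, "z_mm": ovary_z,
             "diameter_mm": ovary_diameter_mm},
        ]
        return cls(kind="clinical", nx=nx, nz=nz, voxel_size_mm=voxel_size_mm,
                   structures=structures, layers=layers,
                   noise_snr_db=noise_snr_db, seed=seed)


@dataclass
class GroundTruth:
    """Per-structure true percentages/totals plus the structure label image."""

    table: pd.DataFrame  # structure_id, name, true_pct, true_total
    label_image: np.ndarray

    def __post_init__(self) -> None:
        pct = self.table["true_pct"].to_numpy(float)
        if np.any((pct < 0) | (pct > 100)):
            raise ValueError("true percentages must lie in [0, 100]")


def _water_mua(grid: WavelengthGrid) -> np.ndarray:
    return np.interp(grid.values, _WATER_NM, _WATER_MUA)


def _tissue_mua(name: str, grid: WavelengthGrid) -> np.ndarray:
    nm, mua = _TISSUE_MUA[name]
    return np.interp(grid.values, nm, mua)


def _musp(musp800: float, b: float, grid: WavelengthGrid) -> np.ndarray:
    return musp800 * (grid.values / 800.0) ** (-b)


def _disk_mask(nx, nz, voxel, x_mm, z_mm, diameter_mm) -> np.ndarray:
    xs = (np.arange(nx) + 0.5) * voxel
    zs = (np.arange(nz) + 0.5) * voxel
    dx = xs[None, :] - x_mm
    dz = zs[:, None] - z_mm
    return dx * dx + dz * dz <= (diameter_mm / 2.0) ** 2


def build_phantom(spec: PhantomSpec, table: ExtinctionTable,
                  grid: WavelengthGrid) -> tuple:
    """Voxelize a :class:`PhantomSpec` into optical-property maps.

    Background: Intralipid-like scattering (mu_s = mu_s'/(1-g), g = 0.9,
    power-law wavelength dependence) over water-like absorption.  Absorber
    voxels get mu_a from the extinction table and the structure composition;
    tube/vessel interiors are treated as non-scattering solutions.
    """
    nl, nz, nx = len(grid), spec.nz, spec.nx
    voxel = spec.voxel_size_mm
    mu_a = np.tile(_water_mua(grid)[:, None, None], (1, nz, nx))
    musp_bg = _musp(spec.background_musp_800, _INTRALIPID_B, grid)
    g = np.full((nz, nx), spec.background_g)
    mu_s = np.tile((musp_bg / (1.0 - spec.background_g))[:, None, None],
                   (1, nz, nx))
    labels = np.zeros((nz, nx), dtype=np.int32)
    label_names = {0: "background"}

    depths = (np.arange(nz) + 0.5) * voxel
    layer_base = 100
    for j, layer in enumerate(spec.layers):
        if layer["shape"] == "slab":
            m = (depths >= layer["z_from_mm"]) & (depths < layer["z_to_mm"])
            mask = np.zeros((nz, nx), bool)
            mask[m, :] = True
        else:
            mask = _disk_mask(nx, nz, voxel, layer["x_mm"], layer["z_mm"],
                              layer["diameter_mm"])
        if not mask.any():
            raise ConfigurationError(f"layer {layer['name']} lies outside the grid")
        name = layer["name"]
        if name in _TISSUE_MUA:
            mu_a[:, mask] = _tissue_mua(name, grid)[:, None]
        musp800, b = _TISSUE_MUSP.get(name, (spec.background_musp_800, _INTRALIPID_B))
        mu_s[:, mask] = (_musp(musp800, b, grid) / (1.0 - _DEFAULT_G))[:, None]
        lab = layer_base + j
        labels[mask] = lab
        label_names[lab] = name

    rows = []
    for i, s in enumerate(spec.structures):
        mask = _disk_mask(nx, nz, voxel, s["x_mm"], s["z_mm"], s["diameter_mm"])
        if not mask.any():
            raise ConfigurationError(f"structure {s['name']} lies outside the grid")
        spectrum = build_absorption(s["composition"], table, grid)
        mu_a[:, mask] = spectrum.amplitudes[:, None]
        mu_s[:, mask] = 0.0  # absorbing solution, no scattering
        lab = i + 1
        labels[mask] = lab
        label_names[lab] = s["name"]
        rows.append({"structure_id": lab, "name": s["name"],
                     "true_pct": s["true_pct"], "true_total": s["true_total"]})

    phantom = DigitalPhantom(grid, voxel, mu_a, mu_s, g, labels, label_names)
    truth = GroundTruth(pd.DataFrame(rows, columns=["structure_id", "name",
                                                    "true_pct", "true_total"]),
                        labels.copy())
    return phantom, truth


def forward_pressure(phantom: DigitalPhantom, fluence: FluenceVolume,
                     gamma=1.0, noise_snr_db: float | None = None,
                     seed: int = 0, mu_b: float = 0.0) -> PressureMap:
    """p0 = Gamma * phi * mu_a voxelwise, optionally damped by the acoustic
    depth factor exp(-mu_b z) and degraded by seeded white Gaussian noise
    scaled to ``noise_snr_db`` relative to the RMS absorber-voxel signal."""
    if fluence.values.shape != phantom.mu_a.shape:
        raise ConfigurationError("fluence and phantom shapes must match")
    gamma = np.asarray(gamma, float)
    p = gamma * fluence.values * phantom.mu_a
    z = phantom.depths_cm()
    if mu_b > 0:
        p = p * np.exp(-mu_b * z)[None, :, None]
    if noise_snr_db is not None and np.isfinite(noise_snr_db):
        absorber = phantom.labels > 0
        rms = np.sqrt(np.mean(p[:, absorber] ** 2))
        sigma = rms * 10.0 ** (-noise_snr_db / 20.0)
        rng = np.random.default_rng(seed)
        p = p + rng.normal(0.0, sigma, size=p.shape)
    return PressureMap(phantom.grid, p, phantom.voxel_size_mm,
                       z0_cm=phantom.voxel_size_mm / 20.0)
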