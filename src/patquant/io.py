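"""HDF5 and CSV round-tripping for the in-memory containers.

HDF5 layout: datasets ``/fluence`` or ``/pressure`` (wavelength x z x x),
``/mu_a``, ``/mu_s``, ``/g``, ``/labels``, ``/so2``, ``/thb``; attributes
``wavelengths_nm``, ``voxel_size_mm`` / ``pixel_size_mm``, ``z0_cm``,
``seed``, ``n_photons``, ``method``.  Undefined %sO2 pixels are NaN.
Eigenspectra, ground truth, cluster tables, compensator reports and ROC
points travel as CSV.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .depthcomp import PressureMap, QuantMaps
from .photon_sim import DigitalPhantom, EigenspectraSet, FluenceVolume
from .phantom_synth import GroundTruth
from .spectra import Spectrum, WavelengthGrid


def write_phantom_h5(path, phantom: DigitalPhantom,
                     truth: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mu_a", data=phantom.mu_a)
        f.create_dataset("mu_s", data=phantom.mu_s)
        f.create_dataset("g", data=phantom.g)
        f.create_dataset("labels", data=phantom.labels)
        f.attrs["wavelengths_nm"] = phantom.grid.values
        f.attrs["voxel_size_mm"] = phantom.voxel_size_mm
        f.attrs["label_names"] = json.dumps(
            {str(k): v for k, v in phantom.label_names.items()})
        if truth is not None:
            f.attrs["ground_truth"] = truth.table.to_json()


def read_phantom_h5(path) -> DigitalPhantom:
    with h5py.File(path, "r") as f:
        names = {int(k): v for k, v in json.loads(f.attrs["label_names"]).items()}
        return DigitalPhantom(
            WavelengthGrid(f.attrs["wavelengths_nm"][:]),
            float(f.attrs["voxel_size_mm"]), f["mu_a"][:], f["mu_s"][:],
            f["g"][:], f["labels"][:], names)


def write_fluence_h5(path, fl: FluenceVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("fluence", data=fl.values)
        f.attrs["wavelengths_nm"] = fl.grid.values
        f.attrs["voxel_size_mm"] = fl.voxel_size_mm
        f.attrs["seed"] = fl.seed
        f.attrs["n_photons"] = fl.n_photons
        f.attrs["conservation"] = json.dumps(fl.conservation)


def read_fluence_h5(path) -> FluenceVolume:
    with h5py.File(path, "r") as f:
        return FluenceVolume(
            WavelengthGrid(f.attrs["wavelengths_nm"][:]), f["fluence"][:],
            float(f.attrs["voxel_size_mm"]), int(f.attrs["n_photons"]),
            int(f.attrs["seed"]), json.loads(f.attrs["conservation"]))


def write_pressure_h5(path, m: PressureMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("pressure", data=m.images)
        if m.mask is not None:
            f.create_dataset("mask", data=m.mask)
        f.attrs["wavelengths_nm"] = m.grid.values
        f.attrs["pixel_size_mm"] = m.pixel_size_mm
        f.attrs["z0_cm"] = m.z0_cm


def read_pressure_h5(path) -> PressureMap:
    with h5py.File(path, "r") as f:
        mask = f["mask"][:].astype(bool) if "mask" in f else None
        return PressureMap(WavelengthGrid(f.attrs["wavelengths_nm"][:]),
                           f["pressure"][:], float(f.attrs["pixel_size_mm"]),
                           float(f.attrs["z0_cm"]), mask)


def write_quantmaps_h5(path, q: QuantMaps) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("so2", data=q.so2_map)
        f.create_dataset("thb", data=q.thb_map)
        f.attrs["method"] = q.method
        if q.grid is not None:
            f.attrs["wavelengths_nm"] = q.grid.values
        f.attrs["pixel_size_mm"] = q.pixel_size_mm
        f.attrs["z0_cm"] = q.z0_cm
        if q.depth_model is not None:
            f.attrs["mu_f"] = q.depth_model.mu_f
            f.attrs["mu_b"] = q.depth_model.mu_b


def read_quantmaps_h5(path) -> QuantMaps:
    from .photon_sim import DepthModel
    with h5py.File(path, "r") as f:
        model = None
        if "mu_f" in f.attrs:
            model = DepthModel(float(f.attrs["mu_f"]), float(f.attrs["mu_b"]))
        grid = WavelengthGrid(f.attrs["wavelengths_nm"][:]) \
            if "wavelengths_nm" in f.attrs else None
        return QuantMaps(f["so2"][:], f["thb"][:], str(f.attrs["method"]),
                         model, grid, float(f.attrs["pixel_size_mm"]),
                         float(f.attrs["z0_cm"]))


def write_eigenspectra_csv(path, eig: EigenspectraSet) -> None:
    data = {"wavelength_nm": eig.phi_ave.grid.values}
    for i, s in enumerate(eig.spectra):
        data[f"phi_{i + 1}"] = s.amplitudes
    data["phi_ave"] = eig.phi_ave.amplitudes
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        fh.write(f"# reference_wavelength_nm={eig.reference_wavelength:g}\n")
        fh.write(f"# provenance={eig.provenance}\n")
        df.to_csv(fh, index=False)


def read_eigenspectra_csv(path) -> EigenspectraSet:
    ref, prov = 800.0, ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("# reference_wavelength_nm="):
                ref = float(line.split("=", 1)[1])
            elif line.startswith("# provenance="):
                prov = line.split("=", 1)[1].strip()
    df = pd.read_csv(path, comment="#")
    grid = WavelengthGrid(df["wavelength_nm"].to_numpy())
    members = [Spectrum(grid, df[c].to_numpy())
               for c in df.columns if c.startswith("phi_") and c != "phi_ave"]
    return EigenspectraSet(members, Spectrum(grid, df["phi_ave"].to_numpy()),
                           ref, prov)


def write_ground_truth_csv(path, truth: GroundTruth) -> None:
    truth.table.to_csv(path, index=False)


def read_ground_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
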