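"""HDF5 containers and delimited-text readers for model objects.

One hierarchical binary container (HDF5) holds named arrays: cross-spectrum
sets (frequencies, real/imaginary parts, trial count, level tag, units),
synthetic scenes (structure, lead field, fields, geometry, parcels) and fit
results.  Tabular exports are plain delimited text with header rows.
Delay matrices declare their unit ("s" or "ms"); milliseconds are converted
on read.  Cross-spectra are re-symmetrized on read and rejected if the
Hermitian drift exceeds tolerance.
"""

from __future__ import annotations

import warnings

import h5py
import numpy as np
import pandas as pd

from .network import LeadField, SpectrumSet, StructuralPrior, StructuralWeights
from .scenes import SyntheticScene, TrialEnsemble
from .spectral import ComponentField, FrequencyGrid

__all__ = [
    "write_cross_spectrum",
    "read_cross_spectrum",
    "write_scene",
    "read_scene",
    "read_structure_tables",
    "field_table",
]

HERMITIAN_TOL = 1e-6


def write_cross_spectrum(path, sset: SpectrumSet, units: str = "power/Hz") -> None:
    """Lossless container write of a spectrum stack."""
    with h5py.File(path, "w") as f:
        g = f.create_group("cross_spectrum")
        g.create_dataset("frequencies_hz", data=sset.grid.omega)
        g.create_dataset("real", data=sset.spectra.real)
        g.create_dataset("imag", data=sset.spectra.imag)
        g.attrs["level"] = sset.level
        g.attrs["m"] = sset.m
        g.attrs["units"] = units
        g.attrs["nonuniform"] = bool(sset.grid.nonuniform)


def read_cross_spectrum(path) -> SpectrumSet:
    with h5py.File(path, "r") as f:
        if "cross_spectrum" not in f:
            raise ValueError("container missing 'cross_spectrum' group")
        g = f["cross_spectrum"]
        if "frequencies_hz" not in g:
            raise ValueError("container missing frequency vector")
        if "units" not in g.attrs:
            raise ValueError("container missing required units tag")
        omega = g["frequencies_hz"][...]
        S = g["real"][...] + 1j * g["imag"][...]
        drift = np.max(np.abs(S - S.conj().transpose(0, 2, 1)))
        scale = max(np.max(np.abs(S)), 1.0)
        if drift > HERMITIAN_TOL * scale:
            raise ValueError(f"cross-spectra not Hermitian (drift {drift:.3g})")
        if drift > 0:
            warnings.warn("symmetrizing cross-spectra with small Hermitian drift")
        grid = FrequencyGrid(omega, nonuniform=bool(g.attrs.get("nonuniform", False)))
        return SpectrumSet(grid, S, level=str(g.attrs.get("level", "sensor")),
                           m=int(g.attrs.get("m", 1)))


def write_scene(path, scene: SyntheticScene) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("scene")
        g.create_dataset("Cbar", data=scene.prior.Cbar)
        g.create_dataset("Dbar_s", data=scene.prior.Dbar)
        g.attrs["w_C"] = scene.weights.w_C
        g.attrs["w_D"] = scene.weights.w_D
        g.create_dataset("lead_field", data=scene.lead.K)
        g.attrs["sigma_noise2"] = scene.lead.sigma_noise2
        g.create_dataset("coords_mm", data=scene.coords)
        g.create_dataset("sensor_coords_mm", data=scene.sensor_coords)
        g.create_dataset("parcels", data=scene.parcels)
        g.create_dataset("gradient", data=scene.gradient)
        g.attrs["seed"] = scene.seed
        fld = f.create_group("field")
        for name in ("A_xi", "B_xi", "E_xi", "A_alpha", "B_alpha",
                     "E_alpha", "F_alpha"):
            fld.create_dataset(name, data=getattr(scene.field, name))
        fld.attrs["alpha_band"] = scene.field.alpha_band


def read_scene(path) -> SyntheticScene:
    with h5py.File(path, "r") as f:
        g = f["scene"]
        fld = f["field"]
        field = ComponentField(
            *[fld[name][...] for name in
              ("A_xi", "B_xi", "E_xi", "A_alpha", "B_alpha", "E_alpha",
               "F_alpha")],
            alpha_band=tuple(fld.attrs["alpha_band"]),
        )
        return SyntheticScene(
            prior=StructuralPrior(g["Cbar"][...], g["Dbar_s"][...]),
            weights=StructuralWeights(float(g.attrs["w_C"]),
                                      float(g.attrs["w_D"])),
            lead=LeadField(g["lead_field"][...],
                           float(g.attrs["sigma_noise2"])),
            field=field,
            coords=g["coords_mm"][...],
            sensor_coords=g["sensor_coords_mm"][...],
            parcels=g["parcels"][...],
            gradient=g["gradient"][...],
            seed=int(g.attrs["seed"]),
        )


def read_structure_tables(
    connectome_path,
    delay_path,
    delay_unit: str = "ms",
) -> StructuralPrior:
    """Read strength and delay matrices from delimited text (header row,
    vertex-indexed).  Enforces zero diagonals (warning), rejects negative
    strengths, prunes delays on absent connections (warning)."""
    C = pd.read_csv(connectome_path, index_col=0).to_numpy(dtype=float)
    D = pd.read_csv(delay_path, index_col=0).to_numpy(dtype=float)
    if C.shape != D.shape:
        raise ValueError("connectome and delay tables disagree in size")
    if np.any(C < 0):
        raise ValueError("negative connection strengths")
    if delay_unit == "ms":
        D = D / 1000.0
    elif delay_unit != "s":
        raise ValueError("delay_unit must be 'ms' or 's'")
    if np.any(np.diag(C) != 0) or np.any(np.diag(D) != 0):
        warnings.warn("nonzero structural diagonal zeroed")
        np.fill_diagonal(C, 0.0)
        np.fill_diagonal(D, 0.0)
    orphan = (D > 0) & (C == 0)
    if np.any(orphan):
        warnings.warn(f"pruning {orphan.sum()} delays without connections")
        D = np.where(orphan, 0.0, D)
    return StructuralPrior(C, D)


def field_table(field: ComponentField, extra: dict | None = None) -> pd.DataFrame:
    """Long-format parameter export: one row per (vertex, component)."""
    rows = []
    for i in range(field.n_v):
        rows.append({"vertex": i, "component": "xi",
                     "A": field.A_xi[i], "B": field.B_xi[i],
                     "E": field.E_xi[i], "F": 0.0,
                     "active": bool(field.active_xi[i])})
        rows.append({"vertex": i, "component": "alpha",
                     "A": field.A_alpha[i], "B": field.B_alpha[i],
                     "E": field.E_alpha[i], "F": field.F_alpha[i],
                     "active": bool(field.active_alpha[i])})
    df = pd.DataFrame(rows)
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df
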