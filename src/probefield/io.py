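"""File formats: probe/domain specs (YAML), grids and fields (legacy VTK
structured points), tabular outputs (CSV), recordings (HDF5 or CSV), and
JSON sidecars with provenance."""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .geometry import ConductivityGrid, Face, ProbeSpec, Role, SimulationDomain, SiteSpec
from .recording import Recording


# ---------------------------------------------------------------- probe spec

def probe_to_dict(spec: ProbeSpec) -> dict:
    return {
        "shaft_length_mm": spec.shaft_length_mm,
        "shaft_width_um": spec.shaft_width_um,
        "shaft_thickness_um": spec.shaft_thickness_um,
        "tip_taper_um": spec.tip_taper_um,
        "sites": [
            {
                "id": s.id,
                "role": s.role.value,
                "face": s.face.value,
                "z_offset_um": s.z_offset,
                "diameter_um": s.diameter,
                "lateral_offset_um": s.lateral_offset,
            }
            for s in spec.sites
        ],
    }


def probe_from_dict(d: dict) -> ProbeSpec:
    sites = tuple(
        SiteSpec(
            id=s["id"],
            role=Role(s["role"]),
            face=Face(s["face"]),
            z_offset=float(s["z_offset_um"]),
            diameter=float(s["diameter_um"]),
            lateral_offset=float(s.get("lateral_offset_um", 0.0)),
        )
        for s in d.get("sites", [])
    )
    return ProbeSpec(
        shaft_length_mm=float(d.get("shaft_length_mm", 9.0)),
        shaft_width_um=float(d.get("shaft_width_um", 400.0)),
        shaft_thickness_um=float(d.get("shaft_thickness_um", 200.0)),
        tip_taper_um=float(d.get("tip_taper_um", 0.0)),
        sites=sites,
    )


def save_probe(spec: ProbeSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(probe_to_dict(spec), sort_keys=False))


def load_probe(path) -> ProbeSpec:
    if str(path) == "default":
        return load_default_probe()
    return probe_from_dict(yaml.safe_load(Path(path).read_text()))


def load_default_probe() -> ProbeSpec:
    ref = resources.files("probefield.data").joinpath("default_probe.yaml")
    return probe_from_dict(yaml.safe_load(ref.read_text()))


def domain_from_dict(d: dict) -> SimulationDomain:
    kwargs = {}
    for key in (
        "extents_mm", "voxel_size_um", "probe_tip_mm",
        "sigma_tissue", "sigma_substrate", "sigma_metal", "allow_clip",
    ):
        if key in d:
            v = d[key]
            kwargs[key] = tuple(v) if isinstance(v, (list, tuple)) else v
    return SimulationDomain(**kwargs)


# ------------------------------------------------------------------ VTK/CSV

def write_vtk_structured_points(
    path, arrays: dict[str, np.ndarray], spacing_mm: float, origin_mm=(0.0, 0.0, 0.0)
) -> None:
    """Legacy-ASCII VTK structured-points file with one or more point arrays.

    Arrays share one (nx, ny, nz) shape; written x-fastest as VTK expects.
    NaN is preserved (ParaView treats it as blanked).
    """
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError("all arrays must share one shape")
    nx, ny, nz = shapes.pop()
    lines = [
        "# vtk DataFile Version 3.0",
        "probefield structured points",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {origin_mm[0]:.9g} {origin_mm[1]:.9g} {origin_mm[2]:.9g}",
        f"SPACING {spacing_mm:.9g} {spacing_mm:.9g} {spacing_mm:.9g}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    chunks = [("\n".join(lines))]
    for name, arr in arrays.items():
        dtype = "int" if np.issubdtype(arr.dtype, np.integer) else "float"
        chunks.append(f"\nSCALARS {name} {dtype} 1\nLOOKUP_TABLE default\n")
        flat = arr.ravel(order="F")
        fmt = "%d" if dtype == "int" else "%.7g"
        chunks.append("\n".join(fmt % v for v in flat))
    Path(path).write_text("".join(chunks) + "\n")


def write_grid_vtk(grid: ConductivityGrid, path, sidecar: bool = True) -> None:
    sigma = np.where(grid.material == 0, grid.sigma_tissue, 0.0)
    write_vtk_structured_points(
        path,
        {"material": grid.material.astype(np.int32), "sigma_S_per_m": sigma},
        grid.spacing_mm,
    )
    if sidecar:
        meta = dict(grid.meta)
        meta["spec_hash"] = sha256_of_obj(meta)
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def profile_to_frame(prof) -> pd.DataFrame:
    return pd.DataFrame(
        {"coordinate_mm": prof.coordinates_mm, "V": prof.values_V}
    )


def curve_to_frame(curve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "current_uA": curve.currents_uA,
            "vta_mm3": curve.volumes_mm3,
            "mode": curve.mode,
        }
    )


# --------------------------------------------------------------- recordings

def save_recording_h5(rec: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data_uV", data=rec.data)
        d.attrs["sampling_rate_hz"] = rec.sampling_rate
        d.attrs["labels"] = json.dumps(rec.labels)


def load_recording_h5(path) -> Recording:
    with h5py.File(path, "r") as f:
        d = f["data_uV"]
        return Recording(
            float(d.attrs["sampling_rate_hz"]),
            d[...],
            json.loads(d.attrs["labels"]),
        )


def save_recording_csv(rec: Recording, path) -> None:
    t = np.arange(rec.n_samples) / rec.sampling_rate
    df = pd.DataFrame({"time_s": t})
    for lab, x in zip(rec.labels, rec.data):
        df[lab] = x
    df.to_csv(path, index=False)


def load_recording_csv(path) -> Recording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    labels = [c for c in df.columns if c != "time_s"]
    return Recording(float(round(fs)), df[labels].to_numpy().T, labels)


def sha256_of_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()
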