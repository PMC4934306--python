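"""End-to-end run orchestration: voxelize -> solve -> profiles -> VTA.

A single YAML/JSON config drives a run; every requested current/mode pair
produces a VTA entry, the base field of each mode is exported, and a
manifest captures config hashes, solver residuals and all volumes so a run
is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .geometry import Face, ProbeSpec, SimulationDomain, site_positions, voxelize
from .solver import (
    StimMode,
    StimulusConfig,
    profile,
    scale_solution,
    solve_potential,
    surface_potential,
)
from .vta import compute_vta

log = logging.getLogger("probefield")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    probe: ProbeSpec
    domain: SimulationDomain
    site_id: str = "s0"
    currents_uA: tuple[float, ...] = (-100.0, -350.0)
    modes: tuple[str, ...] = ("single_side", "double_side")
    interpretation: str = "per_site"
    threshold_V: float = -0.5
    tol: float = 1e-8
    profile_axes: tuple[str, ...] = ("X", "Y", "Z")
    output_dir: Path = Path("probefield_run")
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file {path} does not exist")
        d = yaml.safe_load(path.read_text()) or {}
        return cls.from_dict(d, base_dir=path.parent)

    @classmethod
    def from_dict(cls, d: dict, base_dir: Path = Path(".")) -> "RunConfig":
        probe_ref = d.get("probe", "default")
        if probe_ref != "default":
            probe_path = (base_dir / probe_ref).expanduser()
            if not probe_path.exists():
                raise ConfigError(f"probe spec file {probe_path} does not exist")
            probe = pio.load_probe(probe_path)
        else:
            probe = pio.load_default_probe()
        domain = pio.domain_from_dict(d.get("domain", {}))
        stim = d.get("stimulus", {})
        solver = d.get("solver", {})
        return cls(
            probe=probe,
            domain=domain,
            site_id=str(stim.get("site", "s0")),
            currents_uA=tuple(stim.get("currents_uA", (-100.0, -350.0))),
            modes=tuple(stim.get("modes", ("single_side", "double_side"))),
            interpretation=str(stim.get("interpretation", "per_site")),
            threshold_V=float(d.get("vta", {}).get("threshold_V", -0.5)),
            tol=float(solver.get("tol", 1e-8)),
            profile_axes=tuple(d.get("profiles", {}).get("axes", ("X", "Y", "Z"))),
            output_dir=Path(d.get("output_dir", "probefield_run")),
            raw=d,
        )


def run_pipeline(config: RunConfig, write_fields: bool = True) -> dict:
    """Execute the full simulation chain; returns (and writes) the manifest.

    One direct solve per mode at the smallest-magnitude current; the other
    currents follow by linear rescaling before thresholding.  Any stage
    failure aborts with a stage-attributed error.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        # hash the scientific configuration only (paths excluded)
        "config_hash": pio.sha256_of_obj(_config_fingerprint(config)),
        "stages": {},
        "fields": [],
        "vta": [],
    }
    currents = sorted(config.currents_uA, key=abs)
    if not currents:
        raise ConfigError("no stimulus currents requested")

    t0 = time.time()
    try:
        grid = voxelize(config.probe, config.domain)
    except Exception as e:
        raise RuntimeError(f"stage voxelize failed: {e}") from e
    manifest["stages"]["voxelize"] = {
        "dims": list(grid.dims),
        "voxel_size_um": grid.spacing_um,
        "seconds": round(time.time() - t0, 3),
    }
    log.info("voxelize: dims=%s (%.1fs)", grid.dims, time.time() - t0)

    site = config.probe.find_site(config.site_id, Face.FRONT)
    tip = np.asarray(config.domain.probe_tip_mm)
    site_center_mm = tip + np.array([site.lateral_offset, 0.0, site.z_offset]) / 1000.0

    for mode in config.modes:
        t0 = time.time()
        stim = StimulusConfig(
            site_id=config.site_id,
            current_uA=currents[0],
            mode=StimMode(mode),
            interpretation=config.interpretation,
        )
        try:
            base = solve_potential(grid, stim, tol=config.tol)
        except Exception as e:
            raise RuntimeError(f"stage solve ({mode}) failed: {e}") from e
        entry = {
            "mode": mode,
            "current_uA": currents[0],
            "residual": base.residual,
            "iterations": base.iterations,
            "surface_V": surface_potential(base, config.site_id, Face.FRONT),
            "seconds": round(time.time() - t0, 3),
        }
        manifest["fields"].append(entry)
        log.info("solve %s: %d it, residual %.2e (%.1fs)",
                 mode, base.iterations, base.residual, time.time() - t0)

        if write_fields:
            pio.write_vtk_structured_points(
                out / f"field_{mode}.vtk",
                {"V": np.where(np.isnan(base.values), 0.0, base.values)},
                grid.spacing_mm,
            )
            for ax in config.profile_axes:
                prof = profile(base, ax, site_center_mm)
                pio.profile_to_frame(prof).to_csv(
                    out / f"profile_{mode}_{ax}.csv", index=False
                )

        for cur in currents:
            fld = base if cur == currents[0] else scale_solution(base, cur / currents[0])
            res = compute_vta(fld, config.threshold_V)
            manifest["vta"].append(
                {"mode": mode, "current_uA": cur, "vta_mm3": res.volume_mm3,
                 "voxel_count": res.voxel_count}
            )

    vols = {}
    for row in manifest["vta"]:
        vols.setdefault(row["mode"], []).append(row["vta_mm3"])
    manifest["monotone_in_current"] = all(
        all(a <= b for a, b in zip(v, v[1:])) for v in vols.values()
    )
    manifest["manifest_hash"] = pio.sha256_of_obj(
        {k: manifest[k] for k in ("config_hash", "vta")}
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_fingerprint(config: RunConfig) -> dict:
    return {
        "probe": pio.probe_to_dict(config.probe),
        "domain": vars(config.domain) if not hasattr(config.domain, "__dataclass_fields__")
        else {k: getattr(config.domain, k) for k in config.domain.__dataclass_fields__},
        "site": config.site_id,
        "currents_uA": list(config.currents_uA),
        "modes": list(config.modes),
        "threshold_V": config.threshold_V,
        "tol": config.tol,
    }


def layout_table(probe: ProbeSpec):
    """Site table (id, role, face, x, y, z, diameter) for export."""
    return site_positions(probe)
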