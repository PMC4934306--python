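"""Volume of tissue activated (VTA) estimation.

The VTA proxy used here thresholds the extracellular potential itself: a
tissue voxel counts as activated when V <= threshold (default -0.5 V, the
extracellular excitation threshold for cathodic stimulation).  The default
estimator is voxel counting (volume = activated voxels x voxel volume); a
marching-cubes isosurface and its enclosed mesh volume serve as an
independent cross-check of the same level set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from skimage import measure

from .geometry import TISSUE, ConductivityGrid
from .solver import (
    PotentialField,
    StimMode,
    StimulusConfig,
    scale_solution,
    solve_potential,
)

DEFAULT_THRESHOLD_V = -0.5


@dataclass
class VTAResult:
    threshold_V: float
    volume_mm3: float
    voxel_count: int
    mode: str
    current_uA: float


@dataclass
class VTACurve:
    """VTA as a function of stimulus current for one mode."""

    currents_uA: np.ndarray
    volumes_mm3: np.ndarray
    mode: str


def compute_vta(fld: PotentialField, threshold_V: float = DEFAULT_THRESHOLD_V) -> VTAResult:
    """Count tissue voxels at or below the activation threshold.

    The comparison is inclusive (V <= threshold).  A threshold whose sign
    disagrees with the stimulus polarity yields a warning, not an error.
    """
    if threshold_V < 0 and fld.stimulus.current_uA > 0:
        warnings.warn(
            "negative threshold with anodic (positive) current: VTA will be empty",
            stacklevel=2,
        )
    if threshold_V > 0 and fld.stimulus.current_uA < 0:
        warnings.warn(
            "positive threshold with cathodic (negative) current: VTA will be empty",
            stacklevel=2,
        )
    tis = fld.grid.material == TISSUE
    count = int(np.count_nonzero(tis & (fld.values <= threshold_V)))
    return VTAResult(
        threshold_V=threshold_V,
        volume_mm3=count * fld.grid.voxel_volume_mm3,
        voxel_count=count,
        mode=StimMode(fld.stimulus.mode).value,
        current_uA=fld.stimulus.current_uA,
    )


def isosurface(fld: PotentialField, level_V: float = DEFAULT_THRESHOLD_V) -> trimesh.Trimesh:
    """Triangle mesh of the V = level set, coordinates in millimetres.

    Non-tissue voxels are treated as 0 V (outside the activated region for
    any negative level).  A level outside the field's value range returns an
    empty mesh with a warning.
    """
    vol = np.where(fld.grid.material == TISSUE, fld.values, 0.0)
    vmin, vmax = float(np.nanmin(vol)), float(np.nanmax(vol))
    if not (vmin < level_V < vmax):
        warnings.warn(
            f"level {level_V} V outside field range [{vmin:.3g}, {vmax:.3g}]; empty mesh",
            stacklevel=2,
        )
        return trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int))
    h = fld.grid.spacing_mm
    verts, faces, _, _ = measure.marching_cubes(vol, level=level_V, spacing=(h, h, h))
    verts = verts + 0.5 * h  # cell-centered grid: voxel i sits at (i + 0.5) h
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def mesh_volume_mm3(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume of a closed level-set mesh (mm^3)."""
    if len(mesh.faces) == 0:
        return 0.0
    return float(abs(mesh.volume))


def vta_curve(
    grid: ConductivityGrid,
    site_id: str,
    currents_uA,
    mode: StimMode | str,
    threshold_V: float = DEFAULT_THRESHOLD_V,
    direct: bool = False,
    tol: float = 1e-8,
    interpretation="per_site",
) -> VTACurve:
    """VTA versus stimulus current for one site and mode.

    By default one field is solved at the smallest-magnitude current and the
    remaining points are obtained by linear rescaling before thresholding
    (the boundary-value problem is linear in the source); ``direct=True``
    re-solves each current instead.
    """
    currents = np.asarray(list(currents_uA), dtype=float)
    if currents.size == 0:
        raise ValueError("currents list is empty")
    signs = np.sign(currents)
    if not ((signs > 0).all() or (signs < 0).all()):
        raise ValueError("currents must share one sign (monopolar series)")
    order = np.argsort(np.abs(currents))
    currents = currents[order]

    volumes = np.empty_like(currents)
    base = StimulusConfig(
        site_id=site_id,
        current_uA=currents[0],
        mode=StimMode(mode),
        interpretation=interpretation,
    )
    fld0 = solve_potential(grid, base, tol=tol)
    volumes[0] = compute_vta(fld0, threshold_V).volume_mm3
    for i, cur in enumerate(currents[1:], start=1):
        if direct:
            fld = solve_potential(grid, StimulusConfig(
                site_id=site_id, current_uA=cur, mode=StimMode(mode),
                interpretation=interpretation), tol=tol)
        else:
            fld = scale_solution(fld0, cur / currents[0])
        volumes[i] = compute_vta(fld, threshold_V).volume_mm3
    return VTACurve(currents, volumes, StimMode(mode).value)
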