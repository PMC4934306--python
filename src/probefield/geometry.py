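"""Parametric geometry of a dual-sided deep-brain microelectrode array.

The probe modelled here is a silicon shaft (default 9 mm x 400 um x 200 um)
carrying round gold sites on both planar faces: per face, three large
stimulating sites (diameter 100 um, named ``s0``..``s2`` from tip to base),
seven small recording sites (``r1``..``r7``, diameter 20 um) and four
mid-sized auxiliary sites (``a1``..``a4``, diameter 50 um, reserved for
electrochemical sensing).  The tip-most block interleaves recording and
stimulating sites at a 250 um center-to-center pitch, with the first
recording site 300 um from the tip; a second block interleaves the
auxiliary and remaining recording sites at the same pitch.

Coordinate convention (probe frame): origin at the tip center, right-handed,
``z`` along the shaft toward the base, ``y`` normal to the planar faces
(front face at y = +thickness/2, back at -thickness/2), ``x`` across the
shaft width.  Geometry is expressed in micrometres internally; simulation
domains are specified in millimetres and converted exactly once, in
:func:`voxelize`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

UM_PER_MM = 1000.0

# voxel material labels
TISSUE = 0
SUBSTRATE = 1
METAL = 2
GROUND = 3  # interior Dirichlet (V = 0) cells, used to place the return electrode

DEFAULT_SIGMA_TISSUE = 0.2        # S/m, isotropic brain tissue
DEFAULT_SIGMA_SUBSTRATE = 1e-19   # S/m, silicon substrate; treated as no-flux
DEFAULT_SIGMA_METAL = 5.99e7      # S/m, gold; treated as equipotential


class Role(str, Enum):
    STIMULATING = "stimulating"
    RECORDING = "recording"
    AUXILIARY = "auxiliary"


class Face(str, Enum):
    FRONT = "front"
    BACK = "back"


class ProbeValidationError(ValueError):
    """Raised when an operation receives a probe spec violating its invariants."""

    def __init__(self, report: list[str]):
        self.report = list(report)
        super().__init__("invalid probe spec: " + "; ".join(report))


class VoxelizationError(ValueError):
    pass


@dataclass(frozen=True)
class SiteSpec:
    """One round electrode site on a probe face.

    ``z_offset`` is the distance from the tip to the site center along the
    shaft axis; ``lateral_offset`` is the in-plane offset from the shaft
    centerline.  Both in micrometres.
    """

    id: str
    role: Role
    face: Face
    z_offset: float
    diameter: float
    lateral_offset: float = 0.0


@dataclass(frozen=True)
class ProbeSpec:
    """Shaft dimensions plus the list of sites on both faces."""

    shaft_length_mm: float = 9.0
    shaft_width_um: float = 400.0
    shaft_thickness_um: float = 200.0
    tip_taper_um: float = 0.0
    sites: tuple[SiteSpec, ...] = ()

    def sites_on(self, face: Face) -> list[SiteSpec]:
        return [s for s in self.sites if s.face == face]

    def find_site(self, site_id: str, face: Face | str) -> SiteSpec:
        face = Face(face)
        sid = _canonical_site_id(site_id)
        for s in self.sites:
            if s.id == sid and s.face == face:
                return s
        raise KeyError(f"no site {site_id!r} on face {face.value!r}")


def _canonical_site_id(site_id: str) -> str:
    # accept the '#0'..'#2' aliases used for the stimulating sites
    if site_id.startswith("#"):
        return "s" + site_id[1:]
    return site_id


def default_probe_layout(
    *,
    first_recording_um: float = 300.0,
    pitch_um: float = 250.0,
    recording_first: bool = True,
) -> ProbeSpec:
    """The default dual-sided layout: 14 sites per face, 28 total.

    Tip block: recording and stimulating sites alternate at ``pitch_um``,
    starting (by default) with recording site ``r1`` at ``first_recording_um``
    so the bottom-most stimulating site ``s0`` sits one pitch above it.
    Base block: auxiliary and recording sites alternate at the same pitch.
    The back face mirrors the front exactly.
    """
    order_a = [Role.RECORDING, Role.STIMULATING]
    if not recording_first:
        order_a = order_a[::-1]
    diam = {Role.STIMULATING: 100.0, Role.RECORDING: 20.0, Role.AUXILIARY: 50.0}
    front: list[SiteSpec] = []
    counters = {Role.STIMULATING: 0, Role.RECORDING: 1, Role.AUXILIARY: 1}
    prefix = {Role.STIMULATING: "s", Role.RECORDING: "r", Role.AUXILIARY: "a"}

    def add(role: Role, z: float) -> None:
        sid = f"{prefix[role]}{counters[role]}"
        counters[role] += 1
        front.append(SiteSpec(sid, role, Face.FRONT, z, diam[role]))

    z = first_recording_um
    for i in range(6):  # 3 recording + 3 stimulating, interleaved
        add(order_a[i % 2], z)
        z += pitch_um
    for i in range(8):  # 4 auxiliary + 4 recording, interleaved
        add(Role.AUXILIARY if i % 2 == 0 else Role.RECORDING, z)
        z += pitch_um

    back = [replace(s, face=Face.BACK) for s in front]
    return ProbeSpec(sites=tuple(front + back))


def validate_probe(spec: ProbeSpec) -> list[str]:
    """Return the list of violated invariants (empty when the spec is valid)."""
    report: list[str] = []
    if spec.shaft_length_mm <= 0 or spec.shaft_width_um <= 0 or spec.shaft_thickness_um <= 0:
        report.append("shaft dimensions must be positive")
        return report
    length_um = spec.shaft_length_mm * UM_PER_MM
    half_w = spec.shaft_width_um / 2.0
    for s in spec.sites:
        if s.diameter <= 0:
            report.append(f"site {s.id}/{s.face.value}: diameter must be positive")
            continue
        if s.z_offset < 0:
            report.append(f"site {s.id}/{s.face.value}: z_offset must be >= 0")
            continue
        r = s.diameter / 2.0
        if s.z_offset - r < 0 or s.z_offset + r > length_um:
            report.append(f"site {s.id}/{s.face.value}: disc extends beyond shaft ends")
        if abs(s.lateral_offset) + r > half_w:
            report.append(f"site {s.id}/{s.face.value}: disc extends beyond shaft width")
        elif spec.tip_taper_um > 0 and s.z_offset - r < spec.tip_taper_um:
            # within the taper the available half-width shrinks linearly to 0 at the tip
            z_lo = max(s.z_offset - r, 0.0)
            avail = half_w * z_lo / spec.tip_taper_um
            if abs(s.lateral_offset) + r > avail:
                report.append(f"site {s.id}/{s.face.value}: disc extends beyond tapered tip")
    for face in Face:
        face_sites = spec.sites_on(face)
        for i, a in enumerate(face_sites):
            for b in face_sites[i + 1:]:
                d = math.hypot(a.z_offset - b.z_offset, a.lateral_offset - b.lateral_offset)
                if d < (a.diameter + b.diameter) / 2.0:
                    report.append(
                        f"sites {a.id} and {b.id} on face {face.value} overlap"
                    )
    return report


def site_positions(spec: ProbeSpec) -> pd.DataFrame:
    """Site-center coordinates in the probe frame (micrometres).

    Columns: id, role, face, x_um, y_um, z_um, diameter_um.  Front-face sites
    sit at y = +thickness/2, back-face at -thickness/2.  Raises
    :class:`ProbeValidationError` for an invalid spec.
    """
    report = validate_probe(spec)
    if report:
        raise ProbeValidationError(report)
    half_t = spec.shaft_thickness_um / 2.0
    rows = [
        {
            "id": s.id,
            "role": s.role.value,
            "face": s.face.value,
            "x_um": s.lateral_offset,
            "y_um": half_t if s.face == Face.FRONT else -half_t,
            "z_um": s.z_offset,
            "diameter_um": s.diameter,
        }
        for s in spec.sites
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimulationDomain:
    """A rectangular simulation box, millimetres, with the probe pose inside.

    ``probe_tip_mm`` places the probe-frame origin (tip center) in the domain
    frame; the probe axes stay aligned with the domain axes (the shaft along
    +z).  The default box is chosen so the bottom stimulating site ``s0``
    sits at the domain center.  ``allow_clip`` permits the 9 mm shaft to
    extend beyond the box (the part outside is truncated), which is the
    normal situation for a field simulation focused on one site.
    """

    extents_mm: tuple[float, float, float] = (1.4, 1.4, 2.0)
    voxel_size_um: float = 10.0
    probe_tip_mm: tuple[float, float, float] = (0.7, 0.7, 0.45)
    sigma_tissue: float = DEFAULT_SIGMA_TISSUE
    sigma_substrate: float = DEFAULT_SIGMA_SUBSTRATE
    sigma_metal: float = DEFAULT_SIGMA_METAL
    allow_clip: bool = True


@dataclass
class ConductivityGrid:
    """Voxelized material map of probe + tissue on a regular grid.

    ``material`` holds the labels TISSUE/SUBSTRATE/METAL/GROUND;
    ``site_index`` maps METAL voxels to an index into ``sites`` (-1
    elsewhere).  Substrate voxels are no-flux (the 1e-19 S/m silicon is
    numerically a perfect insulator); metal voxels are equipotential patches
    handled by the solver, so only tissue voxels carry a conductivity.
    """

    material: np.ndarray          # uint8, shape (nx, ny, nz)
    site_index: np.ndarray        # int32, shape (nx, ny, nz)
    spacing_um: float
    sites: list[SiteSpec]
    sigma_tissue: float = DEFAULT_SIGMA_TISSUE
    site_weight: np.ndarray | None = None  # disc area fraction of each METAL voxel face
    meta: dict = field(default_factory=dict)

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.material.shape)  # type: ignore[return-value]

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / UM_PER_MM

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm ** 3

    @property
    def extents_mm(self) -> tuple[float, float, float]:
        h = self.spacing_mm
        return tuple(n * h for n in self.material.shape)  # type: ignore[return-value]

    def axis_centers_mm(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (cell-centered)."""
        return (np.arange(self.material.shape[axis]) + 0.5) * self.spacing_mm

    def site_key_index(self, site_id: str, face: Face | str) -> int:
        face = Face(face)
        sid = _canonical_site_id(site_id)
        for k, s in enumerate(self.sites):
            if s.id == sid and s.face == face:
                return k
        raise KeyError(f"site {site_id!r}/{Face(face).value!r} not meshed in this grid")


def uniform_tissue_grid(
    dims: tuple[int, int, int],
    spacing_um: float,
    sigma_tissue: float = DEFAULT_SIGMA_TISSUE,
) -> ConductivityGrid:
    """An all-tissue grid (homogeneous volume conductor, no probe)."""
    if min(dims) < 1 or spacing_um <= 0:
        raise VoxelizationError("grid dims and spacing must be positive")
    material = np.zeros(dims, dtype=np.uint8)
    site_index = np.full(dims, -1, dtype=np.int32)
    return ConductivityGrid(material, site_index, spacing_um, [], sigma_tissue)


def voxelize(
    spec: ProbeSpec,
    domain: SimulationDomain,
    simulate_roles: tuple[Role, ...] = (Role.STIMULATING,),
) -> ConductivityGrid:
    """Rasterize the probe into a conductivity grid.

    Voxels are cell-centered with half-open slab membership, so an exactly
    aligned shaft rasterizes to its analytic volume.  Only sites whose role
    is in ``simulate_roles`` are meshed as equipotential surface patches
    (default: stimulating sites only — resolving the 20 um recording discs
    would force a much finer global grid); the rest are carried in the spec
    but leave the substrate surface intact.

    Raises :class:`VoxelizationError` when the voxel size does not resolve a
    simulated site with at least 4 voxels across its diameter, when a
    simulated site rasterizes to nothing, or when the probe does not fit and
    ``allow_clip`` is False.
    """
    report = validate_probe(spec)
    if report:
        raise ProbeValidationError(report)
    h = float(domain.voxel_size_um)
    if h <= 0:
        raise VoxelizationError("voxel_size must be positive")
    ext_um = tuple(e * UM_PER_MM for e in domain.extents_mm)
    dims = tuple(int(round(e / h)) for e in ext_um)
    if min(dims) < 1:
        raise VoxelizationError(f"domain {domain.extents_mm} mm is empty at {h} um voxels")

    for s in spec.sites:
        if s.role in simulate_roles and h > s.diameter / 4.0:
            raise VoxelizationError(
                f"voxel size {h} um too coarse for site {s.id}/{s.face.value} "
                f"(diameter {s.diameter} um needs <= {s.diameter / 4.0} um)"
            )

    tip = np.asarray(domain.probe_tip_mm) * UM_PER_MM
    w, t = spec.shaft_width_um, spec.shaft_thickness_um
    length_um = spec.shaft_length_mm * UM_PER_MM
    lo = np.array([tip[0] - w / 2, tip[1] - t / 2, tip[2]])
    hi = np.array([tip[0] + w / 2, tip[1] + t / 2, tip[2] + length_um])
    if not domain.allow_clip:
        if (lo < 0).any() or (hi > np.asarray(ext_um)).any():
            raise VoxelizationError("probe does not fit inside domain extents")

    xc = (np.arange(dims[0]) + 0.5) * h
    yc = (np.arange(dims[1]) + 0.5) * h
    zc = (np.arange(dims[2]) + 0.5) * h
    mx = (xc >= lo[0]) & (xc < hi[0])
    my = (yc >= lo[1]) & (yc < hi[1])
    mz = (zc >= lo[2]) & (zc < hi[2])

    material = np.zeros(dims, dtype=np.uint8)
    shaft = mx[:, None, None] & my[None, :, None] & mz[None, None, :]
    if spec.tip_taper_um > 0:
        # linear taper: half-width shrinks to zero at the tip
        in_taper = mz & (zc < lo[2] + spec.tip_taper_um)
        halfw = (w / 2.0) * np.clip((zc - lo[2]) / spec.tip_taper_um, 0.0, 1.0)
        keep_x = np.abs(xc[:, None] - tip[0]) < halfw[None, :]   # (nx, nz)
        taper_ok = keep_x[:, None, :] | ~in_taper[None, None, :]
        shaft &= taper_ok
    material[shaft] = SUBSTRATE

    site_index = np.full(dims, -1, dtype=np.int32)
    site_weight = np.zeros(dims, dtype=np.float64)
    meshed: list[SiteSpec] = []
    front_idx = np.flatnonzero(my)
    for s in spec.sites:
        if s.role not in simulate_roles:
            continue
        if front_idx.size == 0:
            raise VoxelizationError(f"site {s.id}/{s.face.value}: probe clipped out of domain")
        j = front_idx[-1] if s.face == Face.FRONT else front_idx[0]
        sx = tip[0] + s.lateral_offset
        sz = tip[2] + s.z_offset
        r = s.diameter / 2.0
        # anti-aliased disc: fraction of each voxel face covered (4x4 subsamples),
        # so the patch's effective area matches the analytic disc to first order
        sub = (np.arange(4) + 0.5) / 4.0 - 0.5
        cov = np.zeros((dims[0], dims[2]))
        for du in sub:
            for dv in sub:
                cov += ((xc[:, None] + du * h - sx) ** 2
                        + (zc[None, :] + dv * h - sz) ** 2) <= r * r
        cov /= sub.size ** 2
        disc = cov > 0
        patch = disc & (material[:, j, :] == SUBSTRATE)
        if not patch.any():
            inside = (0 <= sx < ext_um[0]) and (0 <= sz < ext_um[2])
            if domain.allow_clip and not inside:
                warnings.warn(
                    f"site {s.id}/{s.face.value} clipped outside the domain; not meshed",
                    stacklevel=2,
                )
                continue
            raise VoxelizationError(
                f"site {s.id}/{s.face.value}: disc rasterizes to no surface voxels "
                f"(voxel size {h} um too coarse)"
            )
        k = len(meshed)
        meshed.append(s)
        layer_mat = material[:, j, :]
        layer_idx = site_index[:, j, :]
        layer_mat[patch] = METAL
        layer_idx[patch] = k
        site_weight[:, j, :][patch] = cov[patch]

    grid = ConductivityGrid(
        material,
        site_index,
        h,
        meshed,
        domain.sigma_tissue,
        site_weight=site_weight,
        meta={
            "domain_extents_mm": tuple(domain.extents_mm),
            "probe_tip_mm": tuple(domain.probe_tip_mm),
            "voxel_size_um": h,
            "n_sites_meshed": len(meshed),
        },
    )
    return grid


def add_spherical_ground(grid: ConductivityGrid, center_mm, radius_mm: float) -> ConductivityGrid:
    """Mark every tissue voxel whose center lies beyond ``radius_mm`` of
    ``center_mm`` as GROUND (Dirichlet V = 0).

    Embeds a spherical return electrode in the box, which is what the
    closed-form point-source and disc oracles assume.  Modifies in place and
    returns the grid.
    """
    c = np.asarray(center_mm, dtype=float)
    X = grid.axis_centers_mm(0)[:, None, None] - c[0]
    Y = grid.axis_centers_mm(1)[None, :, None] - c[1]
    Z = grid.axis_centers_mm(2)[None, None, :] - c[2]
    far = (X * X + Y * Y + Z * Z) > radius_mm * radius_mm
    grid.material[far & (grid.material == TISSUE)] = GROUND
    return grid
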