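"""Quasi-static extracellular potential solver.

Solves the volume-conductor equation div(sigma grad V) = 0 on the voxelized
probe/tissue grid for monopolar stimulation, with the return electrode
represented by V = 0 on the outer box boundary (a finite-domain stand-in
for a reference at infinity) and, optionally, on interior GROUND voxels.

Discretization is a cell-centered finite-volume scheme on the regular grid:
face transmissivities are sigma*h between tissue cells (uniform sigma), the
flux balance at every tissue cell is enforced exactly by construction, and
the scheme is therefore conservative.  Material handling follows the physics
of the extreme conductivity contrast rather than its literal values:

* substrate (silicon, nominally 1e-19 S/m) is a no-flux internal boundary;
* each stimulating site (gold, 5.99e7 S/m) is a single equipotential patch
  carrying one auxiliary unknown, with its total injected current prescribed.
  Metal patches that are not driven float at zero net current.

The resulting linear system is symmetric positive definite and is solved
with Jacobi-preconditioned conjugate gradients to a relative residual of
1e-8 by default; the solver is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.ndimage import map_coordinates

from .geometry import (
    GROUND,
    METAL,
    SUBSTRATE,
    TISSUE,
    ConductivityGrid,
    Face,
    _canonical_site_id,
)

A_PER_UA = 1e-6
M_PER_UM = 1e-6


class StimMode(str, Enum):
    SINGLE_SIDE = "single_side"
    DOUBLE_SIDE = "double_side"


class CurrentInterpretation(str, Enum):
    PER_SITE = "per_site"
    TOTAL_SPLIT = "total_split"


class SolverError(RuntimeError):
    def __init__(self, msg: str, residual: float | None = None):
        super().__init__(msg)
        self.residual = residual


@dataclass(frozen=True)
class StimulusConfig:
    """Monopolar stimulus: which site(s) carry current, and how much.

    ``current_uA`` is signed (cathodic stimulation is negative).  In
    ``double_side`` mode the same site id is driven on both faces; with the
    default ``per_site`` interpretation each face's site carries the full
    stated current, while ``total_split`` divides it between them.
    ``point_sources`` injects current directly at voxel indices and exists
    for analytic benchmark fields (a single-voxel source approximates an
    ideal point source).
    """

    site_id: str | None = None
    current_uA: float = -100.0
    mode: StimMode = StimMode.DOUBLE_SIDE
    interpretation: CurrentInterpretation = CurrentInterpretation.PER_SITE
    single_face: Face = Face.FRONT
    point_sources: tuple[tuple[tuple[int, int, int], float], ...] = ()

    def active_faces(self) -> list[Face]:
        if StimMode(self.mode) == StimMode.DOUBLE_SIDE:
            return [Face.FRONT, Face.BACK]
        return [Face(self.single_face)]

    def resolve(self, grid: ConductivityGrid) -> list[tuple[int, float]]:
        """Return [(grid site index, current in uA)] for the driven patches."""
        if self.site_id is None:
            return []
        faces = self.active_faces()
        per = float(self.current_uA)
        if CurrentInterpretation(self.interpretation) == CurrentInterpretation.TOTAL_SPLIT:
            per /= len(faces)
        return [(grid.site_key_index(self.site_id, f), per) for f in faces]


@dataclass
class PotentialField:
    """Solved potential on the grid, in volts.

    ``values`` is NaN inside the substrate, equals the site potential inside
    metal patches and 0 in ground voxels.  ``site_potentials`` maps
    (site id, face) to the equipotential patch value for every meshed metal
    site (driven or floating).
    """

    grid: ConductivityGrid
    values: np.ndarray
    site_potentials: dict[tuple[str, str], float]
    residual: float
    iterations: int
    stimulus: StimulusConfig
    scaled_by: float | None = None  # set when derived by linearity

    @property
    def tissue_values(self) -> np.ndarray:
        return self.values[self.grid.material == TISSUE]


def _face_pairs(arr: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    sl_a = [slice(None)] * 3
    sl_b = [slice(None)] * 3
    sl_a[axis] = slice(None, -1)
    sl_b[axis] = slice(1, None)
    return arr[tuple(sl_a)].reshape(-1), arr[tuple(sl_b)].reshape(-1)


def _boundary_slices(axis: int, end: int) -> tuple[slice, ...]:
    sl = [slice(None)] * 3
    sl[axis] = -1 if end else 0
    return tuple(sl)


def solve_potential(
    grid: ConductivityGrid,
    stim: StimulusConfig,
    tol: float = 1e-8,
    max_iter: int = 50000,
) -> PotentialField:
    """Solve for the extracellular potential under the given stimulus.

    Zero-current stimuli return the (exact) identically-zero field.  Raises
    :class:`SolverError` carrying the final residual on non-convergence, and
    when the stimulus drives no site and carries no point source.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    mat = grid.material
    active = stim.resolve(grid)
    if not active and not stim.point_sources:
        raise SolverError("stimulus drives no site and has no point sources")

    n_sites = len(grid.sites)
    tis = mat == TISSUE
    n_t = int(tis.sum())
    if n_t == 0:
        raise SolverError("grid contains no tissue voxels")
    uidx = np.full(mat.shape, -1, dtype=np.int64)
    uidx[tis] = np.arange(n_t)
    n_un = n_t + n_sites

    total_uA = sum(i for _, i in active) + sum(i for _, i in stim.point_sources)
    if total_uA == 0.0 and all(i == 0.0 for _, i in active) and all(
        i == 0.0 for _, i in stim.point_sources
    ):
        values = np.where(mat == SUBSTRATE, np.nan, 0.0)
        pots = {(s.id, s.face.value): 0.0 for s in grid.sites}
        return PotentialField(grid, values, pots, 0.0, 0, stim)

    sigma = grid.sigma_tissue
    h = grid.spacing_um * M_PER_UM
    T_tt = sigma * h          # tissue-tissue face (uniform sigma, harmonic mean)
    T_tm = 2.0 * sigma * h    # tissue half-cell to an equipotential metal surface
    T_tg = sigma * h          # tissue to interior ground cell (Dirichlet at its center)
    T_tb = 2.0 * sigma * h    # tissue to the outer box boundary (Dirichlet at the face)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    diag = np.zeros(n_un)

    weight = grid.site_weight
    if weight is None:
        weight = np.where(mat == METAL, 1.0, 0.0)

    for axis in range(3):
        ma, mb = _face_pairs(mat, axis)
        ia, ib = _face_pairs(uidx, axis)
        sa, sb = _face_pairs(grid.site_index, axis)
        wa, wb = _face_pairs(weight, axis)

        tt = (ma == TISSUE) & (mb == TISSUE)
        i, j = ia[tt], ib[tt]
        rows.append(i); cols.append(j); vals.append(np.full(i.size, -T_tt))
        rows.append(j); cols.append(i); vals.append(np.full(i.size, -T_tt))
        np.add.at(diag, i, T_tt)
        np.add.at(diag, j, T_tt)

        for t_side, m_side, t_idx, m_site, m_w in (
            (ma, mb, ia, sb, wb),
            (mb, ma, ib, sa, wa),
        ):
            tm = (t_side == TISSUE) & (m_side == METAL)
            if tm.any():
                i = t_idx[tm]
                s = n_t + m_site[tm].astype(np.int64)
                T = T_tm * m_w[tm]
                rows.append(i); cols.append(s); vals.append(-T)
                rows.append(s); cols.append(i); vals.append(-T)
                np.add.at(diag, i, T)
                np.add.at(diag, s, T)
            tg = (t_side == TISSUE) & (m_side == GROUND)
            if tg.any():
                np.add.at(diag, t_idx[tg], T_tg)

    for axis in range(3):
        for end in (0, 1):
            bidx = uidx[_boundary_slices(axis, end)].reshape(-1)
            bidx = bidx[bidx >= 0]
            np.add.at(diag, bidx, T_tb)

    for k in range(n_sites):
        if diag[n_t + k] == 0.0:
            raise SolverError(f"metal site {grid.sites[k].id} has no tissue contact")

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_un, n_un),
    )
    A += sp.diags(diag)

    b = np.zeros(n_un)
    for k, i_uA in active:
        b[n_t + k] += i_uA * A_PER_UA
    for ijk, i_uA in stim.point_sources:
        u = uidx[tuple(ijk)]
        if u < 0:
            raise SolverError(f"point source at {ijk} is not in a tissue voxel")
        b[u] += i_uA * A_PER_UA

    M = sp.diags(1.0 / A.diagonal())
    n_it = 0

    def _cb(_xk):
        nonlocal n_it
        n_it += 1

    x, info = spla.cg(A, b, rtol=tol, atol=0.0, maxiter=max_iter, M=M, callback=_cb)
    res = float(np.linalg.norm(b - A @ x) / np.linalg.norm(b))
    if info != 0 or not np.isfinite(res) or res > tol * 1.01:
        raise SolverError(
            f"CG did not converge in {max_iter} iterations (residual {res:.3e})",
            residual=res,
        )

    values = np.full(mat.shape, np.nan)
    values[tis] = x[:n_t]
    values[mat == GROUND] = 0.0
    for k, s in enumerate(grid.sites):
        values[(mat == METAL) & (grid.site_index == k)] = x[n_t + k]
    pots = {(s.id, s.face.value): float(x[n_t + k]) for k, s in enumerate(grid.sites)}
    return PotentialField(grid, values, pots, res, n_it, stim)


def scale_solution(fld: PotentialField, factor: float) -> PotentialField:
    """Rescale a solved field by a current ratio (linearity of the BVP)."""
    stim = replace(fld.stimulus, current_uA=fld.stimulus.current_uA * factor)
    return PotentialField(
        grid=fld.grid,
        values=fld.values * factor,
        site_potentials={k: v * factor for k, v in fld.site_potentials.items()},
        residual=fld.residual,
        iterations=fld.iterations,
        stimulus=stim,
        scaled_by=factor if fld.scaled_by is None else fld.scaled_by * factor,
    )


def surface_potential(fld: PotentialField, site_id: str, face: Face | str) -> float:
    """Equipotential value of a driven site patch, in volts."""
    driven = {fld.grid.sites[k].id for k, _ in fld.stimulus.resolve(fld.grid)}
    sid = _canonical_site_id(site_id)
    if sid not in driven:
        raise KeyError(f"site {site_id!r} is not active in this field's stimulus")
    return fld.site_potentials[(sid, Face(face).value)]


def boundary_current(fld: PotentialField) -> float:
    """Total current (A) leaving the solution through every V = 0 surface.

    For a conservative discretization this equals the injected current to
    solver tolerance; used as the conservation check.
    """
    grid = fld.grid
    mat = grid.material
    V = np.where(np.isnan(fld.values), 0.0, fld.values)
    sigma = grid.sigma_tissue
    h = grid.spacing_um * M_PER_UM
    out = 0.0
    for axis in range(3):
        ma, mb = _face_pairs(mat, axis)
        va, vb = _face_pairs(V, axis)
        tg = (ma == TISSUE) & (mb == GROUND)
        out += sigma * h * va[tg].sum()
        gt = (ma == GROUND) & (mb == TISSUE)
        out += sigma * h * vb[gt].sum()
        for end in (0, 1):
            sl = _boundary_slices(axis, end)
            bmask = mat[sl] == TISSUE
            out += 2.0 * sigma * h * V[sl][bmask].sum()
    return float(out)


@dataclass
class ProfileSeries:
    """1D potential profile along a coordinate axis through a point."""

    axis: str                 # 'X' | 'Y' | 'Z'
    origin_mm: tuple[float, float, float]
    coordinates_mm: np.ndarray
    values_V: np.ndarray      # NaN where the line passes through substrate/metal


_AXIS = {"X": 0, "Y": 1, "Z": 2}


def profile(fld: PotentialField, axis: str, origin_mm) -> ProfileSeries:
    """Trilinearly interpolated potential along an axis-parallel line.

    Sampled at voxel-center spacing across the full domain; samples whose
    interpolation stencil touches substrate or metal are masked NaN.
    """
    ax = _AXIS[axis.upper()]
    grid = fld.grid
    origin = np.asarray(origin_mm, dtype=float)
    ext = grid.extents_mm
    if (origin < 0).any() or (origin > np.asarray(ext)).any():
        raise ValueError(f"origin {origin_mm} outside domain extents {ext}")
    n = grid.dims[ax]
    h = grid.spacing_mm
    coords_mm = (np.arange(n) + 0.5) * h
    # fractional voxel indices: cell-centered, center i at (i + 0.5) h
    pts = np.empty((3, n))
    for d in range(3):
        if d == ax:
            pts[d] = np.arange(n, dtype=float)
        else:
            pts[d] = origin[d] / h - 0.5
    masked = np.where(grid.material == TISSUE, fld.values, np.nan)
    vals = map_coordinates(masked, pts, order=1, mode="nearest")
    return ProfileSeries(axis.upper(), tuple(origin), coords_mm, vals)
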