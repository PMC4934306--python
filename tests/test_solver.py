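"""Finite-volume potential solver: closed-form oracles and invariants."""

import numpy as np
import pytest

from probefield.geometry import Face
from probefield.solver import (
    SolverError,
    StimMode,
    StimulusConfig,
    boundary_current,
    profile,
    scale_solution,
    solve_potential,
    surface_potential,
)
from probefield.synthetic import disc_benchmark_grid

SIGMA = 0.2  # S/m


def point_source_reference(I_A, r_m, R_m):
    """V(r) for a point source with a concentric spherical ground at R."""
    return I_A / (4 * np.pi * SIGMA) * (1 / r_m - 1 / R_m)


def disc_reference(I_A, a_m, R_m):
    """Disc on an insulating plane, hemispherical ground at R:
    spreading resistance 1/(4 sigma a) minus the finite-ground correction."""
    return I_A / (4 * SIGMA * a_m) - I_A / (2 * np.pi * SIGMA * R_m)


class TestZeroAndErrors:
    def test_zero_current_gives_zero_field(self, small_grid):
        stim = StimulusConfig(site_id="s0", current_uA=0.0, mode=StimMode.SINGLE_SIDE)
        fld = solve_potential(small_grid, stim)
        assert np.nanmax(np.abs(fld.values)) == 0.0

    def test_no_active_site_rejected(self, small_grid):
        with pytest.raises(SolverError):
            solve_potential(small_grid, StimulusConfig(site_id=None))

    def test_nonconvergence_reports_residual(self, small_grid):
        stim = StimulusConfig(site_id="s0", current_uA=-100.0)
        with pytest.raises(SolverError) as exc:
            solve_potential(small_grid, stim, tol=1e-12, max_iter=3)
        assert exc.value.residual is not None and exc.value.residual > 1e-12

    def test_inactive_site_surface_potential_rejected(self, field_single_100):
        with pytest.raises(KeyError):
            surface_potential(field_single_100, "s2", Face.FRONT)


class TestPointSourceOracle:
    def test_matches_closed_form_within_2pct(self, point_source_field):
        fld, ci = point_source_field
        grid = fld.grid
        h = grid.spacing_mm
        src = (np.array(ci) + 0.5) * h
        R = 0.9e-3
        errs = []
        for dv in [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 1, 1)]:
            dv = np.asarray(dv, float)
            dv /= np.linalg.norm(dv)
            for r_mm in np.arange(5 * h, 0.48, 0.04):  # 5 voxels .. quarter width
                idx = tuple(int(round(x / h - 0.5)) for x in src + dv * r_mm)
                r = np.linalg.norm((np.array(idx) + 0.5) * h - src) * 1e-3
                ref = point_source_reference(-100e-6, r, R)
                errs.append(abs(fld.values[idx] - ref) / abs(ref))
        assert max(errs) < 0.02

    def test_conservation(self, point_source_field):
        fld, _ = point_source_field
        assert boundary_current(fld) == pytest.approx(-100e-6, rel=1e-6)


class TestDiscOracle:
    def test_surface_potential_within_5pct(self, disc_field_5um):
        fld, R_mm = disc_field_5um
        ref = disc_reference(100e-6, 50e-6, R_mm * 1e-3)
        v = surface_potential(fld, "disc", Face.FRONT)
        assert v == pytest.approx(ref, rel=0.05)

    def test_error_decreases_under_refinement(self):
        errs = []
        for h in (5.0, 2.5):
            grid = disc_benchmark_grid(50.0, h, 0.15)
            stim = StimulusConfig(site_id="disc", current_uA=100.0,
                                  mode=StimMode.SINGLE_SIDE)
            fld = solve_potential(grid, stim)
            ref = disc_reference(100e-6, 50e-6, 0.15e-3)
            errs.append(abs(surface_potential(fld, "disc", Face.FRONT) - ref) / ref)
        assert errs[1] < errs[0]

    def test_spreading_resistance_scale(self, disc_field_5um):
        # 1/(4 sigma a) = 25 kOhm for a 50 um disc in 0.2 S/m
        fld, R_mm = disc_field_5um
        v = surface_potential(fld, "disc", Face.FRONT)
        v_corrected = v + 100e-6 / (2 * np.pi * SIGMA * R_mm * 1e-3)
        assert v_corrected / 100e-6 == pytest.approx(25_000.0, rel=0.05)


class TestLinearity:
    @pytest.fixture(scope="class")
    def pair(self, small_grid):
        mk = lambda cur: solve_potential(
            small_grid,
            StimulusConfig(site_id="s0", current_uA=cur, mode=StimMode.SINGLE_SIDE),
        )
        return mk(-100.0), mk(-150.0)

    def test_scale_solution_identity(self, pair):
        f100, _ = pair
        same = scale_solution(f100, 1.0)
        assert np.array_equal(same.values, f100.values, equal_nan=True)

    def test_scaled_solve_matches_direct(self, pair):
        f100, f150 = pair
        scaled = scale_solution(f100, 1.5)
        denom = np.nanmax(np.abs(f150.values))
        assert np.nanmax(np.abs(scaled.values - f150.values)) / denom < 1e-7

    def test_sign_antisymmetry(self, small_grid, pair):
        f100, _ = pair
        fneg = solve_potential(
            small_grid,
            StimulusConfig(site_id="s0", current_uA=100.0, mode=StimMode.SINGLE_SIDE),
        )
        denom = np.nanmax(np.abs(f100.values))
        assert np.nanmax(np.abs(fneg.values + f100.values)) / denom < 1e-7

    def test_surface_voltage_ratio(self, pair):
        f100, f150 = pair
        r = surface_potential(f150, "s0", Face.FRONT) / surface_potential(
            f100, "s0", Face.FRONT
        )
        assert r == pytest.approx(1.5, abs=1e-6)


class TestSuperposition:
    def test_two_sites_sum_to_joint_solve(self, small_grid):
        def single(face):
            return solve_potential(small_grid, StimulusConfig(
                site_id="s0", current_uA=-100.0,
                mode=StimMode.SINGLE_SIDE, single_face=face))

        front, back = single(Face.FRONT), single(Face.BACK)
        both = solve_potential(small_grid, StimulusConfig(
            site_id="s0", current_uA=-100.0, mode=StimMode.DOUBLE_SIDE))
        denom = np.nanmax(np.abs(both.values))
        err = np.nanmax(np.abs(front.values + back.values - both.values)) / denom
        assert err < 1e-7  # 10x the 1e-8 solver tolerance

    def test_conservation_each_solve(self, small_grid):
        for mode, total in ((StimMode.SINGLE_SIDE, -100e-6),
                            (StimMode.DOUBLE_SIDE, -200e-6)):
            fld = solve_potential(small_grid, StimulusConfig(
                site_id="s0", current_uA=-100.0, mode=mode))
            assert boundary_current(fld) == pytest.approx(total, rel=1e-6)

    def test_total_split_halves_per_face(self, small_grid):
        per = solve_potential(small_grid, StimulusConfig(
            site_id="s0", current_uA=-100.0, mode=StimMode.DOUBLE_SIDE))
        split = solve_potential(small_grid, StimulusConfig(
            site_id="s0", current_uA=-100.0, mode=StimMode.DOUBLE_SIDE,
            interpretation="total_split"))
        assert boundary_current(split) == pytest.approx(-100e-6, rel=1e-6)
        denom = np.nanmax(np.abs(per.values))
        assert np.nanmax(np.abs(split.values - per.values / 2)) / denom < 1e-7


class TestFarField:
    def test_dual_site_matches_point_sources_far_away(self, small_grid):
        # far from the probe the dual-disc field looks like point sources
        # carrying the same currents (solved on the same finite domain, so
        # the boundary effect cancels; only disc-vs-point structure remains)
        fld = solve_potential(small_grid, StimulusConfig(
            site_id="s0", current_uA=-100.0, mode=StimMode.DOUBLE_SIDE))
        grid = fld.grid
        h = grid.spacing_mm
        vox = lambda x, y, z: tuple(int(round(c / h - 0.5)) for c in (x, y, z))
        ref = solve_potential(grid, StimulusConfig(site_id=None, point_sources=(
            (vox(0.5, 0.6 + h, 0.7), -100.0),
            (vox(0.5, 0.4 - h, 0.7), -100.0),
        )))
        errs = []
        for d_mm in (0.30, 0.35, 0.40):
            idx = vox(0.5 + d_mm, 0.5, 0.7)
            errs.append(abs(fld.values[idx] - ref.values[idx]) / abs(ref.values[idx]))
        assert max(errs) < 0.05


class TestProfiles:
    def test_double_side_y_profile_symmetric(self, small_grid):
        fld = solve_potential(small_grid, StimulusConfig(
            site_id="s0", current_uA=-100.0, mode=StimMode.DOUBLE_SIDE))
        prof = profile(fld, "Y", (0.5, 0.5, 0.7))
        v, c = prof.values_V, prof.coordinates_mm
        ok = np.isfinite(v)
        vv, cc = v[ok], c[ok]
        for ci, vi in zip(cc, vv):
            j = np.argmin(np.abs(cc - (1.0 - ci)))
            if abs(cc[j] - (1.0 - ci)) < 1e-9:
                assert vi == pytest.approx(vv[j], rel=0.01)

    def test_profile_monotone_decay_beyond_footprint(self, small_grid):
        fld = solve_potential(small_grid, StimulusConfig(
            site_id="s0", current_uA=-100.0, mode=StimMode.DOUBLE_SIDE))
        prof = profile(fld, "X", (0.5, 0.5, 0.7))
        sel = np.isfinite(prof.values_V) & (prof.coordinates_mm > 0.5 + 0.21)
        assert np.all(np.diff(np.abs(prof.values_V[sel])) < 0)

    def test_stronger_current_dominates_everywhere(self, small_grid):
        fld = solve_potential(small_grid, StimulusConfig(
            site_id="s0", current_uA=-100.0, mode=StimMode.DOUBLE_SIDE))
        p100 = profile(fld, "Z", (0.5, 0.5, 0.7))
        p350 = profile(scale_solution(fld, 3.5), "Z", (0.5, 0.5, 0.7))
        ok = np.isfinite(p100.values_V) & (np.abs(p100.values_V) > 0)
        assert np.all(np.abs(p350.values_V[ok]) > np.abs(p100.values_V[ok]))

    def test_profile_outside_domain_rejected(self, field_single_100):
        with pytest.raises(ValueError):
            profile(field_single_100, "X", (10.0, 0.0, 0.0))

    def test_substrate_masked(self, small_grid):
        fld = solve_potential(small_grid, StimulusConfig(
            site_id="s0", current_uA=-100.0, mode=StimMode.DOUBLE_SIDE))
        prof = profile(fld, "Y", (0.5, 0.5, 0.7))
        # the line crosses the 200 um shaft: some samples must be masked
        assert np.isnan(prof.values_V).any()
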