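"""Synthetic test inputs with known ground truth.

Two families of reference data stand in for wet-lab inputs:

* extracellular recordings — band-limited Gaussian noise at a requested RMS
  plus a stereotyped biphasic spike template placed at Poisson event times,
  fully deterministic under a master seed (per-channel child streams);
* analytic potential fields — a -c/r point-source field on a uniform grid
  (level sets are exact spheres, so VTA estimators can be checked against
  the closed-form sphere volume), plus grid builders for the point-source
  and disc-electrode solver benchmarks with an embedded spherical ground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .geometry import (
    METAL,
    SUBSTRATE,
    ConductivityGrid,
    Face,
    Role,
    SiteSpec,
    add_spherical_ground,
    uniform_tissue_grid,
)
from .recording import Recording, mua_bandpass_sos
from .solver import PotentialField, StimulusConfig


@dataclass(frozen=True)
class SyntheticRecordingSpec:
    """Construction parameters for a synthetic extracellular recording.

    ``p2p_uV`` is the in-band (post MUA band-pass) peak-to-peak amplitude of
    the spike template; the raw template is pre-compensated so an analysis
    band-pass of the emitted recording reproduces it.  ``noise_rms_uV`` is
    the realized RMS of the band-limited noise in the emitted recording.
    """

    duration_s: float = 10.0
    sampling_rate: float = 30000.0
    firing_rate_hz: float = 20.0
    p2p_uV: float = 150.0
    width_ms: float = 0.8
    noise_rms_uV: float = 25.0
    noise_band_hz: tuple[float, float] = (500.0, 5000.0)
    n_channels: int = 1
    seed: int = 0

    def validate(self) -> None:
        pos = (
            self.duration_s, self.sampling_rate, self.firing_rate_hz,
            self.p2p_uV, self.width_ms, self.noise_rms_uV, self.n_channels,
        )
        if any(v <= 0 for v in pos):
            raise ValueError("all recording-spec parameters must be positive")
        if self.noise_band_hz[1] >= self.sampling_rate / 2:
            raise ValueError(
                f"noise band upper edge {self.noise_band_hz[1]} Hz violates Nyquist "
                f"at {self.sampling_rate} Hz"
            )


@dataclass
class GroundTruth:
    """What the generator actually put into the recording, per channel."""

    spike_times_s: list[np.ndarray]
    true_p2p_uV: float
    true_noise_rms_uV: float

    @property
    def implied_snr(self) -> float:
        return self.true_p2p_uV / self.true_noise_rms_uV


def spike_template(spec: SyntheticRecordingSpec) -> np.ndarray:
    """Biphasic (negative-then-positive) spike template, in uV.

    The negative phase carries ~70% of the peak-to-peak, as for a typical
    extracellular somatic spike.  Scaled so the template's peak-to-peak
    *after* the MUA band-pass equals ``spec.p2p_uV``.
    """
    n = max(8, int(round(spec.width_ms * 1e-3 * spec.sampling_rate)))
    t = np.arange(n) / (n - 1)
    neg = np.exp(-0.5 * ((t - 0.30) / 0.08) ** 2)   # narrow depolarization
    pos = np.exp(-0.5 * ((t - 0.60) / 0.20) ** 2)   # broad repolarization
    raw = -0.75 * neg + 0.25 * pos
    # pre-compensate for the analysis band-pass
    sos = mua_bandpass_sos(spec.sampling_rate, *spec.noise_band_hz)
    padded = np.zeros(n * 40)
    padded[15 * n: 16 * n] = raw
    filt = signal.sosfiltfilt(sos, padded)
    scale = spec.p2p_uV / (filt.max() - filt.min())
    return raw * scale


def gen_recording(spec: SyntheticRecordingSpec) -> tuple[Recording, GroundTruth]:
    """Deterministic synthetic recording plus its ground truth.

    Noise: white Gaussian filtered to ``noise_band_hz`` (same Butterworth
    family as the analysis band-pass) and rescaled to the requested RMS.
    Spikes: the template added at homogeneous-Poisson event times; overlaps
    are allowed and each event counted once.
    """
    spec.validate()
    fs = spec.sampling_rate
    n = int(round(spec.duration_s * fs))
    tmpl = spike_template(spec)
    sos = mua_bandpass_sos(fs, *spec.noise_band_hz)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_channels)
    data = np.empty((spec.n_channels, n))
    times: list[np.ndarray] = []
    for ch, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        noise = signal.sosfiltfilt(sos, rng.standard_normal(n))
        noise *= spec.noise_rms_uV / np.sqrt(np.mean(noise ** 2))
        n_ev = rng.poisson(spec.firing_rate_hz * spec.duration_s)
        starts = np.sort(rng.uniform(0, n - len(tmpl), size=n_ev)).astype(int)
        x = noise
        for s0 in starts:
            x[s0: s0 + len(tmpl)] += tmpl
        data[ch] = x
        # event time = template minimum (the detected extremum)
        times.append((starts + int(np.argmin(tmpl))) / fs)
    rec = Recording(fs, data)
    truth = GroundTruth(times, spec.p2p_uV, spec.noise_rms_uV)
    return rec, truth


def gen_point_source_field(
    dims: tuple[int, int, int],
    spacing_um: float,
    c_V_mm: float,
    center_mm=None,
) -> PotentialField:
    """Analytic V(r) = -c/r field on a uniform all-tissue grid.

    The level set V = -L is the sphere r = c/L, so the enclosed volume is
    known in closed form; the singular voxel is clipped to the value at
    half a voxel spacing.  Serves as the oracle for VTA estimators.
    """
    grid = uniform_tissue_grid(dims, spacing_um)
    c = np.asarray(
        center_mm if center_mm is not None else [e / 2 for e in grid.extents_mm],
        dtype=float,
    )
    X = grid.axis_centers_mm(0)[:, None, None] - c[0]
    Y = grid.axis_centers_mm(1)[None, :, None] - c[1]
    Z = grid.axis_centers_mm(2)[None, None, :] - c[2]
    r = np.sqrt(X * X + Y * Y + Z * Z)
    r = np.maximum(r, grid.spacing_mm / 2.0)
    values = -c_V_mm / r
    stim = StimulusConfig(site_id=None, current_uA=-1.0, point_sources=())
    return PotentialField(grid, values, {}, 0.0, 0, stim)


def point_source_benchmark_grid(
    n: int, spacing_um: float, ground_radius_mm: float
) -> tuple[ConductivityGrid, tuple[int, int, int]]:
    """Uniform tissue cube with a spherical ground; returns (grid, center voxel).

    Injecting current at the center voxel approximates a point source whose
    closed-form solution, with the ground sphere of radius R, is
    V(r) = I/(4 pi sigma) (1/r - 1/R).
    """
    grid = uniform_tissue_grid((n, n, n), spacing_um)
    ci = (n // 2,) * 3
    center_mm = [(i + 0.5) * grid.spacing_mm for i in ci]  # ground centered on the source voxel
    add_spherical_ground(grid, center_mm, ground_radius_mm)
    return grid, ci


def disc_benchmark_grid(
    disc_radius_um: float,
    spacing_um: float,
    ground_radius_mm: float,
    substrate_layers: int = 3,
) -> ConductivityGrid:
    """Disc electrode on an insulating plane with a hemispherical ground.

    A thin substrate slab spans the bottom of the box; the disc is an
    equipotential metal patch in the slab's top layer; tissue beyond the
    hemisphere of radius R (centered on the disc) is grounded.  The
    closed-form surface potential is I/(4 sigma a) - I/(2 pi sigma R).
    """
    h = spacing_um
    r_vox = ground_radius_mm * 1000.0 / h
    nxy = int(2 * (r_vox + 2))
    nz = int(r_vox + 2 + substrate_layers)
    grid = uniform_tissue_grid((nxy, nxy, nz), h)
    grid.material[:, :, :substrate_layers] = SUBSTRATE
    cx = grid.axis_centers_mm(0)[nxy // 2]
    cz = grid.axis_centers_mm(2)[substrate_layers - 1]
    X = grid.axis_centers_mm(0)[:, None] - cx
    Y = grid.axis_centers_mm(1)[None, :] - cx
    h_mm = h / 1000.0
    sub = (np.arange(4) + 0.5) / 4.0 - 0.5
    cov = np.zeros((nxy, nxy))
    for du in sub:
        for dv in sub:
            cov += ((X + du * h_mm) ** 2 + (Y + dv * h_mm) ** 2) <= (disc_radius_um / 1000.0) ** 2
    cov /= sub.size ** 2
    disc = cov > 0
    grid.material[:, :, substrate_layers - 1][disc] = METAL
    grid.site_index[:, :, substrate_layers - 1][disc] = 0
    grid.site_weight = np.zeros(grid.material.shape)
    grid.site_weight[:, :, substrate_layers - 1][disc] = cov[disc]
    site = SiteSpec("disc", Role.STIMULATING, Face.FRONT, 0.0, 2 * disc_radius_um)
    grid.sites = [site]
    add_spherical_ground(grid, (cx, cx, cz), ground_radius_mm)
    return grid
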