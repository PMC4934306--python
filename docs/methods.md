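# Methods

## The device and the modelling question

The modelled device is a dual-sided silicon microelectrode array for rat
deep-brain stimulation studies: a 9 mm x 400 um x 200 um shaft with, on
each planar face, three stimulating sites (diameter 100 um, labelled
`s0`-`s2` from tip to base), seven recording sites (20 um, `r1`-`r7`) and
four auxiliary sites (50 um, `a1`-`a4`).  The tip-most block interleaves
recording and stimulating sites at 250 um center-to-center pitch with the
first recording site 300 um from the tip; a second block interleaves the
auxiliary and remaining recording sites at the same pitch; the back face
mirrors the front.  The published description fixes pitches, counts and
the first-site offset but not the exact interleave order; this package
defaults to recording-first (so `s0` sits at z = 550 um), which places the
tip-most site as a recording site, and the order is configurable through
`ProbeSpec`.

Two questions are modelled: (i) what extracellular potential field and
activated tissue volume does monopolar stimulation at a site produce, for
single- versus double-side driving and currents of 100-350 uA; and
(ii) how should multi-unit recordings be reduced to a signal-to-noise
statistic.

## Volume-conductor model

Tissue is a homogeneous, isotropic, purely resistive medium
(sigma = 0.2 S/m), so the potential obeys `div(sigma grad V) = 0` with
current sources on the electrode surfaces (quasi-static approximation; no
capacitive or interface impedance effects).  The two extreme
conductivities in the device are treated by their physical limits rather
than their numeric values:

* the silicon substrate (nominally 1e-19 S/m) is a **no-flux internal
  boundary** — a literal 1e-19 S/m entry would put a ~1e27 contrast into
  the matrix for no physical difference;
* gold sites (5.99e7 S/m) are **equipotential patches**: each driven disc
  contributes one auxiliary unknown (its potential) and one constraint
  (its total injected current), which is the infinite-contrast limit of
  the metal.  Undriven metal sites float at zero net current.

Monopolar stimulation means the return electrode is "at infinity"; on a
finite grid this is Dirichlet V = 0 on the outer box boundary.  For the
closed-form benchmarks the return is instead an embedded spherical (or
hemispherical) ground of radius R, because the references
`V(r) = I/(4 pi sigma) (1/r - 1/R)` (point source) and
`V = I/(4 sigma a) - I/(2 pi sigma R)` (disc of radius a on an insulating
plane) are then exact rather than box-shape-dependent.

### Discretization

Cell-centered finite volumes on a regular voxel grid.  Face
transmissivities are `sigma * h` between tissue cells, `2 sigma * h * w`
between a tissue cell and a metal surface voxel (half-cell distance; `w`
is the anti-aliased disc coverage of that face, computed by 4x4
subsampling so the patch's effective area matches `pi a^2` to first
order), and `2 sigma * h` to the Dirichlet box faces.  The scheme is
conservative by construction: the discrete flux balance holds exactly at
every tissue cell, and the current collected on all V = 0 surfaces equals
the injected current to solver tolerance (this is asserted in tests and
reported by the acceptance script).

The symmetric positive-definite system is solved with Jacobi-
preconditioned conjugate gradients to a relative residual of 1e-8,
deterministically.  Linearity of the boundary-value problem is exploited
throughout: a current series is computed from one solve per mode by
rescaling (`scale_solution`), which tests show agrees with direct
re-solves to ~1e-8.

### Default domain and resolution

The default simulation box is 1.4 x 1.4 x 2.0 mm at 10 um voxels
(~3.9M cells) with the driven site `s0` at the box center and the shaft
clipped where it leaves the box.  The 10 um resolution gives 10 voxels
across a stimulating disc; benchmark solves show the disc surface
potential converging from above with the residual discretization bias at
10 um of a few percent.  The box size is a compromise between boundary
distance and cost; the boundary correction at this size is ~2% of the
surface potential (the `I/(2 pi sigma R)`-scale term).  Both knobs are
plain `SimulationDomain` fields, so boundary-sensitivity studies are a
loop over `extents_mm`.

Recording (20 um) and auxiliary (50 um) sites are carried in the geometry
but not meshed as sources by default: resolving a 20 um disc at 4+ voxels
across would force <= 5 um voxels globally.  Voxelization refuses grids
coarser than 4 voxels across any *simulated* disc, naming the offending
site.

### Published values: what is and is not reproduced

The published surface-voltage series for double-side stimulation at site
s0 (2.3096, 3.4644, 5.7739, 8.0835 V at 100-350 uA) is proportional to
current to its printed rounding (ratios 1.5 / 2.5 / 3.5 within 1e-4);
this proportionality is exactly what a linear volume conductor predicts
and is reproduced here by construction and verified by independent
solves.  The *absolute* voltage depends on the (unreported) mesh, domain
and ground placement of the original model, so it is checked only against
the analytic plausibility band: between the free-disc limit
`1/(8 sigma a)` (1.25 V at 100 uA) and the backed-disc limit
`1/(4 sigma a)` (2.50 V).  The default configuration gives ~2.48 V
(single-side) — inside the band, near the backed-disc limit, as expected
for a disc on a 400 um-wide insulating shaft.

The published VTA magnitudes (0.63-4.28 mm^3 double-side, 0.17-1.24 mm^3
single-side) are likewise not reproducible from the stated parameters:
with sigma = 0.2 S/m and a -0.5 V threshold, a 200 uA total source reaches
-0.5 V only ~0.16 mm from the site, far short of the ~0.5 mm radius their
volumes imply.  The package therefore reproduces the *structure* of those
results — VTA strictly increasing in |I|, double-side >= single-side at
every current — and reports its own magnitudes.

## VTA estimation

A tissue voxel is activated when `V <= threshold` (inclusive; default
-0.5 V for cathodic stimulation).  Volume = voxel count x voxel volume.
Substrate and metal voxels are never counted.  The marching-cubes
isosurface of the same level set, with its enclosed mesh volume, is an
independent cross-check: on the closed-form `-c/r` field (level set an
exact sphere) both estimators agree with `4 pi/3 mm^3` to well under 1%
at 20 um voxels.  The activating quantity is the potential itself, not
the activating function or |E|; threshold sign mismatches with the
stimulus polarity warn rather than fail.

A note on limits: since activation is `V <= threshold` and the cathodic
field is negative, the VTA shrinks as the threshold deepens — a
threshold of -inf captures nothing and a vanishing threshold captures
all tissue at negative potential.

## Recording analysis

The analysis chain is standard extracellular practice.  MUA is extracted
with a 4th-order Butterworth band-pass, 500 Hz-5 kHz, applied
forward-backward (zero phase, so spike timing is preserved); the filter
order is a choice of this package since only the band is published.
Spikes are detected where |x| exceeds `k` times the robust noise SD
`median(|x|)/0.6745` (default k = 4.5), with a 1 ms refractory merge and
peak-to-peak measured within +-0.8 ms of the event extremum.  The
detector is scale-invariant by construction and its false-positive count
on pure Gaussian noise matches the `2 Phi(-k) N` tail bound.

SNR is the mean spike peak-to-peak amplitude divided by the RMS of
background noise, background meaning samples at least 2 ms from every
event.  The mean peak-to-peak is taken from the event-triggered *average*
waveform rather than averaging per-event extrema: at SNR 3-7, per-event
extrema are biased upward by roughly the noise SD, which would
overestimate SNR by 20-30%; the averaged waveform removes this bias.  The
published per-nucleus SNR values (3.6, 6.3, 4.7 for striatum, GPi, STN)
come from in vivo data that is not available, so the statistic is
validated by parameter recovery instead: synthetic recordings constructed
at those SNRs are recovered within ~5% (mean over 10 seeds; the residual
positive bias comes from the analysis band-pass slightly narrowing the
already band-limited noise).

## Synthetic data

`gen_recording` emulates a 30 kHz extracellular channel as band-limited
Gaussian noise (filtered by the same Butterworth family, rescaled to the
requested RMS exactly) plus a stereotyped biphasic spike template at
homogeneous-Poisson event times (overlaps allowed, counted once).  The
template is negative-dominant (~70/30 after filtering, as for a somatic
extracellular spike) and is pre-compensated so its peak-to-peak *after*
the analysis band-pass equals the requested amplitude, making the
constructed SNR well-defined.  One master seed spawns independent
per-channel streams (`numpy.random.SeedSequence`); identical seeds give
bit-identical recordings.

What the generator does **not** emulate — spike-shape variability across
units, bursting and refractory structure, non-Gaussian and nonstationary
noise, stimulation artifacts, electrode drift — bounds what passing tests
show: they validate the statistics and the detector's calibration on
their stated model, not performance on real recordings.

`gen_point_source_field` provides the `-c/r` field (level sets are exact
spheres) used as the VTA oracle, with the singular voxel clipped at half
a voxel spacing.  `point_source_benchmark_grid` and `disc_benchmark_grid`
build the solver benchmark domains with embedded spherical grounds.

## Problem sizes used in tests and the acceptance script

Default-resolution solves use the 1.4 x 1.4 x 2.0 mm / 10 um grid
(~3.9M cells, two direct solves).  Property and linearity tests run on a
reduced 1.0 x 1.0 x 1.4 mm / 15 um grid; the disc benchmark runs at 5 um
(2.5 um for the refinement check) on hemisphere domains of 0.15-0.25 mm
radius; the point-source benchmark on a 96^3 / 20 um cube; SNR recovery
on 10 s, 30 kHz single-channel recordings over 10 seeds per condition.

## Known limitations

* Regular voxel grids only; no adaptive or boundary-fitted meshing, so
  disc edges carry an O(h) discretization bias (quantified by the
  benchmarks and decreasing under refinement).
* Isotropic, frequency-independent tissue; no electrode-electrolyte
  interface impedance; no encapsulation layer.
* The probe pose is axis-aligned with the domain.
* Potential-threshold VTA is a proxy; axon-model-based VTA is out of
  scope.
* Spike detection is amplitude-threshold only; no sorting, and at
  constructed SNR below ~5 the detector necessarily misses events whose
  in-band peak sits near the threshold (SNR recovery therefore uses
  ground-truth event times).
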