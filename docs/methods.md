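# Methods

This note documents the models, numerical choices and known limitations of
`ipdtplan`. It is the companion to the README's usage-level description.

## Tissue model

The simulation domain is the voxel grid of the patient's T1-weighted MRI:
each voxel carries one of seven tissue labels (CSF, grey matter, white
matter, necrotic tumor, non-enhancing tumor, enhancing tumor, perilesional
oedema) plus a background label for extracranial space. The integer coding
(0 background, 1 CSF, 2 grey, 3 white, 4 necrotic, 5 non-enhancing,
6 enhancing, 7 oedema) is fixed by this package; segmentation tools name the
classes but assign no codes.

Per-tissue optical properties at 635 nm (absorption μₐ and scattering μₛ in
mm⁻¹, Henyey–Greenstein anisotropy g, refractive index 1.40 for every
cerebral class) ship as a versioned plain-text table
(`src/ipdtplan/data/tissue_table_635nm.tsv`) and can be overridden per run.
The table's values are treated as exact constants — the sources behind them
are published medians without stated uncertainty. Two quirks of the table
are intentional and taken as published rather than "corrected": oedema
shares white-matter values, and non-enhancing tumor combines white-matter
absorption with a much higher scattering coefficient (69.7 mm⁻¹).

Units are deliberately split: interaction coefficients and all geometry are
per-mm/mm (native to both the table and the stereotactic frame), while
fluence rate and fluence are reported per cm² because the therapeutic
threshold is defined that way. The single mm⁻²→cm⁻² factor lives in
`units.py`; nothing else in the package converts areas.

## Source model

Cylindrical diffusers (available lengths 2, 2.5, 3, 4, 5 cm; linear power
200 mW/cm regardless of length) are modelled as **isotropic line sources**
on the fiber axis; the physical diffuser radius is neglected. The diffusing
segment ends at the trajectory's target point and extends back toward the
entry point — the convention matches how the fiber is advanced to its
target, and is explicit in `diffuser_segment` should a different convention
ever be needed.

The axial emission density is a super-Gaussian
p(z) ∝ exp(−((z−c)²/2w²)ᵏ) on [0, L]: k = 1 recovers a Gaussian, large k a
top-hat, which spans the flat-topped profiles measured on real diffusers.
Parameters (amplitude, c, w, k) are fitted to a measured two-column profile
by bounded least squares with restarts over initial orders k₀ ∈ {1, 2, 3, 5};
the order is bounded below at 1. When no measurement is supplied, a flat-top
default (k = 3, w = 0.42 L, c = L/2) is used.

Launch positions are drawn by numeric inverse-CDF sampling on a 4097-point
grid over [0, L] — dense enough that the interpolation error is orders of
magnitude below Monte Carlo noise (the Kolmogorov–Smirnov distance of 10⁵
samples to the analytic CDF is ~0.003, dominated entirely by sampling
noise). Launch directions are isotropic; packets start with unit weight.

## Transport engine

A voxelized packet Monte Carlo in the classic hop/drop/spin form:

- dimensionless step s = −ln ξ, consumed across voxels as physical length
  s/μₜ with exact ray–voxel boundary sub-stepping (no interpolation across
  heterogeneity boundaries);
- at each interaction, deposit w·μₐ/μₜ, then scatter with the
  Henyey–Greenstein cosine cosθ = (1+g²−((1−g²)/(1−g+2gξ))²)/2g (isotropic
  limit 2ξ−1 at g = 0);
- Russian roulette below weight 10⁻⁴ with survival probability 0.1
  (both configurable);
- voxels with μₜ = 0 are crossed in free flight (fluence still accumulates
  there; fluence exists without interaction).

Boundary conditions: all cerebral tissue shares n = 1.40, so there are no
internal Fresnel events to model; the grid's exterior boundary and any
background voxel terminate the packet as an escape (matched boundary). This
is the simplest defensible choice — extracranial propagation is not a
planning quantity — and it slightly *underestimates* fluence within roughly
one transport mean free path of the skull/background interface.

Two per-voxel fluence estimators are tallied from the same packets:

- **track-length** (default): Σ w·chord / (V·N) × P — well-defined
  everywhere, including CSF (μₐ = 0.004 mm⁻¹) where the absorption
  estimator becomes noisy or degenerate;
- **absorption** (cross-check): deposited / (μₐ·V·N) × P.

On homogeneous phantoms the two agree within Monte Carlo error; the pair is
exercised as an internal oracle in the test suite. Conservation is reported
per run: with roulette disabled the identity launched = deposited + escaped
holds to float round-off because packets falling below the weight floor
deposit their residual locally (a ~10⁻⁴ relative transfer of far-tail energy
into the termination voxel); with roulette enabled the identity holds in
expectation.

Reproducibility: every packet owns an xorshift64* stream seeded by a
splitmix64 hash of (run seed, packet index); launch positions/directions
come from a PCG64 generator seeded from the same run seed. Identical
(grid, source, packet count, seed) therefore give bit-identical tallies,
independent of any batching of the packet loop. Per-fiber seeds in a plan
are derived deterministically from the plan seed, so a multi-fiber result
is exactly the superposition of its single-fiber runs. The engine is a
single-threaded numba kernel; ~1.3×10⁵ packets in a strongly scattering
100³ phantom run in ~15 s after JIT compilation.

The default packet count is 131,072 (2¹⁷) per fiber — enough that the
treated-volume readout varies by well under 1% between seeds — and is
exposed as a parameter.

## Dosimetry

Per-fiber fluence-rate maps are summed voxelwise, multiplied by the
illumination time (default 3600 s; 1 mW/cm² × 1000 s = 1 J/cm²), and
thresholded:

- treated volume: fluence **strictly greater than** 25 J/cm², in cm³;
- high-dose display volume: strictly greater than 250 J/cm².

Strict inequality is the documented reading of "higher than"; both
thresholds accept a `strict=False` switch for sensitivity analyses. An
optional per-tissue photosensitizer weighting (default ratio 100:1
tumor:healthy, reflecting PpIX selectivity) can multiply fluence before
thresholding; it is **off** by default because the treated volume is
defined on fluence alone, and whether reported clinical volumes include
such weighting is not established.

The coverage index is 100·|treated ∩ target|/|target| on the common grid.

## Plan geometry and validation

Stereotactic coordinates are millimetres in the frame of the volume's
affine (X medial-lateral, Y anterior-posterior, Z cranial-caudal);
world↔voxel transforms use the voxel-center convention with 0-based
indices, and the transport kernel requires an axis-aligned affine.

Validation rules, all reported as alerts (never exceptions) so the planner
can iterate:

- **spacing**: closed diffusing segments of any fiber pair must be
  ≥ 9 mm apart (closed-form segment–segment distance); exactly 9 mm
  passes. The limit guards against the thermal hot spot (> 43 °C) between
  close diffusers; it is configurable down to 7 mm, but the default stays
  at the hard 9 mm rule.
- **crossing**: the full entry→target insertion paths (not just the
  diffusing parts) must not approach within a clearance (default 1 mm) —
  two physical guides cannot co-occupy space. Applying the rule to full
  tracks is this package's choice and is deliberately the conservative
  reading.
- **length**: diffuser length must be one of {20, 25, 30, 40, 50} mm.
- **containment**: entry, target and diffusing part must lie inside the
  grid when one is supplied.

Simulation and report export refuse to proceed while alerts remain,
mirroring the gate-ordered clinical workflow. The report embeds per-fiber
coordinates, lengths, powers, fitted emission parameters, seeds,
conservation summaries, the dosimetry summary, and a config hash so every
number is re-derivable from the archive.

## Synthetic phantoms

The phantom generator emulates the *output* of a seven-class segmentation,
not MRI intensities: a white-matter brain sphere with a 3 mm grey cortical
shell, two ventricle-like CSF ellipsoids, and a concentric tumor (necrotic
core 6 mm, enhancing rim 10 mm, non-enhancing 14 mm, oedema shell 20 mm by
default) at 1 mm isotropic resolution on a ~120³ grid; a 60³ fast profile
with proportionally smaller radii serves quick runs. The target mask is the
union of the three solid-tumor compartments, optionally extended into the
oedema (the target-definition question is genuinely open clinically).
Geometry is deterministic; only the emission-profile generator consumes its
noise seed.

What the phantom does **not** emulate — irregular infiltrative tumor
margins, segmentation errors, resection cavities, skull/scalp layers,
partial-volume labels — bounds what passing tests show: they validate the
transport physics, the dosimetry algebra and the workflow contracts on
known geometry, not segmentation robustness on real anatomy.

## Verification strategy and problem sizes

The suite checks the engine against independent oracles: diffusion theory
(point source in white matter, agreement within 15% over r = 2–8 mm at
131,072 packets), Beer–Lambert in a purely absorbing medium (within 3σ over
seeds, against the analytic kernel averaged over voxel volumes — evaluating
it at voxel centers would alias the 1/r² curvature), exact weight
conservation, mirror symmetry, estimator agreement, and refined
dense-sampling for segment distances. The headline single-fiber simulation
uses the full default packet count on a 100³ grid; most unit tests run
3,000–50,000 packets on 40–60³ grids, sizes chosen so the whole suite
completes in a few minutes while keeping every statistical check at ≥3σ
sensitivity.

## Known limitations

- No polarization, no time-resolved transport, no thermal modelling (heat
  enters only through the 9 mm spacing rule).
- No photobleaching, oxygen depletion or fractionation kinetics; fluence is
  the sole dose surrogate.
- The matched exterior boundary ignores index steps at bone/air; fluence
  near the skull is slightly underestimated.
- The line-source model neglects the diffuser's physical radius and any
  bending losses; emission is assumed axially symmetric.
- Measured diffuser profiles are bench data; in-tissue emission may differ.
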