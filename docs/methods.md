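# Methods

## The mapping procedure

The pipeline localizes heterogeneous published gray-matter coordinates onto
common functional networks through a normative resting-state cohort. Its
statistical chain per study contrast is: sphere-union seed → per-subject
seed-to-voxel Pearson r → Fisher z = atanh(r) → one-sample t across
subjects → Benjamini–Hochberg FDR over the in-mask voxel family at
q = 0.05 → restriction to t > 0 → binarization. The K binary maps are
averaged into an overlap probability map and thresholded inclusively at
0.5: a voxel belongs to the network iff at least half of the contrast
seeds are functionally connected to it.

Assumptions worth stating explicitly:

- **Seed aggregation** is the unweighted mean over seed voxels. The
  first-principal-component alternative is a config option; with the small
  seeds used here (a handful of voxels) the two are nearly identical.
- **Two-sided p, then positive masking.** The composition of the FDR step
  with the positive-connectivity restriction is genuinely open; we apply BH
  to two-sided p-values and then keep surviving voxels with t > 0. A
  one-sided mode is available. The two-sided default is slightly
  conservative for positive effects.
- **The t-test treats subjects as exchangeable** and the Fisher z values as
  approximately normal per voxel; z variance across subjects is ≈ 1/(T−3)
  for null correlations, so T ≥ 30 is enforced in the synthetic cohorts.
- Correlations are clipped to ±(1 − 1e−7) before atanh so the seed's own
  voxels stay finite; zero-variance voxels get z = 0 and a QC flag.

## Geometry and voxelization

All volumes live on a shared grid with a NIfTI RAS+ affine; voxel indices
are 0-based and nearest-voxel assignment rounds the continuous index.
Spheres are voxelized on the 3-mm analysis grid by a closed-ball test on
voxel-center distance, **plus the voxel containing each in-grid
coordinate**. The addition matters only when the radius is below the voxel
spacing (the 1-mm sensitivity setting on a 3-mm grid), where a pure
center-distance test would frequently produce empty seeds; with it, a 1-mm
seed degrades gracefully to the single containing voxel, which is also the
behavior of common neuroimaging seed tools.

Gaussian smoothing uses σ = FWHM/(2√(2 ln 2)) per axis in mm, converted to
voxel units, with reflective padding (conserves mass for interior
structures). Kernels with σ below about half a voxel are resolution-limited:
the discrete kernel then deviates from the continuous Gaussian, and the
semigroup identity (smoothing by a then b equals √(a²+b²)) holds only for
FWHMs comfortably above the grid spacing. The pipeline default of 6 mm on a
3-mm grid is safely inside that regime.

Talairach coordinates are converted through a named 4×4 affine shipped as
data (a Lancaster-style pooled matrix, inverted at load); any matrix can be
registered at run time, because published conversions differ and the choice
should be swappable, not hard-coded.

## Time-series preparation

Order: discard the first 10 volumes → gross-motion gate (fail if any axis
strictly exceeds 2 mm translation or 2° rotation) → simultaneous nuisance
regression → 0.01–0.1 Hz bandpass. Regressing all nuisance terms at once
(constant, linear trend, Friston-24, per-spike one-hot columns for frames
with FD > 0.5 mm strictly, optional global signal, WM and CSF series)
avoids reintroducing variance that sequential regression leaves behind;
the residuals are orthogonal to every design column by construction
(pseudoinverse projection, so rank-deficient designs behave as if
dependent columns were dropped).

Framewise displacement is the Power form: FD_t = Σ|Δtranslations| +
r·Σ|Δrotations| with r = 50 mm and rotations in radians; FD_0 = 0. It
depends only on frame-to-frame differences, hence is invariant to constant
offsets. The bandpass is an ideal rectangular filter in the frequency
domain (bins with low ≤ f ≤ high kept, DC always removed): zero-phase and
idempotent, matching the style of the common resting-state toolchains, and
trivially verifiable by FFT.

WM/CSF signals are accepted as given series rather than derived from
tissue masks; the synthetic cohort has no tissue classes to segment.

## Synthetic data: what it emulates and what it does not

`simulate_cohort` plants networks as unions of spherical components whose
voxels share, per subject, a band-limited (0.01–0.08 Hz) unit-variance
latent signal with loading w on top of i.i.d. N(0, σ²) noise; background
voxels are pure noise; the GM mask is an ellipsoid envelope. The expected
within-network voxel-pair correlation is w²/(w² + σ²) — 0.5 at the
reference w = σ = 1 — which the tests verify by Monte Carlo. The latent
band lies inside the 0.01–0.1 Hz analysis band so filtering preserves the
planted structure. Latents are independent across subjects and networks.

The generator does **not** emulate hemodynamic response shapes, scanner
noise spectra (1/f, physiological cycles), spatial autocorrelation of the
noise, motion-correlated artifacts, or inter-subject anatomical
variability. Passing the recovery benchmarks therefore demonstrates that
the statistical chain is correctly implemented and well calibrated under
its stated model — not that the pipeline is robust to every property of
real fMRI.

Reference benchmark setting (chosen once as a realistic desk-scale
analogue of a normative-cohort analysis): grid 20×24×20 at 3 mm
(≈ 6,600 GM voxels), 20 subjects, T = 120 at TR = 2 s, one planted network
of three 9-mm components, w = σ = 1; 8 synthetic studies with one contrast
of 2 foci each, foci drawn from the truth mask with 3-mm jitter. Null
calibration uses 20 cohorts of 10 subjects with no planted network and
seeds from uniform GM foci. Permutation calibration uses P = 100 parcels,
500 permutations, 200 replicates; correlation recovery uses ρ = 0.4 over
50 replicates.

Receptor maps with a target Spearman ρ are built on standardized ranks,
y = w·z(rank(x)) + √(1−w²)·ε, with the mixing weight w calibrated by
brute-force simulation (a cached grid of achieved-ρ values, inverted by
interpolation), because rank correlations of Gaussian mixtures have no
convenient closed form.

## Neurochemical association

The network input to the spatial correlation defaults to the unthresholded
overlap-probability map restricted to GM — richer than the binary mask —
with the binary mask or group-z selectable. The correlation is Spearman by
default (Pearson available), computed over shared parcels of a Voronoi
parcellation (or any supplied label image). The permutation null uniformly
shuffles parcel assignment, so it is exchangeable but not
spatial-autocorrelation preserving; a `null="spin"` hook is reserved for a
spatially constrained null and currently raises. p-values use the add-one
rule (b+1)/(n_perm+1) and are BH-adjusted across the tracer family.

## Numerical choices and degenerate inputs

- FDR family = in-mask voxels; an empty mask is an error, all-p = 1 yields
  an empty map.
- Zero across-subject variance at a voxel: signed infinite t sentinel with
  p = 0 (p = 1 when the mean is also zero) and a QC flag, so degenerate
  voxels are visible rather than silently NaN.
- Thresholds are inclusive where the rule says "at least": probability
  ≥ 0.5, involvement ≥ 20%; FD spike flagging is strict (> 0.5 mm), as is
  the motion gate ("exceeding").
- Probability maps store exact fractions; prob·K integrality is asserted
  to 1e-9.
- All stochastic code paths take explicit seeds; pipeline runs with the
  same config and seed are byte-identical.

## Pipeline engineering

The orchestrator validates geometry before computing, writes a JSON
manifest for every run (including failures) that echoes the full config —
sufficient by itself to replay the run — and logs per-stage voxel counts.
Sensitivity runs share the loaded cohort in memory rather than caching
per-contrast t-maps on disk: at the package's problem sizes the FC step
costs seconds, and a hash-keyed disk cache would add invalidation risk
without measurable benefit.

## Known limitations

- The exchangeable permutation null ignores spatial autocorrelation and is
  anticonservative for smooth maps; use the spin-test hook once a surface
  or geodesic model is available.
- The positive-only restriction discards negative connectivity entirely;
  interpretation of anticorrelations (especially under global signal
  regression) is left out of scope.
- Study contrasts are unweighted: a 30-subject study contributes to the
  overlap denominator exactly as a 364-subject study does.
- The packaged included-studies table demonstrates ingestion with synthetic
  placeholder coordinates; reproducing a published network map requires the
  original peak tables and a real normative cohort.
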