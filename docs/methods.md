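# Methods

`structloc` implements an integrative structural-localization workflow: an
atomic domain structure is placed in a 3D density map by exhaustive
rigid-body correlation docking; the position of a fluorescent acceptor is
localized independently by FRET-based trilateration; atomic models are
compared quantitatively against each other and against maps; and the two
quantitative wet-lab assays that accompany such studies — thermal-shift
melting and one-site ligand binding — are fitted. Every stage can be driven
by the synthetic-data module, which generates inputs with known ground
truth so the whole pipeline is testable without any external downloads.

## Density simulation and scoring

A structure is blurred to a stated resolution by giving every heavy atom an
isotropic 3D Gaussian centred on its coordinate, with FWHM equal to the
resolution (σ = resolution / (2√(2 ln 2))) and total integral equal to the
atomic number. The FWHM convention is the common real-space one; it is a
package choice, documented so alternatives can be swapped in. Hydrogens are
excluded everywhere (crystal models carry riding hydrogens that are
refinement artifacts). Kernels are truncated at 4σ, which keeps >99.8% of
each atom's mass, so discrete integrals match ΣZ to well under 1% — this is
verified by test. The grid spans the heavy-atom bounding box plus a padding
margin; `simulate_on_grid` rasterizes onto an existing grid for map-model
comparison.

The Laplacian filter is the discrete 6-neighbour stencil (face neighbours
minus 6× centre, unit lattice spacing). Boundary voxels replicate the edge
value rather than assuming zero outside: with zero padding a constant map
would filter to nonzero values at the boundary, violating the defining
annihilation property of the Laplacian. Interior behaviour is identical
either way.

Map-map similarity is the Pearson correlation over a voxel mask: the full
grid, or (`model_support`) the voxels where the model-derived map exceeds
10% of its maximum. Maps on different grids are first resampled onto the
target grid by trilinear interpolation; the first argument's grid is
authoritative.

## Exhaustive six-dimensional docking

The search enumerates a deterministic, near-uniform grid of orientations —
a super-Fibonacci spiral on the quaternion hemisphere — sized so the
covering radius matches the requested angular step (empirical covering
constant ≈ 60 rad³: n = 60/step³). For each orientation the probe is
rotated about its centroid, blurred onto the target grid, and all
voxel-granular translations are scored at once by FFT cross-correlation;
because the probe's sums are translation-invariant while its support stays
inside the grid, a single FFT yields the exact full-grid Pearson score for
every valid shift. Translations that would wrap the probe's support around
the periodic grid are masked out. The spherical-harmonic acceleration of
the original rotational-search tools is deliberately not reproduced; the
contract (unbiased 6D search, ranked correlations) is identical at desk
scale.

With Laplacian filtering enabled, **both** the target and the probe map are
filtered before correlation. Filtering only the target would anticorrelate
the probe with the (negative-cored) filtered density at the true pose and
invert the ranking; filtering both is what gives the documented behaviour —
extra penalties for mismatches in surface features — and is required for
the recovery property to hold. No density cut-off is applied in Laplacian
mode: the full grid is correlated, so the surface penalty comes from the
filter rather than a mask.

Per-orientation best hits are clustered greedily in score order: a hit
joins a cluster if it is within 2× the angular step in rotation *and* 1.5×
the voxel in translation of the representative; otherwise it founds a new
cluster. Scores are reported raw and normalized by the top hit (hit 1 has
normalized score 1 by construction). Ties break by enumeration order, so
the search is bit-deterministic given (map, probe, step).

Local refinement maximizes the correlation over the 6 pose parameters with
Nelder-Mead (rotation-vector offset in degrees, translation in Å), keeping
the best pose ever evaluated so the returned correlation can never fall
below the starting one; the simplex terminates at ~0.25°/0.1 Å. Poses that
push the probe centroid outside the map incur a penalty and trigger a
boundary warning.

Default angular step is 20° for tests and routine use, 10° for production
runs; 20° plus refinement recovers generative poses of noiseless and
SNR ≥ 2 synthetic maps to well under 1°/0.5 Å in the bundled tests.

A caveat the synthetic tests exposed: compact multi-helix toys at low
resolution acquire pseudo-symmetries (two parallel helices are nearly C2;
an equilateral helix triangle at 8 Å is nearly D3), and the search then
legitimately returns a symmetry-related pose with an equal score. Recovery
assertions therefore use asymmetric toys (jittered 12-20-residue helices at
6 Å), and placement quality in symmetric settings is judged by
re-computed correlation, not coordinate identity.

## FRET conversion and trilateration

Acceptor-photobleach efficiency is E = 1 − F_pre/F_post; distances follow
the Förster relation R = R0 (1/E − 1)^(1/6) with R0 = 59 Å for the
AF488/Cy3NTA pair (both standard forms, adopted as the package's reading of
the variable definitions). Per-cell efficiencies from one donor site are
averaged first and the mean converted to a single distance (the
distance-averaging alternative is exposed as an option but is biased by the
convexity of the conversion). Distance uncertainty is first-order
propagation |dR/dE|·SEM. Sites with non-positive mean efficiency (no
detectable transfer) are flagged and excluded from trilateration.

The acceptor locus is the intersection of spherical shells: a voxel is
occupied iff every constraint satisfies |‖x − donor_i‖ − R_i| ≤
max(grid_step, tolerance_scale × uncertainty_i), on a grid spanning the
union of shells (default step 2 Å, tolerance scale 1). The locus exports as
an MRC occupancy map for rendering as a volume. Point membership
(`contains`) is evaluated against the analytic shell predicate — the grid
is a rendering, and voxel-centre sampling would inject up to √3/2·step of
quantization error into containment checks.

The point estimate minimizes Σ wᵢ(‖x − donorᵢ‖ − Rᵢ)² with inverse-variance
weights (unit weights when uncertainties are absent), multi-started from
the donor centroid, a linearized closed-form multilateration solution,
points offset from each donor, and — because the objective is
mirror-symmetric about the donors' best-fit plane, trapping in-plane
starts — two starts offset along the plane normal. With exactly three
non-collinear donors both mirror solutions are reported and an ambiguity
flag is set; collinear donors raise a degeneracy error.

Probe (dye) positions are modelled with a uniform accessible-volume
sampler: n uniform draws in the linker-length ball around the attachment
atom (defaults: 20 Å linker, 3 Å clash distance), rejecting draws within
the clash distance of any other heavy atom; the cited simulated-annealing
dye-placement protocol is not described in the source literature available
here, and the accessible-volume model fills the same contract (a physically
plausible dye centroid) in a testable, deterministic way.

### Synthetic geometry and what it shows

The five default donor sites are pairwise 28-56 Å apart, the spacing scale
of the FKBP labelling positions. Two target geometries are used, for two
different questions:

* the **FRET pipeline** target sits 47-68 Å from every donor (0.8-1.16 R0,
  efficiencies 0.3-0.8). This is the regime a trilateration experiment is
  designed for: nearer donors saturate (E → 1), where clipped measurement
  noise biases converted distances by several Å — a genuine property of the
  sixth-power law, not of this implementation.
* the **solver recovery** benchmark (direct distance noise, σ = 2 Å) uses a
  target inside the donor cloud, where the Cramér-Rao bound is ≈3 Å RMS.
  For the exterior FRET-band target the bound itself is ≈4.6 Å RMS
  (geometric dilution of precision: the donors subtend a small solid
  angle), so no correct solver could achieve a 3 Å median there.

Passing tests therefore demonstrate correct conversion, well-behaved
least squares, and honest uncertainty propagation — they do not claim that
trilateration is accurate for acceptors far outside the donor constellation
or at near-saturating transfer.

## Model comparison

Superposition is least-squares (SVD with determinant sign correction, so a
proper rotation is always returned); it is cross-checked in tests against
an independent Horn quaternion-eigenvalue oracle. Per-residue RMSD uses one
global superposition over all paired selected atoms (Cα-only by default;
backbone and all-heavy as options), then the per-residue RMSD of that
residue's atoms; residues missing atoms are skipped and listed in the
alignment note. Residue pairing across numbering schemes is an explicit
user-supplied map — no automatic sequence alignment.

SASA is Shrake-Rupley quadrature with a deterministic Fibonacci sphere
(default 960 points/atom, probe 1.4 Å); buried interface area is half the
SASA lost on complex formation (the total loss is also reported, since the
convention behind published burial figures is often unstated). VDW contacts
are residue pairs with any interatomic distance ≤ r₁ + r₂ + 0.4 Å. VDW
radii come from a bundled element table (C 1.70, N 1.55, O 1.52, S 1.80 Å,
default 1.70).

Per-segment map correlation simulates the full model onto the target grid
and correlates experimental vs simulated density over voxels within 3 Å
(default) of each secondary-structure segment's atoms.

## Assay fits

Melt curves are min-max normalized, smoothed with a Savitzky-Golay window
(7 points, order 2), and differentiated by central differences. Melting
temperatures are prominence-filtered maxima of +dF/dT (unfolding increases
reporter-dye fluorescence), restricted to temperatures before the global
fluorescence maximum to exclude post-aggregation decay; default prominence
threshold is 0.1 of the derivative range, which separates genuine second
transitions from shoulder noise in the two-transition scenario (midpoints
33.6/39.6 °C) while ignoring wiggles. Peak positions are refined by
parabolic interpolation, giving sub-grid (< 0.5 °C on the 0.5 °C protocol
grid) accuracy. When two transitions overlap, each derivative peak is
pulled slightly toward the other (≈0.3 °C at 6 °C separation) — an inherent
property of derivative-based Tm reading, within the stated tolerance.

Saturation binding is an unweighted least-squares fit of
B_max·c/(K_d + c) + baseline with deterministic initialization (baseline
from the signal minimum, B_max from the span, K_d from the half-saturation
concentration); the baseline is fitted, not forced to zero, because cell
assays carry background fluorescence. Fits with no curvature in the sampled
range (K_d beyond 10× the largest concentration, or non-finite/huge errors)
warn rather than fail. Dissociation is A·exp(−t/τ) + baseline with
log-linear initialization; k_off = 1/τ. Standard errors come from the
residual-based covariance.

## Synthetic data

All generators are pure functions of their arguments including the seed
(numpy `default_rng`), so regeneration is bit-identical. Toy structures are
ideal poly-alanine α-helices built by internal-coordinate chaining
(φ = −57°, ψ = −47°, standard bond geometry; Cα-Cα 3.80 Å, rise 1.55
Å/residue) packed on a 10 Å hexagonal grid with small seeded rigid jitter,
with SSE annotation attached. Noisy maps add white Gaussian noise with
variance = (signal variance over model support)/SNR. Melt curves are sums
of logistic transitions on the 25-95 °C, 0.5 °C protocol grid plus a dye
baseline and a linear post-transition aggregation decay. Binding series are
8 log-spaced concentrations (K_d/30 to 30 K_d) and 12 time points (0 to
5/k_off) with multiplicative Gaussian noise.

What the generators do **not** emulate: cryo-EM image formation (CTF,
projection artifacts, anisotropic resolution), dye orientation effects
(κ²), donor bleed-through corrections, non-Gaussian experimental noise, and
conformational flexibility. Passing the bundled tests shows the algorithms
are correct on data obeying the stated models; it does not certify
performance on real micrograph-derived maps or live-cell FRET panels.

## Problem sizes

Test and acceptance runs use 3-helix toys (60 residues, 300 atoms), maps of
roughly 40³ voxels at 1.5 Å, a 20° orientation grid (~1400 orientations),
and 100-replicate noise ensembles — sizes chosen so the full validation
suite runs in a couple of minutes on one CPU while every recovery claim is
still exercised end to end.
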