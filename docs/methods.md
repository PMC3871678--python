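# Methods

This note documents the models inside `neuroscale`, the choices made where
the design was genuinely open, and what the synthetic setting can and
cannot say about real data.

## Synthetic head

Each hemisphere is a closed icosphere mesh (subdivision level L gives
10·4^L + 2 nodes; L=6 gives the canonical 40962) deformed radially,

    r(u) = R0 + A · f(u),

where f is a band-limited spherical-harmonic gaussian random field
(degrees 12–24, giving gyral wavelengths of roughly 1.6–3.2 cm at the
default radius), soft-clipped with tanh at ~1.5σ so that |f| < 1 and A is
the true maximum excursion.  A is calibrated by root finding so each
hemisphere's total area hits 1100 cm², the adult human value.  The
undeformed unit vertex of every node is retained as its spherical mapping,
mirroring how surface-reconstruction pipelines keep a sphere coordinate
per vertex; the left hemisphere is the mirror image of an independently
drawn (optionally identical) fold field.  A 15° polar cap on the medial
side of each hemisphere is flagged non-cortical (medial wall) and carries
zero activity.

Defaults: R0 = 6.2 cm, shells (inner skull / outer skull / scalp) =
8.2/8.7/9.2 cm.  The calibrated amplitude comes out near 1.4 cm, so gyral
crowns reach ~7.6 cm — about 1.6 cm below the scalp — and the ratio of
folded to unfolded area (a gyrification index) is ≈ 2.3.  Both values sit
in the textbook adult range, which is how R0 was fixed; the sensor
correlation structure of EEG in particular is sensitive to cortical depth,
and the anatomical mid-range is also the regime in which the model
reproduces the reference behavior.  Both hemispheres are concentric with
the conductor: the shell model and the spherically-symmetric MEG
formulation require the conductor center to be the origin, and radial
dipoles on an unfolded hemisphere are then exactly silent in MEG — one of
the structural checks in the test suite.  A `center_offset` parameter can
shift the cortex superiorly to mimic the brain sitting in the upper
cranium; it is off by default because it inflates MEG correlation
distances well past the reference values.

Vertex normals are area-weighted face normals of the folded mesh (exactly
radial in the smooth limit, where the discrete estimator's facet bias is
bypassed analytically); node areas are one third of the adjacent triangle
areas, so they sum to the exact mesh area.

## Activation patterns

A scale is defined by its seed count per hemisphere, one of
{1, 6, 14, 42, 162, 642, 2562, 10242, 40962}.  The icosahedral counts use
the nested icosphere lattices; 6 uses the axis directions (±x, ±y, ±z); 14
adds the eight quadrant midpoints (±1,±1,±1)/√3; 1 picks a uniformly
random cortical node.  (The count sometimes quoted as 2565 — an
icosahedral lattice plus surface-closure bookkeeping nodes — is
implemented as the exact 2562 ico4 lattice; the quoted value is recorded
in the scale metadata.)  The per-node cortical area is hemisphere cortical
area divided by seed count, and the gaussian smoothing FWHM is the
estimated inter-seed spacing √(area), expressed on the unit sphere through
the effective folded radius √(hemisphere area / 4π).

Per instance: i.i.d. N(0,1) seed values, gaussian convolution of the seed
impulses over chordal distance (truncated at 3×FWHM; beyond ~6 kernel
sigmas, i.e. below 1e-9 of the peak weight, neighbors are not gathered),
one uniform random rotation (unit quaternion) of the spherical field, a
sample at every node's sphere coordinate for both hemispheres, medial-wall
zeroing, and a z-transform over cortical nodes.  The convolution is
deliberately *not* normalized per node: plain convolution of seed
impulses is what makes the single-seed scale a blob rather than a
degenerate constant, and the z-transform absorbs the amplitude
non-uniformity.  The z-transform is applied per pattern (not pooled over
the ensemble) and after masking, so the documented mean-0/SD-1 invariant
holds exactly for the cortical nodes of every instance.

The generator reproduces: spatial correlation length tracking the FWHM
(the gaussian-kernel prediction puts the r=0.5 falloff at ~0.7 FWHM),
monotone growth of near-pair correlation with scale, uniform per-node
variance under rotation randomization, and bitwise determinism under a
fixed seed.

## Forward models

**EEG.** Unit current dipoles along the node normals in three concentric
shells with conductivities 0.3/0.006/0.3 S/m.  The potential is a Legendre
series; the per-degree radial transfer factor is obtained by propagating
the zero-current scalp condition inward through 2×2 value/flux layer
matrices, which reduces to the classic (2l+1)/l factor for a homogeneous
sphere (a test compares against an independently derived decomposition,
and against MNE's sphere model, r > 0.99999).  The series is truncated
when the largest remaining term falls below 1e-8 of the accumulated
potential.  Topographies are average-referenced by default; an
infinity-reference option exists.

**MEG.** Sarvas' closed-form field of a current dipole in a spherically
symmetric conductor (volume currents included analytically; the result is
independent of the conductivity profile, which is why the shell structure
does not enter).  Magnetometers read the radial component at the sensor;
planar gradiometers take the finite difference of that component across a
1.68 cm tangential baseline, two orthogonal baselines per site.

**DOT.** Continuous-wave Rytov sensitivity,
A(sd, r) = Φs(r)·Φd(r)/Φ(source→detector), with Φ the semi-infinite
diffusion Green's function (extrapolated boundary, effective reflection
coefficient 0.493 for tissue–air) for μa = 0.1 cm⁻¹ and μs′ = 10 cm⁻¹ —
typical adult head values, declared rather than fitted.  Each optode's
half-space is its scalp tangent plane; nodes behind the plane get zero.
The normalizing fluence uses the optode chord distance, making every
channel exactly reciprocal under source–detector exchange.

**fMRI.** Cortical nodes are binned into an axis-aligned 3 mm voxel grid.
A voxel is kept if it contains ≥ 4 nodes and its approximate gray-matter
fraction — node count × mean node area × an assumed 3 mm cortical
thickness / voxel volume, capped at 1 — is ≥ 0.5; kept voxels average
their member nodes uniformly.  Because the synthetic surface has no
gray/white ribbon, the thickness constant stands in for the volumetric
gray-matter calculation; it is recorded in the model metadata.  A z-window
restricts the analysis to a single horizontal slice (the full-resolution
profile uses a 3 mm slab at z ≈ 1.9 cm, the analog of a single-slice
analysis; at coarser meshes the node-count filter is density-matched,
e.g. ≥ 2 nodes at ico5, which carries a quarter of the ico6 node density).

All models are normalized per row to unit L2 norm before any simulation;
zero rows (e.g. a channel with no cortex in view) are dropped and
reported.

## Metrics

**CTF.**  Per sensor, RMS of the response over instances divided by the
RMS of the cortical activation (computed, ≈1 by construction); the
modality CTF is the sensor mean.  Note that with unit-norm rows and
*spatially correlated* patterns the CTF is not bounded by 1: a row aligned
with a coherent patch of n nodes approaches √n.  The implementation keeps
the faithful definition; the suite checks the scale ordering (EEG CTF
strictly decreasing toward smaller scales) and that fMRI voxel averaging
neither amplifies nor attenuates (CTF ≈ 1).

**Correlation distance.**  Pearson correlation of every sensor pair
across the instance axis ("pseudo-timecourse"); per sensor, the maximum
3D distance to any other sensor whose correlation *magnitude* exceeds
0.5, with the montage minimum separation as fallback.  Thresholding |r|
rather than signed r is a deliberate choice: it treats the anticorrelated
lobe of a dipolar EEG/MEG topography as connected, the usual sensor-space
functional-connectivity reading, and it is the convention under which the
reference behavior (EEG correlation distances of 12–14 cm, far beyond the
~60° bound that any signed-correlation concentric-sphere model can reach)
is reproducible.  A `signed` mode is available.  Gradiometer channels at
one site are distinct channels at distance 0; distances use the
channel positions (DOT: pair midpoints).

**Resolvable spatial pattern scale.**  Mean correlation distance vs log10
scale area is fitted with a cubic smoothing spline in the classic
p-convention (minimize p·Σ residuals² + (1−p)·∫f″², p = 0.95, solved by
the Reinsch linear system; the log abscissa reflects the logarithmic scale
spacing).  The threshold is the fitted minimum plus one sensor-wise
standard deviation taken at the scale nearest the fitted minimum (a
config switch offers a pooled-SD variant, since the defining rule does not
say which scale's SD is meant), and the resolvable scale is the smallest
scale at which the fitted curve exceeds the threshold, located by
bisection; if the curve never exceeds it the value is flagged undefined.

## Experiment sizes

The `fast` profile (ico5 mesh, 20 484 sources, K = 200 instances, the 7
largest scales) runs in ~2 minutes and drives the test suite.  The `paper`
profile uses the ico6 mesh (81 924 sources), all nine scales and K = 1000.
The acceptance script uses ico6 with K = 300, which keeps the full
nine-scale experiment near 15 minutes on one CPU while the sensor-mean
statistics are stable to a few percent.  Every random draw derives from
one master seed through fixed per-stage offsets, so stages can be rerun in
isolation and runs are byte-for-byte reproducible; completed scales are
cached per configuration hash and are resumed on rerun.

## What the synthetic setting does and does not show

The generator emulates: multiscale, rotation-randomized, z-scored
activity on a folded cortical sheet; sensor arrays with realistic counts,
spacings and physics; the relative blur of the four modalities.  It does
not emulate: re-entrant (overhanging) sulci — the radial fold field is
single-valued, so opposing sulcal banks can never be closer in 3D than
the sheet geometry allows, which keeps fMRI voxel decorrelation distances
near ~1.7 cm where tighter real folding yields ~1 cm; non-spherical head
and skull geometry, whose far-field structure flattens the EEG
correlation-distance curve at every scale; realistic per-sensor
heterogeneity of the blur floor, which inflates the sensor-wise SD
entering the resolvable-scale threshold and shifts those estimates toward
larger scales.  Consequently correlation distances at the intermediate
6.7 cm² scale and the qualitative ordering fMRI < DOT < MEG < EEG are
quantitatively reproduced, while absolute resolvable-scale values should
be read as order-of-magnitude on this geometry.  Temporally correlated
activity and functional connectivity between distinct patches are out of
scope by design.
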