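# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted beyond what those runs check.

## Synthetic lattices

The generator's job is to emulate the experimental inputs with known
ground truth.

**Subunit motif.** The lattice subunit is represented analytically as a
seeded set of 3D Gaussian blobs inside a ~60 × 40 Å ellipsoid
(`make_subunit_motif`): ten broad "domain" lumps (σ ≈ 3.6–4.5 Å) each
decorated with four sharper sub-blobs (σ ≈ 1.5–2.4 Å, scattered ±3 Å).
The hierarchy is deliberate. A sparse domain layout keeps the motif
asymmetric — its projection correlates well below 0.8 with its own
180°-rotated copy, which is what lets indexing distinguish true lattice
translations from pseudo-translations between symmetry-related copies —
while the sub-blobs populate Fourier reflections out to the sampling
limit, which is what plane-group scoring discriminates on. A homogeneous
blob soup fails on both counts at once: dense soups exceed 0.9 rotational
self-correlation and sparse ones leave too few significant reflections.

**Rendering.** Lattice images are rendered analytically: rotations of the
plane-group generators act on blob centers in the continuum and every
projected Gaussian is evaluated exactly at each lattice node, so the
symmetry of the image is limited only by pixel sampling. A detector/optics
blur of 0.7 × pixel size is added in quadrature, keeping the sampled image
band-limited (aliasing below 1% of the weakest rendered feature). Copies:
p2 places the motif on the node and its 180° rotation at the cell center;
p4 places four 90°-rotated copies around the node. White Gaussian noise is
parameterized by SNR = var(signal)/var(noise); the real detector noise
model is not emulated. Default sampling is 4 Å/px for micrographs and
2 Å/voxel for volumes (the physical 0.835 Å/px of the real collections is
available as a constant). Cell presets: p2 in vitro (120 Å, 100°), p4 in
vitro (120 Å, 90°), and the shell-fragment cells (120 Å, 120°) and
(110 Å, 90°).

**Missing cone.** `make_missing_cone_volume` zeroes Fourier amplitudes in
the double cone of half-angle (90° − max tilt) about z (DC kept), then
adds independent noise to two half-maps (seeds s and s+1); the full map is
their average. `project_volume` rotates (spline order 3) and sums along z;
the Fourier-slice property holds to ~0.1% against an exact-DFT oracle.

**What passing on synthetic data does not show.** The generator has no
CTF, no detector noise correlations, no ice gradient and no beam-induced
distortion; lattice curvature is available only as a smooth optional
displacement field. Results on synthetic data therefore validate the
algorithms' correctness and statistical behavior, not their robustness to
every experimental pathology.

## Lattice indexing

Indexing works on the image autocorrelation (robust to patchy crystals;
the power spectrum would need the same peak analysis on a noisier
surface). Pipeline:

1. **Peak detection.** Local maxima of the autocorrelation; significance
   is the normalized lag correlation times √N pixels, so pure noise tops
   out near the extreme-value ceiling √(2 ln N) ≈ 4.6 while genuine
   lattices at SNR ≥ 0.1 score ≳ 90. Below z = 5 a no-lattice error is
   raised. Peaks get 1D parabolic subpixel refinement.
2. **Candidate bases.** Pairs drawn from the twelve shortest and eight
   tallest Friedel-unique strong peaks (pseudo-translation cross-peaks
   between symmetry-related motif copies can outnumber true peaks at
   short radii; true peaks carry full height). Each pair is refined by
   integer least squares over all strong peaks with a shrinking outlier
   tolerance.
3. **Selection.** Candidates are scored by the median autocorrelation
   peak height over all predicted lattice nodes within 3.5 cells (search
   window ∝ cell size). A spurious small cell predicts nodes where the
   autocorrelation shows nothing and its median collapses; a doubled cell
   scores as well as the true one and loses the smallest-cell tie-break
   among near-equal scores (≥ 0.92 × best).
4. **Halved-cell guard.** If one parity class of lattice nodes is
   systematically weaker (median ratio < 0.9 — pseudo-translation peaks
   of an asymmetric motif sit well below that, genuine classes within a
   few percent), the basis is doubled to the corresponding index-2
   sublattice and re-checked.
5. **Canonicalization.** Lagrange (Gauss) reduction, a ≥ b, γ folded into
   [90°, 150°], deterministic sign. Any basis of the same lattice maps to
   the same triple.

Measured accuracy at the study conditions (2048 px, 4 Å/px, SNR 0.3):
0.03% in length and 0.01° in angle — far inside the 2% / 1.5° contract.

**Plane-group scoring** uses the unit-cell average: the image is sampled
on a 64² fractional-coordinate grid of the indexed cell and averaged over
all lattice translations (with the across-cell variance retained as a
noise estimate). The score of group g is the correlation of this
cell-periodic motif with its copy rotated by the group generator,
maximized over the position of the rotation axis — computed in closed
form: with structure factors F(q), the correlation as a function of the
center c is Re Σ F(q)·conj(F(Rᵀq))·exp(2πi q·(I−R)c), a single inverse
FFT over frequencies (I−Rᵀ)q on a doubled grid. Reflections are whitened
(phase-only weights) above a noise floor of 3× the structure-factor noise,
so a few strong low-order reflections cannot fake a symmetry by chance;
the accidental score for an asymmetric motif is then bounded by the
√(2 ln N_centers / N_reflections) extreme-value level (≈ 0.2–0.4 here).
The 4-fold score additionally demands the 2-fold at the same center
(score(p4) = max_c min(C90(c), C180(c))) since p4 ⊃ p2 — this also
guarantees score(p4) ≤ score(p2). Assignment: p4 if its score exceeds
τ = 0.5 on a square cell (within 5% / 3°) and p2 does not beat it by more
than 0.15; else p2 if above τ; else p1. The margin rule is
subgroup-aware: a true p4 image necessarily scores high on p2 as well, so
"tie → lower symmetry" applies only between non-nested alternatives.
Noisy fractional-coordinate resampling makes non-square "p4" operators
shear operators; their scores are honestly low.

**Clustering** of symmetry labels on micrograph coordinates is DBSCAN per
label with eps = 1.5 × a (min 4 points). A cluster's purity is the
fraction of all particles within eps of its members that carry its label;
a permutation test against label shuffles quantifies spatial segregation.

**Template scheme.** Inclusive arithmetic ranges with the stated steps:
tilt offsets −5°, −2°, +1°, +4° and 61 z rotations (0–180° in 3° steps)
give 4 × 61 = 244 templates per tilted dataset — only this endpoint
convention reproduces that count.

## Directional FSC

Shells are one Fourier voxel wide up to Nyquist. Cones (default 48
Fibonacci directions, 20° half-angle — free parameters, as the underlying
method leaves them unspecified) overlap; each voxel joins every cone
containing it, Friedel pairs are counted once by folding k to the upper
hemisphere, and empty cone∩shell bins are NaN, never zero. The FFT
implementation is exactly (1e-10) equal to per-voxel brute-force sums.
The resolution criterion defaults to FSC = 0.143, linearly interpolated
at the first crossing; curves that never cross report Nyquist with a
flag. Count-weighted averages of the directional curves reproduce the
global curve to < 0.02 per shell on well-sampled grids (48³ in the test);
on very small grids the ratio nonlinearity of per-cone estimates can
exceed that.

## OTF construction

The OTF encodes *orientation anisotropy only*. Per-direction curves are
pooled into 10° polar-angle bands with count weighting (the tilt-limited
artifact is azimuthally symmetric; individual cone∩shell bins at low
radius hold 2–10 voxels and their FSC estimates are useless), low-count
bins inherit values radially within their band, and each shell is then
normalized by its best direction so the radial signal decay — which the
deconvolution data term already handles isotropically — drops out. Shells
with no credible signal in any direction (reference < 0.143) are treated
as unmeasured (weight 0) so the regularizer, not the noise, decides their
content. The result approximates the ideal step-cone transfer function;
values clamp to [0, 1], H(0) = 1, and Friedel symmetry is exact. The
deconvolution pipeline estimates its dFSC with a sharper 12° cone — the
20° reporting default blurs the 30° cone boundary, and band pooling
restores the counts the narrower cone loses.

## Entropy-regularized deconvolution

Objective (per-voxel means; σ = std of the input map):

    J(g) = mean((ifft(H·fft(g)) − f)²)/σ² + λ · mean(log(1 + S/ε)),

with S the sum of squared axial second differences of g and
ε = 1000·σ²/nonlinearity. The log saturates for curvature beyond ~σ/3 at
the nominal nonlinearity of 10,000, i.e. the penalty smooths weak
curvature but charges genuine features little. The mapping of the two
user-facing numbers onto the functional's coefficients is this
implementation's own calibration (chosen during design on missing-cone
phantoms); it is documented here rather than claimed equivalent to any
other software's parameterization.

Non-negativity is **on by default** — without it the roughness penalty
alone cannot restore missing-cone amplitudes at all (a smoothness prior
only shrinks unmeasured coefficients; it is the positivity constraint
that converts the zero-fill's negative z-ringing into in-cone signal).
For signed maps the flag can be disabled, with correspondingly weaker
cone recovery. OTF values below 0.02 are treated as missing data rather
than inverted.

Optimization: preconditioned nonlinear conjugate gradient
(Polak–Ribière) with backtracking line search; the Fourier-diagonal
preconditioner combines the data curvature 2H²/(Nσ²) with the averaged
penalty curvature. Only descending steps are accepted (the recorded
objective sequence is non-increasing); a stall retries steepest descent
before declaring convergence. Defaults: 200 iterations, 1e-5 relative
tolerance.

Measured behavior at the defaults on 20 seeded 64³ spheroid phantoms
(30° cone, SNR 3, full dFSC→OTF→deconvolution pipeline): median
z-elongation-excess reduction well above the 30% floor asserted in the
acceptance test, with the ground-truth L2 error *decreasing* on every
phantom. Elongation is quantified as the z/x ratio of interpolated FWHM
widths of the volume autocorrelation through the origin. The evaluation
phantoms are smooth spheroids (random radius 30–45 Å, offset ±8 Å,
profile exponent 1.5–2.5): isotropic truth makes the elongation purely a
cone artifact, and their power stays inside the noise-supported band —
dense fine-grained phantoms bury most spectral content below the SNR-3
noise floor where no method can recover it, and the missing cone can make
z-stacked sharp features genuinely ambiguous.

Problem sizes throughout (64³ volumes, 1024–2048 px micrographs, 20
phantom seeds) were chosen as the smallest at which the statistics above
are stable.

## Structural metrics

- **Superposition**: Kabsch via SVD with a proper-rotation correction;
  degenerate (collinear) sets are rejected. `rmsd_on_selection` aligns on
  one Cα selection and reports others without re-fitting.
- **Simulated density**: per-atom Gaussians weighted by approximate
  atomic number; σ = d·√(ln 2 / 2)/π so the Fourier envelope falls to ½
  at spatial frequency 1/d. (The self-consistency check asserts this
  envelope directly; an FSC between two noiseless maps of the same atoms
  is identically 1 at every shell regardless of blur, so it cannot probe
  the width.)
- **Fit-in-map**: masked real-space correlation (Pearson within a soft
  mask — by default the model's own simulated density thresholded at 1σ
  with a 6-voxel cosine edge, a free parameter); candidate orientations
  (identity, plus a coarse axis-rotation grid when a global search is
  requested) are scored after an FFT translation search, then refined
  over all six degrees of freedom with Powell's method. Recovery of a
  (15°, 8 Å) displaced pose is exact to < 1° / 0.5 Å in the tests.
- **Lattice expansion**: deterministic integer translations of a tetramer
  by the cell basis with renamed chains and a heavy-atom clash warning
  (> 5% of atoms within 1.5 Å across copies).
- **Channel geometry**: diagonals between Cα centroids of four corner
  selections in cyclic order, reported (shorter, longer). Which residues
  constitute a corner is a configuration choice, not hard-coded.
- **Inter-assembly rotation**: superpose anchor chains, then the Kabsch
  rotation between corresponding probe chains; reports the angle
  arccos((tr R − 1)/2), the axis, and the angle between the axis and the
  lattice normal.
- **Contacts**: inter-chain heavy-atom residue pairs at minimal distance
  within a 3–6 Å cutoff, tagged with region annotations (N-tail 1–37,
  β-hairpin 111–126, loop 272–291, structured loop 245–258, C-tail
  556–602) and classified by editable region-pair rules into the four
  lattice interfaces (hairpin–hairpin → closed hairpin, hairpin–C-tail →
  open hairpin, loop–loop → loop, N-tail involvement → diamond).
- **Sequence mass**: average (not monoisotopic) residue masses plus one
  water, cross-checked against an independent reference implementation;
  selenocysteine is treated by sulfur analogy and unknown letters raise
  an error naming the character.

Checks that require deposited maps or models (tetramer-vs-tetramer
rotation against another phage's cuboid assembly, masked correlations
into a tomography map, channel diagonals of the deposited model, the
full-length protein mass) are implemented as operations and validated on
constructed synthetic oracles; the deposited-data numbers themselves are
not asserted anywhere because the package performs no downloads.

## Known limitations

- Plane-group discrimination covers p1/p2/p4 only (the symmetries the
  shell lattice adopts), not all 17 groups.
- The p4 score on non-square cells measures a lattice-adapted
  pseudo-4-fold, not a true rotation (it is gated off in assignment).
- The deconvolution parameter mapping is a calibration of this
  implementation; identical numbers in other software need not produce
  identical functionals.
- Masked-FSC phase-randomization corrections are out of scope; FSC here
  is meant for unmasked synthetic half-maps.
- Indexing assumes a single dominant lattice per analyzed image region;
  multi-patch micrographs should be cropped per patch first.
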