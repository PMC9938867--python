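# phunlattice

Analysis tools for the 2D crystalline protein lattice that encloses the
phage nucleus — the micron-scale proteinaceous compartment that jumbo
bacteriophages such as ϕPA3 assemble around their replicating genome. The
shell is built from a single ~66.6 kDa protein (PhuN, ϕPA3 Gp53) that
tiles into tetramers with a dimeric asymmetric unit, forming predominantly
p2-symmetric sheets (unit cell ~120 Å, 100° in vitro) with minority p4
domains (120 Å, 90°).

The package implements the computational side of characterizing such
lattices from cryo-EM data:

- **Plane-group indexing** (`lattice_indexing`): estimate the reduced 2D
  unit cell (lengths a ≥ b, inter-axis angle γ ∈ [90°, 150°]) from the
  autocorrelation of a lattice micrograph, score p1/p2/p4 symmetry from
  the lattice-averaged motif, map symmetry labels back to micrograph
  coordinates and cluster them (DBSCAN), and build tilted-picking template
  stacks (±5° about the collection tilt in 3° steps × z rotations 0–180°
  in 3° steps → 244 templates per tilted dataset).
- **Directional FSC** (`anisotropy`): half-map Fourier shell correlation
  FSC(s) = Re Σ F₁F₂\* / √(Σ|F₁|² Σ|F₂|²), globally and restricted to
  angular cones on a Fibonacci-sampled hemisphere — the standard
  representation of preferred-orientation anisotropy from tilt-limited
  collection, which leaves a missing double cone of half-angle
  (90° − θ_max) in Fourier space.
- **Missing-cone deconvolution** (`deconvolution`): build an optical
  transfer function H(k) ∈ [0, 1] from the directional FSC and minimize
  ‖H·ĝ − f̂‖² + λ·Σ log(1 + S/ε) with non-negativity, where S is the
  squared second-derivative magnitude of g — an entropy-style,
  edge-preserving roughness penalty whose saturation is set by the
  `nonlinearity` parameter (defaults: smoothing λ = 0.5, nonlinearity
  10,000). A closed-form Wiener filter and B-factor/low-pass utilities are
  included as baselines.
- **Structural metrics** (`structure_metrics`): Kabsch superposition and
  selection-wise RMSD, model-simulated density, rigid-body fitting with a
  masked real-space correlation, lattice expansion of a tetramer by the
  cell basis, channel corner-to-corner diagonals, inter-assembly rotation
  angles, interface contact maps (Diamond / Open Hairpin / Closed Hairpin
  / Loop), and average protein mass from sequence.
- **Synthetic data** (`synthetic_data`): seeded generators for all of the
  above — plane-group lattice micrographs with known ground truth,
  multi-patch micrographs, tilt-series projections (Fourier-slice exact),
  half-maps with independent noise, and missing-cone volumes.

File formats: MRC2014 maps/images (via gemmi), PDB/mmCIF models (via
gemmi), and a STAR-like whitespace table for particle records.

## Worked example

```python
from phunlattice import (NoiseSpec, index_lattice, make_subunit_motif,
                         preset_spec, render_lattice_image, score_plane_group)

motif = make_subunit_motif(seed=3)
image, truth = render_lattice_image(
    preset_spec("p2-invitro"), motif, image_size=1024, pixel_size=4.0,
    noise=NoiseSpec(snr=0.3, seed=7),
)
model = index_lattice(image)
scores = score_plane_group(image, model)
print(f"cell: a = {model.a_len:.2f} A, b = {model.b_len:.2f} A, "
      f"gamma = {model.gamma:.2f} deg")
print("plane-group scores:", {k: round(v, 3) for k, v in scores.items()})
print("assigned group:", model.assigned_group)
```

prints

```
cell: a = 120.11 A, b = 119.99 A, gamma = 100.01 deg
plane-group scores: {'p1': 1.0, 'p2': 0.914, 'p4': 0.077}
assigned group: p2
```

i.e. from a micrograph at signal-to-noise 0.3 the indexer recovers the
120 Å / 100° in vitro cell to 0.1% / 0.01°, and the symmetry scorer finds
a strong 2-fold (0.914) but no 4-fold (0.077), assigning plane group p2.

A command-line interface mirrors the pipeline stages
(`phunlattice simulate|index|dfsc|deconvolve|fit|metrics`, each with
`--config`, `--seed`, `--out`).

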