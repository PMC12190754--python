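# Methods

This note documents the models and procedures implemented in `essdyn`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Trajectory model and superposition

A trajectory is an ordered list of frames (one C-alpha per residue; full-atom
frames are accepted) labelled by replica id and snapshot time, concatenated
replica-by-replica with a 0-based global frame index. Replicated studies of
the kind this pipeline targets use three 100 ns runs sampled at 1 ns, giving
3 × 101 = 303 frames.

Superposition uses the Kabsch algorithm: SVD of the cross-covariance of the
centered point sets with a determinant correction guaranteeing a proper
rotation (det R = +1). Each frame is fitted independently on its C-alpha set
(optionally a residue mask) and the transform applied to all atoms. The
default reference is the first frame of the first replica — in a real study
that frame is the energy-minimized starting structure; any frame (or an
external structure) can be passed instead. Collinear point sets make the fit
non-unique; the implementation warns and returns a best-effort fit rather
than failing, since a physical chain is never exactly collinear. Fewer than
3 points is an error.

The PCA input is the frames × 3N matrix with columns ordered x, y, z per
residue, residues ascending (449 residues → 1347 columns). Reshaping row r
to (N, 3) recovers frame r exactly.

## Descriptors

- **RMSF**: RMSF_i = √(⟨|r_i(t) − ⟨r_i⟩|²⟩). Two scopes are provided because
  published workflows that "combine" per-replica profiles are ambiguous
  about the reference mean: `per-replica-combined` (default) takes each
  replica's fluctuation about its own mean and merges them as the root of
  the frame-weighted mean square — replica-to-replica basin offsets then do
  not inflate the profile — while `whole-concatenation` uses the global
  mean. Both are tested; the difference is itself a useful diagnostic of
  basin structure.
- **Radius of gyration**: uniform weights by default on C-alpha-only frames
  (mass weighting available for full-atom frames, using standard atomic
  masses).
- **SASA**: Shrake–Rupley quadrature with a Fibonacci (golden-angle) sphere
  lattice, 960 points per atom by default, probe radius 1.4 Å, van der
  Waals radii C 1.7, N 1.55, O 1.52, S 1.8, H 1.2 Å. The quadrature
  reproduces the analytic isolated-sphere area to ≪1% and the two-sphere
  spherical-cap formula to <1.5% at 960 points. Absolute agreement with any
  particular MD engine's SASA is *not* a goal — radii sets differ between
  programs — only internal correctness and the table schema.

## Essential dynamics (PCA)

The default basis is correlation-matrix PCA: every column is standardized to
mean 0, sample sd 1 before decomposition. Standardizing coordinates is
unusual in the essential-dynamics literature (it discards the Å scale of
motion), but it matches workflows that run the PCA through general-purpose
statistics packages, whose tools standardize by default; classical
covariance-based essential dynamics is available via `mode="covariance"` and is what the planted-variance tests
use, since only that mode preserves the planted 9/4/1 Å² mode variances.

The decomposition is computed by SVD of the centered data matrix — exact,
and O(n²p) rather than O(p³) when frames ≪ columns (303 ≪ 1347). Loadings
are unit-norm eigenvectors; scores are the centered data projected onto
them, so score variances equal eigenvalues. Eigenvector sign is fixed by
flipping each loading column so its largest-magnitude entry is positive,
making output deterministic across eigensolvers. Zero-variance columns are
flagged and contribute nothing.

**Component retention** is Horn's parallel analysis. The null spectra come
from 100 draws (default) of independently column-permuted data; the
95th-percentile rule retains leading components while observed λ exceeds the
per-rank noise percentile, stopping at the first failure. A Monte-Carlo
variant drawing i.i.d. standard normals is provided (`method="normal"`);
permutation is the default because it conditions on the observed marginals.
Note the calibration consequence: on *pure noise* the observed top
eigenvalue is exchangeable with its permutation null, so false retention
occurs at the nominal 5% rate — the null-case test therefore checks the
zero-retention frequency binomially (≥90 of 100 seeds, 3σ below the nominal
95%) rather than asserting an impossible exact bound.

## Conformational clustering and loading selection

Frames are clustered in the PC1/PC2 score plane (d configurable; PC3 rarely
adds structure in practice) by K-means with k-means++ initialization and 25
restarts, scanning k = 2…10 and keeping the k with the highest mean
silhouette. A best silhouette below 0.4 sets a `weak_structure` flag: the
partition is reported but should not be interpreted as well-separated
states. Cluster assignments are mapped to contiguous frame-index runs and
replica composition, since basins frequently track individual replicas.

Two loading-selection rules:

1. **Threshold**: a variable (residue × axis) is selected iff
   |loading| ≥ 0.7 on any considered component; the bound is inclusive.
2. **Top decile per cluster**: loading points in the PC1/PC2 plane are
   K-means-clustered with the same k as the score clustering, then within
   each cluster the top 10% by Euclidean distance from the origin is kept,
   rounding the count up and including all boundary ties (over-selection is
   preferred to an arbitrary tie-break; ties are logged).

## DCCM and porcupine fields

C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) over all frames of the aligned
concatenated trajectory (per-replica analysis available by slicing).
Residues with zero displacement variance get a zeroed row/column and are
flagged. The matrix equals the normalized 3×3 block-trace of the 3N
covariance, which the tests verify independently. Block summarization —
needed to turn an N×N matrix into statements like "range A moves opposite
to range B" — segments residues into maximal runs whose consecutive-neighbour
correlation stays above the threshold, then reports every segment pair whose
mean correlation exceeds +threshold or falls below −threshold.

Porcupine fields map a PC eigenvector to one arrow per residue (its x, y, z
loading triplet), anchored at the reference C-alphas. The default scale
makes the longest arrow 10 Å — purely a rendering choice. Variant
comparison (wild-type vs mutant overlay) is realized testably as two fields
on a common reference plus a per-residue arrow-difference table.

## Free-energy landscape and tunnel test

The landscape interpolates an externally supplied per-frame ΔG series
linearly over the Delaunay triangulation of the (PC1, PC2) score points onto
a regular grid (default 100×100). Nodes outside the convex hull stay NaN, so
the landscape never extrapolates minima; at the data points the interpolant
reproduces the inputs exactly. Local minima are grid nodes strictly below
all eight defined neighbours, with hull-edge nodes excluded. How ΔG values
are produced (external stability calculators) is out of scope — they enter
only as a labelled CSV, matched to frames on (replica, time) with loud
errors for missing or extra rows. A population-based alternative
(−RT ln ρ from the score density) is provided for comparison only and is
clearly labelled as not the primary construction.

The tunnel comparison is a pooled-variance two-proportion Z-test, two-sided,
without continuity correction: these choices reproduce p = 0.0062 from the
published counts 23/60 vs 38/60 (|z| ≈ 2.74, pooled 0.51). A printed
z-score of "−274" in the source table is inconsistent with its own p-value
and is treated as a typographical artifact; the package asserts the p-value.

## Synthetic data generator

Frame t of replica c is x(t) = R_t[x_ref + Σ_k a_k(t) v_k + ε] + s_t, where
x_ref is an ideal helical C-alpha trace (3.8 Å spacing), v_k are orthonormal
displacement fields, a_k ~ Normal(μ_kc, σ_k²) with replica-dependent means
μ_kc creating basins, ε is isotropic per-atom noise and (R_t, s_t) an
optional random rigid nuisance that superposition must remove. Defaults
mirror the emulated study: 449 residues, 3 replicas × 101 frames at 1 ns,
mode variances 9/4/1 Å², the first mode split into two anti-phase halves of
the chain, basin centers ≥10σ apart in the mode-1/mode-2 plane, 0.3 Å
noise, nuisance on. The energy is quadratic about each basin center
(weights 0.5 kJ/mol per unit², depths 95/105/100 kJ/mol, 2 kJ/mol noise),
placing landscape minima at basin centers with magnitudes near published
free-energy tables. Tunnel presence is Bernoulli per group at 23/60 and
38/60 over 60 frames per group — the published counts' regime, at which the
Z-test is significant in most seeds. A manifest records every latent value.

What the generator does **not** emulate: force-field physics, solvent,
anharmonicity, temporal autocorrelation within a basin (frames are i.i.d.
given the replica), and sequence-dependent structure. Passing tests
therefore demonstrate algorithmic correctness and parameter recovery under
the stated statistical model, not fidelity to any real protein's dynamics.

One geometric subtlety the generator exposes: an anti-phase two-half mode is
partially equivalent to a rigid rotation, which superposition removes.
Subspace-recovery tests are therefore run in the generator's own reference
frame (nuisance off); the nuisance-invariance test separately confirms that
alignment removes planted rigid motion without distorting the remaining
analyses.

## Pipeline, determinism, problem sizes

`run_pipeline` executes align → descriptors → PCA/parallel analysis →
clustering → loading selection → DCCM → porcupine → landscape → Z-test,
writing every table as CSV/JSON next to a resolved config and a structured
log; stages fail loudly with their name and completed outputs are retained.
Missing optional inputs (energy, tunnel) skip only their stage, with a
warning. All randomness (parallel-analysis draws, K-means restarts,
generator) flows from explicit seeds, and two runs with the same config are
byte-identical in their numeric outputs.

Test problem sizes are chosen to exercise each property at the smallest
scale where the statistics are decisive: 5000 frames for eigenvalue/subspace
recovery (sampling error ~2%), 10⁴ frames for RMSF and DCCM sampling bounds,
the literal 449-residue 3×101 geometry for matrix-shape checks, and reduced
40-residue studies elsewhere. SASA over a long trajectory is strided
(default every 10th frame) because the quadrature is the one O(N·points)
hotspot; the stride is configurable.

## Known limitations

- PDB I/O supports MODEL/ENDMDL coordinate trajectories only; no binary
  formats (xtc/dcd) — convert externally. Insertion codes are rejected;
  altloc 'A'/blank is taken.
- The correlation-PCA default means eigenvalues are unitless counts of
  standardized variance, not Å²; use covariance mode for physically scaled
  spectra.
- DCCM block summarization assumes coordinated regions are contiguous in
  sequence; spatially coupled but sequence-discontiguous sets appear as
  multiple range pairs.
- The landscape is only as good as the supplied ΔG series; no Boltzmann
  reweighting or error model is applied.
- Published MD-derived numbers (eigenvalue tables, ΔG statistics, RMSF
  maxima) depend on unavailable trajectories and external engines; the
  package reproduces their schemas and the statistical machinery, not those
  values.
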