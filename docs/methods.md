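# Methods

## The descriptor

A density map is reduced to a binary occupancy grid by an inclusive
threshold (density ≥ level) and treated as an indicator function
f(**x**) on the unit ball. f is expanded in the Zernike–Canterakis
basis Z_nl^m = R_nl(r) Y_l^m(θ, φ), where Y_l^m are orthonormal
spherical harmonics with the Condon–Shortley phase and R_nl are the
radial polynomials, in the normalization that makes the basis
orthonormal under (3/4π)∫ over the unit ball:

    R_nl(r) = Σ_{ν=0}^{k} q_kl^ν r^(2ν+l),   k = (n − l)/2,
    q_kl^ν = (−1)^(k+ν) / 4^k · sqrt((2l + 4k + 3)/3) · C(2k, k)
             · C(k, ν) · C(2(k+l+ν)+1, 2k) / C(k+l+ν, k).

The moments Ω_nl^m (see README) transform under rotation within each
(n, l) block by a unitary Wigner matrix, so F_nl = ‖Ω_nl^·‖₂ is exactly
rotation-invariant for the continuous object; any residual variation in
practice measures discretization, not the algebra. The printed norm in
the field's shorthand squares Ω literally; for complex coefficients the
well-defined reading is the squared modulus |Ω_nl^m|², which is what is
implemented. The index range is the standard closed −l ≤ m ≤ l. For
real f the moments obey Ω_nl^{−m} = (−1)^m conj(Ω_nl^m), so only m ≥ 0
is stored and the m < 0 half enters the norms as a factor of two.

Order n = 20 gives 121 (n, l) pairs. The ordering of the invariant
vector is (n ascending, l ascending) and is part of the database file
contract.

## Moment evaluation

The integral is approximated as a sum over occupied voxel centers, each
contributing conj(Z_nl^m) at the point times the normalized voxel
volume — a midpoint rule matched to the binary f (no partial-volume or
antialiasing weights). Because every Z_nl^m is a polynomial of total
degree ≤ n, the sum factors through geometric moments
M_rst = Σ w·x^r y^s z^t with r + s + t ≤ 20 (1771 monomials), followed
by one dense matrix–vector contraction against precomputed monomial
coefficients of the basis.

The coefficient table is assembled once per process from exact rational
arithmetic (`fractions.Fraction`) for the radial, solid-harmonic and
multinomial factors, with the single irrational prefactor applied last;
raw binomial terms at n = 20 span ~15 orders of magnitude and summing
them in floating point first would cost most of the mantissa. The test
suite pins this machinery against an independent slow path that
evaluates R_nl · Y_l^m directly per point with scipy's spherical
harmonics: agreement is ~1e-10 relative at order 20.

## Normalization into the unit ball

Neither the centering nor the scaling of the object inside the unit
ball is dictated by the expansion itself; they are design choices, and
they dominate the descriptor's practical stability.

* **Centering** — occupied voxel centers are translated so their
  centroid is at the origin. This absorbs translation exactly (integer
  shifts are bit-reproducible; the map origin cancels).
* **Scale** — points are divided by
  S = max(2 · R_g, r_max · (1 + 1e-6)), where R_g is the radius of
  gyration of the occupied centers and r_max their maximum distance
  from the centroid. A pure r_max scale (the obvious choice) is
  hypersensitive: one voxel appearing at a corner of the surface after
  a rotation rescales every radius by ~1%, which the high-order radial
  polynomials amplify into several-percent descriptor changes. R_g is
  a quadratic mean over the whole object and moves by <0.1% under
  rotation/resampling; with the factor 2 all compact shapes fall on
  the stable R_g branch (r_max/R_g ≈ 1.3 for a ball, ≈ 1.8 for a
  dumbbell) while the r_max term remains as a hard guarantee that
  every point stays strictly inside the ball for extreme aspect
  ratios. Measured on 64³ synthetic shapes, this cuts worst-case
  rotation error from 3–14% to under 1%.
  A consequence worth knowing: the descriptor becomes nearly
  scale-invariant (a uniformly enlarged copy of a shape maps to nearly
  the same fingerprint), so absolute size discrimination is carried by
  the volume filter, not the distance.
* **Working grid** — before thresholding, the density is resampled
  (trilinear) to an isotropic grid with spacing
  h = max(largest extent / 128, smallest voxel / 2): anisotropic
  voxels become isotropic, big maps are capped at 128 voxels per axis,
  and coarse maps are supersampled at most 2×. Supersampling matters:
  re-voxelizing a rotated map at its native 64³ perturbs the occupied
  set (and hence the volume term F_00) by ~1–2%; sampling the same
  density twice as finely cuts the worst-case rotation error of a
  sharp-edged cylinder from ~3% to under 1%. Interpolation preserves
  density units, so contour levels computed on the original grid apply
  unchanged.

## Contours, volume, masks

The sigma level is mean + 1 population SD over all grid values (the
σ-contour convention; for a constant map it degenerates to the mean,
which is permitted and logged). The two core-revealing levels are 1/3
and 2/3 of the maximum density. Maps lacking a recommended contour fall
back to the sigma level with a warning, keeping the pipeline total.

Volume is the occupied-voxel count at the recommended contour on the
*original* grid times the voxel volume, in Å³. The variant-specific
contours do not feed the volume filter; the recommended contour is the
default representation of the map and gives one volume per entry.

Region masks (axis-aligned box or sphere, in origin-aware physical
coordinates) zero the density outside the region, enabling region-wise
comparison of sub-assemblies. No automatic segmentation is attempted.

## Search semantics

Distance on concatenated variants is plain Euclidean over the full
vector, with no per-block weighting. Filters are conjunctive and
applied before ranking (their order is immaterial); the volume-ratio
bounds [0.8, 1.2] and resolution ranges are closed intervals; entries
without a resolution are excluded only while a resolution range is
active. Ties in distance are broken lexicographically by entry id. The
distance < 8.0 "related" flag is annotation only — it never filters —
and because descriptor magnitudes depend on the normalization
convention above, the absolute scale of distances here is not
comparable with values produced by other implementations of the same
descriptor; the flag is kept for interface fidelity.

## Synthetic data

The generator renders indicator solids (ball, ellipsoid, dumbbell,
cylinder, ring), blurs them with an isotropic Gaussian and optionally
adds seeded Gaussian noise. Defaults — 64³ grid, 2 Å voxels,
blur σ = 6.4 Å (FWHM ≈ 15 Å, the contemporary database-wide mean
resolution of deposited EM maps) — give surfaces whose smoothness at
the voxel scale resembles real mid-resolution maps. The recommended
contour is half the pre-noise plateau (the half-maximum surface of a
blurred indicator), and the resolution metadata is 2.355·σ (Gaussian
FWHM). Densities are snapped to float32 values so generated maps
round-trip mode-2 MRC files bit-exactly.

What the generator does *not* emulate: CTF effects, non-uniform
resolution, missing-wedge artifacts, solvent noise structure, or
density derived from atomic models. Passing tests therefore demonstrate
the geometric and retrieval properties of the descriptor pipeline, not
robustness to instrument-specific artifacts.

Problem sizes used in the test suite (64³ for rotation studies, 48³
for retrieval databases, 16³ for the slow-oracle cross-check) were
chosen as the smallest grids at which each property is cleanly
measurable.

## Numerical and degenerate cases

* Thresholding is inclusive (≥), so a level equal to the maximum keeps
  at least one voxel; a level above the maximum yields an empty grid,
  which the descriptor stage rejects with an error naming the level.
* A single occupied voxel normalizes to one point at the origin
  (scale falls back to one voxel edge).
* 90°-multiple rotations about grid axes are exact index permutations;
  arbitrary rotations resample trilinearly about the density centroid.
* All randomness is behind explicit seeds; identical inputs give
  byte-identical outputs.

## Known limitations

* A voxelized ball is not a ball: its occupancy carries genuine
  octahedral (l = 4, 6, …) harmonic content plus lattice-quadrature
  error, so l > 0 invariants of a discretized sphere bottom out near
  1e-3 of F_00 at practical grid sizes rather than at machine
  precision. The suite checks the physically meaningful statement
  (l > 0 suppressed by orders of magnitude relative to an aspherical
  control).
* Absolute invariant values depend on the normalization convention;
  only distances computed within one database are meaningful.
* Local (sub-map) similarity search is out of scope; masks provide
  manual region-wise comparison only.
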