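# Methods

## Pocket model

A pocket is an ordered cloud of N heavy atoms, each a coordinate x_i ∈ ℝ³
(Å) with an optional scalar label l_i (partial charge, elementary charges).
Derived geometry uses fixed conventions:

* covariance of the cloud about its centroid is the population
  (divide-by-N) form;
* principal axes are its eigenvectors ordered by descending eigenvalue,
  sign-normalized so the largest-magnitude component is positive, and
  forced right-handed.  Downstream code never relies on the signs — the
  alignment enumerates them itself;
* the pocket ellipsoid has semi-axis lengths a_k = 2·√λ_k (a ≈2-standard-
  deviation envelope).  Nothing canonical fixes the ellipsoid scale; any
  monotone convention gives the same Vol and Princ-Axis *rankings*, so the
  choice only needs to be fixed and documented.  Volume is (4/3)π·a₁a₂a₃.

Rotations are parameterized by Z-X-Z Euler angles,
R = Rz(φ)·Rx(θ)·Rz(ψ), (φ, θ, ψ) ∈ [0, 2π)³.  Any proper-rotation chart
reaches the same optima; this one is fixed for reproducibility.  The chart
is singular at θ ∈ {0, π} (only φ ± ψ is determined); see the optimizer
notes below.

## Convolution kernel

The fixed-pose similarity is
K(P1, P2) = Σ_ij exp(−‖x_i − y_j‖²/(2σ²))·K_L(l_i, l_j) with
K_L(l, l') = exp(−(l−l')²/λ); λ = ∞ gives the purely geometric kernel.
Equivalently, representing each pocket by a mass density — a sum of
*normalized* isotropic Gaussians of bandwidth σ/√2 on its atoms — the
kernel is (2πσ²)^{3/2} times the L² inner product of the densities.  A
midpoint-rule grid integration of that inner product (step σ/8, 4σ margins)
is kept in the package as an independent numerical oracle for the closed
form; the two agree to well below 1% with a single configuration-
independent constant.

Choices worth making explicit:

* the λ convention is exp(−Δl²/λ) (not Δl²/(2λ²)); the difference is a
  reparameterization of the λ grid and nothing else;
* no size normalization is applied by default (K grows with N1·N2); a
  normalized variant K/√(K11·K22) is available behind a flag;
* the induced metric d = √(K11 − 2K12 + K22) clamps radicands above
  −1e-12 to zero (floating-point noise); anything more negative raises,
  since it would contradict positive definiteness.

## sup-CK: maximization over rigid motions

sup-CK(P1, P2) = max over (R, t) of K(P1, R·P2 + t), a non-concave problem
over SE(3) solved approximately by multi-start gradient ascent on the
6-vector (t, φ, θ, ψ).  The gradient is analytic: with q_j = R y_j + t and
G_ij the weighted Gaussian terms, ∂K/∂t = Σ_ij G_ij (x_i − q_j)/σ², and
each angular derivative contracts the same inner sums against ∂R/∂angle
(products of the rotation generators with the chart factors).  The
finite-difference check is part of the test suite and the acceptance
script.

Starts:

* translation matching the geometric centers, rotation superposing the
  principal axes of P2 onto those of P1 for all 2³ = 8 sign assignments.
  Sign patterns with negative determinant are made proper by flipping the
  third axis, which collapses the 8 hypotheses onto 4 distinct proper
  rotations; duplicates are ascended once.
* when two axis lengths agree within 20% (configurable), the axis
  correspondence is ambiguous and swapped-axis starts are added;
* a few seeded uniform-random rotations (default 4) guard against local
  maxima, and are the fallback when the principal frame is degenerate.

Ascent: all starts are advanced simultaneously (vectorized over the start
axis).  Steps are Barzilai–Borwein spectral steps backtracked by halving
until the objective strictly improves, so the value sequence of every start
is nondecreasing; a start stops when its relative improvement falls below
1e-7 (or after 500 iterations).  Plain fixed-step ascent zig-zags on the
anisotropic ridges of this objective and was replaced after profiling.  Two
further schedule details: every start gets a 30-iteration exploration
budget, after which only the best 2 starts are refined to convergence
(an L-BFGS polish, accepted only if it improves the BB iterate); and starts
whose initial or final angles sit on the θ ∈ {0, π} chart singularity are
perturbed by a small seeded angular noise and re-ascended once, keeping the
result only if better.  Everything is deterministic given the optimizer
seed.

The returned motion applies to the *second* pocket; scores from the two
argument orders agree to optimizer noise (≲0.1% on anisotropic clouds).
Nothing certifies global optimality — the test suite instead checks
dominance over an exhaustive 10°-spaced Euler grid with centroid-matched
translation, and exact recovery of planted rigid motions.

## Baseline measures

* Vol(P1, P2) = |Vol(P1) − Vol(P2)| (dissimilarity, Å³).
* Princ-Axis = Σ_k |a_k − b_k| over descending-sorted semi-axis lengths
  (dissimilarity, Å).  The original formulation of this score does not
  survive in a precise form; the L1 distance is this package's
  interpretation and is pluggable.
* sup-PI: superpose with sup-CK, then locally refine the pose to maximize
  the number L of one-to-one atom pairs within 1 Å (coordinate-wise search,
  steps 0.2 Å / 2°, halved twice, ≤100 moves, accepted only on strict
  increase), and return PI = L/(#P1 + #P2 − L).  Overlap counting is a
  greedy one-to-one matching by ascending pair distance — a cluster of
  atoms cannot all match one atom — with an optimal-assignment oracle
  available for testing.  The union normalization is a choice (the
  alternative L/min(#P1, #P2) is provided).
* sup-CK-Vol: z(sup-CK) − w·z(Vol), where z() standardizes each raw score
  with training-fold statistics (the two scores live on incommensurate
  scales; the combination weight w ≥ 0 is selected by cross-validation like
  any other hyperparameter, over {0, 0.25, 0.5, 1, 2, 4} by default).

## Pocket extraction and charges

From a PDB structure, the pocket for a given ligand is every polymer heavy
atom strictly within R Å of any ligand atom (default R = 5.3; useful range
roughly 4.5–8 Å).  Ligand atoms are never included; waters are dropped;
alternate locations resolve to the highest occupancy; hydrogens are
excluded by default (rarely present in crystal structures).  Hetero
cofactors other than the target ligand are not counted as pocket atoms.

Partial charges come from a (residue, atom) lookup table with a wildcard
residue for backbone atoms and a default of 0 for unlisted (apolar) atoms.
The shipped table contains representative united-atom values written for
this package; it is a labeling scheme, not a force field — the method only
needs a consistent scalar label, and the label scale λ is learned per
dataset.  Users can substitute any `resname,atomname,charge` CSV.

## Evaluation protocol

* **Per-pocket AUC**: rank all other pockets by similarity to the query
  (ascending for dissimilarities); AUC of same-ligand pockets as positives,
  ties credited 0.5 (Mann–Whitney).  Queries whose class has no other
  member are excluded from the mean with a warning.
* **Classification error**: leave-one-out KNN under double cross-
  validation.  For each held-out pocket, every grid point (σ, λ, K, w) is
  scored by inner leave-one-out accuracy on the remaining pockets; the
  best point (first in declared order on ties) predicts the held-out
  pocket.  KNN ties break by vote count, then larger summed similarity of
  the tied class's neighbors, then lexicographic class label — fully
  deterministic.  Similarity matrices are computed once per (σ, λ) and
  sliced per fold: the score between two training pockets does not depend
  on the held-out pocket, so this caching is an identity, not an
  approximation.  The extraction radius R is fixed at extraction time
  rather than re-optimized inside the CV (both the grid defaults and this
  choice are configurable).
* **Kernel PCA**: double-center the similarity matrix, eigendecompose,
  keep the components with the largest positive eigenvalues (sup-CK is
  indefinite), scale coordinates by √eigenvalue, and report the discarded
  negative-eigenvalue mass.

Default grids: σ ∈ {0.5, 1, 2, 4}, λ ∈ {0.125, 0.25, 0.5, ∞},
K ∈ {1, 3, 5}.  Good single defaults are σ = 1 for the geometric kernel,
σ ∈ [2, 4] with λ ≈ 0.25 when charges are used, and K ∈ [3, 5].

## Synthetic benchmarks

The generator emulates the shape of the ligand-prediction benchmarks: C
classes × n pockets, each pocket a uniform-random rigid motion (quaternion-
sampled rotation — uniform Euler angles would bias SO(3) — and translation
in a 50 Å box) of its class template, degraded by isotropic coordinate
jitter (default SD 0.2 Å), atom deletions/insertions (each atom deleted
with probability indel/2, Binomial(n, indel/2) insertions near existing
atoms; default indel 0.05), and charge noise (SD 0.05 e).

Templates are anisotropic shell clouds (axis scales 1.4 : 1 : 0.7, shell
radius 6 ± 1.5 Å, 15–40 atoms, charges from {−0.5, −0.3, 0, 0.2, 0.4}),
derived from one shared anchor cloud by a class-specific deformation scaled
by `class_separation` (default 3): a per-atom displacement field of
0.4·separation Å per coordinate, ±5%·separation axis rescaling, atom-count
resampling and reassignment of half the charges.  The displacement is kept
below the shell anisotropy deliberately — templates stay rim-shaped with
stable principal axes, as real pockets are; at separation 0 all templates
collapse onto the anchor (a planted confusable limit).  A multi-cluster
mode gives selected classes a second independent template with pockets
split between the two: this reproduces the scenario where pockets binding
one ligand form several clusters, which depresses mean AUC while
nearest-neighbor classification is unaffected — the package's demonstration
of why classification error is the better score for ligand prediction.

What the generator does *not* model: real force-field charge
distributions, ligand chemistry, residue connectivity, conformational
(non-rigid) variability between pockets binding one ligand, and the
partial-overlap ambiguity of real extraction at different R.  Passing the
synthetic end-to-end tests therefore demonstrates correctness of the
algorithms and protocol, not biological performance.

## Problem sizes and tolerances

The shipped end-to-end checks run the default 10 × 10 benchmark with the
grid σ ∈ {1, 2}, λ = 0.25, K ∈ {1, 3, 5} (two 100×100 sup-CK_L matrices,
≈ 4950 alignments each) and a single-grid-point CV on the multi-cluster
variant; smaller grids than the full defaults keep the runs at a few
minutes without changing the conclusions.  Numerical tolerances: kernel vs
brute force 1e-12; analytic gradient vs central differences 1e-5 relative
(h = 1e-5); rotation recovery 0.01 rad geodesic; grid-oracle dominance
slack 1e-6; AUC/error thresholds as asserted in the acceptance tests.

## Known limitations

* sup-CK has no global-optimality guarantee; near-isotropic clouds make
  the principal-axis starts uninformative and raise the chance of a local
  maximum (mitigated, not eliminated, by random extra starts).
* The Princ-Axis and Poisson-index normalizations are interpretations
  (pluggable), as is the 2√λ ellipsoid convention.
* The shipped charge table is representative, not a published force field.
* No pocket *detection*: extraction requires a bound ligand (holo
  structure); apo-structure pockets must come from an external detector.
* Scalar labels only in this version; the kernel interface would extend to
  vector labels but does not accept them yet.
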