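# Methods

This note documents the models, numerical choices, and design decisions
behind morphowarp, and what the synthetic-data experiments do and do not
demonstrate.

## Thin-plate splines in 3D

The deformation model is the 3D thin-plate spline: the interpolant of
`h(sᵢ) = tᵢ` minimizing the integrated squared second derivatives (bending
energy). Its fundamental kernel is `U(r) = r`, the plain inter-point
distance; `h` decomposes into an affine part and a kernel expansion with
coefficients `K` satisfying the side conditions `QᵀK = 0`,
`Q = [1 | source]`. Fitting solves the `(M+4)×(M+4)` bordered system by a
dense pivoted LU solve; configurations up to a few thousand points are
expected (the default scheme has 500), so no low-rank approximation is used.
Preconditions: at least 4 pairwise-distinct, non-coplanar source points
(coplanarity detected at relative singular value 1e-10; violations raise
`DegenerateConfigurationError` naming the offending pair where applicable).

**Sign conventions.** The raw distance kernel is conditionally *negative*
definite, so two quantities are sign-adjusted to give the conventional
non-negative bending energy:

- the bending-energy matrix `B` is **minus** the upper-left `M×M` block of
  the inverse bordered system; it is then symmetric PSD with null space
  `{1, x, y, z}` (affine maps cost nothing);
- the model energy is `E = −tr(KᵀΨK)`, which equals `Σ_c t_cᵀ B t_c` at
  `β = 0`.

Any constant rescaling or sign convention cancels in all minimizations and
comparisons; it affects only the absolute numbers reported.

**Smoothing.** `β > 0` regularizes the fit (fidelity traded for lower
bending energy). In the PSD convention this adds `β·I` to the kernel block,
which on the raw distance matrix enters with a minus sign — adding `+β·I`
to raw distances would *increase* energy with β. The implementation uses the
PSD-consistent sign; `E(β)` is non-increasing and the residuals grow with β,
as a smoothing parameter must behave. Default `β = 0` (pure interpolation),
overridable per run.

Per-run energy bookkeeping (initial energy, per-cycle energies, step scales,
final coefficients, and the net energy change after the schedule) is
recorded in `EnergyTrace`. The energy-scaled coefficient block sometimes
written as a "homologous warping" summary is kept as reporting metadata
only; it is never applied as a coordinate transformation, because an
energy-scaled coefficient matrix does not define a meaningful map.

## Mesh geometry

- **Units** are millimetres throughout; no conversions.
- **Closest-point projection is exact.** For query `p`, the distance to the
  nearest vertex `d_v` (itself a point of the surface) bounds the surface
  distance; any triangle attaining the minimum must have a vertex within
  `d_v + longest edge`. All candidate triangles inside that radius (via a
  k-d tree on the vertices) get an exact point-to-triangle test; ties are
  broken toward the lowest face index so runs are bit-reproducible.
- **Vertex normals** are angle-weighted averages of incident face normals —
  robust on the irregular triangulations of real scans; tangent planes
  interpolate them barycentrically. The tangent basis is deterministic:
  `u` is the tangential projection of the global x-axis (y-axis fallback
  near parallelism), `v = n × u`.
- **Curve tangents** are central differences at interior polyline indices,
  one-sided at the endpoints.
- **OBJ I/O** reads `v`/`f` records, tolerates `vt`/`vn`/material records,
  resolves negative (relative) indices, fan-triangulates polygons, and
  drops zero-area faces with a logged count in the load report. Parse
  errors name the offending line. Mesh repair (hole filling, smoothing) is
  out of scope; meshes are assumed clean enough.

## Template construction and sliding

**Seeding.** Semi-landmarks are first placed uniformly at random on the
surface (area-weighted, seeded RNG), then spread by farthest-point
propagation anchored at the prominent landmark (pronasale by default) and
relaxed by tangential repulsion toward the hexagonal equilibrium spacing
`s = sqrt(2A/(√3 n))`, re-projecting onto the surface each round. Requesting
more points than disks of the given radius can pack raises a capacity error
reporting the feasible maximum. Euclidean distance stands in for geodesic
distance during propagation — adequate for the gently curved surfaces this
targets. For `n > 1` the prominent point anchors the propagation but is not
itself returned (an exact duplicate of the fixed pronasale would make the
TPS system singular); `n = 1` returns the prominent point.

**Transfer.** The template-to-target TPS is fitted on the fixed landmarks
only; all semi-landmarks are warped through it and projected to the target
surface. Fixed landmarks are required input — digitized manually or by the
synthetic generator; no automatic anatomical detection is attempted.

**Sliding** minimizes the bending energy *to the template* (not the
Procrustes consensus, and not Procrustes distance): `B` is computed once per
target from the full template configuration, and each cycle solves the
linear least-squares problem in the tangential amplitudes, with surface
tangent frames and curve tangents recomputed at the current positions (the
standard local linearization). The normal system can be solved in closed
form because each parameter moves exactly one point:
`A[a,b] = (d_a·d_b)·B[i_a,i_b]`. A singular system falls back to a
ridge-regularized solve with a logged warning.

Two schedule details:

- Step scales decay geometrically from 100% to 5% over the six default
  cycles (the endpoints are fixed; geometric interpolation of the interior
  values is this package's choice).
- **Monotone safeguard.** The linearized move descends by construction, but
  re-projection onto a curved surface is a second-order perturbation that
  can cost more than a near-converged step gains. Each applied step is
  therefore halved (up to 8 times, else rejected) until the projected
  configuration does not increase the energy. This makes the per-cycle
  energy sequence non-increasing by construction without altering genuine
  sliding progress.

Fixed landmarks are never touched — output fixed coordinates are
bit-identical to the digitized input. Every semi-landmark ends projected on
the target surface.

## Statistics

- **GPA**: iterative centering, scaling to unit centroid size, and
  SVD-based orthogonal Procrustes rotation to the running consensus until
  the consensus moves < 1e-10 (max 100 iterations). Reflections are
  disallowed (`det +1`) — faces have handedness.
- **Shape PCA** uses the sample covariance (divisor `n−1`) of the
  vectorized aligned shapes about the consensus; eigenvalue sums equal the
  total Procrustes variance in the same normalization. Non-zero rank is
  bounded by `min(n−1, 3k−7)` — the 3D similarity shape space removes 3
  translations, 3 rotations and 1 scale. Broken-stick retention keeps
  components while the observed proportion strictly exceeds
  `b_i = (1/p) Σ_{j≥i} 1/j`, stopping at the first failure (so an exactly
  uniform spectrum retains none).
- **Procrustes ANOVA** is the Goodall-style decomposition for the nested
  replicate ⊂ individual ⊂ population design: sums of squared deviations of
  aligned coordinates at each stratum, summed over all 3k coordinates;
  degrees of freedom multiply the design df by the shape dimension `3k−7`;
  each stratum's mean square is tested against the next-lower stratum. The
  F-layout (which stratum tests against which) is documented here as this
  package's convention; other software makes other choices.
- **Permutation tests** on pairwise full-Procrustes distances between group
  mean shapes use random relabelling and the add-one rule
  `p = (1+x)/(1+n)`, so p can never be exactly zero; seeds make runs
  bit-reproducible. Note the p-value floor is only attainable when the
  group sizes admit more distinct relabellings than permutations drawn.
- **Allometry**: multivariate least squares of shape coordinates on
  centroid size, optionally pooled within groups (group means removed from
  both sides); `%predicted = SS_predicted/SS_total`; permutation p by
  shuffling size; regression scores are projections on the normalized
  coefficient vector. Centroid size is *not* log-transformed by default; a
  flag enables it.
- **CVA**: generalized symmetric eigenproblem of the between-group against
  the pooled within-group covariance, computed in a full-rank PCA subspace
  of dimension ≤ n − g; canonical scores have unit pooled within-group
  variance; pairwise Mahalanobis distances come from the same within
  metric. A singular within matrix raises a dimensionality error advising
  PCA reduction.
- **MANOVA** is the classical (parametric) Wilks' lambda test with Rao's F
  approximation, fitted with group, size covariate, and optionally their
  interaction (Type III hypotheses with treatment coding, via
  statsmodels); the slopes test uses the interaction model, the intercepts
  test refits without it. For a univariate response Wilks reduces exactly
  to the classical ANCOVA partial F, which the tests verify to 1e-9.
- Bilateral symmetric/asymmetric decomposition is not implemented (no
  landmark pairing is defined in the default scheme).

## Synthetic faces: what they emulate, and what they do not

`make_face_mesh` builds a smooth parametric face — dome, nose protrusion
(the global maximum along the face axis, by construction), eye depressions,
lip and chin ridges, plus small seeded large-scale bumps — with the 16
anatomical landmarks at grid nodes, hence exactly on-surface.

`simulate_population` composes, per individual: a population-level smooth
TPS deformation field, an individual field, an isotropic scale
(`1 + N(0, scale_sd)`), and an allometric displacement along a fixed smooth
unit field, proportional to the size change. Deformation fields are TPS
maps with random, energy-bounded coefficients **anchored at the 16
anatomical landmarks**: this concentrates simulated variation where real
facial variation is expressed and makes the true correspondence recoverable
in principle from the fixed-landmark inputs the pipeline actually receives,
so that digitization noise (iid Gaussian on the fixed landmarks of each
replicate — the manual step) is the error source, as in a real study.
Fields anchored far from the landmarks would inject variation that no
16-point transfer can see, which tests the generator, not the method.
Ground-truth semi-landmark homologues are carried through the known
deformation and projected to the deformed surface. Folding (any flipped
face normal) raises an amplitude error.

Default conditions: 3 populations × 5 subjects × 3 replicate digitizations
(the measurement-error design), population effect 2.5 mm RMS, individual
effect 1.2 mm RMS, digitization noise 0.5 mm, scale sd 6%, allometric
coefficient 0.03 mm of shape per mm of size.

**What passing tests show** — the optimizer reaches the brute-force
bending-energy optimum; energy descends across the schedule; sliding
recovers deliberately mis-slid (tangentially jittered) points to well under
0.3 mm; on ground-truth deformations sliding reduces the residual left by
the noisy-landmark transfer; the statistical procedures are calibrated
(type-I error, variance-component recovery, effect-size recovery).
**What they do not show** — robustness to scanner artefacts (holes, spikes,
topological noise), expression or pose variation, or the behaviour of the
16-point transfer under deformations that real anatomy might express far
from any fixed landmark. The synthetic surfaces are single-sheet height
fields; self-occluding geometry is untested.

## Problem sizes and determinism

Test and acceptance batteries run at reduced scale chosen as this package's
defaults for routine verification: meshes of 24–48 grid resolution
(≈1.2k–4.6k vertices), schemes of 16 + 40 semi-landmarks for the sliding
batteries and the full 16 + 484 scheme for the export checks, 50 synthetic
targets for the energy-descent battery, 200 null replicates for the type-I
calibration. All randomness flows from explicit seeds; reruns are
bit-identical, including permutation p-values and the full landmarking
pipeline.
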