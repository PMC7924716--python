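# morphowarp

Dense, homologous landmarking of 3D surface scans by template warping and
bending-energy sliding semi-landmarks, with the geometric-morphometric
statistics needed to validate the correspondence.

## Who this is for

Morphometricians and biometric researchers who have a collection of 3D
surface scans (e.g. facial meshes in Wavefront OBJ), a small set of manually
digitized anatomical landmarks per scan, and who want a dense set of
comparable points on every specimen without digitizing hundreds of points by
hand. The default template scheme is the 500-landmark facial configuration:
16 fixed anatomical landmarks (endocanthions, exocanthions, sellion,
pronasale, subnasale, alares, cheilions, labiale superius/inferius, gnathion,
obelions) plus 484 surface semi-landmarks seeded outward from the pronasale
(nose tip) at 1.5 mm radius.

## The method

1. **Template construction.** Semi-landmarks are placed at random on the
   template surface, then spread to quasi-uniform spacing by farthest-point
   propagation from the pronasale followed by tangential repulsion.
2. **Transfer.** For each target, a 3D thin-plate spline (TPS) is fitted
   from the template's fixed landmarks to the digitized target landmarks.
   The TPS interpolant `h(q) = Ψ(q)K + qΓ` (kernel `Ψ_w(q) = ‖q − s_w‖`)
   minimizes the bending energy

   `E(h) = ∭ Σ (∂²h/∂xᵢ∂xⱼ)² dx dy dz`

   subject to the interpolation constraints; `(K, Γ)` solve the bordered
   linear system with the kernel matrix and the affine side conditions.
   All semi-landmarks are warped through `h` and projected onto the closest
   point of the target surface.
3. **Sliding.** Semi-landmarks slide along their local tangent structures
   (tangent plane for surface points, curve tangent for curve points) to
   minimize the bending energy between template and target configuration —
   restricting motion to tangents makes each cycle a linear least-squares
   problem in the tangential amplitudes τ, minimizing
   `Σ_c (y_c + D_c τ)ᵀ B (y_c + D_c τ)` with B the template's
   bending-energy matrix. Six cycles are run with step scales decaying
   geometrically from 100% to 5%, re-projecting onto the surface after every
   cycle. The slid points are then treated as homologous in all downstream
   analyses.
4. **Statistics.** Generalized Procrustes analysis (translation, unit
   centroid size, proper rotations), shape PCA with broken-stick component
   retention, Goodall-style Procrustes ANOVA of the nested
   population/individual/replicate design (the measurement-error
   assessment), pairwise Procrustes-distance permutation tests, multivariate
   regression of shape on centroid size (allometry), canonical variate
   analysis, and Wilks' lambda MANOVA with a size covariate.

Because real facial-scan databases are licensed, the package ships a
synthetic-face generator (`morphowarp.synthetic`) that emulates
multi-population scan data with known ground-truth correspondence: smooth
TPS deformation fields anchored at the anatomical landmarks, per-individual
scale, optional size-coupled (allometric) shape change, and digitization
noise on the fixed landmarks. Every stage of the pipeline is tested against
this ground truth.

## Worked example

```
morphowarp simulate --out demo --seed 1 --resolution 28 \
    --populations 3 --subjects 4 --replicates 3 --n-semis 60
morphowarp landmark run --config demo/config.yaml
morphowarp stats run --table demo/results/landmarks.csv \
    --metadata demo/metadata.csv --out demo/stats --n-perm 999 --seed 1
```

This simulates three populations of four individuals, each digitized three
times, landmarks every replicate (`36 specimens landmarked (228 coordinate
columns); 0 failures`), and prints the statistics summary:

```
[fixed] n=36 k=16: PCA retained 2 components (broken stick); PC1 43.51%
[fixed] Procrustes ANOVA error variance 7.61%
[fixed] allometry: 19.21% of shape variance predicted by centroid size (p=0.001)
[semis] n=36 k=60: PCA retained 3 components (broken stick); PC1 59.41%
[semis] Procrustes ANOVA error variance 4.34%
[semis] allometry: 21.43% of shape variance predicted by centroid size (p=0.001)
[combined] n=36 k=76: PCA retained 2 components (broken stick); PC1 52.24%
[combined] Procrustes ANOVA error variance 5.20%
[combined] allometry: 20.74% of shape variance predicted by centroid size (p=0.001)
```

Reading this: for each landmark partition (fixed anatomical landmarks only,
sliding semi-landmarks only, combined) the digitization-error stratum of the
Procrustes ANOVA accounts for a small share of total shape variance — and
the slid semi-landmarks are *more* repeatable (4.34%) than the manually
digitized fixed points (7.61%), because sliding uses the surface itself to
regularize away digitization noise. The per-partition ANOVA tables, PCA
scores, Procrustes distances, CVA Mahalanobis distances, and MANOVA tables
are written as CSV next to the summary. With the default scheme
(`--n-semis 484`) the flat landmark table has 1,500 coordinate columns
(48 for the 16 fixed landmarks, 1,452 for the 484 semi-landmarks).

The library mirrors the CLI one-to-one: `build_scheme`, `transfer_template`,
`slide`, `gpa_align`, `shape_pca`, `procrustes_anova`, … — see the module
docstrings.

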