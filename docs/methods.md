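# Methods

## Scope

`morphocell` implements a two-part analysis of single-cancer-cell
morphology:

1. **Morphometrics** — six dimensionless shape descriptors computed per cell
   from a segmented 2-D label mask, z-scoring, k-means morphotyping
   (round / droplet / spindle), PCA and t-SNE morphospace projection, and an
   aspect-ratio M1/M2/M3 categorisation.
2. **Mechanics** — a single-cell vertex model of the basal outline whose
   three-phase protocol (isotropic expansion → anterior–posterior
   polarisation → depolarisation) reproduces the round → droplet → spindle
   evolution, plus single-factor perturbations of Rac protrusion, focal
   adhesions and cortical tension.

Segmentation itself (e.g. Cellpose), fibre ridge detection and any
intensity-based quantification are out of scope: masks, fibre polylines and
nuclear masks are consumed as inputs, and the `synthetic_data` module
generates all of them with known ground truth.

## Shape descriptors

All descriptors are computed per connected cell region after hole filling
(8-connectivity for cells, 4 for background). Cells smaller than `min_area`
(default 20 μm²) or touching the image border are excluded — border cells
have truncated geometry. Boundaries are traced with marching squares at the
0.5 level and smoothed with a circular moving average whose window is a
fixed fraction (~1 %) of the contour length; without this, the half-pixel
staircase inflates the perimeter by ~10 % and biases 4πA/P² far below 1 for
a disk. The window scales with the contour so descriptors survive
upsampling.

- **roundness** = 4πA/P² on the traced polygon (1 for a circle). The
  verbal definition ("how closely the shape approaches a circle") admits
  several formulas; 4πA/P² is the standard isoperimetric reading.
- **extent** = cell pixels / bounding-box pixels. Computed on pixels, not
  the polygon: the definition is a pixel ratio and the pixel form is
  exactly invariant under integer upsampling.
- **inscribed-circle ratio** = π·r_max²/A with r_max the maximum of the
  Euclidean distance transform of the (zero-padded) region.
- **aspect ratio** = major/minor axis of the moment-equivalent ellipse
  (eigenvalues of the second central moments, + 1/12 px² per axis so thin
  regions stay non-degenerate).
- **symmetric ratio** — reflect the region across the line through the
  centroid along the minor axis; report |region Δ reflection| / 2A, which is
  0 for a bilaterally symmetric cell and bounded below 1. The raw ratio
  (divide by A, range up to 2) is available via `symmetric_ratio_raw`.
  Implemented on the traced polygon with exact affine reflection; the test
  oracle is an independent raster fold-XOR.
- **signature peaks** — the centroid-to-boundary distance sampled by ray
  casting on a 360-bin angular grid (farthest intersection, so concave
  shapes are well defined), smoothed over 5°, peaks counted with circular
  topology at 5 % of-range prominence. Maxima closer than 10° are merged
  (flat-topped peaks of rasterised shapes split into twins after smoothing)
  and a signature whose range is < 2 % of the mean radius counts as flat
  (zero peaks) — a rasterised disk otherwise accumulates noise peaks.
- **leading edge** — the paper-level notion of lamellipodium extent is made
  operational as the longest contiguous boundary arc with local curvature
  below 2/r_eq (twice the equal-area-circle curvature; configurable) whose
  chord lies within 45° of perpendicular to the major axis. Curvature is
  estimated from circumcircles on a smoothed, arc-length-resampled contour
  with a widened stencil (three-point curvature at pixel spacing is
  noise-dominated). A cell whose whole boundary passes the curvature test
  (a disk) has fraction 1; a cell with no qualifying arc reports 0.

These measurement choices (smoothing window, prominence, curvature
threshold) are stated because the underlying verbal definitions do not pin
them down; all are configurable in `DescriptorConfig`.

## Morphospace

Features are z-scored per column with the sample (n−1) SD. k-means uses
k-means++ with `n_restarts` (default 10) restarts, best inertia kept,
deterministic per seed; labels are renumbered by ascending centroid aspect
ratio so T1 is always the roundest morphotype and runs are comparable
across seeds. PCA fixes each component's sign so its largest-|loading|
entry is positive. t-SNE (perplexity 30, 1000 iterations, PCA init,
seeded) is visualisation-only: the only quantitative claim made of an
embedding is a cluster-separation score (silhouette vs the true classes).
M1/M2/M3 categorisation defaults to population tertiles of the aspect ratio
— no fixed cutoffs are published — with fixed thresholds as an override;
the M2/M3 boundary is right-closed (AR = a2 → M3).

## Vertex model

The basal outline is a closed chain of n = 64 vertices obeying overdamped
force balance per vertex:

    η dx/dt = F_tension + F_area + F_rac + F_adhesion + F_fibre + F_noise

- **Tension**: K_L(ŝ⁺ + ŝ⁻), unit vectors toward the two neighbours;
  contractile, sums to zero over the closed chain.
- **Area elasticity**: −K_a·ŝ·(A−A0)·r̂, with ŝ the mean adjacent edge
  length ("coverage cortical length") and r̂ the outward normal; outward
  below the target area A0, inward above.
- **Rac protrusion**: an outward normal force with Gaussian temporal
  envelope f_rac·N(t; T, σ) restricted to a front sector (vertices within
  `rac_sector` of the +x direction about the centroid). The envelope alone
  carries no spatial information; without the sector restriction no
  anterior–posterior axis can emerge. Sector membership is refreshed from
  vertex position angle each step so the front stays coherent under large
  deformation. The pulse clock restarts at each phase boundary and T is
  the pulse centre.
- **Adhesion**: a Hill-gated friction −f_cams·H·dx/dt with
  H = L_Rho^n/(K + L_Rho^n). Physically, engaged adhesions resist membrane
  sliding. Numerically the friction is folded into the drag
  (dx = dt·F/(η + f_cams·H)): an explicit previous-step form diverges by
  oscillation whenever f_cams·H > η, while the implicit form is
  unconditionally consistent and identical as dt → 0.
- **Stress fibres**: linear springs K_f(L − L0) between boundary vertices
  in front and rear angular sectors (±x) and the centroid — pushing the
  poles out when L < L0, contractile beyond. Two couplings make the fibres
  biologically coherent: (i) their force is transmitted through focal
  adhesions, scaled by γ/(f_half + γ) with γ = f_cams·H, because fibres
  terminate at adhesion sites — this is what lets an adhesion knock-down
  suppress the depolarisation-phase elongation; (ii) polarity-axis fibres
  only exist once a polarity axis does, so the force ramps from zero below
  5 % cell elongation to full strength at 15 %. An unpolarised (Rac-off)
  cell therefore feels no fibre force and stays round, which is also what
  keeps the isotropic control runs isotropic. Anchoring every vertex
  uniformly to the centroid is available (`fibre_sector = π`), but a
  uniform centroid spring is isotropic and cannot hold a spindle's length
  while tension narrows its body.
- **Noise**: f_R per-component unit Gaussians, seeded.

Integration is explicit Euler, all vertices updated simultaneously from
pre-step forces, with a stability guard (max |Δx| < ŝ/2 per step raises
with advice to reduce dt) and optional equal-arc-length resampling when
neighbour spacing becomes > 3:1 (area preserved to < 0.1 %, events logged).

### Parameters and phases

No parameter magnitudes are published for this model. Units are μm / s /
nN; the defaults (η = 1, K_L = 0.5 nN, K_a = 0.01 nN/μm³, A0 = 400 μm²,
f_rac = 400 nN·s with σ = 30 s centred at 180 s of the polarisation phase,
f_cams = 10 with H = ½, K_f = 0.2 nN/μm, L0 = 11.5 μm, f_R = 0.02 nN,
dt = 0.05 s) were fixed once so that the analytic equilibria and the
qualitative three-phase behaviour hold, and ship as the versioned default
configuration. All quantitative claims about the model are relative or
directional — never tied to a particular parameter set.

Default protocol: expansion 120 s (Rac, fibres and adhesion off),
polarisation 250 s (one Rac cycle, fibres near rest length), depolarisation
350 s (Rac off, K_L doubled, K_f tripled, L0 = 17 μm). With tension and
area only, the circular fixed point satisfies
K_a·ŝ·(A0−A) = 2K_L·sin(π/n) per vertex; the simulation reproduces the
closed-form A* to ≪ 1 %. The default run ends its phases with circularity
≈ 1.0 → 0.73 → 0.53 and a final length/width ≈ 1.8.

### Perturbation conditions

The suite runs, with paired seeds: Rac inhibition (f_rac = 0 in
polarisation), focal-adhesion reduction (f_cams 10 → 1 in phases 2–3) and
weakened tension (K_L halved in phases 2–3). Readouts: peak polarity
(minimum width/length during polarisation), final A-P length, and the time
of first crossing of width/length < 0.75 — the threshold at which a cell is
clearly polarised (aspect 4:3). Weaker tension both deepens polarisation
and slows the post-pulse rounding, so it crosses the threshold earlier;
the shallower 0.8 crossing happens on the pulse rise where the lateral
spread of the front dominates and tension hardly matters.

## Synthetic data

The generator emulates a mixed culture of the three morphotypes as label
masks: round cells are noisy ellipses with AR ∈ [1, 1.3]; droplets are a
superellipse front (exponent 4, flat wide leading edge) blended with a
power-taper tail, AR ∈ [1.4, 2.2], asymmetric about the minor axis;
spindles are pole-sharpened lenses with AR ∈ [2.5, 6]. Sizes are normal
(equivalent diameter 40 ± 6 μm), boundary noise is a band-limited radial
perturbation (default 5 % amplitude, modes 2–7), and cells are placed
without overlap on one label image (bounding-disc test, largest first).
Every mask carries a truth table; everything is seed-deterministic.

A separate constructed-covariance generator
(`make_elongation_dominated_features`) emits a feature table in which a
latent elongation axis drives the aspect ratio almost perfectly (r ≈ 0.97)
and the other descriptors only partially; it exists because on rasterised
shape families roundness is itself a nearly deterministic monotone function
of elongation, so "which z-scored descriptor loads PC1 most" is a
coin-flip between aspect ratio and roundness on mask-derived tables. The
constructed table makes the PCA attribution check well-posed.

What the synthetic data does **not** emulate: real segmentation errors
(merged/split cells), intensity textures, protrusive substructure
(filopodia), cell–cell contacts, or the true covariance of descriptors in
cultured cells. Passing tests therefore demonstrate correctness of the
measurement and recovery machinery under controlled geometry, not
performance on micrographs.

## Auxiliary metrics

The fibre **crimp ratio** is arc length / end-to-end chord of a traced
polyline (1 = straight), the standard tortuosity measure; an exactly closed
polyline has no chord and is rejected. Nuclear metrics from a binary 3-D
mask: cross-sectional area and moment aspect ratio on the largest-area x–y
slice, height as z-extent × voxel size, volume as voxel count × voxel
volume, and convexity as volume / convex-hull volume (hull of voxel
centres; a degenerate single-slice mask falls back to corner-padded
voxels). The maximum-area slice and the hull-based convexity are this
package's choices; the source definitions are unstated.

## Problem sizes and tolerances

Defaults used by the tests and the acceptance script: 300-cell populations
(100 per class) for recovery, 20 blobs for oracle equivalence, 64-vertex
cells, 10 paired seeds for the perturbation directions. Descriptor analytic
checks run at 2–3 % (rasterisation-limited), the vertex-model equilibrium
at 2 %, dt-halving at 1 %, clustering at ARI ≥ 0.9 and embeddings at
silhouette ≥ 0.3. Known limitations: descriptor accuracy degrades below
~20 px cell diameter (smoothing dominates); the signature-peak count on
noisy boundaries is sensitive to the prominence convention; the vertex
model is single-cell, 2-D, and has no membrane-reservoir (caveolae)
mechanics — tension changes are imposed, not emergent.
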