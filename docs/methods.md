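# Methods

`beastrack` segments and tracks cell bodies in 2D time-lapse fluorescence
recordings of moving, contractile tissue (the motivating system is Ca²⁺
imaging of enteric neurons expressing GCaMP), and extracts per-cell
mean-intensity time series without registering the stack. This note
documents the model, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Contour model

Each cell boundary is an explicit function in polar coordinates about a
movable pole x₀:

    r(θ) = ψ(θ) = Σₖ c[k] · β_d(θ/h − k),

where β_d is the uniform symmetric B-spline of degree d, knots are regular
with spacing h, and coefficient indices wrap modulo the node count N. The
explicit form restricts the boundary to star-shaped, cell-like topologies
(no splitting or merging; cell division is out of scope) and makes
evaluation, smoothing and analytic derivatives cheap. Defaults: N = 32
nodes (dθ = 2π/N), d = 2 (quadratic: continuous first derivative for
curvature at low cost), h = dθ (one coefficient per node, so the "matrix
size" parameter equals the node count). The interpolation system on the
regular node grid is circulant and is solved spectrally. Node radii are
clamped to ≥ 1 px so the pole can never cross the boundary, which the polar
representation cannot express.

Local curvature is computed analytically from the polar form,
κ = (r² + 2r′² − r r″)/(r² + r′²)^{3/2}, positive for a convex boundary.

A **double contour** couples two such curves around one shared pole: an
inner contour on the nucleus–cytoplasm interface (GCaMP is excluded from
the nucleus, so this interface is sharp and stable) and an outer contour on
the cytoplasm–background interface, constrained by
r_cyt(θₖ) ≥ r_nuc(θₖ) + margin (default 1 px) at every node.

## Energies

The total energy is E = E_d + E_r.

**Data attachment (E_d).** At each node, mean intensities u_in and u_out are
estimated inside and outside the boundary in a column of ρ unit-spaced
samples along the node normal on each side ("ρ samples per side" is our
reading of the band length; the sensitivity to this factor-two choice is
flat). The criterion is the localized mean-separation (Yezzi) energy,
−(u_in − u_out)² per node. Two implementation layers exist:

- The *analysis* operations (`local_band`, `localized_means`, `yezzi_force`)
  use rounded pixel sets and the pointwise force
  (u_in − u_out)·((I − u_in)/n_in + (I − u_out)/n_out), matching the
  textbook formulation; they are the contract the unit tests verify against
  exhaustive pixel classification.
- The *evolution engine* samples the bands bilinearly at continuous
  positions (keeping the energy continuous in the radii), widens the band
  by ±1 px tangential columns for noise averaging, and uses the consistent
  first variation of sliding-band means: du/dr is the band-averaged
  directional image gradient along the normal (gradient field computed once
  per frame on a σ = 1 px smoothed copy), so the force is the descent
  direction of the energy actually being evaluated. With the pointwise
  force, nodes trap in noise minima at realistic SNR; with the consistent
  variation, a bright disk at SNR 5 is recovered to < 0.2 px from a ±30%
  initialization.
- The criterion is *polarity-aware*: the separation is signed so that a
  cytoplasm layer only locks onto bright-inside interfaces and a nucleus
  layer onto dark-inside ones (for correct polarity this equals the squared
  criterion; with inverted polarity the contour is repelled instead of
  locking onto, e.g., the cluster border from outside). GCaMP morphology
  makes the polarity known a priori.

ρ bounds the per-frame motion the data term can see. Default ρ = 8 px;
for one-layer tracking of cells with a prominent dark nucleus we recommend
ρ just below the boundary-to-nucleus distance (ρ = 6 for the default
synthetic geometry), following the rule of keeping the inner band off the
nucleus edge. The nucleus layer's ρ is tied to its own radius
(clip(r_nuc, 4, ρ)): the inward band stays dark even past the pole, while
below ~4 px the band cannot cover frame-to-frame motion.

**Regularization (E_r).** Per contour: w_κ·E_κ + w_A·E_A + w_AS·E_AS plus
competition terms per neighbor:

- Curvature: gradient κ·H(−κ) per node — only concave (locally dented)
  arcs are penalized; a convex cell is untouched.
- Area range: (A − A_min)·H(A_min − A) + (A_max − A)·H(A − A_max), applied
  as a uniform radial force (expand when too small, shrink when too large).
  When no explicit bounds are configured the tracker derives per-cell
  bounds (0.7–1.6× the frame-0 area); during initialization the user
  ellipse's area provides the bounds, so a cell with no visible borders
  cannot engulf its neighborhood nor collapse while overlaps are resolved.
- Area stability: energy |A_t − A_{t−1}|/A_{t−1}; the restoring force is
  proportional to the relative area change (descent on the squared
  surrogate). A fixed-magnitude nudge proved too weak to resist the squeeze
  of competing neighbors.
- Proximity penalty: per node of contour i, (d_T − ψ)·H(d_T − ψ), where ψ
  is the signed Euclidean distance to neighbor j's dense polygon (negative
  inside). Discourages approaches closer than d_T (default 2 px).
- Overlap penalty: w_c · A_overlap when the interiors intersect, with
  inward forces on penetrating nodes proportional to their penetration
  depth. Polygon intersections and signed distances are computed with
  shapely.

Inside the engine the competition terms (pixel units) are scaled by a fixed
factor 0.05 onto the squared-normalized-intensity scale of the data term;
`d_thresh` and `w_comp` keep their interpretable pixel units. Neighbor
pairs are pruned by pole distance. All intensities are min–max normalized
over the stack before tracking so that the default weights transfer.

Defaults (normalized intensities): w_κ = 0.05, w_A = 0.005, w_AS = 2,
w_c = 0.5, d_T = 2 px.

## Optimization

A modified gradient descent with feedback step adjustment: node forces are
projected onto the B-spline coefficient space (circular convolution with
β_d at integer lags, which smooths the evolution along the contour), a
candidate step is taken, and its energy is evaluated; an energy-increasing
step is reverted and the step size halved, an accepted step grows it by
1.1×. The step size equals the largest node displacement (initial 0.5 px);
descent stops below a 0.05 px tolerance or after 60 iterations. Accepted
energies are non-increasing by construction.

The pole is a descent variable too: the energy gradient with respect to the
pole is the sum of node forces projected on their outward normals. The pole
step uses a gained normalization (gain 8 relative to the radial forces) —
large enough that rigid cell motion is followed without being throttled by
the radial noise floor, small enough that a balanced force pattern leaves
the pole in place. For one-layer contours only the *data* force drives the
pole: competition reshapes radii but must not translate a cell.

**Double contours evolve anchor-first.** Phase 1 evolves the nucleus alone
(radii + pole): its sharp, stable interface is the most reliable feature,
and it drags the whole cell rigidly. The nucleus is capped inside the
frozen cytoplasm (r_nuc ≤ r_cyt − margin), because the background is as
dark as a nucleus and an uncapped inner contour can leak to the cell
border. Phase 2 evolves the cytoplasm radii around the fixed pole under the
full energy; the ordering constraint is restored after every step.

**Frame loop.** Cells are updated sequentially (two sweeps, alternating
order) against their neighbors' current contours, then re-centered: the
pole moves to the interior centroid (nucleus centroid for double contours —
tying the shared pole to the outer layer would let a competition-distorted
cytoplasm drag it off the nucleus) and the nodes are re-gridded by linear
interpolation of their polar coordinates. Frame t's result seeds frame
t+1. Initialization evolves each user ellipse solo first (the ellipse is
the per-cell prior), then resolves overlaps jointly under an effectively
infinite overlap weight (40× the configured w_c — so a competition-ablation
run with w_c = 0 genuinely has no competition anywhere). A degenerate
contour (centroid outside the shape, or collapsed resampling) freezes the
cell's last valid contour for that frame and flags it; frozen frames keep
their trace values flagged.

**Signal extraction.** One-layer: mean over the rasterized contour
interior. Double: mean over cytoplasm-minus-nucleus pixels, which excludes
the dark nucleus from the Ca²⁺ signal and brings the raw fluorescence level
close to the true cytoplasmic one.

## Landmark-based ROI propagation

Tracked cell centroids are landmarks. For each consecutive frame pair a
global transform T minimizing Σᵢ ‖xᵢ^{f+1} − T(xᵢ^f)‖² is fitted by linear
least squares (models: translation, 6-parameter affine, 12-parameter
quadratic polynomial; default affine; automatic fallback to the next
simpler model when under-determined or rank-deficient, cells with lost
frames excluded). Manually drawn ROIs are then chained forward with T and
backward with the analytic inverse (refused, with a flag, for the
polynomial model). One global transform is fitted per frame pair; locally
weighted transforms near each ROI would be a possible extension.

## Synthetic benchmark

The generator renders a cluster of ~7 overlapping cells (radius 14 ± 2 px,
nucleus fraction 0.45) with equal cytoplasm baselines (100), dark nuclei
(30) and background (20), per-cell double-exponential Ca²⁺ transients
(amplitude 120, τ_rise 2, τ_decay 10 frames), Gaussian-blurred
"out-of-focus" frames (σ = 7 px, two per 50 frames), and additive Gaussian
sensor noise (SNR ≈ 5), over 100 frames of 256×256 px by default.

Motion emulates contraction: a smooth shared (coherent) velocity process
plus small per-cell wobble (coherence 0.8), mean-reverting toward the rest
position — contractile tissue deforms but the ganglion stays anchored in
the field of view — with per-frame displacement clipped at 3 px. Overlap
is controlled by the center-distance deficit of neighbor pairs (default
0.15 of the summed radii). Overlapping pixels are attributed to the cell
whose boundary they are deepest inside; at rest all cells share one
baseline, so overlaps are borderless exactly as in the recordings this
emulates, while each cell's ground-truth cytoplasm mean equals its
configured waveform to rounding error. Ground truth (per-frame masks,
waveforms, centroid trajectories) is captured before noise.

What the benchmark does *not* emulate: realistic photon statistics,
point-spread functions, intensity gradients within a cell, non-rigid
warping of cell shapes, neuropil background structure, or partial nuclear
GCaMP entry. Passing here shows the machinery tracks borderless,
overlapping, blinking, moving cells under idealized optics; it does not
replace validation on real recordings.

## Known limitations

- A one-layer contour on a cell *fully* enclosed by equal-baseline
  neighbors has no image evidence anywhere on its boundary; it is carried
  by regularization and competition only and degrades over long recordings
  with sustained motion. The double contour is the intended tool for that
  regime, and its extracted signals are also offset-free (a one-layer trace
  includes the dark nucleus, a systematic ~15% downward offset at the
  default geometry). Landmark ROI propagation is the documented fallback
  for cells the contours cannot hold.
- Tracking range is bounded by ρ (and for double contours by the nucleus
  radius); per-frame displacements beyond it lose the cell, by design.
- The double contour requires nucleus–cytoplasm contrast; frames without it
  are flagged (`low_contrast`) and the layer stalls rather than invents an
  interface.
- Robustness at coarse discretizations is better than the original lineage:
  16 nodes track the default scene as well as 32 do, so node count is not a
  failure axis for this implementation.
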