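# Methods

This note documents the models, conventions and numerical choices behind
`psmap`, in the spirit of a methods appendix: what the code assumes, which
knobs matter, and what the synthetic validation does and does not show.

## Phase model and conventions

A phase map assigns each node an instantaneous phase in (−π, π], wrapped
with the half-open convention `wrap(x) = π − ((π − x) mod 2π)` (both ±π
map to +π).  A phase singularity (PS) is a node around which the phase
winds by ±2π along a closed loop; its sign — the chirality — is +1 when
the phase increases along the *clockwise* loop, where clockwise is defined
against the outward surface normal (looking at the surface from outside).
The cylindrical 2D projection is oriented so that on-screen clockwise
(up → right → down → left, rows rendered top-down) coincides with the mesh
convention; all four detectors therefore report the same chirality for the
same field, and the 2×2-plaquette winding number traversed clockwise
on-screen is the reference topological charge.

The Hilbert analytic signal assigns increasing phase to positive-frequency
signals, so synthetic fields advance as +ωt; a cosine electrogram built
from such a field recovers its own phase (no constant offset).  A constant
phase offset moves no singularity, but keeping the pipeline phase-neutral
makes round trips directly comparable sample-by-sample.

## Electrogram processing

* **Resampling**: cubic splines to 512 Hz.  The signal band of interest
  (≤ 150 Hz) is far below Nyquist, so this is lossless in practice.
* **Dominant frequency (DF)**: magnitude spectrum of the detrended,
  Hann-windowed record, zero-padded to ≤ 0.05 Hz resolution; the largest
  peak inside 3–15 Hz (the physiological AF range) defines the local cycle
  length 1/DF.  One cycle length per channel per episode.
* **Sinusoidal recomposition**: the signal is rebuilt as a superposition
  of single-cycle sinusoidal wavelets of period 1/DF, one centered at each
  sample, with amplitude |dV/dt| where the slope is negative and zero
  elsewhere.  The wavelet is a centered single negative *sine* cycle.
  This shape is deliberate: it is odd, so the recomposition of a sinusoid
  is exactly phase-neutral, whereas a (co)sine-even wavelet would shift
  every recovered phase by ±π/2.  Downstroke timing — the physiologically
  meaningful activation marker — is identical either way.
* **Hilbert phase**: frequency-domain analytic signal of the
  mean-subtracted record.  Edge effects are confined to the first and last
  5% of frames, which `edge_frame_mask` flags; round-trip statistics are
  computed on interior frames.
* Channels that are constant or have no spectral peak are recorded as
  failed (phase 0); the pipeline aborts if more than 10% of channels fail.

## The four detectors

Loop-based detectors (1, 2, 4) walk a closed ring of neighbors: the
Manhattan-distance-N "diamond" on the grid (columns wrap at the cylinder
seam, rows clamp — nodes without a complete ring are skipped), or the set
of nodes at graph distance exactly N on the mesh, sorted by angle in the
tangent plane (orthogonal to the angle-weighted vertex normal), clockwise,
starting at the lowest node index.  Search radii count nodes, not mm: the
mean inter-node spacing (~3.45 mm) is a property of the mesh, not of the
algorithm.

* **Monotonic-loop rule (algorithms 1, 2)**: a loop is accepted when,
  traversed from its minimum-phase member, the raw phases are
  non-decreasing with the single wrap crossing at the closing step (or the
  mirrored decreasing case), and the loop range max(φ)−min(φ) clears the
  threshold.  Strict monotonicity is required; jitter breaks it, which is
  why these detectors lose sensitivity on noisy fields much faster than
  the charge-based ones.
* **Candidate pre-selection (algorithm 1)**: Canny runs on the magnitude
  of the wrapped one-step phase gradients (running it on raw phase would
  outline every wrap line).  Candidates are edge pixels with exactly one
  8-connected edge neighbor — the ends of edge lines.  On ideal fields the
  near-core gradient blob closes into a small contour with *no* free ends,
  so pixels of endpoint-free edge components are also taken as candidates:
  a closed contour is the degenerate end of an edge line, and the
  monotonic-loop test still decides.  Hysteresis thresholds default to
  (0.3π, 0.6π) per unit step; the seam is handled by periodic column
  padding.  Confirmed pixels are clustered (8-connected, seam-aware) and
  each cluster is replaced by its center of gravity snapped to the nearest
  cell (ties toward the lower row, then column).
* **Charge kernels (algorithm 3)**: the charge is
  `(∇x ⋆ k_y + ∇y ⋆ k_x) / (2π·m)` where k_x, k_y are wrapped one-step
  phase differences (periodic across the seam; rows clamped, with the
  affected boundary rows blanked), the stencil pairs are the conventional
  sobel 3×3 and nabla 2×2 weights plus standard sobel 5×5 and
  central-difference nabla 3×3 forms, and m is the pair's loop
  multiplicity — its raw response to one ideal vortex centered on a
  plaquette (1, 1, 18 and ≈0.7048 respectively), frozen in
  `kernels.CHARGE_NORM` so every kernel reports charge ±1 at an ideal
  core.  The two published stencil families carry opposite sign
  conventions; each pair is oriented (`kernels.FLIP`) so that charge sign
  equals the winding number.  With this alignment the nabla 2×2 charge is
  *bit-exact* against the brute-force plaquette winding; the smoothing
  kernels spread the response over 2–3 cells and their peak dips to ~0.94
  when a core sits on a node rather than a plaquette center — one reason
  the strict 1.9π default under-detects and the published optimum sits
  near π.
* **Odd-jump rule (algorithm 4)**: along the clockwise ring, the signed
  jump count is s = #(raw consecutive differences < −T) − #(> +T),
  closing pair included; |s| odd marks a PS with chirality sign(s).  Raw
  (not wrapped) differences are essential: the jump of interest is the
  ±2π wrap crossing, which wrapping would erase.

**Cluster refinement**: detections in one frame are joined by an edge when
mesh-adjacent or within 5 mm (straight-line Euclidean — geodesic would
change nothing at this scale); each connected component keeps its
greatest-gradient member (ties toward the lowest node index).  The
operation is idempotent and never increases the count.  Note the
representative is the *strongest* cluster member, not the nearest to the
true core: for algorithm 2 at N = 3 the loop range is nearly constant
across all core-enclosing rings, so the representative can legitimately
sit one or two nodes off-core even on ideal data — consistent with that
algorithm's modest published accuracy, and the reason accuracy checks
distinguish candidate coverage from refined-count uniqueness.

### Threshold monotonicity

Raising the threshold can only shrink the detection sets of algorithms
1–3 (their rules are of the form "statistic ≥ T"), so their per-frame
counts are exactly non-increasing along the 0.1π–2π grid.  Algorithm 4's
rule is a *parity*: when a threshold increase removes one member of an
up/down jump pair (a plain wavefront crossing produces such a pair, with
slightly unequal magnitudes around 5.6–6.0 rad on this grid), the parity
flips and a detection appears.  The decreasing trend holds broadly, but
exact monotonicity is structurally false for that rule; the corresponding
acceptance check is left failing by design and the violation count is
reported, not hidden.

## Evaluation

Matching is per frame: annotations and detections within 5 mm are paired
greedily (nearest pair first, one-to-one); each matched annotation is a
TP, every unmatched detection an FP (duplicates around a matched
annotation included), every unmatched annotation an FN, and TN fills the
node×frame ledger.  TP + FN equals the annotation count by construction.
Counts are pooled (micro-averaged) across episodes before F_β; β = 2
weighs recall over precision, appropriate for 1–4 positives among 2048
nodes, where ROC-style specificity is uninformative.  SSIM is computed
globally from map-level moments (a sliding-window variant is available
behind a flag); CORR is the 2D Pearson coefficient.  The sweep grid is
thresholds 0.1π–2π (step 0.1π) × radii 1–8 (2–8 for algorithm 1; the four
kernels for algorithm 3); argmax ties prefer the larger threshold, then
the smaller radius (stricter and cheaper).  Cross-validation partitions
*episodes* (not frames) into k deterministic folds.

## Synthetic fields

Spirals are built through the conformal map w = exp(i(u + iv)) from the
cylinder to the punctured plane: φ = Σ χ_i·arg(w − w_i) − k·ρ̃ + ωt + noise,
with u the azimuth and v the row scaled to equal per-cell units.  This
makes a single vortex seam-consistent, with the topologically required
compensating charge at the cylinder end — on a capped mesh, the apex node,
which is recorded in the annotation table so that charge-conservation
checks are honest.  The radial pitch saturates, ρ̃ = s·tanh(ρ/s) with
s = 10 cells: near the core the field is an Archimedean spiral
(wavenumber 2π/40 per cell ≈ one wavelength per 14 cm), far away it is
rotation-dominated, keeping the rim of a capped mesh nearly iso-phase
(an unbounded pitch would force ~3 rad of spread onto the apex's ring and
fabricate jump detections no physiological field would produce).
Defaults emulate the target acquisition: 32×64 grid (2048 nodes, ~3.45 mm
spacing), 205-frame episodes at 512 frames/s (~0.4 s, the scale of
annotated rotor episodes), rotor frequency 7 Hz (ω ≈ 0.086 rad/frame),
1–4 cores per frame across scenario kinds, meander drift radius 3 cells,
phase noise up to 0.5 rad.  Cores are kept half a cell off mesh vertices;
annotations snap to the nearest node.  Electrograms are
a·cos(φ) + white noise with per-node amplitude jitter (default ±20%).

What this shows — and does not.  The generator produces smooth,
narrowband, charge-consistent fields with known cores; passing tests
demonstrate that the detectors, metrics and optimization behave correctly
on such fields at clinical scale.  It does not emulate ventricular
far-field contamination, inverse-solution smoothing and its spatial
correlation structure, fractionated or low-amplitude electrograms,
wavebreak, or expert-annotation ambiguity; absolute F_β values measured
here are therefore upper bounds, not forecasts of clinical performance,
and published patient-data scores are not reproducible from synthetic
fields.

## Problem sizes and numerical details

Detection-accuracy checks run at the full clinical scale (205 frames ×
2048 nodes).  Cross-validation uses ten 24-frame episodes with noise
spanning 0–0.5 rad — the sweep surface of a stationary rotor is constant
in time, so short episodes carry the same information at a fraction of the
cost; the round trip uses a 1.5 s recording so every channel exceeds the
1 s minimum for DF estimation.  Rings are precomputed per (mesh, radius)
and grouped by length for vectorized scanning.  Degenerate inputs are
defined errors: constant signals have no phase, zero-variance maps no
correlation, boundary nodes no closed ring (skipped and counted), and
2π loop ranges are unreachable on finite rings.  Charge rows whose
stencil support crosses the open top/bottom boundary are blanked
(conservatively by one extra row).  All randomness flows from explicit
seeds; fixed seeds give byte-identical outputs.

## Known limitations

* Algorithm 1's candidate stage inherits Canny's fragility: under phase
  noise ≳ 0.3 rad the edge map fragments and detection fails long before
  the charge-based detectors degrade.
* The greatest-gradient cluster representative (algorithms 2/4 at larger
  N) is a biased location estimate, as discussed above.
* Reflection antisymmetry of the charge field is exact for nabla 2×2 but
  only alignment-approximate for the smoothing kernels, whose two stencil
  terms re-anchor to different half-cells under mirroring.
* Rotor tracking across frames, PS duration/rotation classification and
  geodesic distances are out of scope; detection is strictly
  single-frame.
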