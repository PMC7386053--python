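# psmap — single-frame phase-singularity detection for cardiac phase maps

During atrial fibrillation (AF), re-entrant spiral waves ("rotors") are
candidate ablation targets.  The tip of a rotor is a **phase singularity
(PS)**: a point in a single phase map around which the instantaneous phase
progresses monotonically through a full 2π cycle.  Automated PS detectors
disagree with each other — the algorithm, its phase-gradient threshold and
its search radius all change which atrial sites get called drivers — and
`psmap` implements the four standard detector families side by side, on
equal footing, with the evaluation machinery needed to compare and
optimize them.  It is written for electrophysiology researchers working
with panoramic (e.g. non-contact, 2048-channel) atrial maps and for
methodologists studying detector behavior on synthetic fields with exact
ground truth.

## What is implemented

**Phase computation** (`psmap.phase`): cubic-spline resampling to 512 Hz,
per-channel dominant frequency (DF), sinusoidal recomposition of each
electrogram with cycle length 1/DF, and the Hilbert analytic signal
`F(t) = f(t) + j h(t)`, whose angle `φ(t) = atan2(h(t), f(t))` is the
instantaneous phase, wrapped to (−π, π].

**Four single-frame detectors** (`psmap.detect`), each frame-independent:

1. **Image-processing** (2D projection): Canny edges of the phase-gradient
   magnitude, edge-line ends as candidates, confirmation by a monotonic 2π
   sweep along the clockwise Manhattan "diamond" ring of radius N, centroid
   clustering.  Default threshold 1.5π, N = 3.
2. **3D neighbor-indexing**: the same monotonic-loop test on the clockwise
   triangulation ring of every mesh node, plus DBSCAN-style refinement.
   Default 1.5π, N = 3.
3. **Topological charge by kernel convolution** (2D projection): the
   winding number `n_t = (1/2π) ∮ ∇φ·dl` evaluated as
   `∇x ⊗ k_y + ∇y ⊗ k_x` with sobel 3×3 / sobel 5×5 / nabla 2×2 /
   nabla 3×3 stencils; cells with |2π·n_t| ≥ 1.9π (default, sobel3) are
   PSs, chirality = sign(n_t).  The nabla 2×2 form is *exactly* the
   2×2-plaquette winding number.
4. **Topological charge on the 3D mesh**: the signed count of phase jumps
   (raw consecutive differences beyond a threshold, default 3.5 rad ≈ 1.1π)
   along the clockwise neighbor ring; an odd count marks a PS.  N = 1.

**Cluster refinement**: duplicate detections that are mesh-adjacent or
within 5 mm are merged, keeping the member with the greatest loop phase
gradient.

**Evaluation** (`psmap.evaluate`): PS-density (PSD) maps on the 64×32
cylindrical projection, global SSIM and 2D Pearson correlation between
maps, TP/FP/FN/TN under a 5 mm tolerance, precision/recall and the
`F_β = (1+β²)·P·R / (β²·P + R)` score with β = 2 (recall over precision,
because frames carry only 1–4 PSs among 2048 nodes), a full parameter
sweep (thresholds 0.1π–2π × radii 1–8 or the four kernels) and 10-fold
episode-level cross-validation.

**Synthetic ground truth** (`psmap.synthetic`): cylinder meshes matching a
2048-node atrial map (~3.45 mm node spacing), planar waves, stationary and
meandering spirals, counter-rotating pairs, closed (capped) surfaces with
charge-balanced fields, and cos-phase electrogram synthesis for end-to-end
pipeline tests.

## Worked example

Simulate a stationary clockwise rotor, detect with algorithm 4 + DBSCAN,
and score against the ground truth:

```bash
psmap simulate --kind spiral --frames 32 --seed 7 --out demo/sim
psmap detect   --phase demo/sim/phase.h5 --mesh demo/sim/mesh.ply \
               --projection demo/sim/projection.csv \
               --algorithm 4 --refine dbscan --out demo/det
psmap evaluate --detections demo/det/detections.csv --truth demo/sim/truth.csv \
               --mesh demo/sim/mesh.ply --projection demo/sim/projection.csv \
               --out demo/eval
```

`demo/det/detections.csv` holds one refined PS per frame:

```
frame,node,row,col,chirality,loop_gradient
0,991,15,31,1,5.589392414405115
1,991,15,31,1,5.589392414405115
...
```

and `demo/eval/evaluation.json` reports

```json
{
  "TP": 32, "FP": 0, "FN": 0, "TN": 65504,
  "tolerance_mm": 5.0, "beta": 2.0,
  "precision": 1.0, "recall": 1.0, "score": 1.0,
  "ssim": 0.47890048903185195,
  "corr": -0.0005199505026521688
}
```

Every frame's detection (node 991, cell 15/31) lies 4.88 mm from the
annotated core (node 1056, cell 16/32) — inside the 5 mm tolerance, so all
32 frames are true positives and `F_β = 1.0`.  The PSD similarity scores
are low precisely because the two maps concentrate their visits on
*different* (adjacent) cells: cell-exact map comparison is stricter than
tolerance-based matching, which is why both are reported.

Chirality is +1 when phase increases along the clockwise loop (viewed from
outside the surface); `loop_gradient` is the max−min phase spread of the
detection loop, used to rank cluster members during refinement.

## Layout

```
src/psmap/
  mesh.py       meshes, neighbor rings, cylindrical projection, PLY/OBJ I/O
  phase.py      resampling, DF, sinusoidal recomposition, Hilbert phase
  kernels.py    charge stencil pairs and their calibration constants
  detect.py     the four detectors, loop statistics, DBSCAN refinement
  evaluate.py   PSD/SSIM/CORR, confusion counts, F_beta, sweep, CV
  synthetic.py  rotor fields with exact ground truth; EGM synthesis
  io.py         CSV/HDF5/JSON formats
  cli.py        psmap simulate|phase|detect|sweep|evaluate|benchmark
docs/methods.md   model assumptions, parameter choices, limitations
```
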