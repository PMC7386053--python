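"""Accuracy and similarity assessment of phase-singularity detections.

Detections are scored against annotations frame by frame with a spatial
tolerance (default 5 mm, roughly one inter-node distance and smaller than
an ablation lesion): an annotation with a detection inside the tolerance
is a true positive, surplus detections around it are false positives, as
are detections near no annotation; unmatched annotations are false
negatives, all remaining node-frames true negatives.  Because frames carry
1-4 singularities among 2048 nodes the classes are extremely imbalanced,
so performance is summarized by precision/recall and the F_beta score with
beta = 2 (recall weighted above precision), not by ROC analysis.

Whole-episode spatial behavior is summarized by PS-density (PSD) maps --
per-cell visit counts on the 64 x 32 projection -- compared with the
global structural similarity index (SSIM) and the 2D Pearson correlation.

``parameter_sweep`` scans the phase-gradient threshold grid (0.1*pi to
2*pi) against search radii 1-8 (or the four kernels for algorithm 3),
pooling confusion counts across episodes; ``cross_validate`` wraps the
sweep in k-fold episode-level cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .detect import DetectorParams, default_params, detect_frame
from .mesh import GridProjection, TriMesh, ring_table


# ---------------------------------------------------------------------------
# PSD maps and similarity
# ---------------------------------------------------------------------------


@dataclass
class PSDMap:
    """Per-cell PS visit counts over an episode, with a [0, 1] normalization."""

    counts: np.ndarray

    @property
    def normalized(self) -> np.ndarray:
        m = self.counts.max()
        return self.counts / m if m > 0 else np.zeros_like(self.counts, dtype=float)


@dataclass
class SimilarityConfig:
    """SSIM stabilization constants; L is the dynamic range (1 for normalized PSD)."""

    k1: float = 0.01
    k2: float = 0.03
    L: float = 1.0

    @property
    def c1(self) -> float:
        return (self.k1 * self.L) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.L) ** 2


def psd_map(detections: pd.DataFrame, projection: GridProjection, frames: int) -> PSDMap:
    """PS-density map: counts[r, c] = number of detections at that cell."""
    counts = np.zeros((projection.rows, projection.cols), dtype=np.int64)
    if len(detections):
        cells = projection.cell_array[detections["node"].to_numpy()]
        valid = cells[:, 0] >= 0
        np.add.at(counts, (cells[valid, 0], cells[valid, 1]), 1)
    return PSDMap(counts=counts)


def _as_map(x) -> np.ndarray:
    return x.normalized if isinstance(x, PSDMap) else np.asarray(x, dtype=float)


def ssim(a, b, cfg: SimilarityConfig | None = None, sliding: bool = False) -> float:
    """Global structural similarity of two normalized maps.

    The merged two-factor form over map-level statistics:
    (2 mu_x mu_y + c1)(2 sigma_xy + c2) /
    ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2)).
    ``sliding=True`` instead averages the windowed SSIM (off by default).
    """
    cfg = cfg or SimilarityConfig()
    x, y = _as_map(a), _as_map(b)
    if x.shape != y.shape:
        raise ValueError("maps must share a shape")
    if sliding:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(x, y, data_range=cfg.L, K1=cfg.k1, K2=cfg.k2))
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cxy = ((x - mx) * (y - my)).mean()
    return float(
        (2 * mx * my + cfg.c1)
        * (2 * cxy + cfg.c2)
        / ((mx * mx + my * my + cfg.c1) * (vx + vy + cfg.c2))
    )


def corr(a, b) -> float:
    """2D Pearson correlation of two maps."""
    x, y = _as_map(a), _as_map(b)
    if x.shape != y.shape:
        raise ValueError("maps must share a shape")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        raise ValueError("undefined correlation for a zero-variance map")
    return float((xc * yc).sum() / denom)


# ---------------------------------------------------------------------------
# Confusion counting and F_beta
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0
    tolerance: float = 5.0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.FP + other.FP,
            self.FN + other.FN,
            self.TN + other.TN,
            self.tolerance,
        )


def _per_frame_nodes(df: pd.DataFrame) -> dict[int, np.ndarray]:
    if not len(df):
        return {}
    out = {}
    for frame, grp in df.groupby("frame"):
        out[int(frame)] = grp["node"].to_numpy()
    return out


def match_detections(
    detections: pd.DataFrame,
    annotations: pd.DataFrame,
    mesh: TriMesh,
    tolerance: float = 5.0,
    n_frames: int | None = None,
) -> ConfusionCounts:
    """Confusion counts under the mm tolerance rule, pooled over frames.

    Per frame, annotations are matched greedily (nearest pair first,
    one-to-one) to detections within ``tolerance``; every matched
    annotation is one TP, every remaining detection one FP (whether it
    duplicates a matched annotation or sits in unannotated territory),
    every unmatched annotation one FN.  TN fills up the node-frame count.
    """
    det = _per_frame_nodes(detections)
    ann = _per_frame_nodes(annotations)
    frames = set(det) | set(ann)
    if n_frames is None:
        n_frames = (max(frames) + 1) if frames else 0
    tp = fp = fn = 0
    for f in frames:
        d = det.get(f, np.array([], dtype=np.int64))
        a = ann.get(f, np.array([], dtype=np.int64))
        if len(d) and len(a):
            dist = np.linalg.norm(
                mesh.vertices[d][:, None, :] - mesh.vertices[a][None, :, :], axis=2
            )
            within = np.argwhere(dist <= tolerance)
            order = np.argsort(dist[within[:, 0], within[:, 1]], kind="stable")
            used_d = np.zeros(len(d), dtype=bool)
            used_a = np.zeros(len(a), dtype=bool)
            matched = 0
            for di, ai in within[order]:
                if not used_d[di] and not used_a[ai]:
                    used_d[di] = used_a[ai] = True
                    matched += 1
            tp += matched
            fp += len(d) - matched
            fn += len(a) - matched
        else:
            fp += len(d)
            fn += len(a)
    total = mesh.node_count * n_frames
    return ConfusionCounts(
        TP=tp, FP=fp, FN=fn, TN=max(total - tp - fp - fn, 0), tolerance=tolerance
    )


def f_beta(counts: ConfusionCounts, beta: float = 2.0) -> dict[str, float]:
    """Precision, recall and the F_beta score (beta = 2 weighs recall higher)."""
    if counts.TP + counts.FP == 0 or counts.TP + counts.FN == 0:
        if counts.TP == 0:
            warnings.warn("degenerate confusion counts: precision/recall set to 0")
            return {"precision": 0.0, "recall": 0.0, "score": 0.0}
    precision = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 0.0
    recall = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    if precision + recall == 0:
        return {"precision": precision, "recall": recall, "score": 0.0}
    b2 = beta * beta
    score = (1 + b2) * precision * recall / (b2 * precision + recall)
    return {"precision": precision, "recall": recall, "score": score}


# ---------------------------------------------------------------------------
# Parameter sweep and cross-validation
# ---------------------------------------------------------------------------


@dataclass
class Episode:
    """One annotated episode: a phase sequence plus its gold-standard table."""

    phase: object  # PhaseSequence
    annotations: pd.DataFrame
    mesh: TriMesh
    projection: GridProjection


@dataclass
class SweepGrid:
    """The parameter grid: thresholds (radians) x radii or kernels."""

    thresholds: np.ndarray = field(
        default_factory=lambda: np.arange(1, 21) * 0.1 * np.pi
    )
    radii: tuple = (1, 2, 3, 4, 5, 6, 7, 8)  # kernel names for algorithm 3

    @classmethod
    def default(cls, algorithm: int) -> "SweepGrid":
        if algorithm == 3:
            return cls(radii=("sobel3", "sobel5", "nabla2", "nabla3"))
        if algorithm == 1:
            return cls(radii=(2, 3, 4, 5, 6, 7, 8))
        return cls()


@dataclass
class SweepResult:
    """F_beta over the grid with the argmax cell and its parameters."""

    algorithm: int
    thresholds: np.ndarray
    radii: tuple
    scores: np.ndarray  # (n_thresholds, n_radii)
    counts: np.ndarray  # (n_thresholds, n_radii, 4) TP FP FN TN
    beta: float

    @property
    def argmax(self) -> tuple[int, int]:
        """Best cell; ties prefer the larger threshold, then the smaller radius."""
        best = (0, 0)
        for i in range(self.scores.shape[0]):
            for j in range(self.scores.shape[1]):
                s, b = self.scores[i, j], self.scores[best]
                if s > b or (s == b and (i, -j) > (best[0], -best[1])):
                    best = (i, j)
        return best

    @property
    def best_params(self) -> tuple[float, object]:
        i, j = self.argmax
        return float(self.thresholds[i]), self.radii[j]

    def plateau(self, tol: float = 0.05) -> list[tuple[int, int]]:
        """4-connected grid cells around the argmax scoring within ``tol`` of it."""
        i0, j0 = self.argmax
        ok = self.scores >= self.scores[i0, j0] - tol
        seen = {(i0, j0)}
        stack = [(i0, j0)]
        while stack:
            i, j = stack.pop()
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if (
                    0 <= ni < ok.shape[0]
                    and 0 <= nj < ok.shape[1]
                    and ok[ni, nj]
                    and (ni, nj) not in seen
                ):
                    seen.add((ni, nj))
                    stack.append((ni, nj))
        return sorted(seen)


def _params_for(algorithm: int, threshold: float, radius_or_kernel, refine: str) -> DetectorParams:
    base = default_params(algorithm, refine=refine)
    if algorithm == 3:
        return replace(base, phase_gradient_threshold=threshold, kernel_name=radius_or_kernel)
    return replace(base, phase_gradient_threshold=threshold, radius_N=int(radius_or_kernel))


def _episode_counts(
    episode: Episode,
    algorithm: int,
    grid: SweepGrid,
    refine: str,
    tolerance: float,
) -> np.ndarray:
    """(n_thr, n_rad, 4) confusion counts for one episode over the whole grid.

    Per-frame ring phases (algorithms 2/4), Canny candidates (1) and charge
    fields (3) are computed once per radius/kernel and reused across the
    threshold axis.
    """
    phase = np.asarray(getattr(episode.phase, "phase", episode.phase), dtype=float)
    n_frames = phase.shape[0]
    mesh, projection = episode.mesh, episode.projection
    out = np.zeros((len(grid.thresholds), len(grid.radii), 4), dtype=np.int64)
    for j, rk in enumerate(grid.radii):
        for i, thr in enumerate(grid.thresholds):
            params = _params_for(algorithm, float(thr), rk, refine)
            table = (
                ring_table(mesh, params.radius_N) if algorithm in (2, 4) else None
            )
            rows = []
            for t in range(n_frames):
                nodes, chir, grad = detect_frame(
                    phase[t], params, mesh=mesh, projection=projection, table=table
                )
                if len(nodes):
                    rows.append(
                        pd.DataFrame({"frame": t, "node": nodes})
                    )
            det = (
                pd.concat(rows, ignore_index=True)
                if rows
                else pd.DataFrame({"frame": [], "node": []})
            )
            c = match_detections(
                det, episode.annotations, mesh, tolerance=tolerance, n_frames=n_frames
            )
            out[i, j] = (c.TP, c.FP, c.FN, c.TN)
    return out


def parameter_sweep(
    episodes: list[Episode],
    algorithm: int,
    grid: SweepGrid | None = None,
    refine: str | None = None,
    beta: float = 2.0,
    tolerance: float = 5.0,
    episode_counts: np.ndarray | None = None,
) -> SweepResult:
    """F_beta surface over the parameter grid, counts pooled across episodes."""
    grid = grid or SweepGrid.default(algorithm)
    if refine is None:
        refine = default_params(algorithm).refine
    if episode_counts is None:
        episode_counts = np.stack(
            [_episode_counts(ep, algorithm, grid, refine, tolerance) for ep in episodes]
        )
    pooled = episode_counts.sum(axis=0)
    scores = np.zeros(pooled.shape[:2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(pooled.shape[0]):
            for j in range(pooled.shape[1]):
                tp, fp, fn, tn = pooled[i, j]
                scores[i, j] = f_beta(ConfusionCounts(tp, fp, fn, tn), beta)["score"]
    return SweepResult(
        algorithm=algorithm,
        thresholds=np.asarray(grid.thresholds, dtype=float),
        radii=tuple(grid.radii),
        scores=scores,
        counts=pooled,
        beta=beta,
    )


def cross_validate(
    episodes: list[Episode],
    algorithm: int,
    grid: SweepGrid | None = None,
    k: int = 10,
    seed: int = 0,
    refine: str | None = None,
    beta: float = 2.0,
    tolerance: float = 5.0,
) -> dict:
    """k-fold cross-validation of the parameter optimization.

    Episodes are partitioned deterministically by ``seed``; per fold the
    argmax of the pooled training F_beta surface is evaluated on the
    held-out episodes.  Returns per-fold parameters and train/test scores.
    """
    grid = grid or SweepGrid.default(algorithm)
    if refine is None:
        refine = default_params(algorithm).refine
    n = len(episodes)
    if n < k:
        raise ValueError(f"need at least k={k} episodes, got {n}")
    counts = np.stack(
        [_episode_counts(ep, algorithm, grid, refine, tolerance) for ep in episodes]
    )
    order = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(order, k)
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fold_idx, test_ids in enumerate(folds):
            train_ids = np.setdiff1d(order, test_ids)
            train = parameter_sweep(
                [], algorithm, grid, refine, beta, tolerance,
                episode_counts=counts[train_ids],
            )
            i, j = train.argmax
            tp, fp, fn, tn = counts[test_ids].sum(axis=0)[i, j]
            test_score = f_beta(ConfusionCounts(tp, fp, fn, tn), beta)["score"]
            results.append(
                {
                    "fold": fold_idx,
                    "test_episodes": [int(x) for x in test_ids],
                    "threshold": float(train.thresholds[i]),
                    "radius_or_kernel": train.radii[j],
                    "train_score": float(train.scores[i, j]),
                    "test_score": float(test_score),
                }
            )
    return {
        "folds": results,
        "mean_test_score": float(np.mean([r["test_score"] for r in results])),
        "mean_train_score": float(np.mean([r["train_score"] for r in results])),
    }
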