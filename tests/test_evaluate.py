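"""PSD maps, SSIM/CORR, tolerance matching, F_beta, sweep and cross-validation."""

import numpy as np
import pandas as pd
import pytest

from psmap.evaluate import (
    ConfusionCounts,
    SimilarityConfig,
    SweepGrid,
    corr,
    cross_validate,
    f_beta,
    match_detections,
    parameter_sweep,
    psd_map,
    ssim,
)
from psmap.mesh import GridProjection


def det_table(rows):
    return pd.DataFrame(rows, columns=["frame", "node"])


class TestPSDMap:
    def test_empty(self):
        proj = GridProjection(rows=8, cols=16)
        m = psd_map(det_table([]), proj, frames=10)
        assert m.counts.sum() == 0 and m.normalized.max() == 0.0

    def test_repeated_cell(self):
        proj = GridProjection(rows=8, cols=16)
        node = proj.node_of(3, 4)
        m = psd_map(det_table([(t, node) for t in range(10)]), proj, frames=10)
        assert m.counts[3, 4] == 10
        assert m.normalized[3, 4] == 1.0
        assert m.counts.sum() == 10

    def test_counts_conserve_detections(self):
        proj = GridProjection(rows=8, cols=16)
        rng = np.random.default_rng(0)
        nodes = rng.integers(0, 8 * 16, 57)
        m = psd_map(det_table(list(enumerate(nodes))), proj, frames=57)
        assert m.counts.sum() == 57


class TestSimilarity:
    def test_ssim_identity(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, (32, 64))
        assert ssim(a, a) == pytest.approx(1.0)

    def test_ssim_constant_maps_analytic_value(self):
        cfg = SimilarityConfig()
        a = np.zeros((32, 64))
        b = np.ones((32, 64))
        # zero variances: value reduces to c1 / (1 + c1)
        assert ssim(a, b, cfg) == pytest.approx(cfg.c1 / (1 + cfg.c1), rel=1e-12)
        assert ssim(a, b, cfg) == pytest.approx(1.0e-4, rel=1e-2)

    def test_ssim_symmetric(self):
        rng = np.random.default_rng(2)
        a, b = rng.uniform(0, 1, (2, 32, 64))
        assert ssim(a, b) == pytest.approx(ssim(b, a))

    def test_corr_identity_and_anticorrelation(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, (32, 64))
        assert corr(a, a) == pytest.approx(1.0)
        assert corr(a, 5.0 - a) == pytest.approx(-1.0)

    def test_corr_matches_two_pass_oracle(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(0, 1, (2, 32, 64))
        abar, bbar = a.mean(), b.mean()
        expected = ((a - abar) * (b - bbar)).sum() / np.sqrt(
            ((a - abar) ** 2).sum() * ((b - bbar) ** 2).sum()
        )
        assert corr(a, b) == pytest.approx(expected, abs=1e-12)

    def test_corr_zero_variance_errors(self):
        with pytest.raises(ValueError):
            corr(np.ones((4, 4)), np.random.default_rng(0).uniform(size=(4, 4)))

    def test_scale_sensitivity_split(self):
        """corr is scale-invariant while ssim is not."""
        rng = np.random.default_rng(5)
        a = rng.uniform(0.1, 0.5, (32, 64))
        assert corr(a, 2 * a) == pytest.approx(1.0)
        assert ssim(a, 2 * a) < 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((4, 4)), np.zeros((4, 5)))


class TestMatching:
    def test_exact_hit(self, full_domain):
        mesh, proj = full_domain
        node = proj.node_of(10, 10)
        c = match_detections(det_table([(0, node)]), det_table([(0, node)]), mesh, 5.0,
                             n_frames=1)
        assert (c.TP, c.FP, c.FN) == (1, 0, 0)
        assert c.TN == mesh.node_count - 1

    def test_detection_beyond_tolerance(self, full_domain):
        mesh, proj = full_domain
        a = proj.node_of(10, 10)
        d = proj.node_of(10, 12)  # two columns: ~6.9 mm
        c = match_detections(det_table([(0, d)]), det_table([(0, a)]), mesh, 5.0, n_frames=1)
        assert (c.TP, c.FP, c.FN) == (0, 1, 1)

    def test_duplicate_detection_is_false_positive(self, full_domain):
        mesh, proj = full_domain
        a = proj.node_of(10, 10)
        c = match_detections(
            det_table([(0, proj.node_of(10, 10)), (0, proj.node_of(10, 11))]),
            det_table([(0, a)]), mesh, 5.0, n_frames=1,
        )
        assert (c.TP, c.FP, c.FN) == (1, 1, 0)

    def test_annotations_conserved(self, full_domain):
        mesh, proj = full_domain
        rng = np.random.default_rng(7)
        ann = det_table([(t, int(n)) for t in range(5)
                         for n in rng.integers(0, mesh.node_count, 3)])
        det = det_table([(t, int(n)) for t in range(5)
                         for n in rng.integers(0, mesh.node_count, 4)])
        c = match_detections(det, ann, mesh, 5.0, n_frames=5)
        assert c.TP + c.FN == len(ann)
        assert c.TP + c.FP == len(det)
        assert c.TP + c.FP + c.FN + c.TN == mesh.node_count * 5


class TestFBeta:
    def test_fixed_point(self):
        # precision == recall == p gives score p for any beta
        c = ConfusionCounts(TP=3, FP=1, FN=1, TN=100)
        for beta in (0.5, 1.0, 2.0, 5.0):
            assert f_beta(c, beta)["score"] == pytest.approx(0.75)

    def test_worked_example(self):
        out = f_beta(ConfusionCounts(TP=1, FP=1, FN=0, TN=10), beta=2.0)
        assert out["precision"] == pytest.approx(0.5)
        assert out["recall"] == pytest.approx(1.0)
        assert out["score"] == pytest.approx(5 * 0.5 / (4 * 0.5 + 1))
        assert out["score"] == pytest.approx(0.833333, abs=1e-6)

    def test_no_true_positives(self):
        with pytest.warns(UserWarning):
            assert f_beta(ConfusionCounts(TP=0, FP=0, FN=0, TN=5))["score"] == 0.0

    def test_beta_moves_score_toward_recall(self):
        c = ConfusionCounts(TP=2, FP=8, FN=1, TN=100)  # precision 0.2 < recall 0.667
        s1 = f_beta(c, 1.0)["score"]
        s2 = f_beta(c, 2.0)["score"]
        assert s2 > s1


class TestSweepAndCV:
    def test_single_cell_grid(self, spiral_episode):
        grid = SweepGrid(thresholds=np.array([3.5]), radii=(1,))
        result = parameter_sweep([spiral_episode], 4, grid, refine="dbscan")
        assert result.scores.shape == (1, 1)
        assert result.argmax == (0, 0)
        assert result.scores[0, 0] == pytest.approx(1.0)

    def test_argmax_tie_prefers_larger_threshold_then_smaller_radius(self, spiral_episode):
        grid = SweepGrid(thresholds=np.array([0.9 * np.pi, 1.1 * np.pi]), radii=(1, 2))
        result = parameter_sweep([spiral_episode], 4, grid, refine="dbscan")
        if np.all(result.scores == result.scores[0, 0]):
            assert result.argmax == (1, 0)

    def test_cv_two_identical_episodes(self, full_domain, make_episode):
        mesh, proj = full_domain
        eps = [make_episode(mesh, proj, frames=4, seed=0) for _ in range(2)]
        grid = SweepGrid(thresholds=np.array([2.0, 3.5]), radii=(1, 2))
        cv = cross_validate(eps, 4, grid, k=2, seed=0, refine="dbscan")
        assert len(cv["folds"]) == 2
        params = {(f["threshold"], f["radius_or_kernel"]) for f in cv["folds"]}
        assert len(params) == 1  # identical training sets pick identical settings
        for f in cv["folds"]:
            assert f["test_score"] == pytest.approx(f["train_score"])

    def test_cv_rejects_too_few_episodes(self, spiral_episode):
        with pytest.raises(ValueError):
            cross_validate([spiral_episode], 4, k=10)

    def test_threshold_axis_of_surface_monotone_after_peak(self, full_domain, make_episode):
        """On ideal data, F_beta never recovers once the threshold passes the
        detection range of the true singularity (recall is lost for good)."""
        mesh, proj = full_domain
        ep = make_episode(mesh, proj, frames=3)
        grid = SweepGrid(thresholds=np.arange(10, 21) * 0.1 * np.pi, radii=(1,))
        result = parameter_sweep([ep], 2, grid, refine="dbscan")
        col = result.scores[:, 0]
        peak = int(np.argmax(col))
        assert np.all(np.diff(col[peak:]) <= 1e-12)
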