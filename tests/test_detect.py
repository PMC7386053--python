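"""The four detectors, loop statistics and DBSCAN-style refinement."""

from dataclasses import replace

import numpy as np
import pytest

from psmap.detect import (
    dbscan_refine,
    default_params,
    detect,
    detect_frame,
    loop_monotonic_stats,
    wrap_phase,
)
from psmap.synthetic import Scenario, make_cylinder_mesh, synth_phase_sequence

CORE = (15.5, 31.5)


@pytest.fixture(scope="module")
def domain():
    return make_cylinder_mesh()


def spiral(domain, core=CORE, chirality=1, frames=1, noise=0.0, seed=0):
    mesh, proj = domain
    sc = Scenario(
        kind="spiral", frames=frames, cores=[core], chirality=[chirality],
        noise_sd=noise, seed=seed,
    )
    seq, ann = synth_phase_sequence(sc, mesh, proj)
    return seq, ann


class TestLoopStats:
    def test_ideal_spiral_ring_is_monotonic(self):
        n = 12
        phases = wrap_phase(2 * np.pi * np.arange(n) / n + 0.3)
        stats = loop_monotonic_stats(phases)
        assert stats.monotonic and stats.direction == 1
        assert stats.gradient == pytest.approx(2 * np.pi * (n - 1) / n, abs=1e-9)

    def test_constant_loop_degenerate(self):
        stats = loop_monotonic_stats([0.4, 0.4, 0.4, 0.4])
        assert not stats.monotonic and stats.gradient == 0.0

    def test_internal_decrease_breaks_monotonicity(self):
        assert not loop_monotonic_stats([0.0, 1.0, 0.5, 2.0]).monotonic

    def test_decreasing_loop_direction(self):
        n = 10
        phases = wrap_phase(-2 * np.pi * np.arange(n) / n)
        stats = loop_monotonic_stats(phases)
        assert stats.monotonic and stats.direction == -1

    def test_needs_three_members(self):
        with pytest.raises(ValueError):
            loop_monotonic_stats([0.0, 1.0])


class TestDetectorsOnIdealFields:
    @pytest.mark.parametrize("algorithm", [1, 2, 3, 4])
    def test_single_spiral_found_near_core(self, domain, algorithm):
        """The candidate detections of every algorithm cover the true core.

        Algorithms 2-4 are checked before cluster collapse: the cluster
        representative (greatest loop gradient) may legitimately sit a
        node or two off-core, but the detection cluster always contains it.
        """
        mesh, proj = domain
        seq, ann = spiral(domain)
        refine = None if algorithm == 1 else "none"
        params = default_params(algorithm, refine=refine)
        nodes, chir, grad = detect_frame(seq.phase[0], params, mesh=mesh, projection=proj)
        assert len(nodes) >= 1
        true = int(ann.node.iloc[0])
        d = np.linalg.norm(mesh.vertices[nodes] - mesh.vertices[true], axis=1)
        assert d.min() <= 5.0
        assert np.all(chir[d <= 5.0] == 1)

    @pytest.mark.parametrize("algorithm", [2, 3, 4])
    def test_dbscan_refined_count_is_one(self, domain, algorithm):
        mesh, proj = domain
        seq, _ = spiral(domain)
        params = default_params(algorithm, refine="dbscan")
        nodes, _, _ = detect_frame(seq.phase[0], params, mesh=mesh, projection=proj)
        assert len(nodes) == 1

    @pytest.mark.parametrize("algorithm", [1, 2, 3, 4])
    def test_planar_wave_yields_nothing(self, domain, algorithm):
        mesh, proj = domain
        sc = Scenario(kind="planar", frames=1)
        seq, ann = synth_phase_sequence(sc, mesh, proj)
        assert len(ann) == 0
        nodes, _, _ = detect_frame(
            seq.phase[0], default_params(algorithm), mesh=mesh, projection=proj
        )
        assert len(nodes) == 0

    def test_counter_rotating_pair(self, domain):
        mesh, proj = domain
        sc = Scenario(kind="spiral_pair", frames=1, cores=[(15.5, 15.5)], chirality=[1])
        seq, ann = synth_phase_sequence(sc, mesh, proj)
        for algorithm in (1, 2, 3, 4):
            refine = "dbscan" if algorithm > 1 else None
            params = default_params(algorithm, refine=refine)
            nodes, chir, _ = detect_frame(seq.phase[0], params, mesh=mesh, projection=proj)
            assert len(nodes) == 2
            assert sorted(chir.tolist()) == [-1, 1]

    def test_uniform_frame_empty_everywhere(self, domain):
        mesh, proj = domain
        frame = np.full(mesh.node_count, 0.7)
        for algorithm in (2, 3, 4):
            nodes, _, _ = detect_frame(
                frame, default_params(algorithm), mesh=mesh, projection=proj
            )
            assert len(nodes) == 0

    def test_full_two_pi_threshold_is_unreachable_on_discrete_rings(self, domain):
        mesh, proj = domain
        seq, _ = spiral(domain)
        params = replace(default_params(2, refine="none"), phase_gradient_threshold=2 * np.pi)
        nodes, _, _ = detect_frame(seq.phase[0], params, mesh=mesh, projection=proj)
        assert len(nodes) == 0


class TestChirality:
    @pytest.mark.parametrize("algorithm", [1, 2, 3, 4])
    def test_mirroring_flips_chirality(self, domain, algorithm):
        mesh, proj = domain
        seq, _ = spiral(domain)
        mirrored = seq.phase[0][proj.node_grid[:, ::-1]].ravel()
        params = default_params(algorithm)
        _, chir_orig, _ = detect_frame(seq.phase[0], params, mesh=mesh, projection=proj)
        _, chir_mirr, _ = detect_frame(mirrored, params, mesh=mesh, projection=proj)
        assert np.all(chir_orig == 1) and np.all(chir_mirr == -1)

    def test_grid_and_mesh_detectors_agree_on_chirality(self, domain):
        mesh, proj = domain
        for chi in (-1, 1):
            seq, _ = spiral(domain, chirality=chi)
            signs = []
            for algorithm in (1, 2, 3, 4):
                _, chir, _ = detect_frame(
                    seq.phase[0], default_params(algorithm), mesh=mesh, projection=proj
                )
                signs.extend(chir.tolist())
            assert signs and all(s == chi for s in signs)


class TestThresholdMonotonicity:
    @pytest.mark.parametrize("algorithm", [1, 2, 3])
    def test_counts_non_increasing_in_threshold(self, domain, algorithm):
        mesh, proj = domain
        seq, _ = spiral(domain, noise=0.25, seed=11)
        counts = []
        for threshold in np.arange(1, 21) * 0.1 * np.pi:
            params = replace(
                default_params(algorithm, refine="none"), phase_gradient_threshold=threshold
            )
            nodes, _, _ = detect_frame(seq.phase[0], params, mesh=mesh, projection=proj)
            counts.append(len(nodes))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDBSCANRefine:
    def test_adjacent_cluster_keeps_max_gradient(self, domain):
        mesh, proj = domain
        nodes = np.array([proj.node_of(10, 10), proj.node_of(10, 11), proj.node_of(11, 10)])
        chir = np.array([1, 1, 1], dtype=np.int8)
        grad = np.array([1.0, 3.0, 2.0])
        out_nodes, out_chir, out_grad = dbscan_refine(nodes, chir, grad, mesh)
        assert out_nodes.tolist() == [proj.node_of(10, 11)]
        assert out_grad.tolist() == [3.0]

    def test_distant_detections_kept(self, domain):
        mesh, proj = domain
        nodes = np.array([proj.node_of(10, 10), proj.node_of(10, 20)])  # ~ 33 mm apart
        out, _, _ = dbscan_refine(nodes, np.ones(2, np.int8), np.ones(2), mesh)
        assert sorted(out.tolist()) == sorted(nodes.tolist())

    def test_empty_input(self, domain):
        mesh, _ = domain
        out, _, _ = dbscan_refine(
            np.array([], dtype=np.int64), np.array([], np.int8), np.array([]), mesh
        )
        assert len(out) == 0

    def test_idempotent_and_never_grows(self, domain):
        mesh, proj = domain
        rng = np.random.default_rng(3)
        nodes = np.unique(rng.integers(0, mesh.node_count, 40))
        chir = np.ones(len(nodes), np.int8)
        grad = rng.uniform(0, 2 * np.pi, len(nodes))
        once = dbscan_refine(nodes, chir, grad, mesh)
        assert len(once[0]) <= len(nodes)
        twice = dbscan_refine(*once, mesh)
        assert np.array_equal(once[0], twice[0])

    def test_gradient_tie_breaks_to_lowest_node(self, domain):
        mesh, proj = domain
        nodes = np.array([proj.node_of(10, 11), proj.node_of(10, 10)])
        out, _, _ = dbscan_refine(nodes, np.ones(2, np.int8), np.array([1.0, 1.0]), mesh)
        assert out.tolist() == [proj.node_of(10, 10)]


class TestMultiFrameApi:
    def test_dataframe_schema_and_frame_independence(self, domain):
        mesh, proj = domain
        seq, ann = spiral(domain, frames=3)
        df = detect(seq, default_params(4, refine="dbscan"))
        assert list(df.columns) == ["frame", "node", "row", "col", "chirality", "loop_gradient"]
        assert sorted(df.frame.unique().tolist()) == [0, 1, 2]
        # stationary rotor: identical detection in every frame
        assert df.groupby("frame").node.first().nunique() == 1

    def test_requires_domain_information(self, domain):
        mesh, proj = domain
        seq, _ = spiral(domain)
        with pytest.raises(ValueError):
            detect_frame(seq.phase[0], default_params(3))
        with pytest.raises(ValueError):
            detect_frame(seq.phase[0], default_params(4))


class TestParams:
    def test_defaults_match_published_table(self):
        p1, p2, p3, p4 = (default_params(a) for a in (1, 2, 3, 4))
        assert p1.phase_gradient_threshold == pytest.approx(1.5 * np.pi)
        assert p1.radius_N == 3 and p1.refine == "centroid"
        assert p2.phase_gradient_threshold == pytest.approx(1.5 * np.pi)
        assert p2.radius_N == 3 and p2.refine == "dbscan"
        assert p3.phase_gradient_threshold == pytest.approx(1.9 * np.pi)
        assert p3.kernel_name == "sobel3"
        assert p4.phase_gradient_threshold == 3.5 and p4.radius_N == 1

    def test_validation(self):
        with pytest.raises(ValueError):
            default_params(5)
        with pytest.raises(ValueError):
            replace(default_params(1), radius_N=1)
        with pytest.raises(ValueError):
            replace(default_params(2), phase_gradient_threshold=0.0)
        with pytest.raises(ValueError):
            replace(default_params(3), kernel_name="gauss")
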