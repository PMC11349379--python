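"""Density simulation, scoring, annealing machinery and the convergence
diagnostic (the heavier planted-pose recovery runs live in the acceptance
suite)."""

import numpy as np
import pytest

from trainxl.core import AssemblyModel, ChainInfo, ChainMap, CrossLinkRecord
from trainxl.fitting import (DEFAULT_WEIGHTS, AnnealSchedule, Pose,
                             ScoreBreakdown, cross_correlation,
                             score_configuration, score_histogram,
                             simulate_density)


def _beads(coords, chain="A"):
    n = len(coords)
    return AssemblyModel(
        chain_ids=np.array([chain] * n, dtype=object),
        res_ids=np.arange(1, n + 1),
        res_names=np.array(["UNK"] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        coords=np.asarray(coords, dtype=float),
        b_factors=np.full(n, 90.0),
    )


class TestSimulateDensity:
    def test_single_atom_peaks_at_its_voxel(self):
        model = _beads([[20.0, 20.0, 20.0]])
        grid = simulate_density(model, resolution=12.0, voxel=4.0)
        peak = np.unravel_index(np.argmax(grid.data), grid.shape)
        pos = grid.origin + np.array(peak) * grid.voxel
        assert np.linalg.norm(pos - [20, 20, 20]) <= np.sqrt(3) * 2.0

    def test_integral_linear_in_atom_count(self):
        one = simulate_density(_beads([[15.0, 15, 15]]), 12.0, 4.0)
        two = simulate_density(_beads([[15.0, 15, 15], [19.0, 15, 15]]),
                               12.0, 4.0)
        assert two.data.sum() == pytest.approx(2 * one.data.sum(), rel=0.01)

    def test_density_shifts_by_exactly_one_voxel(self):
        voxel = 4.0
        base = _beads([[30.0, 30, 30], [36.0, 32, 30]])
        ref = simulate_density(base, 12.0, voxel, padding=24.0)
        moved = base.transformed(np.eye(3), [voxel, 0, 0])
        shifted = simulate_density(moved, 12.0, voxel, grid=ref)
        assert np.allclose(shifted.data[1:, :, :], ref.data[:-1, :, :],
                           atol=1e-6)

    def test_undersampled_resolution_rejected(self):
        with pytest.raises(ValueError, match="twice the voxel"):
            simulate_density(_beads([[0.0, 0, 0]]), resolution=6.0,
                             voxel=4.0)


class TestCrossCorrelation:
    def test_self_fit_is_near_perfect(self, fit_case_single):
        body = fit_case_single.bodies[0]
        cc = cross_correlation(body, fit_case_single.planted_poses[0],
                               fit_case_single.grid,
                               fit_case_single.spec.resolution,
                               body.coords.mean(axis=0))
        assert cc >= 0.99

    def test_uniform_map_scores_zero(self):
        model = _beads([[10.0, 10, 10]])
        grid = simulate_density(model, 12.0, 4.0)
        grid.data[:] = 1.0
        assert cross_correlation(model, Pose.identity(), grid, 12.0,
                                 np.zeros(3)) == 0.0

    def test_decreases_with_translation_offset(self):
        # toy sphere: a blob of beads on a small spherical shell
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(40, 3))
        pts = 6.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        model = _beads(pts + 30.0)
        grid = simulate_density(model, 14.0, 4.0)
        pivot = model.coords.mean(axis=0)
        ccs = []
        for dx in (0.0, 3.0, 6.0, 9.0, 12.0):
            pose = Pose(np.eye(3), pivot + [dx, 0, 0])
            ccs.append(cross_correlation(model, pose, grid, 14.0, pivot))
        assert all(a >= b - 1e-9 for a, b in zip(ccs, ccs[1:]))


class TestPoseAndSchedule:
    def test_improper_rotation_rejected(self):
        flip = np.diag([-1.0, 1.0, 1.0])  # det -1
        with pytest.raises(ValueError, match="proper"):
            Pose(flip, np.zeros(3))

    def test_default_schedule_is_the_six_stage_regime(self):
        sched = AnnealSchedule()
        assert sched.stages == ((75000.0, 1000), (30000.0, 800),
                                (10000.0, 800), (5000.0, 500),
                                (1000.0, 500), (300.0, 300))

    def test_schedule_must_cool_strictly(self):
        with pytest.raises(ValueError, match="decreasing"):
            AnnealSchedule(stages=((100.0, 10), (100.0, 10)))
        with pytest.raises(ValueError, match="positive"):
            AnnealSchedule(stages=((100.0, 10), (50.0, 0)))

    def test_default_restraint_weights(self):
        assert DEFAULT_WEIGHTS == {"connectivity": 1.0, "xlink": 30.0,
                                   "discrete": 10000.0,
                                   "excluded_volume": 10.0, "em": 1000.0}


class TestScoreConfiguration:
    def _two_bodies(self):
        b1 = _beads([[0.0, 0, 0], [4.0, 0, 0]], chain="R0")
        b2 = _beads([[0.0, 0, 0], [4.0, 0, 0]], chain="R1")
        cm = ChainMap(entries={"R0": ChainInfo("BODY0", 0),
                               "R1": ChainInfo("BODY1", 0)})
        return b1, b2, cm

    def test_perfect_configuration_scores_zero(self, fit_case_single):
        case = fit_case_single
        bd = score_configuration(case.bodies, case.planted_poses, case.grid,
                                 resolution=case.spec.resolution)
        assert bd.terms["xlink"] == 0.0
        assert bd.terms["excluded_volume"] == 0.0
        assert bd.total == pytest.approx(0.0, abs=15.0)  # em ~ 1 - cc

    def test_crosslink_violation_formula(self):
        b1, b2, cm = self._two_bodies()
        # place the second body so the linked pair sits at threshold + 1
        poses = [Pose(np.eye(3), [2.0, 0, 0]),
                 Pose(np.eye(3), [2.0, 0, 38.0])]
        rec = CrossLinkRecord("BODY0", 1, "BODY1", 1)
        bd = score_configuration([b1, b2], poses, grid=None,
                                 crosslinks=[rec], chainmap=cm)
        # linked beads end up at (0,0,0) and (0,0,38): 3 A past threshold
        assert bd.terms["xlink"] == pytest.approx((38 - 35) ** 2)
        assert bd.total == pytest.approx(30 * 9)

    def test_total_is_weighted_sum(self):
        bd = ScoreBreakdown(terms={"em": 0.5, "xlink": 2.0,
                                   "connectivity": 0.0,
                                   "excluded_volume": 3.0, "discrete": 0.0},
                            weights=dict(DEFAULT_WEIGHTS))
        expected = 1000 * 0.5 + 30 * 2.0 + 10 * 3.0
        assert bd.total == pytest.approx(expected, abs=1e-9)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            ScoreBreakdown(terms={"em": 0.0}, weights={"em": -1.0})

    def test_pose_count_mismatch_raises(self):
        b1, b2, _ = self._two_bodies()
        with pytest.raises(ValueError, match="one pose per rigid body"):
            score_configuration([b1, b2], [Pose.identity()], grid=None)

    def test_invariant_under_global_rigid_motion_without_em(self):
        from scipy.spatial.transform import Rotation
        b1, b2, cm = self._two_bodies()
        rec = CrossLinkRecord("BODY0", 1, "BODY1", 2)
        poses = [Pose(np.eye(3), [0.0, 0, 0]),
                 Pose(np.eye(3), [50.0, 3.0, 1.0])]
        weights = {**DEFAULT_WEIGHTS, "em": 0.0}
        base = score_configuration([b1, b2], poses, None, [rec], cm,
                                   weights=weights)
        rot = Rotation.from_euler("xyz", [30, -40, 75],
                                  degrees=True).as_matrix()
        shift = np.array([12.0, -8.0, 5.0])
        moved = [Pose(rot @ p.rotation, rot @ p.translation + shift)
                 for p in poses]
        same = score_configuration([b1, b2], moved, None, [rec], cm,
                                   weights=weights)
        assert same.total == pytest.approx(base.total, abs=1e-9)


class TestScoreHistogram:
    def test_single_gaussian_is_not_converged(self):
        rng = np.random.default_rng(0)
        verdict = score_histogram(rng.normal(1000.0, 50.0, 400))
        assert not verdict.converged

    def test_planted_low_mode_is_converged(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(1000.0, 50.0, 380),
                                 rng.normal(500.0, 10.0, 20)])
        assert score_histogram(scores).converged

    def test_verdict_invariant_under_positive_rescaling(self):
        rng = np.random.default_rng(2)
        for scores in (rng.normal(1000, 50, 200),
                       np.concatenate([rng.normal(1000, 50, 190),
                                       rng.normal(400, 5, 10)])):
            base = score_histogram(scores).converged
            assert score_histogram(scores * 7.3).converged == base
            assert score_histogram(scores * 0.01).converged == base

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError, match="30"):
            score_histogram(np.arange(10.0))


class TestRestraintTerms:
    def _bodies_cm(self):
        b1 = _beads([[0.0, 0, 0], [4.0, 0, 0]], chain="R0")
        b2 = _beads([[0.0, 0, 0], [4.0, 0, 0]], chain="R1")
        cm = ChainMap(entries={"R0": ChainInfo("BODY0", 0),
                               "R1": ChainInfo("BODY1", 0)})
        return b1, b2, cm

    def test_connectivity_gap_penalty(self):
        from trainxl.fitting import ConnectivityRestraint
        b1, b2, cm = self._bodies_cm()
        poses = [Pose(np.eye(3), [2.0, 0, 0]),
                 Pose(np.eye(3), [2.0, 0, 12.0])]
        # chain continuation R0:2 -> R1:1, gap = distance((4,0,0),(0,0,12))
        gap = np.linalg.norm([4.0, 0, -12.0])
        restraint = ConnectivityRestraint("R0", 2, "R1", 1, max_gap=5.0)
        bd = score_configuration([b1, b2], poses, None,
                                 connectivity=[restraint])
        assert bd.terms["connectivity"] == pytest.approx((gap - 5.0) ** 2)

    def test_discrete_contact_penalty_is_binary(self):
        from trainxl.fitting import DiscreteContact
        b1, b2, cm = self._bodies_cm()
        near = [Pose(np.eye(3), [2.0, 0, 0]), Pose(np.eye(3), [2.0, 0, 6.0])]
        far = [Pose(np.eye(3), [2.0, 0, 0]), Pose(np.eye(3), [2.0, 0, 60.0])]
        contact = DiscreteContact("R0", "R1", cutoff=10.0)
        assert score_configuration([b1, b2], near, None,
                                   contacts=[contact]).terms["discrete"] == 0
        assert score_configuration([b1, b2], far, None,
                                   contacts=[contact]).terms["discrete"] == 1


class TestLibraryEdgeCases:
    def test_empty_support_map_yields_empty_library(self):
        from trainxl.core import DensityGrid
        from trainxl.fitting import build_fit_library
        model = _beads([[10.0, 10, 10]])
        empty = DensityGrid(np.zeros((8, 8, 8), dtype=np.float32),
                            voxel=4.0, origin=[0.0, 0, 0])
        assert build_fit_library(model, empty, n_positions=50,
                                 resolution=12.0) == []

    def test_anneal_rejects_empty_library(self, fit_case_single):
        from trainxl.fitting import anneal
        with pytest.raises(ValueError, match="non-empty fit library"):
            anneal(fit_case_single.bodies, fit_case_single.grid, [[]],
                   resolution=fit_case_single.spec.resolution)
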