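"""Trajectory analysis: alignment, PCA, distances, RMSD, clusters,
coordination geometry, interaction decomposition."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

import stepmd as sm
from stepmd.analysis import cluster_representative, coordination_geometry
from stepmd.trajectory import Frame, Trajectory


def _rotation_z(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _traj(frames_coords, t0=0.0):
    return Trajectory(
        frames=[Frame(time=t0 + 0.1 * (k + 1), coords=c) for k, c in enumerate(frames_coords)]
    )


class TestFitSuperpose:
    def test_rigid_rotations_align_to_reference(self, rng):
        ref = rng.normal(0, 2, (10, 3))
        frames = [ref @ _rotation_z(a).T + np.array([1.0, -2.0, 0.5]) for a in (0.3, 1.0, 2.0)]
        aligned = sm.fit_superpose_series(_traj(frames), ref, np.arange(10))
        for f in aligned:
            np.testing.assert_allclose(f.coords, ref, atol=1e-9)

    def test_mobile_selection_carried_untouched(self, rng):
        # Scaffold fixed, mobile displaced: after a scaffold-only fit the
        # scaffold RMSD is ~0 and the mobile RMSD equals the displacement.
        ref = rng.normal(0, 2, (12, 3))
        scaffold, mobile = np.arange(8), np.arange(8, 12)
        moved = ref.copy()
        moved[mobile] += np.array([0.0, 0.0, 3.0])
        rot = _rotation_z(0.7)
        frame = moved @ rot.T + np.array([4.0, 1.0, 0.0])
        aligned = sm.fit_superpose_series(_traj([frame]), ref, scaffold)
        out = aligned[0].coords
        assert np.abs(out[scaffold] - ref[scaffold]).max() < 1e-9
        np.testing.assert_allclose(
            np.linalg.norm(out[mobile] - ref[mobile], axis=1), 3.0, atol=1e-9
        )

    def test_idempotent_on_aligned_trajectory(self, rng):
        ref = rng.normal(0, 2, (6, 3))
        frames = [ref + rng.normal(0, 0.1, ref.shape) for _ in range(3)]
        once = sm.fit_superpose_series(_traj(frames), ref, np.arange(6))
        twice = sm.fit_superpose_series(once, ref, np.arange(6))
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-9)


class TestPca:
    def test_identical_frames_zero_eigenvalues(self):
        coords = np.ones((4, 3))
        traj = _traj([coords.copy() for _ in range(5)])
        with pytest.warns(UserWarning, match="zero total variance"):
            res = sm.pca_modes(traj, np.arange(4))
        np.testing.assert_array_equal(res.eigenvalues, 0.0)

    def test_known_covariance_recovered(self, rng):
        # One particle sampled with covariance diag(4, 1, 0): the top two
        # eigenvalues approach 4 and 1 at this sample size.
        n = 4000
        xs = np.zeros((n, 1, 3))
        xs[:, 0, 0] = rng.normal(0, 2.0, n)
        xs[:, 0, 1] = rng.normal(0, 1.0, n)
        traj = _traj(list(xs))
        res = sm.pca_modes(traj, np.array([0]))
        assert res.eigenvalues[0] == pytest.approx(4.0, rel=0.1)
        assert res.eigenvalues[1] == pytest.approx(1.0, rel=0.1)
        assert res.eigenvalues[2] == pytest.approx(0.0, abs=1e-12)

    def test_fractions_sum_to_one_and_modes_orthonormal(self, rng):
        xs = [rng.normal(0, 1, (5, 3)) for _ in range(40)]
        res = sm.pca_modes(_traj(xs), np.arange(5))
        assert res.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        gram = res.modes @ res.modes.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_total_variance_equals_covariance_trace(self, rng):
        xs = np.stack([rng.normal(0, 1, (3, 3)) for _ in range(60)])
        res = sm.pca_modes(_traj(list(xs)), np.arange(3))
        flat = xs.reshape(60, -1)
        trace = np.trace(np.cov(flat.T, bias=True))
        assert res.total_variance == pytest.approx(trace, rel=1e-9)


class TestProjection:
    def test_mean_projects_to_origin_and_variance_matches(self, rng):
        xs = [rng.normal(0, 1, (4, 3)) for _ in range(200)]
        traj = _traj(xs)
        res = sm.pca_modes(traj, np.arange(4))
        proj = sm.project_trajectory(traj, res, n_modes=3)
        np.testing.assert_allclose(proj.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(proj.var(axis=0), res.eigenvalues[:3], rtol=1e-9)

    def test_full_rank_reconstruction(self, rng):
        xs = [rng.normal(0, 1, (3, 3)) for _ in range(30)]
        traj = _traj(xs)
        res = sm.pca_modes(traj, np.arange(3))
        proj = sm.project_trajectory(traj, res, n_modes=9)
        recon = proj @ res.modes + res.mean_coords.ravel()
        np.testing.assert_allclose(recon, np.stack(xs).reshape(30, -1), atol=1e-9)

    def test_too_many_modes_rejected(self, rng):
        traj = _traj([rng.normal(size=(2, 3)) for _ in range(5)])
        res = sm.pca_modes(traj, np.arange(2))
        with pytest.raises(ValueError, match="exceeds"):
            sm.project_trajectory(traj, res, n_modes=7)

    def test_two_basins_separate_in_projection(self, docking_system, rng):
        # Frames jittered around the two designed poses form two separated
        # clusters in the leading-mode projection plane.
        mobile = docking_system.group("mobile_domain")
        frames = []
        labels = []
        for pose, lab in (("undocked", 0), ("docked", 1)):
            base = docking_system.poses[pose]
            for _ in range(25):
                frames.append(base + rng.normal(0, 0.15, base.shape))
                labels.append(lab)
        traj = _traj(frames)
        aligned = sm.fit_superpose_series(
            traj, docking_system.poses["undocked"], docking_system.group("scaffold")
        )
        res = sm.pca_modes(aligned, mobile)
        proj = sm.project_trajectory(aligned, res, n_modes=2)
        assert silhouette_score(proj, labels) > 0.5


class TestDistances:
    def test_three_four_five(self):
        system = sm.ParticleSystem(
            masses=np.ones(2), site_labels={"a": 0, "b": 1}
        )
        traj = _traj([np.array([[0.0, 0, 0], [3.0, 4.0, 0]])])
        series = sm.distance_pairs_series(traj, system, [("a", "b")])
        assert series["a-b"][0] == pytest.approx(5.0)

    def test_static_trajectory_constant_series(self, docking_system):
        pose = docking_system.poses["docked"]
        traj = _traj([pose.copy() for _ in range(4)])
        series = sm.distance_pairs_series(
            traj, docking_system, [("fretA", "fretB"), ("fretA", "fretC")]
        )
        for v in series.values():
            assert np.ptp(v) == 0.0

    def test_pose_difference_matches_designed_displacement(self, docking_system):
        # The undocked→docked rigid translation moves fretA by the designed
        # travel along z; the fretA–fretB distance changes accordingly.
        d = docking_system
        traj = _traj([d.poses["undocked"], d.poses["docked"]])
        series = sm.distance_pairs_series(traj, d, [("scissile", "fretA")])
        za = d.poses["undocked"][d.site("fretA")]
        zb = d.poses["docked"][d.site("fretA")]
        assert series["scissile-fretA"][0] - series["scissile-fretA"][1] == pytest.approx(
            np.linalg.norm(za) - np.linalg.norm(zb)
        )

    def test_unresolved_label_rejected(self, docking_system):
        traj = _traj([docking_system.poses["docked"]])
        with pytest.raises(KeyError):
            sm.distance_pairs_series(traj, docking_system, [("scissile", "bogus")])


class TestGroupwiseRmsd:
    def test_reference_against_itself_is_zero(self, docking_system):
        ref = docking_system.poses["undocked"]
        traj = _traj([ref.copy()])
        for mode in ("global_fit", "self_fit"):
            out = sm.groupwise_rmsd(
                traj, ref, docking_system, ["scaffold", "mobile_domain"], fit_mode=mode
            )
            for series in out.values():
                np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_rigid_rotation_zero_under_global_fit(self, docking_system):
        ref = docking_system.poses["undocked"]
        frame = ref @ _rotation_z(0.9).T + np.array([1.0, 2.0, 3.0])
        out = sm.groupwise_rmsd(
            _traj([frame]), ref, docking_system, ["scaffold", "mobile_domain"]
        )
        for series in out.values():
            np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_displaced_rigid_group_self_vs_global(self, docking_system):
        # Internally rigid but displaced mobile domain: self-fit sees ~0,
        # global fit sees the displacement RMSD.
        d = docking_system
        ref = d.poses["undocked"]
        frame = d.poses["docked"]  # mobile rigidly translated by the travel
        travel = np.linalg.norm(
            (ref - frame)[d.group("mobile_domain")], axis=1
        ).mean()
        self_fit = sm.groupwise_rmsd(
            _traj([frame]), ref, d, ["mobile_domain"], fit_mode="self_fit"
        )
        global_fit = sm.groupwise_rmsd(
            _traj([frame]), ref, d, ["mobile_domain"],
            fit_mode="global_fit", fit_selection=d.group("scaffold"),
        )
        assert self_fit["mobile_domain"][0] == pytest.approx(0.0, abs=1e-9)
        assert global_fit["mobile_domain"][0] == pytest.approx(travel, abs=1e-9)


class TestCluster:
    def test_identical_frames_single_cluster(self, rng):
        coords = rng.normal(0, 1, (5, 3))
        frames = [Frame(time=0.1 * (k + 1), coords=coords.copy()) for k in range(6)]
        res = cluster_representative(frames, np.arange(5), threshold=0.5)
        assert res.representative_index == 0
        assert len(set(res.assignments.tolist())) == 1

    def test_single_frame_is_its_own_representative(self, rng):
        frames = [Frame(time=0.1, coords=rng.normal(size=(4, 3)))]
        res = cluster_representative(frames, np.arange(4))
        assert res.representative_index == 0

    def test_majority_cluster_medoid_matches_exhaustive_oracle(self, rng):
        # 8 frames near pose A, 2 near a well-separated pose B: the
        # representative is the exhaustively computed medoid of the A group.
        base_a = rng.normal(0, 1, (6, 3))
        base_b = base_a + np.array([50.0, 0.0, 0.0]) * np.array([1.0, 1, 1])
        frames = []
        for k in range(8):
            frames.append(Frame(time=0.1 * (k + 1), coords=base_a + rng.normal(0, 0.05, base_a.shape)))
        for k in range(2):
            frames.append(Frame(time=0.9 + 0.1 * k, coords=base_b + rng.normal(0, 0.05, base_b.shape)))
        res = cluster_representative(frames, np.arange(6), threshold=2.0)
        assert res.representative_index < 8
        members = np.arange(8)
        sums = res.rmsd_matrix[np.ix_(members, members)].sum(axis=1)
        assert res.representative_index == int(members[np.argmin(sums)])


class TestCoordination:
    def _system(self, n_ligands=6):
        labels = {"center": 0}
        labels.update({f"L{k}": k + 1 for k in range(n_ligands)})
        return sm.ParticleSystem(masses=np.ones(n_ligands + 1), site_labels=labels)

    def _octahedron(self, scale=1.0):
        return np.array(
            [
                [0.0, 0, 0],
                [scale, 0, 0], [-scale, 0, 0],
                [0, scale, 0], [0, -scale, 0],
                [0, 0, scale], [0, 0, -scale],
            ]
        )

    def test_ideal_octahedron(self):
        system = self._system()
        report = coordination_geometry(
            self._octahedron(), system, "center", [f"L{k}" for k in range(6)], cutoff=1.5
        )
        assert report.ligand_count == 6
        assert report.cis_deviation == pytest.approx(0.0, abs=1e-9)
        assert report.trans_deviation == pytest.approx(0.0, abs=1e-9)
        assert report.is_octahedral

    def test_missing_vertex_not_octahedral(self):
        system = self._system()
        coords = self._octahedron()
        coords[6] = [0, 0, 10.0]  # push one ligand out of the shell
        report = coordination_geometry(
            coords, system, "center", [f"L{k}" for k in range(6)], cutoff=1.5
        )
        assert report.ligand_count == 5
        assert not report.is_octahedral

    def test_perturbed_octahedron_within_propagated_tolerance(self, rng):
        # Vertex noise sigma=0.02 on unit bonds perturbs angles by at most
        # ~3*sqrt(2)*sigma radians; the report stays octahedral under the
        # matching angular tolerance.
        system = self._system()
        sigma = 0.02
        tol_deg = np.degrees(3 * np.sqrt(2) * sigma) + 1e-6
        for _ in range(10):
            coords = self._octahedron()
            coords[1:] += rng.normal(0, sigma, (6, 3))
            report = coordination_geometry(
                coords, system, "center", [f"L{k}" for k in range(6)],
                cutoff=1.5, angle_tolerance=tol_deg,
            )
            assert report.is_octahedral
            assert max(report.cis_deviation, report.trans_deviation) <= tol_deg

    def test_center_must_resolve(self):
        system = self._system()
        with pytest.raises(KeyError):
            coordination_geometry(self._octahedron(), system, "nope", ["L0"], cutoff=1.0)

    def test_positive_cutoff_required(self):
        system = self._system()
        with pytest.raises(ValueError):
            coordination_geometry(self._octahedron(), system, "center", ["L0"], cutoff=0.0)


class TestDecomposition:
    def test_no_cross_terms_in_range_gives_zero(self, docking_system):
        # All pair wells involve the ion; mobile vs scaffold has none.
        total, per = sm.interaction_decomposition(
            docking_system, docking_system.poses["docked"], "mobile_domain", "scaffold"
        )
        assert total == 0.0 and per == {}

    def test_pair_energy_matches_analytic_value(self, docking_system):
        d = docking_system
        total, per = sm.interaction_decomposition(
            d, d.poses["docked"], "mobile_domain", "ion"
        )
        expected = 0.0
        coords = d.poses["docked"]
        mobile = set(d.group("mobile_domain").tolist())
        for t in d.terms:
            if isinstance(t, sm.PairWell) and (t.i in mobile or t.j in mobile):
                r = float(np.linalg.norm(coords[t.i] - coords[t.j]))
                expected += t.energy_at(r)
        assert total == pytest.approx(expected, abs=1e-12)
        assert total < -1.0  # the bridging ion binds the docked domain

    def test_per_particle_contributions_sum_to_total(self, docking_system, rng):
        d = docking_system
        coords = d.poses["docked"] + rng.normal(0, 0.3, d.poses["docked"].shape)
        total, per = sm.interaction_decomposition(d, coords, "mobile_domain", "ion")
        assert sum(per.values()) == pytest.approx(total, abs=1e-12)

    def test_overlapping_groups_rejected(self, docking_system):
        with pytest.raises(ValueError, match="overlap"):
            sm.interaction_decomposition(
                docking_system, docking_system.poses["docked"],
                "mobile_domain", "mobile_domain",
            )
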