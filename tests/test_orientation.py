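"""Interdomain orientation coordinates: axes, references, measures, KDE,
superposition and RMSF."""

import numpy as np
import numpy.testing as npt
import pytest
from scipy.spatial.transform import Rotation

from igface import orientation, structio, synthetic
from igface.orientation import (build_reference, compute_rmsf, inertia_principal_axis,
                                kabsch, kde_density, measure_frame, measure_trajectory,
                                superpose_rmsd)


def _rotmat(seq="xyz", angles=(20, -35, 110)):
    return Rotation.from_euler(seq, angles, degrees=True).as_matrix()


class TestInertiaAxis:
    def test_rod_axis_is_rod_direction(self):
        coords = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)])
        coords[::2, 0] += 0.3  # break perfect degeneracy of the two large moments
        axis = inertia_principal_axis(coords, np.ones(10), sign_reference=[0, 0, 1])
        assert abs(axis @ [0, 0, 1]) > 0.99
        assert axis[2] > 0

    def test_rotated_rod_gives_rotated_axis(self):
        coords = np.column_stack([np.zeros(10), np.zeros(10), np.arange(10.0)])
        coords[::2, 0] += 0.3
        r = _rotmat()
        axis0 = inertia_principal_axis(coords, np.ones(10), sign_reference=[0, 0, 1])
        axis1 = inertia_principal_axis((r @ coords.T).T, np.ones(10),
                                       sign_reference=r @ [0, 0, 1])
        npt.assert_allclose(axis1, r @ axis0, atol=1e-9)

    def test_sheet_normal_not_returned(self):
        # flat square sheet: the smallest moment lies IN the sheet plane,
        # the normal has the largest moment; verify via explicit eigh
        xy = np.array([[x, y, 0.0] for x in range(4) for y in range(4)], dtype=float)
        xy[:, 0] *= 1.5  # make in-plane moments distinct
        masses = np.ones(len(xy))
        axis = inertia_principal_axis(xy, masses, sign_reference=[1, 0, 0])
        com = xy.mean(axis=0)
        r = xy - com
        inertia = sum(m * (np.eye(3) * (ri @ ri) - np.outer(ri, ri))
                      for m, ri in zip(masses, r))
        evals, evecs = np.linalg.eigh(inertia)
        npt.assert_allclose(np.abs(axis), np.abs(evecs[:, 0]), atol=1e-9)
        assert abs(axis @ [0, 0, 1]) < 1e-9  # not the sheet normal

    def test_degenerate_spectrum_rejected(self):
        coords = np.array([[x, y, 0.0] for x in range(3) for y in range(3)], dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            inertia_principal_axis(coords, np.ones(9))


class TestBuildReference:
    def test_principal_axis_is_z_and_center_axis_in_xz(self, complex_truth):
        cx, truth = complex_truth
        ref = build_reference(cx, truth.selections["a"], truth.selections["b"],
                              center_mode="ca")
        # recompute the inertia axis of the aligned CA cloud: must be +z exactly
        for dom in (ref.domain_a, ref.domain_b):
            coords = dom.ref_coords
            axis = inertia_principal_axis(coords, np.ones(len(coords)),
                                          sign_reference=coords[-1] - coords[0])
            npt.assert_allclose(axis @ [0, 0, 1], 1.0, atol=1e-9)

    def test_idempotent_on_own_output(self, complex_truth, complex_reference):
        cx, truth = complex_truth
        m0 = measure_frame(cx.coords, complex_reference)
        m1 = measure_frame(cx.coords, complex_reference)
        assert m0 == m1

    def test_parallel_axes_rejected(self):
        # two collinear rods: centre axis parallel to both principal axes
        def rod(z0, chain):
            atoms = []
            for i in range(8):
                atoms.append(structio.Atom(i + 1, "CA", "C", chain, i + 1, "", "ALA",
                                           [0.3 * (i % 2), 0.0, z0 + 3.4 * i]))
                atoms.append(structio.Atom(100 + i, "CB", "C", chain, i + 1, "", "ALA",
                                           [1.0 + 0.3 * (i % 2), 0.4, z0 + 3.4 * i]))
            return atoms
        st = structio.Structure(rod(0.0, "A") + rod(40.0, "B"))
        with pytest.raises(ValueError, match="principal axis"):
            build_reference(st,
                            structio.DomainSelection("a", [("A", (1, 8))]),
                            structio.DomainSelection("b", [("B", (1, 8))]))


class TestMeasureFrame:
    def test_self_consistency_on_reference(self, complex_truth, complex_reference):
        cx, truth = complex_truth
        m = measure_frame(cx.coords, complex_reference)
        for key, val in truth.measures.items():
            assert m[key] == pytest.approx(val, abs=1e-6), key

    def test_rotation_about_center_axis_shifts_torsion_only(self, complex_truth,
                                                            complex_reference):
        cx, truth = complex_truth
        m0 = measure_frame(cx.coords, complex_reference)
        idx_b = structio.select_domain(cx, truth.selections["b"])
        coords = cx.coords
        # rotate domain b rigidly by +25 degrees about the a->b centre axis
        ref = complex_reference
        w = ref.domain_b.center_weights
        cb = (w[:, None] * coords[ref.domain_b.center_idx]).sum(axis=0) / w.sum()
        wa = ref.domain_a.center_weights
        ca = (wa[:, None] * coords[ref.domain_a.center_idx]).sum(axis=0) / wa.sum()
        axis = (cb - ca) / np.linalg.norm(cb - ca)
        rot = Rotation.from_rotvec(np.radians(25.0) * axis).as_matrix()
        coords[idx_b] = (rot @ (coords[idx_b] - cb).T).T + cb
        m1 = measure_frame(coords, complex_reference)
        assert m1["AB"] - m0["AB"] == pytest.approx(25.0, abs=1e-6)
        for key in ("AC1", "AC2", "BC1", "BC2"):
            assert m1[key] == pytest.approx(m0[key], abs=1e-6), key
        assert m1["dC"] == pytest.approx(m0["dC"], abs=1e-6)

    def test_translation_along_center_axis_changes_dc_only(self, complex_truth,
                                                           complex_reference):
        cx, truth = complex_truth
        m0 = measure_frame(cx.coords, complex_reference)
        coords = cx.coords
        idx_b = structio.select_domain(cx, truth.selections["b"])
        ref = complex_reference
        wa = ref.domain_a.center_weights
        ca = (wa[:, None] * coords[ref.domain_a.center_idx]).sum(axis=0) / wa.sum()
        wb = ref.domain_b.center_weights
        cb = (wb[:, None] * coords[ref.domain_b.center_idx]).sum(axis=0) / wb.sum()
        axis = (cb - ca) / np.linalg.norm(cb - ca)
        coords[idx_b] += 5.0 * axis
        m1 = measure_frame(coords, complex_reference)
        assert m1["dC"] - m0["dC"] == pytest.approx(5.0, abs=1e-6)
        for key in ("AB", "AC1", "AC2", "BC1", "BC2"):
            assert m1[key] == pytest.approx(m0[key], abs=1e-6), key

    def test_global_rigid_body_invariance(self, complex_truth, complex_reference):
        cx, truth = complex_truth
        m0 = measure_frame(cx.coords, complex_reference)
        rot = _rotmat("zxy", (73, -12, 141))
        moved = (rot @ cx.coords.T).T + np.array([11.0, -4.0, 27.0])
        m1 = measure_frame(moved, complex_reference)
        for key in m0:
            assert m1[key] == pytest.approx(m0[key], abs=1e-6), key

    def test_reference_mismatch_warns(self, complex_truth, complex_reference):
        cx, truth = complex_truth
        rng = np.random.default_rng(0)
        coords = cx.coords + rng.normal(0, 4.0, size=(len(cx), 3))
        with pytest.warns(UserWarning, match="RMSD"):
            measure_frame(coords, complex_reference)


class TestMeasureTrajectory:
    def test_static_trajectory_constant_series(self, complex_truth, complex_reference):
        cx, truth = complex_truth
        traj = structio.Trajectory(cx, np.repeat(cx.coords[None], 4, axis=0))
        df = measure_trajectory(traj, complex_reference)
        assert len(df) == 4
        assert df.nunique().max() == 1

    def test_planted_torsion_series_recovered(self):
        dom_a = synthetic.build_toy_domain(7, 6, seed=0)
        dom_b = synthetic.build_toy_domain(7, 6, seed=1, chain="B")
        frames = []
        reference = None
        for torsion in (80.0, 90.0, 100.0):
            cx, truth = synthetic.assemble_complex(dom_a, dom_b, torsion=torsion,
                                                   tilts=(70.0, 80.0), d_c=30.0)
            if reference is None:
                reference = build_reference(cx, truth.selections["a"], truth.selections["b"])
            frames.append(cx.coords)
        traj = structio.Trajectory(cx, np.stack(frames))
        df = measure_trajectory(traj, reference)
        npt.assert_allclose(df["AB"].to_numpy(), [80.0, 90.0, 100.0], atol=1e-4)

    def test_alias_naming(self, complex_truth, complex_reference):
        cx, _ = complex_truth
        traj = structio.Trajectory(cx, cx.coords[None])
        df = measure_trajectory(traj, complex_reference)
        assert list(orientation.alias_measures(df, "fv").columns) == \
            ["HL", "LC1", "LC2", "HC1", "HC2", "dC"]
        assert list(orientation.alias_measures(df, "ch1-cl").columns) == \
            ["cHL", "cLC1", "cLC2", "cHC1", "cHC2", "dC"]


class TestKDE:
    def test_mode_near_sample_center(self):
        rng = np.random.default_rng(1)
        kde = kde_density(rng.normal(90.0, 5.0, 10_000))
        assert kde.mode() == pytest.approx(90.0, abs=0.5)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(2)
        kde = kde_density(rng.normal(50.0, 8.0, 2_000))
        assert kde.integral() == pytest.approx(1.0, abs=1e-3)

    def test_wider_bandwidth_lowers_mode_height(self):
        rng = np.random.default_rng(3)
        samples = rng.normal(90.0, 5.0, 2_000)
        k1 = kde_density(samples, bandwidth=1.0)
        k2 = kde_density(samples, bandwidth=2.0)
        assert k2.density.max() < k1.density.max()

    def test_mixture_density_between_scaled_components(self):
        rng = np.random.default_rng(4)
        s1 = rng.normal(60.0, 4.0, 1_000)
        s2 = rng.normal(100.0, 4.0, 1_000)
        both = np.concatenate([s1, s2])
        bw = 3.0
        k = kde_density(both, bandwidth=bw)
        k1 = kde_density(s1, bandwidth=bw)
        k2 = kde_density(s2, bandwidth=bw)
        def at(kde_obj, x):
            return np.interp(x, kde_obj.grid, kde_obj.density, left=0.0, right=0.0)
        w1 = len(s1) / len(both)
        for x in np.linspace(50, 110, 25):
            mix = w1 * at(k1, x) + (1 - w1) * at(k2, x)
            assert at(k, x) == pytest.approx(mix, abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            kde_density(np.full(10, 90.0))


class TestSuperpose:
    def test_identical_sets_zero_rmsd(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 3))
        _, _, rmsd = superpose_rmsd(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_zero_rmsd(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 3))
        moved = (_rotmat() @ pts.T).T + [3.0, -1.0, 7.0]
        _, _, rmsd = superpose_rmsd(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_displaced_point_matches_scipy_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(4, 3))
        target = pts.copy()
        target[0] += [2.0, 0.0, 0.0]
        _, _, rmsd = superpose_rmsd(pts, target)
        # independent oracle: scipy's Wahba solver returns sqrt of the
        # residual sum of squares at the optimum
        _, rssd = Rotation.align_vectors(target - target.mean(0), pts - pts.mean(0))
        assert rmsd == pytest.approx(rssd / np.sqrt(len(pts)), abs=1e-9)

    def test_reflection_never_returned(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        rot, _, _ = kabsch(pts, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


class TestRMSF:
    def _selection(self, cx):
        return structio.DomainSelection("a", [("A", (1, max(a.resseq for a in cx.atoms
                                                            if a.chain == "A")))])

    def test_static_trajectory_zero_rmsf(self, toy_domain):
        traj = structio.Trajectory(toy_domain, np.repeat(toy_domain.coords[None], 5, axis=0))
        rmsf = compute_rmsf(traj, self._selection(toy_domain))
        assert max(rmsf.values()) == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_jitter_expectation(self, toy_domain):
        # one residue jittered with sigma=0.5 isotropic -> RMSF ~ sqrt(3)*0.5
        rng = np.random.default_rng(9)
        n_frames = 4_000
        frames = np.repeat(toy_domain.coords[None], n_frames, axis=0)
        ca = toy_domain.atom_index("A", 10, "CA")
        frames[:, ca, :] += rng.normal(0, 0.5, size=(n_frames, 3))
        rmsf = compute_rmsf(structio.Trajectory(toy_domain, frames), self._selection(toy_domain))
        assert rmsf[("A", 10, "")] == pytest.approx(np.sqrt(3) * 0.5, rel=0.05)

    def test_rigid_body_motion_removed_by_superposition(self, toy_domain):
        frames = []
        for k in range(6):
            rot = Rotation.from_euler("z", 15.0 * k, degrees=True).as_matrix()
            frames.append((rot @ toy_domain.coords.T).T + [2.0 * k, 0.0, -k])
        rmsf = compute_rmsf(structio.Trajectory(toy_domain, np.stack(frames)),
                            self._selection(toy_domain))
        assert max(rmsf.values()) == pytest.approx(0.0, abs=1e-9)
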