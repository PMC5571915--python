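import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dockint.docking import (
    Grid,
    Pose,
    correlate_direct,
    correlate_fft,
    discretize,
    generate_poses,
    rotation_set,
)
from dockint.io import poses_table

from conftest import build_model


class TestDiscretize:
    def test_single_atom_coarse_grid_one_cell(self):
        m = build_model([[(0.0, 0.0, 0.0)]])
        g = discretize(m, spacing=5.0, role="ligand")
        assert int((g.values == 1).sum()) == 1

    def test_sphere_occupancy_matches_enumeration(self):
        # shell of atoms on a 5 A sphere, 1 A grid
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(80, 3))
        pts = 5.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        m = build_model([[tuple(p)] for p in pts])
        g = discretize(m, spacing=1.0, role="ligand")
        # oracle: cell centres within the vdW radius of any atom, plus the
        # cell nearest each atom centre (coarse-grid guarantee)
        idx = np.argwhere(np.ones(g.values.shape, dtype=bool))
        centers = g.origin + 1.0 * idx
        d = np.linalg.norm(centers[:, None, :] - pts[None, :, :], axis=2)
        inside = (d < 1.7).any(axis=1)
        expect = set(map(tuple, idx[inside]))
        for p in pts:
            expect.add(tuple(np.clip(np.round((p - g.origin) / 1.0).astype(int),
                                     0, np.array(g.values.shape) - 1)))
        got = set(map(tuple, np.argwhere(g.values == 1)))
        assert got == expect

    def test_receptor_interior_penalised(self):
        # tight 3x3x3 block: the central atom's cell is interior
        coords = [[(2.0 * i, 2.0 * j, 2.0 * k)]
                  for i in range(3) for j in range(3) for k in range(3)]
        m = build_model(coords)
        g = discretize(m, spacing=1.0, role="receptor")
        assert (g.values < 0).any()
        assert (g.values == 1).any()

    def test_empty_structure_is_error(self, toy):
        empty = build_model([[(0.0, 0, 0)]])
        empty.coords = np.empty((0, 3))
        with pytest.raises(ValueError):
            discretize(empty, spacing=1.0)

    def test_cell_budget_error_advises_spacing(self, toy):
        with pytest.raises(ValueError, match="spacing"):
            discretize(toy.receptor, spacing=0.01)


class TestCorrelation:
    @pytest.mark.parametrize("shape_r,shape_l", [
        ((6, 6, 6), (4, 4, 4)),
        ((8, 8, 8), (8, 8, 8)),
        ((5, 7, 6), (3, 4, 5)),
        ((16, 16, 16), (6, 6, 6)),
    ])
    def test_fft_equals_direct(self, shape_r, shape_l):
        rng = np.random.default_rng(42)
        r = rng.integers(-15, 2, size=shape_r).astype(float)
        l = (rng.random(shape_l) < 0.3).astype(float)
        np.testing.assert_allclose(correlate_fft(r, l),
                                   correlate_direct(r, l), atol=1e-8)

    def test_integer_grid_correlation_is_exact(self):
        rng = np.random.default_rng(7)
        r = rng.integers(0, 3, size=(8, 8, 8)).astype(float)
        l = rng.integers(0, 2, size=(5, 5, 5)).astype(float)
        fft = np.round(correlate_fft(r, l))
        assert np.array_equal(fft, correlate_direct(r, l))


class TestGeneratePoses:
    def test_designed_fit_attains_top_shape_score(self):
        # complementary plates: face-on-face stacking is shape-optimal, and
        # a translation within one grid cell of the designed offset (zero,
        # the ligand is pre-placed) shares the top score
        rec = build_model([[(5.0 * i, 5.0 * j, 0.0)]
                           for i in range(3) for j in range(3)], chain_id="A")
        lig = build_model([[(5.0 * i, 5.0 * j, 4.0)]
                           for i in range(3) for j in range(3)], chain_id="B")
        run = generate_poses(rec, lig, n_rotations=1, spacing=2.0,
                             n_keep=400, seed=0, top_per_rotation=400,
                             surface_thickness=3.0)
        top = run.poses[0].shape_score
        ties = [p for p in run.poses if p.shape_score >= top - 1e-9]
        assert min(np.abs(p.translation).max() for p in ties) <= 2.0

    def test_single_atoms_dock_adjacent(self):
        rec = build_model([[(0.0, 0.0, 0.0)]], chain_id="A")
        lig = build_model([[(0.0, 0.0, 0.0)]], chain_id="B")
        run = generate_poses(rec, lig, n_rotations=1, spacing=1.0,
                             n_keep=1, seed=0, top_per_rotation=5)
        d = np.linalg.norm(run.poses[0].translation)
        # ligand centre in the receptor contact shell (vdW 1.7 + 1.5)
        assert 1.7 <= d <= 1.7 + 1.5 + 1.0

    def test_best_translation_matches_bruteforce(self):
        rec = build_model([[(0.0, 0.0, 0.0)], [(4.0, 0.0, 0.0)]],
                          chain_id="A")
        lig = build_model([[(0.0, 0.0, 0.0)]], chain_id="B")
        rg = discretize(rec, 1.5, role="receptor")
        lg = discretize(lig, 1.5, role="ligand")
        fft_best = correlate_fft(rg.values, lg.values).max()
        direct_best = correlate_direct(rg.values, lg.values).max()
        assert fft_best == pytest.approx(direct_best, abs=1e-8)
        run = generate_poses(rec, lig, n_rotations=1, spacing=1.5,
                             n_keep=1, seed=0, top_per_rotation=1)
        assert run.poses[0].shape_score == pytest.approx(direct_best)

    def test_deterministic_given_seed(self, toy):
        runs = [generate_poses(toy.receptor, toy.ligand, n_rotations=10,
                               spacing=2.5, n_keep=200, seed=11,
                               top_per_rotation=20, surface_thickness=3.0)
                for _ in range(2)]
        assert poses_table(runs[0]) == poses_table(runs[1])

    def test_warns_when_fewer_candidates_than_requested(self):
        rec = build_model([[(0.0, 0.0, 0.0)]], chain_id="A")
        lig = build_model([[(0.0, 0.0, 0.0)]], chain_id="B")
        with pytest.warns(UserWarning, match="candidates"):
            generate_poses(rec, lig, n_rotations=1, spacing=1.0,
                           n_keep=10**6, seed=0, top_per_rotation=50)


class TestRotationsAndPoses:
    def test_rotation_set_is_deterministic_and_orthonormal(self):
        a = rotation_set(25, seed=3)
        b = rotation_set(25, seed=3)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a[0], np.eye(3))
        for m in a:
            np.testing.assert_allclose(m @ m.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(m) == pytest.approx(1.0)

    def test_improper_rotation_rejected(self):
        flip = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="determinant"):
            Pose(rotation=flip, translation=np.zeros(3), shape_score=0.0)

    @given(st.integers(min_value=2, max_value=40))
    @settings(deadline=None, max_examples=20)
    def test_rotation_set_size(self, n):
        assert rotation_set(n, seed=0).shape == (n, 3, 3)
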