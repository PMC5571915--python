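import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dockint.nip import (
    NIPProfile,
    averaged_buried_surface,
    extend_patch,
    normalize_nip,
    predict_hotspots,
    predict_interface_for_protein,
)
from dockint.sasa import ASAProfile
from dockint.structures import ResidueKey

from conftest import build_model


def profile_for(model, asa_values, rasa_values=None):
    asa = np.asarray(asa_values, dtype=float)
    rasa = (np.asarray(rasa_values, dtype=float) if rasa_values is not None
            else np.full(len(asa), 0.5))
    return ASAProfile(residues=list(model.residues), asa=asa, rasa=rasa,
                      atom_asa=np.zeros(model.n_atoms), probe_radius=1.4,
                      n_points=960, source_id=model.source_id)


class TestAveragedBuriedSurface:
    def test_unchanged_asa_gives_zero(self):
        m = build_model([[(0.0, 0, 0)], [(5.0, 0, 0)]])
        prof = profile_for(m, [100.0, 50.0])
        abs_vals = averaged_buried_surface(prof, np.array([[100.0, 50.0]] * 3))
        np.testing.assert_allclose(abs_vals, 0.0)

    def test_fully_buried_gives_one(self):
        m = build_model([[(0.0, 0, 0)]])
        prof = profile_for(m, [80.0])
        abs_vals = averaged_buried_surface(prof, np.zeros((5, 1)))
        assert abs_vals[0] == pytest.approx(1.0)

    def test_quarter_burial(self):
        m = build_model([[(0.0, 0, 0)]])
        prof = profile_for(m, [100.0])
        abs_vals = averaged_buried_surface(prof, np.array([[75.0]]))
        assert abs_vals[0] == pytest.approx(0.25)

    def test_zero_unbound_asa_gives_zero(self):
        m = build_model([[(0.0, 0, 0)], [(5.0, 0, 0)]])
        prof = profile_for(m, [0.0, 100.0])
        abs_vals = averaged_buried_surface(prof, np.array([[0.0, 50.0]]))
        assert abs_vals[0] == 0.0

    def test_residue_set_mismatch_is_error(self):
        m = build_model([[(0.0, 0, 0)]])
        prof = profile_for(m, [100.0])
        with pytest.raises(ValueError, match="residues"):
            averaged_buried_surface(prof, np.array([[1.0, 2.0]]))

    def test_empty_pose_list_is_error(self):
        m = build_model([[(0.0, 0, 0)]])
        prof = profile_for(m, [100.0])
        with pytest.raises(ValueError):
            averaged_buried_surface(prof, np.empty((0, 1)))


class TestNormalizeNIP:
    def test_worked_example(self):
        np.testing.assert_allclose(normalize_nip([0.4, 0.1, 0.1]),
                                   [1.0, -0.5, -0.5])

    def test_flat_profile_gives_zeros(self):
        np.testing.assert_allclose(normalize_nip([0.3, 0.3, 0.3]), 0.0)

    @given(st.lists(st.floats(min_value=-1.0, max_value=1.0), min_size=2,
                    max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_bounds_and_anchors(self, values):
        nip = normalize_nip(values)
        assert np.all(nip <= 1.0 + 1e-12)
        if np.ptp(values) > 1e-9:
            assert nip.max() == pytest.approx(1.0)
            assert nip[int(np.argmax(values))] == pytest.approx(1.0)


class TestPredictHotspots:
    def test_boundary_is_inclusive(self):
        keys = [ResidueKey("A", i, "", "ALA") for i in (1, 2, 3)]
        hot = predict_hotspots(np.array([0.3, 0.2, 0.19]), keys, cutoff=0.2)
        assert hot == set(keys[:2])

    def test_no_hotspots_below_cutoff(self):
        keys = [ResidueKey("A", 1, "", "ALA")]
        assert predict_hotspots(np.array([0.1]), keys) == set()

    def test_cutoff_one_selects_argmax_only(self):
        keys = [ResidueKey("A", i, "", "ALA") for i in (1, 2, 3)]
        hot = predict_hotspots(normalize_nip([0.5, 0.1, 0.2]), keys,
                               cutoff=1.0)
        assert hot == {keys[0]}

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        keys = [ResidueKey("A", i, "", "ALA") for i in range(20)]
        nip = normalize_nip(rng.random(20))
        sets = [predict_hotspots(nip, keys, cutoff=c)
                for c in (0.05, 0.2, 0.5, 0.9)]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger


class TestExtendPatch:
    def _chain(self, xs, rasas):
        m = build_model([[(x, 0.0, 0.0)] for x in xs])
        return m, profile_for(m, np.full(len(xs), 50.0), rasas)

    def test_lone_hotspot_is_its_own_patch(self):
        m, prof = self._chain([0.0, 20.0], [0.5, 0.5])
        patch = extend_patch({m.residues[0]}, m, prof)
        assert patch == {m.residues[0]}

    def test_buried_neighbour_excluded(self):
        m, prof = self._chain([0.0, 5.0], [0.5, 0.05])
        patch = extend_patch({m.residues[0]}, m, prof)
        assert patch == {m.residues[0]}

    def test_ten_angstrom_boundary(self):
        m, prof = self._chain([0.0, 9.9, 21.0, 10.1], [0.5, 0.5, 0.5, 0.5])
        patch = extend_patch({m.residues[0]}, m, prof)
        numbers = {k.number for k in patch}
        assert numbers == {1, 2}          # 9.9 in, 10.1 and 21.0 out

    def test_contains_seed_and_no_buried_non_seeds(self):
        m, prof = self._chain([0.0, 4.0, 8.0], [0.05, 0.5, 0.04])
        seed = {m.residues[0]}             # buried hot-spot stays in
        patch = extend_patch(seed, m, prof)
        assert seed <= patch
        assert m.residues[2] not in patch  # buried, not a seed

    def test_missing_hotspot_is_error(self):
        m, prof = self._chain([0.0], [0.5])
        ghost = ResidueKey("Z", 9, "", "ALA")
        with pytest.raises(KeyError):
            extend_patch({ghost}, m, prof)

    def test_empty_seed_empty_patch(self):
        m, prof = self._chain([0.0], [0.5])
        assert extend_patch(set(), m, prof) == set()


class TestUnionOverPartners:
    def _profile(self, keys, hot, ext):
        n = len(keys)
        return NIPProfile(residues=list(keys), abs_values=np.zeros(n),
                          nip=np.zeros(n), hotspots=set(hot),
                          extended_interface=set(ext), n_poses_used=100,
                          partner_id="p", per_partner={})

    def test_disjoint_patches_union(self):
        keys = [ResidueKey("A", i, "", "ALA") for i in range(6)]
        a = self._profile(keys, [], keys[:2])
        b = self._profile(keys, [], keys[3:5])
        merged = predict_interface_for_protein([a, b])
        assert len(merged.extended_interface) == 4

    def test_identical_patches_collapse(self):
        keys = [ResidueKey("A", i, "", "ALA") for i in range(4)]
        a = self._profile(keys, keys[:1], keys[:2])
        merged = predict_interface_for_protein([a, a])
        assert merged.extended_interface == set(keys[:2])
        assert merged.hotspots == set(keys[:1])

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            predict_interface_for_protein([])

    def test_flat_abs_yields_no_prediction(self):
        m = build_model([[(0.0, 0, 0)], [(5.0, 0, 0)]])
        prof = profile_for(m, [100.0, 100.0])
        abs_vals = averaged_buried_surface(prof, np.array([[100.0, 100.0]]))
        nip = normalize_nip(abs_vals)
        hot = predict_hotspots(nip, prof.residues, cutoff=0.2)
        assert hot == set()
        assert extend_patch(hot, m, prof) == set()
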