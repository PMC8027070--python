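import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msmkin import geometry
from msmkin.geometry import StateClassifier, StateDefinition
from msmkin.structio import ResidueGroup, StructureFrame, mass_of_element

from test_structio import make_frame


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])


class TestKabsch:
    def test_identity_on_identical_inputs(self, rng):
        pts = rng.normal(size=(10, 3))
        rot, trans = geometry.kabsch(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(trans, 0.0, atol=1e-10)

    def test_recovers_known_rigid_transform(self, rng):
        ref = rng.normal(size=(8, 3))
        rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        mobile = ref @ rz.T + np.array([1.0, 2.0, 3.0])
        rot, trans = geometry.kabsch(mobile, ref)
        moved = mobile @ rot.T + trans
        np.testing.assert_allclose(moved, ref, atol=1e-10)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_reflection_forced_to_proper_rotation(self):
        """A mirror image cannot be superposed by a proper rotation: the fit
        must stay det=+1 and leave a residual no better than the best
        rotation found by scanning an axis-angle grid."""
        ref = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0],
                        [0.0, 1.0, 0.0], [0.3, 0.4, 2.0]])
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        rot, trans = geometry.kabsch(mirrored, ref)
        assert np.linalg.det(rot) == pytest.approx(1.0)
        fitted = np.sqrt(((mirrored @ rot.T + trans - ref) ** 2)
                         .sum(-1).mean())
        assert fitted > 0.1
        # axis-angle grid oracle (~1 deg angular resolution)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        i = np.arange(300)
        zc = 1.0 - 2.0 * (i + 0.5) / 300
        rc = np.sqrt(1.0 - zc ** 2)
        axes = np.stack([rc * np.cos(golden * i), rc * np.sin(golden * i), zc], 1)
        angles = np.radians(np.arange(0.0, 360.0, 1.0))
        mc = mirrored - mirrored.mean(0)
        rcen = ref - ref.mean(0)
        best = np.inf
        for ax in axes:
            k = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]],
                          [-ax[1], ax[0], 0]])
            mats = (np.eye(3) + np.sin(angles)[:, None, None] * k
                    + (1 - np.cos(angles))[:, None, None] * (k @ k))
            dev = ((np.einsum("rij,nj->rni", mats, mc) - rcen) ** 2).sum((1, 2))
            best = min(best, dev.min())
        oracle = np.sqrt(best / len(ref))
        assert fitted <= oracle + 1e-3

    def test_collinear_selection_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            geometry.kabsch(line, line[::-1])


class TestRMSD:
    def test_identical_frames_zero(self):
        f = make_frame()
        assert geometry.rmsd_ca(f, f) == pytest.approx(0.0)

    def test_two_point_closed_form(self):
        a = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        b = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert geometry.rmsd(a, b, fit=True) == pytest.approx(0.5)

    def test_translated_copy_zero_after_fit(self, rng):
        a = rng.normal(size=(12, 3))
        assert geometry.rmsd(a, a + [3.0, -1.0, 7.0], fit=True) == \
            pytest.approx(0.0, abs=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(15, 3))
        b = rng.normal(size=(15, 3))
        base = geometry.rmsd(a, b, fit=True)
        moved = b @ random_rotation(rng).T + rng.normal(size=3) * 10
        assert abs(geometry.rmsd(a, moved, fit=True) - base) < 1e-8

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_pseudometric_symmetry_and_triangle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.normal(size=(3, 10, 3)) * 3
        dab = geometry.rmsd(a, b, fit=True)
        dba = geometry.rmsd(b, a, fit=True)
        dac = geometry.rmsd(a, c, fit=True)
        dcb = geometry.rmsd(c, b, fit=True)
        assert dab == pytest.approx(dba, abs=1e-8)
        assert dab <= dac + dcb + 1e-8


class TestOrderParameters:
    def test_same_group_distance_zero(self):
        f = make_frame()
        g = ResidueGroup.from_range("g", "A", 1, 2)
        assert geometry.group_com_distance(f, g, g) == pytest.approx(0.0)

    def test_rigidly_shifted_groups(self):
        """Two single-residue backbone groups whose atoms differ by a pure
        (0,0,10) shift are exactly 10 A apart in COM."""
        atoms, coords = [], []
        base = np.array([[0.0, 0, 0], [1.5, 0, 0], [2.2, 1.0, 0], [2.2, 2.2, 0.4]])
        for r, shift in ((1, np.zeros(3)), (2, np.array([0.0, 0.0, 10.0]))):
            for name, xyz in zip(("N", "CA", "C", "O"), base + shift):
                atoms.append(("A", r, "GLY", name))
                coords.append(xyz)
        chain, res, rn, an = map(np.array, zip(*atoms))
        f = StructureFrame(chain, res.astype(int), rn, an, np.array(coords),
                           np.array([mass_of_element(a[0]) for a in an]))
        g1 = ResidueGroup("g1", (("A", 1),))
        g2 = ResidueGroup("g2", (("A", 2),))
        assert geometry.group_com_distance(f, g1, g2) == pytest.approx(10.0)

    def test_matches_hand_mass_weighted_com(self):
        f = make_frame(n_res=4)
        g1 = ResidueGroup.from_range("g1", "A", 1, 2)
        g2 = ResidueGroup.from_range("g2", "A", 3, 4)
        expected = []
        for g in (g1, g2):
            idx = g.resolve(f)
            w = f.mass[idx]
            expected.append((w[:, None] * f.coord[idx]).sum(0) / w.sum())
        hand = float(np.linalg.norm(expected[0] - expected[1]))
        assert geometry.group_com_distance(f, g1, g2) == pytest.approx(hand)

    @pytest.mark.parametrize("co_vectors,expected", [
        ([(0, 0, 1), (0, 0, 1)], 0.0),
        ([(1, 0, 0), (1, 0, 0)], 90.0),
        ([(0, 0, 1), (1, 0, 0)], 45.0),
    ])
    def test_tilt_angle_from_carbonyl_vectors(self, co_vectors, expected):
        atoms, coords = [], []
        for r, vec in enumerate(co_vectors, start=1):
            c = np.array([3.0 * r, 0.0, 0.0])
            for name, xyz in (("N", c - 1), ("CA", c - 0.5), ("C", c),
                              ("O", c + np.asarray(vec, dtype=float))):
                atoms.append(("A", r, "ALA", name))
                coords.append(xyz)
        chain, res, rn, an = map(np.array, zip(*atoms))
        f = StructureFrame(chain, res.astype(int), rn, an, np.array(coords),
                           np.array([mass_of_element(a[0]) for a in an]))
        helix = ResidueGroup.from_range("h", "A", 1, len(co_vectors))
        assert geometry.helix_tilt_angle(f, helix) == pytest.approx(expected)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_tilt_invariant_under_translation_and_axis_rotation(self, seed):
        rng = np.random.default_rng(seed)
        f = make_frame(n_res=3)
        helix = ResidueGroup.from_range("h", "A", 1, 3)
        base = geometry.helix_tilt_angle(f, helix)
        ang = rng.uniform(0, 2 * np.pi)
        rz = np.array([[np.cos(ang), -np.sin(ang), 0],
                       [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        moved = f.with_coord(f.coord @ rz.T + rng.normal(size=3) * 20)
        assert geometry.helix_tilt_angle(moved, helix) == \
            pytest.approx(base, abs=1e-8)


class TestStateClassification:
    @pytest.mark.parametrize("theta,d,extra,expected", [
        (85.0, 50.0, {}, "closed"),
        (40.0, 50.0, {}, "open"),
        (60.0, 50.0, {}, "semi-open"),
        (40.0, 60.0, {}, "ECD-unrestricted"),
        (75.0, 50.0, {}, "intermediate"),
        (20.0, 50.0, {}, "intermediate"),      # below every band
        (60.0, 50.0, {"d_ecl1": 30.0, "d_ecl3": 41.0}, "on-side"),
        (60.0, 60.0, {"d_ecl1": 30.0, "d_ecl3": 41.0}, "ECD-unrestricted"),
    ])
    def test_state_definitions(self, theta, d, extra, expected):
        assert geometry.classify_state(theta, d, **extra) == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(0, 180), st.floats(0, 120), st.floats(0, 120),
           st.floats(0, 120))
    def test_every_frame_gets_exactly_one_label(self, theta, d, d1, d3):
        label = geometry.classify_state(theta, d, d1, d3)
        assert label in geometry.STATE_LABELS

    def test_scalar_and_vector_classifiers_agree(self, rng):
        theta = rng.uniform(0, 180, 500)
        d = rng.uniform(20, 80, 500)
        d1 = rng.uniform(30, 70, 500)
        d3 = rng.uniform(30, 70, 500)
        clf = StateClassifier()
        vec = clf.classify_series(theta, d, d1, d3)
        scalars = [clf.classify(*args) for args in zip(theta, d, d1, d3)]
        assert vec.tolist() == scalars

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StateClassifier(bands=(StateDefinition("a", 10, 60),
                                   StateDefinition("b", 50, 90)))


class TestContacts:
    def _two_residue_frame(self, closest):
        # residue 1 atoms at x = 0 .. 0.9, residue 2 at x = gap-0.9 .. gap,
        # so the closest atom pair is exactly `closest` apart
        gap = closest + 1.8
        atoms, coords = [], []
        for r in (1, 2):
            for i, name in enumerate(("N", "CA", "C", "O")):
                x = 0.3 * i if r == 1 else gap - 0.3 * i
                atoms.append(("A", r, "ALA", name))
                coords.append([x, 0.0, 0.0])
        chain, res, rn, an = map(np.array, zip(*atoms))
        return StructureFrame(chain, res.astype(int), rn, an,
                              np.array(coords),
                              np.array([mass_of_element(a[0]) for a in an]))

    @pytest.mark.parametrize("closest,cutoff,expected", [(4.0, 4.5, 1),
                                                         (5.0, 4.5, 0)])
    def test_single_pair_threshold(self, closest, cutoff, expected):
        f = self._two_residue_frame(closest)
        g1 = ResidueGroup("g1", (("A", 1),), atom_filter="heavy")
        g2 = ResidueGroup("g2", (("A", 2),), atom_filter="heavy")
        assert geometry.count_contacts(f, g1, g2, cutoff=cutoff) == expected

    def test_matches_exhaustive_enumeration(self, rng):
        f = make_frame(n_res=6)
        f = f.with_coord(rng.uniform(0, 8, size=f.coord.shape))
        g1 = ResidueGroup.from_range("g1", "A", 1, 3, atom_filter="heavy")
        g2 = ResidueGroup.from_range("g2", "A", 4, 6, atom_filter="heavy")
        cutoff = 3.0
        expected = 0
        for ra in (1, 2, 3):
            for rb in (4, 5, 6):
                ia = np.concatenate([f.atom_indices("A", ra, a)
                                     for a in ("N", "CA", "C", "O")])
                ib = np.concatenate([f.atom_indices("A", rb, a)
                                     for a in ("N", "CA", "C", "O")])
                dmin = min(np.linalg.norm(f.coord[i] - f.coord[j])
                           for i in ia for j in ib)
                expected += dmin < cutoff
        assert geometry.count_contacts(f, g1, g2, cutoff=cutoff) == expected

    def test_overlapping_groups_rejected(self):
        f = make_frame(n_res=3)
        g1 = ResidueGroup.from_range("g1", "A", 1, 2)
        g2 = ResidueGroup.from_range("g2", "A", 2, 3)
        with pytest.raises(ValueError, match="overlap"):
            geometry.count_contacts(f, g1, g2)
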