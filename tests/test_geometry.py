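"""Geometry closed forms: SASA, contact area, centroid distance, volume."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allopath import geometry as geo
from allopath import structure_io as sio
from conftest import make_topology


def two_sphere_buried_area(r1, r2, d):
    """Closed-form buried SASA of two intersecting spheres (cap areas)."""
    if d >= r1 + r2:
        return 0.0
    x1 = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h1 = r1 - x1
    h2 = r2 - (d - x1)
    return 0.5 * (2 * np.pi * r1 * h1 + 2 * np.pi * r2 * h2)


class TestCentroidDistance:
    def test_same_selection_zero(self):
        frame = np.random.default_rng(0).normal(size=(5, 3))
        assert geo.centroid_distance(frame, np.arange(5), np.arange(5)) == 0.0

    def test_hand_geometry(self):
        frame = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        assert geo.centroid_distance(frame, [0], [1]) == pytest.approx(5.0)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        frame = rng.normal(size=(8, 3))
        d1 = geo.centroid_distance(frame, np.arange(4), np.arange(4, 8))
        rot = Rotation.random(random_state=2).as_matrix()
        moved = frame @ rot.T + np.array([10.0, -3.0, 2.0])
        d2 = geo.centroid_distance(moved, np.arange(4), np.arange(4, 8))
        assert d1 == pytest.approx(d2, abs=1e-10)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            geo.centroid_distance(np.zeros((2, 3)), [], [0])


class TestSasa:
    def test_isolated_atom_closed_form(self):
        area = geo.sasa(np.zeros((1, 3)), np.array([1.7]), probe=1.4)
        assert area[0] == pytest.approx(4 * np.pi * 3.1 ** 2, rel=0.02)

    def test_fully_caged_atom_zero(self):
        # octahedral + cubic cage of large atoms around a small one
        dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                         [0, 0, 1], [0, 0, -1]] +
                        [[x, y, z] for x in (-1, 1) for y in (-1, 1)
                         for z in (-1, 1)], float)
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        frame = np.vstack([np.zeros(3), dirs * 2.5])
        radii = np.array([1.2] + [2.2] * len(dirs))
        area = geo.sasa(frame, radii, probe=1.4)
        assert area[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_atoms_match_cap_closed_form(self):
        r1, r2, probe, d = 1.7, 1.5, 1.4, 3.2
        frame = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        areas = geo.sasa(frame, np.array([r1, r2]), probe=probe,
                         n_sphere_points=960)
        e1, e2 = r1 + probe, r2 + probe
        free = 4 * np.pi * (e1 ** 2 + e2 ** 2)
        buried = 2 * two_sphere_buried_area(e1, e2, d)
        assert areas.sum() == pytest.approx(free - buried, rel=0.02)

    def test_unknown_element_raises(self):
        top = [sio.AtomRecord(1, "XX", "Xx", "LIG", "A", 1)]
        with pytest.raises(KeyError, match="Xx"):
            geo.sasa(np.zeros((1, 3)), geo.RadiiTable(), top)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(5)
        frame = rng.normal(scale=3.0, size=(6, 3))
        radii = np.full(6, 1.7)
        a1 = geo.sasa(frame, radii, n_sphere_points=240)
        rot = Rotation.random(random_state=8).as_matrix()
        a2 = geo.sasa(frame @ rot.T + 7.0, radii, n_sphere_points=240)
        assert np.allclose(a1.sum(), a2.sum(), rtol=0.02)


class TestContactArea:
    def _topology(self, n):
        return [sio.AtomRecord(i + 1, "C1", "C", "LIG", "A" if i < n // 2 else "B",
                               i + 1) for i in range(n)]

    def test_separated_chains_zero(self):
        frame = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
        area = geo.contact_area(frame, self._topology(2), [0], [1])
        assert area == 0.0

    def test_two_touching_atoms_cap_formula(self):
        d = 3.0
        frame = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        top = self._topology(2)
        table = geo.RadiiTable()
        area = geo.contact_area(frame, top, [0], [1], table,
                                n_sphere_points=960)
        e = 1.7 + 1.4
        assert area == pytest.approx(two_sphere_buried_area(e, e, d), rel=0.02)

    def test_monotone_as_chains_separate(self):
        rng = np.random.default_rng(3)
        a = rng.normal(scale=1.5, size=(4, 3))
        b = rng.normal(scale=1.5, size=(4, 3)) + np.array([4.0, 0, 0])
        top = self._topology(8)
        areas = []
        for shift in (0.0, 2.0, 4.0, 8.0, 20.0):
            frame = np.vstack([a, b + np.array([shift, 0.0, 0.0])])
            areas.append(geo.contact_area(frame, top, np.arange(4),
                                          np.arange(4, 8), n_sphere_points=240))
        assert areas[-1] == 0.0
        # non-increasing up to quadrature noise
        for x, y in zip(areas, areas[1:]):
            assert y <= x + 1.0

    def test_overlapping_selections_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            geo.contact_area(np.zeros((2, 3)), self._topology(2), [0], [0, 1])


class TestPocketVolume:
    def test_empty_sphere_closed_form(self):
        spec = geo.PocketSpec(center=(0.0, 0.0, 0.0), inclusion_radius=8.0,
                              grid_spacing=0.5)
        vol = geo.pocket_volume(np.empty((0, 3)), [], spec)
        exact = 4.0 / 3.0 * np.pi * 8.0 ** 3
        shell = 4.0 * np.pi * 8.0 ** 2 * 0.5   # one grid-shell tolerance
        assert abs(vol - exact) < shell

    def test_single_atom_removes_its_grid_count(self):
        spec = geo.PocketSpec(center=(0.0, 0.0, 0.0), inclusion_radius=8.0,
                              grid_spacing=0.5)
        top = [sio.AtomRecord(1, "CA", "C", "ALA", "A", 1)]
        empty = geo.pocket_volume(np.empty((0, 3)), [], spec)
        with_atom = geo.pocket_volume(np.zeros((1, 3)), top, spec)
        removed = empty - with_atom
        expanded = 1.7 + 1.4
        exact = 4.0 / 3.0 * np.pi * expanded ** 3
        # removed grid volume matches the expanded-sphere volume
        assert removed == pytest.approx(exact, rel=0.05)

    def test_monotone_in_added_atoms(self):
        spec = geo.PocketSpec(center=(0.0, 0.0, 0.0), inclusion_radius=6.0,
                              grid_spacing=0.5)
        rng = np.random.default_rng(4)
        pts = rng.uniform(-3, 3, size=(5, 3))
        vols = []
        for k in range(6):
            top = [sio.AtomRecord(i + 1, "CA", "C", "ALA", "A", i + 1)
                   for i in range(k)]
            vols.append(geo.pocket_volume(pts[:k], top, spec))
        assert vols == sorted(vols, reverse=True)

    def test_grid_refinement_stable(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(-4, 4, size=(8, 3))
        top = [sio.AtomRecord(i + 1, "CA", "C", "ALA", "A", i + 1)
               for i in range(8)]
        coarse = geo.pocket_volume(pts, top, geo.PocketSpec(
            center=(0.0, 0.0, 0.0), inclusion_radius=7.0, grid_spacing=0.5))
        fine = geo.pocket_volume(pts, top, geo.PocketSpec(
            center=(0.0, 0.0, 0.0), inclusion_radius=7.0, grid_spacing=0.25))
        assert abs(fine - coarse) / fine < 0.03

    def test_lining_centroid_center(self):
        top = make_topology(2, atoms=("CA",))
        frame = np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        spec = geo.PocketSpec(inclusion_radius=5.0, grid_spacing=0.5)
        v = geo.pocket_volume(frame, top, spec, lining_indices=np.array([0, 1]))
        assert v > 0.0
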