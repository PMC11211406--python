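"""Atomistic realization, collision detection and greedy refinement."""

import numpy as np
import pytest

import pbcpack.refine as refine
from pbcpack.cg import anneal, initialize_cg
from pbcpack.refine import (
    PackingError,
    Placement,
    brute_force_collisions,
    detect_collisions,
    fit_z_rotation,
    greedy_resolve,
    pack,
    realize_atoms,
)
from pbcpack.sizing import Constraint, SystemSpec
from pbcpack.synthetic import generate_blob
from .conftest import make_component


class TestDetectCollisions:
    def test_pair_inside_and_outside_tolerance(self):
        box = np.array([50.0] * 3)
        near = [np.array([[0.0, 0, 0]]), np.array([[2.4, 0, 0]])]
        far = [np.array([[0.0, 0, 0]]), np.array([[2.6, 0, 0]])]
        assert detect_collisions(near, box).total == 1
        assert detect_collisions(far, box).total == 0

    def test_wrap_across_boundary(self):
        box = np.array([100.0] * 3)
        coords = [np.array([[0.5, 0, 0]]), np.array([[99.5, 0, 0]])]
        rep = detect_collisions(coords, box)
        assert rep.total == 1
        assert rep.pairs[0][2] == pytest.approx(1.0)

    def test_intra_copy_pairs_excluded(self):
        box = np.array([50.0] * 3)
        coords = [np.array([[0.0, 0, 0], [1.0, 0, 0]])]
        assert detect_collisions(coords, box).total == 0

    def test_small_box_rejected(self):
        with pytest.raises(ValueError):
            detect_collisions([np.zeros((1, 3))], np.array([4.0, 50, 50]))

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(trial)
        box = rng.uniform(15, 40, size=3)
        n_copies = rng.integers(2, 6)
        coords = [
            rng.uniform(-60, 60, size=(rng.integers(5, 120), 3))
            for _ in range(n_copies)
        ]
        rep = detect_collisions(coords, box)
        got = {tuple(sorted((a, b))) for a, b, _d, _ca, _cb in rep.pairs}
        assert got == brute_force_collisions(coords, box)

    def test_matches_brute_force_large_instance(self):
        rng = np.random.default_rng(99)
        box = np.array([30.0, 25.0, 35.0])
        coords = [rng.uniform(0, 30, size=(500, 3)) for _ in range(4)]
        rep = detect_collisions(coords, box)
        got = {tuple(sorted((a, b))) for a, b, _d, _ca, _cb in rep.pairs}
        assert got == brute_force_collisions(coords, box)
        assert rep.total > 0  # dense enough to be a meaningful comparison


class TestPlacementRigidity:
    def test_intra_copy_distances_preserved(self):
        from scipy.spatial.transform import Rotation

        pts = np.random.default_rng(3).normal(size=(40, 3)) * 3
        R = Rotation.random(rng=np.random.default_rng(4)).as_matrix()
        p = Placement((0, 1), R, np.array([5.0, 6, 7]), pts.mean(0))
        moved = p.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-6)


class TestFitZRotation:
    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(3, 3)) * 5
        theta = 0.7
        c, s = np.cos(theta), np.sin(theta)
        Rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        moved = ref @ Rz.T + np.array([2.0, -1.0, 0.0])
        got, _shift = fit_z_rotation(ref, moved)
        assert got == pytest.approx(theta, abs=1e-9)

    def test_single_point_gives_identity(self):
        got, shift = fit_z_rotation(np.array([[1.0, 2, 3]]), np.array([[4.0, 5, 3]]))
        assert got == 0.0
        np.testing.assert_allclose(shift, [3.0, 3.0])


class TestRealizeAtoms:
    def _annealed(self, bodies, cons, counts, dims, seed=1):
        spec = SystemSpec(lattice="cubic", dims=dims, counts=counts)
        cg = initialize_cg(spec, bodies, cons, seed)
        return anneal(cg)

    def test_solvated_com_at_particle_center(self, easy_bodies):
        cons = [Constraint("none")] * 3
        cg = self._annealed(list(easy_bodies), cons, [1, 1, 1], [60.0] * 3)
        rng = np.random.default_rng(0)
        for row, (ci, _copy) in enumerate(cg.copy_refs):
            p = realize_atoms(easy_bodies[ci], cg, row, cons[ci], rng)
            comp = easy_bodies[ci]
            com = comp.masses @ p.apply(comp.positions) / comp.masses.sum()
            np.testing.assert_allclose(com, cg.particle_centers(row)[0], atol=1e-6)

    def test_membrane_z_unchanged_from_upload(self, membrane_body):
        cons = [Constraint("none")]
        cg = self._annealed([membrane_body], cons, [2], [70.0] * 3)
        rng = np.random.default_rng(0)
        for row in range(2):
            p = realize_atoms(membrane_body, cg, row, cons[0], rng)
            placed = p.apply(membrane_body.positions)
            np.testing.assert_allclose(
                placed[:, 2], membrane_body.positions[:, 2], atol=1e-9
            )

    def test_fixed_copy_identity_rotation(self, easy_bodies):
        cons = [Constraint("fixed_xyz", x=1.0, y=2.0, z=3.0), Constraint("none"),
                Constraint("none")]
        cg = self._annealed(list(easy_bodies), cons, [1, 0, 0], [60.0] * 3)
        p = realize_atoms(easy_bodies[0], cg, 0, cons[0], np.random.default_rng(0))
        np.testing.assert_allclose(p.rotation, np.eye(3))
        comp = easy_bodies[0]
        com = comp.masses @ p.apply(comp.positions) / comp.masses.sum()
        np.testing.assert_allclose(com, [1.0, 2.0, 3.0], atol=1e-9)


class TestGreedyResolve:
    def _coords_fn(self, bodies):
        def fn(i, p):
            comp = bodies[p.copy_ref[0]]
            return p.apply(comp.positions[comp.heavy_mask])

        return fn

    def test_two_overlapping_copies_resolve(self):
        blob = generate_blob(100, 0.1, seed=8)
        com = blob.center_of_mass()
        p1 = Placement((0, 1), np.eye(3), np.array([0.0, 0, 0]), com)
        p2 = Placement((0, 2), np.eye(3), np.array([4.0, 0, 0]), com)
        box = np.array([60.0] * 3)
        placements, rep = greedy_resolve(
            [p1, p2], self._coords_fn([blob]), box, seed=1
        )
        assert rep.total == 0
        coords = [self._coords_fn([blob])(i, p) for i, p in enumerate(placements)]
        assert brute_force_collisions(coords, box) == set()

    def test_collision_free_input_unchanged(self):
        blob = generate_blob(60, 0.1, seed=9)
        com = blob.center_of_mass()
        p1 = Placement((0, 1), np.eye(3), np.array([-15.0, 0, 0]), com)
        p2 = Placement((0, 2), np.eye(3), np.array([15.0, 0, 0]), com)
        placements, rep = greedy_resolve(
            [p1, p2], self._coords_fn([blob]), np.array([60.0] * 3), seed=2
        )
        assert rep.total == 0
        assert placements[0] is p1 and placements[1] is p2

    def test_unsatisfiable_raises_packing_error(self):
        blob = generate_blob(150, 0.1, seed=10)
        com = blob.center_of_mass()
        ps = [
            Placement((0, k), np.eye(3), np.zeros(3), com) for k in range(1, 4)
        ]
        with pytest.raises(PackingError):
            greedy_resolve(ps, self._coords_fn([blob]), np.array([12.0] * 3), seed=3)

    def test_total_collisions_never_increase_across_sweeps(self, easy_bodies, monkeypatch):
        totals = []
        original = refine.detect_collisions

        def recording(coords, box, tol=2.5):
            rep = original(coords, box, tol)
            totals.append(rep.total)
            return rep

        monkeypatch.setattr(refine, "detect_collisions", recording)
        occupied = sum(b.metrics.volume for b in easy_bodies) * 2
        side = (occupied / 0.25) ** (1 / 3)
        spec = SystemSpec(lattice="cubic", dims=[side] * 3, counts=[2, 2, 2])
        try:
            pack(spec, list(easy_bodies), [Constraint("none")] * 3, seed=21)
        except PackingError:
            pass
        assert totals == sorted(totals, reverse=True)


class TestPack:
    def test_three_blobs_at_10pct_collision_free(self, easy_bodies):
        occupied = sum(b.metrics.volume for b in easy_bodies)
        side = (occupied / 0.10) ** (1 / 3)
        spec = SystemSpec(lattice="cubic", dims=[side] * 3, counts=[1, 1, 1])
        res = pack(spec, list(easy_bodies), [Constraint("none")] * 3, seed=5)
        assert res.report.total == 0
        coords = [
            p.apply(easy_bodies[p.copy_ref[0]].positions) for p in res.placements
        ]
        assert brute_force_collisions(coords, spec.dims) == set()

    def test_infeasible_density_raises(self, easy_bodies):
        occupied = sum(b.metrics.volume for b in easy_bodies) * 3
        side = max((occupied / 0.60) ** (1 / 3), 2 * 2.5 + 0.1)
        spec = SystemSpec(lattice="cubic", dims=[side] * 3, counts=[3, 3, 3])
        with pytest.raises(PackingError):
            pack(spec, list(easy_bodies), [Constraint("none")] * 3, seed=6)

    def test_seeded_determinism(self, easy_bodies):
        occupied = sum(b.metrics.volume for b in easy_bodies)
        side = (occupied / 0.10) ** (1 / 3)
        spec = SystemSpec(lattice="cubic", dims=[side] * 3, counts=[1, 1, 1])
        a = pack(spec, list(easy_bodies), [Constraint("none")] * 3, seed=7)
        b = pack(spec, list(easy_bodies), [Constraint("none")] * 3, seed=7)
        for pa, pb in zip(a.placements, b.placements):
            np.testing.assert_array_equal(pa.rotation, pb.rotation)
            np.testing.assert_array_equal(pa.translation, pb.translation)

    def test_hydrogens_ignored_in_collision_check(self):
        # a hydrogen 1.0 Å from a heavy atom of another copy is not a collision
        a = make_component([[0.0, 0, 0]], elements=["C"])
        b = make_component([[1.0, 0, 0], [10.0, 0, 0]], elements=["H", "C"])
        coords = [a.positions[a.heavy_mask], b.positions[b.heavy_mask]]
        rep = detect_collisions(coords, np.array([40.0] * 3))
        assert rep.total == 0
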