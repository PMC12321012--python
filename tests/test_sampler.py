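"""Site grids, Euler enumeration, descent-until-contact, and the scan."""


import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slabdock import (
    Rotation,
    ValidationError,
    approach,
    build_connectivity,
    enumerate_rotations,
    generate_grid,
    place_adsorbate,
    scan_surface,
)
from slabdock.fixtures import make_rocksalt_slab, make_toy_adsorbate
from slabdock import Slab, detect_surface_atoms


class TestGrid:
    def test_site_count_square(self):
        slab = make_rocksalt_slab("Na", "Cl", 7.0, 1, 1, 1)
        grid = generate_grid(slab, 0.7)
        assert (grid.n_a, grid.n_b) == (10, 10)
        assert len(grid) == 100

    def test_site_count_rectangular(self):
        slab = Slab(lattice=[[5.0, 0, 0], [0, 3.0, 0], [0, 0, 20.0]],
                    symbols=["Na"], positions=[[0, 0, 0]])
        grid = generate_grid(slab, 1.0)
        assert (grid.n_a, grid.n_b) == (5, 3)
        assert len(grid) == 15

    def test_sites_fractional_half_open(self):
        slab = make_rocksalt_slab()
        grid = generate_grid(slab, 0.9)
        uv = np.array(grid.sites)
        assert (uv >= 0).all() and (uv < 1).all()
        # equidistant: u values are k/n_a
        us = sorted({u for u, _ in grid.sites})
        np.testing.assert_allclose(us, np.arange(grid.n_a) / grid.n_a)

    def test_oversized_spacing_warns_single_site(self):
        slab = make_rocksalt_slab()
        with pytest.warns(UserWarning):
            grid = generate_grid(slab, 100.0)
        assert len(grid) == 1


class TestRotationEnumeration:
    @pytest.mark.parametrize("step,count", [(20, 4913), (90, 27), (120, 8)])
    def test_counts(self, step, count):
        assert len(enumerate_rotations(step)) == count

    def test_non_divisor_step_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_rotations(70)

    def test_lexicographic_order_and_uniqueness(self):
        rots = enumerate_rotations(120)
        tuples = [r.as_tuple() for r in rots]
        assert tuples == sorted(tuples)
        assert len(set(tuples)) == len(tuples)

    @given(st.sampled_from([10, 12, 15, 18, 20, 24, 30, 36, 40, 45, 60, 72,
                            90, 120, 180]))
    @settings(deadline=None, max_examples=15, derandomize=True)
    def test_count_formula_matches_enumeration(self, step):
        n = 360 // step - 1
        assert len(enumerate_rotations(step)) == n ** 3


class TestPlacement:
    def test_rigid_body_preserved(self, rocksalt, polar_diatomic):
        rot = Rotation(40, 80, 260)
        coords = place_adsorbate(polar_diatomic, rocksalt, (0.25, 0.5), rot)
        d0 = np.linalg.norm(polar_diatomic.positions[0] - polar_diatomic.positions[1])
        d1 = np.linalg.norm(coords[0] - coords[1])
        assert d1 == pytest.approx(d0, abs=1e-8)

    def test_com_lateral_equals_site(self, rocksalt, polar_diatomic):
        site = (0.3, 0.7)
        coords = place_adsorbate(polar_diatomic, rocksalt, site, Rotation(0, 0, 0))
        com = polar_diatomic.masses @ coords / polar_diatomic.masses.sum()
        expected = site[0] * rocksalt.lattice[0] + site[1] * rocksalt.lattice[1]
        np.testing.assert_allclose(com[:2], expected[:2], atol=1e-9)

    def test_rotation_periodicity(self, rocksalt, polar_diatomic):
        a = place_adsorbate(polar_diatomic, rocksalt, (0, 0), Rotation(20, 40, 60))
        b = place_adsorbate(polar_diatomic, rocksalt, (0, 0),
                            Rotation(380, 400, 420))
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_default_clearance_no_contact(self, rocksalt, polar_diatomic, model):
        for rot in enumerate_rotations(120):
            coords = place_adsorbate(polar_diatomic, rocksalt, (0.5, 0.5), rot)
            contacts = build_connectivity(rocksalt, coords,
                                          polar_diatomic.symbols, model.radii)
            assert not contacts


class TestConnectivity:
    def test_far_above_empty(self, rocksalt, polar_diatomic, radii):
        coords = polar_diatomic.positions + [0, 0, rocksalt.top_z() + 10.0]
        assert not build_connectivity(rocksalt, coords, polar_diatomic.symbols,
                                      radii)

    def test_h_above_o_contact(self, radii):
        # cutoff = 1.1 * (cov(H) + cov(O)); 0.5 Å is well inside
        slab = Slab(lattice=np.diag([8.0, 8.0, 25.0]), symbols=["O"],
                    positions=[[4.0, 4.0, 2.0]])
        detect_surface_atoms(slab, radii)
        cutoff = 1.1 * (radii.covalent("H") + radii.covalent("O"))
        assert 0.5 < cutoff
        contacts = build_connectivity(slab, np.array([[4.0, 4.0, 2.5]]), ["H"],
                                      radii)
        assert contacts == {(0, 0)}

    def test_only_surface_atoms_participate(self, rocksalt, radii):
        buried = np.flatnonzero(~rocksalt.surface_mask)
        # drop a probe right on top of a buried atom's column, below the slab
        probe = rocksalt.positions[buried[0]] + [0, 0, -0.5]
        contacts = build_connectivity(rocksalt, probe[None], ["O"], radii)
        assert all(rocksalt.surface_mask[s] for s, _ in contacts)

    def test_minimum_image_wraps_laterally(self, rocksalt, radii):
        # probe just outside the cell edge touches the atom at the origin
        a = rocksalt.lattice[0]
        probe = np.array([a[0] - 0.1, 0.0, 1.2])
        contacts = build_connectivity(rocksalt, probe[None], ["O"], radii)
        assert contacts
        # the only atoms within reach are images across the a boundary:
        # every contact partner sits at lateral (0, 0), > 5 Å away unwrapped
        for s, _ in contacts:
            np.testing.assert_allclose(rocksalt.positions[s][:2], [0.0, 0.0],
                                       atol=1e-9)


class TestApproach:
    def test_contact_pose_scored_and_rigid(self, rocksalt, polar_diatomic, model):
        pose = approach(rocksalt, polar_diatomic, (0.25, 0.25), Rotation(0, 0, 0),
                        model)
        assert pose.contact
        assert pose.energy is not None
        assert pose.contacts
        d0 = np.linalg.norm(polar_diatomic.positions[0] - polar_diatomic.positions[1])
        d1 = np.linalg.norm(pose.coords[0] - pose.coords[1])
        assert d1 == pytest.approx(d0, abs=1e-8)

    def test_stopping_height_within_one_step_of_fine_descent(
            self, rocksalt, polar_diatomic, model):
        # fine-grained descent as the oracle for the contact-onset height
        coarse = approach(rocksalt, polar_diatomic, (0.25, 0.25),
                          Rotation(0, 180, 0), model, step=0.5)
        fine = approach(rocksalt, polar_diatomic, (0.25, 0.25),
                        Rotation(0, 180, 0), model, step=0.01)
        z_coarse = coarse.coords[:, 2].min()
        z_fine = fine.coords[:, 2].min()
        assert coarse.contact and fine.contact
        # the fine descent stops at contact onset; the coarse one overshoots
        # below it by less than one coarse step
        assert z_fine >= z_coarse - 0.01 - 1e-9
        assert z_fine - z_coarse <= 0.5 + 1e-9

    def test_step_count_equals_height_quotient(self, rocksalt, polar_diatomic,
                                               model):
        pose = approach(rocksalt, polar_diatomic, (0.25, 0.25), Rotation(0, 0, 0),
                        model, step=0.5, clearance=4.0)
        start = place_adsorbate(polar_diatomic, rocksalt, (0.25, 0.25),
                                Rotation(0, 0, 0), clearance=4.0)
        drop = start[:, 2].min() - pose.coords[:, 2].min()
        assert pose.n_steps == pytest.approx(drop / 0.5)

    def test_no_contact_flagged(self, rocksalt, model):
        # neutral tiny adsorbate with connectivity scale ~0 never contacts
        ads = make_toy_adsorbate("neutral_diatomic")
        pose = approach(rocksalt, ads, (0.1, 0.1), Rotation(0, 0, 0), model,
                        connectivity_scale=1e-6)
        assert not pose.contact
        assert pose.energy is None


def serial_scan_oracle(slab, conformers, grid, rotations, model):
    """Exhaustive double-loop reference for scan_surface."""
    reps = []
    for i, site in enumerate(grid.sites):
        best = None
        for ads in sorted(conformers, key=lambda a: a.conformer_id):
            for rot in rotations:
                pose = approach(slab, ads, site, rot, model, site_index=i)
                if not pose.contact:
                    continue
                key = (pose.energy.e_a, pose.conformer_id, pose.rotation.as_tuple())
                if best is None or key < (best.energy.e_a, best.conformer_id,
                                          best.rotation.as_tuple()):
                    best = pose
        reps.append(best)
    return reps


class TestScan:
    def test_single_combination_is_representative(self, rocksalt, polar_diatomic,
                                                  model):
        grid = generate_grid(rocksalt, 3.0)
        rots = [Rotation(0, 0, 0)]
        reps = scan_surface(rocksalt, polar_diatomic, grid, rots, model)
        assert len(reps) == len(grid)
        for rep in reps:
            assert rep is None or rep.rotation == Rotation(0, 0, 0)

    def test_matches_serial_oracle(self, rocksalt, polar_diatomic, model):
        grid = generate_grid(rocksalt, 4.0)  # 2x2 sites
        rots = enumerate_rotations(90)  # 27 rotations
        reps = scan_surface(rocksalt, polar_diatomic, grid, rots, model)
        oracle = serial_scan_oracle(rocksalt, [polar_diatomic], grid, rots, model)
        assert len(reps) == len(oracle)
        for a, b in zip(reps, oracle):
            assert (a is None) == (b is None)
            if a is not None:
                assert a.rotation == b.rotation
                assert a.energy.e_a == b.energy.e_a
                np.testing.assert_array_equal(a.coords, b.coords)

    def test_worker_count_invariance(self, rocksalt, polar_diatomic, model):
        grid = generate_grid(rocksalt, 4.0)
        rots = enumerate_rotations(120)
        reps1 = scan_surface(rocksalt, polar_diatomic, grid, rots, model,
                             workers=1)
        reps4 = scan_surface(rocksalt, polar_diatomic, grid, rots, model,
                             workers=4)
        for a, b in zip(reps1, reps4):
            assert a.rotation == b.rotation
            assert a.energy.e_a == b.energy.e_a
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_uniform_monolayer_equal_energies(self, model):
        # flat square lattice of identical ions with the grid commensurate
        # to it: every site is related to every other by a lattice
        # translation of the ion sublattice, so all representatives share
        # one E_a
        pts = [[x, y, 3.0] for x in (0.0, 2.0) for y in (0.0, 2.0)]
        slab = Slab(lattice=np.diag([4.0, 4.0, 25.0]), symbols=["Na"] * 4,
                    positions=pts, formal_charges=[1.0] * 4)
        detect_surface_atoms(slab)
        ads = make_toy_adsorbate("polar_diatomic")
        grid = generate_grid(slab, 2.0)
        reps = scan_surface(slab, ads, grid, [Rotation(0, 0, 0)], model)
        energies = [r.energy.e_a for r in reps if r is not None]
        assert len(energies) == len(grid)
        assert max(energies) - min(energies) < 1e-9

    def test_atom_order_relabeling_invariance(self, rocksalt, model):
        from slabdock import Adsorbate

        ads = make_toy_adsorbate("polar_diatomic")
        flipped = Adsorbate(symbols=list(reversed(ads.symbols)),
                            positions=ads.positions[::-1].copy(),
                            partial_charges=ads.partial_charges[::-1].copy(),
                            net_charge=ads.net_charge,
                            conformer_id=ads.conformer_id)
        grid = generate_grid(rocksalt, 3.0)
        rots = enumerate_rotations(120)
        e0 = [r.energy.e_a for r in
              scan_surface(rocksalt, ads, grid, rots, model) if r]
        e1 = [r.energy.e_a for r in
              scan_surface(rocksalt, flipped, grid, rots, model) if r]
        np.testing.assert_allclose(e0, e1, atol=1e-9)
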