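"""Hydration shells, interface analysis, hydrogen bonds, salt bridges,
compressibility, bulk density, SASA — each against a brute-force oracle or
closed form."""
import numpy as np
import pytest

from pacsfe.hydration import (
    DataError,
    ModeError,
    hbond_counts,
    interface_residues,
    interface_water_counts,
    isothermal_compressibility,
    bulk_density,
    pair_distance_matrix,
    sasa,
    shell_volumes_mc,
    shell_water_counts,
    shell_water_counts_brute,
)
from pacsfe.structure import SelectionError, Structure, Trajectory


def build(names, elements, resnames, resids, chains, coords, box=None):
    return Structure(
        names=np.asarray(names), elements=np.asarray(elements),
        resnames=np.asarray(resnames), resids=np.asarray(resids),
        chains=np.asarray(chains), coords=np.asarray(coords, dtype=float),
        box=None if box is None else np.asarray(box, dtype=float),
    )


def solute_plus_waters(water_positions, solute_positions=((0.0, 0.0, 0.0),), box=None):
    ns, nw = len(solute_positions), len(water_positions)
    return build(
        names=["C"] * ns + ["O"] * nw,
        elements=["C"] * ns + ["O"] * nw,
        resnames=["BEA"] * ns + ["HOH"] * nw,
        resids=list(range(1, ns + 1)) + list(range(1, nw + 1)),
        chains=["A"] * ns + ["W"] * nw,
        coords=list(solute_positions) + list(water_positions),
        box=box,
    )


class TestShells:
    def test_forced_shell_membership(self):
        s = solute_plus_waters([[2.5, 0, 0], [4.0, 0, 0], [7.0, 0, 0]])
        sc = shell_water_counts(s, mc_samples=1000)
        assert (sc.n_first, sc.n_second) == (1, 1)

    def test_boundary_is_closed_on_the_right(self):
        s = solute_plus_waters([[3.0, 0, 0], [6.0, 0, 0]])
        sc = shell_water_counts(s, mc_samples=1000)
        assert sc.n_first == 1  # exactly 3.0 Å -> first shell
        assert sc.n_second == 1  # exactly 6.0 Å -> second shell

    def test_additivity_first_plus_second_is_within_six(self):
        rng = np.random.default_rng(0)
        waters = rng.uniform(0, 20, size=(300, 3))
        s = solute_plus_waters(waters, solute_positions=[[10, 10, 10], [12, 10, 10]])
        sc = shell_water_counts(s, mc_samples=1000)
        d = pair_distance_matrix(
            s.coords[s.water_oxygen_indices()],
            s.coords[s.select(water=False)], None,
        ).min(axis=1)
        assert sc.n_first + sc.n_second == int(np.count_nonzero(d <= 6.0))

    @pytest.mark.parametrize("seed", range(20))
    def test_kdtree_equals_brute_force(self, seed, random_solvated_factory):
        s = random_solvated_factory(seed)
        solute = np.flatnonzero(s.mask(water=False))
        sc = shell_water_counts(s, mc_samples=1000)
        assert (sc.n_first, sc.n_second) == shell_water_counts_brute(s, solute)

    def test_pbc_translation_invariance(self, random_solvated_factory):
        s = random_solvated_factory(3)
        sc0 = shell_water_counts(s, mc_samples=1000)
        shifted = s.subset(np.arange(s.n_atoms))
        shifted.coords = np.mod(s.coords + np.array([17.0, -9.0, 30.0]), s.box)
        sc1 = shell_water_counts(shifted, mc_samples=1000)
        assert (sc0.n_first, sc0.n_second) == (sc1.n_first, sc1.n_second)

    def test_mc_volume_of_isolated_shell_sphere(self):
        s = solute_plus_waters([], solute_positions=[[0, 0, 0]])
        v1, _, _ = shell_volumes_mc(s, np.array([0]), n_samples=200_000, seed=1)
        exact = 4.0 / 3.0 * np.pi * 3.0**3
        assert v1 == pytest.approx(exact, rel=0.02)

    def test_no_waters_warns_and_counts_zero(self):
        s = solute_plus_waters([])
        with pytest.warns(RuntimeWarning):
            sc = shell_water_counts(s, mc_samples=1000)
        assert (sc.n_first, sc.n_second) == (0, 0)


def two_chain_trajectory(frames_apart):
    """Chains A, B of two atoms each; each frame either in contact or 20 Å
    apart according to ``frames_apart`` flags."""
    top = build(
        names=["CA", "CB", "CA", "CB"],
        elements=["C", "C", "C", "C"],
        resnames=["ALA", "ALA", "GLY", "GLY"],
        resids=[1, 1, 2, 2],
        chains=["A", "A", "B", "B"],
        coords=np.zeros((4, 3)),
    )
    coords = []
    for apart in frames_apart:
        offset = 20.0 if apart else 4.0
        coords.append(
            [[0, 0, 0], [1.5, 0, 0], [offset, 0, 0], [offset + 1.5, 0, 0]]
        )
    return Trajectory(topology=top, coords=np.array(coords, dtype=float))


class TestInterface:
    def test_permanent_contact_included_with_full_occupancy(self):
        traj = two_chain_trajectory([False] * 4)
        iface = interface_residues(traj, window=np.arange(4))
        assert ("A", 1) in iface.residues and ("B", 2) in iface.residues
        assert iface.occupancy[("A", 1)] == 1.0

    def test_three_of_four_frames_below_threshold(self):
        traj = two_chain_trajectory([False, False, False, True])
        iface = interface_residues(traj, threshold=0.8, window=np.arange(4))
        assert iface.residues == set()
        assert iface.occupancy[("A", 1)] == pytest.approx(0.75)

    def test_scripted_contacts_match_brute_force(self):
        rng = np.random.default_rng(8)
        pattern = rng.random(10) < 0.5
        traj = two_chain_trajectory(pattern)
        window = np.arange(10)
        iface = interface_residues(traj, threshold=0.6, window=window)
        # brute-force occupancy
        frac = 1.0 - pattern.mean()
        expected = {("A", 1), ("B", 2)} if frac >= 0.6 else set()
        assert iface.residues == expected

    def test_missing_chain_raises(self):
        traj = two_chain_trajectory([False, False])
        with pytest.raises(SelectionError):
            interface_residues(traj, chain_a="X", window=np.arange(2))

    def test_interface_waters_reduce_to_shell_counts(self, random_solvated_factory):
        s = random_solvated_factory(5)
        all_residues = {
            (str(s.chains[i]), int(s.resids[i]))
            for i in np.flatnonzero(s.mask(water=False))
        }
        direct = shell_water_counts(s, mc_samples=1000)
        via_interface = interface_water_counts(s, all_residues, mc_samples=1000)
        assert (direct.n_first, direct.n_second) == (
            via_interface.n_first, via_interface.n_second,
        )

    def test_empty_interface_rejected(self, random_solvated_factory):
        with pytest.raises(SelectionError):
            interface_water_counts(random_solvated_factory(1), set())

    def test_scripted_interface_water_count(self):
        # 5 waters within 3 Å of the interface bead, 5 waters 40 Å away
        near = [[2.0 + 0.1 * i, 0, 0] for i in range(5)]
        far = [[40.0, 40.0, 40.0 + i] for i in range(5)]
        s = solute_plus_waters(near + far, solute_positions=[[0, 0, 0], [50, 0, 0]])
        iface = {("A", 1)}
        sc = interface_water_counts(s, iface, mc_samples=1000)
        assert sc.n_first == 5


def hbond_structure(atoms, box=None):
    """atoms: list of (name, element, resname, resid, chain, xyz)."""
    return build(
        names=[a[0] for a in atoms],
        elements=[a[1] for a in atoms],
        resnames=[a[2] for a in atoms],
        resids=[a[3] for a in atoms],
        chains=[a[4] for a in atoms],
        coords=[a[5] for a in atoms],
        box=box,
    )


class TestHBonds:
    def test_ideal_linear_bond_counts_once(self):
        s = hbond_structure([
            ("N", "N", "ALA", 1, "A", (0.0, 0, 0)),
            ("H", "H", "ALA", 1, "A", (1.0, 0, 0)),
            ("O", "O", "GLY", 2, "A", (2.9, 0, 0)),
        ])
        hb = hbond_counts(s)
        assert (hb.H_PP, hb.H_PW, hb.H_PWP) == (1, 0, 0)

    def test_distance_failure(self):
        s = hbond_structure([
            ("N", "N", "ALA", 1, "A", (0.0, 0, 0)),
            ("H", "H", "ALA", 1, "A", (1.0, 0, 0)),
            ("O", "O", "GLY", 2, "A", (3.8, 0, 0)),
        ])
        assert hbond_counts(s).H_PP == 0

    def test_bent_geometry_fails_angle(self):
        s = hbond_structure([
            ("N", "N", "ALA", 1, "A", (0.0, 0, 0)),
            ("H", "H", "ALA", 1, "A", (0.0, 1.0, 0)),  # 90° D-H···A
            ("O", "O", "GLY", 2, "A", (3.0, 0, 0)),
        ])
        assert hbond_counts(s).H_PP == 0

    def test_water_bridge_between_chains(self):
        # water donates to chain A and chain B: H_PW = 2, H_PWP = 1
        s = hbond_structure([
            ("O", "O", "ALA", 1, "A", (0.0, 0, 0)),
            ("O", "O", "GLY", 1, "B", (5.6, 0, 0)),
            ("O", "O", "HOH", 1, "W", (2.8, 0, 0)),
            ("H1", "H", "HOH", 1, "W", (1.9, 0, 0)),
            ("H2", "H", "HOH", 1, "W", (3.7, 0, 0)),
        ])
        hb = hbond_counts(s)
        assert hb.H_PW == 2
        assert hb.H_PWP == 1
        assert hb.H_PP == 0

    def test_angle_mode_without_hydrogens_rejected(self):
        s = hbond_structure([
            ("O", "O", "ALA", 1, "A", (0.0, 0, 0)),
            ("O", "O", "GLY", 2, "A", (3.0, 0, 0)),
        ])
        with pytest.raises(ModeError):
            hbond_counts(s, mode="angle")

    @pytest.mark.parametrize("seed", range(20))
    def test_distance_mode_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_prot, n_wat = 15, 10
        atoms = []
        for i in range(n_prot):
            atoms.append(
                ("O" if i % 2 else "N", "O" if i % 2 else "N", "ALA", i + 1,
                 "A" if i < 8 else "B", tuple(rng.uniform(0, 12, 3)))
            )
        for i in range(n_wat):
            atoms.append(("O", "O", "HOH", i + 1, "W", tuple(rng.uniform(0, 12, 3))))
        s = hbond_structure(atoms)
        hb = hbond_counts(s, mode="distance")
        # brute force over all pairs
        coords = s.coords
        water = s.mask(water=True)
        pp = pw = 0
        partners = {}
        for i in range(s.n_atoms):
            for j in range(i + 1, s.n_atoms):
                if s.chains[i] == s.chains[j] and s.resids[i] == s.resids[j]:
                    continue
                if np.linalg.norm(coords[i] - coords[j]) > 3.5:
                    continue
                if water[i] and water[j]:
                    continue
                if not water[i] and not water[j]:
                    pp += 1
                else:
                    pw += 1
                    w, p = (i, j) if water[i] else (j, i)
                    partners.setdefault(w, set()).add(str(s.chains[p]))
        pwp = sum(1 for tags in partners.values() if len(tags) >= 2)
        assert (hb.H_PP, hb.H_PW, hb.H_PWP) == (pp, pw, pwp)


class TestSaltBridge:
    def lys_asp_trajectory(self, distances):
        top = build(
            names=["NZ", "OD1", "OD2"],
            elements=["N", "O", "O"],
            resnames=["LYS", "ASP", "ASP"],
            resids=[119, 12, 12],
            chains=["A", "B", "B"],
            coords=np.zeros((3, 3)),
        )
        coords = [
            [[0, 0, 0], [d, 0, 0], [d + 0.5, 0, 0]] for d in distances
        ]
        return Trajectory(topology=top, coords=np.array(coords, dtype=float))

    def test_always_formed(self):
        from pacsfe.hydration import salt_bridge_occupancy

        traj = self.lys_asp_trajectory([3.0] * 5)
        assert salt_bridge_occupancy(traj, ("A", 119), ("B", 12)) == 1.0

    def test_alternating_half_occupancy(self):
        from pacsfe.hydration import salt_bridge_occupancy

        traj = self.lys_asp_trajectory([3.0, 5.0] * 5)
        assert salt_bridge_occupancy(traj, ("A", 119), ("B", 12)) == 0.5

    def test_breakage_at_frame_90_of_100(self):
        from pacsfe.hydration import salt_bridge_occupancy

        traj = self.lys_asp_trajectory([3.0] * 90 + [8.0] * 10)
        assert salt_bridge_occupancy(traj, ("A", 119), ("B", 12)) == pytest.approx(0.90)

    def test_missing_residue_raises(self):
        from pacsfe.hydration import salt_bridge_occupancy

        traj = self.lys_asp_trajectory([3.0])
        with pytest.raises(SelectionError):
            salt_bridge_occupancy(traj, ("A", 1), ("B", 12))


class TestCompressibility:
    def test_constant_volume_is_incompressible(self):
        res = isothermal_compressibility(np.full(100, 1234.5), reduced=True)
        assert res.kappa_T == 0.0

    def test_alternating_volumes_reduced_units(self):
        v = np.array([999.0, 1001.0] * 50)
        res = isothermal_compressibility(v, reduced=True, window=np.arange(100))
        assert res.kappa_T == pytest.approx(1.0 / 1000.0)

    def test_gaussian_volumes_recover_sigma2_over_mu(self):
        rng = np.random.default_rng(12)
        mu, sigma = 27000.0, 60.0
        v = rng.normal(mu, sigma, size=100_000)
        res = isothermal_compressibility(v, reduced=True)
        assert res.kappa_T == pytest.approx(sigma**2 / mu, rel=0.03)

    def test_window_defaults_to_last_half(self):
        v = np.concatenate([np.full(50, 5000.0), np.full(50, 1000.0)])
        res = isothermal_compressibility(v, reduced=True)
        assert res.mean_volume == 1000.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(DataError):
            isothermal_compressibility(np.array([1.0, -2.0, 3.0]), reduced=True)

    def test_real_units_scale(self):
        # var=1 Å⁶, mean=1000 Å³, T=300 K in 1/MPa
        v = np.array([999.0, 1001.0] * 50)
        res = isothermal_compressibility(v, temperature=300.0, window=np.arange(100))
        expected = 1.0 * 1e-30 / (1.380649e-23 * 300.0 * 1000.0) * 1e6
        assert res.kappa_T == pytest.approx(expected, rel=1e-9)


class TestBulkDensity:
    def test_fixed_box_and_count(self):
        # 1000 waters in a 10^5 Å³ box -> 10^-2 Å^-3
        box = np.tile([10.0, 100.0, 100.0], (4, 1))
        assert bulk_density(box, 1000, window=np.arange(4)) == pytest.approx(1e-2)

    def test_single_frame_window(self):
        boxes = np.array([[10.0, 10, 10], [20.0, 20, 20]])
        assert bulk_density(boxes, 100, window=np.array([1])) == pytest.approx(
            100 / 8000.0
        )

    def test_fluctuating_series_mean(self):
        rng = np.random.default_rng(1)
        boxes = rng.uniform(20, 22, size=(10, 3))
        counts = np.full(10, 300)
        w = np.arange(10)
        expected = np.mean(300 / boxes.prod(axis=1))
        assert bulk_density(boxes, counts, window=w) == pytest.approx(expected)


class TestSasa:
    def single_atom(self, element="O"):
        return build(
            names=[element], elements=[element], resnames=["UNK"], resids=[1],
            chains=["A"], coords=[[0.0, 0.0, 0.0]],
        )

    def test_isolated_atom_closed_form(self):
        total, _ = sasa(self.single_atom("C"), probe_radius=1.4)
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert total == pytest.approx(exact, rel=0.01)

    def test_fully_overlapping_atoms_count_once(self):
        s = build(
            names=["C", "C"], elements=["C", "C"], resnames=["UNK"] * 2,
            resids=[1, 2], chains=["A", "A"],
            coords=[[0, 0, 0], [0, 0, 0.0]],
        )
        total, _ = sasa(s)
        one, _ = sasa(self.single_atom("C"))
        assert total == pytest.approx(one, rel=1e-9)

    def test_distant_atoms_are_additive(self):
        s = build(
            names=["C", "O"], elements=["C", "O"], resnames=["UNK"] * 2,
            resids=[1, 2], chains=["A", "A"],
            coords=[[0, 0, 0], [50.0, 0, 0]],
        )
        total, _ = sasa(s)
        a, _ = sasa(self.single_atom("C"))
        b, _ = sasa(self.single_atom("O"))
        assert total == pytest.approx(a + b, rel=1e-9)

    def test_unknown_element_requires_override(self):
        s = build(
            names=["XX"], elements=["XX"], resnames=["UNK"], resids=[1],
            chains=["A"], coords=[[0, 0, 0]],
        )
        with pytest.raises(KeyError):
            sasa(s)
        total, _ = sasa(s, radii_overrides={"XX": 2.0})
        assert total == pytest.approx(4 * np.pi * 3.4**2, rel=0.01)

    def test_cross_check_against_independent_implementation(self):
        import biotite.structure as bst

        from pacsfe.hydration import VDW_RADII

        rng = np.random.default_rng(0)
        n = 20
        coords = rng.normal(size=(n, 3)) * 4
        elements = rng.choice(["C", "N", "O"], n)
        s = build(
            names=elements, elements=elements, resnames=["ALA"] * n,
            resids=np.arange(1, n + 1), chains=["A"] * n, coords=coords,
        )
        total, _ = sasa(s, n_points=960)
        arr = bst.AtomArray(n)
        arr.coord = coords.astype(np.float32)
        arr.element = elements
        arr.atom_name = elements
        arr.res_name = np.full(n, "ALA")
        arr.res_id = np.arange(1, n + 1)
        arr.chain_id = np.full(n, "A")
        radii = np.array([VDW_RADII[e] for e in elements])
        ref = float(bst.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii=radii).sum())
        assert total == pytest.approx(ref, rel=0.02)
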