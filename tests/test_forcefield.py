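import numpy as np
import pytest

import translodyn as td
from translodyn import forcefield as ff
from conftest import make_chain


def brute_force_energy(topo, coords):
    """Independent term-by-term re-implementation of the potential."""
    e = dict(bond=0.0, angle=0.0, dihedral=0.0, contact=0.0, repulsion=0.0)
    for (i, j), r0, k in zip(topo.bonds, topo.bond_r0, topo.k_bond):
        r = np.linalg.norm(coords[i] - coords[j])
        e["bond"] += k * (r - r0) ** 2
    for (a, b, c), t0, k in zip(topo.angles, topo.angle_theta0, topo.k_angle):
        u, v = coords[a] - coords[b], coords[c] - coords[b]
        th = np.arccos(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)),
                               -1, 1))
        e["angle"] += k * (th - t0) ** 2
    for (i, j, k_, l), p0, kd in zip(topo.dihedrals, topo.dihedral_phi0,
                                     topo.k_dihedral):
        b1, b2, b3 = (coords[j] - coords[i], coords[k_] - coords[j],
                      coords[l] - coords[k_])
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m = np.cross(n1, b2 / np.linalg.norm(b2))
        phi = np.arctan2(m @ n2, n1 @ n2)
        d = phi - p0
        e["dihedral"] += kd * ((1 - np.cos(d)) + 0.5 * (1 - np.cos(3 * d)))
    cm = topo.contacts
    for i, j, r0, w in zip(cm.i, cm.j, cm.r0, cm.weight):
        r = np.linalg.norm(coords[i] - coords[j])
        e["contact"] += w * ((r0 / r) ** 12 - 2 * (r0 / r) ** 6)
    dead = set(topo.exclusions) | set(topo.steric_deletions)
    rc = topo.sigma_ex
    for i in range(topo.n_atoms):
        for j in range(i + 1, topo.n_atoms):
            if (i, j) in dead:
                continue
            r = np.linalg.norm(coords[i] - coords[j])
            if r < rc:
                e["repulsion"] += topo.eps_ex * (
                    (rc / r) ** 12 - 1 + 12 * (r - rc) / rc)
    return e


def two_atom_structure(distance, chains=("A", "B"), names=("P", "P")):
    return td.Structure(
        atom_names=np.array(list(names), dtype=object),
        elements=np.array(["P", "P"], dtype=object),
        res_ids=np.array([1, 1]),
        res_names=np.array(["G", "G"], dtype=object),
        chain_ids=np.array(list(chains), dtype=object),
        coords=np.array([[0.0, 0, 0], [distance, 0, 0]]))


class TestContactMap:
    @pytest.mark.parametrize("cutoff,expected", [(4.0, 1), (3.5, 0)])
    def test_interchain_pair_cutoff(self, cutoff, expected):
        s = two_atom_structure(3.9)
        cmap = td.compute_contact_map(s, cutoff=cutoff)
        assert cmap.n_contacts == expected
        if expected:
            assert cmap.r0[0] == pytest.approx(3.9)

    def test_matches_all_pairs_enumeration(self):
        rng = np.random.default_rng(7)
        n = 20
        s = td.Structure(
            atom_names=np.array(["P"] * n, dtype=object),
            elements=np.array(["P"] * n, dtype=object),
            res_ids=np.arange(1, n + 1),
            res_names=np.array(["G"] * n, dtype=object),
            chain_ids=np.array(["A"] * 10 + ["B"] * 10, dtype=object),
            coords=rng.uniform(0, 10, (n, 3)))
        cmap = td.compute_contact_map(s, cutoff=4.0, min_seq_sep=4)
        brute = set()
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(s.coords[i] - s.coords[j])
                same = s.chain_ids[i] == s.chain_ids[j]
                if d <= 4.0 and (not same or abs(int(s.res_ids[i]) - int(s.res_ids[j])) >= 4):
                    brute.add((i, j))
        assert set(zip(cmap.i, cmap.j)) == brute

    def test_single_residue_warns_empty(self):
        s = two_atom_structure(3.0, chains=("A", "A"), names=("P", "O"))
        with pytest.warns(UserWarning, match="fewer than 2 residues"):
            cmap = td.compute_contact_map(s)
        assert cmap.n_contacts == 0


class TestSingleBasin:
    def test_linear_chain_bonded_terms(self):
        chain = make_chain(n=4, seed=1)
        topo = td.build_single_basin(chain)
        assert len(topo.bonds) == 3
        assert len(topo.angles) == 2
        assert len(topo.dihedrals) == 1

    def test_native_is_minimum_of_construction(self, toy_chain):
        chain, topo = toy_chain
        eb = td.potential_energy(topo, chain.coords)
        assert eb.bond == eb.angle == eb.dihedral == 0.0
        assert eb.contact == pytest.approx(-topo.contacts.weight.sum())
        assert eb.repulsion == 0.0

    def test_native_gradient_vanishes(self, toy_chain):
        chain, topo = toy_chain
        f = td.forces(topo, chain.coords)
        assert np.linalg.norm(f, axis=1).max() < 1e-6
        # finite-difference oracle on the same configuration
        h = 1e-6
        for atom, axis in [(0, 0), (3, 1), (9, 2)]:
            xp = chain.coords.copy()
            xp[atom, axis] += h
            xm = chain.coords.copy()
            xm[atom, axis] -= h
            fd = -(td.potential_energy(topo, xp).total
                   - td.potential_energy(topo, xm).total) / (2 * h)
            assert fd == pytest.approx(0.0, abs=1e-5)

    def test_native_energy_below_random_perturbations(self, toy_chain):
        chain, topo = toy_chain
        e0 = td.potential_energy(topo, chain.coords).total
        rng = np.random.default_rng(11)
        for _ in range(100):
            pert = chain.coords + rng.uniform(-0.2, 0.2, chain.coords.shape)
            assert td.potential_energy(topo, pert).total >= e0

    def test_multi_atom_residue_rejected(self):
        s = two_atom_structure(3.0, chains=("A", "A"), names=("P", "O"))
        with pytest.raises(ff.ForcefieldError, match="residue 1 of chain A"):
            td.build_single_basin(s)


class TestMergeBasins:
    def test_cross_group_rescale_applies_to_exactly_cross_pairs(self, toy_chain):
        chain, topo = toy_chain
        extra = ff.ContactMap(np.array([0, 1]), np.array([8, 9]),
                              np.array([5.0, 5.0]), np.array([1.0, 1.0]),
                              np.array(["second", "second"], dtype=object))
        groups = {"ribosome": td.AtomGroup("ribosome", np.arange(0, 5)),
                  "mrna_trna": td.AtomGroup("mrna_trna", np.arange(5, 10))}
        rules = [td.ScaleRule("ribosome", "mrna_trna", 0.3)]
        merged = td.merge_basins(topo, extra, rules, groups)
        in_a = np.zeros(10, bool)
        in_a[:5] = True
        cross = ((in_a[merged.contacts.i] & ~in_a[merged.contacts.j])
                 | (~in_a[merged.contacts.i] & in_a[merged.contacts.j]))
        base_w = np.concatenate([topo.contacts.weight, [1.0, 1.0]])
        np.testing.assert_allclose(merged.contacts.weight[cross],
                                   base_w[cross] * 0.3)
        np.testing.assert_allclose(merged.contacts.weight[~cross],
                                   base_w[~cross])

    def test_empty_extra_map_is_identity(self, toy_chain):
        _, topo = toy_chain
        assert td.merge_basins(topo, ff.ContactMap.empty()) is topo

    def test_union_counts_and_basin_a_preserved(self, toy_chain):
        _, topo = toy_chain
        cm = topo.contacts
        # 2 overlapping + 3 disjoint second-basin contacts
        ov_i, ov_j = cm.i[:2], cm.j[:2]
        extra = ff.ContactMap(
            np.concatenate([ov_i, [0, 0, 1]]),
            np.concatenate([ov_j, [7, 9, 8]]),
            np.full(5, 4.4), np.full(5, 1.0),
            np.full(5, "second", dtype=object))
        merged = td.merge_basins(topo, extra)
        assert merged.contacts.n_contacts == cm.n_contacts + 5
        keys = set(zip(merged.contacts.i, merged.contacts.j,
                       merged.contacts.basin))
        brute = (set(zip(cm.i, cm.j, cm.basin))
                 | set(zip(extra.i, extra.j, extra.basin)))
        assert keys == brute
        a_mask = merged.contacts.basin != "second"
        np.testing.assert_array_equal(merged.contacts.i[a_mask], cm.i)
        np.testing.assert_array_equal(merged.contacts.r0[a_mask], cm.r0)

    def test_rule_with_undefined_group_raises(self, toy_chain):
        _, topo = toy_chain
        extra = ff.ContactMap(np.array([0]), np.array([9]), np.array([5.0]),
                              np.array([1.0]), np.array(["b"], dtype=object))
        with pytest.raises(ff.ForcefieldError, match="undefined group"):
            td.merge_basins(topo, extra, [td.ScaleRule("nope", "nope2", 0.3)],
                            groups={})


class TestStericPerturbation:
    @pytest.fixture()
    def clash_system(self, mini):
        structure, _, groups = mini
        topo = ff.Topology(
            n_atoms=structure.n_atoms,
            bonds=np.empty((0, 2), int), bond_r0=np.array([]),
            k_bond=np.array([]), angles=np.empty((0, 3), int),
            angle_theta0=np.array([]), k_angle=np.array([]),
            dihedrals=np.empty((0, 4), int), dihedral_phi0=np.array([]),
            k_dihedral=np.array([]), contacts=ff.ContactMap.empty(),
            sigma_ex=2.5, eps_ex=0.01, exclusions=frozenset())
        # clash pose: P-tRNA dragged onto S13 and the PE loop
        coords = structure.coords.copy()
        s13_center = coords[groups["s13"].members].mean(axis=0)
        trna = groups["trna_p"].members
        coords[trna] += s13_center - coords[trna].mean(axis=0)
        return structure, groups, topo, coords

    def test_removal_drops_repulsion_for_cross_pairs_only(self, clash_system):
        structure, groups, topo, coords = clash_system
        model2 = td.remove_steric_pairs(topo, groups["s13"], groups["trna_p"])
        e1 = td.potential_energy(topo, coords)
        e2 = td.potential_energy(model2, coords)
        brute = brute_force_energy(topo, coords)
        removed = brute["repulsion"] - brute_force_energy(model2, coords)["repulsion"]
        assert removed > 0
        assert e1.repulsion - e2.repulsion == pytest.approx(removed)

    def test_idempotent(self, clash_system):
        _, groups, topo, coords = clash_system
        once = td.remove_steric_pairs(topo, groups["s13"], groups["trna_p"])
        twice = td.remove_steric_pairs(once, groups["s13"], groups["trna_p"])
        assert once.steric_deletions == twice.steric_deletions
        assert (td.potential_energy(once, coords).total
                == td.potential_energy(twice, coords).total)

    def test_model4_composition_matches_term_subtraction(self, clash_system):
        structure, groups, topo, coords = clash_system
        # drag the A-tRNA onto the PE loop as well
        pe_center = structure.coords[groups["pe_loop"].members].mean(axis=0)
        trna_a = groups["trna_a"].members
        coords = coords.copy()
        coords[trna_a] += pe_center - coords[trna_a].mean(axis=0)
        model4 = td.remove_steric_pairs(
            td.remove_steric_pairs(topo, groups["s13"], groups["trna_p"]),
            groups["pe_loop"], groups["trna_p"])
        model4 = td.remove_steric_pairs(model4, groups["s13"], groups["trna_a"])
        model4 = td.remove_steric_pairs(model4, groups["pe_loop"], groups["trna_a"])
        e1 = brute_force_energy(topo, coords)
        e4 = td.potential_energy(model4, coords)
        # brute-force sum of deleted repulsion terms
        deleted = 0.0
        rc = topo.sigma_ex
        for pair_set in [(groups["s13"], groups["trna_p"]),
                         (groups["pe_loop"], groups["trna_p"]),
                         (groups["s13"], groups["trna_a"]),
                         (groups["pe_loop"], groups["trna_a"])]:
            for a in pair_set[0].members:
                for b in pair_set[1].members:
                    r = np.linalg.norm(coords[a] - coords[b])
                    if r < rc:
                        deleted += topo.eps_ex * ((rc / r) ** 12 - 1
                                                  + 12 * (r - rc) / rc)
        assert e4.repulsion == pytest.approx(e1["repulsion"] - deleted)

    def test_overlapping_groups_rejected(self, clash_system):
        _, groups, topo, _ = clash_system
        with pytest.raises(ff.ForcefieldError, match="overlap"):
            td.remove_steric_pairs(topo, groups["head"], groups["s13"])

    def test_perturbation_locality(self, mini, clash_system):
        structure, groups, topo, _ = clash_system
        model2 = td.remove_steric_pairs(topo, groups["s13"], groups["trna_p"])
        # native pose: no deleted pair within repulsive range -> same energy
        e_base = td.potential_energy(topo, structure.coords).total
        e_pert = td.potential_energy(model2, structure.coords).total
        dmin = min(np.linalg.norm(structure.coords[a] - structure.coords[b])
                   for a in groups["s13"].members
                   for b in groups["trna_p"].members)
        assert dmin > topo.sigma_ex
        assert e_base == e_pert


class TestPotentialEnergy:
    def test_contact_at_native_distance(self):
        topo = ff.Topology(
            n_atoms=2, bonds=np.empty((0, 2), int), bond_r0=np.array([]),
            k_bond=np.array([]), angles=np.empty((0, 3), int),
            angle_theta0=np.array([]), k_angle=np.array([]),
            dihedrals=np.empty((0, 4), int), dihedral_phi0=np.array([]),
            k_dihedral=np.array([]),
            contacts=ff.ContactMap(np.array([0]), np.array([1]),
                                   np.array([4.0]), np.array([1.0]),
                                   np.array(["a"], dtype=object)),
            sigma_ex=2.5, eps_ex=0.01, exclusions=frozenset({(0, 1)}))
        eb = td.potential_energy(topo, np.array([[0.0, 0, 0], [4.0, 0, 0]]))
        assert eb.contact == pytest.approx(-1.0)
        assert eb.total == pytest.approx(-1.0)

    def test_stretched_bond_harmonic(self):
        k, r0, delta = 100.0, 1.5, 0.21
        topo = ff.Topology(
            n_atoms=2, bonds=np.array([[0, 1]]), bond_r0=np.array([r0]),
            k_bond=np.array([k]), angles=np.empty((0, 3), int),
            angle_theta0=np.array([]), k_angle=np.array([]),
            dihedrals=np.empty((0, 4), int), dihedral_phi0=np.array([]),
            k_dihedral=np.array([]), contacts=ff.ContactMap.empty(),
            sigma_ex=2.5, eps_ex=0.01, exclusions=frozenset({(0, 1)}))
        eb = td.potential_energy(topo, np.array([[0.0, 0, 0], [r0 + delta, 0, 0]]))
        assert eb.bond == pytest.approx(k * delta**2)

    def test_total_matches_brute_force(self, toy_chain):
        chain, topo = toy_chain
        rng = np.random.default_rng(5)
        coords = chain.coords + rng.normal(0, 0.15, chain.coords.shape)
        eb = td.potential_energy(topo, coords)
        brute = brute_force_energy(topo, coords)
        for term in ("bond", "angle", "dihedral", "contact", "repulsion"):
            assert getattr(eb, term) == pytest.approx(brute[term]), term
        assert eb.total == pytest.approx(sum(brute.values()))

    def test_forces_match_finite_differences(self, toy_chain):
        chain, topo = toy_chain
        rng = np.random.default_rng(6)
        coords = chain.coords + rng.normal(0, 0.1, chain.coords.shape)
        f = td.forces(topo, coords)
        h = 1e-6
        fd = np.zeros_like(coords)
        for i in range(len(coords)):
            for ax in range(3):
                xp = coords.copy()
                xp[i, ax] += h
                xm = coords.copy()
                xm[i, ax] -= h
                fd[i, ax] = -(td.potential_energy(topo, xp).total
                              - td.potential_energy(topo, xm).total) / (2 * h)
        np.testing.assert_allclose(f, fd, atol=5e-6 * max(1, np.abs(f).max()))

    def test_coordinate_count_mismatch(self, toy_chain):
        _, topo = toy_chain
        with pytest.raises(ff.ForcefieldError, match="shape"):
            td.potential_energy(topo, np.zeros((3, 3)))

    def test_energies_finite_for_noncoincident_coords(self, toy_chain):
        chain, topo = toy_chain
        rng = np.random.default_rng(8)
        for _ in range(20):
            coords = rng.uniform(-20, 20, chain.coords.shape)
            assert np.isfinite(td.potential_energy(topo, coords).total)


def test_topology_json_roundtrip(toy_chain):
    _, topo = toy_chain
    import json
    data = json.loads(json.dumps(ff.topology_to_json(topo)))
    back = ff.topology_from_json(data)
    rng = np.random.default_rng(4)
    coords = rng.normal(0, 3, (topo.n_atoms, 3))
    assert (td.potential_energy(back, coords).total
            == pytest.approx(td.potential_energy(topo, coords).total))
    assert back.exclusions == topo.exclusions
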