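"""Combinatorial fragment generation against a brute-force oracle."""

import pytest

from fragrank import (
    BDETable,
    bond_energy,
    fragment_formula,
    fragment_mass,
    generate_fragments,
    molecular_formula,
    parse_structure,
)


def brute_force_states(structure, depth, bond_costs=None):
    """Independent oracle: all (atom set, bond set) states reachable by
    removing up to ``depth`` bonds one at a time, each mapped to the
    cheapest cumulative removal cost over all orders.  Plain set recursion,
    no bitsets, no deduplication shortcuts."""
    atoms = frozenset(range(structure.n_atoms))
    bonds = {i: (b.i, b.j) for i, b in enumerate(structure.bonds)}
    if bond_costs is None:
        bond_costs = {i: 1.0 for i in bonds}

    def components(atom_set, bond_map):
        unseen = set(atom_set)
        comps = []
        while unseen:
            start = unseen.pop()
            comp = {start}
            grew = True
            while grew:
                grew = False
                for bi, (x, y) in bond_map.items():
                    if x in comp and y not in comp and y in atom_set:
                        comp.add(y)
                        grew = True
                    elif y in comp and x not in comp and x in atom_set:
                        comp.add(x)
                        grew = True
            unseen -= comp
            comps.append(frozenset(comp))
        return comps

    best = {}

    def visit(atom_set, bond_ids, cost, d):
        in_bonds = frozenset(
            bi for bi in bond_ids if {bonds[bi][0], bonds[bi][1]} <= atom_set
        )
        key = (atom_set, in_bonds)
        if key not in best or cost < best[key]:
            best[key] = cost
        if d == depth:
            return
        for bi in in_bonds:
            remaining = in_bonds - {bi}
            bmap = {k: bonds[k] for k in remaining}
            for comp in components(atom_set, bmap):
                visit(comp, remaining, cost + bond_costs[bi], d + 1)

    visit(atoms, frozenset(bonds), 0, 0)
    return best


class TestBondEnergy:
    def test_shipped_cc_single(self, bde_table):
        assert bond_energy(bde_table, "C", "C", 1) == 348.0

    def test_symmetric_in_elements(self, bde_table):
        assert bond_energy(bde_table, "N", "C", 1) == bond_energy(
            bde_table, "C", "N", 1
        )

    def test_unknown_pair_falls_back(self, bde_table):
        assert bond_energy(bde_table, "Xe", "C", 1) == bde_table.fallback_energy

    def test_aromatic_is_mean_of_single_and_double(self, bde_table):
        assert bond_energy(bde_table, "C", "C", 1.5) == pytest.approx(
            (348 + 614) / 2
        )

    def test_table_text_round_trip(self):
        t = BDETable.from_text("C C 1 100\nC O ar 200\n# comment\n", 50.0)
        assert t.bond_energy("C", "C", 1) == 100
        assert t.bond_energy("O", "C", 1.5) == 200
        assert t.bond_energy("C", "C", 3) == 50.0


class TestGenerateFragments:
    def test_depth_zero_is_parent_only(self, benzene, bde_table):
        frags = generate_fragments(benzene, 0, bde_table)
        assert len(frags) == 1
        assert frags[0].cleaved_bde == 0.0
        assert frags[0].depth == 0

    def test_propane_depth_one(self, propane, bde_table):
        frags = generate_fragments(propane, 1, bde_table)
        parent_bits = (1 << 3) - 1
        proper = [f for f in frags if f.atom_bits != parent_bits]
        assert len(proper) == 4  # two 1-atom + two 2-atom pieces
        sizes = sorted(bin(f.atom_bits).count("1") for f in proper)
        assert sizes == [1, 1, 2, 2]

    def test_benzene_depth_two_arcs(self, benzene, bde_table):
        frags = generate_fragments(benzene, 2, bde_table)
        parent_bits = (1 << 6) - 1
        reduced_sets = {f.atom_bits for f in frags if f.atom_bits != parent_bits}
        assert len(reduced_sets) == 30  # contiguous arcs: 6 starts x 5 lengths

    def test_disconnected_input_rejected(self, bde_table):
        salt = parse_structure("CC(=O)[O-].[Na+]")
        with pytest.raises(ValueError):
            generate_fragments(salt, 1, bde_table)

    @pytest.mark.parametrize(
        "smiles",
        [
            "CCC",
            "CCO",
            "CC(C)O",
            "c1ccccc1",
            "CC(=O)O",
            "NCC(=O)O",
            "C1CCC1",
            "CC(N)C(=O)O",
            "Oc1ccccc1",
        ],
    )
    @pytest.mark.parametrize("depth", [1, 2])
    def test_equals_brute_force_oracle(self, smiles, depth, bde_table):
        s = parse_structure(smiles)
        frags = generate_fragments(s, depth, bde_table)
        got = {(f.atom_bits, f.bond_bits) for f in frags}
        expected = set()
        for atom_set, bond_set in brute_force_states(s, depth):
            a_bits = sum(1 << a for a in atom_set)
            b_bits = sum(1 << b for b in bond_set)
            expected.add((a_bits, b_bits))
        assert got == expected

    @pytest.mark.parametrize("smiles", ["CC(C)O", "c1ccncc1", "NCC(=O)O"])
    def test_monotone_growth_with_depth(self, smiles, bde_table):
        s = parse_structure(smiles)
        prev = set()
        for depth in range(3):
            cur = {
                (f.atom_bits, f.bond_bits)
                for f in generate_fragments(s, depth, bde_table)
            }
            assert prev <= cur
            prev = cur

    @pytest.mark.parametrize("smiles", ["NCC(=O)O", "CC(C)O", "C1CCC1C"])
    def test_duplicates_keep_minimal_bde(self, smiles, bde_table):
        # states reachable by several removal orders must carry the
        # cheapest cumulative energy over all orders (oracle comparison)
        s = parse_structure(smiles)
        bond_cost = {
            i: bde_table.bond_energy(s.atoms[b.i].symbol, s.atoms[b.j].symbol, b.order)
            for i, b in enumerate(s.bonds)
        }
        oracle = brute_force_states(s, 2, bond_cost)
        for f in generate_fragments(s, 2, bde_table):
            atom_set = frozenset(f.atom_indices())
            bond_set = frozenset(f.bond_indices())
            assert f.cleaved_bde == pytest.approx(
                oracle[(atom_set, bond_set)], abs=1e-9
            )

    def test_deterministic_order(self, propane, bde_table):
        a = generate_fragments(propane, 2, bde_table)
        b = generate_fragments(propane, 2, bde_table)
        assert a == b


class TestFragmentMass:
    def test_parent_fragment_mass_equals_parent(self, propane, bde_table):
        frags = generate_fragments(propane, 1, bde_table)
        parent = max(frags, key=lambda f: f.atom_bits)
        from fragrank import monoisotopic_mass

        assert fragment_mass(parent, propane) == pytest.approx(
            monoisotopic_mass(molecular_formula(propane)), abs=1e-12
        )

    def test_methyl_fragment_hand_sum(self, propane, bde_table):
        frags = generate_fragments(propane, 1, bde_table)
        singles = [f for f in frags if bin(f.atom_bits).count("1") == 1]
        # terminal carbons of the propane skeleton keep their 3 hydrogens
        masses = sorted(fragment_mass(f, propane) for f in singles)
        assert masses[0] == pytest.approx(12 + 3 * 1.0078250319, abs=1e-9)

    def test_complementary_fragments_sum_to_parent(self, bde_table):
        s = parse_structure("CCOC(C)=O")  # ethyl acetate skeleton
        frags = generate_fragments(s, 1, bde_table)
        parent_bits = (1 << s.n_atoms) - 1
        parent_mass = fragment_mass(
            [f for f in frags if f.atom_bits == parent_bits][0], s
        )
        by_depth1 = [f for f in frags if f.depth == 1 and f.atom_bits != parent_bits]
        for f in by_depth1:
            comp_bits = parent_bits ^ f.atom_bits
            partners = [g for g in by_depth1 if g.atom_bits == comp_bits]
            assert partners, "acyclic cleavage must produce the complement"
            assert fragment_mass(f, s) + fragment_mass(partners[0], s) == (
                pytest.approx(parent_mass, abs=1e-9)
            )

    def test_fragment_formula_subformula_of_parent(self, bde_table):
        s = parse_structure("CC(N)C(=O)O")
        parent = molecular_formula(s).as_dict()
        for f in generate_fragments(s, 2, bde_table):
            sub = fragment_formula(f, s).as_dict()
            assert all(sub[el] <= parent.get(el, 0) for el in sub)
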