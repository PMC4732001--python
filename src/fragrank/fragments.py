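"""Combinatorial top-down fragment generation.

Starting from the whole molecular graph, bonds are removed one at a time
up to a configurable tree depth (number of successive cleavage steps).
Removing an acyclic bond splits a fragment into its two connected halves;
removing a ring bond leaves the atom set intact and yields an open-ring
intermediate that can be cleaved further.  Fragments are stored compactly
as bitsets of retained atom and bond indices of the parent structure plus
the cumulative dissociation energy of the cleaved bonds, so masses and
formulas are computed on demand without materialising subgraph molecules.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

from .chem import (
    MONOISOTOPIC_MASS,
    AROMATIC_ORDER,
    Formula,
    Structure,
    monoisotopic_mass,
)


@dataclass(frozen=True)
class FragmentRef:
    """A fragment of a parent structure, as retained-index bitsets.

    ``atom_bits`` / ``bond_bits`` are integers whose set bits are the
    retained atom and bond indices of the parent.  ``cleaved_bde`` is the
    sum of dissociation energies over the bonds removed along the cheapest
    recorded cleavage path; ``depth`` is the number of removals.
    """

    atom_bits: int
    bond_bits: int
    cleaved_bde: float
    depth: int

    def atom_indices(self) -> list[int]:
        return _bits_to_indices(self.atom_bits)

    def bond_indices(self) -> list[int]:
        return _bits_to_indices(self.bond_bits)


def _bits_to_indices(bits: int) -> list[int]:
    out = []
    i = 0
    while bits:
        if bits & 1:
            out.append(i)
        bits >>= 1
        i += 1
    return out


class BDETable:
    """Lookup of bond dissociation energies by element pair and bond order.

    Unknown pairs fall back to ``fallback_energy``; for aromatic bonds with
    no dedicated entry the mean of the pair's single and double energies is
    used when both are present.
    """

    def __init__(
        self, entries: dict[tuple[str, str, float], float], fallback_energy: float = 348.0
    ):
        self._entries = {}
        for (a, b, order), e in entries.items():
            if e <= 0:
                raise ValueError(f"non-positive bond energy for {(a, b, order)}")
            self._entries[(min(a, b), max(a, b), float(order))] = float(e)
        self.fallback_energy = float(fallback_energy)

    def bond_energy(self, a: str, b: str, order: float) -> float:
        key = (min(a, b), max(a, b), float(order))
        if key in self._entries:
            return self._entries[key]
        if order == AROMATIC_ORDER:
            s = self._entries.get((key[0], key[1], 1.0))
            d = self._entries.get((key[0], key[1], 2.0))
            if s is not None and d is not None:
                return (s + d) / 2.0
        return self.fallback_energy

    @staticmethod
    def from_text(text: str, fallback_energy: float = 348.0) -> "BDETable":
        entries: dict[tuple[str, str, float], float] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed bond-energy line: {raw!r}")
            a, b, order_s, energy_s = parts
            order = AROMATIC_ORDER if order_s == "ar" else float(order_s)
            entries[(a, b, order)] = float(energy_s)
        return BDETable(entries, fallback_energy)

    @staticmethod
    def from_file(path: str, fallback_energy: float = 348.0) -> "BDETable":
        with open(path) as fh:
            return BDETable.from_text(fh.read(), fallback_energy)

    @staticmethod
    def default() -> "BDETable":
        text = (
            resources.files("fragrank").joinpath("data/bde_default.txt").read_text()
        )
        return BDETable.from_text(text)


def bond_energy(table: BDETable, a: str, b: str, order: float) -> float:
    return table.bond_energy(a, b, order)


def _connected_components(atom_idx: list[int], bonds: dict[int, tuple[int, int]]):
    """Components of the subgraph on ``atom_idx`` with the given bonds."""
    adj: dict[int, list[tuple[int, int]]] = {a: [] for a in atom_idx}
    for bi, (i, j) in bonds.items():
        adj[i].append((j, bi))
        adj[j].append((i, bi))
    seen: set[int] = set()
    comps = []
    for start in atom_idx:
        if start in seen:
            continue
        comp_atoms = {start}
        comp_bonds: set[int] = set()
        stack = [start]
        seen.add(start)
        while stack:
            cur = stack.pop()
            for nb, bi in adj[cur]:
                comp_bonds.add(bi)
                if nb not in seen:
                    seen.add(nb)
                    comp_atoms.add(nb)
                    stack.append(nb)
        comps.append((comp_atoms, comp_bonds))
    return comps


def generate_fragments(
    s: Structure, tree_depth: int, table: BDETable | None = None
) -> list[FragmentRef]:
    """Enumerate fragments of ``s`` reachable within ``tree_depth`` cleavages.

    Returns the parent fragment (all bits set, zero BDE, depth 0) plus every
    distinct (atom set, bond set) produced by successive single-bond
    removals.  Duplicates arising from different cleavage orders are merged
    keeping the minimal cumulative BDE (and the minimal depth at which that
    energy is attained).  Output is sorted by atom bitset then bond bitset
    for determinism.
    """
    from .chem import is_connected

    if tree_depth < 0:
        raise ValueError("tree_depth must be >= 0")
    if not is_connected(s):
        raise ValueError("cannot fragment a disconnected structure")
    if table is None:
        table = BDETable.default()

    bond_atoms = {bi: (b.i, b.j) for bi, b in enumerate(s.bonds)}
    bond_cost = {
        bi: table.bond_energy(s.atoms[b.i].symbol, s.atoms[b.j].symbol, b.order)
        for bi, b in enumerate(s.bonds)
    }

    parent_atom_bits = (1 << s.n_atoms) - 1
    parent_bond_bits = (1 << len(s.bonds)) - 1

    # best (bde, depth) seen per (atom_bits, bond_bits)
    best: dict[tuple[int, int], tuple[float, int]] = {
        (parent_atom_bits, parent_bond_bits): (0.0, 0)
    }
    frontier = [(parent_atom_bits, parent_bond_bits, 0.0)]

    for depth in range(1, tree_depth + 1):
        next_frontier = []
        for atom_bits, bond_bits, bde in frontier:
            atoms_here = _bits_to_indices(atom_bits)
            for bi in _bits_to_indices(bond_bits):
                i, j = bond_atoms[bi]
                remaining = {
                    k: bond_atoms[k]
                    for k in _bits_to_indices(bond_bits)
                    if k != bi
                }
                new_bde = bde + bond_cost[bi]
                for comp_atoms, comp_bonds in _connected_components(
                    atoms_here, remaining
                ):
                    a_bits = 0
                    for a in comp_atoms:
                        a_bits |= 1 << a
                    b_bits = 0
                    for b in comp_bonds:
                        b_bits |= 1 << b
                    key = (a_bits, b_bits)
                    prev = best.get(key)
                    if prev is None or (new_bde, depth) < prev:
                        best[key] = (new_bde, depth)
                        next_frontier.append((a_bits, b_bits, new_bde))
        frontier = next_frontier

    out = [
        FragmentRef(a_bits, b_bits, bde, depth)
        for (a_bits, b_bits), (bde, depth) in best.items()
    ]
    out.sort(key=lambda f: (f.atom_bits, f.bond_bits))
    return out


def fragment_formula(f: FragmentRef, s: Structure) -> Formula:
    """Composition of the retained heavy atoms plus their implicit hydrogens."""
    counts: Counter[str] = Counter()
    for ai in f.atom_indices():
        atom = s.atoms[ai]
        counts[atom.symbol] += 1
        counts["H"] += atom.n_hydrogens
    return Formula.from_counts(counts)


def fragment_mass(f: FragmentRef, s: Structure) -> float:
    """Neutral monoisotopic mass of the fragment's retained atoms.

    Hydrogens stay attached to the heavy atom that carried them in the
    parent, so complementary fragments of one acyclic cleavage sum exactly
    to the parent mass.
    """
    total = 0.0
    for ai in f.atom_indices():
        atom = s.atoms[ai]
        total += MONOISOTOPIC_MASS[atom.symbol]
        total += atom.n_hydrogens * MONOISOTOPIC_MASS["H"]
    return total


def matchable_fragments(
    fragments: list[FragmentRef], s: Structure
) -> list[FragmentRef]:
    """Reduce fragments to peak-matchable candidates, one per atom set.

    Open-ring intermediates share the atom set (hence the neutral mass) of
    an ancestor; for matching, only the cheapest fragment per atom set
    matters, and intermediates equal to the full parent atom set are
    represented by the parent itself.  The parent (precursor) fragment is
    retained and matchable.
    """
    best: dict[int, FragmentRef] = {}
    for f in fragments:
        cur = best.get(f.atom_bits)
        if cur is None or (f.cleaved_bde, f.depth) < (cur.cleaved_bde, cur.depth):
            best[f.atom_bits] = f
    return sorted(best.values(), key=lambda f: f.atom_bits)
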