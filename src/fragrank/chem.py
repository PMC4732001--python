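"""Molecular structures, formulas and exact masses.

The candidate structures handled here are neutral small molecules given as
InChI or SMILES strings.  Hydrogens are kept implicit: each heavy atom
carries a hydrogen count, and only heavy atoms and heavy-atom bonds appear
in the graph.  This matches the fragmenter, which never cleaves C-H bonds.

Monoisotopic masses come from an embedded table of principal-isotope
masses rather than from the chemistry toolkit, so that mass arithmetic is
bit-for-bit reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

# Principal (most abundant) isotope exact masses, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "B": 11.0093055,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "F": 18.9984032,
    "Na": 22.98976928,
    "Mg": 23.985041697,
    "Al": 26.98153853,
    "Si": 27.9769265327,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885271,
    "K": 38.9637069,
    "Ca": 39.9625912,
    "Fe": 55.9349421,
    "Zn": 63.9291466,
    "Se": 79.9165218,
    "Br": 78.9183376,
    "I": 126.904468,
}

ELECTRON_MASS = 0.00054857990946
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

AROMATIC_ORDER = 1.5  # sentinel bond order for aromatic bonds

_VALID_SYMBOLS = frozenset(
    Chem.GetPeriodicTable().GetElementSymbol(i) for i in range(1, 119)
)


class StructureParseError(ValueError):
    """Raised when a structure string cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    index: int
    symbol: str
    n_hydrogens: int


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float  # 1, 2, 3 or AROMATIC_ORDER


@dataclass
class Structure:
    """Heavy-atom molecular graph with implicit hydrogens.

    ``mol`` retains the toolkit molecule for substructure queries,
    InChIKey generation and logP computation; the atom/bond lists are the
    authoritative graph for fragmentation.
    """

    source_text: str
    atoms: list[Atom]
    bonds: list[Bond]
    properties: dict[str, str] = field(default_factory=dict)
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbours(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        return adj


@dataclass(frozen=True)
class Formula:
    """Elemental composition as symbol -> positive count; neutral by default."""

    counts: tuple[tuple[str, int], ...]
    charge: int = 0

    @staticmethod
    def from_counts(counts: dict[str, int], charge: int = 0) -> "Formula":
        clean = {el: n for el, n in counts.items() if n}
        for el in clean:
            if el not in _VALID_SYMBOLS:
                raise ValueError(f"unknown element symbol: {el!r}")
        return Formula(tuple(sorted(clean.items())), charge)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        d = self.as_dict()
        # Hill order: C, H, then alphabetical
        parts = []
        for el in ["C", "H"] + sorted(k for k in d if k not in ("C", "H")):
            if el in d:
                parts.append(el + (str(d[el]) if d[el] > 1 else ""))
        return "".join(parts)

    @staticmethod
    def parse(text: str) -> "Formula":
        """Parse a plain molecular formula string such as 'C9H12O3S'."""
        import re

        counts: Counter[str] = Counter()
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            counts[m.group(1)] += int(m.group(2) or 1)
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return Formula.from_counts(counts)


def _bond_order(bond: Chem.Bond) -> float:
    if bond.GetIsAromatic():
        return AROMATIC_ORDER
    t = bond.GetBondType()
    if t == Chem.BondType.SINGLE:
        return 1.0
    if t == Chem.BondType.DOUBLE:
        return 2.0
    if t == Chem.BondType.TRIPLE:
        return 3.0
    # dative/other orders are treated as single for dissociation purposes
    return 1.0


def parse_structure(text: str, identifier: str | None = None) -> Structure:
    """Parse an InChI or SMILES string into a :class:`Structure`.

    The input kind is auto-detected from the ``InChI=`` prefix.  Implicit
    hydrogens are assigned by the toolkit's standard valence model.
    """
    if not text or not text.strip():
        raise StructureParseError("empty structure string")
    text = text.strip()
    if text.startswith("InChI="):
        mol = Chem.MolFromInchi(text)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        who = f" (record {identifier})" if identifier else ""
        raise StructureParseError(f"unparsable structure{who}: {text!r}")
    atoms = [
        Atom(a.GetIdx(), a.GetSymbol(), a.GetTotalNumHs())
        for a in mol.GetAtoms()
    ]
    bonds = [
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _bond_order(b))
        for b in mol.GetBonds()
    ]
    return Structure(source_text=text, atoms=atoms, bonds=bonds, mol=mol)


def net_charge(s: Structure) -> int:
    if s.mol is None:
        return 0
    return Chem.GetFormalCharge(s.mol)


def molecular_formula(s: Structure) -> Formula:
    """Elemental composition of the structure including implicit hydrogens."""
    counts: Counter[str] = Counter()
    for a in s.atoms:
        counts[a.symbol] += 1
        counts["H"] += a.n_hydrogens
    return Formula.from_counts(counts)


def monoisotopic_mass(f: Formula) -> float:
    """Exact neutral mass: sum of principal-isotope masses over the formula."""
    total = 0.0
    for el, n in f.counts:
        try:
            total += n * MONOISOTOPIC_MASS[el]
        except KeyError:
            raise ValueError(f"no monoisotopic mass for element {el!r}") from None
    return total


def inchikey_first_block(s: Structure) -> str:
    """First 14 characters of the standard InChIKey (skeleton block).

    Stereoisomers of one connectivity share this value, which is what the
    stereo deduplication and suspect matching rely on.
    """
    if s.mol is None:
        raise ValueError("structure has no toolkit molecule attached")
    key = Chem.MolToInchiKey(s.mol)
    if not key or len(key) < 14:
        raise ValueError(f"InChIKey generation failed for {s.source_text!r}")
    return key[:14]


def is_connected(s: Structure) -> bool:
    """True iff the heavy-atom graph forms a single connected component."""
    n = s.n_atoms
    if n <= 1:
        return True
    adj = s.neighbours()
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == n
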