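"""Candidate records, database readers/writers and parameter files.

Local candidate databases are CSV (``Identifier`` plus ``InChI`` or
``SMILES`` columns; any further columns become candidate properties) or
SDF with SD property tags.  Parameter files are plain ``key=value`` lines
mirroring a shell tool's configuration.  Online database types are
recognised in parameter files but resolve to a stub — no network
retrieval is bundled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .chem import (
    Formula,
    Structure,
    StructureParseError,
    inchikey_first_block,
    is_connected,
    molecular_formula,
    monoisotopic_mass,
    net_charge,
    parse_structure,
)

log = logging.getLogger("fragrank")

RESERVED_COLUMNS = {"Identifier", "InChI", "SMILES"}
ONLINE_DATABASES = {"PubChem", "ChemSpider", "KEGG"}


@dataclass
class CandidateRecord:
    identifier: str
    structure: Structure
    formula: Formula
    monoisotopic_mass: float
    properties: dict[str, object] = field(default_factory=dict)
    score_terms: dict[str, float] = field(default_factory=dict)  # raw values
    normalized_terms: dict[str, float] = field(default_factory=dict)
    final_score: float = 0.0
    _first_block: str | None = field(default=None, repr=False)

    @property
    def first_block(self) -> str:
        if self._first_block is None:
            self._first_block = inchikey_first_block(self.structure)
        return self._first_block

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.structure.mol)

    @property
    def inchi(self) -> str:
        return Chem.MolToInchi(self.structure.mol)


def _build_record(
    identifier: str, structure_text: str, properties: dict[str, object]
) -> CandidateRecord:
    structure = parse_structure(structure_text, identifier=identifier)
    if net_charge(structure) != 0:
        raise StructureParseError(
            f"candidate {identifier!r} carries a net charge; "
            "candidates must be neutral molecules"
        )
    formula = molecular_formula(structure)
    mass = monoisotopic_mass(formula)
    declared = properties.get("MonoisotopicMass")
    if declared not in (None, ""):
        try:
            declared_f = float(declared)
        except (TypeError, ValueError):
            declared_f = None
        if declared_f is not None and abs(declared_f - mass) > 1e-3:
            log.warning(
                "candidate %s: declared mass %.4f differs from computed %.4f; "
                "using the computed value",
                identifier,
                declared_f,
                mass,
            )
    return CandidateRecord(identifier, structure, formula, mass, properties)


def read_candidates(path: str, fmt: str | None = None) -> list[CandidateRecord]:
    """Load a local candidate database (CSV or SDF).

    Records whose structure fails to parse, or which carry a net charge,
    are skipped with a logged warning.  Raises if no valid record remains.
    """
    p = Path(path)
    if fmt is None:
        fmt = "SDF" if p.suffix.lower() in (".sdf", ".sd") else "CSV"
    fmt = fmt.upper()
    if fmt == "CSV":
        records = _read_candidates_csv(p)
    elif fmt == "SDF":
        records = _read_candidates_sdf(p)
    else:
        raise ValueError(f"unsupported candidate database format {fmt!r}")
    if not records:
        raise ValueError(f"no valid candidate records in {path}")
    return records


def _read_candidates_csv(path: Path) -> list[CandidateRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "Identifier" not in df.columns:
        raise ValueError(f"{path}: missing mandatory 'Identifier' column")
    if "InChI" not in df.columns and "SMILES" not in df.columns:
        raise ValueError(f"{path}: need an 'InChI' or 'SMILES' column")
    records = []
    skipped = 0
    for _, row in df.iterrows():
        text = row.get("InChI", "") or row.get("SMILES", "")
        props = {
            k: v for k, v in row.items() if k not in RESERVED_COLUMNS and v != ""
        }
        try:
            records.append(_build_record(str(row["Identifier"]), text, props))
        except StructureParseError as exc:
            skipped += 1
            log.warning("skipping candidate: %s", exc)
    if skipped:
        log.warning("%d of %d records skipped while reading %s", skipped, len(df), path)
    return records


def _read_candidates_sdf(path: Path) -> list[CandidateRecord]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    records = []
    skipped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            log.warning("skipping unparsable SDF record %d in %s", i, path)
            continue
        props = dict(mol.GetPropsAsDict())
        identifier = str(
            props.pop("Identifier", None)
            or (mol.GetProp("_Name") if mol.HasProp("_Name") else "")
            or f"SDF-{i}"
        )
        try:
            records.append(_build_record(identifier, Chem.MolToSmiles(mol), props))
        except StructureParseError as exc:
            skipped += 1
            log.warning("skipping candidate: %s", exc)
    return records


@dataclass
class PrecursorSpec:
    """Exactly one of: neutral mass +/- ppm, molecular formula, or id list."""

    neutral_mass: float | None = None
    mass_ppm: float = 5.0
    formula: Formula | None = None
    identifiers: list[str] | None = None

    def __post_init__(self):
        modes = sum(
            x is not None for x in (self.neutral_mass, self.formula, self.identifiers)
        )
        if modes != 1:
            raise ValueError(
                "exactly one precursor specification (mass, formula or "
                "identifier list) must be given"
            )


def select_candidates(
    records: list[CandidateRecord], spec: PrecursorSpec
) -> list[CandidateRecord]:
    """Pick the records matching the precursor specification.

    The mass window is symmetric and inclusive: |m - target| <= target*ppm*1e-6.
    """
    if spec.neutral_mass is not None:
        half = spec.neutral_mass * spec.mass_ppm * 1e-6
        kept = [
            r
            for r in records
            if abs(r.monoisotopic_mass - spec.neutral_mass) <= half
        ]
    elif spec.formula is not None:
        kept = [r for r in records if r.formula.counts == spec.formula.counts]
    else:
        wanted = set(spec.identifiers or [])
        kept = [r for r in records if r.identifier in wanted]
    if not kept:
        log.warning("precursor selection matched no candidates")
    return kept


def results_frame(records: list[CandidateRecord]) -> pd.DataFrame:
    """Tabulate scored candidates, sorted by final score descending."""
    ordered = sorted(records, key=lambda r: (-r.final_score, r.identifier))
    rows = []
    for r in ordered:
        row: dict[str, object] = {
            "Identifier": r.identifier,
            "InChI": r.inchi,
            "SMILES": r.smiles,
            "MolecularFormula": str(r.formula),
            "MonoisotopicMass": r.monoisotopic_mass,
        }
        for name, v in sorted(r.score_terms.items()):
            row[name] = v
        for name, v in sorted(r.normalized_terms.items()):
            row["Normalized" + name] = v
        row["FinalScore"] = r.final_score
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df["Rank"] = [
            1 + sum(s2 > s1 for s2 in df["FinalScore"]) for s1 in df["FinalScore"]
        ]
    return df


def write_results(
    records: list[CandidateRecord], path: str, fmt: str = "CSV", sep: str = ","
) -> None:
    """Write scored candidates sorted by descending final score.

    CSV carries identifiers, structures, every raw and normalized score
    term, the final score and the rank; SDF carries the same as SD tags.
    Use ``sep='|'`` for the pipe-separated re-import format.
    """
    fmt = fmt.upper()
    if fmt == "CSV":
        results_frame(records).to_csv(path, index=False, sep=sep)
    elif fmt == "SDF":
        df = results_frame(records)
        by_id = {r.identifier: r for r in records}
        writer = Chem.SDWriter(str(path))
        try:
            for _, row in df.iterrows():
                mol = Chem.Mol(by_id[str(row["Identifier"])].structure.mol)
                for col, v in row.items():
                    mol.SetProp(str(col), str(v))
                writer.write(mol)
        finally:
            writer.close()
    else:
        raise ValueError(f"unsupported results format {fmt!r}")


MANDATORY_KEYS = ("PeakListPath", "DatabaseType", "LocalDatabasePath")

KNOWN_KEYS = {
    "PeakListPath",
    "DatabaseType",
    "LocalDatabasePath",
    "NeutralPrecursorMass",
    "DatabaseSearchRelativeMassDeviation",
    "NeutralPrecursorMolecularFormula",
    "PrecursorCompoundIDs",
    "PrecursorIonType",
    "MaximumTreeDepth",
    "FragmentPeakMatchRelativeMassDeviation",
    "FragmentPeakMatchAbsoluteMassDeviation",
    "ScoreTypes",
    "ScoreWeights",
    "FilterIncludedElements",
    "FilterExcludedElements",
    "FilterOnlyElements",
    "FilterSmartsInclusionList",
    "FilterSmartsExclusionList",
    "FilterSuspectLists",
    "ScoreSuspectLists",
    "ScoreSmartsInclusionList",
    "ScoreSmartsExclusionList",
    "ReferenceSources",
    "RetentionTimeTrainingFile",
    "ExperimentalRetentionTime",
    "RetentionTimeSigma",
    "UserLogPColumn",
    "SampleName",
    "ResultsPath",
    "ResultsFormat",
    "RandomSeed",
}


@dataclass
class ParameterSet:
    """Parsed parameter file plus defaults; see ``read_parameters``."""

    raw: dict[str, str]

    def get(self, key: str, default: str | None = None) -> str | None:
        return self.raw.get(key, default)

    @property
    def tree_depth(self) -> int:
        return int(self.raw.get("MaximumTreeDepth", "2"))

    @property
    def match_ppm(self) -> float:
        return float(self.raw.get("FragmentPeakMatchRelativeMassDeviation", "5"))

    @property
    def match_da(self) -> float:
        return float(self.raw.get("FragmentPeakMatchAbsoluteMassDeviation", "0.001"))

    @property
    def precursor_ion_type(self) -> str:
        return self.raw.get("PrecursorIonType", "[M+H]+")

    def precursor_spec(self) -> PrecursorSpec:
        mass = self.raw.get("NeutralPrecursorMass")
        formula = self.raw.get("NeutralPrecursorMolecularFormula")
        ids = self.raw.get("PrecursorCompoundIDs")
        given = [x for x in (mass, formula, ids) if x]
        if len(given) != 1:
            raise ValueError(
                "exactly one of NeutralPrecursorMass, "
                "NeutralPrecursorMolecularFormula or PrecursorCompoundIDs "
                "must be set"
            )
        if mass:
            ppm = float(self.raw.get("DatabaseSearchRelativeMassDeviation", "5"))
            return PrecursorSpec(neutral_mass=float(mass), mass_ppm=ppm)
        if formula:
            return PrecursorSpec(formula=Formula.parse(formula))
        return PrecursorSpec(identifiers=[s.strip() for s in ids.split(",")])

    def score_weights(self) -> dict[str, float]:
        types = self.raw.get("ScoreTypes", "FragmenterScore")
        weights = self.raw.get("ScoreWeights", "")
        names = [t.strip() for t in types.split(",") if t.strip()]
        if weights.strip():
            vals = [float(v) for v in weights.split(",")]
            if len(vals) != len(names):
                raise ValueError("ScoreWeights length differs from score types")
        else:
            vals = [1.0] * len(names)
        return dict(zip(names, vals))


def read_parameters(path: str) -> ParameterSet:
    """Parse a key=value parameter file; unknown keys warn, defaults apply."""
    raw: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
    dbtype = raw.get("DatabaseType", "")
    if dbtype in ONLINE_DATABASES:
        raise ValueError(
            f"database type {dbtype!r} requires network retrieval, which is "
            "not bundled; use LocalCSV or LocalSDF"
        )
    missing = [
        k
        for k in MANDATORY_KEYS
        if k not in raw and not (k == "LocalDatabasePath" and dbtype == "")
    ]
    if missing:
        raise ValueError(f"missing mandatory parameter(s): {', '.join(missing)}")
    for key in raw:
        if key not in KNOWN_KEYS:
            log.warning("unknown parameter key %r ignored", key)
    return ParameterSet(raw)
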