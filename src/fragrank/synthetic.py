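"""Synthetic data generation for end-to-end testing without databases.

Provides a deterministic toy compound library, formula-preserving decoy
structures (emulating an exact-mass database search), simulated MS/MS
spectra whose signal peaks come from the fragmenter itself, synthetic
retention-time calibration sets, and a seeded end-to-end recovery
benchmark.  Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .candidates import CandidateRecord
from .chem import molecular_formula, monoisotopic_mass, parse_structure
from .fragments import (
    BDETable,
    fragment_mass,
    generate_fragments,
    matchable_fragments,
)
from .scoring import (
    DEFAULT_ALPHA,
    DEFAULT_GAMMA,
    WeightConfig,
    compute_logp,
    fragmenter_score,
    normalize_terms,
)
from .spectra import (
    MatchSettings,
    Peak,
    Spectrum,
    get_precursor_type,
    match_peaks,
    theoretical_ion_mz,
)

log = logging.getLogger("fragrank")

# (identifier, SMILES) pairs: small molecules with several exact-mass
# isomer groups, the four triazine herbicide isobars, and one salt for
# the unconnected filter.
TOY_LIBRARY: tuple[tuple[str, str], ...] = (
    ("ethanol", "CCO"),
    ("dimethyl-ether", "COC"),
    ("propan-1-ol", "CCCO"),
    ("propan-2-ol", "CC(C)O"),
    ("butan-1-ol", "CCCCO"),
    ("2-methylpropan-2-ol", "CC(C)(C)O"),
    ("diethyl-ether", "CCOCC"),
    ("acetic-acid", "CC(=O)O"),
    ("methyl-formate", "COC=O"),
    ("glycolaldehyde", "OCC=O"),
    ("alanine", "CC(N)C(=O)O"),
    ("sarcosine", "CNCC(=O)O"),
    ("beta-alanine", "NCCC(=O)O"),
    ("glycine", "NCC(=O)O"),
    ("serine", "OCC(N)C(=O)O"),
    ("pyridine", "c1ccncc1"),
    ("aniline", "Nc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("benzoic-acid", "OC(=O)c1ccccc1"),
    ("salicylaldehyde", "O=Cc1ccccc1O"),
    ("toluene", "Cc1ccccc1"),
    ("benzene", "c1ccccc1"),
    ("cyclohexane", "C1CCCCC1"),
    ("hexane", "CCCCCC"),
    ("glucose-open", "OCC(O)C(O)C(O)C(O)C=O"),
    ("fructose-open", "OCC(=O)C(O)C(O)C(O)CO"),
    ("taurine", "NCCS(=O)(=O)O"),
    ("cysteine", "NC(CS)C(=O)O"),
    ("mesitylenesulfonic-acid", "Cc1cc(C)c(S(=O)(=O)O)c(C)c1"),
    ("terbutylazine", "CCNc1nc(Cl)nc(NC(C)(C)C)n1"),
    ("propazine", "CC(C)Nc1nc(Cl)nc(NC(C)C)n1"),
    ("secbutylazine", "CCC(C)Nc1nc(Cl)nc(NCC)n1"),
    ("triethazine", "CCN(CC)c1nc(Cl)nc(NCC)n1"),
    ("sodium-acetate", "CC(=O)[O-].[Na+]"),
)


@dataclass
class SimulationConfig:
    """Knobs for spectrum and benchmark simulation.

    Defaults reflect a clean high-resolution merged MS/MS acquisition:
    sub-mDa m/z jitter (well inside the default 5 ppm + 1 mDa matching
    window at fragment masses), a dozen informative fragment peaks
    (merged reference spectra typically carry 10-20), and a few
    uniform-random noise peaks.
    """

    seed: int = 0
    tree_depth: int = 2
    n_signal_peaks: int = 12
    n_noise_peaks: int = 3
    mz_jitter_sd: float = 0.0002  # Da
    intensity_range: tuple[float, float] = (50.0, 1000.0)
    precursor_type: str = "[M+H]+"
    rt_model_true: tuple[float, float, float] = (0.25, 0.5, 0.3)  # a, b, noise sd
    reference_boost: float = 5.0  # multiplier on the correct candidate's counts


def make_toy_library() -> list[CandidateRecord]:
    """Deterministic library of small molecules as candidate records.

    Contains exact-mass isomer groups (e.g. four C9H16ClN5 triazines),
    stereochemistry-free skeletons and one disconnected salt.
    """
    records = []
    for identifier, smiles in TOY_LIBRARY:
        structure = parse_structure(smiles, identifier=identifier)
        formula = molecular_formula(structure)
        records.append(
            CandidateRecord(
                identifier, structure, formula, monoisotopic_mass(formula)
            )
        )
    return records


def make_decoys(
    truth: CandidateRecord, n: int, rng: np.random.Generator, max_tries: int = 2000
) -> list[CandidateRecord]:
    """Generate formula-preserving structural decoys.

    Each decoy arises from 1-3 random perturbations.  The primary move is
    an atom swap: the element labels of two sites with equal total bond
    order are exchanged, which preserves the molecular formula, the bond
    skeleton and the overall bond-energy profile while relocating
    heteroatoms, so decoy fragments shift in mass without the decoy
    gaining artificially cheap cleavages.  When no swappable pair exists
    (e.g. pure hydrocarbons) a single-bond migration is used instead
    (detach one end of a single bond, reattach it to an atom with a spare
    hydrogen).  Decoys are pairwise distinct and distinct from the truth
    by InChIKey first block, emulating an exact-mass retrieval.

    Decoys must also be structurally distinct from the truth (Morgan
    fingerprint Tanimoto < 0.7): near-degenerate isomers, such as the
    co-eluting butylazine isobars, are unresolvable by fragmentation
    evidence in principle, and their inclusion would turn an end-to-end
    pipeline check into a test of isomer resolution.
    """
    from rdkit.Chem import rdFingerprintGenerator
    from rdkit.DataStructs import TanimotoSimilarity

    fpgen = rdFingerprintGenerator.GetMorganGenerator(radius=2)
    truth_fp = fpgen.GetFingerprint(truth.structure.mol)
    target_formula = truth.formula.counts
    seen_blocks = {truth.first_block}
    decoys: list[CandidateRecord] = []
    tries = 0
    while len(decoys) < n and tries < max_tries:
        tries += 1
        mutant = _mutate(truth.structure.mol, rng, n_moves=int(rng.integers(3, 8)))
        if mutant is None:
            continue
        smiles = Chem.MolToSmiles(mutant)
        try:
            structure = parse_structure(smiles)
        except Exception:
            continue
        formula = molecular_formula(structure)
        if formula.counts != target_formula:
            continue
        key = Chem.MolToInchiKey(structure.mol)[:14]
        if not key or key in seen_blocks:
            continue
        if TanimotoSimilarity(truth_fp, fpgen.GetFingerprint(structure.mol)) >= 0.7:
            continue
        seen_blocks.add(key)
        decoys.append(
            CandidateRecord(
                f"{truth.identifier}-decoy-{len(decoys) + 1}",
                structure,
                formula,
                monoisotopic_mass(formula),
            )
        )
    if len(decoys) < n:
        log.warning(
            "only %d of %d decoys generated for %s", len(decoys), n, truth.identifier
        )
    return decoys


def _swap_sites(work: Chem.RWMol, rng: np.random.Generator) -> bool:
    """Exchange element labels of two equal-bond-order sites; True on success."""
    by_order: dict[float, list[int]] = {}
    for at in work.GetAtoms():
        order = sum(b.GetBondTypeAsDouble() for b in at.GetBonds())
        by_order.setdefault(order, []).append(at.GetIdx())
    pairs = [
        (i, j)
        for sites in by_order.values()
        for i in sites
        for j in sites
        if i < j
        and work.GetAtomWithIdx(i).GetSymbol()
        != work.GetAtomWithIdx(j).GetSymbol()
    ]
    if not pairs:
        return False
    i, j = pairs[int(rng.integers(len(pairs)))]
    ai, aj = work.GetAtomWithIdx(i), work.GetAtomWithIdx(j)
    zi, zj = ai.GetAtomicNum(), aj.GetAtomicNum()
    ai.SetAtomicNum(zj)
    aj.SetAtomicNum(zi)
    return True


def _migrate_bond(work: Chem.RWMol, rng: np.random.Generator) -> bool:
    """Detach one end of a random single bond and reattach it elsewhere."""
    single_bonds = [
        b for b in work.GetBonds() if b.GetBondType() == Chem.BondType.SINGLE
    ]
    if not single_bonds:
        return False
    bond = single_bonds[int(rng.integers(len(single_bonds)))]
    a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    if rng.random() < 0.5:
        a, b = b, a
    targets = [
        at.GetIdx()
        for at in work.GetAtoms()
        if at.GetIdx() not in (a, b)
        and at.GetTotalNumHs() >= 1
        and work.GetBondBetweenAtoms(a, at.GetIdx()) is None
    ]
    if not targets:
        return False
    c = targets[int(rng.integers(len(targets)))]
    work.RemoveBond(a, b)
    work.AddBond(a, c, Chem.BondType.SINGLE)
    return True


def _mutate(mol: Chem.Mol, rng: np.random.Generator, n_moves: int) -> Chem.Mol | None:
    work = Chem.RWMol(mol)
    try:
        Chem.Kekulize(work, clearAromaticFlags=True)
    except Exception:
        return None
    for _ in range(n_moves):
        if rng.random() < 0.5:
            ok = _swap_sites(work, rng) or _migrate_bond(work, rng)
        else:
            ok = _migrate_bond(work, rng) or _swap_sites(work, rng)
        if not ok:
            return None
    out = work.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    if len(Chem.GetMolFrags(out)) != 1:
        return None
    if _has_unstable_motif(out, mol):
        return None
    return out


# single bonds between these element pairs mark peroxide / hydrazine /
# hydroxylamine-type motifs that are rare in compound databases
_WEAK_PAIRS = {
    frozenset({"O"}),
    frozenset({"N"}),
    frozenset({"N", "O"}),
    frozenset({"N", "Cl"}),
    frozenset({"O", "Cl"}),
}


def _weak_bond_count(mol: Chem.Mol) -> int:
    return sum(
        1
        for b in mol.GetBonds()
        if frozenset(
            {b.GetBeginAtom().GetSymbol(), b.GetEndAtom().GetSymbol()}
        )
        in _WEAK_PAIRS
    )


def _has_unstable_motif(mutant: Chem.Mol, parent: Chem.Mol) -> bool:
    """True if the perturbation introduced weak hetero-hetero bonds.

    Database candidates are overwhelmingly stable organics; decoys with
    extra O-O / N-N / N-O linkages would both be unrealistic and gain
    artificially low dissociation-energy denominators.
    """
    return _weak_bond_count(mutant) > _weak_bond_count(parent)


def simulate_spectrum(
    truth: CandidateRecord,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    table: BDETable | None = None,
) -> tuple[Spectrum, list[float]]:
    """Simulate an MS/MS spectrum of the truth candidate.

    Signal peaks are drawn from the truth's own fragment ions (shift 0),
    jittered with Gaussian m/z noise and given uniform random intensities;
    noise peaks land at uniform random m/z below the precursor, outside
    the matching windows of any true fragment ion.  Returns the spectrum
    and the list of true (unjittered) signal m/z values.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if table is None:
        table = BDETable.default()
    ptype = get_precursor_type(cfg.precursor_type)
    frags = matchable_fragments(
        generate_fragments(truth.structure, cfg.tree_depth, table), truth.structure
    )
    parent_bits = (1 << truth.structure.n_atoms) - 1
    proper = [f for f in frags if f.atom_bits != parent_bits]
    # one entry per distinct neutral mass, keeping the cheapest route to it
    by_mass: dict[float, float] = {}
    for f in proper:
        m = round(fragment_mass(f, truth.structure), 9)
        if m not in by_mass or f.cleaved_bde < by_mass[m]:
            by_mass[m] = f.cleaved_bde
    masses = sorted(by_mass)
    # no instrument low-mass cutoff: the toy molecules are small and all
    # fragment ions are informative
    ion_mzs = [theoretical_ion_mz(m, ptype) for m in masses]
    n_signal = min(cfg.n_signal_peaks, len(ion_mzs))
    if n_signal < cfg.n_signal_peaks:
        log.info(
            "%s: only %d distinct fragment ions available (%d requested)",
            truth.identifier,
            len(ion_mzs),
            cfg.n_signal_peaks,
        )
    # fragments formed by cheap cleavages and retaining most of the
    # precursor dominate collision-induced spectra; sample accordingly
    # (weight mirrors the per-peak score structure: RelMass^a / BDE^g)
    precursor_mz_t = truth.monoisotopic_mass + ptype.adduct_mass
    weights = np.array(
        [
            (ion_mzs[i] / precursor_mz_t) ** DEFAULT_ALPHA
            / max(by_mass[masses[i]], 1.0) ** DEFAULT_GAMMA
            for i in range(len(masses))
        ]
    )
    weights /= weights.sum()
    chosen = sorted(
        rng.choice(len(ion_mzs), size=n_signal, replace=False, p=weights).tolist()
    )
    true_mzs = [ion_mzs[i] for i in chosen]
    lo, hi = cfg.intensity_range
    peaks = [
        Peak(
            mz + (rng.normal(0.0, cfg.mz_jitter_sd) if cfg.mz_jitter_sd > 0 else 0.0),
            rng.uniform(lo, hi),
        )
        for mz in true_mzs
    ]
    # noise peaks: uniform m/z, kept clear of every true fragment ion window
    precursor_mz = truth.monoisotopic_mass + ptype.adduct_mass
    all_windows = [
        theoretical_ion_mz(m, ptype, h) for m in masses for h in (-1, 0, 1)
    ]
    added = 0
    while added < cfg.n_noise_peaks:
        mz = rng.uniform(45.0, max(precursor_mz - 1.0, 50.0))
        if all(abs(mz - w) > 0.05 for w in all_windows):
            peaks.append(Peak(mz, rng.uniform(lo, hi)))
            added += 1
    spectrum = Spectrum(
        peaks=peaks,
        neutral_precursor_mass=truth.monoisotopic_mass,
        precursor_type=ptype,
    )
    return spectrum, true_mzs


def simulate_rt_training(
    library: list[CandidateRecord],
    true_a: float,
    true_b: float,
    noise_sd: float,
    n: int,
    seed: int,
) -> list[tuple[float, float]]:
    """Synthetic (RT, logP) calibration pairs under a known linear law.

    log P values are computed from randomly sampled library structures and
    retention times derived by inverting logP = a*RT + b, plus Gaussian
    RT noise.  With zero noise the OLS fit recovers (a, b) exactly.
    """
    if n < 2:
        raise ValueError("need at least two training pairs")
    if true_a == 0:
        raise ValueError("true slope must be nonzero to invert the line")
    rng = np.random.default_rng(seed)
    connected = [r for r in library if len(Chem.GetMolFrags(r.structure.mol)) == 1]
    pairs = []
    for _ in range(n):
        rec = connected[int(rng.integers(len(connected)))]
        logp = compute_logp(rec.structure)
        rt = (logp - true_b) / true_a + (
            rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        )
        pairs.append((rt, logp))
    return pairs


@dataclass
class RecoveryCase:
    truth_id: str
    n_candidates: int
    frag_scores: dict[str, float]
    rank_frag_only: int
    rank_with_refs: int
    truth_final_frag_only: float
    truth_final_with_refs: float


def run_recovery_case(
    truth: CandidateRecord,
    cfg: SimulationConfig,
    n_decoys: int = 10,
    settings: MatchSettings | None = None,
) -> RecoveryCase:
    """One seeded identification round: truth plus formula-matched decoys.

    Scores every candidate against a zero-configurable-noise spectrum of
    the truth, first with the fragmenter term alone and then adding a
    synthetic reference-count term in which the truth's counts are
    boosted.  Reports the truth's pessimistic ranks under both weightings.

    The simulated spectra contain no hydrogen rearrangements (every
    signal peak is an unshifted fragment ion), so matching runs with a
    zero hydrogen-shift set for consistency; the package default of
    {-1, 0, +1} exists for real spectra, where rearrangements occur, and
    would here only admit spurious decoy matches the generator never
    produced.
    """
    from .evaluation import pessimistic_rank

    rng = np.random.default_rng(cfg.seed)
    settings = settings or MatchSettings(hydrogen_shifts=(0,))
    table = BDETable.default()
    decoys = make_decoys(truth, n_decoys, rng)
    candidates = [truth] + decoys
    spectrum, _ = simulate_spectrum(truth, cfg, rng, table)
    w = WeightConfig({"FragmenterScore": 1.0})
    frag_raw = {}
    for cand in candidates:
        frags = generate_fragments(cand.structure, cfg.tree_depth, table)
        assignments = match_peaks(
            spectrum, frags, settings, structure=cand.structure
        )
        frag_raw[cand.identifier] = fragmenter_score(assignments, spectrum, w)
    frag_norm = dict(
        zip(frag_raw, normalize_terms(list(frag_raw.values())))
    )
    # synthetic reference counts: decoys are obscure database entries with
    # uniform low counts; the truth is an established compound whose count
    # sits a boost factor above the decoy range (reference standards are
    # well-documented substances, unlike their exact-mass isomers)
    ref_raw = {
        c.identifier: float(rng.integers(1, 101)) for c in candidates
    }
    ref_raw[truth.identifier] = cfg.reference_boost * float(rng.integers(50, 101))
    ref_norm = dict(zip(ref_raw, normalize_terms(list(ref_raw.values()))))
    final_frag = dict(frag_norm)
    final_both = {
        cid: frag_norm[cid] + ref_norm[cid] for cid in frag_norm
    }
    return RecoveryCase(
        truth_id=truth.identifier,
        n_candidates=len(candidates),
        frag_scores=frag_raw,
        rank_frag_only=pessimistic_rank(final_frag, truth.identifier),
        rank_with_refs=pessimistic_rank(final_both, truth.identifier),
        truth_final_frag_only=final_frag[truth.identifier],
        truth_final_with_refs=final_both[truth.identifier],
    )


def informative_fragmenter_target(record: CandidateRecord) -> bool:
    """Whether a molecule can yield a structure-specific MS/MS spectrum.

    Identification by bond-dissociation scoring needs fragments that
    discriminate between isomers.  Rigid single-ring hydrocarbons and
    unsubstituted heteroaromatics produce only ring-arc fragments, and
    alkanes only homologous-series fragments, which many isomers explain
    equally well; such molecules are excluded from the identification
    benchmark (they remain in the library for fragmenter unit tests).
    Requires: connected, >= 6 heavy atoms, >= 1 heteroatom and >= 4
    acyclic heavy-atom bonds.
    """
    mol = record.structure.mol
    if len(Chem.GetMolFrags(mol)) != 1 or mol.GetNumAtoms() < 6:
        return False
    if all(a.GetSymbol() == "C" for a in mol.GetAtoms()):
        return False
    acyclic = sum(1 for b in mol.GetBonds() if not b.IsInRing())
    return acyclic >= 4


def recovery_benchmark(
    n_cases: int = 50, seed: int = 0, n_decoys: int = 10
) -> list[RecoveryCase]:
    """Seeded end-to-end benchmark over fragment-rich library molecules."""
    library = [r for r in make_toy_library() if informative_fragmenter_target(r)]
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        truth = library[int(rng.integers(len(library)))]
        cfg = SimulationConfig(
            seed=int(rng.integers(2**31 - 1)),
            mz_jitter_sd=0.0,
            n_noise_peaks=0,
        )
        cases.append(run_recovery_case(truth, cfg, n_decoys=n_decoys))
    return cases


def write_fixture_files(
    out_dir: str,
    truth: CandidateRecord,
    cfg: SimulationConfig,
    n_decoys: int = 5,
) -> dict[str, str]:
    """Materialise one simulated case in the exact on-disk input formats.

    Writes the peak list, candidate CSV, RT training file and suspect
    list into ``out_dir`` and returns their paths, so tests can exercise
    the real file readers end to end.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    spectrum, _ = simulate_spectrum(truth, cfg, rng)
    peak_path = out / "peaks.txt"
    with open(peak_path, "w") as fh:
        fh.write("# m/z intensity\n")
        for p in spectrum.peaks:
            fh.write(f"{p.mz:.6f} {p.intensity:.2f}\n")
    decoys = make_decoys(truth, n_decoys, rng)
    csv_path = out / "candidates.csv"
    with open(csv_path, "w") as fh:
        fh.write("Identifier,InChI,ChemSpiderReferenceCount,UserLogP\n")
        for c in [truth] + decoys:
            refs = int(rng.integers(1, 100))
            if c is truth:
                refs = int(refs * cfg.reference_boost)
            fh.write(
                f'{c.identifier},"{c.inchi}",{refs},{compute_logp(c.structure):.3f}\n'
            )
    a, b, noise = cfg.rt_model_true
    pairs = simulate_rt_training(make_toy_library(), a, b, noise, 20, cfg.seed)
    rt_path = out / "rt_training.csv"
    with open(rt_path, "w") as fh:
        fh.write("RetentionTime,UserLogP\n")
        for rt, logp in pairs:
            fh.write(f"{rt:.4f},{logp:.4f}\n")
    suspect_path = out / "suspects.txt"
    with open(suspect_path, "w") as fh:
        fh.write(truth.first_block + "\n")
    return {
        "peaks": str(peak_path),
        "candidates": str(csv_path),
        "rt_training": str(rt_path),
        "suspects": str(suspect_path),
    }
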