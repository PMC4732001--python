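"""Candidate scoring terms and their weighted combination.

The final score of a candidate is a weighted sum of normalized evidence
terms: the fragmenter score from matched peaks, substructure inclusion /
exclusion scores, combined literature/patent reference counts, a binary
suspect-list flag, a Gaussian retention-time score from a linear
RT - log P calibration, and arbitrary user-supplied score columns.  Each
raw term is normalized to the maximum over the candidate list before
weighting, so all normalized terms lie in [0, 1].
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra import MatchAssignment, Spectrum

log = logging.getLogger("fragrank")

# Fragmenter exponents: relative mass, relative intensity, BDE penalty.
DEFAULT_ALPHA = 1.84
DEFAULT_BETA = 0.59
DEFAULT_GAMMA = 0.47

RT_SIGMA_DEFAULT = 1.5  # log P units

# Recognised reference-count property names, by database flavour.
PUBCHEM_REFERENCE_SOURCES = ("PubChemNumberPatents", "PubChemPubMedCount")
CHEMSPIDER_REFERENCE_SOURCES = (
    "ChemSpiderReferenceCount",
    "ChemSpiderExternalReferenceCount",
    "ChemSpiderRSCCount",
    "ChemSpiderPubMedCount",
    "ChemSpiderDataSourceCount",
)


@dataclass
class WeightConfig:
    """Per-term weights and fragmenter exponents."""

    weights: dict[str, float] = field(default_factory=lambda: {"FragmenterScore": 1.0})
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self):
        for name, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative weight for term {name!r}")
        if not any(w > 0 for w in self.weights.values()):
            raise ValueError("at least one term weight must be positive")
        if self.alpha <= 0 or self.beta <= 0 or self.gamma <= 0:
            raise ValueError("fragmenter exponents must be positive")


@dataclass
class RTModel:
    """Linear retention-time -> log P calibration with Gaussian spread.

    ``logp_source`` tags which log P flavour the model was trained on
    (e.g. "internal" for toolkit-computed values or a candidate column
    name such as "UserLogP"); candidates must be scored with the same
    flavour.
    """

    slope: float
    intercept: float
    sigma: float = RT_SIGMA_DEFAULT
    logp_source: str = "internal"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def predict_logp(self, rt: float) -> float:
        return self.slope * rt + self.intercept


def fragmenter_score(
    assignments: list[MatchAssignment], spec: Spectrum, w: WeightConfig
) -> float:
    """Peak-explanation score: sum over matched peaks of
    RelMass^alpha * RelInt^beta / (sum of cleaved BDE)^gamma.

    RelMass is the peak m/z over the precursor ion m/z and RelInt the peak
    intensity over the spectrum's base-peak intensity, so both lie in
    (0, 1].  A matched precursor fragment has zero cleaved energy; its
    denominator is taken as 1 so the term stays finite.
    """
    if not assignments:
        return 0.0
    max_int = spec.max_intensity
    prec_mz = spec.precursor_ion_mz
    total = 0.0
    for a in assignments:
        rel_mass = a.peak.mz / prec_mz
        rel_int = a.peak.intensity / max_int
        denom = a.matched_bde**w.gamma if a.matched_bde > 0 else 1.0
        total += rel_mass**w.alpha * rel_int**w.beta / denom
    return total


def normalize_terms(values: list[float]) -> list[float]:
    """Divide by the list maximum; an all-zero list stays all zero."""
    if any(v < 0 for v in values):
        raise ValueError("raw scores must be non-negative")
    m = max(values, default=0.0)
    if m == 0:
        return [0.0 for _ in values]
    return [v / m for v in values]


def combine_final(terms: dict[str, float], w: WeightConfig) -> float:
    """Weighted sum of normalized terms; missing terms contribute 0."""
    total = 0.0
    for name, weight in w.weights.items():
        if weight < 0:
            raise ValueError(f"negative weight for term {name!r}")
        if name not in terms:
            log.warning("score term %r missing; contributes 0", name)
            continue
        total += weight * terms[name]
    return total


def substructure_match_count(structure, patterns: list[str]) -> int:
    """Number of SMARTS patterns present in the structure.

    Each pattern contributes at most 1, however many times it occurs;
    overlapping patterns are counted independently.
    """
    from rdkit import Chem

    if structure.mol is None:
        raise ValueError("structure has no toolkit molecule attached")
    count = 0
    for p in patterns:
        q = Chem.MolFromSmarts(p)
        if q is None:
            raise ValueError(f"invalid SMARTS pattern: {p!r}")
        if structure.mol.HasSubstructMatch(q):
            count += 1
    return count


def inclusion_score(counts: list[int]) -> list[float]:
    """Match counts over the list maximum; all zero if the maximum is 0."""
    return normalize_terms([float(c) for c in counts])


def exclusion_score(counts: list[int], n_patterns: int) -> list[float]:
    """(n - N) over the maximum of (n - N'); all zero if that maximum is 0."""
    return normalize_terms([float(n_patterns - c) for c in counts])


def combined_reference_count(
    counts: dict[str, float], selected_sources: tuple[str, ...]
) -> float:
    """Cumulative reference term: sum of the selected source counts.

    Selection is binary per source; absent properties count as 0.
    """
    if not selected_sources:
        raise ValueError("at least one reference source must be selected")
    return float(sum(float(counts.get(src, 0) or 0) for src in selected_sources))


def combined_reference_score(
    per_candidate_counts: list[dict[str, float]], selected_sources: tuple[str, ...]
) -> tuple[list[float], list[float]]:
    """Raw cumulative counts and their max-normalized scores per candidate."""
    raw = [
        combined_reference_count(c, selected_sources) for c in per_candidate_counts
    ]
    return raw, normalize_terms(raw)


def suspect_score(first_block: str, suspects: frozenset[str] | set[str]) -> int:
    """1 iff the candidate's InChIKey first block appears in the suspect set."""
    return 1 if first_block in suspects else 0


def fit_rt_model(
    training: list[tuple[float, float]],
    sigma: float = RT_SIGMA_DEFAULT,
    logp_source: str = "internal",
) -> RTModel:
    """Ordinary least squares fit of log P = a * RT + b.

    At least two distinct retention times are required; below ten points a
    warning is emitted since the calibration becomes unreliable.
    """
    if len(training) < 2:
        raise ValueError("RT calibration needs at least two (RT, logP) pairs")
    rts = np.array([t[0] for t in training], dtype=float)
    logps = np.array([t[1] for t in training], dtype=float)
    if np.ptp(rts) == 0:
        raise ValueError("all retention times identical; cannot fit a line")
    if len(training) < 10:
        warnings.warn(
            f"only {len(training)} RT calibration points; "
            "at least ten are recommended",
            stacklevel=2,
        )
    slope, intercept = np.polyfit(rts, logps, 1)
    return RTModel(float(slope), float(intercept), sigma, logp_source)


def rt_score_from_logp(
    logp_predicted: float, logp_candidate: float, sigma: float = RT_SIGMA_DEFAULT
) -> float:
    """Gaussian density of the |predicted - candidate| log P deviation."""
    dev = abs(logp_predicted - logp_candidate)
    return math.exp(-(dev**2) / (2 * sigma**2)) / (sigma * math.sqrt(2 * math.pi))


def rt_score(m: RTModel, rt_unknown: float, logp_candidate: float) -> float:
    """Retention score of a candidate for a spectrum measured at rt_unknown."""
    return rt_score_from_logp(m.predict_logp(rt_unknown), logp_candidate, m.sigma)


def compute_logp(structure) -> float:
    """Internal octanol-water partition estimate (Crippen) from the structure."""
    from rdkit.Chem import Crippen

    if structure.mol is None:
        raise ValueError("structure has no toolkit molecule attached")
    return float(Crippen.MolLogP(structure.mol))


def attach_user_scores(
    results, score_columns: list[str]
) -> dict[str, list[float]]:
    """Extract user-defined score columns from a results table.

    ``results`` is a pandas DataFrame (e.g. a re-imported pipe-separated
    results file).  Each named column becomes one raw term vector, to be
    normalized and weighted like any built-in term.
    """
    out: dict[str, list[float]] = {}
    for col in score_columns:
        if col not in results.columns:
            raise ValueError(f"user score column {col!r} not found in results")
        values = []
        for idx, v in results[col].items():
            try:
                values.append(float(v))
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {v!r} in column {col!r}, row {idx}"
                ) from None
        out[col] = values
    return out
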