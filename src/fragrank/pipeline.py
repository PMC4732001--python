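"""End-to-end orchestration: load, filter, fragment, match, score, rank.

Stage order: read candidates -> precursor selection -> unconnected filter
-> element filter -> substructure filter -> suspect-inclusion filter ->
fragmentation + peak matching + fragmenter score -> auxiliary scores
(references, retention time, substructure, suspects, user columns) ->
per-term normalization -> weighted combination -> InChIKey first-block
deduplication -> ranking -> output.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import pandas as pd

from .candidates import (
    CandidateRecord,
    ParameterSet,
    read_candidates,
    results_frame,
    select_candidates,
    write_results,
)
from .filters import (
    ElementFilterSpec,
    dedupe_first_block,
    filter_elements,
    filter_substructures,
    filter_unconnected,
    read_suspect_list,
    suspect_inclusion_filter,
)
from .fragments import BDETable, generate_fragments
from .scoring import (
    RT_SIGMA_DEFAULT,
    WeightConfig,
    combined_reference_count,
    compute_logp,
    exclusion_score,
    fit_rt_model,
    fragmenter_score,
    inclusion_score,
    normalize_terms,
    rt_score,
    substructure_match_count,
    suspect_score,
)
from .spectra import (
    MatchSettings,
    Spectrum,
    get_precursor_type,
    match_peaks,
    read_peak_list,
)

log = logging.getLogger("fragrank")


@dataclass
class RunReport:
    """Stage-by-stage bookkeeping of one pipeline run."""

    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    parameters: dict[str, str] = field(default_factory=dict)
    elapsed_seconds: float = 0.0


def _split_list(value: str | None) -> list[str]:
    if not value:
        return []
    return [v.strip() for v in value.split(",") if v.strip()]


def read_rt_training(
    path: str, logp_column: str | None = None
) -> tuple[list[tuple[float, float]], str]:
    """Read an RT calibration table.

    The file must have a ``RetentionTime`` column plus either the named
    logP column (e.g. ``UserLogP``) or an ``InChI`` column from which
    log P is computed internally.  Returns the pairs and the tag of the
    log P source used.
    """
    from .chem import parse_structure

    df = pd.read_csv(path, sep=None, engine="python")
    if "RetentionTime" not in df.columns:
        raise ValueError(f"{path}: missing 'RetentionTime' column")
    if logp_column and logp_column in df.columns:
        pairs = [
            (float(rt), float(lp))
            for rt, lp in zip(df["RetentionTime"], df[logp_column])
        ]
        return pairs, logp_column
    if "InChI" in df.columns:
        pairs = [
            (float(rt), compute_logp(parse_structure(str(inchi))))
            for rt, inchi in zip(df["RetentionTime"], df["InChI"])
        ]
        return pairs, "internal"
    raise ValueError(
        f"{path}: need either a {logp_column or 'UserLogP'!r} or an 'InChI' column"
    )


def _candidate_logp(record: CandidateRecord, source: str) -> float | None:
    if source == "internal":
        return compute_logp(record.structure)
    value = record.properties.get(source)
    if value in (None, ""):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def run_pipeline(params: ParameterSet) -> tuple[list[CandidateRecord], RunReport]:
    """Execute the full identification workflow for one spectrum."""
    t0 = time.perf_counter()
    report = RunReport(parameters=dict(params.raw))

    weights = params.score_weights()
    wconf = WeightConfig(weights)
    settings = MatchSettings(params.match_ppm, params.match_da)
    ptype = get_precursor_type(params.precursor_ion_type)
    table = BDETable.default()

    peaks = read_peak_list(params.get("PeakListPath"))
    candidates = read_candidates(
        params.get("LocalDatabasePath"),
        {"LocalCSV": "CSV", "LocalSDF": "SDF"}.get(params.get("DatabaseType", "")),
    )
    report.counts["loaded"] = len(candidates)

    spec = params.precursor_spec()
    candidates = select_candidates(candidates, spec)
    report.counts["selected"] = len(candidates)

    candidates = filter_unconnected(candidates)
    report.counts["after_unconnected_filter"] = len(candidates)

    efilter = ElementFilterSpec(
        only=frozenset(_split_list(params.get("FilterOnlyElements"))) or None,
        must=frozenset(_split_list(params.get("FilterIncludedElements"))) or None,
        exclude=frozenset(_split_list(params.get("FilterExcludedElements"))) or None,
    )
    candidates = filter_elements(candidates, efilter)
    report.counts["after_element_filter"] = len(candidates)

    candidates = filter_substructures(
        candidates,
        _split_list(params.get("FilterSmartsInclusionList")),
        _split_list(params.get("FilterSmartsExclusionList")),
    )
    report.counts["after_substructure_filter"] = len(candidates)

    filter_suspect_paths = _split_list(params.get("FilterSuspectLists"))
    if filter_suspect_paths:
        blocks: set[str] = set()
        for p in filter_suspect_paths:
            blocks |= read_suspect_list(p)
        candidates = suspect_inclusion_filter(candidates, frozenset(blocks))
    report.counts["after_suspect_filter"] = len(candidates)

    if not candidates:
        msg = "no candidates left after filtering; writing empty results"
        log.warning(msg)
        report.warnings.append(msg)

    if candidates:
        # precursor mass for the spectrum: the specified neutral mass when
        # given, else each candidate's own mass defines RelMass scaling.
        base_mass = spec.neutral_mass
        for cand in candidates:
            spectrum = Spectrum(
                peaks=list(peaks),
                neutral_precursor_mass=base_mass or cand.monoisotopic_mass,
                precursor_type=ptype,
            )
            frags = generate_fragments(cand.structure, params.tree_depth, table)
            assignments = match_peaks(
                spectrum, frags, settings, structure=cand.structure
            )
            cand.score_terms["FragmenterScore"] = fragmenter_score(
                assignments, spectrum, wconf
            )
            cand.score_terms["NoExplPeaks"] = float(len(assignments))

    _auxiliary_scores(candidates, params, wconf)
    _combine(candidates, wconf)
    report.counts["scored"] = len(candidates)

    candidates = dedupe_first_block(candidates)
    report.counts["after_dedupe"] = len(candidates)

    candidates.sort(key=lambda c: (-c.final_score, c.identifier))

    out_path = params.get("ResultsPath")
    if out_path:
        write_results(candidates, out_path, params.get("ResultsFormat", "CSV"))
    report.elapsed_seconds = time.perf_counter() - t0
    return candidates, report


def _auxiliary_scores(
    candidates: list[CandidateRecord], params: ParameterSet, wconf: WeightConfig
) -> None:
    if not candidates:
        return
    weights = wconf.weights

    if "CombinedReferenceScore" in weights:
        sources = tuple(
            _split_list(params.get("ReferenceSources"))
            or ["ChemSpiderReferenceCount"]
        )
        for c in candidates:
            c.score_terms["CombinedReferenceScore"] = combined_reference_count(
                {k: v for k, v in c.properties.items()}, sources
            )

    inc_patterns = _split_list(params.get("ScoreSmartsInclusionList"))
    if "SmartsSubstructureInclusionScore" in weights and inc_patterns:
        counts = [
            substructure_match_count(c.structure, inc_patterns) for c in candidates
        ]
        for c, s in zip(candidates, inclusion_score(counts)):
            c.score_terms["SmartsSubstructureInclusionScore"] = s

    exc_patterns = _split_list(params.get("ScoreSmartsExclusionList"))
    if "SmartsSubstructureExclusionScore" in weights and exc_patterns:
        counts = [
            substructure_match_count(c.structure, exc_patterns) for c in candidates
        ]
        for c, s in zip(candidates, exclusion_score(counts, len(exc_patterns))):
            c.score_terms["SmartsSubstructureExclusionScore"] = s

    if "SuspectListScore" in weights:
        blocks: set[str] = set()
        for p in _split_list(params.get("ScoreSuspectLists")):
            blocks |= read_suspect_list(p)
        for c in candidates:
            c.score_terms["SuspectListScore"] = float(
                suspect_score(c.first_block, blocks)
            )

    if "RetentionTimeScore" in weights:
        training_path = params.get("RetentionTimeTrainingFile")
        rt_value = params.get("ExperimentalRetentionTime")
        if not training_path or rt_value is None:
            raise ValueError(
                "RetentionTimeScore needs RetentionTimeTrainingFile and "
                "ExperimentalRetentionTime"
            )
        logp_col = params.get("UserLogPColumn")
        pairs, source = read_rt_training(training_path, logp_col)
        sigma = float(params.get("RetentionTimeSigma", str(RT_SIGMA_DEFAULT)))
        model = fit_rt_model(pairs, sigma=sigma, logp_source=source)
        for c in candidates:
            logp = _candidate_logp(c, source)
            if logp is None:
                log.warning(
                    "candidate %s lacks a %r log P value; RT score set to 0",
                    c.identifier,
                    source,
                )
                c.score_terms["RetentionTimeScore"] = 0.0
            else:
                c.score_terms["RetentionTimeScore"] = rt_score(
                    model, float(rt_value), logp
                )

    # any remaining weighted term that names a numeric candidate property
    # becomes a user-defined score column (e.g. UserLogP-derived scores,
    # external fragmenter probabilities, individual reference counts)
    builtin = {
        "FragmenterScore",
        "CombinedReferenceScore",
        "SmartsSubstructureInclusionScore",
        "SmartsSubstructureExclusionScore",
        "SuspectListScore",
        "RetentionTimeScore",
    }
    for term in weights:
        if term in builtin:
            continue
        for c in candidates:
            value = c.properties.get(term)
            if value in (None, ""):
                raise ValueError(
                    f"score term {term!r} missing for candidate {c.identifier}"
                )
            try:
                c.score_terms[term] = float(value)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {value!r} for score term {term!r} "
                    f"of candidate {c.identifier}"
                ) from None


def _combine(candidates: list[CandidateRecord], wconf: WeightConfig) -> None:
    from .scoring import combine_final

    if not candidates:
        return
    for term in wconf.weights:
        raw = [c.score_terms.get(term, 0.0) for c in candidates]
        for c, v in zip(candidates, normalize_terms(raw)):
            c.normalized_terms[term] = v
    for c in candidates:
        c.final_score = combine_final(c.normalized_terms, wconf)


def rescore(
    results_path: str,
    score_names: list[str],
    score_weights: list[float],
    out_path: str | None = None,
    sep: str = "|",
) -> pd.DataFrame:
    """Re-rank a previously written results table with new score columns.

    Implements the two-step workflow for externally computed scores
    (e.g. vendor log P models or another fragmenter's probabilities): run
    the pipeline, export, add columns, re-import pipe-separated and
    recombine without re-fragmenting.  Named columns that already exist in
    normalized form (``Normalized<name>``) are reused; raw columns are
    normalized to their maximum.
    """
    if len(score_names) != len(score_weights):
        raise ValueError("score names and weights differ in length")
    df = pd.read_csv(results_path, sep=sep)
    final = pd.Series(0.0, index=df.index)
    for name, weight in zip(score_names, score_weights):
        if weight < 0:
            raise ValueError(f"negative weight for term {name!r}")
        norm_col = "Normalized" + name
        if norm_col in df.columns:
            values = df[norm_col].astype(float)
        elif name in df.columns:
            raw = df[name].astype(float)
            if (raw < 0).any():
                raise ValueError(f"negative raw values in column {name!r}")
            m = raw.max()
            values = raw / m if m > 0 else raw * 0.0
            df[norm_col] = values
        else:
            raise ValueError(f"score column {name!r} not found in {results_path}")
        final = final + weight * values
    df["FinalScore"] = final
    df = df.sort_values(
        ["FinalScore", "Identifier"], ascending=[False, True]
    ).reset_index(drop=True)
    df["Rank"] = [
        1 + int((df["FinalScore"] > s).sum()) for s in df["FinalScore"]
    ]
    if out_path:
        df.to_csv(out_path, index=False, sep=sep)
    return df
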