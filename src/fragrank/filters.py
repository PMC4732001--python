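"""Candidate-list filters.

Structural filters (unconnected, element, substructure, suspect
inclusion) run before fragmentation; the InChIKey first-block
deduplication runs after scoring, keeping the best-scoring stereoisomer
per molecular skeleton.  All filters preserve input order and are
idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .chem import _VALID_SYMBOLS

log = logging.getLogger("fragrank")


@dataclass
class ElementFilterSpec:
    """Element restrictions on candidate formulas.

    ``only``: keep candidates composed solely of these elements (option a).
    ``must``: required elements (option b); ``exclude``: forbidden elements
    (option c).  ``must``/``exclude`` combine conjunctively; ``only`` is
    mutually exclusive with them.
    """

    only: frozenset[str] | None = None
    must: frozenset[str] | None = None
    exclude: frozenset[str] | None = None

    def __post_init__(self):
        if self.only is not None and (self.must or self.exclude):
            raise ValueError(
                "'only' element mode cannot be combined with must/exclude"
            )
        if self.must and self.exclude and set(self.must) & set(self.exclude):
            raise ValueError("must and exclude element sets overlap")
        for group in (self.only, self.must, self.exclude):
            for el in group or ():
                if el not in _VALID_SYMBOLS:
                    raise ValueError(f"unknown element symbol in filter: {el!r}")

    @property
    def is_empty(self) -> bool:
        return not (self.only or self.must or self.exclude)


def filter_unconnected(candidates: list) -> list:
    """Drop salts and other multi-component structures."""
    from .chem import is_connected

    kept = [c for c in candidates if is_connected(c.structure)]
    dropped = len(candidates) - len(kept)
    if dropped:
        log.info("unconnected filter removed %d candidate(s)", dropped)
    return kept


def filter_elements(candidates: list, spec: ElementFilterSpec) -> list:
    if spec.is_empty:
        return list(candidates)
    kept = []
    for c in candidates:
        elements = set(c.formula.as_dict())
        if spec.only is not None:
            ok = elements <= set(spec.only)
        else:
            ok = True
            if spec.must:
                ok = ok and set(spec.must) <= elements
            if spec.exclude:
                ok = ok and not (elements & set(spec.exclude))
        if ok:
            kept.append(c)
    return kept


def filter_substructures(
    candidates: list, include: list[str], exclude: list[str]
) -> list:
    """Keep candidates matching any include SMARTS and no exclude SMARTS."""
    from rdkit import Chem

    inc = [(p, Chem.MolFromSmarts(p)) for p in include]
    exc = [(p, Chem.MolFromSmarts(p)) for p in exclude]
    for p, q in inc + exc:
        if q is None:
            raise ValueError(f"invalid SMARTS pattern: {p!r}")
    kept = []
    for c in candidates:
        mol = c.structure.mol
        if inc and not any(mol.HasSubstructMatch(q) for _, q in inc):
            continue
        if any(mol.HasSubstructMatch(q) for _, q in exc):
            continue
        kept.append(c)
    return kept


def suspect_inclusion_filter(candidates: list, suspects: frozenset[str]) -> list:
    """Keep only candidates whose InChIKey first block is in the suspect set."""
    if not suspects:
        log.warning("suspect inclusion filter enabled with an empty suspect set")
    return [c for c in candidates if c.first_block in suspects]


def dedupe_first_block(scored_candidates: list) -> list:
    """One candidate per InChIKey first block: the highest final score.

    Ties break on ascending identifier for determinism.  Output preserves
    the input order of the retained records.
    """
    best: dict[str, object] = {}
    for c in scored_candidates:
        cur = best.get(c.first_block)
        if (
            cur is None
            or c.final_score > cur.final_score
            or (c.final_score == cur.final_score and c.identifier < cur.identifier)
        ):
            best[c.first_block] = c
    chosen = set(id(c) for c in best.values())
    return [c for c in scored_candidates if id(c) in chosen]


def read_suspect_list(path: str) -> frozenset[str]:
    """Load InChIKeys (full or first block only), one per line, to a block set."""
    blocks = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            blocks.add(line.split("-")[0][:14].upper())
    return frozenset(blocks)
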