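"""Ranking metrics for benchmarking identification performance.

Ranks are reported pessimistically (ties count against the correct
candidate), as expected ranks (ties broken uniformly at random), and as
the relative ranking position (RRP), where 1 is the best possible
position in the list and 0 the worst.  A seeded uniform sampler over the
weight simplex supports searching for good term-weight combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger("fragrank")


@dataclass(frozen=True)
class RankResult:
    pessimistic_rank: int
    expected_rank: float
    rrp: float
    total_candidates: int


def _partition(scores: dict[str, float], correct: str) -> tuple[int, int, int]:
    if correct not in scores:
        raise ValueError(f"correct candidate {correct!r} not in score list")
    s = scores[correct]
    better = sum(v > s for v in scores.values())
    tied = sum(v == s for v in scores.values())  # includes the correct one
    worse = len(scores) - better - tied
    return better, tied, worse


def pessimistic_rank(scores: dict[str, float], correct: str) -> int:
    """Worst rank of the correct candidate over all tie orderings."""
    better, tied, _ = _partition(scores, correct)
    return better + tied


def expected_rank(scores: dict[str, float], correct: str) -> float:
    """Mean rank under uniformly random ordering of tied candidates."""
    better, tied, _ = _partition(scores, correct)
    return better + (tied + 1) / 2


def relative_ranking_position(scores: dict[str, float], correct: str) -> float:
    """RRP in [0, 1]: 0.5 * (1 + (worse - better) / (total - 1)).

    Ties count in neither the better nor the worse group.  A single-item
    list has only one possible position and scores 1.
    """
    better, _, worse = _partition(scores, correct)
    total = len(scores)
    if total < 2:
        log.warning("RRP of a single-candidate list is trivially 1")
        return 1.0
    return 0.5 * (1 + (worse - better) / (total - 1))


def rank_result(scores: dict[str, float], correct: str) -> RankResult:
    return RankResult(
        pessimistic_rank(scores, correct),
        expected_rank(scores, correct),
        relative_ranking_position(scores, correct),
        len(scores),
    )


def topk_counts(ranks: list[float], ks: list[int]) -> dict[int, int]:
    """Number of queries ranked at or better than each threshold k."""
    if any(r < 1 for r in ranks):
        raise ValueError("ranks must be >= 1")
    return {k: sum(r <= k for r in ranks) for k in ks}


def sample_weight_simplex(
    n_terms: int, n_draws: int, seed: int
) -> np.ndarray:
    """Uniform draws from the standard simplex (weights summing to one).

    Uses the sorted-uniform-spacings construction, equivalent to a flat
    Dirichlet; reproducible for a fixed seed.
    """
    if n_terms < 2 or n_draws < 1:
        raise ValueError("need n_terms >= 2 and n_draws >= 1")
    rng = np.random.default_rng(seed)
    cuts = np.sort(rng.random((n_draws, n_terms - 1)), axis=1)
    padded = np.hstack(
        [np.zeros((n_draws, 1)), cuts, np.ones((n_draws, 1))]
    )
    return np.diff(padded, axis=1)


def weight_sweep_topk(
    term_scores: list[dict[str, dict[str, float]]],
    correct_ids: list[str],
    term_names: list[str],
    n_draws: int,
    seed: int,
    ks: list[int] = [1, 5, 10],
) -> list[tuple[np.ndarray, dict[int, int]]]:
    """Re-rank each query under randomly drawn weight vectors.

    ``term_scores[q][candidate][term]`` holds normalized term values for
    query q.  Returns, per drawn weight vector, the Top-k counts of the
    correct candidates' pessimistic ranks.
    """
    draws = sample_weight_simplex(len(term_names), n_draws, seed)
    out = []
    for w in draws:
        ranks = []
        for per_cand, correct in zip(term_scores, correct_ids):
            finals = {
                cid: float(sum(wi * terms.get(t, 0.0) for wi, t in zip(w, term_names)))
                for cid, terms in per_cand.items()
            }
            ranks.append(pessimistic_rank(finals, correct))
        out.append((w, topk_counts(ranks, ks)))
    return out
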