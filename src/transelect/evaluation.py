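"""Metrics for the two tasks: gate classification and enzyme selection.

Selection quality is judged the way a bench chemist would: did the k enzymes
the model would have you test include any of the experimentally co-best
enzymes (tie-aware top-k accuracy), and how much ee was left on the table by
trusting the single top-ranked enzyme (regret, bounded above by the spread
between the best and worst observed ee).  The naive baseline always proposes
the k enzymes that are most frequently top-performing across the dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Sentinel for a regret that cannot be evaluated (rank-1 enzyme's ee unmeasured).
UNDEFINED = None


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based (Mann-Whitney) AUROC with average ranks for tied scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both classes must be present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class SubstrateRanking:
    """Enzymes ordered best-predicted-first by DDG, ties broken lexically."""

    substrate_id: str
    enzyme_order: tuple[str, ...]
    predicted_ddg: Mapping[str, float]

    @staticmethod
    def from_predictions(
        substrate_id: str, predicted_ddg: Mapping[str, float]
    ) -> "SubstrateRanking":
        ties = len(set(predicted_ddg.values())) < len(predicted_ddg)
        if ties:
            logger.info(
                "substrate %s: predicted-DDG ties broken by enzyme_id order",
                substrate_id,
            )
        order = tuple(sorted(predicted_ddg, key=lambda e: (-predicted_ddg[e], e)))
        return SubstrateRanking(substrate_id, order, dict(predicted_ddg))


@dataclass(frozen=True)
class ObservedTopSet:
    """Enzymes sharing the maximum measured ee within the tie tolerance."""

    substrate_id: str
    enzymes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.enzymes:
            raise ValueError("observed top set must be non-empty")


def observed_top_set(
    ee_by_enzyme: Mapping[str, float | None],
    tie_tolerance: float = 0.0,
    substrate_id: str = "",
) -> ObservedTopSet:
    """{e : ee_e >= max(ee) - tol} over measured enzymes only."""
    measured = {e: v for e, v in ee_by_enzyme.items() if v is not None}
    if not measured:
        raise ValueError(
            f"substrate {substrate_id!r}: no measured ee; exclude upstream"
        )
    best = max(measured.values())
    return ObservedTopSet(
        substrate_id,
        frozenset(e for e, v in measured.items() if v >= best - tie_tolerance),
    )


def topk_success(ranking: SubstrateRanking, top_set: ObservedTopSet, k: int) -> int:
    """1 iff any experimentally co-best enzyme is among the k first-ranked."""
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, len(ranking.enzyme_order))
    return int(bool(set(ranking.enzyme_order[:k]) & top_set.enzymes))


def topk_accuracy(
    rankings: Sequence[SubstrateRanking],
    top_sets: Sequence[ObservedTopSet],
    k: int,
) -> float:
    """Mean top-k success over substrates; non-decreasing in k, 1 at k=panel."""
    if not rankings:
        raise ValueError("at least one substrate required")
    if len(rankings) != len(top_sets):
        raise ValueError("rankings and top sets must align")
    return float(
        np.mean([topk_success(r, t, k) for r, t in zip(rankings, top_sets)])
    )


def regret(
    ranking: SubstrateRanking, ee_by_enzyme: Mapping[str, float | None]
) -> float | None:
    """Best measured ee minus the rank-1 enzyme's measured ee (percent).

    0 when the rank-1 enzyme is itself co-best; UNDEFINED (None, excluded
    from aggregates) when the rank-1 enzyme's ee was not measured.
    """
    measured = {e: v for e, v in ee_by_enzyme.items() if v is not None}
    if not measured:
        raise ValueError("regret needs at least one measured ee")
    rank1 = ranking.enzyme_order[0]
    if rank1 not in measured:
        logger.info(
            "substrate %s: rank-1 enzyme %s has unmeasured ee; regret UNDEFINED",
            ranking.substrate_id,
            rank1,
        )
        return UNDEFINED
    return float(max(measured.values()) - measured[rank1])


def max_possible_regret(ee_by_enzyme: Mapping[str, float | None]) -> float:
    """Spread between the highest and lowest measured ee for a substrate."""
    measured = [v for v in ee_by_enzyme.values() if v is not None]
    if not measured:
        raise ValueError("max possible regret needs at least one measured ee")
    return float(max(measured) - min(measured))


def naive_topk_baseline(
    top_sets: Sequence[ObservedTopSet], k: int, panel_enzyme_ids: Sequence[str] | None = None
) -> list[str]:
    """The k enzymes most frequently found in observed top sets.

    Frequency ties break by enzyme_id lexical order (logged).  Enzymes never
    observed on top get frequency 0 (requires `panel_enzyme_ids` to surface
    them when k exceeds the number of ever-top enzymes).
    """
    if not top_sets:
        raise ValueError("at least one training substrate required")
    counts: dict[str, int] = {e: 0 for e in (panel_enzyme_ids or [])}
    for ts in top_sets:
        for e in ts.enzymes:
            counts[e] = counts.get(e, 0) + 1
    ordered = sorted(counts, key=lambda e: (-counts[e], e))
    values = sorted(counts.values(), reverse=True)
    if len(values) > 1 and len(set(values)) < len(values):
        logger.info("naive baseline: frequency ties broken by enzyme_id order")
    return ordered[:k]
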