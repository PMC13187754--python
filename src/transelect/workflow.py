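"""The connected two-stage enzyme-selection workflow.

Stage 1 gates each enzyme of the panel with its conversion classifier
(will this substrate exceed 25% conversion?).  Stage 2 ranks only the
gate-positive enzymes by predicted DDG, descending; the top-ranked enzyme is
the recommendation.  A substrate whose gates are all negative is predicted
non-reactive and no enzyme is proposed.  When the product's required
stereochemistry is known, the panel can first be constrained to the S- or
R-selective subset.

Against experimental data each substrate's outcome is classified:

* reactive branch (some enzyme experimentally exceeded the conversion
  threshold): ideal if the top-ranked enzyme gave >25% conversion with <1% ee
  regret; acceptable if the second-ranked enzyme did when the first did not;
  poor otherwise.
* unsuccessful branch (no enzyme exceeded the threshold): ideal with 0
  positive gate predictions, acceptable with 1 or 2, poor with more than 2.

Robustness is probed by perturbing the measured endpoints with bounded
uniform noise (up to +-5% conversion, +-1% ee) and re-classifying on fixed
model predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .evaluation import SubstrateRanking, regret as regret_metric
from .io import EnzymePanel, RunConfig, ValidationError
from .models import ConversionModel, SelectivityModel, predict_ddg

REGRET_IDEAL_CUTOFF = 1.0  # percent ee, strict "<"


@dataclass(frozen=True)
class SelectionReport:
    """Two-stage output for one substrate."""

    substrate_id: str
    gate_predictions: Mapping[str, int]   # enzyme -> {0, 1}
    ranking: SubstrateRanking             # over gate-positive enzymes only
    chosen_enzyme: str | None             # None iff no gate is positive
    constraint: str = "none"              # none | S_only | R_only

    @property
    def n_positive(self) -> int:
        return int(sum(self.gate_predictions.values()))


@dataclass(frozen=True)
class OutcomeClass:
    label: str      # ideal | acceptable | poor
    branch: str     # reactive | unsuccessful
    rationale: str


def two_stage_select(
    substrate_id: str,
    feature_row,
    conversion_models: Mapping[str, ConversionModel],
    selectivity_models: Mapping[str, SelectivityModel],
    panel: EnzymePanel,
    constraint: str = "none",
) -> SelectionReport:
    """Gate every (constraint-allowed) enzyme, then rank the positives by DDG."""
    if constraint not in ("none", "S_only", "R_only"):
        raise ValueError(f"unknown constraint {constraint!r}")
    if constraint == "none":
        enzymes = panel.enzyme_ids
    else:
        enzymes = panel.subset(constraint[0]).enzyme_ids
        if not enzymes:
            raise ValidationError(
                f"constraint {constraint!r} removes every enzyme from the panel"
            )
    gates: dict[str, int] = {}
    for e in enzymes:
        if e not in conversion_models or e not in selectivity_models:
            raise KeyError(f"models missing for panel enzyme {e!r}")
        gates[e] = int(conversion_models[e].predict(_as_matrix(feature_row, conversion_models[e]))[0])
    positives = [e for e in enzymes if gates[e] == 1]
    predicted = {
        e: predict_ddg(selectivity_models[e], _as_row(feature_row)).value
        for e in positives
    }
    ranking = SubstrateRanking.from_predictions(substrate_id, predicted)
    chosen = ranking.enzyme_order[0] if positives else None
    return SelectionReport(
        substrate_id=substrate_id,
        gate_predictions=gates,
        ranking=ranking,
        chosen_enzyme=chosen,
        constraint=constraint,
    )


def _as_row(feature_row):
    return feature_row


def _as_matrix(feature_row, model: ConversionModel) -> np.ndarray:
    import pandas as pd

    names = getattr(model, "feature_names", None)
    if isinstance(feature_row, pd.Series):
        if names:
            feature_row = feature_row[names]
        return feature_row.to_numpy(dtype=float)[None, :]
    return np.asarray(feature_row, dtype=float)[None, :]


def classify_outcome(
    report: SelectionReport,
    experimental: Mapping[str, tuple[float, float | None]],  # enzyme -> (conversion, ee)
    config: RunConfig | None = None,
) -> OutcomeClass:
    """Classify a substrate's workflow outcome against experiment.

    `experimental` must cover every panel enzyme the report considered; ee may
    be None (unmeasured).  Regret for rank-2 is computed against the same
    substrate-level observed maximum as for rank-1.
    """
    config = config or RunConfig()
    threshold = config.conversion_threshold
    conversions = {e: c for e, (c, _) in experimental.items()}
    ees = {e: ee for e, (_, ee) in experimental.items()}

    reactive = any(c > threshold for c in conversions.values())
    if not reactive:
        n_pos = report.n_positive
        if n_pos == 0:
            return OutcomeClass("ideal", "unsuccessful",
                                "non-reactive substrate, all gates negative")
        if n_pos <= 2:
            return OutcomeClass("acceptable", "unsuccessful",
                                f"non-reactive substrate, {n_pos} positive gate(s)")
        return OutcomeClass("poor", "unsuccessful",
                            f"non-reactive substrate, {n_pos} positive gates")

    if report.chosen_enzyme is None:
        return OutcomeClass("poor", "reactive", "false negative gate")

    measured = {e: v for e, v in ees.items() if v is not None}

    def rank_passes(enzyme: str) -> bool:
        if conversions[enzyme] <= threshold:
            return False
        if not measured:
            return False
        if enzyme not in measured:
            return False  # regret undefined -> cannot certify < 1% regret
        r = max(measured.values()) - measured[enzyme]
        return r < REGRET_IDEAL_CUTOFF

    order = report.ranking.enzyme_order
    if rank_passes(order[0]):
        return OutcomeClass("ideal", "reactive",
                            "rank-1 enzyme exceeded the gate with <1% ee regret")
    if len(order) > 1 and rank_passes(order[1]):
        return OutcomeClass("acceptable", "reactive",
                            "rank-2 enzyme exceeded the gate with <1% ee regret")
    return OutcomeClass("poor", "reactive",
                        "neither top-2 enzyme achieved an ideal outcome")


def perturb_and_reclassify(
    reports: Sequence[SelectionReport],
    experimental: Mapping[str, Mapping[str, tuple[float, float | None]]],
    conversion_halfwidth: float = 5.0,
    ee_halfwidth: float = 1.0,
    n_reps: int = 100,
    seed: int = 0,
    config: RunConfig | None = None,
) -> np.ndarray:
    """Noise-robustness of the outcome labels on fixed model predictions.

    Per replicate, adds independent uniform(-a, +a) noise to every measured
    conversion and uniform(-b, +b) to every measured ee (both clamped to
    [0, 100]), re-runs :func:`classify_outcome`, and reports the fraction of
    substrates whose label changed.  Seeded and reproducible.
    """
    if conversion_halfwidth < 0 or ee_halfwidth < 0:
        raise ValueError("noise half-widths must be >= 0")
    config = config or RunConfig()
    base = {
        r.substrate_id: classify_outcome(r, experimental[r.substrate_id], config).label
        for r in reports
    }
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_reps)
    for rep in range(n_reps):
        changed = 0
        for r in reports:
            perturbed: dict[str, tuple[float, float | None]] = {}
            for e, (conv, ee) in experimental[r.substrate_id].items():
                conv_p = float(np.clip(
                    conv + rng.uniform(-conversion_halfwidth, conversion_halfwidth),
                    0.0, 100.0))
                ee_p = None if ee is None else float(np.clip(
                    ee + rng.uniform(-ee_halfwidth, ee_halfwidth), 0.0, 100.0))
                perturbed[e] = (conv_p, ee_p)
            if classify_outcome(r, perturbed, config).label != base[r.substrate_id]:
                changed += 1
        fractions[rep] = changed / len(reports)
    return fractions
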