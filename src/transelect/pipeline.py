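"""Orchestration: from a reaction table and feature table to fitted
per-enzyme models, leave-one-ketone-out predictions, rankings and the
model-vs-baseline top-k comparison.

This is the glue the CLI, the examples and the benchmark evaluations share;
the science lives in :mod:`models`, :mod:`evaluation` and :mod:`workflow`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import (
    ObservedTopSet,
    SubstrateRanking,
    max_possible_regret,
    naive_topk_baseline,
    observed_top_set,
    regret,
    topk_accuracy,
)
from .io import EnzymePanel, FeatureTable, ReactionOutcome, RunConfig
from .models import (
    ConstantConversionModel,
    ConversionModel,
    DegenerateTrainingError,
    SelectivityModel,
    binarize_conversion,
    drop_unmeasured_ee,
    forward_mvlr_select,
    loocv,
    train_conversion_classifier,
)
from .thermo import ee_to_ddg


def reactions_by_enzyme(
    reactions: Sequence[ReactionOutcome],
) -> dict[str, list[ReactionOutcome]]:
    out: dict[str, list[ReactionOutcome]] = {}
    for r in reactions:
        out.setdefault(r.enzyme_id, []).append(r)
    return out


def ee_by_enzyme_for_substrate(
    reactions: Sequence[ReactionOutcome], substrate_id: str
) -> dict[str, float | None]:
    return {
        r.enzyme_id: r.ee for r in reactions if r.substrate_id == substrate_id
    }


def selectivity_training_data(
    enzyme_reactions: Sequence[ReactionOutcome],
    features: FeatureTable,
    config: RunConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(X, y, substrate_ids) for one enzyme: measured-ee rows only, y = DDG."""
    config = config or RunConfig()
    kept = drop_unmeasured_ee(enzyme_reactions)
    sids = [r.substrate_id for r in kept]
    X = features.df.loc[sids].to_numpy(dtype=float)
    y = np.array(
        [ee_to_ddg(r.ee, config.temperature_reaction).value for r in kept]
    )
    return X, y, sids


def fit_selectivity_models(
    reactions: Sequence[ReactionOutcome],
    features: FeatureTable,
    panel: EnzymePanel,
    config: RunConfig | None = None,
) -> dict[str, SelectivityModel]:
    """Forward-MVLR model per enzyme, trained on all its measured rows."""
    config = config or RunConfig()
    by_enzyme = reactions_by_enzyme(reactions)
    out: dict[str, SelectivityModel] = {}
    for e in panel.enzyme_ids:
        X, y, _ = selectivity_training_data(by_enzyme.get(e, []), features, config)
        if len(y) < 5:
            warnings.warn(f"enzyme {e!r}: only {len(y)} measured rows; skipped")
            continue
        out[e] = forward_mvlr_select(
            X, y, feature_names=features.feature_names, enzyme_id=e
        )
    return out


def fit_conversion_models(
    reactions: Sequence[ReactionOutcome],
    features: FeatureTable,
    panel: EnzymePanel,
    config: RunConfig | None = None,
):
    """RF gate per enzyme; single-class enzymes get a constant gate + warning."""
    config = config or RunConfig()
    by_enzyme = reactions_by_enzyme(reactions)
    out: dict[str, ConversionModel | ConstantConversionModel] = {}
    for e in panel.enzyme_ids:
        rows = by_enzyme.get(e, [])
        sids = [r.substrate_id for r in rows]
        sub = FeatureTable(features.df.loc[sids], features.tag)
        labels = [binarize_conversion(r.conversion, config.conversion_threshold)
                  for r in rows]
        try:
            out[e] = train_conversion_classifier(sub, labels, config, enzyme_id=e)
        except DegenerateTrainingError:
            constant = labels[0] if labels else 0
            warnings.warn(
                f"enzyme {e!r}: single-class conversion labels; constant gate "
                f"prediction {constant}"
            )
            out[e] = ConstantConversionModel(enzyme_id=e, constant_class=constant)
    return out


def loocv_ddg_predictions(
    reactions: Sequence[ReactionOutcome],
    features: FeatureTable,
    panel: EnzymePanel,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Substrates x enzymes matrix of predicted DDG, leakage-free.

    For substrates inside an enzyme's training set the prediction is that
    substrate's held-out LOOCV fold; substrates the enzyme never saw
    (censored ee) are predicted by the enzyme's full model — it was trained
    without them anyway.
    """
    config = config or RunConfig()
    by_enzyme = reactions_by_enzyme(reactions)
    all_sids = features.substrate_ids
    preds = pd.DataFrame(np.nan, index=all_sids, columns=panel.enzyme_ids)
    for e in panel.enzyme_ids:
        X, y, sids = selectivity_training_data(by_enzyme.get(e, []), features, config)
        if len(y) < 5 or np.ptp(y) == 0:
            warnings.warn(f"enzyme {e!r}: unusable selectivity training set; skipped")
            continue

        def trainer(Xtr, ytr):
            return forward_mvlr_select(
                Xtr, ytr, feature_names=features.feature_names, enzyme_id=e
            )

        result = loocv(X, y, trainer, metric="r2", substrate_ids=sids)
        preds.loc[sids, e] = result.predictions
        full_model = forward_mvlr_select(
            X, y, feature_names=features.feature_names, enzyme_id=e
        )
        unseen = [s for s in all_sids if s not in sids]
        if unseen:
            preds.loc[unseen, e] = [
                full_model.predict_raw(features.row(s)) for s in unseen
            ]
    return preds


@dataclass(frozen=True)
class SelectivityBenchmark:
    """Tie-aware top-k curve for the model and the naive frequency baseline."""

    topk_model: dict[int, float]
    topk_baseline: dict[int, float]
    regrets: dict[str, float | None]
    max_regrets: dict[str, float]
    n_substrates_scored: int


def benchmark_selectivity(
    reactions: Sequence[ReactionOutcome],
    features: FeatureTable,
    panel: EnzymePanel,
    config: RunConfig | None = None,
    ks: Sequence[int] | None = None,
) -> SelectivityBenchmark:
    """LOOCV top-k accuracy of DDG ranking vs the k-most-frequent baseline.

    Substrates with no measured ee at all are excluded from scoring (their
    count is len(features) - n_substrates_scored).
    """
    config = config or RunConfig()
    ks = list(ks) if ks is not None else list(range(1, len(panel) + 1))
    preds = loocv_ddg_predictions(reactions, features, panel, config)

    rankings: list[SubstrateRanking] = []
    top_sets: list[ObservedTopSet] = []
    regrets: dict[str, float | None] = {}
    max_regrets: dict[str, float] = {}
    for sid in features.substrate_ids:
        ee_map = ee_by_enzyme_for_substrate(reactions, sid)
        if all(v is None for v in ee_map.values()):
            continue
        row = preds.loc[sid]
        ranking = SubstrateRanking.from_predictions(
            sid, {e: float(row[e]) for e in panel.enzyme_ids if np.isfinite(row[e])}
        )
        rankings.append(ranking)
        top_sets.append(observed_top_set(ee_map, config.tie_tolerance, sid))
        regrets[sid] = regret(ranking, ee_map)
        max_regrets[sid] = max_possible_regret(ee_map)

    topk_model = {k: topk_accuracy(rankings, top_sets, k) for k in ks}
    topk_baseline = {}
    for k in ks:
        proposal = set(naive_topk_baseline(top_sets, k, panel.enzyme_ids))
        topk_baseline[k] = float(
            np.mean([bool(proposal & ts.enzymes) for ts in top_sets])
        )
    return SelectivityBenchmark(
        topk_model=topk_model,
        topk_baseline=topk_baseline,
        regrets=regrets,
        max_regrets=max_regrets,
        n_substrates_scored=len(rankings),
    )
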