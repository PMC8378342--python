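"""End-to-end orchestration: occurrences + layers → gated weighted ensemble →
scenario projections and range-change summaries.

These functions tie the stages together exactly as the command-line interface
runs them, and are the programmatic entry point for scripted analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ensemble as ens
from . import evaluation as ev
from . import occurrence as occ
from . import projection as proj
from . import sdm_core as core
from .env_stack import LayerStack

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "prepare_training", "fit_ensemble_pipeline", "project_scenarios"]


@dataclass
class PipelineResult:
    """Everything a full fit produces, ready for projection."""

    table: core.TrainingTable
    records: list
    means: pd.DataFrame
    retained: list[str]
    ensemble: ens.EnsembleModel
    threshold: float
    current_map: proj.SuitabilityMap
    current_binary: proj.BinaryMap
    importance: ens.ImportanceResult | None = None


def prepare_training(
    stack: LayerStack,
    presences: occ.PresenceSet,
    n_pseudo: int = 5000,
    pa_strategy: str = "sre",
    envelope_quantile: float = 0.025,
    thinning: bool = True,
    seed: int = 0,
):
    """Thin + extent-filter presences, draw pseudo-absences, assemble the table."""
    if thinning:
        presences = occ.thin_to_grid(presences, stack.grid)
    presences = occ.filter_extent(presences, stack.grid)
    if len(presences) == 0:
        raise ValueError("no presences left inside the study extent")
    background = occ.generate_pseudo_absences(
        stack,
        presences,
        n=n_pseudo,
        envelope_quantile=envelope_quantile,
        seed=seed,
        strategy=pa_strategy,
    )
    table = core.make_training_table(stack, presences, background)
    logger.info(
        "training table: %d presences + %d pseudo-absences on %d predictors",
        int((table.y == 1).sum()),
        int((table.y == 0).sum()),
        len(table.predictors),
    )
    return table, presences, background


def fit_ensemble_pipeline(
    stack: LayerStack,
    presences: occ.PresenceSet,
    n_pseudo: int = 5000,
    k: int = 5,
    repetitions: int = 10,
    seed: int = 0,
    algorithms=core.ALGORITHMS,
    tss_gate: float = ev.TSS_GATE,
    auc_gate: float = ev.AUC_GATE,
    metric: str = "tss",
    hyperparameters: dict | None = None,
    pa_strategy: str = "sre",
    envelope_quantile: float = 0.025,
    thinning: bool = True,
    compute_importance: bool = True,
    n_permutations: int = 10,
) -> PipelineResult:
    """The full protocol on one current-period stack.

    Pseudo-absence sampling, repeated stratified CV over the algorithm zoo,
    TSS/AUC gating, full-data refits of the retained algorithms weighted by
    their CV mean metric, the ensemble's TSS-maximizing binarization
    threshold, and (optionally) permutation variable importance.
    """
    seeds = core._spawn_seeds(seed, 4)
    table, presences, background = prepare_training(
        stack,
        presences,
        n_pseudo=n_pseudo,
        pa_strategy=pa_strategy,
        envelope_quantile=envelope_quantile,
        thinning=thinning,
        seed=seeds[0],
    )
    records = core.fit_evaluate(
        table,
        algorithms=algorithms,
        k=k,
        repetitions=repetitions,
        seed=seeds[1],
        hyperparameters=hyperparameters,
    )
    retained, means = ev.aggregate_and_gate(records, tss_min=tss_gate, auc_min=auc_gate)
    logger.info("gating: retained %s of %s algorithms", retained, list(algorithms))
    if not retained:
        raise RuntimeError("no algorithm passed the TSS/AUC gates")

    hyperparameters = hyperparameters or {}
    members = [
        core.fit(
            core.LearnerSpec(a, hyperparameters.get(a, {}), seeds[2] + i), table
        )
        for i, a in enumerate(retained)
    ]
    model = ens.build_ensemble(members, means[metric], metric=metric)

    train_scores = model.predict(table.X)
    threshold, train_tss = ev.optimal_threshold(train_scores, table.y)
    logger.info("ensemble threshold %.4f (training TSS %.3f)", threshold, train_tss)

    current_map = proj.project(model, stack)
    current_binary = proj.binarize(current_map, threshold)

    importance = None
    if compute_importance:
        importance = ens.importance_table(model, table, n_perm=n_permutations, seed=seeds[3])

    return PipelineResult(
        table=table,
        records=records,
        means=means,
        retained=retained,
        ensemble=model,
        threshold=threshold,
        current_map=current_map,
        current_binary=current_binary,
        importance=importance,
    )


def project_scenarios(
    result_or_model,
    stack: LayerStack,
    scenarios,
    threshold: float | None = None,
    current_binary: proj.BinaryMap | None = None,
):
    """Project onto every scenario stack and tabulate range changes.

    The binarization threshold is frozen from the current-period ensemble and
    reused unchanged for every future scenario.  Returns
    ``(summaries, table, binary maps by scenario)``.
    """
    if isinstance(result_or_model, PipelineResult):
        model = result_or_model.ensemble
        threshold = result_or_model.threshold if threshold is None else threshold
        current_binary = (
            result_or_model.current_binary if current_binary is None else current_binary
        )
    else:
        model = result_or_model
        if threshold is None or current_binary is None:
            raise ValueError("threshold and current_binary required with a bare model")

    summaries, maps = [], {}
    for delta in scenarios:
        future_stack = proj.apply_scenario(stack, delta)
        future_binary = proj.binarize(proj.project(model, future_stack), threshold)
        maps[delta.scenario_id] = future_binary
        summaries.append(proj.range_change(current_binary, future_binary))
        logger.info(
            "scenario %s: loss %.1f%%, gain %.1f%%",
            delta.scenario_id,
            summaries[-1].perc_loss,
            summaries[-1].perc_gain,
        )
    return summaries, proj.range_change_table(summaries), maps
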