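"""End-to-end pipeline: filters → normalization → imputation → rollup →
profiles → (optional) pathway cross-check, with a reproducibility manifest.

Stage order follows the canonical cascade: m-score filter, anchor
normalization, proteotypic filter, replicate-consistency filter,
minimum-peptide filter, imputation, rollup. A run is fully determined by
(input table, config, seed); the manifest written alongside the outputs
records the config (and its hash), the seed, per-stage row counts and the
package version, and suffices to reproduce the run byte-identically.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .filters import (
    min_peptide_filter,
    mscore_filter,
    proteotypic_filter,
    replicate_consistency_filter,
)
from .io import condition_order as _cond_order
from .io import read_peptide_table, run_roster, write_matrix
from .pathway import (
    ConsistencyReport,
    TrapPrediction,
    build_default_graph,
    consistency_check,
    load_graph,
    predict_accumulation,
)
from .profiles import (
    EnrichmentMatrix,
    FoldChangeTable,
    accumulation_classes,
    assign_stage,
    fold_changes,
    scale_to_max,
)
from .quantify import ProteinQuant, impute_missing, normalize_anchor, rollup

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    quant: ProteinQuant
    enrichment: EnrichmentMatrix
    stages: pd.DataFrame
    fold_change: FoldChangeTable
    classes: dict[str, pd.DataFrame] = field(default_factory=dict)
    predictions: dict[str, TrapPrediction] = field(default_factory=dict)
    consistency: dict[str, ConsistencyReport] = field(default_factory=dict)
    stage_counts: list[tuple[str, int]] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _safe(name: str) -> str:
    return name.replace(":", "-").replace("/", "-")


def run_pipeline(
    config: PipelineConfig, table: pd.DataFrame | None = None
) -> PipelineResult:
    """Execute the full pipeline; see module docstring for stage order.

    ``table`` may be passed directly; otherwise ``config.input_table`` is
    read. Outputs are written under ``config.outdir`` when set.
    """
    if table is None:
        if config.input_table is None:
            raise ValueError("no input table: set config.input_table or pass table=")
        table = read_peptide_table(config.input_table)

    roster = run_roster(table)
    cond_order = config.condition_order or _cond_order(roster)
    missing_conds = set(cond_order) - set(roster["condition"])
    if missing_conds:
        raise ValueError(f"configured condition(s) absent from input: {sorted(missing_conds)}")

    counts: list[tuple[str, int]] = [("input", len(table))]

    def stage(name, fn, t):
        try:
            out = fn(t)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        counts.append((name, len(out)))
        logger.info("stage %-22s %7d rows", name, len(out))
        return out

    cfg_f = config.filter
    t = stage("mscore_filter", lambda x: mscore_filter(x, cfg_f), table)
    t = stage(
        "normalize_anchor",
        lambda x: normalize_anchor(
            x, config.anchors, target=config.normalize_target, mode=config.normalize_mode
        ),
        t,
    )
    if cfg_f.proteotypic_only:
        t = stage("proteotypic_filter", proteotypic_filter, t)
    t = stage(
        "replicate_consistency",
        lambda x: replicate_consistency_filter(x, runs=roster),
        t,
    )
    t = stage(
        "min_peptide_filter", lambda x: min_peptide_filter(x, cfg_f.min_peptides), t
    )
    t = stage(
        "impute_missing",
        lambda x: impute_missing(
            x, lo=config.impute_lo, hi=config.impute_hi, seed=config.seed, runs=roster
        ),
        t,
    )

    pq = rollup(t, runs=roster, condition_order=cond_order)
    profile_conditions = config.profile_conditions or cond_order
    em = scale_to_max(pq, conditions=profile_conditions)
    stages_df = assign_stage(em, plateau_tol=config.plateau_tol)
    fc = fold_changes(pq)

    result = PipelineResult(
        quant=pq,
        enrichment=em,
        stages=stages_df,
        fold_change=fc,
        stage_counts=counts,
    )

    graph = None
    for mutant, control in config.comparisons:
        key = f"{mutant}_vs_{control}"
        result.classes[key] = accumulation_classes(
            pq,
            mutant,
            control,
            up_threshold=config.up_threshold,
            down_threshold=config.down_threshold,
        )
        perturbation = config.perturbations.get(mutant)
        if perturbation:
            if graph is None:
                graph = (
                    load_graph(config.pathway_graph)
                    if config.pathway_graph
                    else build_default_graph()
                )
            pred = predict_accumulation(graph, perturbation)
            result.predictions[key] = pred
            result.consistency[key] = consistency_check(
                pred, result.classes[key], factors=graph.core_factors
            )

    result.manifest = {
        "package": "pre60s",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "stage_counts": [[n, c] for n, c in counts],
    }

    if config.outdir:
        _write_outputs(config, result)
    return result


def _write_outputs(config: PipelineConfig, result: PipelineResult) -> None:
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    pq = result.quant
    write_matrix(pq.intensity, os.path.join(outdir, "protein_run_intensity.tsv"))
    write_matrix(pq.condition_mean, os.path.join(outdir, "condition_means.tsv"))
    write_matrix(pq.condition_sd, os.path.join(outdir, "condition_sds.tsv"))
    write_matrix(pq.imputed_fraction, os.path.join(outdir, "imputed_fraction.tsv"))
    write_matrix(result.enrichment.scaled, os.path.join(outdir, "enrichment.tsv"))
    result.stages.to_csv(os.path.join(outdir, "stages.tsv"), sep="\t", index_label="protein_group")
    write_matrix(result.fold_change.fold_change, os.path.join(outdir, "fold_changes.tsv"))
    write_matrix(result.fold_change.sd, os.path.join(outdir, "fold_change_sds.tsv"))
    pd.DataFrame(result.stage_counts, columns=["stage", "rows"]).to_csv(
        os.path.join(outdir, "filter_report.tsv"), sep="\t", index=False
    )
    for key, classes in result.classes.items():
        classes.to_csv(
            os.path.join(outdir, f"classes_{_safe(key)}.tsv"),
            sep="\t",
            index_label="protein_group",
        )
    for key, pred in result.predictions.items():
        pd.DataFrame(
            {
                "factor": sorted(pred.accumulated) + sorted(pred.not_recruited),
                "prediction": ["accumulated"] * len(pred.accumulated)
                + ["not_recruited"] * len(pred.not_recruited),
            }
        ).to_csv(os.path.join(outdir, f"prediction_{_safe(key)}.tsv"), sep="\t", index=False)
    for key, report in result.consistency.items():
        report.table.to_csv(
            os.path.join(outdir, f"consistency_{_safe(key)}.tsv"), sep="\t"
        )
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


def run_from_manifest(manifest_path: str) -> PipelineResult:
    """Re-run a pipeline from a previously written manifest."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = PipelineConfig.from_dict(manifest["config"])
    return run_pipeline(config)
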