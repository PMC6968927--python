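"""Identification filter cascade for peptide-assay tables.

Every operation is a pure row selection: output rows are a subset of input
rows, no intensity is modified, and each filter (and the full cascade) is
idempotent. Comparisons against both m-score thresholds are strict
("below"). Paralog protein groups are atomic — a filter never splits
``RPL19A/RPL19B``.
"""

from __future__ import annotations

import logging

import pandas as pd

from .config import FilterConfig
from .io import observed_mask, run_roster

logger = logging.getLogger(__name__)


def protein_gate(table: pd.DataFrame, cfg: FilterConfig) -> set[str]:
    """Protein groups with at least one confident non-decoy peptide row.

    A group passes iff some non-decoy row has
    ``m_score < cfg.protein_gate_mscore``. Computed on the unfiltered
    table, before any peptide-level removal.
    """
    if table.empty:
        return set()
    hits = table[(~table["decoy"]) & (table["m_score"] < cfg.protein_gate_mscore)]
    return set(hits["protein_group"])


def mscore_filter(table: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Keep peptide assays with ``m_score < peptide_mscore`` on gated
    proteins; decoy rows are removed when ``cfg.drop_decoys``.

    The protein-level gate means a confident peptide row on a non-gated
    protein is still removed.
    """
    if table.empty:
        return table.copy()
    gate = protein_gate(table, cfg)
    keep = (table["m_score"] < cfg.peptide_mscore) & table["protein_group"].isin(gate)
    if cfg.drop_decoys:
        keep &= ~table["decoy"]
    return table[keep].copy()


def proteotypic_filter(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only rows whose peptide maps to a single protein group."""
    return table[table["proteotypic"]].copy()


def replicate_consistency_filter(
    table: pd.DataFrame,
    n_replicates: int | None = None,
    runs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Keep assays observed in every replicate of at least one condition.

    An assay (protein_group, peptide_id) is kept — across *all* its rows,
    including rows in other conditions — iff there exists a condition in
    which it has an observed (non-missing) intensity in all replicates.

    ``n_replicates`` fixes the required per-condition replicate count; by
    default it is derived per condition from the run roster (``runs`` or,
    failing that, the runs present in ``table``).
    """
    if table.empty:
        return table.copy()
    roster = runs if runs is not None else run_roster(table)
    if n_replicates is not None:
        required = {c: n_replicates for c in roster["condition"].unique()}
    else:
        required = roster.groupby("condition")["replicate"].nunique().to_dict()

    obs = table[observed_mask(table)]
    counts = (
        obs.groupby(["protein_group", "peptide_id", "condition"])["replicate"]
        .nunique()
        .reset_index(name="n_obs")
    )
    counts["needed"] = counts["condition"].map(required)
    complete = counts[counts["n_obs"] >= counts["needed"]]
    kept_assays = set(zip(complete["protein_group"], complete["peptide_id"]))

    key = list(zip(table["protein_group"], table["peptide_id"]))
    mask = pd.Series([k in kept_assays for k in key], index=table.index)
    return table[mask].copy()


def min_peptide_filter(table: pd.DataFrame, min_peptides: int = 2) -> pd.DataFrame:
    """Remove all rows of protein groups with fewer than ``min_peptides``
    distinct surviving peptides."""
    if table.empty:
        return table.copy()
    n_pep = table.groupby("protein_group")["peptide_id"].nunique()
    keep_proteins = set(n_pep.index[n_pep >= min_peptides])
    return table[table["protein_group"].isin(keep_proteins)].copy()


def apply_filters(
    table: pd.DataFrame,
    cfg: FilterConfig,
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Run the full cascade in its canonical order.

    m-score filter → proteotypic filter → replicate-consistency filter →
    minimum-peptide filter. (In the full pipeline, anchor normalization is
    applied between the m-score and proteotypic stages; normalization does
    not change row membership, so the cascade composes identically.)

    With ``cfg.replicate_before_mscore`` the replicate rule is evaluated on
    the unfiltered table instead. Per-stage row counts are logged.
    """
    roster = run_roster(table)
    stages: list[tuple[str, pd.DataFrame]] = [("input", table)]

    if cfg.replicate_before_mscore:
        table = replicate_consistency_filter(table, n_replicates, runs=roster)
        stages.append(("replicate_consistency", table))
    table = mscore_filter(table, cfg)
    stages.append(("mscore", table))
    if cfg.proteotypic_only:
        table = proteotypic_filter(table)
        stages.append(("proteotypic", table))
    if not cfg.replicate_before_mscore:
        table = replicate_consistency_filter(table, n_replicates, runs=roster)
        stages.append(("replicate_consistency", table))
    table = min_peptide_filter(table, cfg.min_peptides)
    stages.append(("min_peptides", table))

    for name, t in stages:
        logger.info("filter stage %-22s %7d rows", name, len(t))
    return table


def stage_counts(
    table: pd.DataFrame,
    cfg: FilterConfig,
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Per-stage row/assay/protein counts of the cascade (filter report)."""
    roster = run_roster(table)
    rows = []

    def record(name: str, t: pd.DataFrame):
        rows.append(
            {
                "stage": name,
                "rows": len(t),
                "assays": t.groupby(["protein_group", "peptide_id"]).ngroups,
                "proteins": t["protein_group"].nunique(),
            }
        )

    record("input", table)
    t = table
    if cfg.replicate_before_mscore:
        t = replicate_consistency_filter(t, n_replicates, runs=roster)
        record("replicate_consistency", t)
    t = mscore_filter(t, cfg)
    record("mscore", t)
    if cfg.proteotypic_only:
        t = proteotypic_filter(t)
        record("proteotypic", t)
    if not cfg.replicate_before_mscore:
        t = replicate_consistency_filter(t, n_replicates, runs=roster)
        record("replicate_consistency", t)
    t = min_peptide_filter(t, cfg.min_peptides)
    record("min_peptides", t)
    return pd.DataFrame(rows)
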