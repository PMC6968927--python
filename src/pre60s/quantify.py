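"""Anchor normalization, bounded-uniform imputation and protein rollup.

Normalization rescales each run by a single multiplicative factor so that
the run's *anchor summary* — the mean over anchor r-protein groups of the
summed peptide intensities of that group — sits at a common level across
runs. Averaging across anchor proteins (rather than pooling peptides)
keeps anchors with many peptides from dominating. The common level
defaults to 1.0, i.e. intensities are expressed relative to the run's mean
anchor-protein intensity; this makes the normalized table exactly
invariant to any per-run rescaling of the input (a run-level batch effect
is absorbed completely). ``target="grand_mean"`` instead restores the
dataset's average anchor level, preserving the original intensity scale at
the cost of that exact invariance. ``mode="log"`` replaces the arithmetic
mean across anchor proteins by a geometric mean.

Imputation fills every missing (assay x run) cell with ``u * m`` where
``u ~ Uniform(lo, hi)`` (defaults 0.7-0.9) and ``m`` is the assay's lowest
observed intensity anywhere in the dataset. Draws are consumed in sorted
(protein_group, peptide_id, run_id) order so the result is independent of
input row order.

Rollup sums peptide-assay intensities to a protein intensity per run, then
derives per-condition means and sample (n-1) standard deviations over
replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnchorSet
from .io import condition_order as _cond_order
from .io import observed_mask, run_roster

logger = logging.getLogger(__name__)


def anchor_summaries(
    table: pd.DataFrame, anchors: AnchorSet, mode: str = "linear"
) -> pd.Series:
    """Per-run anchor summary: mean (or geometric mean) over anchor protein
    groups of the group's summed observed peptide intensity in that run.

    Raises ``ValueError`` naming the first offending run and anchor if an
    anchor group has no observed assay in some run.
    """
    roster = run_roster(table)
    obs = table[observed_mask(table)]
    anchor_rows = obs[obs["protein_group"].isin(set(anchors))]
    sums = (
        anchor_rows.groupby(["run_id", "protein_group"])["intensity"]
        .sum()
        .unstack("protein_group")
        .reindex(index=roster["run_id"], columns=list(anchors))
    )
    if sums.isna().any().any():
        run = sums.index[sums.isna().any(axis=1)][0]
        anchor = sums.columns[sums.loc[run].isna()][0]
        raise ValueError(
            f"anchor {anchor!r} has no observed assay in run {run!r}"
        )
    if mode == "log":
        return np.exp(np.log(sums).mean(axis=1)).rename("anchor_summary")
    if mode != "linear":
        raise ValueError(f"unknown mode {mode!r}")
    return sums.mean(axis=1).rename("anchor_summary")


def normalize_anchor(
    table: pd.DataFrame,
    anchors: AnchorSet | None = None,
    target: str | float = "unit",
    mode: str = "linear",
) -> pd.DataFrame:
    """Mean-center run intensities on the anchor r-protein set.

    Each run's intensities are multiplied by one factor so that its anchor
    summary equals a common level: 1.0 for ``target="unit"`` (default; see
    module docstring), the grand mean of the input summaries for
    ``target="grand_mean"``, or any explicit float. Relative intensities
    within a run are unchanged. The per-run factors are stored in
    ``result.attrs["anchor_factors"]``.
    """
    anchors = anchors if anchors is not None else AnchorSet()
    summaries = anchor_summaries(table, anchors, mode=mode)
    if target == "unit":
        level = 1.0
    elif target == "grand_mean":
        level = float(summaries.mean())
    else:
        level = float(target)
    factors = level / summaries
    out = table.copy()
    out["intensity"] = out["intensity"] * out["run_id"].map(factors).astype(float)
    out.attrs["anchor_factors"] = factors
    return out


def impute_missing(
    table: pd.DataFrame,
    lo: float = 0.7,
    hi: float = 0.9,
    seed: int | np.random.Generator | None = None,
    runs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Complete the (assay x run) grid with bounded-uniform imputed values.

    Every cell with no observed intensity receives ``u * m`` with
    ``u ~ Uniform(lo, hi)`` drawn independently per cell and ``m`` the
    assay's minimum observed intensity across all runs. Observed cells are
    untouched. The returned table gains a boolean ``imputed`` column.

    ``runs`` fixes the run roster (run_id, condition, replicate); it
    defaults to the runs present in ``table``. A seed (or Generator) is
    mandatory whenever there is at least one cell to impute. An assay with
    zero observed values is an error.
    """
    if not 0 < lo <= hi:
        raise ValueError("need 0 < lo <= hi")
    roster = runs if runs is not None else run_roster(table)
    obs = table[observed_mask(table)].copy()

    assay_min = obs.groupby(["protein_group", "peptide_id"])["intensity"].min()
    all_assays = table[["protein_group", "peptide_id"]].drop_duplicates()
    no_obs = [
        t for t in all_assays.itertuples(index=False)
        if (t.protein_group, t.peptide_id) not in assay_min.index
    ]
    if no_obs:
        a = no_obs[0]
        raise ValueError(
            f"assay ({a.protein_group!r}, {a.peptide_id!r}) has no observed "
            f"intensity; cannot impute"
        )

    # per-assay flags for the rows we synthesize
    flags = (
        obs.groupby(["protein_group", "peptide_id"])[["decoy", "proteotypic"]]
        .first()
    )

    observed_cells = set(
        zip(obs["protein_group"], obs["peptide_id"], obs["run_id"])
    )
    run_info = roster.set_index("run_id")
    missing = [
        (pg, pep, run)
        for (pg, pep) in assay_min.index
        for run in roster["run_id"]
        if (pg, pep, run) not in observed_cells
    ]
    missing.sort()

    obs["imputed"] = False
    if not missing:
        return obs.reset_index(drop=True)

    if seed is None:
        raise ValueError("a seed is required when there are cells to impute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.uniform(lo, hi, size=len(missing))

    new_rows = pd.DataFrame(
        {
            "run_id": [run for _, _, run in missing],
            "condition": [run_info.at[run, "condition"] for _, _, run in missing],
            "replicate": [run_info.at[run, "replicate"] for _, _, run in missing],
            "protein_group": [pg for pg, _, _ in missing],
            "peptide_id": [pep for _, pep, _ in missing],
            "intensity": [
                u * assay_min[(pg, pep)]
                for u, (pg, pep, _) in zip(draws, missing)
            ],
            "m_score": np.nan,
            "decoy": [flags.at[(pg, pep), "decoy"] for pg, pep, _ in missing],
            "proteotypic": [
                flags.at[(pg, pep), "proteotypic"] for pg, pep, _ in missing
            ],
            "imputed": True,
        }
    )
    logger.info("imputed %d of %d grid cells", len(missing), len(assay_min) * len(roster))
    out = pd.concat([obs, new_rows], ignore_index=True)
    return out


@dataclass
class ProteinQuant:
    """Protein x run intensities with per-condition summaries.

    ``intensity`` is the protein x run matrix of summed peptide
    intensities; ``condition_mean`` / ``condition_sd`` are the arithmetic
    mean and sample (n-1) standard deviation over that condition's
    replicate runs; ``imputed_fraction`` is the per-cell fraction of
    contributing peptide values that were imputed; ``runs`` is the run
    roster and ``condition_order`` the display order of conditions.
    """

    intensity: pd.DataFrame
    condition_mean: pd.DataFrame
    condition_sd: pd.DataFrame
    imputed_fraction: pd.DataFrame
    runs: pd.DataFrame
    condition_order: list[str]

    @property
    def proteins(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def replicate_intensity(self) -> pd.DataFrame:
        """Protein x run matrix with a (condition, replicate) MultiIndex."""
        cols = pd.MultiIndex.from_frame(
            self.runs.set_index("run_id").loc[self.intensity.columns][
                ["condition", "replicate"]
            ]
        )
        out = self.intensity.copy()
        out.columns = cols
        return out


def rollup(
    table: pd.DataFrame,
    runs: pd.DataFrame | None = None,
    condition_order: list[str] | None = None,
) -> ProteinQuant:
    """Sum peptide assays to protein intensities and summarize conditions.

    Requires a complete (assay x run) grid — i.e. an imputed table; an
    incomplete grid raises ``ValueError`` listing missing cells.
    """
    roster = runs if runs is not None else run_roster(table)
    order = condition_order if condition_order is not None else _cond_order(roster)

    obs = table[observed_mask(table)]
    cell_counts = (
        obs.groupby(["protein_group", "peptide_id"])["run_id"].nunique()
    )
    incomplete = cell_counts[cell_counts < len(roster)]
    if not incomplete.empty:
        examples = []
        run_set = set(roster["run_id"])
        for (pg, pep) in incomplete.index[:5]:
            have = set(obs[(obs["protein_group"] == pg) & (obs["peptide_id"] == pep)]["run_id"])
            for run in sorted(run_set - have)[:2]:
                examples.append(f"({pg}, {pep}, {run})")
        raise ValueError(
            f"incomplete (assay x run) grid: {len(incomplete)} assay(s) with "
            f"missing cells, e.g. {'; '.join(examples)} — impute first"
        )

    intensity = (
        obs.groupby(["protein_group", "run_id"])["intensity"]
        .sum()
        .unstack("run_id")
        .reindex(columns=roster["run_id"])
    )
    if "imputed" in table.columns:
        imp = (
            obs.groupby(["protein_group", "run_id"])["imputed"]
            .mean()
            .unstack("run_id")
            .reindex(columns=roster["run_id"])
        )
    else:
        imp = pd.DataFrame(0.0, index=intensity.index, columns=intensity.columns)

    run_to_cond = roster.set_index("run_id")["condition"]
    grouped = intensity.T.groupby(intensity.columns.map(run_to_cond))
    condition_mean = grouped.mean().T.reindex(columns=order)
    condition_sd = grouped.std(ddof=1).T.reindex(columns=order)

    return ProteinQuant(
        intensity=intensity,
        condition_mean=condition_mean,
        condition_sd=condition_sd,
        imputed_fraction=imp,
        runs=roster.reset_index(drop=True),
        condition_order=list(order),
    )
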