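"""Residence profiles, fold changes and accumulation classes.

These operations turn a :class:`~pre60s.quantify.ProteinQuant` into the
heat-map and bar-plot objects of bait-resolved AP-MS profiling: each
protein's condition means scaled to its own maximum (maximum enrichment =
1), fold changes relative to the highest-intensity condition, an automated
residence-stage assignment, and mutant-vs-control accumulation classes.
Ties at a row maximum are broken toward the earliest condition in the
condition order and logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import ProteinQuant

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentMatrix:
    """Per-protein profiles scaled to each protein's maximum.

    ``scaled`` has values in [0, 1] with a per-row maximum of exactly 1;
    ``stage_of_max`` is the condition where the maximum is attained
    (earliest on ties).
    """

    scaled: pd.DataFrame
    condition_order: list[str]
    stage_of_max: pd.Series


@dataclass
class FoldChangeTable:
    """Fold changes relative to each protein's highest-intensity condition.

    ``fold_change`` is <= 1 with the reference condition exactly 1; ``sd``
    is the per-condition replicate standard deviation divided by the
    reference mean.
    """

    reference_condition: pd.Series
    fold_change: pd.DataFrame
    sd: pd.DataFrame


def _log_ties(means: pd.DataFrame, what: str) -> None:
    ties = (means.eq(means.max(axis=1), axis=0)).sum(axis=1)
    n_tied = int((ties > 1).sum())
    if n_tied:
        logger.info(
            "%s: %d protein(s) with tied row maxima; earliest condition used",
            what,
            n_tied,
        )


def scale_to_max(
    pq: ProteinQuant, conditions: list[str] | None = None
) -> EnrichmentMatrix:
    """Scale each protein's condition means to its maximum over the
    selected conditions.

    Proteins whose means are all zero (or missing) across the selection
    are excluded with a warning.
    """
    conditions = conditions if conditions is not None else pq.condition_order
    unknown = set(conditions) - set(pq.condition_mean.columns)
    if unknown:
        raise ValueError(f"unknown condition(s): {sorted(unknown)}")
    means = pq.condition_mean[list(conditions)]
    row_max = means.max(axis=1)
    dead = row_max.isna() | (row_max <= 0)
    if dead.any():
        warnings.warn(
            f"excluding {int(dead.sum())} protein(s) with no positive "
            f"condition mean among {list(conditions)}"
        )
        means = means[~dead]
        row_max = row_max[~dead]
    _log_ties(means, "scale_to_max")
    scaled = means.div(row_max, axis=0)
    return EnrichmentMatrix(
        scaled=scaled,
        condition_order=list(conditions),
        stage_of_max=scaled.idxmax(axis=1).rename("stage_of_max"),
    )


def fold_changes(
    pq: ProteinQuant, conditions: list[str] | None = None
) -> FoldChangeTable:
    """Fold change per protein relative to the condition with the highest
    protein intensity mean; SDs are propagated on the same scale."""
    conditions = conditions if conditions is not None else pq.condition_order
    means = pq.condition_mean[list(conditions)]
    row_max = means.max(axis=1)
    dead = row_max.isna() | (row_max <= 0)
    if dead.any():
        warnings.warn(
            f"excluding {int(dead.sum())} protein(s) with no positive "
            f"condition mean among {list(conditions)}"
        )
        means = means[~dead]
        row_max = row_max[~dead]
    _log_ties(means, "fold_changes")
    reference = means.idxmax(axis=1).rename("reference_condition")
    fc = means.div(row_max, axis=0)
    sd = pq.condition_sd.loc[means.index, list(conditions)].div(row_max, axis=0)
    return FoldChangeTable(reference_condition=reference, fold_change=fc, sd=sd)


def assign_stage(em: EnrichmentMatrix, plateau_tol: float = 0.25) -> pd.DataFrame:
    """Residence interval per protein from its scaled profile.

    The stage is the maximal contiguous run of conditions with scaled
    enrichment within ``plateau_tol`` of 1 that contains the maximum;
    a one-hot profile yields a single-condition interval. Returns a frame
    with ``start`` and ``end`` condition labels.
    """
    if not 0 <= plateau_tol < 1:
        raise ValueError("plateau_tol must be in [0, 1)")
    cols = em.condition_order
    cutoff = 1.0 - plateau_tol
    values = em.scaled[cols].to_numpy()
    out = []
    for row in values:
        peak = int(np.nanargmax(row))
        lo = peak
        while lo > 0 and row[lo - 1] >= cutoff:
            lo -= 1
        hi = peak
        while hi < len(cols) - 1 and row[hi + 1] >= cutoff:
            hi += 1
        out.append((cols[lo], cols[hi]))
    return pd.DataFrame(out, index=em.scaled.index, columns=["start", "end"])


def accumulation_classes(
    pq: ProteinQuant,
    mutant_condition: str,
    control_condition: str,
    up_threshold: float = 2.0,
    down_threshold: float = 0.5,
) -> pd.DataFrame:
    """Classify proteins by their mutant / control condition-mean ratio.

    ``accumulated`` if ratio >= up_threshold, ``depleted`` if ratio <=
    down_threshold, else ``unchanged``. A zero control mean yields an
    infinite ratio, classed accumulated and flagged. Returns a frame with
    columns ``ratio``, ``cls``, ``infinite_ratio`` and the imputed
    fractions backing each side of the ratio.
    """
    for c in (mutant_condition, control_condition):
        if c not in pq.condition_mean.columns:
            raise ValueError(f"condition {c!r} not present")
    if not down_threshold < up_threshold:
        raise ValueError("need down_threshold < up_threshold")
    mut = pq.condition_mean[mutant_condition]
    ctl = pq.condition_mean[control_condition]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mut / ctl
    ratio = ratio.where(ctl > 0, np.inf)
    cls = pd.Series("unchanged", index=ratio.index, name="cls")
    cls[ratio >= up_threshold] = "accumulated"
    cls[ratio <= down_threshold] = "depleted"

    run_cond = pq.runs.set_index("run_id")["condition"]
    imp = pq.imputed_fraction
    imp_by_cond = imp.T.groupby(imp.columns.map(run_cond)).mean().T
    return pd.DataFrame(
        {
            "ratio": ratio,
            "cls": cls,
            "infinite_ratio": ~np.isfinite(ratio),
            "imputed_fraction_mutant": imp_by_cond[mutant_condition],
            "imputed_fraction_control": imp_by_cond[control_condition],
        }
    )


def plot_enrichment(em: EnrichmentMatrix, path: str | None = None, order_by_stage: bool = True):
    """Render the enrichment matrix as a purple-to-gold heat map.

    Maximum enrichment is purple, minimum gold. Plotting is a convenience;
    the matrix values are the contract. Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    scaled = em.scaled
    if order_by_stage:
        key = em.stage_of_max.map({c: i for i, c in enumerate(em.condition_order)})
        scaled = scaled.loc[key.sort_values(kind="stable").index]
    cmap = LinearSegmentedColormap.from_list("gold_purple", ["#d4a017", "#4b0082"])
    fig, ax = plt.subplots(
        figsize=(1.2 * len(em.condition_order) + 2, 0.12 * len(scaled) + 1.5)
    )
    im = ax.imshow(scaled.to_numpy(), aspect="auto", cmap=cmap, vmin=0, vmax=1)
    ax.set_xticks(range(len(em.condition_order)), em.condition_order, rotation=45)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="relative enrichment")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
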