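"""Synthetic AP-MS / DIA peptide-assay tables with known ground truth.

The generator emulates the statistical structure of bait-resolved SWATH
pull-down data along a maturation axis: a set of bait conditions ordered by
maturation stage (early nucleolar ``Ssf1`` → nucleoplasmic ``Rix1`` →
export-competent ``Arx1`` → cytoplasmic ``Lsg1``), three replicate
purifications per condition, and optionally mutant-trapped conditions in
which chosen assembly factors accumulate or fail to be recruited.

Each assembly factor occupies a contiguous *residence interval* of the
ordered conditions (recruitment stage → release stage) with plateau
occupancy inside and a configurable residual outside; anchor r-proteins are
flat across all conditions. Observed intensities follow a multiplicative
model::

    I = abundance x occupancy(condition) x peptide_efficiency
        x run_factor x exp(Normal(0, log_noise_sd))

with logistic intensity-dependent dropout, decoy rows drawn from the low
intensity tail, and per-row identification m-scores. Missing measurements
are absent rows, as extraction software emits them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import DEFAULT_ANCHORS
from .io import REQUIRED_COLUMNS


@dataclass(frozen=True)
class MscoreDist:
    """Log10-uniform mixture for identification scores.

    Scores are ``10**U(low_exp, high_exp)`` with probability
    ``1 - tail_frac`` and ``10**U(tail_low_exp, tail_high_exp)`` otherwise.
    """

    low_exp: float
    high_exp: float
    tail_frac: float = 0.0
    tail_low_exp: float = 0.0
    tail_high_exp: float = 0.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        body = 10.0 ** rng.uniform(self.low_exp, self.high_exp, size=n)
        if self.tail_frac <= 0:
            return np.minimum(body, 1.0)
        tail = 10.0 ** rng.uniform(self.tail_low_exp, self.tail_high_exp, size=n)
        pick_tail = rng.random(n) < self.tail_frac
        return np.minimum(np.where(pick_tail, tail, body), 1.0)


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults define the package's study conditions.

    Intensity units are arbitrary; abundances are drawn log10-normally
    around ``10**abundance_mu_log10``. ``dropout_midpoint`` is the log10
    intensity at which half the assays drop out (``None`` disables
    dropout); ``dropout_slope`` is per log10-intensity unit.
    """

    conditions: tuple[str, ...] = ("Ssf1", "Rix1", "Arx1", "Lsg1")
    n_replicates: int = 3
    n_factors: int = 100
    n_anchor: int = 12
    peptides_per_protein: tuple[int, int] = (3, 8)
    log_noise_sd: float = 0.1
    run_effect_range: tuple[float, float] = (0.7, 1.4)
    dropout_midpoint: float | None = 2.5
    dropout_slope: float = 1.5
    decoy_fraction: float = 0.1
    target_mscore_dist: MscoreDist = MscoreDist(-9.0, -3.0)
    poor_mscore_dist: MscoreDist = MscoreDist(-3.0, 0.0)
    poor_mscore_midpoint: float | None = 3.0
    poor_mscore_slope: float = 2.0
    decoy_mscore_dist: MscoreDist = MscoreDist(-3.0, 0.0)
    residual_occupancy: float = 0.05
    abundance_mu_log10: float = 5.0
    abundance_sd_log10: float = 0.8
    #: anchors are stoichiometric core r-proteins (one copy per particle),
    #: so their abundance spread is much tighter than assembly factors'
    anchor_abundance_sd_log10: float = 0.3
    peptide_eff_sd_log10: float = 0.8
    shared_peptide_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("condition list must be non-empty")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_factors < 1 or self.n_anchor < 1:
            raise ValueError("protein counts must be positive")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("peptides_per_protein must satisfy 1 <= lo <= hi")
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must be in [0, 1)")
        if not 0 <= self.residual_occupancy:
            raise ValueError("residual_occupancy must be non-negative")

    def dropout_probability(self, intensity: np.ndarray) -> np.ndarray:
        """Probability that an assay of the given intensity is missing.

        Logistic and decreasing in log10 intensity; identically zero when
        ``dropout_midpoint`` is ``None``. Always within [0, 1].
        """
        intensity = np.asarray(intensity, dtype=float)
        if self.dropout_midpoint is None:
            return np.zeros_like(intensity)
        return expit(-self.dropout_slope * (np.log10(intensity) - self.dropout_midpoint))

    def poor_mscore_probability(self, intensity: np.ndarray) -> np.ndarray:
        """Probability that an observation scores poorly (m-score from the
        poor-score distribution rather than the confident one).

        Identification confidence tracks signal strength: abundant assays
        are confidently identified in every run while weak ones score
        erratically. Logistic, decreasing in log10 intensity; zero when
        ``poor_mscore_midpoint`` is ``None``.
        """
        intensity = np.asarray(intensity, dtype=float)
        if self.poor_mscore_midpoint is None:
            return np.zeros_like(intensity)
        return expit(
            -self.poor_mscore_slope * (np.log10(intensity) - self.poor_mscore_midpoint)
        )


@dataclass(frozen=True)
class GroundTruth:
    """True relative occupancy per protein per condition.

    ``occupancy`` is proteins x conditions (non-negative, arbitrary units);
    ``residence`` holds the (start, end) condition labels of each factor's
    residence interval on the bait axis; anchors are flat across all
    conditions. ``stage_of_max`` is the condition of maximal occupancy
    (earliest condition on ties).
    """

    occupancy: pd.DataFrame
    is_anchor: pd.Series
    protein_abundance: pd.Series
    residence: pd.DataFrame

    @property
    def conditions(self) -> list[str]:
        return list(self.occupancy.columns)

    @property
    def proteins(self) -> list[str]:
        return list(self.occupancy.index)

    @property
    def factors(self) -> list[str]:
        return list(self.occupancy.index[~self.is_anchor])

    @property
    def stage_of_max(self) -> pd.Series:
        return self.occupancy.idxmax(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format ground-truth table (protein, condition, occupancy,
        stage_of_max, is_anchor) for TSV export."""
        long = self.occupancy.stack().rename("occupancy").reset_index()
        long.columns = ["protein_group", "condition", "occupancy"]
        long["stage_of_max"] = long["protein_group"].map(self.stage_of_max)
        long["is_anchor"] = long["protein_group"].map(self.is_anchor)
        return long


def _anchor_names(n_anchor: int) -> list[str]:
    names = list(DEFAULT_ANCHORS[:n_anchor])
    names += [f"RPL_ANCHOR{i}" for i in range(len(names), n_anchor)]
    return names


def make_ground_truth(p: SimulationParams) -> GroundTruth:
    """Draw residence intervals, abundances and occupancy profiles.

    Each factor receives a contiguous residence interval over the ordered
    conditions with plateau occupancy 1 inside and ``residual_occupancy``
    outside; anchors are 1 everywhere. Deterministic under ``p.seed``.
    """
    rng = np.random.default_rng([0, p.seed])
    conditions = list(p.conditions)
    n_cond = len(conditions)

    anchors = _anchor_names(p.n_anchor)
    factors = [f"AF{i:03d}" for i in range(1, p.n_factors + 1)]
    proteins = anchors + factors

    starts = rng.integers(0, n_cond, size=p.n_factors)
    ends = np.array([rng.integers(a, n_cond) for a in starts])

    occ = np.full((len(proteins), n_cond), 1.0)
    for i, (a, b) in enumerate(zip(starts, ends)):
        row = np.full(n_cond, p.residual_occupancy)
        row[a : b + 1] = 1.0
        occ[len(anchors) + i] = row

    abundance = np.concatenate(
        [
            10.0
            ** rng.normal(
                p.abundance_mu_log10, p.anchor_abundance_sd_log10, size=len(anchors)
            ),
            10.0
            ** rng.normal(p.abundance_mu_log10, p.abundance_sd_log10, size=len(factors)),
        ]
    )

    residence = pd.DataFrame(
        {
            "start": [conditions[0]] * len(anchors)
            + [conditions[a] for a in starts],
            "end": [conditions[-1]] * len(anchors)
            + [conditions[b] for b in ends],
        },
        index=pd.Index(proteins, name="protein_group"),
    )
    return GroundTruth(
        occupancy=pd.DataFrame(
            occ, index=pd.Index(proteins, name="protein_group"), columns=conditions
        ),
        is_anchor=pd.Series(
            [True] * len(anchors) + [False] * len(factors),
            index=proteins,
            name="is_anchor",
        ),
        protein_abundance=pd.Series(abundance, index=proteins, name="abundance"),
        residence=residence,
    )


def add_trap_condition(
    gt: GroundTruth,
    name: str,
    base_condition: str,
    trapped: Iterable[str],
    impaired: Iterable[str] = (),
    gain: float = 4.0,
) -> GroundTruth:
    """Append a mutant-trapped condition to a ground truth.

    The new condition copies ``base_condition``; ``trapped`` factors are
    raised to ``gain`` x plateau occupancy (they stall on the particle),
    ``impaired`` factors are set to zero occupancy (they fail to be
    recruited). Residence intervals on the bait axis are kept unchanged.
    """
    if name in gt.occupancy.columns:
        raise ValueError(f"condition {name!r} already present")
    if base_condition not in gt.occupancy.columns:
        raise ValueError(f"unknown base condition {base_condition!r}")
    trapped = set(trapped)
    impaired = set(impaired)
    if trapped & impaired:
        raise ValueError("a factor cannot be both trapped and impaired")
    unknown = (trapped | impaired) - set(gt.proteins)
    if unknown:
        raise ValueError(f"unknown protein(s): {sorted(unknown)}")

    occ = gt.occupancy.copy()
    occ[name] = occ[base_condition]
    occ.loc[list(trapped), name] = gain
    occ.loc[list(impaired), name] = 0.0
    return dataclasses.replace(gt, occupancy=occ)


def simulate_peptide_table(
    gt: GroundTruth,
    p: SimulationParams,
    return_latent: bool = False,
):
    """Simulate a long-format peptide-assay table from a ground truth.

    One run per condition x replicate. Zero-occupancy assays are absent;
    positive-occupancy assays are dropped with logistic probability
    decreasing in log intensity; decoy rows are appended with intensities
    from the low tail of the target distribution. Deterministic under
    ``p.seed``.

    When ``return_latent`` is true, also returns the complete latent table
    (one row per assay x run before dropout) with a ``dropped`` flag —
    useful for studying the missingness mechanism.
    """
    if list(p.conditions) != gt.conditions:
        raise ValueError(
            f"condition mismatch: params {list(p.conditions)} vs "
            f"ground truth {gt.conditions}"
        )
    rng = np.random.default_rng([1, p.seed])
    conditions = gt.conditions
    reps = range(1, p.n_replicates + 1)

    runs = pd.DataFrame(
        [(f"{c}_r{r}", c, r) for c in conditions for r in reps],
        columns=["run_id", "condition", "replicate"],
    )
    run_factor = rng.uniform(*p.run_effect_range, size=len(runs))

    proteins = gt.proteins
    lo, hi = p.peptides_per_protein
    pep_counts = rng.integers(lo, hi + 1, size=len(proteins))
    n_pep = int(pep_counts.sum())
    efficiency = 10.0 ** rng.normal(0.0, p.peptide_eff_sd_log10, size=n_pep)
    proteotypic = rng.random(n_pep) >= p.shared_peptide_fraction

    pep_protein = np.repeat(np.arange(len(proteins)), pep_counts)
    pep_names = [
        f"{proteins[ip]}_pep{j + 1}_2"
        for ip, j in zip(
            pep_protein,
            np.concatenate([np.arange(k) for k in pep_counts]),
        )
    ]

    occ = gt.occupancy.to_numpy()  # proteins x conditions
    abundance = gt.protein_abundance.to_numpy()

    # latent grid: peptides x runs, keeping only positive-occupancy cells
    run_cond_idx = runs["condition"].map({c: i for i, c in enumerate(conditions)})
    occ_cells = occ[pep_protein][:, run_cond_idx]  # n_pep x n_runs
    mean = (
        abundance[pep_protein][:, None]
        * occ_cells
        * efficiency[:, None]
        * run_factor[None, :]
    )
    noise = np.exp(rng.normal(0.0, p.log_noise_sd, size=mean.shape))
    intensity = mean * noise

    present = occ_cells > 0
    p_miss = np.zeros_like(intensity)
    p_miss[present] = p.dropout_probability(intensity[present])
    dropped = (rng.random(intensity.shape) < p_miss) & present
    m_score = p.target_mscore_dist.sample(rng, intensity.size).reshape(intensity.shape)
    p_poor = np.zeros_like(intensity)
    p_poor[present] = p.poor_mscore_probability(intensity[present])
    poor = rng.random(intensity.shape) < p_poor
    m_poor = p.poor_mscore_dist.sample(rng, intensity.size).reshape(intensity.shape)
    m_score = np.where(poor, m_poor, m_score)

    pep_idx, run_idx = np.nonzero(present)
    latent = pd.DataFrame(
        {
            "run_id": runs["run_id"].to_numpy()[run_idx],
            "condition": runs["condition"].to_numpy()[run_idx],
            "replicate": runs["replicate"].to_numpy()[run_idx],
            "protein_group": np.asarray(proteins)[pep_protein[pep_idx]],
            "peptide_id": np.asarray(pep_names)[pep_idx],
            "intensity": intensity[pep_idx, run_idx],
            "m_score": m_score[pep_idx, run_idx],
            "decoy": False,
            "proteotypic": proteotypic[pep_idx],
            "dropped": dropped[pep_idx, run_idx],
        }
    )
    observed = (
        latent[~latent["dropped"]]
        .drop(columns="dropped")
        .reset_index(drop=True)
    )

    # decoy rows: identifiers never overlap targets; intensities from the
    # low tail of the observed target distribution
    n_decoy = int(round(p.decoy_fraction * len(observed)))
    if n_decoy > 0:
        n_dec_prot = max(1, p.n_factors // 5)
        dec_prot_idx = rng.integers(0, n_dec_prot, size=n_decoy)
        dec_pep_idx = rng.integers(0, 3, size=n_decoy)
        dec_run_idx = rng.integers(0, len(runs), size=n_decoy)
        q10 = float(np.quantile(observed["intensity"], 0.1))
        dec_intensity = q10 * 10.0 ** rng.normal(0.0, 0.3, size=n_decoy)
        decoys = pd.DataFrame(
            {
                "run_id": runs["run_id"].to_numpy()[dec_run_idx],
                "condition": runs["condition"].to_numpy()[dec_run_idx],
                "replicate": runs["replicate"].to_numpy()[dec_run_idx],
                "protein_group": [f"DECOY_P{i:03d}" for i in dec_prot_idx],
                "peptide_id": [
                    f"DECOY_P{i:03d}_pep{j + 1}_2"
                    for i, j in zip(dec_prot_idx, dec_pep_idx)
                ],
                "intensity": dec_intensity,
                "m_score": p.decoy_mscore_dist.sample(rng, n_decoy),
                "decoy": True,
                "proteotypic": True,
            }
        )
        decoys = decoys.drop_duplicates(subset=["peptide_id", "run_id"])
        observed = pd.concat([observed, decoys], ignore_index=True)

    observed = observed[list(REQUIRED_COLUMNS)]
    if return_latent:
        return observed, latent
    return observed


@dataclass(frozen=True)
class TrapSpec:
    """Ground-truth perturbation of one mutant-trapped condition."""

    trapped: frozenset[str]
    impaired: frozenset[str]


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete simulated study: table + ground truth + trap design."""

    table: pd.DataFrame
    ground_truth: GroundTruth
    params: SimulationParams
    bait_conditions: tuple[str, ...]
    control_condition: str
    trap_sets: dict[str, TrapSpec]


def default_dataset(seed: int = 0, n_factors: int = 100) -> SyntheticDataset:
    """The canonical simulated study: four bait conditions plus two
    mutant-trapped conditions, three replicates each.

    Twenty factors are trapped (gain 4x) and five are recruitment-impaired
    in each mutant condition, chosen deterministically from the seed.
    """
    p0 = SimulationParams(seed=seed, n_factors=n_factors)
    gt = make_ground_truth(p0)
    rng = np.random.default_rng([2, seed])
    factors = np.asarray(gt.factors)

    control = p0.conditions[-1]
    resident_at_control = set(
        gt.occupancy.index[(gt.occupancy[control] > 0) & ~gt.is_anchor]
    )

    def pick_sets():
        # 20% of factors trapped, 5% recruitment-impaired (20 and 5 at the
        # canonical 100-factor size)
        n_trap = max(1, round(0.2 * len(factors)))
        n_imp = max(1, round(0.05 * len(factors)))
        trapped = set(rng.choice(factors, size=n_trap, replace=False))
        imp_pool = sorted(resident_at_control - trapped)
        impaired = set(
            rng.choice(imp_pool, size=min(n_imp, len(imp_pool)), replace=False)
        )
        return frozenset(trapped), frozenset(impaired)

    trap_sets: dict[str, TrapSpec] = {}
    for mutant in (f"{control}:Drg1DN", f"{control}:Nog1DN"):
        trapped, impaired = pick_sets()
        gt = add_trap_condition(gt, mutant, control, trapped, impaired)
        trap_sets[mutant] = TrapSpec(trapped=trapped, impaired=impaired)

    p = replace(p0, conditions=tuple(gt.conditions))
    table = simulate_peptide_table(gt, p)
    return SyntheticDataset(
        table=table,
        ground_truth=gt,
        params=p,
        bait_conditions=p0.conditions,
        control_condition=control,
        trap_sets=trap_sets,
    )
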