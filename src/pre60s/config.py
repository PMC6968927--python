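"""Configuration objects for the quantification pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

#: Core 60S ribosomal-protein groups of assumed constant stoichiometry, used
#: to mean-center run intensities. Paralog pairs are atomic identifiers.
#: The list is kept verbatim from the analysis it reproduces — note that
#: RPL14A, RPL14B and RPL14A/RPL14B appear as three distinct identifiers.
DEFAULT_ANCHORS: tuple[str, ...] = (
    "RPL28",
    "RPL14B",
    "RPL14A",
    "RPL3",
    "RPL19A/RPL19B",
    "RPL35A/RPL35B",
    "RPL12A/RPL12B",
    "RPL27A/RPL27B",
    "RPL2B/RPL2A",
    "RPL14A/RPL14B",
    "RPL7B/RPL7A",
    "RPL1A/RPL1B",
)

#: Three-protein anchor variant (heat-map figure legend names three 60S
#: r-proteins rather than the full Methods list).
THREE_PROTEIN_ANCHORS: tuple[str, ...] = ("RPL28", "RPL3", "RPL1A/RPL1B")


def dedupe_anchors(anchors: Sequence[str]) -> list[str]:
    """De-duplicate anchor identifiers, preserving first-seen order."""
    return list(dict.fromkeys(anchors))


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the identification filter cascade.

    Attributes
    ----------
    peptide_mscore:
        Keep peptide assays with m-score strictly below this value.
    protein_gate_mscore:
        A protein group passes the gate if at least one of its non-decoy
        peptide rows has m-score strictly below this value (the value
        corresponds to a 1% protein FDR in the source analysis).
    min_peptides:
        Proteins with fewer distinct surviving peptides are removed.
    replicate_rule:
        Descriptive label of the replicate-consistency rule; the only
        implemented rule is "all replicates of >=1 condition".
    drop_decoys:
        Remove decoy rows at the m-score stage.
    proteotypic_only:
        Keep only proteotypic peptides.
    replicate_before_mscore:
        Evaluate the replicate-consistency rule on the unfiltered table
        instead of after the m-score filter (alternative cascade order).
    """

    peptide_mscore: float = 0.01
    protein_gate_mscore: float = 0.00000208508
    min_peptides: int = 2
    replicate_rule: str = "all replicates of >=1 condition"
    drop_decoys: bool = True
    proteotypic_only: bool = True
    replicate_before_mscore: bool = False

    def __post_init__(self) -> None:
        if self.protein_gate_mscore > self.peptide_mscore:
            raise ValueError(
                "protein_gate_mscore must not exceed peptide_mscore"
            )
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")


@dataclass(frozen=True)
class AnchorSet:
    """Protein groups of assumed constant stoichiometry used for
    normalization. Non-empty; duplicates are dropped by identifier."""

    protein_groups: tuple[str, ...] = DEFAULT_ANCHORS

    def __post_init__(self) -> None:
        deduped = tuple(dedupe_anchors(self.protein_groups))
        if not deduped:
            raise ValueError("anchor set must be non-empty")
        object.__setattr__(self, "protein_groups", deduped)

    def __iter__(self):
        return iter(self.protein_groups)

    def __len__(self) -> int:
        return len(self.protein_groups)


@dataclass
class PipelineConfig:
    """Full pipeline configuration (see ``docs/methods.md`` for rationale).

    ``comparisons`` lists (mutant_condition, control_condition) pairs for
    accumulation-class calling; ``perturbations`` optionally maps a mutant
    condition to a named perturbation of the pathway graph (e.g.
    ``{"Lsg1:Nog1DN": "Nog1DN"}``) to enable the prediction cross-check.
    """

    input_table: str | None = None
    outdir: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    anchors: AnchorSet = field(default_factory=AnchorSet)
    normalize_target: str | float = "unit"
    normalize_mode: str = "linear"
    impute_lo: float = 0.7
    impute_hi: float = 0.9
    seed: int | None = None
    condition_order: list[str] | None = None
    profile_conditions: list[str] | None = None
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    up_threshold: float = 2.0
    down_threshold: float = 0.5
    plateau_tol: float = 0.25
    pathway_graph: str | None = None
    perturbations: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["anchors"] = list(self.anchors.protein_groups)
        d["comparisons"] = [list(pair) for pair in self.comparisons]
        return d

    def sha256(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "filter" in d and isinstance(d["filter"], dict):
            d["filter"] = FilterConfig(**d["filter"])
        if "anchors" in d and not isinstance(d["anchors"], AnchorSet):
            d["anchors"] = AnchorSet(tuple(d["anchors"]))
        if "comparisons" in d:
            d["comparisons"] = [tuple(p) for p in d["comparisons"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
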