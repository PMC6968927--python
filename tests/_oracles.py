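"""Brute-force reference implementations used to cross-check the package.

Everything here is written as direct enumeration over rows/events, kept
deliberately independent of the pandas/networkx implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def rows_of(table: pd.DataFrame) -> list[dict]:
    return table.to_dict("records")


def _is_obs(row: dict) -> bool:
    v = row["intensity"]
    return v is not None and not (isinstance(v, float) and math.isnan(v))


# --- filter oracles ---------------------------------------------------------

def oracle_protein_gate(rows: list[dict], gate_mscore: float) -> set[str]:
    out = set()
    for r in rows:
        if not r["decoy"] and r["m_score"] < gate_mscore:
            out.add(r["protein_group"])
    return out


def oracle_mscore_filter(
    rows: list[dict],
    peptide_mscore: float,
    gate_mscore: float,
    drop_decoys: bool = True,
) -> list[dict]:
    gate = oracle_protein_gate(rows, gate_mscore)
    out = []
    for r in rows:
        if r["m_score"] >= peptide_mscore:
            continue
        if r["protein_group"] not in gate:
            continue
        if drop_decoys and r["decoy"]:
            continue
        out.append(r)
    return out


def oracle_proteotypic(rows: list[dict]) -> list[dict]:
    return [r for r in rows if r["proteotypic"]]


def oracle_required_replicates(rows: list[dict]) -> dict[str, int]:
    per_cond: dict[str, set] = {}
    for r in rows:
        per_cond.setdefault(r["condition"], set()).add(r["replicate"])
    return {c: len(reps) for c, reps in per_cond.items()}


def oracle_replicate_filter(
    rows: list[dict], required: dict[str, int] | None = None
) -> list[dict]:
    if required is None:
        required = oracle_required_replicates(rows)
    seen: dict[tuple, dict[str, set]] = {}
    for r in rows:
        if not _is_obs(r):
            continue
        key = (r["protein_group"], r["peptide_id"])
        seen.setdefault(key, {}).setdefault(r["condition"], set()).add(r["replicate"])
    kept = {
        key
        for key, conds in seen.items()
        if any(len(reps) >= required[c] for c, reps in conds.items())
    }
    return [r for r in rows if (r["protein_group"], r["peptide_id"]) in kept]


def oracle_min_peptides(rows: list[dict], min_peptides: int) -> list[dict]:
    peps: dict[str, set] = {}
    for r in rows:
        peps.setdefault(r["protein_group"], set()).add(r["peptide_id"])
    kept = {p for p, s in peps.items() if len(s) >= min_peptides}
    return [r for r in rows if r["protein_group"] in kept]


def oracle_cascade(
    rows: list[dict],
    peptide_mscore: float,
    gate_mscore: float,
    min_peptides: int,
    required: dict[str, int] | None = None,
) -> list[dict]:
    if required is None:
        required = oracle_required_replicates(rows)
    out = oracle_mscore_filter(rows, peptide_mscore, gate_mscore)
    out = oracle_proteotypic(out)
    out = oracle_replicate_filter(out, required)
    out = oracle_min_peptides(out, min_peptides)
    return out


def row_keys(rows: list[dict]) -> set[tuple]:
    return {(r["run_id"], r["protein_group"], r["peptide_id"]) for r in rows}


# --- rollup oracle ----------------------------------------------------------

def oracle_rollup(rows: list[dict]) -> dict[tuple, float]:
    """(protein_group, run_id) -> summed peptide intensity."""
    out: dict[tuple, float] = {}
    for r in rows:
        if not _is_obs(r):
            continue
        key = (r["protein_group"], r["run_id"])
        out[key] = out.get(key, 0.0) + r["intensity"]
    return out


# --- reachability oracle ----------------------------------------------------

def oracle_reachable(events: dict, blocked: set[str]) -> set[str]:
    """Fixed-point iteration: repeatedly fire any enabled event until no
    change. ``events`` maps name -> object with a ``requires`` tuple."""
    fired: set[str] = set()
    changed = True
    while changed:
        changed = False
        for name, ev in events.items():
            if name in fired or name in blocked:
                continue
            if all(req in fired for req in ev.requires):
                fired.add(name)
                changed = True
    return fired


# --- random table generator -------------------------------------------------

def random_table(
    rng: np.random.Generator,
    max_rows: int = 200,
    anchors: tuple[str, ...] = (),
) -> pd.DataFrame:
    """A small random peptide-assay table spanning both m-score thresholds,
    with missing intensities, decoys and shared peptides.

    When ``anchors`` is given, those protein groups receive an observed,
    confidently scored row in every run (so normalization preconditions
    hold); remaining content is unconstrained.
    """
    n_cond = int(rng.integers(1, 4))
    n_rep = int(rng.integers(1, 4))
    runs = [
        (f"C{c}_r{r}", f"C{c}", r)
        for c in range(1, n_cond + 1)
        for r in range(1, n_rep + 1)
    ]
    n_prot = int(rng.integers(2, 9))
    proteins = [f"P{i}" for i in range(1, n_prot)] + ["RPX1A/RPX1B"]
    anchor_rows: list[dict] = []
    rows: list[dict] = []
    for run_id, cond, rep in runs:
        for a in anchors:
            anchor_rows.append(
                {
                    "run_id": run_id,
                    "condition": cond,
                    "replicate": rep,
                    "protein_group": a,
                    "peptide_id": f"{a}_pep1_2",
                    "intensity": float(10 ** rng.uniform(3, 6)),
                    "m_score": 1e-8,
                    "decoy": False,
                    "proteotypic": True,
                }
            )
    for prot in proteins:
        is_decoy = rng.random() < 0.1
        name = f"DECOY_{prot}" if is_decoy else prot
        n_pep = int(rng.integers(1, 5))
        for j in range(1, n_pep + 1):
            proteotypic = rng.random() < 0.8
            for run_id, cond, rep in runs:
                if rng.random() > 0.6:
                    continue
                missing = rng.random() < 0.05
                rows.append(
                    {
                        "run_id": run_id,
                        "condition": cond,
                        "replicate": rep,
                        "protein_group": name,
                        "peptide_id": f"{name}_pep{j}_2",
                        "intensity": float("nan")
                        if missing
                        else float(10 ** rng.uniform(2, 6)),
                        "m_score": float(10 ** rng.uniform(-9, 0)),
                        "decoy": is_decoy,
                        "proteotypic": proteotypic,
                    }
                )
    rng.shuffle(rows)
    rows = anchor_rows + rows[: max(0, max_rows - len(anchor_rows))]
    return pd.DataFrame(
        rows,
        columns=[
            "run_id",
            "condition",
            "replicate",
            "protein_group",
            "peptide_id",
            "intensity",
            "m_score",
            "decoy",
            "proteotypic",
        ],
    )
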