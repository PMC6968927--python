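"""Reading, writing and validation of long-format peptide-assay tables.

The pipeline's universal currency is a tab-separated table with one row per
peptide precursor per MS run, the shape produced by targeted DIA extraction
tools (OpenSWATH / pyProphet / TRIC). Columns:

===============  ========================================================
run_id           opaque run label; one-to-one with (condition, replicate)
condition        bait / genotype label, e.g. ``Lsg1`` or ``Lsg1:Nog1DN``
replicate        1-based replicate index within the condition
protein_group    protein identifier; paralog groups such as
                 ``RPL19A/RPL19B`` are a single atomic identifier
peptide_id       precursor identifier (sequence + charge)
intensity        positive real, arbitrary units; empty field = missing
m_score          identification error-rate score in [0, 1] (lower = better)
decoy            ``True``/``False`` — decoy library entry
proteotypic      ``True``/``False`` — peptide maps to a single protein group
===============  ========================================================

Missing intensities may be encoded either as an empty field or by the row
being absent altogether; both are treated identically downstream.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS: tuple[str, ...] = (
    "run_id",
    "condition",
    "replicate",
    "protein_group",
    "peptide_id",
    "intensity",
    "m_score",
    "decoy",
    "proteotypic",
)

_BOOL_VALUES = {
    "true": True, "false": False, "1": True, "0": False,
    "t": True, "f": False, "yes": True, "no": False,
}


class PeptideTableError(ValueError):
    """Raised when a peptide-assay table violates the column contract."""


def _parse_bool(value: str) -> bool:
    try:
        return _BOOL_VALUES[value.strip().lower()]
    except KeyError:
        raise ValueError(f"not a boolean: {value!r}") from None


def read_peptide_table(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a peptide-assay TSV.

    Parameters
    ----------
    path:
        Tab-separated file with a header row containing at least the
        required columns (see module docstring).
    column_map:
        Optional mapping from file column names to contract names, to adapt
        other extraction-tool dialects (e.g. ``{"ProteinName":
        "protein_group"}``).

    Returns
    -------
    Validated :class:`pandas.DataFrame`. Malformed rows are reported with
    their 1-based line numbers (the header is line 1).

    Raises
    ------
    PeptideTableError
        On missing columns or malformed field values.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise PeptideTableError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    raw = raw[list(REQUIRED_COLUMNS)]

    errors: list[str] = []

    def convert(col: str, fn, allow_empty: bool = False):
        out = []
        for i, value in enumerate(raw[col].tolist()):
            line = i + 2  # header is line 1
            if value == "" and allow_empty:
                out.append(np.nan)
                continue
            try:
                out.append(fn(value))
            except (ValueError, TypeError):
                errors.append(f"line {line}: bad {col} value {value!r}")
                out.append(np.nan)
        return out

    table = pd.DataFrame(
        {
            "run_id": raw["run_id"],
            "condition": raw["condition"],
            "replicate": convert("replicate", int),
            "protein_group": raw["protein_group"],
            "peptide_id": raw["peptide_id"],
            "intensity": convert("intensity", float, allow_empty=True),
            "m_score": convert("m_score", float),
            "decoy": convert("decoy", _parse_bool),
            "proteotypic": convert("proteotypic", _parse_bool),
        }
    )
    if errors:
        head = "; ".join(errors[:10])
        more = f" (+{len(errors) - 10} more)" if len(errors) > 10 else ""
        raise PeptideTableError(f"{path}: {head}{more}")

    bad_int = table.index[table["intensity"].notna() & (table["intensity"] <= 0)]
    for i in bad_int[:10]:
        errors.append(f"line {i + 2}: non-positive intensity")
    bad_ms = table.index[
        table["m_score"].isna()
        | (table["m_score"] < 0)
        | (table["m_score"] > 1)
    ]
    for i in bad_ms[:10]:
        errors.append(f"line {i + 2}: m_score outside [0, 1]")
    if errors:
        raise PeptideTableError(f"{path}: " + "; ".join(errors))

    table["replicate"] = table["replicate"].astype(int)
    table["decoy"] = table["decoy"].astype(bool)
    table["proteotypic"] = table["proteotypic"].astype(bool)
    validate_run_bijection(table)
    return table


def validate_run_bijection(table: pd.DataFrame) -> None:
    """Check that ``run_id`` and ``(condition, replicate)`` are one-to-one."""
    if table.empty:
        return
    per_run = table.groupby("run_id")[["condition", "replicate"]].nunique()
    bad = per_run[(per_run["condition"] > 1) | (per_run["replicate"] > 1)]
    if not bad.empty:
        raise PeptideTableError(
            f"run_id(s) mapped to multiple (condition, replicate): "
            f"{', '.join(bad.index[:5])}"
        )
    per_pair = table.groupby(["condition", "replicate"])["run_id"].nunique()
    bad_pair = per_pair[per_pair > 1]
    if not bad_pair.empty:
        pairs = ", ".join(str(p) for p in bad_pair.index[:5])
        raise PeptideTableError(
            f"(condition, replicate) pair(s) mapped to multiple run_ids: {pairs}"
        )


def write_peptide_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a peptide-assay table as TSV (empty field = missing intensity).

    Values round-trip bit-exactly through :func:`read_peptide_table`.
    """
    cols = [c for c in REQUIRED_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, sep="\t", index=False)


def run_roster(table: pd.DataFrame) -> pd.DataFrame:
    """Distinct runs of a table, in order of first appearance.

    Returns a frame with columns ``run_id``, ``condition``, ``replicate``.
    """
    roster = table[["run_id", "condition", "replicate"]].drop_duplicates()
    return roster.reset_index(drop=True)


def condition_order(table: pd.DataFrame) -> list[str]:
    """Condition labels in order of first appearance."""
    return list(dict.fromkeys(table["condition"]))


def write_matrix(df: pd.DataFrame, path: str | os.PathLike, index_label: str = "protein_group") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def observed_mask(table: pd.DataFrame) -> pd.Series:
    """True for rows carrying an observed (non-missing) intensity."""
    return table["intensity"].notna()
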