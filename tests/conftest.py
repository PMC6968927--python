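import numpy as np
import pandas as pd
import pytest


def mk_rows(*specs, **defaults) -> pd.DataFrame:
    """Build a peptide-assay table from terse row specs.

    Each spec is a dict; missing fields are filled from sensible defaults
    (confident m-score, non-decoy, proteotypic). ``run_id`` is derived from
    (condition, replicate) when omitted.
    """
    base = {
        "condition": "C1",
        "replicate": 1,
        "protein_group": "P1",
        "peptide_id": "P1_pep1_2",
        "intensity": 100.0,
        "m_score": 1e-8,
        "decoy": False,
        "proteotypic": True,
    }
    base.update(defaults)
    rows = []
    for spec in specs:
        row = dict(base)
        row.update(spec)
        row.setdefault("run_id", f"{row['condition']}_r{row['replicate']}")
        rows.append(row)
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


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture(scope="session")
def default_study():
    """The canonical simulated study, shared across tests (read-only)."""
    from pre60s.synthetic import default_dataset

    return default_dataset(seed=0)


@pytest.fixture(scope="session")
def default_study_result(default_study):
    """Pipeline output on the canonical study (read-only)."""
    from pre60s import PipelineConfig, run_pipeline

    ds = default_study
    control = ds.control_condition
    cfg = PipelineConfig(
        seed=1,
        profile_conditions=list(ds.bait_conditions),
        comparisons=[(m, control) for m in ds.trap_sets],
        perturbations={
            f"{control}:Drg1DN": "Drg1DN",
            f"{control}:Nog1DN": "Nog1DN",
        },
    )
    return run_pipeline(cfg, table=ds.table)
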