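import numpy as np
import pandas as pd
import pytest

import _oracles as orc
from conftest import mk_rows
from pre60s.config import AnchorSet
from pre60s.io import run_roster
from pre60s.quantify import (
    anchor_summaries,
    impute_missing,
    normalize_anchor,
    rollup,
)

ANCHORS = AnchorSet(("A1", "A2"))


def anchored_table(rng):
    return orc.random_table(rng, anchors=("A1", "A2"))


# --- anchor normalization ---------------------------------------------------

def test_grand_mean_target_leaves_single_run_unchanged():
    table = mk_rows(
        {"protein_group": "A1", "peptide_id": "a1", "intensity": 10.0},
        {"protein_group": "A2", "peptide_id": "a2", "intensity": 30.0},
        {"protein_group": "P1", "peptide_id": "p1", "intensity": 5.0},
    )
    out = normalize_anchor(table, ANCHORS, target="grand_mean")
    pd.testing.assert_series_equal(out["intensity"], table["intensity"])


def test_two_run_closed_form():
    """Run B is exactly 2x run A: normalization equalizes the anchor
    summaries, and with the grand-mean target the common level is
    (S_A + S_B)/2 = 30, i.e. run A scales by 1.5 and run B by 0.75."""
    rows_a = [
        {"condition": "C1", "protein_group": "A1", "peptide_id": "a1", "intensity": 10.0},
        {"condition": "C1", "protein_group": "A2", "peptide_id": "a2", "intensity": 30.0},
        {"condition": "C1", "protein_group": "P1", "peptide_id": "p1", "intensity": 8.0},
    ]
    rows_b = [dict(r, condition="C2", intensity=2 * r["intensity"]) for r in rows_a]
    table = mk_rows(*rows_a, *rows_b)
    out = normalize_anchor(table, ANCHORS, target="grand_mean")
    got = out.set_index(["condition", "peptide_id"])["intensity"]
    assert got[("C1", "p1")] == pytest.approx(8.0 * 1.5, rel=1e-12)
    assert got[("C2", "p1")] == pytest.approx(16.0 * 0.75, rel=1e-12)
    s = anchor_summaries(out, ANCHORS)
    assert np.allclose(s, 30.0, rtol=1e-12)


def test_post_normalization_summaries_equal_grand_mean(rng):
    for target in ("unit", "grand_mean", 42.0):
        for _ in range(5):
            table = anchored_table(rng)
            out = normalize_anchor(table, ANCHORS, target=target)
            s = anchor_summaries(out, ANCHORS)
            assert np.allclose(s, s.mean(), rtol=1e-9)


def test_normalization_is_exactly_invariant_to_run_rescaling(rng):
    """A per-run multiplicative batch effect is absorbed completely: the
    default normalization of the rescaled table is bit-comparable to that
    of the original."""
    table = anchored_table(rng)
    run = table["run_id"].iloc[0]
    scaled = table.copy()
    scaled.loc[scaled["run_id"] == run, "intensity"] *= 7.3
    a = normalize_anchor(table, ANCHORS)["intensity"].to_numpy()
    b = normalize_anchor(scaled, ANCHORS)["intensity"].to_numpy()
    np.testing.assert_allclose(b, a, rtol=1e-12, equal_nan=True)


def test_relative_intensities_within_run_unchanged(rng):
    table = anchored_table(rng)
    out = normalize_anchor(table, ANCHORS)
    obs = table["intensity"].notna()
    for run in table["run_id"].unique():
        mask = (table["run_id"] == run) & obs
        before = table.loc[mask, "intensity"].to_numpy()
        after = out.loc[mask, "intensity"].to_numpy()
        ratio = after / before
        assert np.allclose(ratio, ratio[0], rtol=1e-12)


def test_missing_anchor_error_names_run_and_anchor():
    table = mk_rows(
        {"condition": "C1", "protein_group": "A1", "peptide_id": "a1"},
        {"condition": "C1", "protein_group": "A2", "peptide_id": "a2"},
        {"condition": "C2", "protein_group": "A1", "peptide_id": "a1"},
    )
    with pytest.raises(ValueError, match=r"A2.*C2_r1"):
        normalize_anchor(table, ANCHORS)


def test_log_mode_uses_geometric_mean():
    table = mk_rows(
        {"protein_group": "A1", "peptide_id": "a1", "intensity": 10.0},
        {"protein_group": "A2", "peptide_id": "a2", "intensity": 1000.0},
    )
    s = anchor_summaries(table, ANCHORS, mode="log")
    assert s.iloc[0] == pytest.approx(100.0, rel=1e-12)


# --- imputation -------------------------------------------------------------

def test_no_missing_cells_leaves_table_unchanged():
    table = mk_rows(
        {"replicate": 1, "intensity": 10.0},
        {"replicate": 2, "intensity": 20.0},
    )
    out = impute_missing(table, seed=1)
    assert not out["imputed"].any()
    pd.testing.assert_frame_equal(out.drop(columns="imputed"), table)


def test_imputed_values_bounded_by_assay_minimum(rng):
    table = orc.random_table(rng)
    table = table[table["intensity"].notna()]
    out = impute_missing(table, seed=3)
    mins = (
        table.groupby(["protein_group", "peptide_id"])["intensity"].min()
    )
    imp = out[out["imputed"]]
    for _, row in imp.iterrows():
        m = mins[(row["protein_group"], row["peptide_id"])]
        assert 0.7 * m <= row["intensity"] <= 0.9 * m
    # imputed flag count equals missing-cell count
    n_runs = len(run_roster(table))
    n_assays = table.groupby(["protein_group", "peptide_id"]).ngroups
    assert len(imp) == n_assays * n_runs - len(table)


def test_imputation_mean_matches_uniform_distribution():
    """1e4 imputed draws for one assay with known minimum m: the sample
    mean must lie within 3 standard errors of 0.8 m."""
    m = 50.0
    runs = [{"condition": "C1", "replicate": 1, "peptide_id": "p", "intensity": m}]
    runs += [
        {"condition": f"X{i}", "replicate": 1, "peptide_id": "p", "intensity": np.nan}
        for i in range(10_000)
    ]
    table = mk_rows(*runs)
    out = impute_missing(table, seed=5)
    draws = out.loc[out["imputed"], "intensity"]
    se = (0.2 * m / np.sqrt(12)) / np.sqrt(len(draws))
    assert len(draws) == 10_000
    assert abs(draws.mean() - 0.8 * m) < 3 * se


def test_imputation_deterministic_and_row_order_independent(rng):
    table = orc.random_table(rng)
    table = table[table["intensity"].notna()]
    a = impute_missing(table, seed=11)
    b = impute_missing(table, seed=11)
    pd.testing.assert_frame_equal(a, b, check_exact=True)
    shuffled = table.sample(frac=1.0, random_state=0)
    c = impute_missing(shuffled, seed=11)
    key = ["protein_group", "peptide_id", "run_id"]
    pd.testing.assert_frame_equal(
        a.sort_values(key).reset_index(drop=True),
        c.sort_values(key).reset_index(drop=True),
        check_exact=True,
    )


def test_assay_with_no_observation_is_an_error():
    table = mk_rows(
        {"peptide_id": "p1", "intensity": np.nan},
        {"peptide_id": "p2", "intensity": 10.0},
    )
    with pytest.raises(ValueError, match="p1"):
        impute_missing(table, seed=1)


def test_seed_required_only_when_cells_are_missing():
    complete = mk_rows({"intensity": 10.0})
    impute_missing(complete)  # fine without a seed
    sparse = mk_rows(
        {"replicate": 1, "intensity": 10.0},
        {"replicate": 2, "peptide_id": "q", "intensity": 5.0},
    )
    with pytest.raises(ValueError, match="seed"):
        impute_missing(sparse)


# --- rollup -----------------------------------------------------------------

def test_single_peptide_protein_equals_its_peptide():
    table = mk_rows(
        {"replicate": 1, "intensity": 12.5},
        {"replicate": 2, "intensity": 20.0},
    )
    pq = rollup(table)
    assert pq.intensity.loc["P1", "C1_r1"] == 12.5
    assert pq.intensity.loc["P1", "C1_r2"] == 20.0


def test_peptides_sum_within_run():
    table = mk_rows(
        {"peptide_id": "p1", "intensity": 10.0},
        {"peptide_id": "p2", "intensity": 30.0},
    )
    pq = rollup(table)
    assert pq.intensity.loc["P1", "C1_r1"] == 40.0


def test_rollup_matches_bruteforce_and_conserves_totals(rng):
    for _ in range(20):
        table = orc.random_table(rng)
        table = table[table["intensity"].notna()]
        # complete the grid so the rollup precondition holds
        table = impute_missing(table, seed=7)
        pq = rollup(table)
        expected = orc.oracle_rollup(orc.rows_of(table))
        for (prot, run), value in expected.items():
            assert pq.intensity.loc[prot, run] == pytest.approx(value, rel=1e-12)
        # conservation: per-run rollup total equals per-run peptide total
        totals = table.groupby("run_id")["intensity"].sum()
        for run, value in totals.items():
            assert pq.intensity[run].sum() == pytest.approx(value, rel=1e-12)


def test_condition_mean_and_sample_sd():
    table = mk_rows(
        {"replicate": 1, "intensity": 10.0},
        {"replicate": 2, "intensity": 14.0},
        {"replicate": 3, "intensity": 18.0},
    )
    pq = rollup(table)
    assert pq.condition_mean.loc["P1", "C1"] == pytest.approx(14.0)
    assert pq.condition_sd.loc["P1", "C1"] == pytest.approx(4.0)  # n-1 denominator


def test_incomplete_grid_is_rejected_with_cell_listing():
    table = mk_rows(
        {"replicate": 1, "peptide_id": "p1"},
        {"replicate": 2, "peptide_id": "p1"},
        {"replicate": 1, "peptide_id": "p2"},
    )
    with pytest.raises(ValueError, match=r"p2.*C1_r2"):
        rollup(table)


def test_imputed_fraction_tracks_provenance(rng):
    table = orc.random_table(rng)
    table = table[table["intensity"].notna()]
    out = impute_missing(table, seed=13)
    pq = rollup(out)
    frac = pq.imputed_fraction
    assert ((frac >= 0) & (frac <= 1)).all().all()
    expected = out.groupby(["protein_group", "run_id"])["imputed"].mean()
    for (prot, run), value in expected.items():
        assert frac.loc[prot, run] == pytest.approx(value)


# --- property-based checks ---------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.floats(min_value=1e-3, max_value=1e3), st.integers(min_value=0, max_value=999))
def test_run_rescaling_absorbed_for_any_factor(c, table_seed):
    """Multiplying one run's intensities by any positive constant leaves
    the normalized table unchanged to floating-point precision."""
    table = orc.random_table(np.random.default_rng(table_seed), anchors=("A1", "A2"))
    run = table["run_id"].iloc[0]
    scaled = table.copy()
    scaled.loc[scaled["run_id"] == run, "intensity"] *= c
    a = normalize_anchor(table, ANCHORS)["intensity"].to_numpy()
    b = normalize_anchor(scaled, ANCHORS)["intensity"].to_numpy()
    np.testing.assert_allclose(b, a, rtol=1e-9, equal_nan=True)
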