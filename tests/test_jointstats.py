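"""Cross-tabulation, reversal screening, and heatmap clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from meriparray.differential import percent_of
from meriparray.exceptions import DataError
from meriparray.jointstats import cluster_profiles, crosstab_meth_expr, reversal_screen
from .conftest import records_from_classes


def test_crosstab_reproduces_quadrant_totals():
    """Cells 228/439/190/204 give 1,061 methylation-changed genes, 62.9%/37.1% shares."""
    records = records_from_classes(
        [
            ("hyper", "up", 228),        # expression-changed & hyper
            ("hyper", "unchanged", 439),
            ("hypo", "down", 190),       # expression-changed & hypo
            ("hypo", "unchanged", 204),
            ("unchanged", "unchanged", 1000),
        ]
    )
    ct = crosstab_meth_expr(records)
    m = ct.marginals
    assert m["n_hyper"] == 667 and m["n_hypo"] == 394
    assert m["n_methylation_changed"] == 1061
    assert percent_of(m["n_hyper"], m["n_methylation_changed"], 1) == 62.9
    assert percent_of(m["n_hypo"], m["n_methylation_changed"], 1) == 37.1


def test_crosstab_hyper_share_of_stress_contrast():
    """Cells 2535/4982/56/32 give 7,605 changed genes, 98.8% hypermethylated."""
    records = records_from_classes(
        [
            ("hyper", "up", 2535),
            ("hyper", "unchanged", 4982),
            ("hypo", "down", 56),
            ("hypo", "unchanged", 32),
        ]
    )
    m = crosstab_meth_expr(records).marginals
    assert m["n_methylation_changed"] == 7605
    assert percent_of(m["n_hyper"], m["n_methylation_changed"], 1) == 98.8


def test_crosstab_all_unchanged_fills_center_cell_only():
    records = records_from_classes([("unchanged", "unchanged", 7)])
    ct = crosstab_meth_expr(records)
    assert ct.counts.loc["unchanged", "unchanged"] == 7
    assert ct.counts.to_numpy().sum() == 7


def test_crosstab_rejects_duplicate_genes():
    records = records_from_classes([("hyper", "up", 2)])
    records["gene_id"] = "same"
    with pytest.raises(DataError, match="duplicate"):
        crosstab_meth_expr(records)


@given(
    counts=st.lists(st.integers(min_value=0, max_value=20), min_size=9, max_size=9)
)
def test_crosstab_partitions_the_universe(counts):
    cells = [
        (meth, expr)
        for meth in ("hyper", "unchanged", "hypo")
        for expr in ("up", "unchanged", "down")
    ]
    records = records_from_classes(
        [(meth, expr, n) for (meth, expr), n in zip(cells, counts)]
    )
    if records.empty:
        return
    ct = crosstab_meth_expr(records)
    assert ct.counts.to_numpy().sum() == len(records)
    all_genes = sorted(g for genes in ct.genes.values() for g in genes)
    assert all_genes == sorted(records["gene_id"])  # disjoint and exhaustive


def _records(rows):
    return pd.DataFrame(
        [
            {
                "gene_id": g,
                "fc_expression": 1.0,
                "class_expression": e,
                "fc_methylation": 1.0,
                "class_methylation": m,
            }
            for g, e, m in rows
        ]
    )


def test_reversal_screen_definitions():
    a = _records(
        [
            ("g1", "up", "unchanged"),
            ("g2", "up", "unchanged"),
            ("g3", "down", "unchanged"),
            ("g4", "unchanged", "hyper"),
            ("g5", "unchanged", "hypo"),
            ("g6", "unchanged", "hyper"),
        ]
    )
    b = _records(
        [
            ("g1", "down", "unchanged"),   # up then down
            ("g2", "up", "unchanged"),     # up in both -> no set
            ("g3", "up", "unchanged"),     # down then up
            ("g4", "unchanged", "hypo"),   # hyper->hypo, expression stable
            ("g5", "unchanged", "hyper"),  # hypo->hyper, expression stable
            ("g6", "up", "hypo"),          # hyper->hypo but expression changed in B
        ]
    )
    sets = reversal_screen(a, b)
    assert sets.up_then_down == ["g1"]
    assert sets.down_then_up == ["g3"]
    assert sets.hyper_then_hypo == ["g4", "g6"]
    assert sets.hypo_then_hyper == ["g5"]
    assert sets.stable_expression_m6a_reversed == ["g4", "g5"]
    assert sets.stable_expression_hyper_to_hypo == ["g4"]


def test_reversal_screen_mirror_identity(noiseless_sim):
    from meriparray.differential import Contrast, run_contrast

    _, _, _, genes = noiseless_sim
    rec_a = run_contrast(genes, Contrast("CUMS_Sham", "WT"))
    rec_b = run_contrast(genes, Contrast("CUMS_DBS", "CUMS_Sham"))
    forward = reversal_screen(rec_a, rec_b)
    backward = reversal_screen(rec_b, rec_a)
    assert forward.up_then_down == backward.down_then_up
    assert forward.hyper_then_hypo == backward.hypo_then_hyper


def test_reversal_screen_uses_shared_universe_only():
    a = _records([("g1", "up", "unchanged"), ("g2", "up", "unchanged")])
    b = _records([("g1", "down", "unchanged"), ("g3", "down", "unchanged")])
    sets = reversal_screen(a, b)
    assert sets.up_then_down == ["g1"]
    with pytest.raises(DataError):
        reversal_screen(a, _records([("zz", "up", "hyper")]))


def test_reversal_matches_ground_truth_exactly(noiseless_sim):
    """At zero noise the screened sets equal the planted reversal sets."""
    from meriparray.differential import Contrast, run_contrast

    _, _, truth, genes = noiseless_sim
    rec_a = run_contrast(genes, Contrast("CUMS_Sham", "WT"))
    rec_b = run_contrast(genes, Contrast("CUMS_DBS", "CUMS_Sham"))
    sets = reversal_screen(rec_a, rec_b)
    ta = truth.classes_for("CUMS_Sham_vs_WT").set_index("gene_id")
    tb = truth.classes_for("CUMS_DBS_vs_CUMS_Sham").set_index("gene_id")
    expected_up_down = sorted(
        ta.index[(ta["class_expression"] == "up") & (tb["class_expression"] == "down")]
    )
    assert sets.up_then_down == expected_up_down
    expected_hyper_hypo = sorted(
        ta.index[(ta["class_methylation"] == "hyper") & (tb["class_methylation"] == "hypo")]
    )
    assert sets.hyper_then_hypo == expected_hyper_hypo
    assert len(expected_hyper_hypo) > 0


def test_cluster_identical_rows_merge_first_at_zero_height():
    matrix = np.array([[1.0, 2.0], [5.0, 9.0], [1.0, 2.0]])
    result = cluster_profiles(matrix)
    assert result.merge_heights[0] == 0.0
    first = set(result.linkage[0, :2].astype(int))
    assert first == {0, 2}


def test_cluster_average_linkage_hand_example():
    """1-D points {0, 1, 10}: first merge at height 1, then average distance 9.5."""
    result = cluster_profiles(np.array([[0.0], [1.0], [10.0]]))
    np.testing.assert_allclose(result.merge_heights, [1.0, 9.5])


def test_cluster_leaf_order_is_permutation():
    rng = np.random.default_rng(0)
    matrix = rng.normal(size=(12, 3))
    result = cluster_profiles(matrix)
    assert sorted(result.leaf_order) == list(range(12))


def test_cluster_rejects_degenerate_inputs():
    with pytest.raises(DataError):
        cluster_profiles(np.array([[1.0, 2.0]]))
    with pytest.raises(DataError):
        cluster_profiles(np.array([[1.0], [np.nan]]))
    # constant rows are allowed: zero distances merge first
    result = cluster_profiles(np.zeros((3, 2)))
    assert (result.merge_heights == 0).all()
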