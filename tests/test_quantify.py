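"""Spike-in normalization and m6A/expression quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from meriparray.exceptions import DataError
from meriparray.quantify import (
    collapse_probes_to_genes,
    compute_expression,
    compute_m6a_percent,
    normalize_spikein,
    quantify_probes,
)
from .conftest import make_raw


def test_normalization_hand_example():
    """Spike-ins {4,16} vs {16,64} (log2 means 3 and 5), probe 32 vs 128, G = 4.

    Both channels normalize the probe to log2 intensity 6.
    """
    raw = make_raw(
        ["S"],
        [
            {"probe_id": "SPK0", "control_type": "spikein", "S": (4, 16)},
            {"probe_id": "SPK1", "control_type": "spikein", "S": (16, 64)},
            {"probe_id": "P1", "entrez_id": "1", "S": (32, 128)},
        ],
    )
    norm = normalize_spikein(raw, pseudocount=0.0)
    probe = norm[norm["probe_id"] == "P1"].iloc[0]
    assert probe["cy5_norm_log2"] == pytest.approx(6.0, abs=1e-12)
    assert probe["cy3_norm_log2"] == pytest.approx(6.0, abs=1e-12)


def test_normalization_invariant_to_channel_rescaling(tiny_raw):
    """Multiplying a whole channel (spike-ins included) by a constant changes nothing.

    With a fixed anchor the normalized values themselves are invariant; with
    the data-derived grand-mean anchor the invariance holds for every
    anchor-free quantity (log2 differences, hence m6A% and fold changes).
    """
    import pandas as pd

    from meriparray.arrayio import RawArraySet

    scaled = RawArraySet(samples=list(tiny_raw.samples), table=tiny_raw.table.copy())
    scaled.table["cy5_raw_A"] *= 37.5
    scaled.table["cy3_raw_B"] *= 0.004

    base = normalize_spikein(tiny_raw, pseudocount=0.0, anchor=0.0)
    renorm = normalize_spikein(scaled, pseudocount=0.0, anchor=0.0)
    np.testing.assert_allclose(
        renorm[["cy5_norm_log2", "cy3_norm_log2"]],
        base[["cy5_norm_log2", "cy3_norm_log2"]],
        atol=1e-10,
    )

    base_default = quantify_probes(normalize_spikein(tiny_raw, pseudocount=0.0))
    renorm_default = quantify_probes(normalize_spikein(scaled, pseudocount=0.0))
    np.testing.assert_allclose(
        renorm_default["m6a_percent"], base_default["m6a_percent"], atol=1e-10
    )


def test_spikein_mean_equalized_across_samples_and_channels(tiny_raw):
    norm = normalize_spikein(tiny_raw, pseudocount=0.0)
    spikes = norm[norm["control_type"] == "spikein"]
    grand = np.log2(tiny_raw.table.loc[:1, [c for c in tiny_raw.table.columns if "raw" in c]]).to_numpy().mean()
    for (sample,), group in spikes.groupby(["sample_id"]):
        assert group["cy5_norm_log2"].mean() == pytest.approx(grand, abs=1e-12)
        assert group["cy3_norm_log2"].mean() == pytest.approx(grand, abs=1e-12)


def test_probe_equal_to_spikein_normalizes_to_grand_mean():
    raw = make_raw(
        ["S"],
        [
            {"probe_id": "SPK0", "control_type": "spikein", "S": (8, 8)},
            {"probe_id": "SPK1", "control_type": "spikein", "S": (8, 8)},
            {"probe_id": "P1", "entrez_id": "1", "S": (8, 8)},
        ],
    )
    norm = normalize_spikein(raw, pseudocount=0.0)
    assert norm.loc[norm["probe_id"] == "P1", "cy5_norm_log2"].iloc[0] == pytest.approx(3.0)


def test_too_few_spikeins_rejected():
    raw = make_raw(
        ["S"],
        [
            {"probe_id": "SPK0", "control_type": "spikein", "S": (8, 8)},
            {"probe_id": "P1", "entrez_id": "1", "S": (8, 8)},
        ],
    )
    with pytest.raises(DataError, match="spike-in"):
        normalize_spikein(raw)


def test_zero_intensity_with_zero_pseudocount_directs_to_pseudocount():
    raw = make_raw(
        ["S"],
        [
            {"probe_id": "SPK0", "control_type": "spikein", "S": (8, 8)},
            {"probe_id": "SPK1", "control_type": "spikein", "S": (16, 16)},
            {"probe_id": "P1", "entrez_id": "1", "S": (0, 8)},
        ],
    )
    with pytest.raises(DataError, match="pseudocount"):
        normalize_spikein(raw, pseudocount=0.0)
    norm = normalize_spikein(raw, pseudocount=1.0)  # guarded: no error
    assert np.isfinite(norm["cy5_norm_log2"]).all()


@pytest.mark.parametrize(
    "cy5, cy3, expected",
    [(100, 100, 50.0), (75, 25, 75.0), (0, 250, 0.0), (250, 0, 100.0)],
)
def test_m6a_percent_examples(cy5, cy3, expected):
    assert compute_m6a_percent(cy5, cy3) == pytest.approx(expected)


def test_m6a_percent_errors():
    with pytest.raises(DataError):
        compute_m6a_percent(0, 0)
    with pytest.raises(DataError):
        compute_m6a_percent(-1, 10)


@given(
    cy5=st.floats(min_value=1e-6, max_value=1e9),
    cy3=st.floats(min_value=1e-6, max_value=1e9),
)
def test_m6a_percent_bounded_and_complementary(cy5, cy3):
    p = compute_m6a_percent(cy5, cy3)
    q = compute_m6a_percent(cy3, cy5)
    assert 0.0 <= p <= 100.0
    assert p + q == pytest.approx(100.0)


def test_expression_examples_and_commutativity():
    assert compute_expression(100, 50) == 150.0
    assert compute_expression(0, 0) == 0.0
    assert compute_expression(3.5, 7.25) == compute_expression(7.25, 3.5)
    with pytest.raises(DataError):
        compute_expression(-1, 5)


def _quantified_probes(raw):
    return quantify_probes(normalize_spikein(raw, pseudocount=0.0))


def test_collapse_prefers_highest_mean_expression():
    raw = make_raw(
        ["A", "B"],
        [
            {"probe_id": "SPK0", "control_type": "spikein", "A": (8, 8), "B": (8, 8)},
            {"probe_id": "SPK1", "control_type": "spikein", "A": (8, 8), "B": (8, 8)},
            {"probe_id": "P_low", "entrez_id": "9", "A": (5, 5), "B": (5, 5)},
            {"probe_id": "P_high", "entrez_id": "9", "A": (10, 10), "B": (10, 10)},
        ],
    )
    genes, dropped = collapse_probes_to_genes(_quantified_probes(raw))
    assert dropped == 0
    assert set(genes["probe_id"]) == {"P_high"}
    assert genes["gene_id"].nunique() == 1


def test_collapse_tie_breaks_on_smallest_probe_id():
    raw = make_raw(
        ["A"],
        [
            {"probe_id": "SPK0", "control_type": "spikein", "A": (8, 8)},
            {"probe_id": "SPK1", "control_type": "spikein", "A": (8, 8)},
            {"probe_id": "P_b", "entrez_id": "9", "A": (10, 10)},
            {"probe_id": "P_a", "entrez_id": "9", "A": (10, 10)},
        ],
    )
    genes, _ = collapse_probes_to_genes(_quantified_probes(raw))
    assert set(genes["probe_id"]) == {"P_a"}


def test_collapse_drops_and_counts_probes_without_entrez():
    raw = make_raw(
        ["A"],
        [
            {"probe_id": "SPK0", "control_type": "spikein", "A": (8, 8)},
            {"probe_id": "SPK1", "control_type": "spikein", "A": (8, 8)},
            {"probe_id": "P1", "entrez_id": "1", "A": (10, 10)},
            {"probe_id": "P2", "entrez_id": "", "A": (10, 10)},
            {"probe_id": "CTRL", "control_type": "control", "A": (10, 10)},
        ],
    )
    genes, dropped = collapse_probes_to_genes(_quantified_probes(raw))
    assert dropped == 1
    assert set(genes["gene_id"]) == {"1"}
    assert "CTRL" not in set(genes["probe_id"])
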