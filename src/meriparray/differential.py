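"""Replicate-free fold-change calling between two pooled samples.

With one pooled array per condition there are no replicates, so no p-values
are produced anywhere in this module: the fold change is the only evidence.
Genes are trichotomized per axis by the canonical cut-offs FC >= 1.5
(up-regulated / hypermethylated) and FC <= 0.67 (down-regulated /
hypomethylated); both the cut-offs and their inclusivity are configurable.
Note the conventional 0.67 is not exactly 1/1.5, so the up/down calls are not
perfectly mirror-symmetric unless ``down_threshold`` is set to ``1/1.5``.
"""

from __future__ import annotations

import dataclasses
import decimal
import logging

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

EXPRESSION_CLASSES = ("up", "unchanged", "down")
METHYLATION_CLASSES = ("hyper", "unchanged", "hypo")

#: methylation fold-change bases supported by :func:`run_contrast`
METHYLATION_BASES = ("percent", "modified_channel")


@dataclasses.dataclass(frozen=True)
class Thresholds:
    """Fold-change cut-offs for the trichotomous call."""

    up_threshold: float = 1.5
    down_threshold: float = 0.67
    inclusive: bool = True

    def validate(self) -> None:
        if not (self.down_threshold < 1.0 < self.up_threshold):
            raise ConfigurationError(
                "thresholds: require down_threshold < 1 < up_threshold"
            )


@dataclasses.dataclass(frozen=True)
class Contrast:
    """A test-vs-reference sample pair, e.g. CUMS_Sham vs WT."""

    test_sample: str
    ref_sample: str
    name: str = ""

    def __post_init__(self):
        if self.test_sample == self.ref_sample:
            raise ConfigurationError("contrast: test_sample must differ from ref_sample")
        if not self.name:
            object.__setattr__(self, "name", f"{self.test_sample}_vs_{self.ref_sample}")


def fold_change(test_value, ref_value, epsilon: float = 0.0):
    """Ratio ``(test + epsilon) / (ref + epsilon)``; accepts scalars or arrays."""
    if epsilon < 0:
        raise ConfigurationError("epsilon: must be >= 0")
    test = np.asarray(test_value, dtype=float)
    ref = np.asarray(ref_value, dtype=float)
    if (test + epsilon <= 0).any() or (ref + epsilon <= 0).any():
        raise DataError(
            "fold change undefined for non-positive value with epsilon "
            f"{epsilon}; use a positive epsilon"
        )
    result = (test + epsilon) / (ref + epsilon)
    return float(result) if result.ndim == 0 else result


def classify_fc(fc, thresholds: Thresholds = Thresholds(), labels=EXPRESSION_CLASSES):
    """Trichotomize fold changes into ``(up, unchanged, down)``-style labels.

    With ``inclusive=True`` (default) the cut-offs themselves are called
    changed (FC >= up_threshold / FC <= down_threshold); with
    ``inclusive=False`` the comparisons are strict.
    """
    thresholds.validate()
    up_label, mid_label, down_label = labels
    values = np.asarray(fc, dtype=float)
    if (values <= 0).any() or not np.isfinite(values).all():
        raise DataError("fold changes must be positive and finite")
    if thresholds.inclusive:
        is_up = values >= thresholds.up_threshold
        is_down = values <= thresholds.down_threshold
    else:
        is_up = values > thresholds.up_threshold
        is_down = values < thresholds.down_threshold
    result = np.where(is_up, up_label, np.where(is_down, down_label, mid_label))
    return str(result[()]) if result.ndim == 0 else result


def run_contrast(
    quantified: pd.DataFrame,
    contrast: Contrast,
    thresholds: Thresholds = Thresholds(),
    methylation_basis: str = "percent",
    epsilon: float = 0.0,
) -> pd.DataFrame:
    """Per-gene expression and methylation fold changes plus class calls.

    ``methylation_basis='percent'`` computes the methylation fold change on
    the m6A percentage (the default notion of methylation level);
    ``'modified_channel'`` uses the normalized Cy5 intensity instead.  Genes
    present in only one of the two samples are excluded and logged.
    """
    if methylation_basis not in METHYLATION_BASES:
        raise ConfigurationError(
            f"methylation_basis: expected one of {METHYLATION_BASES}, got {methylation_basis!r}"
        )
    present = set(quantified["sample_id"].unique())
    for sample in (contrast.test_sample, contrast.ref_sample):
        if sample not in present:
            raise DataError(f"sample {sample!r} absent from quantified table")

    meth_col = "m6a_percent" if methylation_basis == "percent" else "cy5_norm_lin"
    cols = ["gene_id", "expression", meth_col]
    test = quantified.loc[quantified["sample_id"] == contrast.test_sample, cols]
    ref = quantified.loc[quantified["sample_id"] == contrast.ref_sample, cols]
    merged = test.merge(ref, on="gene_id", suffixes=("_test", "_ref"), how="inner")
    n_excluded = len(set(test["gene_id"]).symmetric_difference(ref["gene_id"]))
    if n_excluded:
        logger.info(
            "contrast %s: excluded %d gene(s) present in only one sample",
            contrast.name, n_excluded,
        )

    fc_expr = fold_change(
        merged["expression_test"].to_numpy(), merged["expression_ref"].to_numpy(), epsilon
    )
    fc_meth = fold_change(
        merged[f"{meth_col}_test"].to_numpy(), merged[f"{meth_col}_ref"].to_numpy(), epsilon
    )
    records = pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "fc_expression": fc_expr,
            "class_expression": classify_fc(fc_expr, thresholds, EXPRESSION_CLASSES),
            "fc_methylation": fc_meth,
            "class_methylation": classify_fc(fc_meth, thresholds, METHYLATION_CLASSES),
        }
    )
    return records.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def percent_of(count: int, total: int, decimals: int = 1) -> float:
    """Percentage ``100 * count / total`` rounded half-away-from-zero."""
    if total <= 0:
        raise ConfigurationError("total: must be > 0")
    if count < 0:
        raise ConfigurationError("count: must be >= 0")
    value = decimal.Decimal(count) * 100 / decimal.Decimal(total)
    quantum = decimal.Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=decimal.ROUND_HALF_UP))


def summarize_contrast(records: pd.DataFrame, universe_size: int, decimals: int = 1) -> dict:
    """Counts and universe percentages of changed genes for one contrast."""
    if universe_size <= 0:
        raise ConfigurationError("universe_size: must be > 0")
    if universe_size < len(records):
        raise ConfigurationError("universe_size: smaller than the number of records")
    n_up = int((records["class_expression"] == "up").sum())
    n_down = int((records["class_expression"] == "down").sum())
    n_hyper = int((records["class_methylation"] == "hyper").sum())
    n_hypo = int((records["class_methylation"] == "hypo").sum())
    any_changed = (records["class_expression"] != "unchanged") | (
        records["class_methylation"] != "unchanged"
    )
    summary = {
        "n_up": n_up,
        "n_down": n_down,
        "n_expression_changed": n_up + n_down,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "n_methylation_changed": n_hyper + n_hypo,
        "n_any_changed": int(any_changed.sum()),
        "universe_size": int(universe_size),
    }
    for key in (
        "n_up", "n_down", "n_expression_changed",
        "n_hyper", "n_hypo", "n_methylation_changed", "n_any_changed",
    ):
        summary[f"pct_{key[2:]}"] = percent_of(summary[key], universe_size, decimals)
    return summary
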