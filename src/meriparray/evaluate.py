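"""Recovery metrics of pipeline class calls against simulated ground truth."""

from __future__ import annotations

import pandas as pd

from .exceptions import DataError
from .simulate import GroundTruth


def class_recovery(
    records: pd.DataFrame, truth: GroundTruth, contrast_name: str
) -> dict[str, dict[str, float]]:
    """Per-class sensitivity and false-positive rate for one contrast.

    For each planted class (up/down on the expression axis, hyper/hypo on the
    methylation axis): sensitivity is the fraction of planted genes called as
    their class; the false-positive rate is the fraction of genes NOT planted
    in that class that the pipeline nevertheless calls as it.
    """
    truth_classes = truth.classes_for(contrast_name)
    merged = records.merge(
        truth_classes, on="gene_id", suffixes=("", "_true"), how="inner"
    )
    if merged.empty:
        raise DataError("records share no genes with the ground truth")
    out: dict[str, dict[str, float]] = {}
    for axis, label in (
        ("class_expression", "up"),
        ("class_expression", "down"),
        ("class_methylation", "hyper"),
        ("class_methylation", "hypo"),
    ):
        truth_col = f"{axis}_true"
        planted = merged[truth_col] == label
        called = merged[axis] == label
        sensitivity = float((planted & called).sum() / planted.sum()) if planted.any() else float("nan")
        fpr = float((~planted & called).sum() / (~planted).sum()) if (~planted).any() else float("nan")
        out[label] = {
            "n_planted": int(planted.sum()),
            "sensitivity": sensitivity,
            "false_positive_rate": fpr,
        }
    return out


def misclassified_count(records: pd.DataFrame, truth: GroundTruth, contrast_name: str) -> int:
    """Number of genes whose (expression, methylation) call differs from truth."""
    truth_classes = truth.classes_for(contrast_name)
    merged = records.merge(truth_classes, on="gene_id", suffixes=("", "_true"), how="inner")
    wrong = (merged["class_expression"] != merged["class_expression_true"]) | (
        merged["class_methylation"] != merged["class_methylation_true"]
    )
    return int(wrong.sum())
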