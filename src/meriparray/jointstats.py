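"""Joint methylation/expression statistics across one or two contrasts.

Three operations: cross-tabulating the methylation class against the
expression class within one contrast (the quadrant analysis behind
"expression stayed the same but m6A changed"), screening for genes whose
stress-induced change is reversed by the intervention, and ordering genes for
heatmap display by agglomerative hierarchical clustering.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .differential import EXPRESSION_CLASSES, METHYLATION_CLASSES
from .exceptions import DataError

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CrossTab:
    """3x3 methylation-by-expression contingency table with per-cell gene lists."""

    counts: pd.DataFrame                       # index: hyper/unchanged/hypo; cols: up/unchanged/down
    genes: dict[tuple[str, str], list[str]]    # (meth_class, expr_class) -> sorted gene ids

    @property
    def marginals(self) -> dict[str, int]:
        c = self.counts
        return {
            "n_hyper": int(c.loc["hyper"].sum()),
            "n_hypo": int(c.loc["hypo"].sum()),
            "n_methylation_changed": int(c.loc["hyper"].sum() + c.loc["hypo"].sum()),
            "n_up": int(c["up"].sum()),
            "n_down": int(c["down"].sum()),
            "n_expression_changed": int(c["up"].sum() + c["down"].sum()),
            "n_total": int(c.to_numpy().sum()),
        }


def crosstab_meth_expr(records: pd.DataFrame) -> CrossTab:
    """Cross-tabulate one contrast's methylation classes against expression classes.

    Every gene lands in exactly one cell; duplicate gene ids are an error.
    """
    dup = records["gene_id"].duplicated()
    if dup.any():
        raise DataError(f"duplicate gene_id: {records.loc[dup, 'gene_id'].iloc[0]!r}")
    counts = pd.DataFrame(
        0, index=list(METHYLATION_CLASSES), columns=list(EXPRESSION_CLASSES), dtype=int
    )
    observed = pd.crosstab(records["class_methylation"], records["class_expression"])
    for meth in observed.index:
        for expr in observed.columns:
            counts.loc[meth, expr] = int(observed.loc[meth, expr])
    genes = {
        (meth, expr): sorted(
            records.loc[
                (records["class_methylation"] == meth)
                & (records["class_expression"] == expr),
                "gene_id",
            ]
        )
        for meth in METHYLATION_CLASSES
        for expr in EXPRESSION_CLASSES
    }
    return CrossTab(counts=counts, genes=genes)


@dataclasses.dataclass
class ReversalSets:
    """Gene sets jointly classified across two contrasts A then B."""

    up_then_down: list[str]
    down_then_up: list[str]
    hyper_then_hypo: list[str]
    hypo_then_hyper: list[str]
    stable_expression_hyper_to_hypo: list[str]
    stable_expression_hypo_to_hyper: list[str]

    @property
    def stable_expression_m6a_reversed(self) -> list[str]:
        return sorted(
            self.stable_expression_hyper_to_hypo + self.stable_expression_hypo_to_hyper
        )

    @property
    def counts(self) -> dict[str, int]:
        return {
            "up_then_down": len(self.up_then_down),
            "down_then_up": len(self.down_then_up),
            "hyper_then_hypo": len(self.hyper_then_hypo),
            "hypo_then_hyper": len(self.hypo_then_hyper),
            "stable_expression_m6a_reversed": len(self.stable_expression_m6a_reversed),
            "stable_expression_hyper_to_hypo": len(self.stable_expression_hyper_to_hypo),
            "stable_expression_hypo_to_hyper": len(self.stable_expression_hypo_to_hyper),
        }


def reversal_screen(records_a: pd.DataFrame, records_b: pd.DataFrame) -> ReversalSets:
    """Screen for genes whose contrast-A change is inverted in contrast B.

    Only the shared gene universe is screened; non-shared genes are logged and
    dropped.  The "expression stable but m6A reversed" set requires the
    contrast-B expression class to be unchanged and strictly opposite
    methylation classes between the contrasts.
    """
    merged = records_a.merge(records_b, on="gene_id", suffixes=("_a", "_b"), how="inner")
    if merged.empty:
        raise DataError("contrasts share no genes; reversal screen undefined")
    n_dropped = len(set(records_a["gene_id"]).symmetric_difference(records_b["gene_id"]))
    if n_dropped:
        logger.info("reversal screen: dropped %d non-shared gene(s)", n_dropped)

    def genes(mask) -> list[str]:
        return sorted(merged.loc[mask, "gene_id"])

    expr_a = merged["class_expression_a"]
    expr_b = merged["class_expression_b"]
    meth_a = merged["class_methylation_a"]
    meth_b = merged["class_methylation_b"]
    hyper_to_hypo = (meth_a == "hyper") & (meth_b == "hypo")
    hypo_to_hyper = (meth_a == "hypo") & (meth_b == "hyper")
    stable_b = expr_b == "unchanged"
    return ReversalSets(
        up_then_down=genes((expr_a == "up") & (expr_b == "down")),
        down_then_up=genes((expr_a == "down") & (expr_b == "up")),
        hyper_then_hypo=genes(hyper_to_hypo),
        hypo_then_hyper=genes(hypo_to_hyper),
        stable_expression_hyper_to_hypo=genes(stable_b & hyper_to_hypo),
        stable_expression_hypo_to_hyper=genes(stable_b & hypo_to_hyper),
    )


@dataclasses.dataclass
class ClusterResult:
    """Leaf order and merge tree from agglomerative clustering."""

    leaf_order: np.ndarray       # permutation of row indices, heatmap top to bottom
    linkage: np.ndarray          # scipy linkage matrix (merge tree with heights)

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_profiles(matrix) -> ClusterResult:
    """Order rows for heatmap display by Euclidean average-linkage clustering.

    Zero distances (identical or constant rows) are allowed and merge first.
    Deterministic for a given input; requires >= 2 rows and no missing values.
    """
    values = np.asarray(matrix, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if values.ndim != 2 or values.shape[0] < 2:
        raise DataError("clustering requires a 2-D matrix with at least 2 rows")
    if not np.isfinite(values).all():
        raise DataError("clustering input must not contain missing/non-finite values")
    linkage = hierarchy.linkage(values, method="average", metric="euclidean")
    leaf_order = np.asarray(hierarchy.leaves_list(linkage))
    return ClusterResult(leaf_order=leaf_order, linkage=linkage)
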