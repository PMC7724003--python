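"""Spike-in normalization and per-gene m6A/expression quantification.

Normalization anchors every channel of every sample to the same spike-in
level: for channel ``c`` of sample ``s`` the scale term is the mean of the
log2 spike-in intensities, and each probe's normalized log2 intensity is::

    log2(raw + pseudocount) - mean_spikein_log2[s, c] + G

where ``G`` is an anchor constant, by default the grand mean of spike-in
log2 intensities over all samples and channels in the run.  ``G`` is
cosmetic: it keeps values on an intensity-like scale and cancels in every
downstream fold change and in the m6A percentage.  Pass a fixed ``anchor``
to make normalized values themselves invariant to channel rescaling (the
data-derived default shifts with the data by construction).

From the normalized linear intensities (``2**log2``), the m6A modification
percentage is ``100 * cy5 / (cy5 + cy3)`` and the expression level is the
total ``cy5 + cy3``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .arrayio import CHANNELS, RawArraySet
from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: Default pseudocount added before any log2, guarding zero intensities.
DEFAULT_PSEUDOCOUNT = 1.0


def normalize_spikein(
    raw: RawArraySet,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    anchor: float | None = None,
) -> pd.DataFrame:
    """Spike-in-normalize all probes of all samples.

    Returns a long-format frame with one row per (probe, sample) carrying the
    identity columns plus ``cy5_norm_log2``, ``cy3_norm_log2`` and their
    linear-scale counterparts.  After normalization the spike-in mean log2
    intensity equals the grand spike-in mean ``G`` in every channel of every
    sample (exact to machine precision).
    """
    raw.validate()
    if pseudocount < 0:
        raise ConfigurationError("pseudocount: must be >= 0")
    table = raw.table
    spike_mask = (table["control_type"] == "spikein").to_numpy()
    if spike_mask.sum() < 2:
        raise DataError("need at least 2 spike-in probes to normalize")

    cols = raw.intensity_columns()
    values = table[cols].to_numpy(dtype=float)
    if pseudocount == 0 and (values == 0).any():
        raise DataError(
            "zero intensity encountered with pseudocount 0; set pseudocount > 0"
        )
    spike_values = values[spike_mask] + pseudocount
    if (spike_values <= 0).any():
        raise DataError("spike-in probes must have positive intensity in every channel")

    log2 = np.log2(values + pseudocount)
    spike_log2 = log2[spike_mask]
    col_means = spike_log2.mean(axis=0)            # per sample x channel
    grand_mean = float(spike_log2.mean()) if anchor is None else float(anchor)
    norm_log2 = log2 - col_means[None, :] + grand_mean

    frames = []
    ident = table[["probe_id", "gene_symbol", "entrez_id", "control_type"]]
    for si, sample in enumerate(raw.samples):
        i5 = cols.index(f"cy5_raw_{sample}")
        i3 = cols.index(f"cy3_raw_{sample}")
        frame = ident.copy()
        frame["sample_id"] = sample
        frame["cy5_norm_log2"] = norm_log2[:, i5]
        frame["cy3_norm_log2"] = norm_log2[:, i3]
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out["cy5_norm_lin"] = np.exp2(out["cy5_norm_log2"])
    out["cy3_norm_lin"] = np.exp2(out["cy3_norm_log2"])
    return out


def compute_m6a_percent(cy5_norm_lin, cy3_norm_lin):
    """Modification percentage: ``100 * cy5 / (cy5 + cy3)``, in [0, 100].

    Accepts scalars or arrays; raises :class:`DataError` on negative inputs or
    an all-zero channel pair (undefined percentage).
    """
    cy5 = np.asarray(cy5_norm_lin, dtype=float)
    cy3 = np.asarray(cy3_norm_lin, dtype=float)
    if (cy5 < 0).any() or (cy3 < 0).any():
        raise DataError("normalized intensities must be >= 0")
    total = cy5 + cy3
    if (total == 0).any():
        raise DataError("both channels zero: modification percentage undefined")
    result = 100.0 * cy5 / total
    return float(result) if result.ndim == 0 else result


def compute_expression(cy5_norm_lin, cy3_norm_lin):
    """Expression level: the total of the two normalized channel intensities."""
    cy5 = np.asarray(cy5_norm_lin, dtype=float)
    cy3 = np.asarray(cy3_norm_lin, dtype=float)
    if not (np.isfinite(cy5).all() and np.isfinite(cy3).all()):
        raise DataError("intensities must be finite")
    if (cy5 < 0).any() or (cy3 < 0).any():
        raise DataError("normalized intensities must be >= 0")
    result = cy5 + cy3
    return float(result) if result.ndim == 0 else result


def quantify_probes(normalized: pd.DataFrame) -> pd.DataFrame:
    """Add ``m6a_percent`` and ``expression`` columns to a normalized table."""
    out = normalized.copy()
    out["m6a_percent"] = compute_m6a_percent(
        out["cy5_norm_lin"].to_numpy(), out["cy3_norm_lin"].to_numpy()
    )
    out["expression"] = compute_expression(
        out["cy5_norm_lin"].to_numpy(), out["cy3_norm_lin"].to_numpy()
    )
    return out


def collapse_probes_to_genes(quantified_probes: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse probe-level rows to one representative probe per gene.

    Control and spike-in probes are excluded.  The representative probe for a
    gene (keyed by ``entrez_id``) is the one with the highest mean expression
    across all samples; exact ties go to the lexicographically smallest
    ``probe_id``.  Probes lacking an ``entrez_id`` are dropped; the second
    return value is the count of dropped probes.
    """
    genes = quantified_probes[quantified_probes["control_type"] == "none"]
    has_id = genes["entrez_id"].astype(str).str.len() > 0
    n_dropped = int(genes.loc[~has_id, "probe_id"].nunique())
    if n_dropped:
        logger.info("dropped %d probe(s) lacking an entrez_id", n_dropped)
    genes = genes[has_id]
    if genes.empty:
        return (
            pd.DataFrame(
                columns=[
                    "gene_id", "gene_symbol", "probe_id", "sample_id",
                    "cy5_norm_log2", "cy3_norm_log2", "cy5_norm_lin", "cy3_norm_lin",
                    "m6a_percent", "expression",
                ]
            ),
            n_dropped,
        )
    mean_expr = genes.groupby("probe_id")["expression"].mean()
    ranking = (
        mean_expr.rename("mean_expression")
        .reset_index()
        .merge(
            genes[["probe_id", "entrez_id"]].drop_duplicates(),
            on="probe_id",
        )
        .sort_values(["mean_expression", "probe_id"], ascending=[False, True])
    )
    representative = ranking.drop_duplicates("entrez_id")["probe_id"]
    out = genes[genes["probe_id"].isin(set(representative))].copy()
    out = out.rename(columns={"entrez_id": "gene_id"})
    out = out[
        [
            "gene_id", "gene_symbol", "probe_id", "sample_id",
            "cy5_norm_log2", "cy3_norm_log2", "cy5_norm_lin", "cy3_norm_lin",
            "m6a_percent", "expression",
        ]
    ].sort_values(["gene_id", "sample_id"], kind="mergesort").reset_index(drop=True)
    return out, n_dropped


def quantify_arrayset(
    raw: RawArraySet, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> tuple[pd.DataFrame, int]:
    """Full quantification: normalize, compute m6A%/expression, collapse to genes."""
    normalized = normalize_spikein(raw, pseudocount=pseudocount)
    probes = quantify_probes(normalized)
    return collapse_probes_to_genes(probes)
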