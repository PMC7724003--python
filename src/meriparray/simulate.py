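"""Synthetic two-color m6A epitranscriptomic array data with known ground truth.

The generator emulates a pooled-sample MeRIP microarray experiment: three
conditions (wild type, stressed sham, stressed + deep-brain stimulation), one
pooled array per condition with no replicates, gene probes plus spike-in
control probes, and two channels per array (Cy5 = immunoprecipitated
methylated RNA, Cy3 = unmodified supernatant).

Generative model, per gene g and sample s::

    expression_true[s, g] = 2**Normal(mu, sd) * 2**(cumulative planted expression log2 FC)
    fraction_true[s, g]   = Beta(alpha, beta) * (cumulative planted methylation multiplier)
    cy5_raw = scale[s, cy5] * expression_true * fraction_true       * 2**eps
    cy3_raw = scale[s, cy3] * expression_true * (1 - fraction_true) * 2**eps'

with eps, eps' independent Normal(0, noise_sd) on the log2 scale.  Planted
effects are applied cumulatively along the ordered condition chain, so a gene
up-regulated in the first contrast and down-regulated in the second returns to
its baseline in the third condition.  Spike-in probes have fixed true
intensities, identical across samples and channels, so spike-in normalization
can remove the per-sample per-channel scale bias exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arrayio import CHANNELS, RawArraySet, sha256_of, write_raw_table
from .exceptions import ConfigurationError, DataError

EFFECT_KEYS = ("expression_up", "expression_down", "hyper", "hypo")

#: Ceiling on the true modification fraction after planted effects; keeps the
#: unmodified channel strictly positive while preserving exact planted FCs.
MAX_TRUE_FRACTION = 0.95


def default_effect_fractions(contrast_names: Sequence[str]) -> dict[str, dict[str, float]]:
    """Default planted-effect fractions for the canonical two contrasts.

    Chosen to reproduce the study design's observed proportions: in the
    stress-vs-wild-type contrast ~21.9% of genes change expression (down:up
    3:1) and ~17.8% change methylation (almost entirely hyper); in the
    stimulation-vs-sham contrast ~16.8% change expression (up:down 3:1) and
    ~2.5% change methylation (hyper:hypo ≈ 63:37).
    """
    canonical = [
        {"expression_up": 0.055, "expression_down": 0.164, "hyper": 0.176, "hypo": 0.002},
        {"expression_up": 0.126, "expression_down": 0.042, "hyper": 0.016, "hypo": 0.009},
    ]
    out: dict[str, dict[str, float]] = {}
    for i, name in enumerate(contrast_names):
        out[name] = dict(canonical[i]) if i < len(canonical) else dict.fromkeys(EFFECT_KEYS, 0.0)
    return out


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic array experiment.

    All intensity parameters are on the log2 scale of arbitrary fluorescence
    units.  ``effect_fractions`` maps each ordered contrast name
    (``<test>_vs_<ref>`` for consecutive condition pairs) to the fraction of
    genes planted per effect class; expression and methylation assignments are
    drawn independently, so a gene may change on both axes in one contrast.
    """

    n_genes: int = 5000
    n_spikeins: int = 8
    conditions: tuple[str, ...] = ("WT", "CUMS_Sham", "CUMS_DBS")
    baseline_log2_expression_mean: float = 10.0
    baseline_log2_expression_sd: float = 1.5
    baseline_m6a_fraction_alpha: float = 4.0
    baseline_m6a_fraction_beta: float = 2.0
    effect_fractions: dict[str, dict[str, float]] | None = None
    effect_log2fc: float = 2.0
    channel_scale: dict[str, dict[str, float]] | None = None
    noise_sd: float = 0.1
    spikein_log2_levels: tuple[float, ...] | None = None
    seed: int = 0

    @property
    def contrast_names(self) -> list[str]:
        return [
            f"{test}_vs_{ref}"
            for ref, test in zip(self.conditions[:-1], self.conditions[1:])
        ]

    def resolved_effect_fractions(self) -> dict[str, dict[str, float]]:
        if self.effect_fractions is None:
            return default_effect_fractions(self.contrast_names)
        return {
            name: {k: float(self.effect_fractions.get(name, {}).get(k, 0.0)) for k in EFFECT_KEYS}
            for name in self.contrast_names
        }

    def validate(self) -> None:
        if not isinstance(self.n_genes, (int, np.integer)) or self.n_genes < 1:
            raise ConfigurationError("n_genes: must be a positive integer")
        if not isinstance(self.n_spikeins, (int, np.integer)) or self.n_spikeins < 2:
            raise ConfigurationError("n_spikeins: must be an integer >= 2")
        if len(self.conditions) < 2:
            raise ConfigurationError("conditions: need at least two condition labels")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("conditions: labels must be unique")
        if self.baseline_log2_expression_sd < 0:
            raise ConfigurationError("baseline_log2_expression_sd: must be >= 0")
        if self.baseline_m6a_fraction_alpha <= 0 or self.baseline_m6a_fraction_beta <= 0:
            raise ConfigurationError(
                "baseline_m6a_fraction_alpha/beta: Beta shape parameters must be > 0"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be >= 0")
        if self.effect_log2fc < 0:
            raise ConfigurationError("effect_log2fc: must be >= 0")
        if self.effect_fractions is not None:
            known = set(self.contrast_names)
            for name in self.effect_fractions:
                if name not in known:
                    raise ConfigurationError(
                        f"effect_fractions: unknown contrast {name!r}"
                        f" (expected one of {sorted(known)})"
                    )
        for name, fracs in self.resolved_effect_fractions().items():
            for key, value in fracs.items():
                if not 0.0 <= value <= 1.0:
                    raise ConfigurationError(
                        f"effect_fractions[{name}][{key}]: must be in [0, 1]"
                    )
            if sum(fracs.values()) > 1.0 + 1e-12:
                raise ConfigurationError(
                    f"effect_fractions[{name}]: the four fractions must sum to <= 1"
                )
        if self.channel_scale is not None:
            for sample, per_channel in self.channel_scale.items():
                if sample not in self.conditions:
                    raise ConfigurationError(f"channel_scale: unknown sample {sample!r}")
                for ch, value in per_channel.items():
                    if ch not in CHANNELS:
                        raise ConfigurationError(f"channel_scale[{sample}]: unknown channel {ch!r}")
                    if not value > 0:
                        raise ConfigurationError(f"channel_scale[{sample}][{ch}]: must be > 0")
        if self.spikein_log2_levels is not None and len(self.spikein_log2_levels) != self.n_spikeins:
            raise ConfigurationError("spikein_log2_levels: length must equal n_spikeins")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        from .arrayio import read_flat_config

        allowed = {f.name for f in dataclasses.fields(cls)}
        data = read_flat_config(path, allowed)
        if "conditions" in data:
            data["conditions"] = tuple(data["conditions"])
        if "spikein_log2_levels" in data and data["spikein_log2_levels"] is not None:
            data["spikein_log2_levels"] = tuple(data["spikein_log2_levels"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclasses.dataclass
class GroundTruth:
    """Planted truth behind a simulated dataset.

    ``classes``: one row per (gene, contrast) with the planted
    ``class_expression`` (up/down/unchanged) and ``class_methylation``
    (hyper/hypo/unchanged).  ``levels``: one row per (gene, sample) with the
    noise-free ``true_expression`` and ``true_m6a_fraction``.
    """

    classes: pd.DataFrame
    levels: pd.DataFrame

    def classes_for(self, contrast_name: str) -> pd.DataFrame:
        sub = self.classes[self.classes["contrast"] == contrast_name]
        if sub.empty:
            raise DataError(f"no ground-truth classes for contrast {contrast_name!r}")
        return sub.reset_index(drop=True)


def _gene_ids(n_genes: int) -> pd.DataFrame:
    idx = np.arange(n_genes)
    return pd.DataFrame(
        {
            "probe_id": [f"P{i:06d}" for i in idx],
            "gene_symbol": [f"Gene{i}" for i in idx],
            "entrez_id": [str(100001 + i) for i in idx],
            "control_type": "none",
        }
    )


def simulate_dataset(config: SimulationConfig) -> tuple[RawArraySet, GroundTruth]:
    """Generate one raw two-channel table per condition plus its ground truth.

    Deterministic given ``config.seed``: gene-level parameters and effect
    assignments come from one child RNG stream, per-sample measurement noise
    from one child stream per sample.
    """
    config.validate()
    n_genes = int(config.n_genes)
    n_spk = int(config.n_spikeins)
    samples = list(config.conditions)
    contrasts = config.contrast_names
    fractions = config.resolved_effect_fractions()
    lfc = float(config.effect_log2fc)

    children = np.random.SeedSequence(int(config.seed)).spawn(1 + len(samples))
    gene_rng = np.random.default_rng(children[0])

    expr_base = np.exp2(
        gene_rng.normal(
            config.baseline_log2_expression_mean,
            config.baseline_log2_expression_sd,
            n_genes,
        )
    )
    frac_draw = gene_rng.beta(
        config.baseline_m6a_fraction_alpha, config.baseline_m6a_fraction_beta, n_genes
    )

    if config.channel_scale is None:
        # modest sample x channel biases so normalization is actually exercised
        scale = {
            s: {ch: float(np.exp2(gene_rng.uniform(-0.5, 0.5))) for ch in CHANNELS}
            for s in samples
        }
    else:
        scale = {
            s: {ch: float(config.channel_scale.get(s, {}).get(ch, 1.0)) for ch in CHANNELS}
            for s in samples
        }

    # planted per-contrast log2 deltas, accumulated along the condition chain
    expr_delta = np.zeros((len(contrasts), n_genes))
    meth_delta = np.zeros((len(contrasts), n_genes))
    for ci, name in enumerate(contrasts):
        frac = fractions[name]
        n_up = int(round(frac["expression_up"] * n_genes))
        n_down = int(round(frac["expression_down"] * n_genes))
        n_hyper = int(round(frac["hyper"] * n_genes))
        n_hypo = int(round(frac["hypo"] * n_genes))
        perm_expr = gene_rng.permutation(n_genes)
        perm_meth = gene_rng.permutation(n_genes)
        expr_delta[ci, perm_expr[:n_up]] = lfc
        expr_delta[ci, perm_expr[n_up:n_up + n_down]] = -lfc
        meth_delta[ci, perm_meth[:n_hyper]] = lfc
        meth_delta[ci, perm_meth[n_hyper:n_hyper + n_hypo]] = -lfc

    expr_cum = np.vstack([np.zeros(n_genes), np.cumsum(expr_delta, axis=0)])
    meth_cum = np.vstack([np.zeros(n_genes), np.cumsum(meth_delta, axis=0)])

    # keep the true fraction below MAX_TRUE_FRACTION for every condition while
    # preserving exact planted multipliers (no clipping)
    max_mult = np.exp2(meth_cum.max(axis=0))
    frac_base = frac_draw * np.minimum(1.0, MAX_TRUE_FRACTION / max_mult)
    true_frac = frac_base[None, :] * np.exp2(meth_cum)          # (n_samples, n_genes)
    true_expr = expr_base[None, :] * np.exp2(expr_cum)

    if config.spikein_log2_levels is None:
        spk_levels = np.exp2(np.linspace(8.0, 14.0, n_spk))
    else:
        spk_levels = np.exp2(np.asarray(config.spikein_log2_levels, dtype=float))

    ident = _gene_ids(n_genes)
    spikes = pd.DataFrame(
        {
            "probe_id": [f"SPK{j:03d}" for j in range(n_spk)],
            "gene_symbol": [f"SpikeIn{j}" for j in range(n_spk)],
            "entrez_id": "",
            "control_type": "spikein",
        }
    )
    table = pd.concat([ident, spikes], ignore_index=True)

    noise = float(config.noise_sd)
    for si, s in enumerate(samples):
        rng_s = np.random.default_rng(children[1 + si])
        true_cy5 = np.concatenate([true_expr[si] * true_frac[si], spk_levels])
        true_cy3 = np.concatenate([true_expr[si] * (1.0 - true_frac[si]), spk_levels])
        eps5 = rng_s.normal(0.0, noise, n_genes + n_spk) if noise > 0 else 0.0
        eps3 = rng_s.normal(0.0, noise, n_genes + n_spk) if noise > 0 else 0.0
        table[f"cy5_raw_{s}"] = scale[s]["cy5"] * true_cy5 * np.exp2(eps5)
        table[f"cy3_raw_{s}"] = scale[s]["cy3"] * true_cy3 * np.exp2(eps3)

    arrayset = RawArraySet(
        samples=samples,
        table=table,
        provenance={"generator": "meriparray.simulate", "seed": int(config.seed)},
    )
    arrayset.validate()

    gene_id = ident["entrez_id"].to_numpy()
    class_rows = []
    for ci, name in enumerate(contrasts):
        class_expr = np.where(
            expr_delta[ci] > 0, "up", np.where(expr_delta[ci] < 0, "down", "unchanged")
        )
        class_meth = np.where(
            meth_delta[ci] > 0, "hyper", np.where(meth_delta[ci] < 0, "hypo", "unchanged")
        )
        class_rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "contrast": name,
                    "class_expression": class_expr,
                    "class_methylation": class_meth,
                }
            )
        )
    level_rows = [
        pd.DataFrame(
            {
                "gene_id": gene_id,
                "sample_id": s,
                "true_expression": true_expr[si],
                "true_m6a_fraction": true_frac[si],
            }
        )
        for si, s in enumerate(samples)
    ]
    truth = GroundTruth(
        classes=pd.concat(class_rows, ignore_index=True),
        levels=pd.concat(level_rows, ignore_index=True),
    )
    return arrayset, truth


def write_dataset(
    dataset: RawArraySet, truth: GroundTruth, directory: str | Path
) -> dict:
    """Write the raw table and ground-truth tables plus a checksum manifest.

    Refuses to write anything for an empty gene list.
    """
    gene_rows = dataset.table[dataset.table["control_type"] == "none"]
    if gene_rows.empty:
        raise DataError("dataset contains no gene probes; nothing written")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "raw_intensities": write_raw_table(dataset, directory / "raw_intensities.tsv"),
    }
    try:
        truth.classes.to_csv(directory / "truth_classes.tsv", sep="\t", index=False)
        truth.levels.to_csv(directory / "truth_levels.tsv", sep="\t", index=False)
    except OSError as exc:
        raise DataError(f"I/O failure while writing dataset to {directory}: {exc}") from exc
    paths["truth_classes"] = directory / "truth_classes.tsv"
    paths["truth_levels"] = directory / "truth_levels.tsv"
    manifest = {
        "files": {
            name: {"path": p.name, "sha256": sha256_of(p)} for name, p in paths.items()
        }
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
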