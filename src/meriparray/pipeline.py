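"""End-to-end pipeline driver: simulate/read -> quantify -> contrasts -> joint -> enrich.

The run configuration is validated up front, every stage logs its summary
counts, and all outputs are written as TSV with a checksummed manifest plus a
snapshot of the effective configuration, so a run is fully auditable and
byte-reproducible given the same config and seed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import arrayio, differential, enrichment, jointstats, quantify
from .exceptions import ConfigurationError, MeripArrayError, PipelineError
from .simulate import GroundTruth, SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    output_dir: Path
    raw_path: Path | None = None
    simulation: SimulationConfig | None = None
    contrasts: list[tuple[str, str]] | None = None      # (test, ref) pairs
    up_threshold: float = 1.5
    down_threshold: float = 0.67
    inclusive: bool = True
    pseudocount: float = quantify.DEFAULT_PSEUDOCOUNT
    methylation_basis: str = "percent"
    gmt_path: Path | None = None
    enrichment_alpha: float = 0.05
    seed: int = 0
    overwrite: bool = False

    def thresholds(self) -> differential.Thresholds:
        return differential.Thresholds(
            up_threshold=self.up_threshold,
            down_threshold=self.down_threshold,
            inclusive=self.inclusive,
        )

    def validate(self) -> None:
        if (self.raw_path is None) == (self.simulation is None):
            raise ConfigurationError(
                "exactly one of raw_path (read data) or simulation (generate data) is required"
            )
        self.thresholds().validate()
        if self.pseudocount < 0:
            raise ConfigurationError("pseudocount: must be >= 0")
        if self.methylation_basis not in differential.METHYLATION_BASES:
            raise ConfigurationError(
                f"methylation_basis: expected one of {differential.METHYLATION_BASES}"
            )
        if not 0 < self.enrichment_alpha < 1:
            raise ConfigurationError("enrichment_alpha: must be in (0, 1)")
        if self.simulation is not None:
            self.simulation.validate()
        if self.contrasts is not None:
            for test, ref in self.contrasts:
                if test == ref:
                    raise ConfigurationError(
                        f"contrasts: test and ref sample are both {test!r}"
                    )

    def snapshot(self) -> dict:
        snap = dataclasses.asdict(self)
        for key in ("output_dir", "raw_path", "gmt_path"):
            if snap[key] is not None:
                snap[key] = str(snap[key])
        if snap["contrasts"] is not None:
            snap["contrasts"] = [list(pair) for pair in snap["contrasts"]]
        return snap

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        data = arrayio.read_flat_config(Path(path), allowed)
        if "output_dir" not in data:
            raise ConfigurationError(f"{path}: output_dir is required")
        if "simulation" in data and data["simulation"] is not None:
            data["simulation"] = SimulationConfig(**data["simulation"])
        for key in ("output_dir", "raw_path", "gmt_path"):
            if data.get(key) is not None:
                data[key] = Path(data[key])
        if data.get("contrasts") is not None:
            data["contrasts"] = [tuple(pair) for pair in data["contrasts"]]
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclasses.dataclass
class PipelineResult:
    """In-memory outputs of a pipeline run."""

    quantified: pd.DataFrame
    records: dict[str, pd.DataFrame]            # contrast name -> differential records
    summaries: dict[str, dict]                  # contrast name -> summary counts
    crosstabs: dict[str, jointstats.CrossTab]
    reversal: jointstats.ReversalSets | None
    enrichment: dict[str, pd.DataFrame]
    truth: GroundTruth | None
    manifest: dict
    output_dir: Path


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MeripArrayError as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc
        return wrapper
    return decorator


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write results to ``config.output_dir``."""
    config.validate()

    truth: GroundTruth | None = None
    if config.simulation is not None:
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        raw, truth = _stage("simulate")(simulate_dataset)(sim_cfg)
        logger.info("simulate: %d probes x %d samples", len(raw.table), len(raw.samples))
    else:
        raw = _stage("read")(arrayio.read_raw_table)(config.raw_path)

    quantified, n_dropped = _stage("quantify")(quantify.quantify_arrayset)(
        raw, pseudocount=config.pseudocount
    )
    n_genes = quantified["gene_id"].nunique()
    logger.info("quantify: %d genes (%d probe(s) dropped without entrez_id)", n_genes, n_dropped)

    pairs = config.contrasts
    if pairs is None:
        pairs = list(zip(raw.samples[1:], raw.samples[:-1]))
    thresholds = config.thresholds()
    records: dict[str, pd.DataFrame] = {}
    summaries: dict[str, dict] = {}
    crosstabs: dict[str, jointstats.CrossTab] = {}
    for test, ref in pairs:
        contrast = differential.Contrast(test_sample=test, ref_sample=ref)
        recs = _stage("differential")(differential.run_contrast)(
            quantified, contrast, thresholds, config.methylation_basis
        )
        records[contrast.name] = recs
        summaries[contrast.name] = differential.summarize_contrast(recs, n_genes)
        logger.info("differential %s: %s", contrast.name, summaries[contrast.name])
        crosstabs[contrast.name] = _stage("joint")(jointstats.crosstab_meth_expr)(recs)

    reversal = None
    if len(pairs) >= 2:
        names = list(records)
        reversal = _stage("joint")(jointstats.reversal_screen)(
            records[names[0]], records[names[1]]
        )
        logger.info("reversal screen %s -> %s: %s", names[0], names[1], reversal.counts)

    enrich_results: dict[str, pd.DataFrame] = {}
    if config.gmt_path is not None:
        collection = _stage("enrich")(enrichment.read_gene_sets)(config.gmt_path)
        universe = set(quantified["gene_id"].unique())
        for name, recs in records.items():
            for axis, changed in (
                ("expression", recs["class_expression"] != "unchanged"),
                ("methylation", recs["class_methylation"] != "unchanged"),
            ):
                query = set(recs.loc[changed, "gene_id"])
                if not query:
                    logger.info("enrich %s/%s: empty query, skipped", name, axis)
                    continue
                enrich_results[f"{name}_{axis}"] = _stage("enrich")(
                    enrichment.fisher_enrich
                )(query, collection, universe)

    tables: dict[str, pd.DataFrame] = {
        "quantified": quantified,
    }
    for name, recs in records.items():
        tables[f"differential_{name}"] = recs
        tables[f"crosstab_{name}"] = crosstabs[name].counts.rename_axis(
            "class_methylation"
        ).reset_index()
        tables[f"summary_{name}"] = pd.DataFrame([summaries[name]])
    if reversal is not None:
        rows = [
            {"set": set_name, "gene_id": g}
            for set_name, members in (
                ("up_then_down", reversal.up_then_down),
                ("down_then_up", reversal.down_then_up),
                ("hyper_then_hypo", reversal.hyper_then_hypo),
                ("hypo_then_hyper", reversal.hypo_then_hyper),
                ("stable_expression_hyper_to_hypo", reversal.stable_expression_hyper_to_hypo),
                ("stable_expression_hypo_to_hyper", reversal.stable_expression_hypo_to_hyper),
            )
            for g in members
        ]
        tables["reversal_sets"] = pd.DataFrame(rows, columns=["set", "gene_id"])
    for key, table in enrich_results.items():
        tables[f"enrichment_{key}"] = table
    if truth is not None:
        tables["truth_classes"] = truth.classes
        tables["truth_levels"] = truth.levels

    manifest = _stage("write")(arrayio.write_results)(
        tables, config.output_dir, overwrite=config.overwrite, config=config.snapshot()
    )
    return PipelineResult(
        quantified=quantified,
        records=records,
        summaries=summaries,
        crosstabs=crosstabs,
        reversal=reversal,
        enrichment=enrich_results,
        truth=truth,
        manifest=manifest,
        output_dir=Path(config.output_dir),
    )
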