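"""Readers and writers for the tab-separated formats used throughout the pipeline.

The raw-intensity dialect models the essential columns of a two-color
feature-extraction export: one row per probe with identity columns
(``probe_id``, ``gene_symbol``, ``entrez_id``, ``control_type``) followed by
one pair of intensity columns per hybridized sample
(``cy5_raw_<sample>``, ``cy3_raw_<sample>``).  Cy5 carries the
immunoprecipitated (m6A-modified) channel, Cy3 the unmodified supernatant.

All outputs are UTF-8 TSV with a header row, ``.`` decimal separator and no
quoting; a JSON manifest with SHA-256 checksums accompanies every result set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

CHANNELS = ("cy5", "cy3")
REQUIRED_COLUMNS = ("probe_id", "gene_symbol", "entrez_id", "control_type")
CONTROL_TYPES = ("none", "spikein", "control")
MANIFEST_NAME = "manifest.json"


@dataclasses.dataclass
class RawArraySet:
    """A set of raw two-channel arrays sharing one probe universe.

    ``table`` is wide: one row per probe, identity columns plus
    ``cy5_raw_<sample>``/``cy3_raw_<sample>`` for each entry of ``samples``.
    """

    samples: list[str]
    table: pd.DataFrame
    provenance: dict = dataclasses.field(default_factory=dict)

    def intensity_columns(self) -> list[str]:
        return [f"{ch}_raw_{s}" for s in self.samples for ch in CHANNELS]

    def validate(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise DataError("sample labels must be unique")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"missing required column(s): {', '.join(missing)}")
        for col in self.intensity_columns():
            if col not in self.table.columns:
                raise DataError(f"missing required column: {col}")
        dup = self.table["probe_id"].duplicated()
        if dup.any():
            raise DataError(
                f"duplicate probe_id: {self.table.loc[dup, 'probe_id'].iloc[0]!r}"
            )
        bad = ~self.table["control_type"].isin(CONTROL_TYPES)
        if bad.any():
            raise DataError(
                f"invalid control_type {self.table.loc[bad, 'control_type'].iloc[0]!r}"
                f" (expected one of {CONTROL_TYPES})"
            )


def read_raw_table(path: str | Path) -> RawArraySet:
    """Read a raw intensity TSV into a validated :class:`RawArraySet`.

    Raises :class:`DataError` naming the offending column/row on malformed
    input (missing column, non-numeric or negative intensity, duplicate
    probe_id, unknown control_type).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise DataError(f"cannot read raw table {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s): {', '.join(missing)}")

    cy5_samples = [c[len("cy5_raw_"):] for c in df.columns if c.startswith("cy5_raw_")]
    cy3_samples = [c[len("cy3_raw_"):] for c in df.columns if c.startswith("cy3_raw_")]
    if not cy5_samples:
        raise DataError(f"{path}: no cy5_raw_<sample> intensity columns found")
    for s in cy5_samples:
        if s not in cy3_samples:
            raise DataError(f"{path}: missing required column: cy3_raw_{s}")
    for s in cy3_samples:
        if s not in cy5_samples:
            raise DataError(f"{path}: missing required column: cy5_raw_{s}")

    for col in [f"{ch}_raw_{s}" for s in cy5_samples for ch in CHANNELS]:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            row = int(values.index[values.isna()][0])
            raise DataError(
                f"{path}: non-numeric intensity in column {col!r} at data row {row + 1}"
            )
        if (values < 0).any():
            row = int(values.index[values < 0][0])
            raise DataError(
                f"{path}: negative intensity in column {col!r} at data row {row + 1}"
            )
        df[col] = values.astype(float)

    arrayset = RawArraySet(samples=cy5_samples, table=df, provenance={"source": str(path)})
    arrayset.validate()
    n_ctrl = int((df["control_type"] != "none").sum())
    logger.info("read %d probes (%d control/spike-in) from %s", len(df), n_ctrl, path)
    return arrayset


def write_raw_table(arrayset: RawArraySet, path: str | Path) -> Path:
    """Write a :class:`RawArraySet` in the raw TSV dialect."""
    arrayset.validate()
    path = Path(path)
    cols = list(REQUIRED_COLUMNS) + arrayset.intensity_columns()
    try:
        arrayset.table[cols].to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise DataError(f"cannot write raw table {path}: {exc}") from exc
    return path


def sha256_of(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    directory: str | Path,
    *,
    overwrite: bool = False,
    config: Mapping | None = None,
) -> dict:
    """Write every table as ``<name>.tsv`` plus a checksummed JSON manifest.

    An existing manifest in ``directory`` is a collision unless
    ``overwrite=True``.  The effective configuration, when given, is persisted
    as ``config_snapshot.yaml`` next to the outputs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / MANIFEST_NAME
    if manifest_path.exists() and not overwrite:
        raise DataError(
            f"manifest already exists at {manifest_path}; pass overwrite=True to replace"
        )
    entries: dict[str, dict] = {}
    try:
        if config is not None:
            snap = directory / "config_snapshot.yaml"
            with open(snap, "w", encoding="utf-8") as fh:
                yaml.safe_dump(dict(config), fh, sort_keys=True)
            entries["config_snapshot"] = {
                "path": snap.name,
                "sha256": sha256_of(snap),
            }
        for name, table in tables.items():
            out = directory / f"{name}.tsv"
            table.to_csv(out, sep="\t", index=False)
            entries[name] = {"path": out.name, "sha256": sha256_of(out)}
        manifest = {"files": entries}
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise DataError(f"I/O failure while writing results to {directory}: {exc}") from exc
    logger.info("wrote %d result file(s) to %s", len(entries), directory)
    return manifest


def read_flat_config(path: str | Path, allowed_keys: set[str]) -> dict:
    """Load a flat key-value YAML config, rejecting unknown keys."""
    path = Path(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a key-value mapping")
    unknown = sorted(set(data) - allowed_keys)
    if unknown:
        raise ConfigurationError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    return data
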