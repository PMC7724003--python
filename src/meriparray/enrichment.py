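"""Classic over-representation analysis with the one-sided Fisher exact test.

For a query list of n genes drawn from a universe of N genes, and a gene set
covering K universe genes of which k are in the query, the enrichment p-value
is the hypergeometric upper tail P(X >= k) — identical to a one-sided
Fisher's exact test on the 2x2 overlap table.  Raw p-values are primary;
Benjamini-Hochberg adjusted values are reported alongside.

Gene sets are read from GMT files (``name<TAB>description<TAB>member...``).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Collection, Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets plus an optional background universe."""

    sets: dict[str, GeneSet]
    universe: frozenset[str] | None = None

    def with_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection(sets=self.sets, universe=frozenset(universe))


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; duplicate members within a set are counted once."""
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    try:
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise DataError(
                        f"{path}: malformed GMT line {lineno}: expected at least "
                        "3 tab-separated fields (name, description, members)"
                    )
                name, description = fields[0], fields[1]
                members = frozenset(m for m in fields[2:] if m)
                if not members:
                    raise DataError(f"{path}: GMT line {lineno}: set {name!r} has no members")
                sets[name] = GeneSet(name=name, description=description, members=members)
    except OSError as exc:
        raise DataError(f"cannot read GMT file {path}: {exc}") from exc
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> Path:
    """Write a collection back to GMT (members sorted for determinism)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(collection.sets):
            gs = collection.sets[name]
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")
    return path


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ConfigurationError("p_values: all values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrich(
    query: Collection[str],
    collection: GeneSetCollection,
    universe: Collection[str] | None = None,
) -> pd.DataFrame:
    """Test every gene set for over-representation in the query list.

    Set members and the query are intersected with the universe first; query
    genes outside the universe are dropped and logged, sets with no universe
    members are skipped and logged.  Results are sorted by p-value then
    term_id.
    """
    if universe is None:
        universe = collection.universe
    if not universe:
        raise ConfigurationError("universe: a non-empty background universe is required")
    universe = frozenset(universe)
    query = set(query)
    outside = query - universe
    if outside:
        logger.info("dropped %d query gene(s) outside the universe", len(outside))
    query &= universe
    if not query:
        raise DataError("query is empty after intersecting with the universe")

    N, n = len(universe), len(query)
    rows = []
    for name in sorted(collection.sets):
        gs = collection.sets[name]
        members = gs.members & universe
        if not members:
            logger.info("skipped gene set %r: no members in the universe", name)
            continue
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": gs.name,
                "term_name": gs.description,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "enrichment_ratio": (k / n) / (K / N),
                "p_value": min(p, 1.0),
            }
        )
    if not rows:
        raise DataError("no gene set has members in the universe")
    results = pd.DataFrame(rows).sort_values(
        ["p_value", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    results["adjusted_p"] = adjust_bh(results["p_value"].to_numpy())
    return results
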