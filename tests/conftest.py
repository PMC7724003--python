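import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from meriparray.arrayio import RawArraySet
from meriparray.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_raw(samples, probes):
    """Build a RawArraySet from a list of probe dicts.

    Each probe dict: probe_id, gene_symbol, entrez_id, control_type, and a
    (cy5, cy3) tuple per sample keyed by sample name.
    """
    rows = []
    for p in probes:
        row = {
            "probe_id": p["probe_id"],
            "gene_symbol": p.get("gene_symbol", p["probe_id"]),
            "entrez_id": p.get("entrez_id", ""),
            "control_type": p.get("control_type", "none"),
        }
        for s in samples:
            cy5, cy3 = p[s]
            row[f"cy5_raw_{s}"] = float(cy5)
            row[f"cy3_raw_{s}"] = float(cy3)
        rows.append(row)
    return RawArraySet(samples=list(samples), table=pd.DataFrame(rows))


@pytest.fixture
def tiny_raw():
    """Two samples, two spike-ins, three genes with known intensities."""
    return make_raw(
        ["A", "B"],
        [
            {"probe_id": "SPK0", "control_type": "spikein", "A": (4, 4), "B": (8, 8)},
            {"probe_id": "SPK1", "control_type": "spikein", "A": (16, 16), "B": (32, 32)},
            {"probe_id": "P1", "entrez_id": "101", "A": (32, 32), "B": (64, 64)},
            {"probe_id": "P2", "entrez_id": "102", "A": (60, 20), "B": (240, 80)},
            {"probe_id": "P3", "entrez_id": "103", "A": (10, 30), "B": (10, 30)},
        ],
    )


@pytest.fixture(scope="session")
def noiseless_sim():
    """Seeded 800-gene noise-free simulation with channel bias, plus quantified genes.

    Plants 10% of genes per effect class in both contrasts so every joint
    set (reversals, stable-expression cells) is populated.
    """
    from meriparray.quantify import quantify_arrayset

    fractions = {
        name: {"expression_up": 0.1, "expression_down": 0.1, "hyper": 0.1, "hypo": 0.1}
        for name in ("CUMS_Sham_vs_WT", "CUMS_DBS_vs_CUMS_Sham")
    }
    cfg = SimulationConfig(n_genes=800, noise_sd=0.0, effect_fractions=fractions, seed=7)
    raw, truth = simulate_dataset(cfg)
    genes, _ = quantify_arrayset(raw, pseudocount=0.0)
    return cfg, raw, truth, genes


def records_from_classes(pairs):
    """DifferentialRecord table realizing given (meth_class, expr_class, count) cells."""
    rows = []
    i = 0
    for meth, expr, count in pairs:
        for _ in range(count):
            fc_e = {"up": 2.0, "down": 0.5, "unchanged": 1.0}[expr]
            fc_m = {"hyper": 2.0, "hypo": 0.5, "unchanged": 1.0}[meth]
            rows.append(
                {
                    "gene_id": f"g{i:06d}",
                    "fc_expression": fc_e,
                    "class_expression": expr,
                    "fc_methylation": fc_m,
                    "class_methylation": meth,
                }
            )
            i += 1
    return pd.DataFrame(rows)
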