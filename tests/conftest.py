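import numpy as np
import pandas as pd
import pytest

from melmeth import (
    BetaMatrix,
    ProbeAnnotation,
    SimulationConfig,
    simulate_beta,
    simulate_manifest,
)

# study conditions of the recovery experiments: 15 samples per stage,
# 5000 probes with 5% planted stage effects of 0.4 on the beta scale
RECOVERY_CONFIG = SimulationConfig(
    seed=20260101,
    n_nevus=15,
    n_primary=15,
    n_meta=15,
    n_probes=5000,
    frac_dev_hyper=0.015,
    frac_dev_hypo=0.015,
    frac_prog_hyper=0.01,
    frac_prog_hypo=0.01,
    effect_delta=0.4,
    beta_precision=50.0,
    frac_missing=0.01,
    n_prognostic=0,
)


@pytest.fixture(scope="session")
def recovery_sim():
    """Seeded simulation used by the parameter-recovery tests."""
    bm, truth = simulate_beta(RECOVERY_CONFIG)
    return RECOVERY_CONFIG, bm, truth


@pytest.fixture(scope="session")
def recovery_groups():
    cfg = RECOVERY_CONFIG
    nevus = [f"nevus_{i:03d}" for i in range(cfg.n_nevus)]
    primary = [f"primary_{i:03d}" for i in range(cfg.n_primary)]
    meta = [f"meta_{i:03d}" for i in range(cfg.n_meta)]
    return nevus, primary, meta


@pytest.fixture(scope="session")
def toy_manifest():
    """Regular layout: islands of 1 kb every 10 kb, genes every 10 kb."""
    return simulate_manifest(800, island_spacing=10_000, tss_spacing=10_000, seed=3)


def make_annotation(rows, tss=None):
    """Build a ProbeAnnotation from (probe_id, pos, island, genes, feats) tuples."""
    recs = {}
    for pid, pos, island, genes, feats in rows:
        start, end = (np.nan, np.nan) if island is None else island
        recs[pid] = {
            "chrom": "chr1",
            "pos": pos,
            "strand": "+",
            "gene_symbols": genes,
            "gene_features": feats,
            "island_start": start,
            "island_end": end,
            "snp_overlap": 0,
            "is_genotyping": 0,
        }
    probes = pd.DataFrame.from_dict(recs, orient="index")
    probes.index.name = "probe_id"
    tss_df = pd.DataFrame(tss or [], columns=["gene", "tss_pos"])
    return ProbeAnnotation(probes, tss_df)


def make_beta(values, probes=None, samples=None):
    arr = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=probes, columns=samples))
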