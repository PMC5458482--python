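"""Methylation–expression concordance and gene-set overlap.

Differential-expression tables (one per public dataset re-analysis) are
joined to differentially methylated genes at the symbol level.  A gene is
"concordant negative" when its methylation direction opposes a significant
expression change in at least one table: hypermethylated & downregulated,
or hypomethylated & upregulated.  No per-sample correlation is computed —
methylation and expression come from different cohorts, so direction-level
concordance is the operative definition.

The gene-set step is a hypergeometric over-representation test over GMT
gene sets (the ranked-list GSEA statistic is out of scope here).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .screen import bh_adjust, share_pct

logger = logging.getLogger(__name__)

EXPRESSION_CALLS = ("down", "up", "ns")


def call_expression(de: pd.DataFrame, fc_min: float = 1.0, q_max: float = 0.05) -> pd.Series:
    """Per-gene expression call from a logFC/q table.

    "down" if logFC ≤ −fc_min and q < q_max (at least a twofold drop at
    fc_min = 1 in log2 units), "up" symmetrically, otherwise "ns".
    """
    lfc = pd.to_numeric(de["logFC"], errors="raise").to_numpy(dtype=float)
    if not np.all(np.isfinite(lfc)):
        bad = de["gene"].iloc[int(np.argmax(~np.isfinite(lfc)))]
        raise ValueError(f"non-finite logFC for gene {bad!r}")
    q = pd.to_numeric(de["q"], errors="raise").to_numpy(dtype=float)
    call = np.where(
        (lfc <= -fc_min) & (q < q_max),
        "down",
        np.where((lfc >= fc_min) & (q < q_max), "up", "ns"),
    )
    genes = de["gene"].astype(str).str.upper()
    return pd.Series(call, index=genes, name="call")


def integrate(
    dm_genes: pd.Series | dict,
    de_tables: dict[str, pd.DataFrame],
    fc_min: float = 1.0,
    q_max: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Join DM gene directions with expression calls across tables.

    ``dm_genes`` maps gene symbol -> 'hyper' | 'hypo'.  Symbols are
    matched exactly after uppercasing.  Returns per-gene records (one
    call column per table, plus the concordant_negative flag) and a
    summary with counts and one-decimal percentage shares.
    """
    dm = pd.Series(dm_genes, dtype=object)
    dm.index = dm.index.astype(str).str.upper()
    calls = {src: call_expression(de, fc_min=fc_min, q_max=q_max) for src, de in de_tables.items()}

    records = pd.DataFrame({"direction": dm})
    for src in sorted(calls):
        records[f"call_{src}"] = [calls[src].get(g, "absent") for g in records.index]
    call_cols = [c for c in records.columns if c.startswith("call_")]
    records["testable"] = (records[call_cols] != "absent").any(axis=1) if call_cols else False

    def _concordant(row) -> bool:
        want = "down" if row["direction"] == "hyper" else "up"
        return any(row[c] == want for c in call_cols)

    if len(records) and call_cols:
        records["concordant_negative"] = records.apply(_concordant, axis=1)
    else:
        records["concordant_negative"] = False

    n_testable = int(records["testable"].sum())
    conc = records[records["concordant_negative"]]
    n_conc = len(conc)
    n_hyper_down = int((conc["direction"] == "hyper").sum())
    n_hypo_up = int((conc["direction"] == "hypo").sum())
    summary = {
        "n_dm_genes": len(records),
        "n_testable": n_testable,
        "n_concordant": n_conc,
        "concordant_pct": share_pct(n_conc, n_testable),
        "n_hyper_down": n_hyper_down,
        "n_hypo_up": n_hypo_up,
        "hyper_down_pct": share_pct(n_hyper_down, n_conc),
        "hypo_up_pct": share_pct(n_hypo_up, n_conc),
    }
    return records, summary


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g.upper() for g in parts[2:] if g}
    return sets


def geneset_overlap(
    query_genes,
    gene_sets: dict[str, set[str]],
    universe_n: int | None = None,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in gene sets.

    For each set of size K in a universe of size M with a query of size
    n and overlap k, the upper-tail p-value P(X ≥ k) is reported with a
    BH q across sets; rows come back sorted by q.  When an explicit
    ``universe`` set is given, sets and query are intersected with it
    (departures logged).
    """
    query = {str(g).upper() for g in query_genes}
    if universe is not None:
        universe = {str(g).upper() for g in universe}
        dropped = query - universe
        if dropped:
            logger.info("query genes outside universe dropped: %d", len(dropped))
        query &= universe
        m = len(universe)
    elif universe_n is not None:
        m = int(universe_n)
    else:
        raise ValueError("provide universe or universe_n")

    rows = []
    for name, members in gene_sets.items():
        members = {str(g).upper() for g in members}
        if universe is not None:
            outside = members - universe
            if outside:
                logger.info("set %s: %d genes outside universe intersected away", name, len(outside))
            members &= universe
        k_set = len(members)
        if m < len(query) or m < k_set:
            raise ValueError("universe smaller than query or set")
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, m, k_set, len(query)))
        rows.append((name, k_set, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out.sort_values(["q", "p", "set"]).reset_index(drop=True)
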