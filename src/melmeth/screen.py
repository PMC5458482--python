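"""Group-median differential methylation (DGMB) screening.

The stage ordering is nevus < primary < metastasis throughout; in every
two-group comparison ``group_b`` is the more advanced stage, the effect
statistic is DGMB = median(b) − median(a), and "hyper" means a gain of
methylation toward the later stage.

The selection procedure filters on effect size first: probes with
|DGMB| below the cutoff are dropped before any testing, and the
Benjamini–Hochberg family consists only of the DGMB-passing probes.
The alternative ordering (test everything, adjust, then gate) is
available via ``gate_order="test_first"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .io import (
    BetaMatrix,
    PROMOTER_FEATURES,
    ProbeAnnotation,
    island_context_series,
)

logger = logging.getLogger(__name__)

ISLAND_CONTEXTS = ("island", "shore", "shelf", "open_sea")


# ---------------------------------------------------------------------------
# primitive statistics


def mann_whitney(values_a, values_b, mode: str = "auto", min_group_n: int = 3) -> float:
    """Two-sided Mann–Whitney p-value.

    Exact enumeration when the pooled size is ≤ 12 and there are no ties;
    otherwise the normal approximation with tie and continuity
    corrections.  ``mode`` can force "exact" or "asymptotic".
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < min_group_n or len(b) < min_group_n:
        raise ValueError(f"need at least {min_group_n} non-missing values per group")
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    if mode == "auto":
        pooled = np.concatenate([a, b])
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_island_test(table) -> float:
    """Two-tailed Fisher exact p for a 2×2 direction × island table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# ANOVA pre-screen and clustering


def anova_screen(
    bm: BetaMatrix,
    groups: dict[str, list[str]],
    delta: float = 0.33,
    conf: float = 0.99,
    return_table: bool = False,
):
    """Probes differing across stage groups by one-way ANOVA.

    A probe is selected when the ANOVA p-value is below 1 − conf AND at
    least one pair of groups differs in group median by ≥ delta.  Probes
    with fewer than two groups having ≥ 2 non-missing values are skipped.
    With ``return_table=True`` the per-probe F, p and maximal group-median
    spread come back as a DataFrame alongside the selected index.
    """
    for name, members in groups.items():
        if len(members) == 0:
            raise ValueError(f"group {name!r} has no samples")
    mats = {name: bm.values[list(members)].to_numpy(dtype=float) for name, members in groups.items()}
    alpha = 1.0 - conf
    selected = []
    rows = []
    for i, pid in enumerate(bm.probe_ids):
        vals = [m[i][~np.isnan(m[i])] for m in mats.values()]
        vals = [v for v in vals if len(v) >= 2]
        if len(vals) < 2:
            continue
        medians = [np.median(v) for v in vals]
        spread = max(medians) - min(medians)
        if np.all([np.all(v == vals[0][0]) for v in vals]):
            f, p = np.nan, np.nan
        else:
            res = stats.f_oneway(*vals)
            f, p = float(res.statistic), float(res.pvalue)
        keep = spread >= delta and np.isfinite(p) and p < alpha
        if keep:
            selected.append(pid)
        if return_table:
            rows.append((pid, f, p, spread, keep))
    index = pd.Index(selected, name="probe_id")
    if return_table:
        table = pd.DataFrame(
            rows, columns=["probe_id", "F", "p", "median_spread", "selected"]
        ).set_index("probe_id")
        return index, table
    return index


def ward_cluster(bm: BetaMatrix, probe_subset=None, k: int = 2):
    """Ward hierarchical clustering of samples on Euclidean distance.

    Missing values are mean-imputed per probe before distances are
    computed.  Returns the scipy linkage matrix and k-cluster labels
    (pandas Series indexed by sample).
    """
    values = bm.values if probe_subset is None else bm.values.loc[probe_subset]
    if values.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    x = values.to_numpy(dtype=float)
    row_means = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=1)
    row_means = np.where(np.isnan(row_means), 0.5, row_means)
    inds = np.where(np.isnan(x))
    x[inds] = row_means[inds[0]]
    z = linkage(x.T, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return z, pd.Series(labels, index=values.columns, name="cluster")


# ---------------------------------------------------------------------------
# DGMB comparison


@dataclass
class GroupComparison:
    """Per-probe result of one two-group DGMB comparison.

    ``table`` columns: median_a, median_b, dgmb, tested, p_raw, p_adj,
    direction, significant.  Probes with too few non-missing values on
    either side are absent from the table (logged as untestable).
    """

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    table: pd.DataFrame
    dgmb_min: float
    alpha: float

    @property
    def significant_probes(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    def significant_by_direction(self, direction: str) -> pd.Index:
        t = self.table
        return t.index[t["significant"] & (t["direction"] == direction)]


def dgmb_compare(
    bm: BetaMatrix,
    group_a,
    group_b,
    name: str = "comparison",
    dgmb_min: float = 0.25,
    alpha: float = 0.05,
    min_group_n: int = 3,
    gate_order: str = "gate_first",
    mw_mode: str = "auto",
) -> GroupComparison:
    """Two-group screen: DGMB effect gate, Mann–Whitney, BH adjustment.

    With the default ``gate_order="gate_first"`` only probes with
    |DGMB| ≥ dgmb_min are tested and form the BH family; with
    ``"test_first"`` all testable probes are tested and adjusted, and the
    effect gate is applied afterwards.
    """
    group_a, group_b = tuple(group_a), tuple(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if gate_order not in ("gate_first", "test_first"):
        raise ValueError(f"unknown gate_order {gate_order!r}")
    xa = bm.values[list(group_a)].to_numpy(dtype=float)
    xb = bm.values[list(group_b)].to_numpy(dtype=float)

    na = (~np.isnan(xa)).sum(axis=1)
    nb = (~np.isnan(xb)).sum(axis=1)
    testable = (na >= min_group_n) & (nb >= min_group_n)
    n_untestable = int((~testable).sum())
    if n_untestable:
        logger.info("%s: %d probes untestable (<%d non-missing per side)", name, n_untestable, min_group_n)

    med_a = np.nanmedian(xa[testable], axis=1)
    med_b = np.nanmedian(xb[testable], axis=1)
    dgmb = med_b - med_a

    tab = pd.DataFrame(
        {
            "median_a": med_a,
            "median_b": med_b,
            "dgmb": dgmb,
            "tested": False,
            "p_raw": np.nan,
            "p_adj": np.nan,
        },
        index=bm.probe_ids[testable],
    )

    if gate_order == "gate_first":
        to_test = tab.index[np.abs(tab["dgmb"]) >= dgmb_min]
    else:
        to_test = tab.index

    pvals = []
    for pid in to_test:
        i = bm.probe_ids.get_loc(pid)
        pvals.append(mann_whitney(xa[i], xb[i], mode=mw_mode, min_group_n=min_group_n))
    tab.loc[to_test, "p_raw"] = pvals
    tab.loc[to_test, "tested"] = True
    if len(to_test):
        tab.loc[to_test, "p_adj"] = bh_adjust(np.asarray(pvals))

    tab["direction"] = np.where(tab["dgmb"] >= 0, "hyper", "hypo")
    tab["significant"] = (
        tab["tested"]
        & (np.abs(tab["dgmb"]) >= dgmb_min)
        & (tab["p_adj"] < alpha)
    )
    return GroupComparison(name, group_a, group_b, tab, dgmb_min, alpha)


# ---------------------------------------------------------------------------
# crossing hit lists into stage partitions


@dataclass
class StagePartition:
    """Development (nevus→tumor) vs progression (primary→metastasis) changes.

    Development probes must be significant with consistent direction in
    BOTH nevi-vs-primary and nevi-vs-metastasis; probes significant in
    only one nevi comparison are kept separately in ``dev_single`` and
    direction conflicts in ``dev_conflict``.
    """

    dev_hyper_probes: pd.Index
    dev_hypo_probes: pd.Index
    prog_hyper_probes: pd.Index
    prog_hypo_probes: pd.Index
    dev_single: pd.Index
    dev_conflict: pd.Index
    gene_sets: dict[str, set] = field(default_factory=dict)
    common_genes: set = field(default_factory=set)

    @property
    def dev_genes(self) -> set:
        return self.gene_sets.get("dev_hyper", set()) | self.gene_sets.get("dev_hypo", set())

    @property
    def prog_genes(self) -> set:
        return self.gene_sets.get("prog_hyper", set()) | self.gene_sets.get("prog_hypo", set())


def _genes_of(probes, exploded: pd.DataFrame) -> set:
    sub = exploded[exploded["probe_id"].isin(probes)]
    return {g.upper() for g in sub["gene"]}


def cross_hit_lists(
    cmp_nevus_primary: GroupComparison,
    cmp_nevus_meta: GroupComparison,
    cmp_primary_meta: GroupComparison,
    ann: ProbeAnnotation | None = None,
) -> StagePartition:
    """Cross the two nevi comparisons into consistent development changes
    and take primary-vs-metastasis hits as progression changes."""
    universe = cmp_nevus_primary.table.index
    dev_hyper = cmp_nevus_primary.significant_by_direction("hyper").intersection(
        cmp_nevus_meta.significant_by_direction("hyper")
    )
    dev_hypo = cmp_nevus_primary.significant_by_direction("hypo").intersection(
        cmp_nevus_meta.significant_by_direction("hypo")
    )
    sig_np = cmp_nevus_primary.significant_probes
    sig_nm = cmp_nevus_meta.significant_probes
    both = sig_np.intersection(sig_nm)
    conflict = both.difference(dev_hyper.union(dev_hypo))
    single = sig_np.symmetric_difference(sig_nm)
    if len(conflict):
        logger.info("development crossing: %d probes excluded for direction conflict", len(conflict))

    prog_hyper = cmp_primary_meta.significant_by_direction("hyper")
    prog_hypo = cmp_primary_meta.significant_by_direction("hypo")

    gene_sets: dict[str, set] = {}
    common: set = set()
    if ann is not None:
        ex = ann.exploded()
        gene_sets = {
            "dev_hyper": _genes_of(dev_hyper, ex),
            "dev_hypo": _genes_of(dev_hypo, ex),
            "prog_hyper": _genes_of(prog_hyper, ex),
            "prog_hypo": _genes_of(prog_hypo, ex),
        }
        common = (gene_sets["dev_hyper"] | gene_sets["dev_hypo"]) & (
            gene_sets["prog_hyper"] | gene_sets["prog_hypo"]
        )
    return StagePartition(
        dev_hyper_probes=dev_hyper,
        dev_hypo_probes=dev_hypo,
        prog_hyper_probes=prog_hyper,
        prog_hypo_probes=prog_hypo,
        dev_single=pd.Index(single, name="probe_id"),
        dev_conflict=pd.Index(conflict, name="probe_id"),
        gene_sets=gene_sets,
        common_genes=common,
    )


# ---------------------------------------------------------------------------
# compartment profiling


@dataclass
class CompartmentProfile:
    """Counts/fractions of significant probes per genomic compartment,
    with a Fisher test for island association between directions."""

    context_counts: pd.DataFrame  # direction × island context
    feature_counts: pd.DataFrame  # direction × gene feature
    context_fractions: pd.DataFrame
    fisher_table: np.ndarray  # {hyper,hypo} × {island, non-island}
    fisher_p: float

    def to_dict(self) -> dict:
        return {
            "context_counts": self.context_counts.to_dict(),
            "feature_counts": self.feature_counts.to_dict(),
            "context_fractions": self.context_fractions.to_dict(),
            "fisher_table": self.fisher_table.tolist(),
            "fisher_p": self.fisher_p,
        }


def compartment_profile(hyper_probes, hypo_probes, ann: ProbeAnnotation) -> CompartmentProfile:
    """Profile hyper/hypo probe sets over island contexts and gene features."""
    ctx = island_context_series(ann)
    ex = ann.exploded().set_index("probe_id")
    directions = {"hyper": pd.Index(hyper_probes), "hypo": pd.Index(hypo_probes)}
    for d, probes in directions.items():
        missing = probes.difference(ann.probe_ids)
        if len(missing):
            raise ValueError(f"{d} probes missing from annotation: {list(missing[:5])}")

    ctx_counts = pd.DataFrame(0, index=list(directions), columns=list(ISLAND_CONTEXTS))
    feat_counts = pd.DataFrame(
        0, index=list(directions), columns=["TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR"]
    )
    for d, probes in directions.items():
        vc = ctx.loc[probes].value_counts()
        for c in ISLAND_CONTEXTS:
            ctx_counts.loc[d, c] = int(vc.get(c, 0))
        if len(probes):
            sub = ex[ex.index.isin(probes)]
            fvc = sub["feature"].value_counts()
            for f in feat_counts.columns:
                feat_counts.loc[d, f] = int(fvc.get(f, 0))

    totals = ctx_counts.sum(axis=1)
    fractions = ctx_counts.div(totals.replace(0, np.nan), axis=0)

    table = np.array(
        [
            [ctx_counts.loc["hyper", "island"], int(totals["hyper"] - ctx_counts.loc["hyper", "island"])],
            [ctx_counts.loc["hypo", "island"], int(totals["hypo"] - ctx_counts.loc["hypo", "island"])],
        ]
    )
    p = fisher_island_test(table)
    return CompartmentProfile(ctx_counts, feat_counts, fractions, table, p)


# ---------------------------------------------------------------------------
# reporting


def share_pct(part: float, whole: float) -> float | None:
    """Percentage share rounded to one decimal; None for an empty whole."""
    if whole == 0:
        return None
    return round(100.0 * part / whole, 1)


def report_partition_fractions(partition: StagePartition, ann: ProbeAnnotation | None = None) -> dict:
    """Summary of gene counts per stage with one-decimal percentage shares.

    For each direction: the development and progression unique-gene
    counts, their shares of the pooled (dev + prog) list, and — when
    annotation is available — the share of development genes with at
    least one significant promoter-feature probe.
    """
    out: dict = {}
    for direction in ("hyper", "hypo"):
        dev_genes = partition.gene_sets.get(f"dev_{direction}", set())
        prog_genes = partition.gene_sets.get(f"prog_{direction}", set())
        pooled = len(dev_genes) + len(prog_genes)
        block = {
            "dev_genes": len(dev_genes),
            "prog_genes": len(prog_genes),
            "dev_share_pct": share_pct(len(dev_genes), pooled),
            "prog_share_pct": share_pct(len(prog_genes), pooled),
        }
        if ann is not None:
            ex = ann.exploded()
            dev_probes = partition.dev_hyper_probes if direction == "hyper" else partition.dev_hypo_probes
            prom = ex[ex["probe_id"].isin(dev_probes) & ex["feature"].isin(PROMOTER_FEATURES)]
            prom_genes = {g.upper() for g in prom["gene"]} & dev_genes
            block["dev_promoter_genes"] = len(prom_genes)
            block["dev_promoter_share_pct"] = share_pct(len(prom_genes), len(dev_genes))
        out[direction] = block
    out["common_genes"] = len(partition.common_genes)
    return out
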