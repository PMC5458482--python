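"""End-to-end orchestration of the methylome-progression analysis.

``run_pipeline`` executes: (optional) simulation → probe QC → ANOVA
screen + Ward clustering → per-comparison DGMB screens → hit-list
crossing → compartment profiling → expression integration → survivor
signature + marker survival evaluation, writing per-stage TSVs and one
JSON summary.  Re-running with the same config and seed reproduces the
summary byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    BetaMatrix,
    ProbeAnnotation,
    qc_filter_probes,
    read_beta_matrix,
    read_manifest,
    read_sample_sheet,
    write_beta_matrix,
    write_manifest,
    write_sample_sheet,
)
from .integration import integrate
from .screen import (
    anova_screen,
    compartment_profile,
    cross_hit_lists,
    dgmb_compare,
    report_partition_fractions,
    ward_cluster,
)
from .simulate import (
    GroundTruth,
    SimulationConfig,
    gene_truth,
    simulate_beta,
    simulate_expression,
    simulate_manifest,
    simulate_survival_from_risk,
)
from .survival import cox_fit, dichotomize, logrank_test, survivor_signature

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run.

    Threshold defaults are the study's published operating points:
    DGMB ≥ 0.25 at BH-adjusted p < 0.05, ANOVA screen at Δ ≥ 0.33 with
    confidence 0.99, survivor signature at mean difference ≥ 0.2 with
    q < 0.01, expression calls at |log2FC| ≥ 1 with q < 0.05, and a
    48-month survivor landmark.
    """

    outdir: str = "melmeth_out"
    seed: int = 0
    # inputs; when beta_path is None a simulated cohort is generated
    beta_path: str | None = None
    detection_path: str | None = None
    manifest_path: str | None = None
    tss_path: str | None = None
    sample_sheet_path: str | None = None
    de_table_paths: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    # thresholds
    dgmb_min: float = 0.25
    alpha: float = 0.05
    anova_delta: float = 0.33
    anova_conf: float = 0.99
    diff_min: float = 0.2
    q_max: float = 0.01
    fc_min: float = 1.0
    expr_q_max: float = 0.05
    cutoff_months: float = 48.0
    min_group_n: int = 3
    gate_order: str = "gate_first"
    dichotomize_rule: str = "median"
    concordant_frac: float = 0.5

    def validate(self) -> None:
        if not (0 < self.dgmb_min < 1 and 0 < self.alpha < 1 and 0 < self.anova_delta < 1):
            raise ValueError("thresholds out of range")
        if not (0 < self.anova_conf < 1 and 0 < self.q_max < 1 and 0 < self.expr_q_max < 1):
            raise ValueError("thresholds out of range")
        if self.gate_order not in ("gate_first", "test_first"):
            raise ValueError("gate_order must be gate_first or test_first")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _json_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return [_json_ready(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the summary dict (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in dataclasses.asdict(config).items() if not k.endswith("_path")},
    }

    truth: GroundTruth | None = None
    if config.beta_path is None:
        sim = SimulationConfig(seed=config.seed, **config.simulate)
        bm, truth = simulate_beta(sim)
        ann = simulate_manifest(sim.n_probes, seed=config.seed,
                                frac_snp=sim.frac_snp, frac_genotyping=sim.frac_genotyping)
        de_tables, planted_dir = simulate_expression(
            truth, ann, concordant_frac=config.concordant_frac, seed=config.seed
        )
        groups = pd.Series(
            ["nevus"] * sim.n_nevus + ["primary"] * sim.n_primary + ["metastasis"] * sim.n_meta,
            index=bm.sample_ids,
        )
        surv = simulate_survival_from_risk(truth, cutoff_months=config.cutoff_months, seed=config.seed)
        sheet = pd.DataFrame({"sample_id": bm.sample_ids, "group": groups.to_numpy()})
        sheet = sheet.merge(
            surv.rename(columns={"time": "survival_months"}), on="sample_id", how="left"
        )
        sheet["event"] = sheet["event"].map(lambda v: bool(v) if pd.notna(v) else False)
        sheet["survival_months"] = sheet["survival_months"].fillna(0.0)
        write_beta_matrix(bm, outdir / "beta.tsv")
        write_manifest(ann, outdir / "manifest.tsv", outdir / "tss.tsv")
        write_sample_sheet(sheet, outdir / "sample_sheet.csv")
        truth.probe_class.rename("class").to_csv(outdir / "ground_truth.tsv", sep="\t")
        summary["simulated"] = True
    else:
        bm = read_beta_matrix(config.beta_path, config.detection_path)
        ann = read_manifest(config.manifest_path, config.tss_path)
        sheet = read_sample_sheet(config.sample_sheet_path)
        de_tables = {
            src: pd.read_csv(p, sep="\t") for src, p in (config.de_table_paths or {}).items()
        }
        groups = sheet.set_index("sample_id")["group"]
        summary["simulated"] = False

    # --- QC
    n0 = len(bm.probe_ids)
    bm = qc_filter_probes(bm, ann)
    summary["qc"] = {"probes_in": n0, "probes_out": len(bm.probe_ids), "removed": n0 - len(bm.probe_ids)}

    by_group = {g: groups.index[groups == g].tolist() for g in ("nevus", "primary", "metastasis")}

    # --- ANOVA screen + Ward clustering
    anova_probes = anova_screen(bm, by_group, delta=config.anova_delta, conf=config.anova_conf)
    summary["anova"] = {"selected_probes": len(anova_probes)}
    if len(anova_probes) >= 1:
        _, labels = ward_cluster(bm, anova_probes, k=3)
        labels.to_csv(outdir / "ward_clusters.tsv", sep="\t")
        summary["ward"] = {"k": 3, "cluster_sizes": labels.value_counts().sort_index().tolist()}

    # --- DGMB comparisons
    comparisons = {
        "nevus_vs_primary": (by_group["nevus"], by_group["primary"]),
        "nevus_vs_metastasis": (by_group["nevus"], by_group["metastasis"]),
        "primary_vs_metastasis": (by_group["primary"], by_group["metastasis"]),
    }
    cmp_results = {}
    for cname, (ga, gb) in comparisons.items():
        res = dgmb_compare(
            bm, ga, gb, name=cname, dgmb_min=config.dgmb_min, alpha=config.alpha,
            min_group_n=config.min_group_n, gate_order=config.gate_order,
        )
        res.table.to_csv(outdir / f"dgmb_{cname}.tsv", sep="\t", index_label="probe_id")
        cmp_results[cname] = res
        summary.setdefault("dgmb", {})[cname] = {
            "tested": int(res.table["tested"].sum()),
            "significant": int(res.table["significant"].sum()),
            "hyper": len(res.significant_by_direction("hyper")),
            "hypo": len(res.significant_by_direction("hypo")),
        }

    # --- crossing + compartments
    partition = cross_hit_lists(
        cmp_results["nevus_vs_primary"],
        cmp_results["nevus_vs_metastasis"],
        cmp_results["primary_vs_metastasis"],
        ann,
    )
    part_rows = []
    for stage, direction, probes in (
        ("development", "hyper", partition.dev_hyper_probes),
        ("development", "hypo", partition.dev_hypo_probes),
        ("progression", "hyper", partition.prog_hyper_probes),
        ("progression", "hypo", partition.prog_hypo_probes),
    ):
        for pid in probes:
            part_rows.append((pid, stage, direction))
    pd.DataFrame(part_rows, columns=["probe_id", "stage", "direction"]).to_csv(
        outdir / "partition.tsv", sep="\t", index=False
    )
    summary["partition"] = {
        "dev_hyper_probes": len(partition.dev_hyper_probes),
        "dev_hypo_probes": len(partition.dev_hypo_probes),
        "prog_hyper_probes": len(partition.prog_hyper_probes),
        "prog_hypo_probes": len(partition.prog_hypo_probes),
        "report": report_partition_fractions(partition, ann),
    }

    dev_hyper_all = partition.dev_hyper_probes.union(partition.prog_hyper_probes)
    dev_hypo_all = partition.dev_hypo_probes.union(partition.prog_hypo_probes)
    profile = compartment_profile(dev_hyper_all, dev_hypo_all, ann)
    (outdir / "compartments.json").write_text(json.dumps(_json_ready(profile.to_dict()), indent=2))
    summary["compartments"] = {"fisher_p": profile.fisher_p}

    # --- expression integration
    dm_dir = {}
    for g in partition.gene_sets.get("dev_hyper", set()) | partition.gene_sets.get("prog_hyper", set()):
        dm_dir[g] = "hyper"
    for g in partition.gene_sets.get("dev_hypo", set()) | partition.gene_sets.get("prog_hypo", set()):
        dm_dir.setdefault(g, "hypo")
    records, int_summary = integrate(dm_dir, de_tables, fc_min=config.fc_min, q_max=config.expr_q_max)
    records.to_csv(outdir / "integration.tsv", sep="\t", index_label="gene")
    summary["integration"] = int_summary
    if truth is not None:
        planted = set(simulate_expression(truth, ann, config.concordant_frac, config.seed)[1].index)
        recovered = set(records.index[records["concordant_negative"]])
        summary["integration"]["planted_concordant"] = len(planted)
        summary["integration"]["recovered_of_planted"] = len(planted & recovered)

    # --- prognosis
    prognosis: dict = {}
    surv_sheet = sheet.dropna(subset=["survival_months"]) if "survival_months" in sheet else sheet
    try:
        sig = survivor_signature(
            bm, surv_sheet, cutoff_months=config.cutoff_months,
            diff_min=config.diff_min, q_max=config.q_max, min_group_n=config.min_group_n,
        )
        sig.table.to_csv(outdir / "survivor_signature.tsv", sep="\t", index_label="probe_id")
        prognosis["signature_probes"] = int(sig.table["selected"].sum())

        # dichotomize the top signature probe as a marker and evaluate it
        if sig.table["selected"].any():
            top = sig.table[sig.table["selected"]].sort_values("p_adj").index[0]
            prim = surv_sheet[surv_sheet["group"] == "primary"].set_index("sample_id")
            vals = bm.values.loc[top, prim.index]
            marker = dichotomize(vals.fillna(vals.median()), rule=config.dichotomize_rule)
            rec = prim.assign(marker=(marker == "high").astype(int))
            rec = rec.rename(columns={"survival_months": "time"})
            hi, lo = marker == "high", marker == "low"
            chi2, p = logrank_test(
                rec["time"][hi], rec["event"][hi], rec["time"][lo], rec["event"][lo]
            )
            prognosis["top_probe"] = {"probe": top, "logrank_chi2": chi2, "logrank_p": p}
            covs = ["marker"] + [c for c in ("breslow_mm", "ulceration") if c in rec.columns]
            cox = cox_fit(rec.reset_index(), covariates=covs)
            prognosis["top_probe"]["cox"] = {
                c: {k: (None if pd.isna(v) else float(v)) for k, v in row.items() if k != "flag"} | {"flag": row["flag"]}
                for c, row in cox.table.iterrows()
            }
    except ValueError as exc:
        prognosis["skipped"] = str(exc)
        logger.warning("prognosis stage skipped: %s", exc)
    summary["prognosis"] = prognosis

    (outdir / "summary.json").write_text(json.dumps(_json_ready(summary), indent=2, sort_keys=True))
    return summary
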