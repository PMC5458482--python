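"""Seeded synthetic inputs with planted ground truth.

Emulates the statistical structure of a three-stage melanoma methylome
study: a 450K-style beta matrix over nevus / primary / metastasis groups
with planted stage-specific probes, a toy single-chromosome manifest with
CpG islands and TSSs, differential-expression tables with sign-concordant
effects for a known gene subset, and survival times whose hazard depends
on a planted prognostic marker.

Model choices
-------------
* Beta values are drawn from a Beta distribution parameterised by
  (mean, precision) — the standard bounded noise model for methylation
  fractions.  Per-probe baseline means come from a bimodal mixture
  (low ~0.15 / high ~0.85) mimicking the marginal distribution of real
  450K arrays; hyper-plants start in the low mode and hypo-plants in the
  high mode so the shifted mean stays inside (0, 1).
* Planted classes: ``dev_hyper``/``dev_hypo`` shift BOTH primary and
  metastasis group means by ±effect_delta relative to nevi (development
  changes); ``prog_hyper``/``prog_hypo`` shift metastases only
  (progression changes); ``prognostic`` probes are shifted by
  prognostic_delta in the short-survival half of the primary samples.
* Missingness is completely at random at rate frac_missing.
* Survival is exponential with a multiplicative hazard for high-marker
  samples and independent uniform censoring tuned to the target
  censoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import BetaMatrix, ProbeAnnotation

PROBE_CLASSES = ("null", "dev_hyper", "dev_hypo", "prog_hyper", "prog_hypo", "prognostic")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the discovery-cohort design: 14 nevi, 33 primary
    melanomas, 28 metastases; stage effects of 0.4 on the beta scale
    (comfortably above the DGMB 0.25 cutoff), survivor effects of 0.3
    (above the 0.2 mean-difference cutoff), and a total of 5% of probes
    planted with stage effects.
    """

    seed: int = 0
    n_nevus: int = 14
    n_primary: int = 33
    n_meta: int = 28
    n_probes: int = 5000
    frac_dev_hyper: float = 0.015
    frac_dev_hypo: float = 0.015
    frac_prog_hyper: float = 0.01
    frac_prog_hypo: float = 0.01
    effect_delta: float = 0.4
    beta_precision: float = 50.0
    frac_missing: float = 0.01
    n_prognostic: int = 50
    prognostic_delta: float = 0.3
    hazard_ratio: float = 3.0
    censor_frac: float = 0.3
    frac_snp: float = 0.03
    frac_genotyping: float = 0.01

    def validate(self) -> None:
        fracs = (
            self.frac_dev_hyper,
            self.frac_dev_hypo,
            self.frac_prog_hyper,
            self.frac_prog_hypo,
            self.frac_missing,
            self.frac_snp,
            self.frac_genotyping,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("all fractions must be in [0, 1]")
        planted = (
            self.frac_dev_hyper
            + self.frac_dev_hypo
            + self.frac_prog_hyper
            + self.frac_prog_hypo
        )
        if planted > 1:
            raise ValueError("planted-class fractions sum above 1")
        if planted * self.n_probes + self.n_prognostic > self.n_probes:
            raise ValueError("planted probes exceed n_probes")
        if not 0 < self.effect_delta < 1:
            raise ValueError("effect_delta must be in (0, 1)")
        if not 0 < self.prognostic_delta < 1:
            raise ValueError("prognostic_delta must be in (0, 1)")
        if min(self.n_nevus, self.n_primary, self.n_meta) < 1:
            raise ValueError("group sizes must be >= 1")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.beta_precision <= 0:
            raise ValueError("beta_precision must be positive")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0 <= self.censor_frac < 1:
            raise ValueError("censor_frac must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted truth: per-probe class, and the survival risk label of
    each primary sample (high = planted short-survival methylation)."""

    probe_class: pd.Series
    sample_risk: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def probes_of(self, cls: str) -> pd.Index:
        return self.probe_class.index[self.probe_class == cls]


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, precision: float) -> np.ndarray:
    a = mean * precision
    b = (1.0 - mean) * precision
    return rng.beta(a, b)


def simulate_beta(config: SimulationConfig) -> tuple[BetaMatrix, GroundTruth]:
    """Generate the beta matrix and its planted ground truth.

    Identical config (including seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    n = config.n_probes
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id")
    sample_ids = (
        [f"nevus_{i:03d}" for i in range(config.n_nevus)]
        + [f"primary_{i:03d}" for i in range(config.n_primary)]
        + [f"meta_{i:03d}" for i in range(config.n_meta)]
    )
    groups = np.array(
        ["nevus"] * config.n_nevus + ["primary"] * config.n_primary + ["metastasis"] * config.n_meta
    )

    # assign planted classes to a disjoint random subset of probes
    counts = {
        "dev_hyper": int(round(config.frac_dev_hyper * n)),
        "dev_hypo": int(round(config.frac_dev_hypo * n)),
        "prog_hyper": int(round(config.frac_prog_hyper * n)),
        "prog_hypo": int(round(config.frac_prog_hypo * n)),
        "prognostic": config.n_prognostic,
    }
    classes = np.full(n, "null", dtype=object)
    order = rng.permutation(n)
    cursor = 0
    for cls, k in counts.items():
        classes[order[cursor : cursor + k]] = cls
        cursor += k

    # bimodal baselines; plants start in the mode that leaves room for the shift
    mode_low = rng.random(n) < 0.5
    baseline = np.where(mode_low, rng.beta(3, 17, size=n), rng.beta(17, 3, size=n))
    hyperish = np.isin(classes, ["dev_hyper", "prog_hyper", "prognostic"])
    hypoish = np.isin(classes, ["dev_hypo", "prog_hypo"])
    baseline[hyperish] = rng.beta(3, 17, size=int(hyperish.sum()))
    baseline[hypoish] = rng.beta(17, 3, size=int(hypoish.sum()))
    baseline = np.clip(baseline, 0.02, 0.98)

    # keep planted baselines in the range that leaves room for their shift
    for cls_mask, shift in (
        (np.isin(classes, ["dev_hyper", "prog_hyper"]), config.effect_delta),
        (classes == "prognostic", config.prognostic_delta),
    ):
        hi = 1.0 - shift - 0.02
        if hi < 0.02:
            raise ValueError("shifted group mean leaves (0, 1); lower effect size")
        baseline[cls_mask] = np.clip(baseline[cls_mask], 0.02, hi)
    lo = config.effect_delta + 0.02
    if lo > 0.98:
        raise ValueError("shifted group mean leaves (0, 1); lower effect_delta")
    baseline[hypoish] = np.clip(baseline[hypoish], lo, 0.98)

    # per-(probe, group) target means
    delta = config.effect_delta
    mean_nevus = baseline.copy()
    mean_primary = baseline.copy()
    mean_meta = baseline.copy()
    mean_primary[classes == "dev_hyper"] += delta
    mean_meta[classes == "dev_hyper"] += delta
    mean_primary[classes == "dev_hypo"] -= delta
    mean_meta[classes == "dev_hypo"] -= delta
    mean_meta[classes == "prog_hyper"] += delta
    mean_meta[classes == "prog_hypo"] -= delta
    for arr in (mean_nevus, mean_primary, mean_meta):
        if np.any((arr <= 0) | (arr >= 1)):
            raise ValueError("shifted group mean leaves (0, 1); lower effect_delta")

    means = np.empty((n, len(sample_ids)))
    means[:, groups == "nevus"] = mean_nevus[:, None]
    means[:, groups == "primary"] = mean_primary[:, None]
    means[:, groups == "metastasis"] = mean_meta[:, None]

    # prognostic probes: shifted in the short-survival half of primaries
    primary_idx = np.where(groups == "primary")[0]
    risk_high = np.zeros(len(sample_ids), dtype=bool)
    high_primaries = rng.permutation(primary_idx)[: len(primary_idx) // 2]
    risk_high[high_primaries] = True
    prog_rows = classes == "prognostic"
    shifted = means[np.ix_(prog_rows, risk_high)] + config.prognostic_delta
    if np.any(shifted >= 1):
        raise ValueError("prognostic shift leaves (0, 1); lower prognostic_delta")
    means[np.ix_(prog_rows, risk_high)] = shifted

    values = _beta_draw(rng, means, config.beta_precision)
    miss = rng.random(values.shape) < config.frac_missing
    values = values.astype(float)
    values[miss] = np.nan

    bm = BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))
    truth = GroundTruth(
        probe_class=pd.Series(classes, index=probe_ids, name="probe_class"),
        sample_risk=pd.Series(
            np.where(risk_high[np.isin(np.arange(len(sample_ids)), primary_idx)], "high", "low"),
            index=[sample_ids[i] for i in primary_idx],
            name="risk",
        ),
    )
    return bm, truth


def simulate_manifest(
    n_probes: int,
    island_spacing: int = 10_000,
    tss_spacing: int = 10_000,
    seed: int = 0,
    island_width: int = 1000,
    gene_span: int = 5000,
    frac_snp: float = 0.03,
    frac_genotyping: float = 0.01,
) -> ProbeAnnotation:
    """Toy single-chromosome layout with regularly spaced islands and TSSs.

    Probes sit on a uniform grid along the chromosome, so compartment
    fractions are computable in closed form.  One gene starts at each TSS
    (at the island start when spacings coincide); probes within the gene
    span get an Illumina-style feature by distance from the TSS.  SNP and
    genotyping flags are seeded Bernoulli draws.
    """
    if island_spacing <= 0 or tss_spacing <= 0:
        raise ValueError("spacings must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])

    chrom_len = n_probes * 100  # one probe per 100 bp grid cell
    pos = (np.arange(n_probes) * 100 + 50).astype(int) + 1
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(n_probes)], name="probe_id")

    # islands at regular spacing (possibly none)
    islands: list[tuple[int, int]] = []
    if island_spacing <= chrom_len:
        s = island_spacing
        while s + island_width - 1 <= chrom_len:
            islands.append((s, s + island_width - 1))
            s += island_spacing

    # nearest island per probe
    island_start = np.full(n_probes, np.nan)
    island_end = np.full(n_probes, np.nan)
    if islands:
        starts = np.array([i[0] for i in islands])
        ends = np.array([i[1] for i in islands])
        mids = (starts + ends) / 2
        nearest = np.abs(pos[:, None] - mids[None, :]).argmin(axis=1)
        island_start = starts[nearest].astype(float)
        island_end = ends[nearest].astype(float)

    # genes: one TSS per tss_spacing, gene body extends gene_span downstream
    tss_pos = np.arange(tss_spacing, chrom_len + 1, tss_spacing, dtype=int)
    genes = [f"GENE{i + 1:05d}" for i in range(len(tss_pos))]
    tss_df = pd.DataFrame({"gene": genes, "tss_pos": tss_pos})

    gene_symbols = [""] * n_probes
    gene_features = [""] * n_probes
    if len(tss_pos) > 0:
        nearest_g = np.abs(pos[:, None] - tss_pos[None, :]).argmin(axis=1)
        for i in range(n_probes):
            g = nearest_g[i]
            d = pos[i] - tss_pos[g]  # signed; negative = upstream
            if -1500 <= d < -200:
                feat = "TSS1500"
            elif -200 <= d < 0:
                feat = "TSS200"
            elif 0 <= d < 200:
                feat = "5UTR"
            elif 200 <= d < 500:
                feat = "1stExon"
            elif 500 <= d < gene_span - 500:
                feat = "Body"
            elif gene_span - 500 <= d < gene_span:
                feat = "3UTR"
            else:
                continue
            gene_symbols[i] = genes[g]
            gene_features[i] = feat

    probes = pd.DataFrame(
        {
            "chrom": "chrT",
            "pos": pos,
            "strand": "+",
            "gene_symbols": gene_symbols,
            "gene_features": gene_features,
            "island_start": island_start,
            "island_end": island_end,
            "snp_overlap": (rng.random(n_probes) < frac_snp).astype(int),
            "is_genotyping": (rng.random(n_probes) < frac_genotyping).astype(int),
        },
        index=probe_ids,
    )
    return ProbeAnnotation(probes, tss_df)


def gene_truth(truth: GroundTruth, ann: ProbeAnnotation) -> pd.Series:
    """Per-gene planted methylation direction derived from probe classes.

    A gene is 'hyper' ('hypo') if its planted probes are majority-hyper
    (-hypo); genes whose planted probes tie are ambiguous and excluded.
    Prognostic-class probes carry no stage direction and are ignored.
    """
    directed = truth.probe_class[truth.probe_class.isin(["dev_hyper", "dev_hypo", "prog_hyper", "prog_hypo"])]
    if directed.empty:
        return pd.Series(dtype=object)
    ex = ann.exploded().set_index("probe_id")
    votes: dict[str, int] = {}
    for pid, cls in directed.items():
        if pid not in ex.index:
            continue
        sign = 1 if cls.endswith("hyper") else -1
        rows = ex.loc[[pid]]
        for gene in rows["gene"]:
            votes[gene.upper()] = votes.get(gene.upper(), 0) + sign
    out = {g: ("hyper" if v > 0 else "hypo") for g, v in votes.items() if v != 0}
    return pd.Series(out, dtype=object, name="direction")


def simulate_expression(
    truth: GroundTruth,
    ann: ProbeAnnotation,
    concordant_frac: float = 0.5,
    seed: int = 0,
    sources: tuple[str, ...] = ("DE_A", "DE_B", "DE_C"),
) -> tuple[dict[str, pd.DataFrame], pd.Series]:
    """Differential-expression tables with planted concordant genes.

    A seeded ``concordant_frac`` of planted DM genes get, in one randomly
    chosen table, a logFC of sign opposite to their methylation direction
    with |logFC| ≥ 1 and q < 0.05 (the twofold / q<0.05 calling rule);
    every other (gene, table) row is null: |logFC| < 1 and q ≥ 0.05.
    Returns the tables and the planted concordant-gene direction series.
    """
    if not 0 <= concordant_frac <= 1:
        raise ValueError("concordant_frac must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    gdir = gene_truth(truth, ann)
    all_genes = sorted({g.upper() for g in ann.tss["gene"]} | set(gdir.index))

    planted = np.array(sorted(gdir.index))
    k = int(round(concordant_frac * len(planted)))
    concordant = set(rng.permutation(planted)[:k]) if len(planted) else set()
    carrier = {g: sources[rng.integers(len(sources))] for g in sorted(concordant)}

    tables: dict[str, pd.DataFrame] = {}
    for src in sources:
        rows = []
        for g in all_genes:
            if g in concordant and carrier[g] == src:
                mag = 1.0 + rng.exponential(0.5)
                lfc = -mag if gdir[g] == "hyper" else mag
                q = rng.uniform(1e-6, 0.049)
            else:
                lfc = rng.uniform(-0.9, 0.9)
                q = rng.uniform(0.05, 1.0)
            rows.append((g, lfc, q))
        tables[src] = pd.DataFrame(rows, columns=["gene", "logFC", "q"]).assign(source=src)
    planted_dir = gdir[gdir.index.isin(concordant)]
    return tables, planted_dir


def simulate_survival_from_risk(
    truth: GroundTruth,
    cutoff_months: float = 48.0,
    seed: int = 0,
    misalign_frac: float = 0.05,
) -> pd.DataFrame:
    """Survival records aligned with the planted methylation risk groups.

    High-risk primaries (the samples carrying the prognostic-probe shift)
    die of disease before the landmark; low-risk primaries survive past
    it.  This is the strong-separation regime in which the survivor
    signature is identifiable: an exponential hazard ratio of realistic
    size leaves the landmark groups too mixed for a planted mean shift to
    survive group averaging (see simulate_survival for that regime).
    A fixed ``misalign_frac`` of each risk group lands on the wrong side
    of the landmark, so a marker tracking the risk groups predicts
    survival strongly without perfectly separating it.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])
    risk = truth.sample_risk
    n = len(risk)
    high = (risk == "high").to_numpy()
    dies_early = high.copy()
    for grp in (np.where(high)[0], np.where(~high)[0]):
        k = int(round(misalign_frac * len(grp)))
        flip = rng.permutation(grp)[:k]
        dies_early[flip] = ~dies_early[flip]
    times = np.where(
        dies_early,
        rng.uniform(0.15 * cutoff_months, 0.9 * cutoff_months, size=n),
        cutoff_months + rng.uniform(0.15 * cutoff_months, 1.5 * cutoff_months, size=n),
    )
    event = np.where(dies_early, True, rng.random(n) < 0.5)
    return pd.DataFrame(
        {
            "sample_id": risk.index,
            "time": np.round(times, 1),
            "event": event.astype(bool),
            "breslow_mm": np.round(rng.lognormal(0.7, 0.6, size=n), 2),
            "ulceration": (rng.random(n) < 0.4).astype(int),
            "marker_level": np.where(high, "high", "low"),
        }
    )


def simulate_survival(
    sample_ids,
    marker_levels,
    hazard_ratio: float = 3.0,
    censor_frac: float = 0.3,
    seed: int = 0,
    baseline_hazard: float = 1.0 / 48.0,
) -> pd.DataFrame:
    """Exponential survival with a multiplicative hazard for high-marker
    samples and independent uniform censoring tuned to ``censor_frac``.

    ``marker_levels`` is a binary (or 'high'/'low') vector per sample.
    The default baseline hazard puts median survival near the 48-month
    landmark used for survivor-signature work.  Returns records with
    time (months), event flag, and clinical covariates (Breslow mm,
    ulceration) drawn independently of the marker.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0 <= censor_frac < 1:
        raise ValueError("censor_frac must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    sample_ids = list(sample_ids)
    high = np.asarray(
        [lv in (1, True, "high") for lv in marker_levels], dtype=bool
    )
    if len(high) != len(sample_ids):
        raise ValueError("marker_levels length mismatch")

    haz = baseline_hazard * np.where(high, hazard_ratio, 1.0)
    times = rng.exponential(1.0 / haz)

    event = np.ones(len(times), dtype=bool)
    ctimes = times.copy()
    if censor_frac > 0:
        p_high = high.mean()

        def censored_prob(c: float) -> float:
            # P(T > C), C ~ U(0, c), T ~ Exp(h), mixed over marker groups
            out = 0.0
            for h, w in ((baseline_hazard, 1 - p_high), (baseline_hazard * hazard_ratio, p_high)):
                if w > 0:
                    out += w * (1 - np.exp(-h * c)) / (h * c)
            return out

        c_max = brentq(lambda c: censored_prob(c) - censor_frac, 1e-6, 1e7)
        cens = rng.uniform(0, c_max, size=len(times))
        event = times <= cens
        ctimes = np.minimum(times, cens)

    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time": ctimes,
            "event": event,
            "breslow_mm": np.round(rng.lognormal(0.7, 0.6, size=len(times)), 2),
            "ulceration": (rng.random(len(times)) < 0.4).astype(int),
            "marker_level": np.where(high, "high", "low"),
        }
    )
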